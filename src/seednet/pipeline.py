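"""End-to-end orchestration: filter -> stage medians -> PCA + association
test -> coexpression network + topology -> subnetworks -> fuzzy clustering ->
promoter motif calling -> scanner consensus -> overrepresentation.

Configuration is a flat key=value text file (``#`` comments allowed); every
numeric default is the standard analysis setting: log2 presence cutoff 6.0
with >= 3 present calls, correlation threshold 0.90 (positive edges only),
c = 6 clusters with fuzzifier m = 1.75 and core membership 0.90, 80%
similarity scanning, 4th-order Markov backgrounds x10 per promoter, and an
FDR bound of 0.15 on background-calibrated motif calls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

from . import clustering, expression, motifs, network, synthetic

log = logging.getLogger("seednet")


@dataclasses.dataclass
class PipelineConfig:
    expression_tsv: str = ""
    design_tsv: str = ""
    promoter_fasta: str = ""
    pwm_file: str = ""
    output_dir: str = "seednet_out"
    seed_genes: str = ""  # optional file with one gene id per line

    presence_cutoff: float = 6.0
    min_present: int = 3
    corr_threshold: float = 0.90
    n_clusters: int = 6
    fuzzifier: float = 1.75
    core_threshold: float = 0.90
    scan_threshold: float = 0.80
    markov_order: int = 4
    n_background: int = 10
    fdr_max: float = 0.15
    n_perm: int = 999
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 < self.corr_threshold < 1, "corr_threshold must be in (0, 1)"),
            (0 < self.scan_threshold <= 1, "scan_threshold must be in (0, 1]"),
            (0.5 < self.core_threshold <= 1, "core_threshold must be in (0.5, 1]"),
            (0 < self.fdr_max < 1, "fdr_max must be in (0, 1)"),
            (self.fuzzifier > 1, "fuzzifier must be > 1"),
            (self.n_clusters >= 2, "n_clusters must be >= 2"),
            (self.min_present >= 1, "min_present must be >= 1"),
            (self.markov_order >= 0, "markov_order must be >= 0"),
            (self.n_background >= 1, "n_background must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                ftype = fields[key].type
                if ftype in ("int", int):
                    kwargs[key] = int(value)
                elif ftype in ("float", float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclasses.dataclass
class RunReport:
    """Per-stage counts and summary results of a pipeline run."""

    config: dict
    stages: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages}, fh, indent=2)


def _timed(stages: dict, name: str, started: float, **info) -> None:
    stages[name] = {"elapsed_s": round(time.perf_counter() - started, 3), **info}
    log.info("stage %s done: %s", name, info)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on the configured inputs, writing all artifacts to
    ``output_dir`` and returning a consistency-checked report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    # --- expression filtering ------------------------------------------------
    t0 = time.perf_counter()
    m = expression.read_expression(config.expression_tsv, config.design_tsv)
    expressed = expression.filter_expressed(
        m, cutoff=config.presence_cutoff, min_present=config.min_present
    )
    (out / "expressed_genes.txt").write_text("\n".join(expressed) + "\n")
    _timed(stages, "filter", t0, total_genes=len(m.gene_ids), expressed=len(expressed))

    # --- stage medians, PCA, association test --------------------------------
    t0 = time.perf_counter()
    sm = expression.stage_medians(m, genes=expressed)
    sm_out = sm.copy()
    sm_out.index.name = "gene"
    sm_out.to_csv(out / "stage_medians.tsv", sep="\t", float_format="%.6f")
    pca = expression.pca_samples(m)
    expression.write_pca(pca, out / "pca_scores.tsv")
    gtest = expression.global_association_test(
        m, expressed, n_perm=config.n_perm, seed=config.seed
    )
    (out / "global_test.json").write_text(
        json.dumps(dataclasses.asdict(gtest), indent=2)
    )
    _timed(
        stages,
        "expression_summary",
        t0,
        n_stages=sm.shape[1],
        pc1_variance=float(pca.variance_fractions[0]),
        association_p=gtest.p_value,
    )

    # --- coexpression network ------------------------------------------------
    t0 = time.perf_counter()
    net = network.build_network_from_medians(sm, threshold=config.corr_threshold)
    network.export_network(net, out / "network_edges.tsv", format="edge_tsv")
    network.export_network(net, out / "network.sif", format="sif")
    if net.number_of_edges() > 0:
        topo = network.topology_stats(net)
        topo.to_tsv(out / "topology.tsv")
        topo_info = {
            "nodes": topo.n_nodes,
            "edges": topo.n_edges,
            "clustering_coefficient": topo.clustering_coefficient,
        }
    else:
        topo_info = {"nodes": 0, "edges": 0}
    if topo_info["nodes"] > len(expressed):
        raise RuntimeError("report inconsistency: network nodes exceed expressed genes")
    _timed(stages, "network", t0, **topo_info)

    # --- optional subnetworks ------------------------------------------------
    if config.seed_genes:
        t0 = time.perf_counter()
        seeds = [
            s.strip() for s in Path(config.seed_genes).read_text().splitlines() if s.strip()
        ]
        sub = network.extract_subnetwork(net, seeds, mode="neighborhood")
        network.export_network(sub, out / "subnetwork_edges.tsv", format="edge_tsv")
        _timed(stages, "subnetwork", t0, seeds=len(seeds), nodes=sub.number_of_nodes())

    # --- fuzzy clustering ----------------------------------------------------
    t0 = time.perf_counter()
    standardized = clustering.standardize_profiles(sm)
    fcm = clustering.fuzzy_cmeans(
        standardized,
        c=config.n_clusters,
        m=config.fuzzifier,
        seed=config.seed,
    )
    cores = clustering.cluster_cores(fcm, core_threshold=config.core_threshold)
    clustering.write_memberships(fcm, cores, out / "memberships.tsv")
    clustering.write_centers(fcm, out / "cluster_centers.tsv")
    _timed(
        stages,
        "clustering",
        t0,
        clustered=len(standardized),
        cluster_sizes=fcm.hard_labels().value_counts().to_dict(),
        core_sizes={k: len(v) for k, v in cores.cores.items()},
        iterations=fcm.n_iter,
    )

    # --- promoter motifs -----------------------------------------------------
    if config.promoter_fasta and config.pwm_file:
        t0 = time.perf_counter()
        promoters = motifs.read_fasta(config.promoter_fasta)
        pwms = motifs.read_pwms(config.pwm_file)
        hits_rel = motifs.scan_relative_many(
            promoters, pwms, threshold=config.scan_threshold
        )
        model = motifs.train_markov(promoters, order=config.markov_order)
        hits_fdr = motifs.call_fdr_many(
            promoters,
            pwms,
            model,
            n_bg=config.n_background,
            fdr_max=config.fdr_max,
            seed=config.seed,
        )
        consensus = motifs.consensus_hits(hits_rel, hits_fdr)
        motifs.write_hits(consensus, pwms, out / "consensus_hits.tsv")
        table = motifs.enrichment(consensus, pwms, set(promoters))
        table.counts.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        enriched = list(table.counts.loc[table.counts.overrepresented, "pwm_id"])
        _timed(
            stages,
            "motifs",
            t0,
            promoters=len(promoters),
            pwms=len(pwms),
            gc=round(motifs.gc_content(promoters), 4),
            similarity_hits=len(hits_rel),
            fdr_hits=len(hits_fdr),
            consensus_hits=len(consensus),
            enriched_pwms=enriched,
        )

    report = RunReport(config=dataclasses.asdict(config), stages=stages)
    report.to_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# Default synthetic fixture
# ---------------------------------------------------------------------------

#: Default fixture conditions: 2,000 genes over 8 stages x 3 replicates with
#: six separable archetypes, 300 AT-rich promoters (G+C 0.33) of 1,200 bp and
#: 20 PWMs, with MA1 planted in 60% of the promoters.
FIXTURE_N_GENES = 2000
FIXTURE_N_PROMOTERS = 300
FIXTURE_N_PWMS = 20
FIXTURE_PLANT_FRACTION = 0.6
FIXTURE_NOISE_SD = 0.25


def fixture_archetypes() -> list[tuple[str, "np.ndarray"]]:
    """Six separable archetypes (no flat profile, which standardizes to noise)."""
    arcs = dict(synthetic.default_archetypes())
    names = [
        "fa_like",
        "oleosin_like",
        "lea_like",
        "fa_like_mirror",
        "oleosin_like_mirror",
        "lea_like_mirror",
    ]
    return [(n, arcs[n]) for n in names]


def make_fixture(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the default synthetic dataset (expression, design, promoters,
    PWMs, truth) and return the paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    arcs = fixture_archetypes()
    expr_cfg = synthetic.SyntheticExpressionConfig(
        n_genes=FIXTURE_N_GENES,
        cluster_archetypes=arcs,
        noise_sd=FIXTURE_NOISE_SD,
        seed=seed,
    )
    m, truth_expr = synthetic.generate_expression(expr_cfg)
    pwms = synthetic.random_pwms(FIXTURE_N_PWMS, seed=seed + 1)
    # the planted matrix is high-information by construction (the benchmark
    # measures recovery of a strong, well-conserved site)
    pwms[0] = synthetic.random_pwms(
        1, seed=seed + 101, width_range=(11, 12), dominant_prob=(0.93, 0.97)
    )[0]
    prom_cfg = synthetic.SyntheticPromoterConfig(
        n_sequences=FIXTURE_N_PROMOTERS,
        planted=[("MA1", FIXTURE_PLANT_FRACTION, "both")],
        seed=seed + 2,
    )
    promoters, truth_prom = synthetic.generate_promoters(prom_cfg, pwms)

    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "promoters": out / "promoters.fasta",
        "pwms": out / "pwms.txt",
        "truth": out / "truth.tsv",
    }
    expression.write_expression(m, paths["expression"], paths["design"])
    motifs.write_fasta(promoters, paths["promoters"])
    motifs.write_pwms(pwms, paths["pwms"])
    truth = synthetic.SyntheticTruth(
        gene_clusters=truth_expr.gene_clusters, placements=truth_prom.placements
    )
    synthetic.write_truth(truth, paths["truth"])
    return paths
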