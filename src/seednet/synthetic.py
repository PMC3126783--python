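"""Synthetic seed-development datasets with known ground truth.

The generator emulates the statistical shape of an eight-stage seed-maturation
microarray series (three replicates per stage, log2 intensities) and of
AT-rich plant promoter sets (G+C around 33%) carrying planted transcription
factor binding sites, so that every downstream stage — filtering, network
inference, fuzzy clustering, motif calling — can be tested against a recorded
truth without any external download.

Temporal archetypes follow the canonical seed-maturation patterns: fatty-acid
biosynthesis genes rise steadily to a peak at the expanded-cotyledon stage and
decline through late maturation; oleosin / seed-storage-protein genes jump
more than 1000-fold (>10 log2 units) between the globular and bilateral
stages and stay high; late-embryogenesis-abundant (LEA) genes rise late; and
mirror-image and flat profiles round out the set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .motifs import PWM, BASES, MarkovModel, revcomp, sample_markov


@dataclasses.dataclass
class SyntheticExpressionConfig:
    n_genes: int
    n_stages: int = 8
    n_replicates: int = 3
    cluster_archetypes: list[tuple[str, np.ndarray]] | None = None
    cluster_proportions: list[float] | None = None
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.cluster_archetypes is None:
            self.cluster_archetypes = default_archetypes(self.n_stages)
        k = len(self.cluster_archetypes)
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / k] * k
        if len(self.cluster_proportions) != k:
            raise ValueError("one proportion per archetype required")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        for label, template in self.cluster_archetypes:
            if len(template) != self.n_stages:
                raise ValueError(
                    f"archetype {label!r}: template length {len(template)} != "
                    f"n_stages {self.n_stages}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclasses.dataclass
class SyntheticPromoterConfig:
    n_sequences: int
    length: int = 1200
    background_gc: float = 0.33
    background_order: int = 4
    planted: list[tuple[str, float, str]] = dataclasses.field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        for pwm_id, fraction, policy in self.planted:
            if not 0 <= fraction <= 1:
                raise ValueError(f"planting fraction for {pwm_id} outside [0, 1]")
            if policy not in ("both", "plus", "minus"):
                raise ValueError(f"unknown strand policy {policy!r}")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth: gene -> archetype label and sequence -> planted motifs
    as (pwm_id, 1-based start, strand) triples."""

    gene_clusters: dict[str, str] = dataclasses.field(default_factory=dict)
    placements: dict[str, list[tuple[str, int, int]]] = dataclasses.field(
        default_factory=dict
    )


def default_archetypes(n_stages: int = 8) -> list[tuple[str, np.ndarray]]:
    """Stage-profile templates (log2 scale) for the canonical seed patterns.

    Only defined for the eight-stage series the templates describe.
    """
    if n_stages != 8:
        raise ValueError("default archetypes are 8-stage templates")
    fa = np.array([0.0, 1.0, 2.5, 4.0, 6.0, 5.5, 3.5, 2.0])
    oleosin = np.array([0.0, 10.0, 10.6, 11.0, 11.2, 11.3, 11.3, 11.3])
    lea = np.array([0.0, 0.0, 0.2, 0.5, 1.5, 3.0, 5.0, 7.0])
    flat = np.zeros(8)
    return [
        ("fa_like", fa),
        ("oleosin_like", oleosin),
        ("lea_like", lea),
        ("flat", flat),
        ("fa_like_mirror", -fa),
        ("oleosin_like_mirror", -oleosin),
        ("lea_like_mirror", -lea),
    ]


def generate_expression(
    config: SyntheticExpressionConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression = baseline(gene) + template(cluster, stage) + N(0, noise_sd).

    Baselines are uniform over ``baseline_range`` so the expressed-gene filter
    is exercised; columns carry stage and replicate metadata; output is
    deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.cluster_archetypes)
    assignments = rng.choice(k, size=config.n_genes, p=config.cluster_proportions)
    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    templates = np.stack([t for _, t in config.cluster_archetypes])
    labels = [lab for lab, _ in config.cluster_archetypes]

    stage_names = [f"S{i+1}" for i in range(config.n_stages)]
    sample_ids, stage_col, rep_col = [], [], []
    for s in stage_names:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{s}_r{r}")
            stage_col.append(s)
            rep_col.append(str(r))

    profile = baselines[:, None] + templates[assignments]  # genes x stages
    expanded = np.repeat(profile, config.n_replicates, axis=1)
    noise = rng.normal(0.0, config.noise_sd, size=expanded.shape)
    gene_ids = [f"gene_{i+1:05d}" for i in range(config.n_genes)]
    values = pd.DataFrame(expanded + noise, index=gene_ids, columns=sample_ids)
    design = pd.DataFrame(
        {"stage": stage_col, "replicate": rep_col}, index=pd.Index(sample_ids, name="sample")
    )
    truth = SyntheticTruth(
        gene_clusters={g: labels[a] for g, a in zip(gene_ids, assignments)}
    )
    return ExpressionMatrix(values=values, design=design), truth


def generate_promoters(
    config: SyntheticPromoterConfig, pwms: list[PWM]
) -> tuple[dict[str, str], SyntheticTruth]:
    """AT-rich Markov background promoters with motifs planted from PWMs.

    Each planted site is an independent sample from the PWM's per-position
    base distributions, written over the background at a uniformly chosen
    position (reverse-complemented for antisense placements); the returned
    truth records every placement.
    """
    by_id = {p.id: p for p in pwms}
    for pwm_id, _, _ in config.planted:
        if pwm_id not in by_id:
            raise ValueError(f"unknown pwm_id {pwm_id!r}")
        if by_id[pwm_id].width > config.length:
            raise ValueError(f"sequence length < width of {pwm_id}")

    rng = np.random.default_rng(config.seed)
    model = MarkovModel.from_base_composition(
        config.background_gc, config.background_order
    )
    seqs = sample_markov(
        model, config.length, n=config.n_sequences, seed=int(rng.integers(2**31))
    )
    ids = [f"synthseq_{i+1:04d}" for i in range(config.n_sequences)]
    sequences = dict(zip(ids, seqs))
    truth = SyntheticTruth(placements={})

    for pwm_id, fraction, policy in config.planted:
        pwm = by_id[pwm_id]
        w = pwm.width
        n_carry = int(round(fraction * config.n_sequences))
        carriers = rng.choice(config.n_sequences, size=n_carry, replace=False)
        for idx in sorted(carriers):
            sid = ids[idx]
            site = "".join(
                BASES[rng.choice(4, p=pwm.matrix[j])] for j in range(w)
            )
            if policy == "both":
                strand = 1 if rng.random() < 0.5 else -1
            else:
                strand = 1 if policy == "plus" else -1
            start = int(rng.integers(0, config.length - w + 1))  # 0-based
            inserted = site if strand == 1 else revcomp(site)
            seq = sequences[sid]
            sequences[sid] = seq[:start] + inserted + seq[start + w :]
            truth.placements.setdefault(sid, []).append((pwm_id, start + 1, strand))
    return sequences, truth


def random_pwms(
    n: int,
    seed: int = 0,
    width_range: tuple[int, int] = (8, 12),
    dominant_prob: tuple[float, float] = (0.85, 0.97),
) -> list[PWM]:
    """Seeded collection of informative synthetic PWMs (ids MA1, MA2, ...).

    Each position concentrates most probability on one base, giving
    high-information motifs comparable to curated plant TF matrices.
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        matrix = np.zeros((w, 4))
        for j in range(w):
            dom = int(rng.integers(4))
            p = float(rng.uniform(*dominant_prob))
            rest = rng.dirichlet(np.ones(3)) * (1 - p)
            row = np.insert(rest, dom, p)
            matrix[j] = row / row.sum()
        pwms.append(PWM(f"MA{i+1}", f"SYNTF{i+1}", matrix))
    return pwms


# ---------------------------------------------------------------------------
# Truth serialization (single TSV with a `kind` discriminator column)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tid\tlabel_or_pwm\tstart\tstrand\n")
        for gene, label in truth.gene_clusters.items():
            fh.write(f"cluster\t{gene}\t{label}\t.\t.\n")
        for sid, placements in truth.placements.items():
            for pwm_id, start, strand in placements:
                fh.write(f"motif\t{sid}\t{pwm_id}\t{start}\t{strand:+d}\n")


def read_truth(path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    truth = SyntheticTruth()
    for row in df.itertuples(index=False):
        if row.kind == "cluster":
            truth.gene_clusters[row.id] = row.label_or_pwm
        else:
            truth.placements.setdefault(row.id, []).append(
                (row.label_or_pwm, int(row.start), int(row.strand))
            )
    return truth
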