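"""Expression-matrix IO, expressed-gene filtering, stage medians, PCA and a
group-association permutation test.

The analyses here operate on GCRMA-style log2 intensity matrices laid out as
genes x samples, with a design table mapping each sample to a developmental
stage and replicate. A gene is called "present" in a sample when its log2
value reaches a cutoff (default 6.0), and "expressed" when it is present in at
least ``min_present`` samples; transiently expressed genes (one stage = three
replicates) are thereby retained.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus the sample design.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``design``: DataFrame indexed by sample id with columns ``stage`` and
    ``replicate``. Stage order is order of first appearance in the design,
    never lexicographic (so e.g. a tenth stage sorts after the ninth).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stage_order(self) -> list[str]:
        """Stages in order of first appearance in the design."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(str(self.design.loc[s, "stage"]), None)
        return list(seen)


@dataclasses.dataclass
class PcaResult:
    """Sample scores on principal components and per-component variance fractions."""

    scores: pd.DataFrame
    variance_fractions: np.ndarray


@dataclasses.dataclass
class GlobalTestResult:
    """Permutation test of whether a gene set varies with the sample grouping.

    The statistic is the between-group sum of squares of sample values, summed
    over the gene set; significance is assessed by permuting sample group
    labels. This is a permutation substitute for a parametric global test and
    is flagged as such in ``method``.
    """

    statistic: float
    n_perm: int
    p_value: float
    seed: int
    method: str = "permutation between-group sum of squares"


def read_expression(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) and a design TSV.

    The design TSV has columns ``sample``, ``stage`` and optionally
    ``replicate``; row order defines stage order.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {matrix_path}: {exc}") from exc
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    if "sample" not in design.columns or "stage" not in design.columns:
        raise ValueError("design file needs 'sample' and 'stage' columns")
    if "replicate" not in design.columns:
        design["replicate"] = (
            design.groupby("stage", sort=False).cumcount() + 1
        ).astype(str)
    design = design.set_index("sample")
    return ExpressionMatrix(values=values, design=design)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, design_path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    d = m.design.reset_index()
    d.columns = ["sample"] + list(m.design.columns)
    d.to_csv(design_path, sep="\t", index=False)


def filter_expressed(
    m: ExpressionMatrix, cutoff: float = 6.0, min_present: int = 3
) -> list[str]:
    """Gene ids present (value >= cutoff) in at least ``min_present`` samples.

    Presence is counted over individual samples, not stages; a value exactly at
    the cutoff counts as present.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    n_samples = m.values.shape[1]
    if not 1 <= min_present <= n_samples:
        raise ValueError(f"min_present must be in [1, {n_samples}]")
    present = (m.values.to_numpy() >= cutoff).sum(axis=1)
    return [g for g, n in zip(m.gene_ids, present) if n >= min_present]


def stage_medians(m: ExpressionMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene median over each stage's replicate samples.

    Returns a genes x stages DataFrame; stage columns follow design order.
    """
    stages = m.stage_order
    values = m.values if genes is None else m.values.loc[genes]
    cols = {}
    for stage in stages:
        samples = [s for s in m.sample_ids if str(m.design.loc[s, "stage"]) == stage]
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = values[samples].median(axis=1)
    return pd.DataFrame(cols)


def pca_samples(m: ExpressionMatrix) -> PcaResult:
    """PCA of samples in gene space: genes centred, no unit-variance scaling."""
    if m.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    # samples x genes, centre each gene
    x = m.values.to_numpy().T
    x = x - x.mean(axis=0, keepdims=True)
    total = float((x**2).sum())
    if total == 0.0:
        raise ValueError("zero total variance: all samples identical per gene")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(x.shape)
    scores = u[:, :k] * s[:k]
    fractions = s[:k] ** 2 / float((s**2).sum())
    cols = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        variance_fractions=fractions,
    )


def write_pca(res: PcaResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fracs = "\t".join(f"{f:.6g}" for f in res.variance_fractions)
        fh.write(f"# variance_fractions\t{fracs}\n")
        out = res.scores.copy()
        out.index.name = "sample"
        out.to_csv(fh, sep="\t")


def _between_group_ss(x: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Sum over genes of the between-group sum of squares of sample values."""
    grand = x.mean(axis=1, keepdims=True)
    total = 0.0
    for idx in group_idx:
        gm = x[:, idx].mean(axis=1, keepdims=True)
        total += len(idx) * float(((gm - grand) ** 2).sum())
    return total


def global_association_test(
    m: ExpressionMatrix,
    genes: list[str],
    grouping: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> GlobalTestResult:
    """Permutation test: does the gene set's expression vary with the grouping?

    ``grouping`` gives one group label per sample (default: the design stage).
    p = (1 + #{permuted statistic >= observed}) / (n_perm + 1), so p is never 0.
    """
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if grouping is None:
        grouping = [str(m.design.loc[s, "stage"]) for s in m.sample_ids]
    labels = np.asarray(grouping)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    group_idx = [np.flatnonzero(labels == g) for g in uniq]
    if any(len(i) == 0 for i in group_idx):
        raise ValueError("group with zero samples")
    x = m.values.loc[genes].to_numpy()
    observed = _between_group_ss(x, group_idx)
    rng = np.random.default_rng(seed)
    n = x.shape[1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _between_group_ss(x[:, perm], group_idx) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return GlobalTestResult(statistic=observed, n_perm=n_perm, p_value=p, seed=seed)
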