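"""Promoter motif detection: PWM parsing and scanning, Markov background
models, FDR-controlled hit calling, scanner consensus and overrepresentation.

Two complementary hit callers are provided, mirroring the common practice of
intersecting a similarity-threshold scanner with a background-calibrated one:

* :func:`scan_relative` — min-max normalised log-odds score per window, hit
  when the relative score reaches a similarity threshold (default 80%).
* :func:`call_fdr` — per input sequence, 10 length-matched background
  sequences are drawn from a 4th-order Markov model; a raw-score threshold is
  chosen by sweeping observed scores so that the estimated false discovery
  rate stays below a bound (default 0.15).

Only sites called by both routes are retained (:func:`consensus_hits`), and a
motif is flagged overrepresented in a gene set when its consensus-hit count
exceeds the mean plus one standard deviation of counts across all PWMs.

Coordinates are 1-based inclusive, relative to the promoter start; strand +1
is the sense strand, -1 the antisense strand, with antisense hits reported in
sense-strand coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)  # 4 encodes N / anything else
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Sequence string -> int codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PWM:
    """Position frequency matrix: width x 4 base frequencies (A, C, G, T)."""

    id: str
    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: matrix must be width x 4")
        if self.matrix.shape[0] == 0:
            raise ValueError(f"PWM {self.id}: empty matrix")
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.id}: negative frequency")
        sums = self.matrix.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError(f"PWM {self.id}: zero row")
        if np.abs(sums - 1.0).max() > 1e-3:
            raise ValueError(f"PWM {self.id}: row sums deviate from 1 by >1e-3")
        self.matrix = self.matrix / sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.name, self.matrix[::-1, ::-1].copy())


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse a plain-text PWM collection.

    Format: a definition line ``>ID description...``; one row per motif
    position with 4 whitespace-separated frequencies (A, C, G, T); a blank
    line between matrices. Rows are renormalised to sum to exactly 1.
    """
    pwms: list[PWM] = []
    cur_id: str | None = None
    cur_name = ""
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal cur_id, rows
        if cur_id is not None:
            if not rows:
                raise ValueError(f"PWM {cur_id}: empty matrix")
            pwms.append(PWM(cur_id, cur_name, np.array(rows)))
        cur_id, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                cur_id = parts[0]
                cur_name = parts[1].strip() if len(parts) > 1 else ""
            else:
                if cur_id is None:
                    raise ValueError(f"line {lineno}: matrix row before any '>' header")
                fields = line.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"line {lineno}: expected 4 fields (A C G T), got {len(fields)}"
                    )
                rows.append([float(f) for f in fields])
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, pwm in enumerate(pwms):
            if i:
                fh.write("\n")
            fh.write(f">{pwm.id} {pwm.name}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{v:.4f}" for v in row) + "\n")


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits: 2 - H(position), in [0, 2]."""
    f = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    return 2.0 + terms.sum(axis=1)


def gc_content(sequences: list[str] | dict[str, str]) -> float:
    """Pooled (G+C)/(A+C+G+T) over all sequences; N bases are ignored."""
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    if not sequences:
        raise ValueError("no sequences")
    counts = np.zeros(5, dtype=np.int64)
    for seq in sequences:
        counts += np.bincount(encode(seq), minlength=5)
    acgt = counts[:4].sum()
    if acgt == 0:
        raise ValueError("no countable A/C/G/T bases")
    return float((counts[1] + counts[2]) / acgt)


# ---------------------------------------------------------------------------
# Window scoring and the similarity (relative-score) scanner
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifHit:
    """A strand-aware PWM match on a promoter, 1-based inclusive coordinates."""

    seq_id: str
    pwm_id: str
    start: int
    end: int
    strand: int  # +1 sense, -1 antisense
    rel_score: float
    raw_score: float

    def key(self) -> tuple[str, str, int, int]:
        return (self.seq_id, self.pwm_id, self.strand, self.start)


def _log_odds(pwm: PWM, pseudocount: float = 0.01) -> np.ndarray:
    """Smoothed log-odds vs a uniform background: log((f+c)/(1+4c) / 0.25)."""
    fprime = (pwm.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
    return np.log(fprime / 0.25)


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Raw log-odds score of every window; NaN where the window contains N.

    ``codes`` may be 1-D (one sequence) or 2-D (equal-length sequences
    stacked), in which case scores come back with the same leading shape.
    """
    w = lo.shape[0]
    lo5 = np.hstack([lo, np.full((w, 1), np.nan)])
    n_win = codes.shape[-1] - w + 1
    if n_win < 1:
        raise ValueError("sequence shorter than motif width")
    scores = np.zeros(codes.shape[:-1] + (n_win,))
    for j in range(w):
        scores += lo5[j, codes[..., j : j + n_win]]
    return scores


def scan_relative(
    seq: str,
    pwm: PWM,
    threshold: float = 0.80,
    seq_id: str = "seq",
    pseudocount: float = 0.01,
) -> list[MotifHit]:
    """Scan one sequence on both strands; hit when relative score >= threshold.

    The relative score min-max normalises the raw log-odds between the worst
    and best attainable window scores of the PWM. Windows containing N are
    skipped. Antisense windows are scored against the reverse-complemented
    PWM and reported in sense-strand coordinates.
    """
    codes = encode(seq)
    w = pwm.width
    if len(codes) < w:
        raise ValueError(f"sequence {seq_id!r} shorter than motif width {w}")
    hits: list[MotifHit] = []
    for strand, p in ((1, pwm), (-1, pwm.reverse_complement())):
        lo = _log_odds(p, pseudocount)
        smin = float(lo.min(axis=1).sum())
        smax = float(lo.max(axis=1).sum())
        span = smax - smin
        raw = _window_scores(codes, lo)
        rel = (raw - smin) / span if span > 0 else np.ones_like(raw)
        for i in np.flatnonzero(rel >= threshold):
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    pwm_id=pwm.id,
                    start=int(i) + 1,
                    end=int(i) + w,
                    strand=strand,
                    rel_score=float(rel[i]),
                    raw_score=float(raw[i]),
                )
            )
    hits.sort(key=lambda h: (h.start, -h.strand))
    return hits


def scan_relative_many(
    sequences: dict[str, str], pwms: list[PWM], threshold: float = 0.80
) -> list[MotifHit]:
    """Relative-score scan of every sequence against every PWM."""
    hits: list[MotifHit] = []
    for pwm in pwms:
        for sid, seq in sequences.items():
            hits.extend(scan_relative(seq, pwm, threshold, seq_id=sid))
    return hits


# ---------------------------------------------------------------------------
# Markov background model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MarkovModel:
    """k-th order Markov model over ACGT with lower-order start fallbacks.

    ``probs[o]`` has shape (4**o, 4): conditional next-base distributions for
    every length-o context (contexts indexed base-4, A=0..T=3). Positions
    before ``order`` bases are available use the matching lower order.
    """

    order: int
    probs: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if len(self.probs) != self.order + 1:
            raise ValueError("need one probability table per order 0..k")
        for o, p in enumerate(self.probs):
            if p.shape != (4**o, 4):
                raise ValueError(f"order-{o} table must have shape ({4**o}, 4)")
            if np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"order-{o} conditionals must sum to 1")

    @classmethod
    def from_base_composition(cls, gc: float, order: int = 4) -> "MarkovModel":
        """Context-independent model with stationary G+C fraction ``gc``."""
        if not 0 < gc < 1:
            raise ValueError("gc must be in (0, 1)")
        base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return cls(order, [np.tile(base, (4**o, 1)) for o in range(order + 1)])


def _kmer_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 index of every k-mer window (windows containing N are dropped)."""
    n = len(codes) - k + 1
    if n < 1:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        win = codes[j : j + n]
        valid &= win < 4
        idx = idx * 4 + np.where(win < 4, win, 0)
    return idx[valid]


def train_markov(sequences: list[str] | dict[str, str], order: int = 4) -> MarkovModel:
    """Fit conditional base frequencies with add-one smoothing.

    (k+1)-mer counts are pooled across sequences for each order 0..k; the
    lower-order tables provide start-of-sequence fallbacks.
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    if not sequences or all(len(s) == 0 for s in sequences):
        raise ValueError("empty input")
    coded = [encode(s) for s in sequences]
    probs = []
    for o in range(order + 1):
        counts = np.ones((4**o, 4))  # add-one smoothing
        for codes in coded:
            idx = _kmer_indices(codes, o + 1)
            np.add.at(counts, (idx // 4, idx % 4), 1)
        probs.append(counts / counts.sum(axis=1, keepdims=True))
    return MarkovModel(order, probs)


def sample_markov(
    model: MarkovModel, length: int, n: int = 1, seed: int = 0
) -> list[str]:
    """Draw ``n`` sequences of ``length`` bases; deterministic under ``seed``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.zeros((n, length), dtype=np.int8)
    ctx = np.zeros(n, dtype=np.int64)
    for pos in range(length):
        o = min(pos, model.order)
        p = model.probs[o][ctx]
        r = rng.random(n)
        draws = (p.cumsum(axis=1) < r[:, None]).sum(axis=1).clip(max=3)
        out[:, pos] = draws
        if pos + 1 < model.order:
            ctx = ctx * 4 + draws
        elif model.order > 0:
            ctx = (ctx % (4 ** (model.order - 1))) * 4 + draws
    return [decode(row) for row in out]


# ---------------------------------------------------------------------------
# FDR-calibrated hit calling
# ---------------------------------------------------------------------------

def _all_window_scores(codes: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Raw scores for every (window, strand): returns (plus, minus) arrays."""
    lo_p = _log_odds(pwm)
    lo_m = _log_odds(pwm.reverse_complement())
    return _window_scores(codes, lo_p), _window_scores(codes, lo_m)


def call_fdr(
    sequences: dict[str, str],
    pwm: PWM,
    model: MarkovModel,
    n_bg: int = 10,
    fdr_max: float = 0.15,
    seed: int = 0,
) -> list[MotifHit]:
    """Call hits at the most permissive raw-score threshold with FDR <= bound.

    For every input sequence, ``n_bg`` background sequences of the same length
    are sampled from the Markov model. Candidate thresholds t are the observed
    real-sequence window scores in descending order;
    FDR(t) = (background windows >= t / n_bg) / (real windows >= t). The hits
    returned are the real windows at the smallest admissible t (the largest
    hit set with estimated FDR <= ``fdr_max``); empty when no t qualifies.
    """
    if n_bg < 1:
        raise ValueError("n_bg must be >= 1")
    w = pwm.width
    lo = _log_odds(pwm)
    smin = float(lo.min(axis=1).sum())
    smax = float(lo.max(axis=1).sum())
    span = smax - smin

    # score every real window first (arrays only; hit objects are built
    # after the threshold is known)
    per_seq: list[tuple[str, np.ndarray, np.ndarray]] = []
    real_scores: list[np.ndarray] = []
    lengths: dict[int, int] = {}
    for sid, seq in sequences.items():
        codes = encode(seq)
        if len(codes) < w:
            continue
        lengths[len(codes)] = lengths.get(len(codes), 0) + 1
        plus, minus = _all_window_scores(codes, pwm)
        per_seq.append((sid, plus, minus))
        real_scores.append(plus[~np.isnan(plus)])
        real_scores.append(minus[~np.isnan(minus)])
    if not real_scores or all(len(s) == 0 for s in real_scores):
        return []
    real = np.sort(np.concatenate(real_scores))

    rng = np.random.default_rng(seed)
    bg_scores: list[np.ndarray] = []
    for length, count in sorted(lengths.items()):
        seqs = sample_markov(
            model, length, n=n_bg * count, seed=int(rng.integers(2**31))
        )
        codes = np.stack([encode(s) for s in seqs])
        plus, minus = _all_window_scores(codes, pwm)
        for raw in (plus, minus):
            bg_scores.append(raw[~np.isnan(raw)].ravel())
    bg = np.sort(np.concatenate(bg_scores))

    # candidate thresholds: observed real scores, descending; pick the
    # smallest t whose estimated FDR stays within the bound
    thresholds = np.unique(real)[::-1]
    n_real = len(real) - np.searchsorted(real, thresholds, side="left")
    n_bg_ge = len(bg) - np.searchsorted(bg, thresholds, side="left")
    fdr = (n_bg_ge / n_bg) / n_real
    admissible = np.flatnonzero(fdr <= fdr_max)
    if len(admissible) == 0:
        return []
    t_star = float(thresholds[admissible[-1]])

    hits: list[MotifHit] = []
    for sid, plus, minus in per_seq:
        for strand, raw in ((1, plus), (-1, minus)):
            with np.errstate(invalid="ignore"):
                idx = np.flatnonzero(raw >= t_star)
            for i in idx:
                hits.append(
                    MotifHit(
                        seq_id=sid,
                        pwm_id=pwm.id,
                        start=int(i) + 1,
                        end=int(i) + w,
                        strand=strand,
                        rel_score=float((raw[i] - smin) / span) if span > 0 else 1.0,
                        raw_score=float(raw[i]),
                    )
                )
    hits.sort(key=lambda h: (h.seq_id, h.start, -h.strand))
    return hits


def call_fdr_many(
    sequences: dict[str, str],
    pwms: list[PWM],
    model: MarkovModel,
    n_bg: int = 10,
    fdr_max: float = 0.15,
    seed: int = 0,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for k, pwm in enumerate(pwms):
        hits.extend(call_fdr(sequences, pwm, model, n_bg, fdr_max, seed=seed + k))
    return hits


# ---------------------------------------------------------------------------
# Consensus of the two scanners, overrepresentation, AW-box
# ---------------------------------------------------------------------------

def consensus_hits(hits_a: list[MotifHit], hits_b: list[MotifHit]) -> list[MotifHit]:
    """Hits from ``hits_a`` confirmed by ``hits_b`` at the same
    (sequence, PWM, strand, start); score fields carried from ``hits_a``."""
    keys_b = {h.key() for h in hits_b}
    return [h for h in hits_a if h.key() in keys_b]


@dataclasses.dataclass
class EnrichmentTable:
    """Per-PWM consensus-hit counts over a gene set with the mean+SD flag."""

    counts: "pd.DataFrame"  # columns: pwm_id, tf_name, count, overrepresented
    mean: float
    sd: float


def enrichment(
    hits: list[MotifHit], pwms: list[PWM], gene_set: set[str] | list[str]
) -> EnrichmentTable:
    """Flag PWMs whose hit count in the gene set exceeds mean + SD of all PWMs.

    Counts include zeros for loaded-but-unmatched PWMs; SD is the sample
    standard deviation (n-1 denominator).
    """
    import pandas as pd

    if len(pwms) < 2:
        raise ValueError("need >= 2 PWMs for a standard deviation")
    gene_set = set(gene_set)
    counts = {p.id: 0 for p in pwms}
    for h in hits:
        if h.seq_id in gene_set and h.pwm_id in counts:
            counts[h.pwm_id] += 1
    values = np.array([counts[p.id] for p in pwms], dtype=float)
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    table = pd.DataFrame(
        {
            "pwm_id": [p.id for p in pwms],
            "tf_name": [p.name for p in pwms],
            "count": values.astype(int),
            "overrepresented": values > mu + sd,
        }
    )
    return EnrichmentTable(counts=table, mean=mu, sd=sd)


#: AW-box pattern [CnTnG](n)7[CG]: fixed bases at offsets 0, 2, 4 and a C/G
#: at offset 12 of a 13-bp window.
AW_BOX_WIDTH = 13


def scan_aw_box(seq: str) -> list[tuple[int, int]]:
    """All AW-box matches on both strands as (1-based start, strand) pairs.

    Antisense matches are located on the reverse complement and reported in
    sense-strand coordinates of their leftmost base.
    """
    L = len(seq)
    matches: list[tuple[int, int]] = []

    def plus_matches(codes: np.ndarray) -> np.ndarray:
        n = len(codes) - AW_BOX_WIDTH + 1
        if n < 1:
            return np.empty(0, dtype=int)
        ok = (
            (codes[0:n] == 1)  # C
            & (codes[2 : 2 + n] == 3)  # T
            & (codes[4 : 4 + n] == 2)  # G
            & ((codes[12 : 12 + n] == 1) | (codes[12 : 12 + n] == 2))  # C or G
        )
        # middle positions are wildcards but must be real bases, not N
        for off in (1, 3, 5, 6, 7, 8, 9, 10, 11):
            ok &= codes[off : off + n] < 4
        return np.flatnonzero(ok)

    codes = encode(seq)
    for i in plus_matches(codes):
        matches.append((int(i) + 1, 1))
    rc = _COMPLEMENT[codes][::-1]
    for q in plus_matches(rc):
        matches.append((L - int(q) - AW_BOX_WIDTH + 1, -1))
    matches.sort(key=lambda m: (m[0], -m[1]))
    return matches


# ---------------------------------------------------------------------------
# Promoter extraction and IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_promoters(
    genome: dict[str, str] | str | Path,
    gene_table: "pd.DataFrame",
    upstream: int = 1000,
    utr: int = 200,
) -> dict[str, str]:
    """Promoter = up to ``upstream`` bases 5' of the TSS plus the first
    ``utr`` transcribed bases, read 5'->3' on the gene's strand.

    ``gene_table`` columns: gene, chrom, tss (1-based), strand (+/-), and
    optionally ``neighbor`` — the nearest boundary of the upstream neighbour;
    when the intergenic gap is shorter than ``upstream`` the promoter is
    truncated at that boundary. Sequences are clipped at chromosome ends.
    """
    if not isinstance(genome, dict):
        genome = read_fasta(genome)
    out: dict[str, str] = {}
    for row in gene_table.itertuples(index=False):
        gene, chrom, tss = str(row.gene), str(row.chrom), int(row.tss)
        strand = str(row.strand)
        neighbor = getattr(row, "neighbor", None)
        neighbor = None if neighbor is None or (isinstance(neighbor, float) and np.isnan(neighbor)) else int(neighbor)
        if chrom not in genome:
            raise ValueError(f"gene {gene}: chromosome {chrom!r} not in genome")
        chrom_seq = genome[chrom]
        L = len(chrom_seq)
        if not 1 <= tss <= L:
            raise ValueError(f"gene {gene}: TSS {tss} outside chromosome (1..{L})")
        if strand == "+":
            up_start = max(1, tss - upstream)
            if neighbor is not None and tss - neighbor - 1 < upstream:
                up_start = max(up_start, neighbor + 1)
            end = min(L, tss + utr - 1)
            out[gene] = chrom_seq[up_start - 1 : end]
        elif strand == "-":
            up_end = min(L, tss + upstream)
            if neighbor is not None and neighbor - tss - 1 < upstream:
                up_end = min(up_end, neighbor - 1)
            start = max(1, tss - utr + 1)
            out[gene] = revcomp(chrom_seq[start - 1 : up_end])
        else:
            raise ValueError(f"gene {gene}: malformed strand {strand!r}")
    return out


def write_hits(hits: list[MotifHit], pwms: list[PWM], path: str | Path) -> None:
    """Hit table TSV: sequence, PWM, TF name, 1-based coordinates, strand,
    relative and raw scores."""
    names = {p.id: p.name for p in pwms}
    with open(path, "w") as fh:
        fh.write("seq_id\tpwm_id\ttf_name\tstart\tend\tstrand\trel_score\traw_score\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.pwm_id}\t{names.get(h.pwm_id, '')}\t"
                f"{h.start}\t{h.end}\t{h.strand:+d}\t{h.rel_score:.4f}\t{h.raw_score:.4f}\n"
            )
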