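# Methods

This note documents the models and procedures implemented in `seednet`, the
defaults and why they were chosen, and what the synthetic benchmark does and
does not establish.

## Expression processing

Input is a genes × samples matrix of log2 intensities (GCRMA-style
normalisation is assumed to have happened upstream; `seednet` starts from the
log2 matrix) plus a design table mapping samples to stages and replicates.
Stage order is the order of first appearance in the design file, never a
lexicographic sort, so stage labels such as `S10` follow `S9`.

**Expressed-gene filter.** A gene is "present" in a sample when its log2
value is ≥ the cutoff (default 6.0) and "expressed" when present in ≥
`min_present` samples (default 3, one stage's worth of replicates, so a gene
transiently expressed at a single stage is retained). The boundary is
inclusive (≥, not >): a gene sitting exactly at 6.0 counts as present, which
makes the printed cutoff attainable. Presence is counted over samples, not
stages.

**Stage medians.** Replicates are collapsed to per-stage medians
(numpy/pandas median; the even-count median is the midpoint). All downstream
correlation and clustering operates on these 8-point profiles.

**PCA.** Samples are projected after centring each gene; no unit-variance
scaling (the data are already on a common log2 scale). Variance fractions
come from the singular values; a matrix whose samples are identical up to
gene-wise constants has zero total variance and is rejected rather than
producing NaNs.

**Group-association test.** The question "does this gene set vary across
stages?" is answered by a permutation test: statistic = Σ over genes of the
between-group (stage) sum of squares of sample values; sample stage labels
are permuted `n_perm` times (default 999) and
p = (1 + #{permuted ≥ observed}) / (n_perm + 1), so p is never 0 and its
floor is 1/(n_perm+1). This is a permutation substitute for parametric
global tests of group association; the result object records the method
name. Calibration is verified by simulation: empirical type-I error at
nominal 0.05 over 200 null datasets falls within 0.05 ± 0.04.

## Coexpression network

Pearson correlations are computed over the 8 stage medians (n = 8, and the
Fisher-Z p-value uses n = 8 accordingly). Genes with zero variance across
stages are excluded (r undefined). An edge requires r ≥ threshold (default
0.90), **positive correlations only** — anti-correlation is biologically a
different relationship and never forms an edge. The boundary is inclusive.
For large matrices `correlated_pairs` streams gene blocks (default 2,000
rows) against the standardized matrix and emits only above-threshold pairs,
so 12,000+ genes never require a dense all-pairs table.

**Fisher's Z.** z = atanh(r), statistic z·√(n−3), one-sided upper normal
tail. At r = 0.90, n = 8: z = 1.47222, statistic = 3.29198, p = 0.0005 to
one significant figure.

**Topology.** The clustering coefficient averages 2T(v)/(k_v(k_v−1)) over
nodes with degree ≥ 2 only (the local coefficient is undefined below that);
the alternative convention (count low-degree nodes as 0) can be compared by
using `networkx.average_clustering` directly. The degree histogram uses the
fixed bins 1; 2–49; 50–99; 100–149; 150–199; 200–249; 250–299; ≥300.

**Scale-free fit.** Degrees are binned into ≤ 10 logarithmically spaced bins
(empty bins dropped). Counts are width-normalised to densities before the
log–log OLS — without that normalisation the slope of log-binned counts
estimates γ−1, not γ, and the fit of a known k⁻² distribution would not
recover 2. γ = −slope; R² is the coefficient of determination, reported as 0
when the slope is positive (no decaying power law). At least 5 distinct
degree values are required.

**Subnetworks.** Two modes: induced subgraph on seed genes plus their first
neighbours, or the union of connected components containing any seed. Seeds
missing from the network are reported but not fatal; all seeds missing is an
error.

## Fuzzy c-means

Profiles are standardized per gene (mean 0, SD 1, population SD); flat
profiles cannot be standardized and are dropped with a warning. The
clusterer is the classic Bezdek iteration: centres
c_i = Σ_j u_ij^m x_j / Σ_j u_ij^m, memberships
u_ij = 1/Σ_k (d_ij/d_kj)^(2/(m−1)) with Euclidean d, stopping when
max|ΔU| < 1e-6 or after 1,000 iterations. A gene coinciding exactly with a
centre receives membership 1 there (split equally over coinciding centres).
The exponentiation is computed on distances normalised by the row minimum so
m close to 1 (e.g. 1.01, the hard/k-means limit) does not overflow.

Defaults: c = 6, m = 1.75, core membership ≥ 0.90 — the standard settings
for an 8-point seed-maturation series. Initial memberships are symmetric
Dirichlet draws keyed on (seed, crc32(gene id)), which makes the run
deterministic under the seed *and* exactly equivariant under input row
permutation. Convergence tolerance and iteration cap are configurable; the
objective J = Σ u^m d² is recorded per iteration and is non-increasing.
Cluster labels are canonicalized by the stage at which each centre peaks
(ties broken by peak height), so cluster numbering is comparable across
runs. Clustering operates on stage medians, consistent with the network
stage; clustering the 24 raw samples instead is a one-line change (pass the
sample matrix), not a separate mode.

## Promoter motifs

**PWM format.** Plain text: `>ID description` then one row per position with
4 frequencies (A, C, G, T), blank line between matrices; rows are
renormalised on load (tolerance 1e-3).

**Relative-score scanner.** Frequencies are smoothed,
f′ = (f + 0.01)/(1 + 0.04), and scored log-odds against a uniform
background: S = Σ log(f′(base)/0.25). The relative score min-max normalises
S between the per-position-min and per-position-max attainable scores; a hit
requires relative score ≥ 0.80. This reconstructs the usual "80% similarity"
semantics of PWM scanners; the pseudocount and background are configurable
because published cutoffs do not pin them down. Antisense windows are scored
against the reverse-complemented matrix and reported in sense-strand
coordinates (1-based, inclusive; strands +1/−1). Windows containing N are
skipped, not wildcarded.

**Markov backgrounds.** k-th order (default 4) conditional base frequencies
with add-one smoothing, pooled over all input promoters, with lower-order
fallbacks for the first k positions. The same machinery generates the
synthetic promoter backgrounds (a context-independent instance with the
target G+C) and the FDR caller's null sequences.

**FDR caller.** For each input sequence, 10 background sequences of matched
length are sampled from the Markov model. Candidate thresholds t are the
observed real-window scores in descending order;
FDR(t) = (background windows ≥ t / n_bg) / (real windows ≥ t); the call set
is the real windows at the smallest admissible t (largest hit set with
FDR(t) ≤ 0.15), empty if none qualifies. This is a threshold-sweep
implementation of the "matched-background FDR bound" contract, not an EM
fit of a mixture model; the distinction matters only for scores near the
threshold.

**Consensus and overrepresentation.** A hit survives iff both scanners call
the same (sequence, PWM, strand, start); identical starts are well-defined
because both scanners share the PWM width. Overrepresentation in a gene set:
count consensus hits per PWM (zeros included for every loaded PWM), flag
counts > mean + sample SD (ddof = 1) over all PWMs. Computing μ, σ over only
PWMs with ≥ 1 hit is a documented alternative (subset the PWM list before
calling).

**AW-box.** The WRI1-binding pattern [CnTnG](n)₇[CG] is matched literally on
13-bp windows of both strands: C at offset 0, T at 2, G at 4, C or G at 12,
any real base elsewhere.

**Promoter extraction.** Promoter = up to 1000 bp upstream of the TSS plus
the first 200 transcribed bases, truncated at the upstream neighbour's
boundary when the intergenic gap is shorter than 1000 bp (so the neighbour's
3′ end is never included), clipped at chromosome ends, reverse-complemented
for minus-strand genes so output always reads 5′→3′.

## Synthetic data

The generator emulates an 8-stage × 3-replicate log2 intensity series: gene
value = baseline + archetype template[stage] + i.i.d. Gaussian noise on the
log2 scale. Archetype templates encode the canonical maturation patterns
(FA-like rise to a peak at stage 5 of 8 then decline; oleosin-like
10-log2-unit jump after stage 1 then plateau; LEA-like late rise; flat;
mirror images). Baselines are uniform on 6–12 log2 units so the expression
filter at 6.0 is genuinely exercised. Promoter backgrounds come from the
Markov machinery with stationary G+C 0.33 (matching the A/T-rich composition
of plant promoters, < 35% G+C); planted sites are sampled from the PWM
columns and overwrite background bases, so coordinates never shift.

**Default benchmark conditions** (used by the shared test fixture and the
acceptance script): 2,000 genes, six archetypes (FA/oleosin/LEA + mirrors,
equal proportions), noise SD 0.25 log2 units; 300 promoters of 1,200 bp; 20
synthetic PWMs of width 8–12 with 0.85–0.97 dominant-base probability; the
planted PWM (MA1) in 60% of promoters on random strands. The planted matrix
is constructed at high information content (width 11–12, dominant-base
probability 0.93–0.97) for every seed: the benchmark measures recovery of a
strong, well-conserved site, and that property is part of the design rather
than left to the draw of the PWM generator. The flat archetype
is excluded from the benchmark because a flat profile standardizes to pure
noise, making planted-label recovery undefined for it. Replicate noise SD is
a free choice (no published per-stage variances exist for this design); 0.25
is realistic for well-replicated arrays after normalisation and is exposed
in the config.

**What the benchmark does not show.** Noise is i.i.d. — no replicate
correlation structure, batch effects, probe saturation, or
intensity-dependent variance; archetypes are exact templates rather than a
continuum of profiles; synthetic PWMs are cleaner than many curated
matrices; promoters are homogeneous Markov text without repeats, TATA
structure, or positional motif bias. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated generative model,
not field performance on array data.

## Numerical and degenerate-input choices

- Permutation p-values are never 0 (add-one numerator and denominator).
- Zero-variance genes: excluded from correlation, dropped with a warning by
  standardization, rejected by PCA only when *all* variance is zero.
- FCM: d = 0 → membership 1; ties over identical centres split equally.
- Power-law fit: empty log-bins dropped; positive slope → R² = 0; all-equal
  degrees rejected.
- FDR caller: zero real windows → empty call set (no division by zero).
- Edge/threshold boundaries are inclusive everywhere a published cutoff is
  quoted (r ≥ 0.90, log2 ≥ 6.0, membership ≥ 0.90, relative score ≥ 0.80).

## Problem sizes

The shared fixture (2,000 genes / 300 promoters / 20 PWMs) runs the full
pipeline in well under a minute on one CPU; the block-streamed correlation
stage holds at 12,000+ genes. Oracle-equivalence tests use ≤ 100-node graphs
and ≤ 10 kb sequences where exhaustive enumeration is exact and fast.

## Known limitations

- The group-association permutation test is a generic substitute; it does
  not reproduce any specific parametric global-test statistic.
- The FDR caller's threshold sweep estimates FDR empirically from 10
  backgrounds; with very few real windows the estimate is coarse.
- The relative-score definition (pseudocount 0.01, uniform background) is
  one reasonable reconstruction of "80% similarity"; other scanners differ
  in smoothing details, so absolute hit counts are scanner-specific even
  when the consensus logic is identical.
- Network construction assumes the 8-point stage-median profiles; with very
  few stages Pearson r is unstable, which is exactly why the edge threshold
  is as stringent as 0.90.
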