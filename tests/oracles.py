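"""Naive brute-force oracles, independent of the library implementations.

Each oracle recomputes a quantity by direct enumeration (O(n^2)/O(n^3)
loops over pairs, triangles, windows) so the vectorised library paths can be
checked exactly on small inputs.
"""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def clustering_coefficient(edges: set[frozenset]) -> float:
    """Mean over nodes of degree >= 2 of 2*triangles/(k*(k-1))."""
    nodes = sorted({v for e in edges for v in e})
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    locals_ = []
    for v in nodes:
        k = len(adj[v])
        if k < 2:
            continue
        tri = 0
        neigh = sorted(adj[v])
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                if neigh[j] in adj[neigh[i]]:
                    tri += 1
        locals_.append(2 * tri / (k * (k - 1)))
    return sum(locals_) / len(locals_)


def degree_histogram(degrees, bins) -> list[int]:
    counts = [0] * len(bins)
    for d in degrees:
        for i, (lo, hi) in enumerate(bins):
            if lo <= d <= hi:
                counts[i] += 1
                break
    return counts


def neighborhood_subgraph(edges: set[frozenset], seeds: set) -> set[frozenset]:
    """Induced edge set on seeds plus their first neighbours, by edge scan."""
    nodes = set(seeds)
    for e in edges:
        a, b = tuple(e)
        if a in seeds:
            nodes.add(b)
        if b in seeds:
            nodes.add(a)
    return {e for e in edges if set(e) <= nodes}


def pwm_window_hits(seq: str, matrix, threshold: float, pseudocount: float = 0.01):
    """Per-window relative-score scan by direct loops; returns
    (start_1based, strand, rel, raw) tuples sorted like the scanner."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(matrix)
    hits = []
    for strand in (1, -1):
        if strand == 1:
            mat = matrix
        else:
            mat = [[row[3 - j] for j in range(4)] for row in reversed(matrix)]
        lo = [
            [math.log(((f + pseudocount) / (1 + 4 * pseudocount)) / 0.25) for f in row]
            for row in mat
        ]
        smin = sum(min(row) for row in lo)
        smax = sum(max(row) for row in lo)
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if any(b not in idx for b in window):
                continue
            raw = sum(lo[j][idx[b]] for j, b in enumerate(window))
            rel = (raw - smin) / (smax - smin) if smax > smin else 1.0
            if rel >= threshold:
                hits.append((i + 1, strand, rel, raw))
    hits.sort(key=lambda h: (h[0], -h[1]))
    return hits


def aw_box_matches(seq: str):
    """AW-box [CnTnG](n)7[CG] by direct character checks on both strands."""
    def plus(s):
        out = []
        for i in range(len(s) - 12):
            win = s[i : i + 13]
            if "N" in win:
                continue
            if win[0] == "C" and win[2] == "T" and win[4] == "G" and win[12] in "CG":
                out.append(i + 1)
        return out

    matches = [(p, 1) for p in plus(seq)]
    rc = revcomp(seq)
    for q in plus(rc):
        matches.append((len(seq) - (q - 1) - 13 + 1, -1))
    matches.sort(key=lambda m: (m[0], -m[1]))
    return matches


def consensus_match(hits_a, hits_b):
    """O(n^2) intersection on (seq, pwm, strand, start)."""
    out = []
    for ha in hits_a:
        for hb in hits_b:
            if (
                ha.seq_id == hb.seq_id
                and ha.pwm_id == hb.pwm_id
                and ha.strand == hb.strand
                and ha.start == hb.start
            ):
                out.append(ha)
                break
    return out
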