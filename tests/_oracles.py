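"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (pair
enumeration, all-pairs interval overlap, exhaustive placement enumeration)
and never call the code paths they check.
"""

from __future__ import annotations

import numpy as np


def kendall_tau_b_bruteforce(x, y) -> float:
    """Tau-b by O(n^2) enumeration of concordant/discordant pairs with the
    tie-corrected denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = 0
    tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx == dy:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def _tie_term(v) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) // 2 for c in counts))


def count_window_overlaps_bruteforce(reads, chrom, start, end) -> int:
    """All-pairs >=1 bp overlap count; ``reads`` is an iterable of
    (chrom, start, end)."""
    return sum(1 for c, s, e in reads if c == chrom and s < end and start < e)


def interval_overlap_len(a, b) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def shared_flags_bruteforce(peaks_a, peaks_b, min_overlap_bp=1):
    """For every peak of a: does any peak of b overlap by >= min_overlap_bp."""
    flags = []
    for ca, sa, ea in peaks_a:
        hit = any(
            cb == ca and interval_overlap_len((sa, ea), (sb, eb)) >= min_overlap_bp
            for cb, sb, eb in peaks_b
        )
        flags.append(hit)
    return flags


def classify_read_bruteforce(blocks, exons, introns) -> str:
    """Splice-state classification by exhaustive per-base reasoning."""
    covered_intron = any(
        interval_overlap_len(b, i) > 0 for b in blocks for i in introns
    )
    if covered_intron:
        return "unspliced"
    all_exonic = all(
        any(es <= b[0] and b[1] <= ee for es, ee in exons) for b in blocks
    )
    if not all_exonic:
        return "ambiguous"
    if len(blocks) == 1:
        return "spliced"
    gaps = [(blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1)]
    return "spliced" if all(g in list(introns) for g in gaps) else "ambiguous"


def expected_unspliced_fraction(models, rho: float, read_length: int) -> float:
    """Exhaustive read-placement enumeration: probability a pre-mRNA read of
    ``read_length`` overlaps an intron, averaged over genes sampled
    uniformly, times ``rho``. Mature reads never count as unspliced."""
    probs = []
    for g in models:
        n_placements = g.end - g.start - read_length + 1
        fully_exonic = sum(
            max(0, (e - s) - read_length + 1) for s, e in g.exons
        )
        probs.append(1.0 - fully_exonic / n_placements)
    return rho * float(np.mean(probs))
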