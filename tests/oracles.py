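"""Independent brute-force oracles used to validate the implementation."""

from itertools import combinations


def smith_waterman_score(query: str, target: str, match: int, mismatch: int,
                         gap_open: int, gap_extend: int) -> float:
    """Exhaustive affine-gap local alignment score (Gotoh recurrences).

    Gap of length m costs gap_open + (m - 1) * gap_extend, matching the
    production aligner's convention. Scores only; O(len(q) * len(t)).
    """
    n, m = len(query), len(target)
    neg = float("-inf")
    best = 0.0
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    for i in range(1, n + 1):
        h_row = [0.0] * (m + 1)
        e_row = [neg] * (m + 1)
        f = neg
        for j in range(1, m + 1):
            e_row[j] = max(h_prev[j] + gap_open, e_prev[j] + gap_extend)
            f = max(h_row[j - 1] + gap_open, f + gap_extend)
            s = match if query[i - 1] == target[j - 1] else mismatch
            h_row[j] = max(0.0, h_prev[j - 1] + s, e_row[j], f)
            best = max(best, h_row[j])
        h_prev, e_prev = h_row, e_row
    return best


def defined_deletions_brute_force(cut_sites_1, cut_sites_2):
    """All unordered distinct cut-site pairs, as sorted (start, end) tuples."""
    pairs = set()
    for a in cut_sites_1:
        for b in cut_sites_2:
            if a != b:
                pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def chi_square_equal_thirds(counts):
    """Pearson goodness-of-fit statistic against equal thirds, by hand."""
    total = sum(counts)
    expected = total / 3.0
    return sum((o - expected) ** 2 / expected for o in counts)
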