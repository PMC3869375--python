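"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately naive — O(n^2) scans, per-window
enumeration, exact rational arithmetic — and shares no code with the
package's implementations.
"""

from fractions import Fraction
from math import comb, log10

from scipy import stats


def brute_overlap_partition(set_a, set_b):
    """All-pairs overlap scan; intervals as (chrom, start, end) tuples."""
    def hit(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    a_hits = [any(hit(a, b) for b in set_b) for a in set_a]
    b_hits = [any(hit(b, a) for a in set_a) for b in set_b]
    n_both = sum(a_hits)
    return n_both, len(set_a) - n_both, len(set_b) - sum(b_hits)


def brute_candidate_islands(positions, chrom_length, window, gap,
                            eligibility_p, lam):
    """Window-by-window enumeration of the island definition.

    Returns a list of (start, end, chip_count, score) tuples for one
    chromosome, merging eligible windows separated by <= gap ineligible
    windows.
    """
    n_windows = -(-chrom_length // window)
    counts = [0] * n_windows
    for p in positions:
        if 0 <= p < chrom_length:
            counts[p // window] += 1
    eligible = [i for i in range(n_windows)
                if stats.poisson.sf(counts[i] - 1, lam) < eligibility_p]
    islands = []
    run = []
    for idx in eligible:
        if run and idx - run[-1] - 1 > gap:
            islands.append(run)
            run = []
        run.append(idx)
    if run:
        islands.append(run)
    out = []
    for run in islands:
        first, last = run[0], run[-1]
        chip = sum(counts[first:last + 1])
        score = sum(-stats.poisson.logpmf(counts[i], lam) for i in run)
        out.append((first * window, (last + 1) * window, chip, float(score)))
    return out


def brute_emergent(ordered_sets):
    """Per-time emergent members by all-pairs scan against earlier sets."""
    def hit(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    out = []
    earlier = []
    for current in ordered_sets:
        out.append([iv for iv in current
                    if not any(hit(iv, e) for e in earlier)])
        earlier.extend(current)
    return out


def brute_classify(me1, me3, k27ac, tss, radius):
    """Rule-by-rule element classification; islands as (chrom, start, end),
    tss as (gene_id, chrom, pos).  Returns (promoter_classes, enhancer_classes)
    keyed by gene_id and by me1 interval respectively."""
    def hit(x, y):
        return x[0] == y[0] and x[1] < y[2] and y[1] < x[2]

    promoters = {}
    for gene_id, chrom, pos in tss:
        window = (chrom, max(0, pos - radius), pos + radius)
        if any(hit(window, m) for m in me3):
            promoters[gene_id] = ("active_promoter"
                                  if any(hit(window, k) for k in k27ac)
                                  else "silent_promoter")
    enhancers = {}
    for iv in me1:
        chrom, start, end = iv
        center = (start + end) // 2
        if any(c == chrom and abs(p - center) <= radius for _, c, p in tss):
            continue
        if any(hit(iv, m) for m in me3):
            continue
        enhancers[iv] = ("active_enhancer"
                         if any(hit(iv, k) for k in k27ac)
                         else "silent_enhancer")
    return promoters, enhancers


def exact_log10_hypergeom_tail(N, K, n, k, strict=False):
    """Exact rational upper tail via integer binomials."""
    lo = k + 1 if strict else k
    if lo <= 0:
        return 0.0
    total = sum(comb(K, i) * comb(N - K, n - i)
                for i in range(lo, min(n, K) + 1))
    if total == 0:
        return float("-inf")
    frac = Fraction(total, comb(N, n))
    return log10(frac.numerator) - log10(frac.denominator)


def exact_log10_binomial_tail(n, k, p0_frac, strict=False):
    """Exact rational upper tail; p0 passed as a Fraction."""
    lo = k + 1 if strict else k
    if lo <= 0:
        return 0.0
    q = 1 - p0_frac
    total = sum(comb(n, i) * p0_frac ** i * q ** (n - i)
                for i in range(lo, n + 1))
    if total == 0:
        return float("-inf")
    return log10(total.numerator) - log10(total.denominator)
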