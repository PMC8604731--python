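"""Independent oracle implementations used to validate the package.

Everything here is deliberately naive — per-base scans, exhaustive
enumeration, brute-force grid searches — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


# --- per-base copy-number oracles -------------------------------------------


def _chrom_arrays(profile, chromosome):
    """Per-base (total, minor) arrays over the covered bases of a chromosome,
    in coordinate order, plus a parallel array of positions."""
    seg = profile.segments
    cseg = seg[seg.chromosome == chromosome].sort_values("start")
    totals, minors, positions = [], [], []
    for row in cseg.itertuples(index=False):
        n = row.end - row.start + 1
        totals.append(np.full(n, row.total_cn, dtype=np.int16))
        minors.append(np.full(n, row.minor_cn, dtype=np.int16))
        positions.append(np.arange(row.start, row.end + 1, dtype=np.int32))
    if not totals:
        return None
    return (
        np.concatenate(totals),
        np.concatenate(minors),
        np.concatenate(positions),
    )


def perbase_aneuploidy(profile):
    """Per-base scan oracle for LOH/imbalance fractions, breakpoints, entropy."""
    loh_bases = imb_bases = covered = 0
    n_break = 0
    state_counts: dict[int, int] = {}
    for chrom in profile.segments.chromosome.unique():
        arrays = _chrom_arrays(profile, chrom)
        if arrays is None:
            continue
        total, minor, _ = arrays
        covered += total.size
        major = total - minor
        loh_bases += int(((minor == 0) & (total >= 1)).sum())
        imb_bases += int((major != minor).sum())
        for t, c in zip(*np.unique(total, return_counts=True)):
            state_counts[int(t)] = state_counts.get(int(t), 0) + int(c)
        # transitions between consecutive covered bases (gaps ignored)
        changed = (total[1:] != total[:-1]) | (minor[1:] != minor[:-1])
        n_break += int(changed.sum())
    probs = np.array([c / covered for c in state_counts.values()])
    entropy = float(-(probs * np.log(probs)).sum()) if probs.size > 1 else 0.0
    return loh_bases / covered, imb_bases / covered, n_break, entropy


def perbase_arm_status_fraction(profile, arm, reference):
    """Per-base fractions of an arm in gain / loss / LOH status."""
    arrays = _chrom_arrays(profile, arm.chromosome)
    gain = loss = loh = 0
    if arrays is not None:
        total, minor, pos = arrays
        inside = (pos >= arm.start) & (pos <= arm.end)
        t, m = total[inside], minor[inside]
        gain = int((t > reference).sum())
        loss = int((t < reference).sum())
        loh = int(((m == 0) & (t >= 1)).sum())
    return gain / arm.length, loss / arm.length, loh / arm.length


def reimplemented_hrd(profile, assembly, loh_min, lst_min, lst_gap):
    """Second implementation of the HRD component scores from their
    definitions, using plain per-chromosome python loops."""
    # merge equal-state abutting segments first
    segs = []
    for row in profile.segments.sort_values(["chromosome", "start"]).itertuples(
        index=False
    ):
        if (
            segs
            and segs[-1][0] == row.chromosome
            and segs[-1][2] + 1 == row.start
            and segs[-1][3] == row.total_cn
            and segs[-1][4] == row.minor_cn
        ):
            segs[-1][2] = row.end
        else:
            segs.append([row.chromosome, row.start, row.end, row.total_cn, row.minor_cn])
    tai = loh_score = lst = 0
    by_chrom: dict[str, list] = {}
    for s in segs:
        by_chrom.setdefault(s[0], []).append(s)
    for chrom, cseg in by_chrom.items():
        clen = assembly.chromosome_length(chrom)
        cen_s, cen_e = assembly.centromere(chrom)
        for chrom_, start, end, total, minor in cseg:
            length = end - start + 1
            if (total - minor) != minor and (start == 1 or end == clen):
                if not (start <= cen_s and end >= cen_e):
                    tai += 1
            if minor == 0 and total >= 1 and length >= loh_min:
                if not (start == 1 and end == clen):
                    loh_score += 1
        for left, right in zip(cseg, cseg[1:]):
            len_l = left[2] - left[1] + 1
            len_r = right[2] - right[1] + 1
            gap = right[1] - left[2] - 1
            state_differs = (left[3], left[4]) != (right[3], right[4])
            if len_l >= lst_min and len_r >= lst_min and gap <= lst_gap and state_differs:
                lst += 1
    return tai, loh_score, lst


# --- exact-test enumeration oracles ------------------------------------------


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def mannwhitney_two_sided_enum(xs, ys) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Assumes no ties. p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    pooled = sorted(list(xs) + list(ys))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(xs)
    u_obs = sum(1 for x in xs for y in ys if x > y)
    us = []
    for combo in combinations(range(len(pooled)), n1):
        group = set(combo)
        a_vals = [pooled[i] for i in combo]
        b_vals = [pooled[i] for i in range(len(pooled)) if i not in group]
        us.append(sum(1 for x in a_vals for y in b_vals if x > y))
    us = np.array(us)
    p_le = float((us <= u_obs).mean())
    p_ge = float((us >= u_obs).mean())
    return min(1.0, 2.0 * min(p_le, p_ge))


def clopper_pearson_bisect(k, n, level, tol=1e-10):
    """Clopper-Pearson bounds by bisection on the exact binomial tails."""
    alpha = 1.0 - level

    def binom_sf(p, lo):  # P(X >= k) at success prob p
        return sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(lo, n + 1)
        )

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    # lower bound solves P(X >= k) = alpha/2; upper solves P(X <= k) = alpha/2,
    # i.e. P(X >= k+1) = 1 - alpha/2 (both left sides increase with p)
    low = 0.0 if k == 0 else bisect(lambda p: binom_sf(p, k), alpha / 2, 0.0, 1.0)
    high = (
        1.0
        if k == n
        else bisect(lambda p: binom_sf(p, k + 1), 1.0 - alpha / 2, 0.0, 1.0)
    )
    return low, high


def bh_stepup_reference(pvalues):
    """Reference Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def ccf_grid_oracle(vaf, purity, total_cn, cap=1.5):
    """Brute-force multiplicity grid search.

    For each multiplicity the implied CCF is capped at ``cap``; the expected
    VAF is recomputed and the multiplicity minimizing |expected - observed|
    is chosen, ties broken toward the raw (unrounded) multiplicity.
    """
    denom = purity * total_cn + 2.0 * (1.0 - purity)
    raw = vaf / purity * denom
    best = None
    for m in range(1, total_cn + 1):
        ccf = min(cap, vaf * denom / (purity * m))
        expected = purity * m * ccf / denom
        err = abs(expected - vaf)
        key = (round(err, 12), abs(m - raw))
        if best is None or key < best[0]:
            best = (key, m, ccf)
    return best[1], best[2]


def km_no_censoring(times):
    """Empirical survival function: S(t) = #{T > t}/n at each event time."""
    times = np.sort(np.asarray(times, dtype=float))
    n = times.size
    uniq = np.unique(times)
    surv = np.array([(times > t).sum() / n for t in uniq])
    return uniq, surv
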