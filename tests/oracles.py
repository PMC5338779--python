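"""Independent brute-force oracles, coded separately from the package.

Everything here favours explicit loops and textbook formulas over the
vectorised routines under test, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def average_ranks(values) -> list[float]:
    """1-based average ranks computed by explicit sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(counts: np.ndarray, trim_m=0.30, trim_a=0.05) -> list[float]:
    """Step-by-step trimmed-mean-of-M-values evaluation.

    Reference sample: upper-quartile/library-size ratio closest to the
    mean of that ratio. Per sample: pairwise-positive genes, log2 ratio M
    and mean log2 abundance A against the reference, double rank-trim,
    inverse binomial-variance weighted mean, 2**mean; factors rescaled to
    geometric mean one.
    """
    n_genes, n_samples = counts.shape
    lib = [sum(counts[g][s] for g in range(n_genes)) for s in range(n_samples)]
    uq = [float(np.quantile([counts[g][s] / lib[s] for g in range(n_genes)], 0.75))
          for s in range(n_samples)]
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda s: abs(uq[s] - mean_uq))

    raw = []
    for s in range(n_samples):
        if s == ref:
            raw.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for g in range(n_genes):
            o, r = counts[g][s], counts[g][ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[s], r / lib[ref]
            ms.append(math.log2(po / pr))
            as_.append(0.5 * math.log2(po * pr))
            ws.append((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = average_ranks(ms)
        ra = average_ranks(as_)
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
                kept += 1
        raw.append(2.0 ** (num / den) if kept else 1.0)
    log_gm = sum(math.log(f) for f in raw) / n_samples
    return [f / math.exp(log_gm) for f in raw]


def signal2noise_oracle(tumor_rows, control_rows, floor_frac=0.2, abs_floor=0.04) -> float:
    """One gene's Signal2Noise score from explicit mean/sd arithmetic."""
    def mean(xs):
        return sum(xs) / len(xs)

    def sd(xs):
        m = mean(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    mu_t, mu_c = mean(tumor_rows), mean(control_rows)
    s_t = max(sd(tumor_rows), floor_frac * abs(mu_t), abs_floor)
    s_c = max(sd(control_rows), floor_frac * abs(mu_c), abs_floor)
    return (mu_t - mu_c) / (s_t + s_c)


def es_oracle(scores, is_hit, weight_p=1.0) -> tuple[float, list[float]]:
    """Position-by-position running-sum walk and its signed extremum."""
    n = len(scores)
    n_hit = sum(is_hit)
    total = sum(abs(scores[i]) ** weight_p for i in range(n) if is_hit[i])
    walk = []
    cur = 0.0
    for i in range(n):
        if is_hit[i]:
            cur += (abs(scores[i]) ** weight_p / total) if total > 0 else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        walk.append(cur)
    es = max(walk, key=abs)
    return es, walk


def km_oracle(times, events) -> list[tuple[float, float]]:
    """(event time, S) pairs from an explicit product of (1 - d/n)."""
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out = []
    for t in distinct:
        at_risk = sum(1 for ti in times if ti >= t)
        deaths = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def logrank_chi2_oracle(times, events, labels) -> float:
    """Two-group observed-minus-expected log-rank chi-square, by loop."""
    groups = sorted(set(labels))
    assert len(groups) == 2
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in distinct:
        n = sum(1 for ti in times if ti >= t)
        n1 = sum(1 for ti, li in zip(times, labels) if ti >= t and li == groups[0])
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        d1 = sum(1 for ti, ei, li in zip(times, events, labels)
                 if ti == t and ei == 1 and li == groups[0])
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def logrank_permutation_p(times, events, labels, n_perm, seed) -> float:
    """Permutation tail probability of the log-rank chi-square."""
    rng = np.random.default_rng(seed)
    obs = logrank_chi2_oracle(times, events, labels)
    labels = list(labels)
    count = 0
    for _ in range(n_perm):
        perm = list(rng.permutation(labels))
        if logrank_chi2_oracle(times, events, perm) >= obs - 1e-12:
            count += 1
    return count / n_perm


def mann_whitney_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided p by enumerating all C(n1+n2, n1) assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = average_ranks(pooled)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2)
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs + 1e-12) / total
    p_ge = sum(1 for u in us if u >= u_obs - 1e-12) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def spearman_oracle(x, y) -> float:
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def quantile_oracle(values, q) -> float:
    """Linear interpolation between order statistics (type-7 convention)."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def median_oracle(values) -> float:
    """Sort-and-pick-middle median."""
    xs = sorted(values)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2
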