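"""Independent brute-force oracles used to validate the package's statistics.

Everything here is deliberately written with plain loops and explicit
formulas, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# Simple Good-Turing reference (Gale & Sampson recipe, scalar arithmetic)
# ---------------------------------------------------------------------------

def sgt_reference(n_c: dict[int, int]):
    """Return (c_star, p0, s_star, p_star) for a count-of-counts spectrum.

    Scalar reimplementation of the Gale-Sampson procedure: Z-transform of
    the spectrum, least-squares log-log line fitted by hand, raw Turing
    estimates for low counts, switch to the smoothed line at the first
    count where |turing - smoothed| <= 1.65 sd or where n_{c+1} is absent,
    then renormalize to (1 - p0).
    """
    counts = sorted(n_c)
    S = sum(c * n_c[c] for c in counts)
    n1 = n_c.get(1, 0)
    p0 = n1 / S

    if len(counts) == 1:
        c = counts[0]
        c_star = {c: float(c)}
    else:
        # Z values with neighbor gaps
        z_log, c_log = [], []
        for idx, c in enumerate(counts):
            q = counts[idx - 1] if idx > 0 else 0
            t = counts[idx + 1] if idx + 1 < len(counts) else 2 * c - q
            z = n_c[c] / (0.5 * (t - q))
            c_log.append(math.log(c))
            z_log.append(math.log(z))
        # least squares by the textbook formulas
        k = len(counts)
        mean_x = sum(c_log) / k
        mean_y = sum(z_log) / k
        sxy = sum((x - mean_x) * (y - mean_y) for x, y in zip(c_log, z_log))
        sxx = sum((x - mean_x) ** 2 for x in c_log)
        slope = sxy / sxx
        c_star = {}
        use_smooth = False
        for c in counts:
            smooth = (c + 1) * ((c + 1) / c) ** slope
            if not use_smooth:
                if (c + 1) not in n_c:
                    use_smooth = True
                else:
                    nc, nc1 = n_c[c], n_c[c + 1]
                    turing = (c + 1) * nc1 / nc
                    sd = math.sqrt((c + 1) ** 2 * (nc1 / nc**2) * (1 + nc1 / nc))
                    if abs(turing - smooth) <= 1.65 * sd:
                        use_smooth = True
            c_star[c] = smooth if use_smooth else turing

    s_star = sum(n_c[c] * c_star[c] for c in counts)
    p_star = {c: (1 - p0) * c_star[c] / s_star for c in counts}
    return c_star, p0, s_star, p_star


# ---------------------------------------------------------------------------
# Exact Wilcoxon null distributions by full enumeration
# ---------------------------------------------------------------------------

def _average_ranks(values):
    """Average ranks of a sequence, ties shared (no library calls)."""
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


def signed_rank_enumeration(x1, x2):
    """(T_signed, p_greater, p_less) by enumerating all 2^n sign vectors.

    Zero differences dropped; |Z| ranked with average ranks; the null
    distribution is that of the positive-rank sum conditional on the
    observed rank multiset.
    """
    z = [a - b for a, b in zip(x1, x2) if a != b]
    n = len(z)
    if n == 0:
        return 0.0, 1.0, 1.0
    ranks = _average_ranks([abs(v) for v in z])
    t_signed = sum(r if v > 0 else -r for r, v in zip(ranks, z))
    w_obs = sum(r for r, v in zip(ranks, z) if v > 0)
    ge = le = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            ge += 1
        if w <= w_obs + 1e-12:
            le += 1
    total = 2**n
    return t_signed, ge / total, le / total


def rank_sum_enumeration(x1, x2):
    """(W, p_greater, p_less) by enumerating all C(n1+n2, n2) assignments.

    W is the sum of pooled ranks of x2 (sample B); p_greater (A enriched)
    is the lower tail of W.  Valid for tie-free inputs.
    """
    pooled = list(x1) + list(x2)
    ranks = _average_ranks(pooled)
    n1, n2 = len(x1), len(x2)
    w_obs = sum(ranks[n1:])
    lo = hi = total = 0
    for combo in itertools.combinations(range(n1 + n2), n2):
        w = sum(ranks[i] for i in combo)
        total += 1
        if w <= w_obs + 1e-12:
            lo += 1
        if w >= w_obs - 1e-12:
            hi += 1
    return w_obs, lo / total, hi / total


# ---------------------------------------------------------------------------
# Brute-force pattern rule application
# ---------------------------------------------------------------------------

def pattern_rules_reference(ders, genes_of, shift_threshold=1000):
    """Label dicts {'sample','center','start','genes'} by direct rule reading.

    For every DER: partners are other-sample DERs sharing a gene; no
    partner -> Only; nearest (|center - center|, then start) partner within
    shift_threshold -> Unchanged, else Shift.  Returns {index: label}.
    """
    labels = {}
    for i, der in enumerate(ders):
        partners = [
            (abs(der["center"] - other["center"]), other["start"], j)
            for j, other in enumerate(ders)
            if other["sample"] != der["sample"]
            and genes_of[j] & genes_of[i]
        ]
        if not partners:
            labels[i] = "Only"
        else:
            dist, _, _ = min(partners)
            labels[i] = "Unchanged" if dist <= shift_threshold else "Shift"
    return labels
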