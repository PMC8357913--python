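"""Independently coded reference implementations used only by tests.

These are deliberately written with scalar Python loops and the standard
library / textbook formulas, so they share no code path with the package.
"""

import math
import statistics


def _med(values):
    vals = [v for v in values if v is not None and not math.isnan(v)]
    return statistics.median(vals) if vals else None


def oracle_median_polish(mat, tol=1e-10, max_iter=500):
    """Iterative two-way median polish, scalar implementation.

    Same sweep convention as the package (row sweep first, overall absorbs
    the median of the opposite effects after each sweep); returns
    (overall, row_effects, col_effects) with NaN column effects for columns
    with no data.
    """
    rows = len(mat)
    cols = len(mat[0])
    z = [[(None if v is None or math.isnan(v) else float(v)) for v in row]
         for row in mat]
    t = 0.0
    r = [0.0] * rows
    c = [0.0] * cols
    # columns with no data at all get NaN effects
    dead_col = [all(z[i][j] is None for i in range(rows)) for j in range(cols)]
    for j in range(cols):
        if dead_col[j]:
            c[j] = math.nan
    for _ in range(max_iter):
        delta = 0.0
        for i in range(rows):
            m = _med(z[i])
            m = 0.0 if m is None else m
            for j in range(cols):
                if z[i][j] is not None:
                    z[i][j] -= m
            r[i] += m
            delta = max(delta, abs(m))
        d_c = _med([x for x in c if not math.isnan(x)])
        d_c = 0.0 if d_c is None else d_c
        t += d_c
        for j in range(cols):
            c[j] -= d_c
        delta = max(delta, abs(d_c))
        for j in range(cols):
            if dead_col[j]:
                continue
            m = _med([z[i][j] for i in range(rows)])
            m = 0.0 if m is None else m
            for i in range(rows):
                if z[i][j] is not None:
                    z[i][j] -= m
            c[j] += m
            delta = max(delta, abs(m))
        d_r = _med(r)
        d_r = 0.0 if d_r is None else d_r
        t += d_r
        for i in range(rows):
            r[i] -= d_r
        delta = max(delta, abs(d_r))
        if delta < tol:
            break
    return t, r, c


def oracle_bh(pvalues):
    """Benjamini-Hochberg by the step-up definition: q_(i) = min_{j>=i} p_(j)m/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        best = min(pvalues[order[j - 1]] * m / j for j in range(rank, m + 1))
        q[idx] = min(best, 1.0)
    return q


def oracle_pearson(x, y):
    """Pearson r from raw sums (brute-force covariance)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def oracle_hypergeom_upper(k, N, K, n):
    """P(X >= k) for X hypergeometric(N, K, n) by exhaustive summation."""
    total = 0.0
    for kk in range(k, min(K, n) + 1):
        total += (math.comb(K, kk) * math.comb(N - K, n - kk)) / math.comb(N, n)
    return min(total, 1.0)


def oracle_pooled_t(a, b):
    """Two-sample pooled-variance t test: (t, df, two-sided p) via textbook formulas."""
    import scipy.stats as st
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = ss / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df, 2 * st.t.sf(abs(t), df)
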