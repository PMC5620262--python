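"""Independent straight-from-formula reference implementations.

Plain-Python loops, no shared code with the package, used to cross-check the
pooling and rank-correlation machinery on small random inputs.
"""

import math

from scipy import stats


def oracle_iv(log_ors, ses):
    """Inverse-variance fixed pooled log OR and SE."""
    num = den = 0.0
    for t, s in zip(log_ors, ses):
        w = 1.0 / (s * s)
        num += w * t
        den += w
    return num / den, math.sqrt(1.0 / den)


def oracle_q_tau2(log_ors, ses):
    """Cochran Q, its P, and the DerSimonian-Laird tau^2."""
    mean, _ = oracle_iv(log_ors, ses)
    q = sw = sw2 = 0.0
    for t, s in zip(log_ors, ses):
        w = 1.0 / (s * s)
        q += w * (t - mean) ** 2
        sw += w
        sw2 += w * w
    df = len(log_ors) - 1
    p = stats.chi2.sf(q, df) if df > 0 else 1.0
    tau2 = max(0.0, (q - df) / (sw - sw2 / sw)) if df > 0 else 0.0
    return q, p, tau2


def oracle_dl(log_ors, ses):
    """DerSimonian-Laird random-effects pooled log OR and SE."""
    _, _, tau2 = oracle_q_tau2(log_ors, ses)
    num = den = 0.0
    for t, s in zip(log_ors, ses):
        w = 1.0 / (s * s + tau2)
        num += w * t
        den += w
    return num / den, math.sqrt(1.0 / den)


def oracle_mh(cells):
    """Mantel-Haenszel pooled log OR with the Robins-Breslow-Greenland SE.

    ``cells`` is a sequence of (a, b, c, d) tuples.
    """
    r = s = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        r += a * d / n
        s += b * c / n
    log_or = math.log(r / s)
    t1 = t2 = t3 = 0.0
    for a, b, c, d in cells:
        n = a + b + c + d
        p = (a + d) / n
        q = (b + c) / n
        t1 += p * (a * d / n)
        t2 += p * (b * c / n) + q * (a * d / n)
        t3 += q * (b * c / n)
    var = t1 / (2 * r * r) + t2 / (2 * r * s) + t3 / (2 * s * s)
    return log_or, math.sqrt(var)


def oracle_kendall_score(u, v):
    """Kendall's S by exhaustive pair enumeration."""
    s = 0
    k = len(u)
    for i in range(k):
        for j in range(i + 1, k):
            du = u[j] - u[i]
            dv = v[j] - v[i]
            if du * dv > 0:
                s += 1
            elif du * dv < 0:
                s -= 1
    return s


def oracle_egger(log_ors, ses):
    """Egger intercept t-statistic via explicit normal equations."""
    y = [t / s for t, s in zip(log_ors, ses)]
    x = [1.0 / s for s in ses]
    k = len(y)
    xbar = sum(x) / k
    ybar = sum(y) / k
    sxx = sum((xi - xbar) ** 2 for xi in x)
    sxy = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = sum((yi - intercept - slope * xi) ** 2 for xi, yi in zip(x, y))
    sigma2 = rss / (k - 2)
    se_int = math.sqrt(sigma2 * (1.0 / k + xbar * xbar / sxx))
    t = intercept / se_int
    return intercept, t, 2.0 * stats.t.sf(abs(t), k - 2)
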