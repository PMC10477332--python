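"""Naive loop-based reference implementations of every scalar feature.

Deliberately slow and literal (nested Python loops, explicit DFT sums) so
they are independent of the vectorized/jitted implementations they check.
Only intended for short series (n <= a few hundred).
"""
import cmath
import math


def apen_naive(x, m, r):
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        cnt = n - mm + 1
        templates = [x[i:i + mm] for i in range(cnt)]
        total = 0.0
        for a in templates:
            c = 0
            for b in templates:
                if max(abs(u - v) for u, v in zip(a, b)) <= r:
                    c += 1
            total += math.log(c / cnt)
        return total / cnt

    return phi(m) - phi(m + 1)


def _dft(x):
    n = len(x)
    return [sum(x[t] * cmath.exp(-2j * cmath.pi * k * t / n)
                for t in range(n)) for k in range(n)]


def psd_mean_naive(x):
    x = list(map(float, x))
    spec = _dft(x)
    return sum(abs(v) ** 2 for v in spec) / len(x)


def hjorth_naive(x):
    x = list(map(float, x))

    def var(s):
        mu = sum(s) / len(s)
        return sum((v - mu) ** 2 for v in s) / len(s)

    d1 = [b - a for a, b in zip(x, x[1:])]
    d2 = [b - a for a, b in zip(d1, d1[1:])]
    activity = var(x)
    mobility = math.sqrt(var(d1) / var(x))
    if var(d1) == 0:
        return activity, mobility, 0.0
    complexity = math.sqrt(var(d2) / var(d1)) / mobility
    return activity, mobility, complexity


def c0_naive(x):
    x = list(map(float, x))
    n = len(x)
    spec = _dft(x)
    powers = [abs(v) ** 2 for v in spec]
    mean_p = sum(powers) / n
    kept = [v if p > mean_p else 0.0 for v, p in zip(spec, powers)]
    y = [sum(kept[k] * cmath.exp(2j * cmath.pi * k * t / n)
             for k in range(n)) / n for t in range(n)]
    num = sum(abs(a - b) ** 2 for a, b in zip(x, y))
    den = sum(v ** 2 for v in x)
    return num / den


def higuchi_naive(x, kmax):
    x = list(map(float, x))
    n = len(x)
    log_l, log_inv_t = [], []
    for k in range(1, kmax + 1):
        lk = 0.0
        for m0 in range(k):
            steps = (n - 1 - m0) // k
            if steps < 1:
                continue
            dist = sum(abs(x[m0 + i * k] - x[m0 + (i - 1) * k])
                       for i in range(1, steps + 1))
            lk += dist * (n - 1) / (steps * k) / k
        log_l.append(math.log(lk / k))
        log_inv_t.append(math.log(1.0 / k))
    # least-squares slope
    mt = sum(log_inv_t) / len(log_inv_t)
    ml = sum(log_l) / len(log_l)
    num = sum((t - mt) * (l - ml) for t, l in zip(log_inv_t, log_l))
    den = sum((t - mt) ** 2 for t in log_inv_t)
    return num / den
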