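"""Independent brute-force oracles used to pin down expected values.

Everything here is written as plain scalar loops, deliberately sharing no
code with the package implementation.
"""

import math


def _pstd(xs):
    mu = sum(xs) / len(xs)
    return math.sqrt(sum((v - mu) ** 2 for v in xs) / len(xs))


def _cheb(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def sample_entropy_oracle(x, m=2, r=None, r_factor=0.2):
    """Exhaustive template-pair counting for sample entropy."""
    x = [float(v) for v in x]
    n = len(x)
    if r is None:
        r = r_factor * _pstd(x)
    n_templ = n - m
    tm = [x[i:i + m] for i in range(n_templ)]
    tm1 = [x[i:i + m + 1] for i in range(n_templ)]
    a = b = 0
    for i in range(n_templ):
        for j in range(i + 1, n_templ):
            if _cheb(tm[i], tm[j]) < r:
                b += 1
            if _cheb(tm1[i], tm1[j]) < r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def fuzzy_entropy_oracle(x, m=2, n_fuzzy=2, r=None, r_factor=0.15):
    """Exhaustive membership-sum evaluation for fuzzy entropy."""
    x = [float(v) for v in x]
    n = len(x)
    if r is None:
        r = r_factor * _pstd(x)

    def phi(dim):
        templ = []
        for i in range(n - m):
            t = x[i:i + dim]
            mu = sum(t) / dim
            templ.append([v - mu for v in t])
        total = 0.0
        count = 0
        for i in range(len(templ)):
            for j in range(i + 1, len(templ)):
                total += math.exp(-((_cheb(templ[i], templ[j]) / r)
                                    ** n_fuzzy))
                count += 1
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def permutation_entropy_patterns(x, m, tau=1):
    """Ordinal-pattern counts with stable (order-of-occurrence) tie-break."""
    x = [float(v) for v in x]
    counts = {}
    for i in range(len(x) - (m - 1) * tau):
        window = [x[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def permutation_entropy_oracle(x, m=4, tau=1, normalized=True):
    counts = permutation_entropy_patterns(x, m, tau)
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    if normalized:
        return h / math.log(math.factorial(m))
    return h


def pe_energy_oracle(x, m=3, segments=10, tau=1):
    """Total and relative permutation-entropy energy by direct evaluation."""
    x = [float(v) for v in x]
    seg_len = len(x) // segments
    total = 0.0
    for k in range(segments):
        total += permutation_entropy_oracle(
            x[k * seg_len:(k + 1) * seg_len], m, tau, normalized=False)
    whole = permutation_entropy_oracle(x, m, tau, normalized=False)
    return total, whole / total


def hurst_rr_oracle(x, scales):
    """Step-by-step range-response evaluation: per segment the cumulative
    deviate range R and population std S; feature = min over scales of the
    mean R (S = 0 segments excluded)."""
    x = [float(v) for v in x]
    scale_means = []
    for s in scales:
        n_seg = len(x) // s
        ranges = []
        for k in range(n_seg):
            seg = x[k * s:(k + 1) * s]
            mu = sum(seg) / s
            dev = [v - mu for v in seg]
            z, acc = [], 0.0
            for v in dev:
                acc += v
                z.append(acc)
            r = max(z) - min(z)
            sd = math.sqrt(sum(v * v for v in dev) / s)
            if sd > 0:
                ranges.append(r)
        if ranges:
            scale_means.append(sum(ranges) / len(ranges))
    return min(scale_means)


def tuned_index_rollout(raw_values, w_prev=0.8, w_cur=0.2, history=4):
    """Scalar roll-out of the output smoother over a raw-value sequence."""
    hist, out = [], []
    for raw in raw_values:
        if not hist:
            t = raw
        else:
            t = w_prev * (sum(hist) / len(hist)) + w_cur * raw
        t = min(max(t, 0.0), 100.0)
        out.append(t)
        hist = (hist + [raw])[-history:]
    return out


def pearson_oracle(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den
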