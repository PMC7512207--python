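"""Independent brute-force oracles, deliberately written without numpy
vectorization or any code shared with the package implementation."""

import math


def sampen_oracle(x, m, r):
    """Plain double-loop template counting; returns (bm, bm1, value or None)."""
    x = list(map(float, x))
    nvec = len(x) - m
    bm = bm1 = 0
    for i in range(nvec):
        for j in range(nvec):
            if i == j:
                continue
            d = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d < r:
                bm += 1
                d1 = max(d, abs(x[i + m] - x[j + m]))
                if d1 < r:
                    bm1 += 1
    if bm == 0 or bm1 == 0:
        return bm, bm1, None
    return bm, bm1, -math.log(bm1 / bm)


def fuzzyen_oracle(x, m, r, n):
    """Direct evaluation of the mean-centred exponential-similarity entropy.

    Both template lengths use the same nvec = N - m templates.
    """
    x = list(map(float, x))
    nvec = len(x) - m

    def phi(mlen):
        templates = []
        for i in range(nvec):
            mu = sum(x[i:i + mlen]) / mlen
            templates.append([x[i + k] - mu for k in range(mlen)])
        total = 0.0
        for i in range(nvec):
            s = 0.0
            for j in range(nvec):
                if j == i:
                    continue
                d = max(abs(a - b)
                        for a, b in zip(templates[i], templates[j]))
                s += math.exp(-(d ** n) / r)
            total += s / (nvec - 1)
        return total / nvec

    return math.log(phi(m)) - math.log(phi(m + 1))


def lz76_oracle(bits):
    """Exhaustive Lempel-Ziv production parsing: each component is the
    shortest prefix-novel substring (search window allows overlap)."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = 0
    i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def su_oracle(counts):
    """Symmetrical uncertainty from a {(a, b): count} contingency table,
    via direct probability arithmetic (base-2 logs)."""
    total = sum(counts.values())
    pa = {}
    pb = {}
    for (a, b), c in counts.items():
        pa[a] = pa.get(a, 0) + c / total
        pb[b] = pb.get(b, 0) + c / total

    def h(dist):
        return -sum(p * math.log2(p) for p in dist if p > 0)

    ha = h(pa.values())
    hb = h(pb.values())
    hab = h(c / total for c in counts.values())
    if ha + hb == 0:
        return 0.0
    return 2.0 * (ha + hb - hab) / (ha + hb)
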