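"""Independent brute-force reference implementations used only by tests.

Deliberately naive (explicit loops, no shared code with the package) so
they can serve as oracles for the vectorised implementations.
"""

from __future__ import annotations

import math


def naive_movmean3(areas):
    n = len(areas)
    out = []
    for i in range(n):
        window = [areas[j] for j in (i - 1, i, i + 1) if 0 <= j < n]
        out.append(sum(window) / len(window))
    return out


def naive_ratios(areas):
    means = naive_movmean3(areas)
    return [a / m for a, m in zip(areas, means)]


def naive_prominence(areas):
    r = naive_ratios(areas)
    mean = sum(r) / len(r)
    return math.sqrt(sum((v - mean) ** 2 for v in r) / (len(r) - 1))


def naive_expansion(areas):
    means = naive_movmean3(areas)
    return max(means) / ((areas[0] + areas[-1]) / 2.0)


def naive_ks_d(x, y):
    """Double-loop ECDF-difference enumeration over all pooled points."""
    best = 0.0
    for point in list(x) + list(y):
        fx = sum(1 for v in x if v <= point) / len(x)
        fy = sum(1 for v in y if v <= point) / len(y)
        best = max(best, abs(fx - fy))
    return best
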