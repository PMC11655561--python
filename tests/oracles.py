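"""Independent brute-force oracles used to check the implementation.

These are deliberately naive (loops, literal definitions) and share no code
with the package.
"""

from __future__ import annotations

import numpy as np


def point_in_polygon(x: float, y: float, vertices: np.ndarray) -> bool:
    """Ray-casting membership test (even-odd rule), boundary not guaranteed."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    inside = False
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: q_(i) = min_{j >= i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def brute_anova_f(samples: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F from the definition, no shortcuts."""
    all_values = np.concatenate([np.asarray(s, float) for s in samples])
    grand = all_values.mean()
    ssb = 0.0
    ssw = 0.0
    for s in samples:
        s = np.asarray(s, float)
        ssb += len(s) * (s.mean() - grand) ** 2
        for v in s:
            ssw += (v - s.mean()) ** 2
    k = len(samples)
    n = len(all_values)
    return (ssb / (k - 1)) / (ssw / (n - k)), k - 1, n - k
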