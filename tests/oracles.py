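"""Independent brute-force oracles used to check the library implementations.

Everything here is written from the defining formulas with plain Python
loops (or a geometrically explicit construction, for hulls) and shares no
code path with the package.
"""

from __future__ import annotations

import numpy as np

ORDER = "ARNDCQEGHILKMFPSTWYV"


def brute_natural_vector(sequence: str) -> np.ndarray:
    """60-vector from explicit loops: counts, mean 1-based positions, D2."""
    n = len(sequence)
    counts, means, moments = [], [], []
    for k in ORDER:
        pos = [i + 1 for i, ch in enumerate(sequence) if ch == k]
        nk = len(pos)
        if nk == 0:
            counts.append(0.0)
            means.append(0.0)
            moments.append(0.0)
            continue
        mu = sum(pos) / nk
        d2 = sum((p - mu) ** 2 for p in pos) / (nk * n)
        counts.append(float(nk))
        means.append(mu)
        moments.append(d2)
    return np.array(counts + means + moments)


def brute_central_moment(positions, j, n) -> float:
    nk = len(positions)
    mu = sum(positions) / nk
    return sum((p - mu) ** j for p in positions) / (nk ** (j - 1) * n ** (j - 1))


def brute_apf(sequence: str, table: dict[str, list[float]]) -> np.ndarray:
    """Per-residue accumulation of the ten factor values."""
    acc = np.zeros(10)
    for ch in sequence:
        acc += np.asarray(table[ch])
    return acc / len(sequence)


def convex_polygon_contains(point, vertices, tol=1e-9) -> bool:
    """2-D containment by cross products against a counterclockwise polygon."""
    p = np.asarray(point, dtype=float)
    v = np.asarray(vertices, dtype=float)
    m = len(v)
    for i in range(m):
        a, b = v[i], v[(i + 1) % m]
        cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
        if cross < -tol:
            return False
    return True


def facet_hull_contains(point, generators, tol=1e-9) -> bool:
    """Containment via explicit facet inequalities from qhull (2-D/3-D use)."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(np.asarray(generators, dtype=float))
    p = np.asarray(point, dtype=float)
    return bool(np.all(hull.equations[:, :-1] @ p + hull.equations[:, -1] <= tol))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ORDER), size=length))
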