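"""Convex-hull exclusivity classification of feature points.

Each structural class defines the convex hull of its feature points.  A
query point p is a member of a class's hull iff it is a convex combination
of that class's points: there exist lambda >= 0 with sum(lambda) = 1 and
||G^T lambda - p||_inf <= tol, where G stacks the class's generator points.
Membership is decided directly as this linear feasibility problem (one
small LP per query, solved with HiGHS) — no facet construction, which would
be hopeless in 10 dimensions with thousands of generators.  Boundary points
count as inside; the coordinatewise tolerance (default 1e-8) absorbs
floating-point slack, and loosening it can only add members.

The per-class exclusivity rate is C_i = A_i / N_i where A_i counts the
class-i points lying in their own hull and in no other class's hull.
Because every class point is a generator of its own hull, own-class
membership holds by construction; separation is therefore governed entirely
by cross-class memberships.  High-dimensional feature spaces are analyzed
block-by-block (width-10 column blocks) since hull separation weakens as
dimension grows much faster than sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .feature_table import FeatureMatrix
from .rates import ClassRate, RatesTable

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-8


@dataclass
class HullMembership:
    """Boolean membership of every point in every class hull."""

    matrix: np.ndarray  # (n_points, n_classes) booleans
    class_order: list[str]
    point_labels: list[str]
    tol: float


def hull_distance(point: Sequence[float], generators: np.ndarray) -> float:
    """Minimal sup-norm distance from ``point`` to the generators' convex hull.

    Solved as one LP over (lambda, t): minimize t subject to
    |G^T lambda - p| <= t, sum(lambda) = 1, lambda >= 0.  Zero (up to solver
    precision) means the point is inside or on the boundary.
    """
    p = np.asarray(point, dtype=float).ravel()
    G = np.atleast_2d(np.asarray(generators, dtype=float))
    if G.shape[0] < 1:
        raise ValueError("need at least one generator")
    if G.shape[1] != p.size:
        raise ValueError(f"dimension mismatch: point {p.size}, generators {G.shape[1]}")
    m, d = G.shape
    # Fast path: an exact generator match.
    if np.any(np.all(G == p, axis=1)):
        return 0.0
    # variables: lambda (m), t (1)
    ones_t = np.ones((d, 1))
    A_ub = np.block([[G.T, -ones_t], [-G.T, -ones_t]])
    b_ub = np.concatenate([p, -p])
    A_eq = np.concatenate([np.ones(m), [0.0]])[None, :]
    c = np.zeros(m + 1)
    c[-1] = 1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0.0, 1.0)] * m + [(0.0, None)],
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"hull-distance LP failed: {res.message}")
    return float(max(res.fun, 0.0))


def in_hull(
    point: Sequence[float],
    generators: np.ndarray,
    tol: float = DEFAULT_TOL,
) -> bool:
    """True iff ``point`` is within ``tol`` (sup-norm) of the generators' hull.

    Decided by thresholding the hull distance, so loosening ``tol`` can only
    turn non-members into members, never the reverse.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    return hull_distance(point, generators) <= tol


def membership_matrix(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str] | None = None,
    tol: float = DEFAULT_TOL,
    class_order: Sequence[str] | None = None,
) -> HullMembership:
    """Hull membership of every point against every class's generator set.

    A point's own-class entry is asserted true without recomputation (it is
    a generator of that hull).
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        labels = labels if labels is not None else features.labels
    else:
        X = np.asarray(features, dtype=float)
    if labels is None:
        raise ValueError("labels are required")
    labels = list(labels)
    if class_order is None:
        order: dict[str, None] = {}
        for lab in labels:
            order.setdefault(lab, None)
        class_order = list(order)
    else:
        class_order = list(class_order)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    lab_arr = np.asarray(labels)
    member = np.zeros((X.shape[0], len(class_order)), dtype=bool)
    for j, cls in enumerate(class_order):
        G = X[lab_arr == cls]
        for i in range(X.shape[0]):
            if labels[i] == cls:
                member[i, j] = True
            else:
                member[i, j] = in_hull(X[i], G, tol)
    return HullMembership(member, class_order, labels, tol)


def hull_rates(
    membership: HullMembership,
    method: str = "features",
    block: str | None = None,
) -> RatesTable:
    """Exclusivity rates C_i = A_i / N_i from a membership matrix."""
    rates = []
    member = membership.matrix
    lab_arr = np.asarray(membership.point_labels)
    for j, cls in enumerate(membership.class_order):
        mask = lab_arr == cls
        n_i = int(mask.sum())
        if n_i == 0:
            continue
        others = np.delete(member[mask], j, axis=1)
        exclusive = member[mask, j] & ~others.any(axis=1)
        rates.append(ClassRate(cls, int(exclusive.sum()), n_i))
    return RatesTable(method=method, classifier="hull", rates=rates, block=block)


def hull_rates_by_block(
    features: FeatureMatrix,
    block_size: int = 10,
    tol: float = DEFAULT_TOL,
    method: str = "features",
) -> list[RatesTable]:
    """Partition a feature matrix into column blocks and rate each block."""
    from .feature_table import partition_features

    out = []
    for spec, sub in partition_features(features, block_size):
        membership = membership_matrix(sub, tol=tol)
        out.append(hull_rates(membership, method=method, block=spec.name))
    return out
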