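"""The 13 morphometric features and the Sholl profile.

Size and topology metrics (lengths, surface area, branch counts, branch
orders), directional statistics of the arbor (root angles and their von
Mises-Fisher concentration, the *centripetal bias*), and convex-hull
geometry (area, volume, sphericity).

Branch-order convention: a primary process (emerging from the soma) has
order 0; at a bifurcation both daughters advance one order; a single-child
continuation keeps its order.  First/second-order counts are counts of
processes at orders 1 and 2.

The root angle at a point is the angle between the root-ward tangent (the
local path direction toward the parent) and the straight line from the
point to the soma root, so a straight, radially growing neurite scores 0
everywhere.  The centripetal bias is the concentration of a von
Mises-Fisher distribution on the unit sphere fitted to the root angles with
mean direction fixed at angle 0 (roughly the inverse variance of the
angular distribution): large for narrow, soma-directed trees.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .features import MORPH_FEATURES, FeatureVector
from .morphology import Morphology

KAPPA_MAX = 1e3
MIN_ANGLES = 10


def tree_metrics(m: Morphology) -> FeatureVector:
    """Lengths, surface area, primary/branch/order counts.

    Segment lengths are parent-child Euclidean distances over non-soma
    segments; the surface area sums frustum lateral areas pi*(r_p+r_c)*slant
    (the soma surface itself is excluded, and a segment leaving the soma is
    treated as a cylinder of the child's radius).
    """
    out = FeatureVector(registry=MORPH_FEATURES)
    arr = m.segment_arrays()
    slant = arr["length"]
    r_p = np.where(arr["soma_parent"], arr["r_child"], arr["r_parent"])
    total_length = float(np.sum(slant))
    total_area = float(np.sum(math.pi * (r_p + arr["r_child"]) * slant))

    n_primary = sum(
        1
        for n in m.nodes
        if m.is_soma(n)
        for c in m.children(n.id)
        if not m.is_soma(c)
    )
    n_branch = sum(
        1
        for n in m.nodes
        if not m.is_soma(n)
        and len([c for c in m.children(n.id) if not m.is_soma(c)]) >= 2
    )

    # branch-order bookkeeping: walk processes from the soma
    order_counts: dict[int, int] = {}
    stack: list[tuple[int, int]] = []  # (node id at process start, order)
    for n in m.nodes:
        if m.is_soma(n):
            for c in m.children(n.id):
                if not m.is_soma(c):
                    stack.append((c.id, 0))
    while stack:
        nid, order = stack.pop()
        order_counts[order] = order_counts.get(order, 0) + 1
        cur = nid
        while True:
            kids = [c for c in m.children(cur) if not m.is_soma(c)]
            if len(kids) == 1:
                cur = kids[0].id
            elif len(kids) >= 2:
                for k in kids:
                    stack.append((k.id, order + 1))
                break
            else:
                break

    out.set("total_length", total_length)
    out.set("total_area", total_area)
    out.set("n_primary", n_primary)
    out.set("n_branch_points", n_branch)
    out.set("n_first_order", order_counts.get(1, 0))
    out.set("n_second_order", order_counts.get(2, 0))
    if n_primary > 0:
        out.set("length_normalized", total_length / n_primary)
        out.set("branch_points_normalized", n_branch / n_primary)
    else:
        out.set_missing("length_normalized", "no primary processes")
        out.set_missing("branch_points_normalized", "no primary processes")
    return out


def _resample_offsets(length: float, step: float) -> np.ndarray:
    """Midpoint-convention sample offsets along a segment of given length."""
    if length <= 0:
        return np.empty(0)
    n = max(1, int(length / step))
    return (np.arange(n) + 0.5) * (length / n)


def root_angles(m: Morphology, resample_step: float = 1.0) -> np.ndarray:
    """Root angles (rad, in [0, pi]) at points resampled every
    ``resample_step`` micrometres along all neurite segments."""
    if resample_step <= 0:
        raise ValueError("resample_step must be positive")
    soma = m.root.xyz
    arr = m.segment_arrays()
    length = arr["length"]
    keep = length > 0
    if not np.any(keep):
        return np.empty(0)
    P, C, length = arr["parent"][keep], arr["child"][keep], length[keep]
    unit = (C - P) / length[:, None]
    # points every resample_step along each segment, measured from the
    # segment's proximal node
    n_pts = np.maximum(np.ceil(length / resample_step - 1e-12).astype(int), 1)
    seg_idx = np.repeat(np.arange(len(length)), n_pts)
    within = (np.arange(n_pts.sum()) - np.repeat(np.cumsum(n_pts) - n_pts, n_pts))
    offs = within * resample_step
    pts = P[seg_idx] + unit[seg_idx] * offs[:, None]
    to_soma = soma[None, :] - pts
    dist = np.linalg.norm(to_soma, axis=1)
    ok = dist > 1e-9
    cosang = np.einsum("ij,ij->i", to_soma[ok], -unit[seg_idx][ok]) / dist[ok]
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def centripetal_bias(angles: np.ndarray) -> float:
    """von Mises-Fisher concentration of root angles about direction 0.

    Fisher's closed-form estimator from the mean resultant length
    rbar = mean(cos theta):  kappa = rbar*(3 - rbar^2)/(1 - rbar^2),
    clamped to [0, 1e3]; non-positive rbar gives 0.

    Raises ValueError for fewer than 10 angles.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < MIN_ANGLES:
        raise ValueError(f"need at least {MIN_ANGLES} angles, got {angles.size}")
    rbar = float(np.mean(np.cos(angles)))
    if rbar <= 0:
        return 0.0
    if rbar >= 1.0:
        return KAPPA_MAX
    kappa = rbar * (3.0 - rbar**2) / (1.0 - rbar**2)
    return float(np.clip(kappa, 0.0, KAPPA_MAX))


def hull_metrics(points: np.ndarray) -> tuple[float, float, float]:
    """(area, volume, sphericity) of the 3-D convex hull of a point set.

    Sphericity is the surface area of the sphere having the hull's volume
    divided by the hull's surface area: pi^(1/3)*(6V)^(2/3)/A, which is 1
    for a sphere and smaller for any other shape.  Raises
    :class:`scipy.spatial.QhullError` for degenerate (coplanar) inputs.
    """
    points = np.asarray(points, float)
    if points.shape[0] < 4:
        raise QhullError("fewer than 4 points")
    hull = ConvexHull(points)
    area = float(hull.area)
    volume = float(hull.volume)
    sphericity = math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area
    return area, volume, sphericity


def convex_hull_metrics(m: Morphology) -> FeatureVector:
    """Convex-hull area, volume and sphericity over all node coordinates."""
    out = FeatureVector(registry=MORPH_FEATURES)
    try:
        area, volume, sphericity = hull_metrics(m.coordinates())
    except QhullError:
        for n in ("hull_area", "hull_volume", "sphericity"):
            out.set_missing(n, "degenerate point set (coplanar or too few points)")
        return out
    out.set("hull_area", area)
    out.set("hull_volume", volume)
    out.set("sphericity", sphericity)
    return out


def sholl_profile(
    m: Morphology, step: float = 10.0, resample_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sholl intersections every ``step`` micrometres from the root.

    Counts, for each shell radius, the sign changes of (distance-to-root -
    radius) along neurite paths resampled at ``resample_step``.
    Returns (radii, counts); all-zero counts for a soma-only tree.
    """
    soma = m.root.xyz
    arr = m.segment_arrays()
    length = arr["length"]
    keep = length > 0
    if not np.any(keep):
        return np.array([step]), np.array([0])
    P, C, length = arr["parent"][keep], arr["child"][keep], length[keep]
    unit = (C - P) / length[:, None]
    los, his = [], []
    for i in range(len(length)):
        offs = np.concatenate([[0.0], _resample_offsets(float(length[i]), resample_step),
                               [float(length[i])]])
        d = np.linalg.norm(P[i][None, :] + np.outer(offs, unit[i]) - soma[None, :], axis=1)
        los.append(np.minimum(d[:-1], d[1:]))
        his.append(np.maximum(d[:-1], d[1:]))
    lo = np.concatenate(los)
    hi = np.concatenate(his)
    dmax = float(hi.max())
    radii = np.arange(step, dmax + step, step)
    # an interval (lo, hi] crosses shells k with lo < k*step <= hi
    kmin = np.floor(lo / step + 1e-12).astype(int) + 1
    kmax = np.floor(hi / step + 1e-12).astype(int)
    counts = np.zeros(radii.size + 1, dtype=int)
    valid = kmax >= kmin
    np.add.at(counts, kmin[valid] - 1, 1)
    ends = kmax[valid]
    np.add.at(counts, np.minimum(ends, radii.size), -1)
    counts = np.cumsum(counts)[:radii.size]
    return radii, counts.astype(int)


def extract_morph_features(m: Morphology, resample_step: float = 1.0) -> FeatureVector:
    """All 13 morphometric features; per-feature missing markers propagate."""
    out = tree_metrics(m)
    angles = root_angles(m, resample_step)
    if angles.size == 0:
        out.set_missing("mean_root_angle", "no neurite points")
    else:
        out.set("mean_root_angle", float(np.mean(angles)))
    try:
        out.set("centripetal_bias", centripetal_bias(angles))
    except ValueError:
        out.set_missing("centripetal_bias", f"fewer than {MIN_ANGLES} root angles")
    hull = convex_hull_metrics(m)
    for name in ("hull_area", "hull_volume", "sphericity"):
        if name in hull.reasons:
            out.set_missing(name, hull.reasons[name])
        else:
            out.set(name, hull[name])
    return out
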