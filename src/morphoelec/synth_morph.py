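"""Stochastic multipolar neuronal-tree generator.

Trees grow from a soma at the origin: ``n_primary`` trunks start in random
directions and elongate in fixed-length segments whose orientations are
drawn from a von Mises-Fisher distribution about the current radial
(soma-to-tip) direction with concentration ``kappa``; branch events are
pre-scheduled along the length budget (an unbiased dithered count), so
branch-point totals are exactly calibrated; growth is confined to an
oblate spheroid (equatorial radius ``max_extent``, polar radius
``z_scale * max_extent``) whose flattening controls how spherical the
arbor's convex hull is without reshaping the direction distribution.
Steps that would leave the volume are re-drawn or reflected off the
boundary, so recorded segment lengths stay exact.

The generator returns the tree plus a bookkeeping record of exact ground
truth (total length, primary/branch counts, the generating kappa).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology, Node, SOMA_TYPE

NEURITE_TYPE = 3


@dataclass
class MorphGenParams:
    """Growth-model parameters (lengths in micrometres)."""

    n_primary: int = 4
    total_length: float = 1500.0   # length budget for the whole tree
    segment_length: float = 1.0
    branch_rate: float = 0.005     # expected branch points per micrometre
    kappa: float = 15.0            # orientation concentration about radial
    radius: float = 0.5            # neurite radius (constant)
    taper: float = 0.0             # radius loss per micrometre of path
    max_extent: float = 150.0      # equatorial radius of the growth volume
    z_scale: float = 1.0           # polar/equatorial axis ratio (<1 = flatter)
    soma_radius: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_primary < 1 or self.total_length <= 0 or self.segment_length <= 0:
            raise ValueError("n_primary, total_length and segment_length must be positive")
        if self.kappa < 0 or self.branch_rate < 0 or not (0 < self.z_scale <= 1):
            raise ValueError("kappa, branch_rate must be >= 0 and 0 < z_scale <= 1")


@dataclass
class MorphGroundTruth:
    total_length: float
    n_primary: int
    n_branch_points: int
    kappa: float
    n_segments: int = 0
    params: MorphGenParams | None = field(default=None, repr=False)


def sample_vmf(mean: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One unit vector from a von Mises-Fisher distribution on the 2-sphere."""
    mx, my, mz = (float(x) for x in mean)
    nrm = math.sqrt(mx * mx + my * my + mz * mz)
    if kappa < 1e-9 or nrm == 0.0:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)
    mx, my, mz = mx / nrm, my / nrm, mz / nrm
    # inverse-CDF sample of w = cos(angle to mean)
    u = rng.random()
    w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    phi = rng.random() * 2.0 * math.pi
    s = math.sqrt(max(1.0 - w * w, 0.0))
    # orthonormal frame about the mean
    hx, hy, hz = (1.0, 0.0, 0.0) if abs(mx) < 0.9 else (0.0, 1.0, 0.0)
    e1x, e1y, e1z = my * hz - mz * hy, mz * hx - mx * hz, mx * hy - my * hx
    n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
    e2x, e2y, e2z = my * e1z - mz * e1y, mz * e1x - mx * e1z, mx * e1y - my * e1x
    c, sn = math.cos(phi), math.sin(phi)
    return np.array(
        [
            w * mx + s * (c * e1x + sn * e2x),
            w * my + s * (c * e1y + sn * e2y),
            w * mz + s * (c * e1z + sn * e2z),
        ]
    )


def grow_morphology(
    params: MorphGenParams, rng: np.random.Generator | None = None
) -> tuple[Morphology, MorphGroundTruth]:
    """Grow one tree; deterministic for a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    for attempt in range(5):
        result = _grow_once(params, rng)
        if result is not None:
            return result
    raise RuntimeError("tree generation produced no segments after 5 attempts")


def _grow_once(params: MorphGenParams, rng: np.random.Generator):
    p = params
    soma = Node(1, SOMA_TYPE, 0.0, 0.0, 0.0, p.soma_radius, None)
    nodes = [soma]
    next_id = 2
    tips: deque[tuple[np.ndarray, int, float]] = deque()  # (pos, node id, path len)
    n_branch = 0
    n_segments = 0
    seg = p.segment_length
    origin = np.zeros(3)

    zs2 = p.z_scale * p.z_scale
    ext2 = p.max_extent * p.max_extent

    def inside(q: np.ndarray) -> bool:
        return q[0] * q[0] + q[1] * q[1] + q[2] * q[2] / zs2 <= ext2

    def step_from(pos: np.ndarray, radial: np.ndarray) -> np.ndarray:
        # re-draw a few times, then reflect off the spheroid boundary
        for _ in range(3):
            d = sample_vmf(radial, p.kappa, rng)
            new_pos = pos + d * seg
            if inside(new_pos):
                return new_pos
        n = np.array([pos[0], pos[1], pos[2] / zs2])
        nn = np.linalg.norm(n)
        if nn > 0:
            n /= nn
            d = d - 2.0 * float(d @ n) * n
            new_pos = pos + d * seg
            if inside(new_pos):
                return new_pos
        return pos - pos / max(np.linalg.norm(pos), 1e-9) * seg  # step inward

    total = 0.0
    for _ in range(p.n_primary):
        d = sample_vmf(np.array([0.0, 0.0, 1.0]), 0.0, rng)
        pos = d * seg
        r = max(0.1, p.radius - p.taper * seg)
        nodes.append(Node(next_id, NEURITE_TYPE, *pos, r, 1))
        tips.append((pos, next_id, seg))
        next_id += 1
        n_segments += 1
        total += seg

    # pre-scheduled branch events: an unbiased (dithered) count placed
    # uniformly over the early/mid growth of the tree
    expect = p.branch_rate * p.total_length
    n_target = int(math.floor(expect) + (rng.random() < (expect - math.floor(expect))))
    milestones = deque(np.sort(rng.uniform(0.05, 0.85, n_target)) * p.total_length)

    while tips and total < p.total_length - seg / 2.0:
        pos, nid, path = tips.popleft()
        radial = pos - origin
        branching = (
            bool(milestones)
            and total >= milestones[0]
            and (p.total_length - total) >= 2.0 * seg
        )
        if branching:
            milestones.popleft()
            n_branch += 1
        for _ in range(2 if branching else 1):
            new_pos = step_from(pos, radial)
            new_path = path + seg
            r = max(0.1, p.radius - p.taper * new_path)
            nodes.append(Node(next_id, NEURITE_TYPE, *new_pos, r, nid))
            tips.append((new_pos, next_id, new_path))
            next_id += 1
            total += seg
            n_segments += 1

    if n_segments == 0:
        return None
    morph = Morphology(nodes)
    gt = MorphGroundTruth(
        total_length=seg * n_segments,
        n_primary=p.n_primary,
        n_branch_points=n_branch,
        kappa=p.kappa,
        n_segments=n_segments,
        params=p,
    )
    return morph, gt
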