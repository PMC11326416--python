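"""SWC neuronal reconstructions: parsing, validation and serialization.

The SWC dialect accepted here is the common 7-column whitespace-separated
format (``id type x y z radius parent``) with ``#`` comment lines.  A valid
morphology has exactly one root (parent -1), the root is a soma-type node
(type 1), there are no cycles or orphan references, and all radii are
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SOMA_TYPE = 1


class SWCError(ValueError):
    """Malformed SWC content or an invalid tree."""


@dataclass(frozen=True)
class Node:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int | None  # None for the root

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Morphology:
    """A rooted neuronal tree (positions in micrometres)."""

    nodes: list[Node] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {n.id: n for n in self.nodes}
        if len(self._index) != len(self.nodes):
            raise SWCError("duplicate node ids")
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        if roots[0].type_code != SOMA_TYPE:
            raise SWCError("root must be a soma-type node")
        for n in self.nodes:
            if n.radius <= 0:
                raise SWCError(f"node {n.id}: radius must be positive")
            if n.parent_id is not None and n.parent_id not in self._index:
                raise SWCError(f"node {n.id}: missing parent {n.parent_id}")
        # cycle check / reachability from the root
        self._children: dict[int, list[Node]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                self._children[n.parent_id].append(n)
        seen: set[int] = set()
        stack = [roots[0].id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise SWCError("cycle detected")
            seen.add(i)
            stack.extend(c.id for c in self._children[i])
        if len(seen) != len(self.nodes):
            raise SWCError("nodes not reachable from the root (cycle or forest)")
        self._root = roots[0]

    @property
    def root(self) -> Node:
        return self._root

    def node(self, node_id: int) -> Node:
        return self._index[node_id]

    def children(self, node_id: int) -> list[Node]:
        return self._children[node_id]

    def is_soma(self, node: Node) -> bool:
        return node.type_code == SOMA_TYPE

    def neurite_segments(self) -> list[tuple[Node, Node]]:
        """(parent, child) pairs where the child is a non-soma node."""
        return [
            (self._index[n.parent_id], n)
            for n in self.nodes
            if n.parent_id is not None and not self.is_soma(n)
        ]

    def segment_arrays(self) -> dict[str, np.ndarray]:
        """Vectorized view of the neurite segments (cached)."""
        if not hasattr(self, "_segarr"):
            segs = self.neurite_segments()
            if segs:
                P = np.array([p.xyz for p, _ in segs])
                C = np.array([c.xyz for _, c in segs])
                rp = np.array([p.radius for p, _ in segs])
                rc = np.array([c.radius for _, c in segs])
                soma_parent = np.array([self.is_soma(p) for p, _ in segs])
            else:
                P = C = np.empty((0, 3))
                rp = rc = np.empty(0)
                soma_parent = np.empty(0, dtype=bool)
            self._segarr = {
                "parent": P, "child": C, "r_parent": rp, "r_child": rc,
                "soma_parent": soma_parent,
                "length": np.linalg.norm(C - P, axis=1) if len(segs) else np.empty(0),
            }
        return self._segarr

    def coordinates(self) -> np.ndarray:
        """All node coordinates, shape (n, 3)."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes])


def parse_swc(text: str) -> Morphology:
    """Parse SWC text; raises :class:`SWCError` with a line number on error."""
    nodes: list[Node] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            tcode = int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        nodes.append(Node(nid, tcode, x, y, z, r, None if parent < 0 else parent))
    if not nodes:
        raise SWCError("empty SWC file")
    return Morphology(nodes)


def load_swc(path: str | Path) -> Morphology:
    return parse_swc(Path(path).read_text())


def serialize_swc(m: Morphology) -> str:
    """Canonical SWC text: ids ascending, full repr precision."""
    lines = ["# id type x y z radius parent"]
    for n in sorted(m.nodes, key=lambda n: n.id):
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.id} {n.type_code} {float(n.x)!r} {float(n.y)!r} {float(n.z)!r} "
            f"{float(n.radius)!r} {parent}"
        )
    return "\n".join(lines) + "\n"


def save_swc(m: Morphology, path: str | Path) -> None:
    Path(path).write_text(serialize_swc(m))
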