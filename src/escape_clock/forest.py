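"""Copy-number gain histories as rooted forests of final DNA copies.

A segment's gain history is represented as two rooted trees, one per
parental allele. Internal nodes are gain events (each duplicating exactly
one extant copy; whole-genome doubling duplicates every extant copy at a
single shared time). Leaves are the final copies observed in the tumor.
Every edge carries the time interval during which a mutation landing on
that copy lineage is inherited by all leaves below it.

Time is mutation time on [0, 1]: 0 is conception, 1 the end of the clonal
evolutionary period. Root edges start at 0; leaf edges end at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GainNode",
    "Edge",
    "CopyForest",
    "GainPosterior",
    "forest_from_records",
    "edges_with_multiplicity",
    "total_length_by_multiplicity",
]

ALLELES = ("major", "minor")

# values accepted as "no parent" in on-disk node records
_ROOT_SENTINELS = {None, "", "NA", "na", "None", "none", "-1", -1}


class ForestError(ValueError):
    """Invalid gain-history structure."""


@dataclass
class GainNode:
    node_id: int
    parent_id: Optional[int]
    allele: str
    time: float
    is_wgd: bool
    children: list = field(default_factory=list, repr=False)
    leaf_count: int = 0


@dataclass(frozen=True)
class Edge:
    """A copy lineage interval.

    ``t_start`` is the time of the event creating the copy (0 for the
    original parental copy), ``t_end`` the time of the next gain on the
    copy (1 if it survives unduplicated). ``leaf_count`` is the number of
    final copies descending through this lineage: the multiplicity any
    SNV arising on it will have.
    """

    allele: str
    t_start: float
    t_end: float
    leaf_count: int
    node_id: Optional[int]  # gain node terminating this edge; None for leaf edges
    parent_node_id: Optional[int]  # gain node starting this edge; None for root edges

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


class CopyForest:
    """Gain history of one copy-number segment (one posterior draw).

    Parameters
    ----------
    nodes
        Gain-event nodes with parent links resolved.
    major_cn, minor_cn
        Final allele-specific copy numbers; validated against the leaf
        counts implied by the node structure.
    segment_id
        Optional label used in error messages.
    """

    def __init__(
        self,
        nodes: Sequence[GainNode],
        major_cn: int,
        minor_cn: int,
        segment_id: Optional[str] = None,
    ):
        self.segment_id = segment_id
        self.major_cn = int(major_cn)
        self.minor_cn = int(minor_cn)
        self.nodes = {n.node_id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ForestError(f"segment {segment_id}: duplicate node ids")
        self._link()
        self._validate()
        self.edges: list[Edge] = self._build_edges()

    # -- construction ---------------------------------------------------

    def _link(self) -> None:
        self._roots: dict[str, Optional[GainNode]] = {a: None for a in ALLELES}
        for n in self.nodes.values():
            n.children = []
        for n in self.nodes.values():
            if n.allele not in ALLELES:
                raise ForestError(
                    f"segment {self.segment_id}: unknown allele {n.allele!r}"
                )
            if n.parent_id is None:
                if self._roots[n.allele] is not None:
                    raise ForestError(
                        f"segment {self.segment_id}: allele {n.allele} has two "
                        f"root gains (the original copy can only be duplicated once)"
                    )
                self._roots[n.allele] = n
            else:
                try:
                    parent = self.nodes[n.parent_id]
                except KeyError:
                    raise ForestError(
                        f"segment {self.segment_id}: node {n.node_id} references "
                        f"missing parent {n.parent_id}"
                    ) from None
                parent.children.append(n)

    def _validate(self) -> None:
        # acyclicity + time ordering + binary branching
        for n in self.nodes.values():
            if not (0.0 <= n.time <= 1.0):
                raise ForestError(
                    f"segment {self.segment_id}: node {n.node_id} time {n.time} "
                    f"outside [0, 1]"
                )
            if len(n.children) > 2:
                raise ForestError(
                    f"segment {self.segment_id}: node {n.node_id} has "
                    f"{len(n.children)} child gains; a gain yields two copies"
                )
            for c in n.children:
                if c.allele != n.allele:
                    raise ForestError(
                        f"segment {self.segment_id}: child {c.node_id} allele "
                        f"differs from parent {n.node_id}"
                    )
                if c.time < n.time:
                    raise ForestError(
                        f"segment {self.segment_id}: time inversion between "
                        f"nodes {n.node_id} (t={n.time}) and {c.node_id} (t={c.time})"
                    )
        # cycle check via reachability from roots
        seen: set[int] = set()
        for allele in ALLELES:
            root = self._roots[allele]
            if root is None:
                continue
            stack = [root]
            while stack:
                n = stack.pop()
                if n.node_id in seen:
                    raise ForestError(
                        f"segment {self.segment_id}: cycle at node {n.node_id}"
                    )
                seen.add(n.node_id)
                stack.extend(n.children)
        if len(seen) != len(self.nodes):
            raise ForestError(
                f"segment {self.segment_id}: {len(self.nodes) - len(seen)} node(s) "
                f"unreachable from any root (cyclic parent links?)"
            )
        # leaf counts, bottom-up
        for n in self._postorder():
            n.leaf_count = sum(c.leaf_count for c in n.children) + (
                2 - len(n.children)
            )
        for allele, cn in (("major", self.major_cn), ("minor", self.minor_cn)):
            root = self._roots[allele]
            implied = 1 if root is None else root.leaf_count
            if implied != cn:
                raise ForestError(
                    f"segment {self.segment_id}: {allele} allele forest implies "
                    f"{implied} final copies but copy number is {cn}"
                )

    def _postorder(self) -> list[GainNode]:
        out: list[GainNode] = []
        for allele in ALLELES:
            root = self._roots[allele]
            if root is None:
                continue
            stack: list[tuple[GainNode, bool]] = [(root, False)]
            while stack:
                n, expanded = stack.pop()
                if expanded:
                    out.append(n)
                else:
                    stack.append((n, True))
                    stack.extend((c, False) for c in n.children)
        return out

    def _build_edges(self) -> list[Edge]:
        edges: list[Edge] = []
        for allele in ALLELES:
            root = self._roots[allele]
            if root is None:
                edges.append(Edge(allele, 0.0, 1.0, 1, None, None))
                continue
            edges.append(Edge(allele, 0.0, root.time, root.leaf_count, root.node_id, None))
            stack = [root]
            while stack:
                n = stack.pop()
                for c in n.children:
                    edges.append(
                        Edge(allele, n.time, c.time, c.leaf_count, c.node_id, n.node_id)
                    )
                    stack.append(c)
                for _ in range(2 - len(n.children)):
                    edges.append(Edge(allele, n.time, 1.0, 1, None, n.node_id))
        return edges

    # -- queries --------------------------------------------------------

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def wgd_time(self) -> Optional[float]:
        """Shared time of WGD nodes, or None if this history has no WGD."""
        times = {n.time for n in self.nodes.values() if n.is_wgd}
        if not times:
            return None
        if len(times) > 1:
            raise ForestError(
                f"segment {self.segment_id}: WGD nodes at distinct times {sorted(times)}"
            )
        return times.pop()

    def edges_covering(self, t: float) -> list[Edge]:
        """Edges whose interval contains time ``t`` (copies extant at ``t``)."""
        return [e for e in self.edges if e.t_start <= t < e.t_end]

    def to_records(self) -> list[tuple[int, Optional[int], str, float, bool]]:
        """Serialize gain nodes as (node_id, parent_id, allele, time, is_wgd)."""
        return [
            (n.node_id, n.parent_id, n.allele, n.time, n.is_wgd)
            for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
        ]

    def with_times(self, times: dict[int, float]) -> "CopyForest":
        """Copy of this forest with node times replaced (same topology)."""
        nodes = [
            GainNode(n.node_id, n.parent_id, n.allele, times[n.node_id], n.is_wgd)
            for n in self.nodes.values()
        ]
        return CopyForest(nodes, self.major_cn, self.minor_cn, self.segment_id)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CopyForest(segment={self.segment_id!r}, CN=({self.major_cn},"
            f"{self.minor_cn}), gains={len(self.nodes)})"
        )


def _normalize_parent(parent_id) -> Optional[int]:
    if isinstance(parent_id, float) and np.isnan(parent_id):
        return None
    if parent_id in _ROOT_SENTINELS:
        return None
    return int(parent_id)


def forest_from_records(
    records: Iterable[tuple],
    final_cn: tuple[int, int],
    segment_id: Optional[str] = None,
) -> CopyForest:
    """Build a :class:`CopyForest` from gain-node records.

    Parameters
    ----------
    records
        Iterable of ``(node_id, parent_id, allele, time, is_wgd)``; a
        parent of ``None``/NA/-1 marks a gain on the original parental
        copy.
    final_cn
        ``(major, minor)`` final copy numbers; must match the leaf counts
        implied by the records.
    """
    nodes = [
        GainNode(
            int(nid),
            _normalize_parent(pid),
            str(allele),
            float(time),
            bool(_parse_bool(is_wgd)),
        )
        for nid, pid, allele, time, is_wgd in records
    ]
    return CopyForest(nodes, final_cn[0], final_cn[1], segment_id=segment_id)


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "t", "1", "yes"}
    return bool(x)


def edges_with_multiplicity(forest: CopyForest, m: int) -> list[Edge]:
    """All edges on which an SNV would attain multiplicity ``m``."""
    if m < 1:
        raise ValueError("multiplicity must be >= 1")
    return [e for e in forest.edges if e.leaf_count == m]


def total_length_by_multiplicity(forest: CopyForest) -> dict[int, float]:
    """Summed edge time-length per multiplicity class.

    Under uniform mutation arrival per copy per unit mutation time, these
    lengths are proportional to the prior mass of each multiplicity state.
    """
    out: dict[int, float] = {}
    for e in forest.edges:
        out[e.leaf_count] = out.get(e.leaf_count, 0.0) + e.length
    return out


class GainPosterior:
    """Ordered posterior draws of a segment's gain history.

    All draws share one topology; only gain times differ between draws.
    Stored as one topology forest plus an (S, n_nodes) matrix of node
    times; full :class:`CopyForest` draws are materialized lazily.
    """

    def __init__(
        self,
        segment_id: str,
        draws: Optional[Sequence[CopyForest]] = None,
        *,
        topology: Optional[CopyForest] = None,
        times: Optional[np.ndarray] = None,
    ):
        self.segment_id = segment_id
        if draws is not None:
            if not draws:
                raise ForestError(f"segment {segment_id}: no posterior draws")
            topology = draws[0]
            topo = {
                (n.node_id, n.parent_id, n.allele, n.is_wgd)
                for n in topology.nodes.values()
            }
            for i, f in enumerate(draws[1:], start=2):
                t = {(n.node_id, n.parent_id, n.allele, n.is_wgd) for n in f.nodes.values()}
                if t != topo or (f.major_cn, f.minor_cn) != (
                    topology.major_cn,
                    topology.minor_cn,
                ):
                    raise ForestError(
                        f"segment {segment_id}: draw {i} topology differs from draw 1"
                    )
            self._node_order = sorted(topology.nodes)
            times = np.array(
                [[f.nodes[nid].time for nid in self._node_order] for f in draws],
                dtype=float,
            )
            self._draws: Optional[list[CopyForest]] = list(draws)
        elif topology is not None and times is not None:
            self._node_order = sorted(topology.nodes)
            times = np.asarray(times, dtype=float)
            if times.ndim != 2 or times.shape[1] != len(self._node_order):
                raise ForestError(
                    f"segment {segment_id}: times matrix shape {times.shape} does not "
                    f"match {len(self._node_order)} gain nodes"
                )
            self._draws = None
        else:
            raise TypeError("provide either draws or (topology, times)")
        self.topology = topology
        self.times = times
        self._col = {nid: j for j, nid in enumerate(self._node_order)}
        self._validate_times()

    def _validate_times(self) -> None:
        t = self.times
        if t.size and (np.any(t < 0) or np.any(t > 1)):
            raise ForestError(f"segment {self.segment_id}: draw times outside [0, 1]")
        for n in self.topology.nodes.values():
            if n.parent_id is not None:
                bad = t[:, self._col[n.parent_id]] > t[:, self._col[n.node_id]] + 1e-12
                if bad.any():
                    raise ForestError(
                        f"segment {self.segment_id}: time inversion between nodes "
                        f"{n.parent_id} and {n.node_id} in draw {int(np.argmax(bad))}"
                    )
        wgd_cols = [self._col[n.node_id] for n in self.topology.nodes.values() if n.is_wgd]
        if len(wgd_cols) > 1:
            ref = t[:, wgd_cols[0]]
            if not np.allclose(t[:, wgd_cols], ref[:, None], atol=1e-9):
                raise ForestError(
                    f"segment {self.segment_id}: WGD nodes not simultaneous in every draw"
                )

    @property
    def S(self) -> int:
        return self.times.shape[0]

    @property
    def draws(self) -> list[CopyForest]:
        if self._draws is None:
            self._draws = [
                self.topology.with_times(dict(zip(self._node_order, row)))
                for row in self.times
            ]
        return self._draws

    @property
    def major_cn(self) -> int:
        return self.topology.major_cn

    @property
    def minor_cn(self) -> int:
        return self.topology.minor_cn

    @property
    def total_cn(self) -> int:
        return self.topology.total_cn

    def edge_time_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-draw edge intervals: (starts, ends) of shape (S, E) and
        leaf counts (E,), in the topology's edge order."""
        S = self.S
        E = len(self.topology.edges)
        starts = np.zeros((S, E))
        ends = np.ones((S, E))
        for j, e in enumerate(self.topology.edges):
            if e.parent_node_id is not None:
                starts[:, j] = self.times[:, self._col[e.parent_node_id]]
            if e.node_id is not None:
                ends[:, j] = self.times[:, self._col[e.node_id]]
        lc = np.array([e.leaf_count for e in self.topology.edges], dtype=int)
        return starts, ends, lc

    def wgd_times(self) -> Optional[np.ndarray]:
        """Per-draw WGD times, or None for a WGD-free history."""
        for n in self.topology.nodes.values():
            if n.is_wgd:
                return self.times[:, self._col[n.node_id]].copy()
        return None
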