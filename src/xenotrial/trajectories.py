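"""Repeated driver trajectories across clone trees and their change under therapy.

Inputs are fixed per-case clone trees (inferred elsewhere) whose nodes carry
driver events.  Each driver node is assigned its nearest ancestral driver
(germline, GL, if none), yielding ordered transitions and maximal GL-to-leaf
driver paths.  Trajectories supported by multiple cases at the same timepoint
are "repeated"; pre- vs post-treatment repeated sets are compared per driver
family into unchanged / truncated_to_early / extended / divergent_extension /
disappeared / newborn.

Drivers co-occurring in one clone are rendered as an unordered "A/B" co-event:
within-clone ordering is never invented.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "GL",
    "DELTA_CLASSES",
    "CloneTree",
    "Trajectory",
    "TrajectoryDelta",
    "extract_transitions",
    "repeated_trajectories",
    "compare_trajectory_sets",
]

GL = "GL"

DELTA_CLASSES = (
    "unchanged",
    "truncated_to_early",
    "extended",
    "divergent_extension",
    "disappeared",
    "newborn",
)


@dataclass
class CloneTree:
    """A rooted clone tree for one case at one timepoint.

    ``parent`` maps every non-root node to its parent; the root is ``GL``.
    ``drivers`` maps nodes to their driver event labels (genes, possibly
    suffixed by event kind).
    """

    case_id: str
    timepoint: str
    parent: dict[str, str]
    drivers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = set(self.parent)
        if GL in nodes:
            raise ValueError("GL is the root and cannot have a parent")
        for child, par in self.parent.items():
            if par != GL and par not in nodes:
                raise ValueError(f"parent {par!r} of {child!r} is not a node")
        # cycle check by walking each node to the root
        for node in nodes:
            seen = {node}
            cur = node
            while cur != GL:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError(f"cycle detected through {node!r}")
                seen.add(cur)
        for node in self.drivers:
            if node != GL and node not in nodes:
                raise ValueError(f"drivers listed for unknown node {node!r}")

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = defaultdict(list)
        for child, par in self.parent.items():
            ch[par].append(child)
        for v in ch.values():
            v.sort()
        return ch


def _label(events: Sequence[str]) -> str:
    """Co-occurring drivers of one clone as an unordered co-event label."""
    return "/".join(sorted(set(events)))


def extract_transitions(tree: CloneTree) -> tuple[list[tuple[str, str]],
                                                  list[tuple[str, ...]]]:
    """Ordered driver transitions and maximal GL-to-leaf driver paths.

    Each driver-bearing clone emits exactly one event (its co-event label)
    whose immediate upstream event is the nearest ancestral clone's label (GL
    if none).  Paths run from GL through chains of driver labels to clones
    with no driver-bearing descendants.  Deterministic given the tree.
    """
    children = tree.children()
    transitions: list[tuple[str, str]] = []
    paths: list[tuple[str, ...]] = []

    def walk(node: str, upstream: str, prefix: tuple[str, ...]) -> None:
        events = tree.drivers.get(node, [])
        if node != GL and events:
            lab = _label(events)
            transitions.append((upstream, lab))
            upstream = lab
            prefix = prefix + (lab,)
        kids = children.get(node, [])
        # a path ends where no descendant carries drivers
        if not any(_has_driver_below(k, children, tree.drivers) for k in kids):
            if len(prefix) > 1:
                paths.append(prefix)
            return
        for k in kids:
            if _has_driver_below(k, children, tree.drivers):
                walk(k, upstream, prefix)

    walk(GL, GL, (GL,))
    # distinct clones can carry identical driver labels; keep label paths
    # that are maximal (not a proper prefix of another)
    unique = set(paths)
    maximal = [p for p in sorted(unique)
               if not any(q != p and q[:len(p)] == p for q in unique)]
    return transitions, maximal


def _has_driver_below(node: str, children: Mapping[str, list[str]],
                      drivers: Mapping[str, Sequence[str]]) -> bool:
    if drivers.get(node):
        return True
    return any(_has_driver_below(k, children, drivers)
               for k in children.get(node, []))


def _clonal_nodes(tree: CloneTree) -> set[str]:
    """Nodes on the unbranched chain from the root: their events are clonal."""
    children = tree.children()
    clonal: set[str] = set()
    cur = GL
    while True:
        kids = children.get(cur, [])
        if len(kids) != 1:
            break
        cur = kids[0]
        clonal.add(cur)
    return clonal


@dataclass
class Trajectory:
    path: tuple[str, ...]  # starts at GL
    timepoint: str
    support: int
    cases: list[str]
    n_clonal: int = 0
    n_subclonal: int = 0


def repeated_trajectories(trees: Sequence[CloneTree], min_support: int = 2,
                          include_transitions: bool = True) -> list[Trajectory]:
    """Trajectories supported by >= min_support distinct cases per timepoint.

    Full maximal paths and (optionally) their two-node transitions are both
    counted.  Clonal vs subclonal placement of the path's last event is
    tallied across supporting trees (a clone is clonal while the tree has not
    yet branched).
    """
    if len({t.case_id for t in trees}) < 2:
        raise ValueError("need trees from at least two cases")
    support: dict[tuple[str, tuple[str, ...]], set[str]] = defaultdict(set)
    clonal_ct: Counter = Counter()
    sub_ct: Counter = Counter()
    for tree in trees:
        transitions, paths = extract_transitions(tree)
        clonal = _clonal_nodes(tree)
        label_clonal = {
            _label(tree.drivers[n]): (n in clonal)
            for n in tree.drivers if n != GL and tree.drivers[n]
        }
        items = {tuple(p) for p in paths}
        if include_transitions:
            items |= {(a, b) for a, b in transitions}
        for item in items:
            key = (tree.timepoint, item)
            support[key].add(tree.case_id)
            if label_clonal.get(item[-1], False):
                clonal_ct[key] += 1
            else:
                sub_ct[key] += 1
    out = []
    for (tp, path), cases in support.items():
        if len(cases) >= min_support:
            out.append(Trajectory(path=path, timepoint=tp, support=len(cases),
                                  cases=sorted(cases),
                                  n_clonal=clonal_ct[(tp, path)],
                                  n_subclonal=sub_ct[(tp, path)]))
    out.sort(key=lambda t: (-t.support, t.path))
    return out


@dataclass
class TrajectoryDelta:
    family: str  # first post-GL driver label
    pre_paths: list[tuple[str, ...]]
    post_paths: list[tuple[str, ...]]
    change: str


def _is_proper_prefix(p: tuple[str, ...], q: tuple[str, ...]) -> bool:
    return len(p) < len(q) and q[: len(p)] == p


def compare_trajectory_sets(pre: Sequence[Trajectory], post: Sequence[Trajectory],
                            min_support_pre: Optional[int] = None,
                            min_support_post: Optional[int] = None,
                            ) -> list[TrajectoryDelta]:
    """Classify per-family change between pre- and post-treatment trajectories.

    Both sets must have been built with the same support threshold (pass the
    thresholds to have this checked).  Families are keyed by the first post-GL
    driver.  The decision cascade (disappeared, newborn, unchanged,
    truncated_to_early, extended, divergent_extension) makes the classes
    mutually exclusive and exhaustive over the union of families.
    """
    if (min_support_pre is not None and min_support_post is not None
            and min_support_pre != min_support_post):
        raise ValueError("pre and post sets were built with different min_support")
    fam_pre: dict[str, set[tuple[str, ...]]] = defaultdict(set)
    fam_post: dict[str, set[tuple[str, ...]]] = defaultdict(set)
    for t in pre:
        fam_pre[t.path[1]].add(t.path)
    for t in post:
        fam_post[t.path[1]].add(t.path)
    out = []
    for fam in sorted(set(fam_pre) | set(fam_post)):
        p, q = fam_pre.get(fam, set()), fam_post.get(fam, set())
        early = (GL, fam)
        if not q:
            change = "disappeared"
        elif not p:
            change = "newborn"
        elif p == q:
            change = "unchanged"
        elif q == {early}:
            change = "truncated_to_early"
        elif all(any(_is_proper_prefix(pp, qq) or pp == qq for pp in p) for qq in q) \
                and any(_is_proper_prefix(pp, qq) for pp in p for qq in q):
            change = "extended"
        else:
            change = "divergent_extension"
        out.append(TrajectoryDelta(family=fam, pre_paths=sorted(p),
                                   post_paths=sorted(q), change=change))
    return out
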