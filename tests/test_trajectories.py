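"""Driver-path extraction, repeated-trajectory counting, pre/post deltas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenotrial.trajectories import (GL, CloneTree, DELTA_CLASSES, Trajectory,
                                    compare_trajectory_sets,
                                    extract_transitions,
                                    repeated_trajectories)


def _tree(parent, drivers, case="c1", tp="pre"):
    return CloneTree(case_id=case, timepoint=tp, parent=parent, drivers=drivers)


class TestCloneTreeValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            _tree({"a": "b", "b": "a"}, {})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            _tree({"a": "zzz"}, {})


class TestExtractTransitions:
    def test_single_driver_clone(self):
        t = _tree({"a": GL}, {"a": ["TP53"]})
        transitions, paths = extract_transitions(t)
        assert transitions == [(GL, "TP53")]
        assert paths == [(GL, "TP53")]

    def test_driver_chain(self):
        t = _tree({"a": GL, "b": "a", "c": "b"},
                  {"a": ["TP53"], "b": ["LRP1B"], "c": ["AKAP9", "ZFHX3"]})
        _, paths = extract_transitions(t)
        assert paths == [(GL, "TP53", "LRP1B", "AKAP9/ZFHX3")]

    def test_driverless_clone_is_skipped_in_ordering(self):
        t = _tree({"a": GL, "b": "a", "c": "b"},
                  {"a": ["NCOR2"], "c": ["MUC16"]})
        transitions, paths = extract_transitions(t)
        assert (GL, "NCOR2") in transitions and ("NCOR2", "MUC16") in transitions
        assert paths == [(GL, "NCOR2", "MUC16")]

    def test_branching_shares_prefix(self):
        t = _tree({"a": GL, "b": "a", "c": "a"},
                  {"a": ["X"], "b": ["Y"], "c": ["Z"]})
        _, paths = extract_transitions(t)
        assert set(paths) == {(GL, "X", "Y"), (GL, "X", "Z")}

    def test_one_event_per_driver_clone(self):
        t = _tree({"a": GL, "b": "a", "c": "a", "d": "c"},
                  {"a": ["X"], "c": ["Y"], "d": ["Z", "W"]})
        transitions, _ = extract_transitions(t)
        n_driver_clones = 3
        assert len(transitions) == n_driver_clones


def _random_tree(rng, n_nodes, case, tp):
    """Random clone tree with random driver placement (for oracle checks)."""
    names = [f"n{i}" for i in range(n_nodes)]
    parent = {}
    for i, name in enumerate(names):
        parent[name] = GL if i == 0 else names[rng.integers(0, i)]
    genes = ["A", "B", "C", "D", "E"]
    drivers = {}
    for name in names:
        k = int(rng.integers(0, 3))
        if k:
            drivers[name] = sorted(rng.choice(genes, size=k, replace=False))
    return _tree(parent, drivers, case=case, tp=tp)


def _oracle_paths(tree):
    """Exhaustive enumeration: driver labels along every root-to-leaf walk,
    keeping only maximal paths."""
    children = tree.children()
    leaves = [n for n in tree.parent if not children.get(n)]
    raw = set()
    for leaf in leaves:
        chain = []
        cur = leaf
        while cur != GL:
            chain.append(cur)
            cur = tree.parent[cur]
        chain.reverse()
        labels = tuple([GL] + ["/".join(sorted(set(tree.drivers[n])))
                               for n in chain if tree.drivers.get(n)])
        if len(labels) > 1:
            raw.add(labels)
    return {p for p in raw
            if not any(q != p and q[:len(p)] == p for q in raw)}


class TestPathEnumerationOracle:
    def test_matches_exhaustive_oracle_on_small_trees(self):
        rng = np.random.default_rng(17)
        for trial in range(200):
            tree = _random_tree(rng, int(rng.integers(1, 8)), "c", "pre")
            _, paths = extract_transitions(tree)
            assert set(paths) == _oracle_paths(tree), tree.parent


class TestRepeatedTrajectories:
    def _cohort(self, paths_per_case, tp="pre"):
        trees = []
        for case, chains in paths_per_case.items():
            parent, drivers = {}, {}
            for ci, chain in enumerate(chains):
                prev = GL
                for gi, gene in enumerate(chain):
                    node = f"{case}_{ci}_{gi}"
                    parent[node] = prev
                    drivers[node] = [gene]
                    prev = node
            trees.append(_tree(parent, drivers, case=case, tp=tp))
        return trees

    def test_support_counting(self):
        trees = self._cohort({
            "c1": [["CDKN2A"]], "c2": [["CDKN2A"]], "c3": [["CDKN2A"]],
            "c4": [["PIK3CA"]], "c5": [["BRD4"]], "c6": [["MUC4"]],
            "c7": [["PCLO"]], "c8": [["ASXL2"]]})
        rep = repeated_trajectories(trees, min_support=2)
        assert [t for t in rep if t.path == (GL, "CDKN2A")][0].support == 3
        assert not [t for t in rep if t.path == (GL, "PIK3CA")]

    def test_single_case_support_excluded(self):
        trees = self._cohort({"c1": [["X", "Y"]], "c2": [["Z"]]})
        assert repeated_trajectories(trees, min_support=2) == []

    def test_identical_trees_support_all_paths(self):
        trees = self._cohort({f"c{i}": [["A", "B"]] for i in range(5)})
        rep = repeated_trajectories(trees, min_support=2)
        full = [t for t in rep if t.path == (GL, "A", "B")]
        assert full and full[0].support == 5

    def test_clonal_vs_subclonal_counts(self):
        # unbranched chain: both drivers clonal; branch point makes leaves subclonal
        t1 = _tree({"a": GL, "b": "a"}, {"a": ["X"], "b": ["Y"]}, case="c1")
        t2 = _tree({"a": GL, "b": "a", "c": "a"},
                   {"a": ["X"], "b": ["Y"], "c": ["Z"]}, case="c2")
        rep = repeated_trajectories([t1, t2], min_support=2)
        gx = [t for t in rep if t.path == (GL, "X")][0]
        assert gx.n_clonal == 2 and gx.n_subclonal == 0


class TestCompareTrajectorySets:
    def _traj(self, path, tp):
        return Trajectory(path=tuple(path), timepoint=tp, support=2, cases=["a", "b"])

    def test_truncation_to_early_transition(self):
        pre = [self._traj([GL, "NCOR2", "MUC16"], "pre")]
        post = [self._traj([GL, "NCOR2"], "post")]
        deltas = compare_trajectory_sets(pre, post)
        assert deltas[0].change == "truncated_to_early"

    def test_newborn_trajectory(self):
        post = [self._traj([GL, "NOTCH1", "AKAP9"], "post")]
        deltas = compare_trajectory_sets([], post)
        assert deltas[0].change == "newborn"

    def test_identical_sets_unchanged(self):
        pre = [self._traj([GL, "TP53", "LRP1B"], "pre")]
        post = [self._traj([GL, "TP53", "LRP1B"], "post")]
        assert compare_trajectory_sets(pre, post)[0].change == "unchanged"

    def test_extension_and_divergence(self):
        pre = [self._traj([GL, "TP53"], "pre"), self._traj([GL, "FAT3", "MUC16"], "pre")]
        post = [self._traj([GL, "TP53", "LRP1B"], "post"),
                self._traj([GL, "FAT3", "CTTN"], "post")]
        by_fam = {d.family: d.change for d in compare_trajectory_sets(pre, post)}
        assert by_fam["TP53"] == "extended"
        assert by_fam["FAT3"] == "divergent_extension"

    def test_disappeared(self):
        pre = [self._traj([GL, "CTNNA2", "TRAF3"], "pre")]
        assert compare_trajectory_sets(pre, [])[0].change == "disappeared"

    def test_mismatched_min_support_rejected(self):
        with pytest.raises(ValueError, match="min_support"):
            compare_trajectory_sets([], [], 2, 3)

    def test_classes_exclusive_and_exhaustive_on_random_pairs(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            pre_trees = [_random_tree(rng, int(rng.integers(1, 6)), f"c{i}", "pre")
                         for i in range(4)]
            post_trees = [_random_tree(rng, int(rng.integers(1, 6)), f"c{i}", "post")
                          for i in range(4)]
            pre = repeated_trajectories(pre_trees, min_support=2)
            post = repeated_trajectories(post_trees, min_support=2)
            deltas = compare_trajectory_sets(pre, post)
            fams = {t.path[1] for t in pre} | {t.path[1] for t in post}
            assert {d.family for d in deltas} == fams
            assert all(d.change in DELTA_CLASSES for d in deltas)
            assert len(deltas) == len({d.family for d in deltas})
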