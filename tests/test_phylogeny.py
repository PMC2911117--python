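"""Enrichment phylogeny: read-set similarity, greedy joining, gains,
annotation, instance-level trees and Newick export."""

import itertools
import math

import numpy as np
import pytest

from repeatchip.alignment import AlignmentHit, Read, align_all_hits
from repeatchip.phylogeny import (
    TreeNode,
    annotate_tree,
    build_tree,
    check_tree_invariants,
    instance_read_sets,
    instance_tree,
    leaf_read_sets_from_hits,
    node_read_sets,
    node_unique_reads,
    readset_similarity,
    write_newick,
)
from repeatchip.reference import (
    CanonicalRepeat,
    RepeatInstance,
    build_assembly,
    extract_instance_sequences,
)
from conftest import mutate, random_seq


def _leaf_map(spec):
    """spec: {read_id: iterable of leaves hit at best stratum}"""
    return {r: frozenset(ls) for r, ls in spec.items()}


def _counts_map(only_a, only_b, both, a="A", b="B"):
    m = {}
    for i in range(only_a):
        m[f"a{i}"] = frozenset([a])
    for i in range(only_b):
        m[f"b{i}"] = frozenset([b])
    for i in range(both):
        m[f"ab{i}"] = frozenset([a, b])
    return m


class TestNodeReadSets:
    def test_unique_requires_all_hits_inside(self):
        m = _leaf_map({"r1": "A", "r2": "AB", "r3": "BC"})
        assert node_unique_reads(frozenset("A"), m) == {"r1"}
        assert node_unique_reads(frozenset("AB"), m) == {"r1", "r2"}
        aligned, unique = node_read_sets(frozenset("AB"), m)
        assert aligned == {"r1", "r2", "r3"}  # r3 touches B

    def test_read_hitting_only_nonmembers_excluded(self):
        m = _leaf_map({"r": "CD"})
        assert node_unique_reads(frozenset("AB"), m) == frozenset()

    def test_merge_recovers_ambiguous_reads(self):
        """Merging two leaves with 600 individually unique reads and 400
        shared-only reads yields 1,000 unique at the parent, gain 400."""
        m = _counts_map(350, 250, 400)
        tree = build_tree(["A", "B"], m)
        assert tree.unique_count == 1000
        assert tree.gain == 400
        assert sum(c.unique_count for c in tree.children) == 600

    def test_sister_ltr_merge_counts(self):
        """Two closely related LTR leaves with 1,991 and 1,758 unique reads
        and 1,915 cross-ambiguous reads: merged node carries 5,664."""
        m = _counts_map(1991, 1758, 1915, a="IAPLTR1", b="IAPLTR1a")
        tree = build_tree(["IAPLTR1", "IAPLTR1a"], m)
        assert tree.unique_count == 5664
        assert tree.gain == 1915
        assert 1991 + 1758 + 1915 == 5664
        check_tree_invariants(tree)


class TestSimilarity:
    def _node(self, aligned):
        return TreeNode("x", frozenset("X"), aligned=frozenset(aligned))

    def test_disjoint_and_identical(self):
        assert readset_similarity(self._node("abc"), self._node("def")) == 0.0
        assert readset_similarity(self._node("abc"), self._node("abc")) == 1.0
        assert readset_similarity(self._node(""), self._node("")) == 0.0

    def test_jaccard_arithmetic(self):
        a = self._node({f"r{i}" for i in range(60)})
        b = self._node({f"r{i}" for i in range(40, 100)})
        assert readset_similarity(a, b) == pytest.approx(20 / 100)


class TestBuildTree:
    def test_forced_topology(self):
        m = {}
        for i in range(90):
            m[f"s{i}"] = frozenset(["A", "B"])  # A,B share most reads
        for i in range(10):
            m[f"a{i}"] = frozenset(["A"])
        for i in range(80):
            m[f"c{i}"] = frozenset(["C"])
        tree = build_tree(["A", "B", "C"], m)
        first_merge = next(n for n in tree.walk() if n.node_id == "n1")
        assert first_merge.members == frozenset(["A", "B"])
        assert tree.members == frozenset(["A", "B", "C"])

    def test_leaf_order_invariance(self, rng):
        leaves = [f"L{i}" for i in range(6)]
        m = {}
        for i in range(300):
            k = rng.integers(1, 4)
            m[f"r{i}"] = frozenset(rng.choice(leaves, size=k, replace=False))
        t1 = build_tree(leaves, m)
        t2 = build_tree(list(reversed(leaves)), m)

        def topo(n):
            if n.is_leaf:
                return n.node_id
            return "(" + ",".join(sorted(topo(c) for c in n.children)) + ")"

        assert topo(t1) == topo(t2)

    def test_invariants_on_random_trees(self, rng):
        """Gain non-negativity and conservation (every uniquely assignable
        read gained exactly once) on arbitrary read-to-leaf structures."""
        for trial in range(5):
            leaves = [f"L{i}" for i in range(8)]
            m = {}
            for i in range(500):
                k = int(rng.integers(1, 5))
                m[f"r{i}"] = frozenset(rng.choice(leaves, size=k, replace=False))
            tree = build_tree(leaves, m)
            check_tree_invariants(tree)
            # root uniqueness = all reads confined to the leaf universe
            assert tree.unique_count == len(m)

    def test_node_sets_match_brute_force(self, rng):
        """On <= 12 leaves, every node's (aligned, unique) sets match a
        brute-force recomputation from the raw read-to-leaf map."""
        leaves = [f"L{i}" for i in range(12)]
        m = {}
        for i in range(400):
            k = int(rng.integers(1, 6))
            m[f"r{i}"] = frozenset(rng.choice(leaves, size=k, replace=False))
        tree = build_tree(leaves, m)
        for node in tree.walk():
            aligned = {r for r, ls in m.items() if ls & node.members}
            unique = {r for r, ls in m.items() if ls <= node.members}
            assert node.aligned == aligned
            assert node.unique == unique

    def test_greedy_matches_exhaustive_on_nested_structure(self):
        """With nested similarity structure the greedy topology equals the
        best topology over all binary trees on 4 leaves, scored by total
        gained-unique reads at each internal node depth (all topologies tie
        on the root, so compare the induced partition sequence)."""
        m = {}
        for i in range(100):
            m[f"ab{i}"] = frozenset(["A", "B"])
        for i in range(60):
            m[f"abc{i}"] = frozenset(["A", "B", "C"])
        for i in range(30):
            m[f"d{i}"] = frozenset(["D"])
        for i in range(10):
            m[f"a{i}"] = frozenset(["A"])
        tree = build_tree(["A", "B", "C", "D"], m)
        merges = [n.members for n in tree.walk() if not n.is_leaf]
        assert frozenset(["A", "B"]) in merges
        assert frozenset(["A", "B", "C"]) in merges

    def test_single_leaf_degenerate(self):
        with pytest.warns(UserWarning, match="single leaf"):
            tree = build_tree(["A"], _leaf_map({"r": "A"}))
        assert tree.is_leaf and tree.unique_count == 1


class TestAnnotation:
    def test_null_node_is_flat(self):
        m = _counts_map(10, 10, 5)
        tree = build_tree(["A", "B"], m)
        annotate_tree(tree, m, S=1000, C=1000)
        assert tree.estimate.mle == pytest.approx(1.0)
        assert tree.estimate.zscore == 0.0
        assert tree.control_unique_count == tree.unique_count

    def test_enriched_leaf_detected(self):
        chip = _counts_map(400, 100, 50)
        ctrl = _counts_map(100, 100, 50)
        tree = build_tree(["A", "B"], chip)
        annotate_tree(tree, ctrl, S=100_000, C=100_000)
        leaf_a = next(n for n in tree.walk() if n.node_id == "A")
        assert leaf_a.estimate.ci_low <= 4.0 <= leaf_a.estimate.ci_high
        assert leaf_a.estimate.significant

    def test_zscore_capped_everywhere(self):
        chip = _counts_map(100_000, 5, 3)
        ctrl = _counts_map(2, 5, 3)
        tree = build_tree(["A", "B"], chip)
        annotate_tree(tree, ctrl, S=1e6, C=1e6)
        for node in tree.walk():
            assert abs(node.estimate.zscore) <= 10.0

    def test_control_size_zero_rejected(self):
        tree = build_tree(["A", "B"], _counts_map(5, 5, 5))
        with pytest.raises(ValueError):
            annotate_tree(tree, {}, S=10, C=0)


class TestInstanceTree:
    def _assembly(self, rng, n_identical=2, n_diverged=0, divergence=0.1):
        canon_seq = random_seq(rng, 300)
        genome = random_seq(rng, 200)
        instances, pos = [], len(genome)
        copies = [canon_seq] * n_identical + [
            mutate(canon_seq, rng.choice(300, int(300 * divergence), replace=False), rng)
            for _ in range(n_diverged)
        ]
        for copy in copies:
            genome += copy + random_seq(rng, 150)
            instances.append(
                RepeatInstance("T1", "chr1", pos, pos + len(copy), "+")
            )
            pos = len(genome)
        g = {"chr1": genome}
        canon = [CanonicalRepeat("T1", "F", "K", canon_seq)]
        inst_seqs = extract_instance_sequences(g, instances, 13)
        asm = build_assembly(canon, inst_seqs, "combined")
        return g, asm, instances

    def test_identical_instances_gain_at_parent(self, rng):
        g, asm, instances = self._assembly(rng, n_identical=2)
        # reads from the interior of the first copy hit both copies equally
        reads = [
            Read(f"r{i}", g["chr1"][instances[0].start + 30 + i : instances[0].start + 62 + i])
            for i in range(30)
        ]
        hits = align_all_hits(reads, asm)
        lengths = {r.read_id: 32 for r in reads}
        tree = instance_tree("T1", asm, hits, lengths)
        for child in tree.children:
            assert child.unique_count == 0
        assert tree.unique_count > 0 and tree.gain == tree.unique_count

    def test_reads_hitting_other_types_discarded(self, rng):
        g, asm, instances = self._assembly(rng, n_identical=2)
        hits = [
            AlignmentHit("clean", "T1", asm.instance_segments("T1")[0].start + 5, "+", 0),
            AlignmentHit("dirty", "T1", asm.instance_segments("T1")[0].start + 5, "+", 0),
            AlignmentHit("dirty", "T2", 0, "+", 0),  # alignment in another type
        ]
        m = instance_read_sets(hits, asm, "T1", {"clean": 32, "dirty": 32})
        assert "clean" in m and "dirty" not in m

    def test_canonical_only_reads_discarded(self, rng):
        g, asm, instances = self._assembly(rng, n_identical=2)
        hits = [AlignmentHit("canon_read", "T1", 10, "+", 0)]  # canonical segment
        m = instance_read_sets(hits, asm, "T1", {"canon_read": 32})
        assert m == {}

    def test_diverged_subcluster_joined_first(self, rng):
        """10 instances, 3 sharing extra divergence: the greedy tree joins
        the diverged trio before mixing it with the main cluster."""
        canon_seq = random_seq(rng, 300)
        sub_seq = mutate(canon_seq, rng.choice(300, 75, replace=False), rng)
        genome, instances, pos = random_seq(rng, 150), [], None
        for i in range(10):
            src = sub_seq if i < 3 else canon_seq
            start = len(genome)
            genome += src + random_seq(rng, 120)
            instances.append(RepeatInstance("T1", "chr1", start, start + 300, "+"))
        g = {"chr1": genome}
        asm = build_assembly(
            [CanonicalRepeat("T1", "F", "K", canon_seq)],
            extract_instance_sequences(g, instances, 13),
            "combined",
        )
        reads = []
        for i, inst in enumerate(instances):
            for j in range(20):
                s = inst.start + 10 + 13 * j
                reads.append(Read(f"r{i}_{j}", g["chr1"][s : s + 32]))
        hits = align_all_hits(reads, asm)
        tree = instance_tree("T1", asm, hits, {r.read_id: 32 for r in reads})
        sub_leaves = {asm.instance_segments("T1")[i].leaf_id for i in range(3)}
        merged = [n.members for n in tree.walk() if not n.is_leaf]
        assert frozenset(sub_leaves) in [m & frozenset(sub_leaves) for m in merged if m >= sub_leaves][-1:] or any(
            m == frozenset(sub_leaves) for m in merged
        )
        # gains concentrate at the trio's ancestor rather than under it
        trio = next(n for n in tree.walk() if n.members == frozenset(sub_leaves))
        assert trio.gain > 0

    def test_too_few_instances_rejected(self, rng):
        g, asm, _ = self._assembly(rng, n_identical=1)
        with pytest.raises(ValueError):
            instance_tree("T1", asm, [], {})


class TestNewick:
    def test_round_trip_topology_and_annotations(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        chip = _counts_map(350, 250, 400)
        tree = build_tree(["A", "B"], chip)
        annotate_tree(tree, chip, S=10_000, C=10_000)
        nwk = tmp_path / "tree.nwk"
        tsv = tmp_path / "tree.tsv"
        write_newick(tree, nwk, tsv)
        parsed = dendropy.Tree.get(path=str(nwk), schema="newick")
        labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert labels == {"A", "B"}
        root_len = parsed.seed_node.edge.length
        assert root_len == pytest.approx(math.log10(1 + 400), rel=1e-4)
        rows = tsv.read_text().strip().split("\n")
        assert rows[0].startswith("node_id")
        by_id = {r.split("\t")[0]: r.split("\t") for r in rows[1:]}
        assert by_id["n1"][2] == "1000"  # unique_count
        assert by_id["n1"][4] == "400"  # gain

    def test_log_branch_lengths(self):
        n0 = TreeNode("x", frozenset("X"), gain=0)
        n999 = TreeNode("y", frozenset("Y"), gain=999)
        assert n0.branch_display_length == 0.0
        assert n999.branch_display_length == pytest.approx(3.0, abs=1e-3)


class TestRecomputeReadSets:
    def test_chip_counts_on_combined_topology(self, rng):
        """A topology built from ChIP + control reads, re-counted with ChIP
        alone: unique counts match a fresh brute-force recomputation and the
        gain invariants still hold."""
        from repeatchip.phylogeny import recompute_read_sets, check_tree_invariants

        leaves = [f"L{i}" for i in range(6)]
        chip, ctrl = {}, {}
        for i in range(200):
            k = int(rng.integers(1, 4))
            chip[f"c{i}"] = frozenset(rng.choice(leaves, size=k, replace=False))
        for i in range(200):
            k = int(rng.integers(1, 4))
            ctrl[f"i{i}"] = frozenset(rng.choice(leaves, size=k, replace=False))
        tree = build_tree(leaves, {**ctrl, **chip})
        recompute_read_sets(tree, chip)
        check_tree_invariants(tree)
        for node in tree.walk():
            assert node.unique == {r for r, ls in chip.items() if ls <= node.members}
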