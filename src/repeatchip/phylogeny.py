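"""Read-set enrichment phylogeny.

Homologous repeat sequences are grouped bottom-up into a binary tree so
that each merge recovers reads that were ambiguous between the merged
sets: a read is *unique* to a node when every one of its equal-best
alignments targets a member of that node. The pair with the highest
read-set similarity — the Jaccard ratio of shared to total aligning reads
— is merged at each step, and each branch records the number of uniquely
assignable reads gained over the node's children (displayed on a log10
scale). Per-node enrichment is then annotated from the unique ChIP and
control counts using the fold-enrichment model.

Leaves are either repeat types or, for instance-level trees of a single
type, its individual genomic instances; in the instance case, reads with
any alignment outside the considered instance set are discarded first.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import AlignmentHit
from .assignment import group_hits_by_read, best_stratum_hits
from .reference import RepeatAssembly
from .stats import EnrichmentEstimate

# read_leaf_map: read_id -> frozenset of leaf ids hit at the read's best stratum
ReadLeafMap = Mapping[str, frozenset]


def leaf_read_sets_from_hits(hits: Iterable[AlignmentHit]) -> dict[str, frozenset[str]]:
    """Best-stratum target sets per read (leaves are repeat-type records)."""
    out = {}
    for read_id, read_hits in group_hits_by_read(hits).items():
        out[read_id] = frozenset(h.target for h in best_stratum_hits(read_hits))
    return out


def instance_read_sets(
    hits: Iterable[AlignmentHit],
    assembly: RepeatAssembly,
    type_name: str,
    read_lengths: Mapping[str, int],
) -> dict[str, frozenset[str]]:
    """Best-stratum instance-segment sets per read, for instance-level trees.

    A read with any admitted alignment outside the considered instance set —
    i.e. in another repeat type — is discarded entirely. Alignments to the
    same type's canonical (consensus) segment are ignored rather than
    discarded: the consensus represents the very instances under study, not
    an outside sequence.
    """
    out = {}
    for read_id, read_hits in group_hits_by_read(hits).items():
        leaf_sets = []
        outside = False
        for h in read_hits:
            if h.target != type_name:
                outside = True
                break
            seg = assembly.segment_at(h.target, h.offset, read_lengths[read_id])
            if seg is None:
                outside = True
                break
            if seg.kind != "instance":
                continue  # same-type canonical segment: neutral
            leaf_sets.append((h.mismatches, seg.leaf_id))
        if outside or not leaf_sets:
            continue
        best = min(mm for mm, _ in leaf_sets)
        out[read_id] = frozenset(leaf for mm, leaf in leaf_sets if mm == best)
    return out


@dataclass
class TreeNode:
    """A node of the enrichment phylogeny (0 or 2 children)."""

    node_id: str
    members: frozenset
    children: tuple = ()
    aligned: frozenset = frozenset()  # reads with >=1 best-stratum hit in members
    unique: frozenset = frozenset()  # reads with ALL best-stratum hits in members
    gain: int = 0
    control_unique_count: int | None = None
    estimate: EnrichmentEstimate | None = None

    @property
    def unique_count(self) -> int:
        return len(self.unique)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def branch_display_length(self) -> float:
        return math.log10(1 + self.gain)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


def node_read_sets(
    members: frozenset, read_leaf_map: ReadLeafMap
) -> tuple[frozenset, frozenset]:
    """(aligned, unique) read-id sets of a member set."""
    aligned, unique = set(), set()
    for read_id, leaves in read_leaf_map.items():
        inter = leaves & members
        if inter:
            aligned.add(read_id)
            if len(inter) == len(leaves):
                unique.add(read_id)
    return frozenset(aligned), frozenset(unique)


def node_unique_reads(members: frozenset, read_leaf_map: ReadLeafMap) -> frozenset:
    """Reads all of whose best-stratum alignments target a member."""
    return node_read_sets(members, read_leaf_map)[1]


def readset_similarity(a: TreeNode, b: TreeNode) -> float:
    """Jaccard similarity of the aligned read sets (shared / total)."""
    union = len(a.aligned | b.aligned)
    if union == 0:
        return 0.0
    return len(a.aligned & b.aligned) / union


def _min_name(node: TreeNode) -> str:
    return min(str(m) for m in node.members)


def build_tree(leaves: Sequence, read_leaf_map: ReadLeafMap) -> TreeNode:
    """Greedy agglomerative construction of the enrichment phylogeny.

    At each step the pair of active nodes with the highest read-set
    similarity is merged (ties broken lexicographically on the smallest
    member name of each side, for determinism), until a single binary root
    remains. Branch gains are the unique reads gained by each merge.
    """
    if not leaves:
        raise ValueError("no leaves given")
    active: list[TreeNode] = []
    for leaf in sorted(leaves, key=str):
        members = frozenset([leaf])
        aligned, unique = node_read_sets(members, read_leaf_map)
        active.append(
            TreeNode(
                node_id=str(leaf),
                members=members,
                aligned=aligned,
                unique=unique,
                gain=len(unique),
            )
        )
    if len(active) == 1:
        warnings.warn("single leaf: degenerate tree", stacklevel=2)
        return active[0]

    counter = 0
    while len(active) > 1:
        best_key, best_pair = None, None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                na, nb = _min_name(a), _min_name(b)
                if nb < na:
                    na, nb = nb, na
                key = (-readset_similarity(a, b), na, nb)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        a, b = active[i], active[j]
        counter += 1
        members = a.members | b.members
        aligned, unique = node_read_sets(members, read_leaf_map)
        gain = len(unique) - a.unique_count - b.unique_count
        node = TreeNode(
            node_id=f"n{counter}",
            members=members,
            children=(a, b),
            aligned=aligned,
            unique=unique,
            gain=gain,
        )
        assert gain >= 0, "unique reads cannot be lost by merging"
        active = [n for idx, n in enumerate(active) if idx not in (i, j)] + [node]
    return active[0]


def recompute_read_sets(tree: TreeNode, read_leaf_map: ReadLeafMap) -> TreeNode:
    """Re-derive aligned/unique sets and gains on a fixed topology.

    Used when the topology was built from one read set (e.g. ChIP plus
    control combined) but counts must reflect another (ChIP alone).
    """
    for node in tree.walk():
        node.aligned, node.unique = node_read_sets(node.members, read_leaf_map)
    for node in tree.walk():
        node.gain = node.unique_count - sum(c.unique_count for c in node.children)
        assert node.gain >= 0
    return tree


def annotate_tree(
    tree: TreeNode,
    control_leaf_map: ReadLeafMap,
    S: float,
    C: float,
    alpha: float = 0.05,
) -> TreeNode:
    """Attach per-node enrichment estimates from unique ChIP/control counts."""
    if C <= 0:
        raise ValueError("control dataset size must be positive")
    for node in tree.walk():
        c = len(node_unique_reads(node.members, control_leaf_map))
        node.control_unique_count = c
        node.estimate = EnrichmentEstimate.from_counts(
            node.node_id, node.unique_count, c, S, C, alpha
        )
    return tree


def instance_tree(
    type_name: str,
    assembly: RepeatAssembly,
    hits: Iterable[AlignmentHit],
    read_lengths: Mapping[str, int],
) -> TreeNode:
    """Enrichment phylogeny over the annotated instances of one repeat type."""
    leaves = [seg.leaf_id for seg in assembly.instance_segments(type_name)]
    if len(leaves) < 2:
        raise ValueError(f"{type_name}: need at least 2 instances, got {len(leaves)}")
    read_leaf_map = instance_read_sets(hits, assembly, type_name, read_lengths)
    return build_tree(leaves, read_leaf_map)


def check_tree_invariants(tree: TreeNode) -> None:
    """Gain non-negativity and conservation: every unique read gained once."""
    total_gain = 0
    for node in tree.walk():
        child_unique = sum(c.unique_count for c in node.children)
        assert node.unique_count >= child_unique
        assert node.gain == node.unique_count - child_unique
        total_gain += node.gain
    assert total_gain == tree.unique_count


def _newick_node(node: TreeNode) -> str:
    anno = f"[&unique={node.unique_count},gain={node.gain}"
    if node.estimate is not None:
        e = node.estimate
        anno += (
            f",control_unique={node.control_unique_count},mle={e.mle:.6g},"
            f"ci_low={e.ci_low:.6g},ci_high={e.ci_high:.6g},zscore={e.zscore:.4g}"
        )
    anno += "]"
    label = f"{node.node_id}{anno}:{node.branch_display_length:.6g}"
    if node.is_leaf:
        return label
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}){label}"


def write_newick(tree: TreeNode, path, annotation_path=None) -> None:
    """Write the tree as Newick, branch lengths log10(1 + gain), with an
    annotation comment per node and a companion TSV keyed by node id."""
    with open(path, "w") as fh:
        fh.write(_newick_node(tree) + ";\n")
    if annotation_path is not None:
        write_node_table(tree, annotation_path)


def write_node_table(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "node_id\tmembers\tunique_count\tcontrol_unique_count\tgain\t"
            "branch_display_length\tmle\tci_low\tci_high\tzscore\tsignificant\n"
        )
        for node in tree.walk():
            e = node.estimate
            stat = (
                f"{e.mle:.6g}\t{e.ci_low:.6g}\t{e.ci_high:.6g}\t{e.zscore:.4g}\t{e.significant}"
                if e is not None
                else "\t\t\t\t"
            )
            members = ",".join(sorted(str(m) for m in node.members))
            ctrl = "" if node.control_unique_count is None else node.control_unique_count
            fh.write(
                f"{node.node_id}\t{members}\t{node.unique_count}\t{ctrl}\t{node.gain}\t"
                f"{node.branch_display_length:.6g}\t{stat}\n"
            )
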