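"""Readers/writers for FASTA and Newick plus the core data structures.

Everything downstream consumes the types defined here: aligned sequence
records, haplotype alignments with multiplicities, raw p-distance matrices
and validated ultrametric trees with node-age bookkeeping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentError,
    EmptyInputError,
    MetadataError,
    NonBinaryTreeError,
    NonUltrametricError,
    UnknownTipError,
)

logger = logging.getLogger(__name__)

#: relative root-to-tip spread accepted by default when validating trees
DEFAULT_ULTRAMETRIC_TOLERANCE = 1e-6

#: characters removed pairwise before computing p-distances
MISSING_CHARS = frozenset("-N?")

METADATA_COLUMNS = ("id", "dataset", "clade", "habitat", "seq_length")


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A single named nucleotide sequence with optional metadata."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercased :class:`SequenceRecord` objects."""
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise EmptyInputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    if not bio:
        raise EmptyInputError("refusing to write an empty FASTA file")
    SeqIO.write(bio, str(path), "fasta-2line")


def as_alignment(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Validate a record collection as an alignment and return it as a list.

    Enforces non-emptiness, unique ids and equal sequence lengths.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("alignment holds no sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate sequence ids: {dupes}")
    lengths = {r.length for r in records}
    if len(lengths) > 1:
        raise AlignmentError(
            f"ragged alignment: sequence lengths {sorted(lengths)} differ"
        )
    return records


@dataclass
class HaplotypeAlignment:
    """Alignment after exact-duplicate collapsing, with multiplicities.

    ``multiplicity[h]`` counts how many raw input sequences collapsed into
    the retained haplotype ``h``; multiplicities sum to the raw sample size.
    """

    records: list[SequenceRecord]
    multiplicity: dict[str, int]

    @property
    def n_raw(self) -> int:
        return sum(self.multiplicity.values())

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def expanded_sequences(self) -> list[str]:
        """Sequences repeated according to their multiplicities."""
        out: list[str] = []
        for r in self.records:
            out.extend([r.seq] * self.multiplicity[r.id])
        return out


def collapse_haplotypes(
    records: Sequence[SequenceRecord],
) -> HaplotypeAlignment:
    """Merge exact-string duplicate sequences into unique haplotypes.

    Identity is exact string equality after uppercasing; gaps and ambiguity
    codes count as ordinary differing characters.  The retained id is the
    first-seen one.
    """
    records = as_alignment(records)
    seen: dict[str, SequenceRecord] = {}
    multiplicity: dict[str, int] = {}
    for rec in records:
        if rec.seq in seen:
            multiplicity[seen[rec.seq].id] += 1
        else:
            seen[rec.seq] = rec
            multiplicity[rec.id] = 1
    kept = list(seen.values())
    return HaplotypeAlignment(records=kept, multiplicity=multiplicity)


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric raw p-distance matrix with zero diagonal.

    Cells for pairs with zero comparable sites hold ``nan``.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:  # pragma: no cover - defensive
            raise UnknownTipError(str(exc)) from exc

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self._index[lab] for lab in labels]
        return self.values[np.ix_(idx, idx)]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites under pairwise deletion of gap/N sites."""
    if len(a) != len(b):
        raise AlignmentError("sequences differ in length")
    arr_a = np.frombuffer(a.upper().encode(), dtype="S1")
    arr_b = np.frombuffer(b.upper().encode(), dtype="S1")
    missing = np.isin(arr_a, _MISSING_BYTES) | np.isin(arr_b, _MISSING_BYTES)
    ok = ~missing
    n_comp = int(ok.sum())
    if n_comp == 0:
        return float("nan")
    return float((arr_a[ok] != arr_b[ok]).sum() / n_comp)


_MISSING_BYTES = np.array(sorted(c.encode() for c in MISSING_CHARS), dtype="S1")


def p_distance_matrix(
    aln: HaplotypeAlignment | Sequence[SequenceRecord],
) -> DistanceMatrix:
    """All-pairs raw p-distance under pairwise deletion.

    Sites with a gap, ``N`` or ``?`` in either member of a pair are dropped
    for that pair only.  A pair with no comparable site yields ``nan`` and is
    logged.
    """
    if isinstance(aln, HaplotypeAlignment):
        records = aln.records
    else:
        records = as_alignment(aln)
    if len(records) < 2:
        raise AlignmentError("p-distance matrix needs at least 2 sequences")
    labels = [r.id for r in records]
    mat = np.array(
        [np.frombuffer(r.seq.encode(), dtype="S1") for r in records]
    )
    valid = ~np.isin(mat, _MISSING_BYTES)
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        ok = valid[i] & valid[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & ok
        comp = ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(comp > 0, diff.sum(axis=1) / comp, np.nan)
        values[i, i + 1:] = row
        values[i + 1:, i] = row
    if np.isnan(values[np.triu_indices(n, 1)]).any():
        logger.warning(
            "p_distance_matrix: some pairs share zero comparable sites; "
            "their distances are undefined (nan)"
        )
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# ultrametric trees
# ---------------------------------------------------------------------------

class UltrametricTree:
    """A rooted binary tree with time branch lengths, validated on creation.

    Wraps a :mod:`dendropy` tree; rejects polytomies, negative edge lengths
    and root-to-tip spreads exceeding ``tolerance`` (relative to tree depth).
    Node ages (time before present) are precomputed; tips sit at age 0.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
    ) -> None:
        self._tree = tree
        self.tolerance = tolerance
        self._validate_and_index()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick_string(
        cls,
        newick: str,
        tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
    ) -> "UltrametricTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
        return cls(tree, tolerance=tolerance)

    # -- validation / indexing -------------------------------------------

    def _validate_and_index(self) -> None:
        tree = self._tree
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise NonBinaryTreeError("tree needs at least 2 tips")
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise NonBinaryTreeError(
                    f"non-binary node with {len(kids)} children"
                )
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise NonUltrametricError("edge without a branch length")
                if node.edge.length < 0:
                    raise NonUltrametricError(
                        f"negative edge length {node.edge.length}"
                    )
        # depths from root
        depth: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + node.edge.length
        tip_depths = np.array([depth[leaf] for leaf in leaves])
        span = float(tip_depths.max() - tip_depths.min())
        scale = max(float(tip_depths.max()), np.finfo(float).tiny)
        if span > self.tolerance * scale:
            raise NonUltrametricError(
                f"root-to-tip spread {span:g} exceeds tolerance "
                f"{self.tolerance:g} x depth {scale:g}"
            )
        self._depth = depth
        self._root_age = float(tip_depths.max())
        self._age = {
            node: (0.0 if node.is_leaf() else max(self._root_age - d, 0.0))
            for node, d in depth.items()
        }
        labels = []
        self._tip_nodes: dict[str, dendropy.Node] = {}
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label is None or label in self._tip_nodes:
                raise MetadataError(f"missing or duplicate tip label {label!r}")
            labels.append(label)
            self._tip_nodes[label] = leaf
        self._tip_labels = labels
        self._patristic_cache: dict[str, object] | None = None

    # -- basic accessors --------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def root_age(self) -> float:
        return self._root_age

    def age(self, node: dendropy.Node) -> float:
        return self._age[node]

    def internal_ages(self) -> np.ndarray:
        """Ages of internal nodes, sorted descending (root first)."""
        ages = [self._age[n] for n in self._tree.preorder_internal_node_iter()]
        return np.sort(np.asarray(ages))[::-1]

    def branching_times(self) -> np.ndarray:
        return self.internal_ages()

    def mrca_age(self, labels: Sequence[str]) -> float:
        for lab in labels:
            if lab not in self._tip_nodes:
                raise UnknownTipError(lab)
        taxa = [self._tip_nodes[lab].taxon for lab in labels]
        if len(set(labels)) == 1:
            return 0.0
        node = self._tree.mrca(taxa=taxa)
        return self._age[node]

    # -- distances --------------------------------------------------------

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of edge lengths along the path between tips ``a`` and ``b``."""
        for lab in (a, b):
            if lab not in self._tip_nodes:
                raise UnknownTipError(lab)
        if a == b:
            return 0.0
        na, nb = self._tip_nodes[a], self._tip_nodes[b]
        anc_a = []
        node = na
        while node is not None:
            anc_a.append(node)
            node = node.parent_node
        anc_set = set(anc_a)
        node = nb
        while node not in anc_set:
            node = node.parent_node
        mrca = node
        return float(
            self._depth[na] + self._depth[nb] - 2.0 * self._depth[mrca]
        )

    def _pair_matrices(self) -> dict[str, object]:
        """Patristic-distance and MRCA-age matrices over all tip pairs."""
        if self._patristic_cache is not None:
            return self._patristic_cache
        idx = {lab: i for i, lab in enumerate(self._tip_labels)}
        n = self.n_tips
        pat = np.zeros((n, n))
        mrca = np.zeros((n, n))
        below: dict[dendropy.Node, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                below[node] = [idx[label]]
                continue
            kids = node.child_nodes()
            left, right = below[kids[0]], below[kids[1]]
            for i in left:
                for j in right:
                    d = (
                        self._depth[self._tip_nodes[self._tip_labels[i]]]
                        + self._depth[self._tip_nodes[self._tip_labels[j]]]
                        - 2.0 * self._depth[node]
                    )
                    pat[i, j] = pat[j, i] = d
                    mrca[i, j] = mrca[j, i] = self._age[node]
            below[node] = left + right
        self._patristic_cache = {
            "labels": list(self._tip_labels),
            "patristic": pat,
            "mrca_age": mrca,
        }
        return self._patristic_cache

    def patristic_matrix(self) -> DistanceMatrix:
        cache = self._pair_matrices()
        return DistanceMatrix(
            labels=list(cache["labels"]), values=cache["patristic"].copy()
        )

    def mrca_age_matrix(self) -> DistanceMatrix:
        cache = self._pair_matrices()
        return DistanceMatrix(
            labels=list(cache["labels"]), values=cache["mrca_age"].copy()
        )

    # -- manipulation -----------------------------------------------------

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def prune_to(self, labels: Sequence[str]) -> "UltrametricTree":
        """Induced subtree on ``labels`` (edge lengths preserved)."""
        labels = list(labels)
        for lab in labels:
            if lab not in self._tip_nodes:
                raise UnknownTipError(lab)
        if len(labels) < 2:
            raise NonBinaryTreeError("cannot prune below 2 tips")
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        newick = sub.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return UltrametricTree.from_newick_string(
            newick, tolerance=max(self.tolerance, 1e-9)
        )

    def rescale(self, factor: float) -> "UltrametricTree":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return UltrametricTree(clone, tolerance=self.tolerance)


def read_newick(
    path: str | Path,
    tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
) -> UltrametricTree:
    """Read a rooted binary ultrametric Newick tree, validating on load."""
    text = Path(path).read_text().strip()
    if not text:
        raise EmptyInputError(f"empty Newick file {path}")
    return UltrametricTree.from_newick_string(text, tolerance=tolerance)


def write_newick(tree: UltrametricTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


# ---------------------------------------------------------------------------
# node times
# ---------------------------------------------------------------------------

@dataclass
class NodeTimes:
    """Node ages, descending branching times and inter-node intervals.

    ``intervals`` lists ``(width, n_lineages)`` pairs walking from the root
    (2 lineages) to the present (n lineages); the widths partition
    ``[0, root_age]``.
    """

    ages: dict
    branching_times: np.ndarray
    intervals: list[tuple[float, int]]


def node_times(tree: UltrametricTree) -> NodeTimes:
    ages = {
        node: tree.age(node)
        for node in tree.dendropy_tree.preorder_node_iter()
    }
    bt = tree.branching_times()
    n = tree.n_tips
    bounds = np.concatenate([bt, [0.0]])
    intervals = [
        (float(bounds[k - 2] - bounds[k - 1]), k) for k in range(2, n + 1)
    ]
    return NodeTimes(ages=ages, branching_times=bt, intervals=intervals)


def patristic_distance(tree: UltrametricTree, a: str, b: str) -> float:
    return tree.patristic_distance(a, b)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated metadata table (id, dataset, clade, habitat,
    seq_length)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata table lacks columns: {missing}")
    if df["id"].duplicated().any():
        raise MetadataError("metadata table holds duplicate ids")
    return df


def attach_metadata(
    records: Sequence[SequenceRecord], meta: pd.DataFrame
) -> list[SequenceRecord]:
    table: Mapping[str, dict] = meta.set_index("id").to_dict("index")
    out = []
    for rec in records:
        if rec.id not in table:
            raise MetadataError(f"no metadata row for sequence {rec.id!r}")
        rec.meta = dict(table[rec.id])
        out.append(rec)
    return out


def validate_join(
    tree: UltrametricTree, records: Sequence[SequenceRecord]
) -> None:
    """Require an exact, case-sensitive 1:1 match of tip labels and ids."""
    tips = set(tree.tip_labels)
    ids = {r.id for r in records}
    if tips != ids:
        missing_seq = sorted(tips - ids)[:5]
        missing_tip = sorted(ids - tips)[:5]
        raise MetadataError(
            "tip labels and sequence ids do not match "
            f"(tips without sequences: {missing_seq}; "
            f"sequences without tips: {missing_tip})"
        )


def collapse_and_prune(
    tree: UltrametricTree, records: Sequence[SequenceRecord]
) -> tuple[UltrametricTree, HaplotypeAlignment]:
    """Collapse duplicate sequences and prune the tree to retained haplotypes.

    Mirrors pre-analysis haplotype collapsing: the gene tree keeps one tip
    per unique sequence (first-seen id) and the multiplicities remember how
    many samples each haplotype represents.
    """
    validate_join(tree, records)
    hap = collapse_haplotypes(records)
    kept = [r.id for r in hap.records]
    if len(kept) == tree.n_tips:
        return tree, hap
    pruned = tree.prune_to(kept)
    return pruned, hap


def expand_by_multiplicity(hap: HaplotypeAlignment) -> list[str]:
    return hap.expanded_sequences()


__all__ = [
    "SequenceRecord",
    "HaplotypeAlignment",
    "DistanceMatrix",
    "UltrametricTree",
    "NodeTimes",
    "read_fasta",
    "write_fasta",
    "as_alignment",
    "collapse_haplotypes",
    "p_distance",
    "p_distance_matrix",
    "read_newick",
    "write_newick",
    "node_times",
    "patristic_distance",
    "read_metadata",
    "attach_metadata",
    "validate_join",
    "collapse_and_prune",
]
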