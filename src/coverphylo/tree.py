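"""Phylogenetic trees and the distance structures derived from them.

The analysis pipeline consumes a rooted tree with branch lengths covering
cover-crop and weed taxa.  This module parses Newick, resolves polytomies
into dichotomies with zero-length branches (a distance-preserving step),
relabels tips according to a sister-taxon substitution table, and converts
the tree into the phylogenetic variance-covariance matrix ``C`` (shared
root-to-tip path length) and the patristic distance matrix
``d_ij = C_ii + C_jj - 2 C_ij`` that mean-pairwise-distance metrics average.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "MissingBranchLengthError",
    "PhyloTree",
    "TaxonMatrix",
    "VcvMatrix",
    "PatristicMatrix",
    "SubstitutionMap",
    "SubstitutionReport",
    "parse_newick",
    "read_newick",
    "resolve_polytomies",
    "apply_substitutions",
    "vcv_matrix",
    "patristic_distances",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed; carries the offset."""


class MissingBranchLengthError(ValueError):
    """Raised when a distance computation hits an edge without a length."""


def _precheck_newick(text: str) -> None:
    """Scan for unbalanced parentheses / a missing ';' terminator.

    Bracketed comments and quoted labels are skipped so that stray
    parentheses inside them do not trip the balance check.
    """
    depth = 0
    in_quote = False
    in_comment = False
    terminated = False
    for offset, ch in enumerate(text):
        if in_comment:
            if ch == "]":
                in_comment = False
            continue
        if in_quote:
            if ch == "'":
                in_quote = False
            continue
        if ch == "'":
            in_quote = True
        elif ch == "[":
            in_comment = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at offset {offset} in Newick input"
                )
        elif ch == ";":
            if depth != 0:
                raise NewickParseError(
                    f"';' at offset {offset} inside {depth} unclosed '('"
                )
            terminated = True
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of Newick input (offset {len(text)})"
        )
    if not terminated:
        raise NewickParseError(
            f"Newick input not terminated by ';' (offset {len(text)})"
        )


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths.

    Thin wrapper over :class:`dendropy.Tree` exposing exactly what the
    downstream analysis needs: tip labels, binarity, ultrametricity, and
    root-to-tip depths.  Zero-length edges are legal everywhere (polytomy
    resolution inserts them); missing edge lengths are tolerated at parse
    time and rejected only when distances are requested.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise NewickParseError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self._taxa = tuple(labels)

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _precheck_newick(text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several DataError types
            raise NewickParseError(f"Newick parse failed: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        # pairs with preserve_underscores on the parse side so labels with
        # underscores or spaces survive a write -> parse round trip
        self._tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            preserve_spaces=True,
        )
        return out.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- properties -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxa(self) -> tuple[str, ...]:
        return self._taxa

    @property
    def n_tips(self) -> int:
        return len(self._taxa)

    @property
    def is_binary(self) -> bool:
        for node in self._tree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                return False
        return True

    @property
    def has_missing_lengths(self) -> bool:
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                return True
        return False

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths: dict[str, float] = {}
        self._check_lengths()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                node._root_dist = node.edge.length or 0.0
            else:
                node._root_dist = node.parent_node._root_dist + node.edge.length
            if node.is_leaf():
                depths[node.taxon.label] = node._root_dist
        return depths

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        """Relative tip-depth spread below ``rel_tol``.

        Reported, not enforced: MPD is defined on any additive tree.
        """
        d = np.array(list(self.tip_depths().values()))
        dmax = d.max()
        if dmax == 0:
            return True
        return (d.max() - d.min()) / dmax < rel_tol

    def _check_lengths(self) -> None:
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                child = node.taxon.label if node.is_leaf() else "internal node"
                parent = node.parent_node
                pname = (
                    parent.taxon.label
                    if parent.taxon is not None
                    else "internal node"
                )
                raise MissingBranchLengthError(
                    f"edge {pname} -> {child} has no branch length"
                )

    def __repr__(self) -> str:
        kind = "binary" if self.is_binary else "non-binary"
        return f"<PhyloTree {self.n_tips} tips, {kind}>"


def parse_newick(text: str) -> PhyloTree:
    """Parse a ';'-terminated Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def read_newick(path) -> PhyloTree:
    return PhyloTree.from_file(path)


# -- polytomy resolution ------------------------------------------------


def resolve_polytomies(tree: PhyloTree, seed: int) -> PhyloTree:
    """Resolve every polytomy into dichotomies joined by zero-length edges.

    At each multifurcating node, two children are drawn at random and
    joined under a new zero-length internal node; this repeats until the
    node is binary.  The tip set and every patristic distance are
    unchanged; only the (arbitrary) topology of the zero-length region
    depends on ``seed``.
    """
    rng = random.Random(seed)
    out = tree.copy()
    dtree = out.dendropy_tree
    for node in list(dtree.preorder_internal_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            a, b = rng.sample(range(len(children)), 2)
            ca, cb = children[a], children[b]
            node.remove_child(ca)
            node.remove_child(cb)
            merged = dendropy.Node()
            merged.edge.length = 0.0
            merged.add_child(ca)
            merged.add_child(cb)
            node.add_child(merged)
    return PhyloTree(dtree)


# -- sister-taxon substitution ------------------------------------------


@dataclass(frozen=True)
class SubstitutionMap:
    """Observed-name -> tree-tip substitutions (sister-taxon stand-ins).

    Species observed in the field but absent from the phylogeny are
    represented on the tree by a named sister taxon; applying the map
    relabels that tip to the observed name.
    """

    pairs: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        # dict keys are unique by construction; guard against two observed
        # names claiming the same tip, which would collide after relabeling
        targets = list(self.pairs.values())
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        if dupes:
            raise ValueError(
                f"multiple observed names map to the same tree tip: {dupes}"
            )

    @classmethod
    def from_table(cls, path) -> "SubstitutionMap":
        """Read a 2-column delimited table: observed_name, tree_name.

        An optional third column holds a provenance note per pair.
        """
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        for col in ("observed_name", "tree_name"):
            if col not in cols:
                raise ValueError(f"substitution table missing column {col!r}")
        pairs = dict(zip(df["observed_name"], df["tree_name"]))
        if len(pairs) != len(df):
            raise ValueError("duplicate observed_name entries in substitution table")
        prov = {}
        if "note" in cols:
            prov = {
                o: n
                for o, n in zip(df["observed_name"], df["note"])
                if isinstance(n, str)
            }
        return cls(pairs=pairs, provenance=prov)


@dataclass(frozen=True)
class SubstitutionReport:
    applied: tuple[tuple[str, str], ...]
    unmatched_observed: tuple[str, ...]


def apply_substitutions(
    tree: PhyloTree,
    submap: SubstitutionMap,
    observed_taxa: list[str] | tuple[str, ...],
) -> tuple[PhyloTree, SubstitutionReport]:
    """Relabel sister-taxon tips to the names observed in the biomass data.

    Returns the relabeled tree plus a report of the substitutions applied
    and the observed taxa that still have no tip on the tree (these are
    later excluded from phylogenetic computations but kept in biomass
    totals).  Raises if a map target is not a tip, or if an observed name
    and its stand-in tip both occur in the observed data (the identity of
    the tip would be ambiguous).
    """
    tips = set(tree.taxa)
    observed = set(observed_taxa)
    for obs, target in submap.pairs.items():
        if target not in tips:
            raise ValueError(
                f"substitution {obs!r} -> {target!r}: {target!r} is not a tip"
            )
        if obs in observed and target in observed:
            raise ValueError(
                f"ambiguous substitution {obs!r} -> {target!r}: both names "
                "occur in the observed data"
            )
    out = tree.copy()
    applied = []
    for obs, target in submap.pairs.items():
        if obs not in observed:
            continue  # substitution irrelevant to this dataset
        for leaf in out.dendropy_tree.leaf_node_iter():
            if leaf.taxon.label == target:
                leaf.taxon.label = obs
                applied.append((obs, target))
                break
    out = PhyloTree(out.dendropy_tree)
    unmatched = tuple(sorted(observed - set(out.taxa)))
    return out, SubstitutionReport(applied=tuple(applied), unmatched_observed=unmatched)


# -- distance matrices ---------------------------------------------------


class TaxonMatrix:
    """Symmetric taxon-by-taxon matrix with ordered labels."""

    def __init__(self, taxa: tuple[str, ...], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(taxa), len(taxa)):
            raise ValueError("matrix shape does not match taxon list")
        self.taxa = tuple(taxa)
        self.values = values
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, taxa) -> "TaxonMatrix":
        idx = [self._index[t] for t in taxa]
        return type(self)(tuple(taxa), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {len(self.taxa)} taxa>"


class VcvMatrix(TaxonMatrix):
    """Phylogenetic variance-covariance matrix.

    Entry ``C_ij`` is the shared root-to-tip path length of taxa i and j;
    the diagonal holds tip depths.
    """


class PatristicMatrix(TaxonMatrix):
    """Patristic (tip-to-tip path length) distance matrix ``d_ij``."""


def vcv_matrix(tree: PhyloTree) -> VcvMatrix:
    """Phylogenetic variance-covariance matrix of the tree's tips.

    Computed in a single postorder pass: tips in different child subtrees
    of a node share exactly that node's root distance.
    """
    tree._check_lengths()
    dtree = tree.dendropy_tree
    taxa = tree.taxa
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            node._root_dist = node.edge.length or 0.0
        else:
            node._root_dist = node.parent_node._root_dist + node.edge.length
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = node._root_dist
            node._tip_idx = [i]
            continue
        groups = [child._tip_idx for child in node.child_nodes()]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ii = np.asarray(groups[gi])
                jj = np.asarray(groups[gj])
                C[np.ix_(ii, jj)] = node._root_dist
                C[np.ix_(jj, ii)] = node._root_dist
        node._tip_idx = [i for g in groups for i in g]
    return VcvMatrix(taxa, C)


def patristic_distances(tree: PhyloTree) -> PatristicMatrix:
    """Patristic distance matrix via ``d_ij = C_ii + C_jj - 2 C_ij``."""
    C = vcv_matrix(tree)
    diag = np.diag(C.values)
    D = diag[:, None] + diag[None, :] - 2.0 * C.values
    np.fill_diagonal(D, 0.0)
    # zero-length resolution can leave tiny negative rounding residue
    D[D < 0] = np.where(D[D < 0] > -1e-12, 0.0, D[D < 0])
    return PatristicMatrix(C.taxa, D)
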