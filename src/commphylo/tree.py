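"""Regional phylogeny handling: newick I/O, age calibration, distances, Faith's PD.

The phylogeny is the backbone of every metric in this package.  Trees are
stored as rooted :class:`dendropy.Tree` objects wrapped in :class:`PhyloTree`,
with branch lengths in millions of years (Myr).  Megatree-style trees (as
produced by taxonomy-grafting tools) typically arrive with topology but few
reliable branch lengths; :func:`bladj_calibrate` implements the classic
branch-length-adjustment scheme in which a small set of dated nodes (ages
taken from a fossil/molecular calibration table) anchors the tree and every
undated node receives an age by even interpolation between its nearest dated
ancestor and nearest dated descendant (tips count as dated at age 0).  The
result is ultrametric in age, so patristic distances read directly as twice
the age of the most recent common ancestor.

Polytomies are allowed everywhere: grafted regional trees are polytomy-rich
and none of the metrics downstream require a binary tree.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative tolerance used for ultrametricity / age-consistency checks
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural invariant."""


class CalibrationError(ValueError):
    """Raised when age constraints are inconsistent with the tree."""


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"<unlabelled node {id(node):#x}>"


def _check_balanced(text: str) -> None:
    """Pre-scan parentheses so parse errors can report a character offset."""
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced parentheses: unexpected ')' at character offset {i}"
                    )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of statement "
            f"(length {len(text)})"
        )


@dataclass(frozen=True)
class AgeConstraints:
    """Fixed node ages (Myr) keyed by node label.

    This is the interface to whatever age database the user calibrates
    against; the package never fetches ages itself.  The constraint file is
    two-column text, ``node_label age``, whitespace- or comma-delimited, with
    ``#`` comments.
    """

    ages: dict

    def __post_init__(self):
        for label, age in self.ages.items():
            if not label:
                raise ValueError("empty node label in age constraints")
            if age < 0:
                raise ValueError(f"negative age for node {label!r}: {age}")

    @classmethod
    def read(cls, path) -> "AgeConstraints":
        ages = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'node_label age', got {raw!r}")
            ages[parts[0]] = float(parts[1])
        return cls(ages)

    def items(self):
        return self.ages.items()

    def __contains__(self, label):
        return label in self.ages

    def __getitem__(self, label):
        return self.ages[label]

    def __len__(self):
        return len(self.ages)


class DistanceMatrix:
    """Symmetric species-by-species patristic distance matrix (Myr)."""

    __slots__ = ("labels", "values", "_index")

    def __init__(self, labels, values):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("distance matrix shape does not match label count")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise ValueError("negative distances")
        self.labels = labels
        self.values = values
        self._index = {l: i for i, l in enumerate(labels)}

    def get(self, a, b) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self._index]
        if missing:
            raise KeyError(f"species absent from distance matrix: {sorted(missing)}")
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __len__(self):
        return len(self.labels)


class PhyloTree:
    """A rooted phylogeny with branch lengths (Myr) and optional node ages.

    Thin wrapper around :class:`dendropy.Tree` that enforces the invariants
    the analysis relies on (unique non-empty tip labels, a single root) and
    carries node ages after calibration (tips at age 0, every parent at least
    as old as its children).
    """

    def __init__(self, dtree: dendropy.Tree, calibrated: bool = False):
        dtree.is_rooted = True
        self._tree = dtree
        self.calibrated = calibrated
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    @classmethod
    def read_newick(cls, path) -> "PhyloTree":
        return parse_newick(Path(path).read_text())

    def _validate(self):
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree contains a tip with an empty label")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self):
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root_age(self):
        return getattr(self._tree.seed_node, "age", None)

    def age_of(self, label: str) -> float:
        """Age (Myr) of the node carrying ``label`` (tip or internal label)."""
        for node in self._tree.preorder_node_iter():
            if _node_name(node) == label:
                age = getattr(node, "age", None)
                if age is None:
                    raise KeyError(f"node {label!r} has no age (tree not calibrated?)")
                return age
        raise KeyError(f"no node labelled {label!r}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(dendropy.Tree(self._tree), calibrated=self.calibrated)

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = []
        for leaf in self._tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                if node.edge.length is None:
                    return False
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        depths = np.array(depths)
        scale = max(depths.max(), 1e-12)
        return bool(np.all(np.abs(depths - depths.max()) <= rtol * scale))

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        ).strip()
        return s + "\n"

    def write_newick(self, path) -> None:
        Path(path).write_text(self.to_newick())


def parse_newick(text: str) -> PhyloTree:
    """Parse a single ';'-terminated newick statement into a :class:`PhyloTree`.

    Quoted labels are accepted; underscores are kept literal (no
    underscore-to-space conversion).  Polytomies are allowed.
    """
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise TreeValidationError(f"duplicate tip label: {e}") from e
    except Exception as e:  # dendropy raises several reader-specific errors
        raise NewickParseError(str(e)) from e
    return PhyloTree(dtree)


def write_newick(tree: PhyloTree, path=None) -> str:
    s = tree.to_newick()
    if path is not None:
        Path(path).write_text(s)
    return s


# ---------------------------------------------------------------------------
# BLADJ-style calibration
# ---------------------------------------------------------------------------

def bladj_calibrate(tree: PhyloTree, constraints: AgeConstraints | None = None,
                    root_age: float | None = None) -> PhyloTree:
    """Assign node ages by even interpolation between dated nodes.

    Dated nodes are the root (via ``root_age`` or a constraint on the root's
    label), every constrained internal node, and all tips (age 0).  Nodes are
    visited from the root toward the tips; each undated node interpolates
    between the age already fixed on its parent and its nearest originally
    dated descendant, where "nearest" counts intervening nodes (ties broken
    toward the older candidate so ancestor ages can never undercut a dated
    descendant on an equally short path).  On a chain of undated nodes this
    reduces to dividing the dated-to-dated age interval into equal steps.

    Branch lengths are recomputed as age differences, so the output is
    ultrametric in age.

    Raises :class:`CalibrationError` when a constraint contradicts ancestry
    order (a descendant dated older than its ancestor), naming both nodes.
    """
    cons = dict(constraints.items()) if constraints is not None else {}
    out = dendropy.Tree(tree.dendropy_tree)

    by_label = {}
    for node in out.preorder_node_iter():
        name = _node_name(node)
        if not name.startswith("<unlabelled"):
            by_label.setdefault(name, node)

    missing = [l for l in cons if l not in by_label]
    if missing:
        raise CalibrationError(f"constrained labels absent from tree: {sorted(missing)}")

    root = out.seed_node
    root_label = _node_name(root)
    if root_label in cons:
        root_val = cons[root_label]
        if root_age is not None and abs(root_age - root_val) > ULTRAMETRIC_RTOL * max(1.0, root_val):
            raise CalibrationError(
                f"root age argument ({root_age}) conflicts with constraint on "
                f"{root_label!r} ({root_val})"
            )
    elif root_age is not None:
        root_val = float(root_age)
    else:
        raise CalibrationError("root age must be fixed by a constraint or the root_age argument")

    def constraint_age(node):
        name = _node_name(node)
        if name in cons:
            return cons[name]
        return None

    # ancestry-order consistency among constrained nodes (tips are 0)
    for node in out.preorder_node_iter():
        a = constraint_age(node)
        if node.is_leaf() and a is not None and a != 0:
            raise CalibrationError(f"tip {_node_name(node)!r} constrained to nonzero age {a}")
        if a is None and not node.is_leaf():
            continue
        age_here = 0.0 if node.is_leaf() else a
        anc = node.parent_node
        while anc is not None:
            a_anc = root_val if anc is root and constraint_age(anc) is None else constraint_age(anc)
            if a_anc is not None and age_here - a_anc > ULTRAMETRIC_RTOL * max(1.0, age_here):
                raise CalibrationError(
                    f"descendant {_node_name(node)!r} (age {age_here}) is older than "
                    f"ancestor {_node_name(anc)!r} (age {a_anc})"
                )
            anc = anc.parent_node

    # nearest originally-dated descendant: (steps, age); ties -> older age
    ndd = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            ndd[node] = (0, 0.0)
        elif constraint_age(node) is not None:
            ndd[node] = (0, constraint_age(node))
        else:
            best = None
            for ch in node.child_nodes():
                s, a = ndd[ch]
                cand = (s + 1, a)
                if best is None or cand[0] < best[0] or (cand[0] == best[0] and cand[1] > best[1]):
                    best = cand
            ndd[node] = best

    # top-down assignment
    for node in out.preorder_node_iter():
        if node is root:
            node.age = root_val if constraint_age(node) is None else constraint_age(node)
        elif node.is_leaf():
            node.age = 0.0
        else:
            a = constraint_age(node)
            if a is not None:
                node.age = a
            else:
                ap = node.parent_node.age
                s, aw = ndd[node]
                node.age = ap - (ap - aw) / (s + 1)

    # recompute branch lengths, validating age monotonicity
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        bl = node.parent_node.age - node.age
        if bl < -ULTRAMETRIC_RTOL * max(1.0, node.parent_node.age):
            raise CalibrationError(
                f"negative branch above {_node_name(node)!r}: parent "
                f"{_node_name(node.parent_node)!r} age {node.parent_node.age} < "
                f"child age {node.age}"
            )
        node.edge.length = max(bl, 0.0)

    return PhyloTree(out, calibrated=True)


# ---------------------------------------------------------------------------
# Distances and Faith's PD
# ---------------------------------------------------------------------------

def cophenetic(tree: PhyloTree) -> DistanceMatrix:
    """All-pairs patristic (cophenetic) distances between tips.

    Entry (i, j) is the sum of branch lengths on the path between tips i and
    j.  On an age-calibrated tree this equals twice the age of the pair's most
    recent common ancestor.
    """
    tips = tree.tip_labels
    if len(tips) == 1:
        return DistanceMatrix(tips, np.zeros((1, 1)))
    idx = {l: i for i, l in enumerate(tips)}
    n = len(tips)
    M = np.zeros((n, n))
    carry = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            carry[node] = [(idx[node.taxon.label], 0.0)]
            continue
        lists = []
        for ch in node.child_nodes():
            bl = ch.edge.length
            if bl is None:
                raise TreeValidationError(
                    f"missing branch length on edge above {_node_name(ch)!r}"
                )
            lists.append([(i, d + bl) for i, d in carry.pop(ch)])
        for a in range(len(lists)):
            for b in range(a + 1, len(lists)):
                for i, di in lists[a]:
                    for j, dj in lists[b]:
                        M[i, j] = M[j, i] = di + dj
        carry[node] = [x for lst in lists for x in lst]
    return DistanceMatrix(tips, M)


def faith_pd(tree: PhyloTree, species, rooted: str = "mrca") -> float:
    """Faith's phylogenetic diversity of a species set (Myr of branch length).

    Sums the branch lengths of the minimal spanning subtree connecting the
    sampled tips.  With ``rooted="mrca"`` (default) the subtree is rooted at
    the most recent common ancestor of the sample, so a single species has
    PD = 0; with ``rooted="root"`` the path from the MRCA up to the global
    root is included as well (both conventions are in common use).
    """
    species = set(species)
    if not species:
        raise ValueError("faith_pd requires at least one species")
    if rooted not in ("mrca", "root"):
        raise ValueError(f"rooted must be 'mrca' or 'root', got {rooted!r}")
    tipset = set(tree.tip_labels)
    unknown = species - tipset
    if unknown:
        raise TreeValidationError(f"species absent from tree: {sorted(unknown)}")

    total = len(species)
    count = {}
    mrca = None
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in species else 0
        else:
            c = sum(count[ch] for ch in node.child_nodes())
        count[node] = c
        if mrca is None and c == total:
            mrca = node  # postorder: first node covering the full sample is deepest

    def edge_len(node):
        if node.edge.length is None:
            raise TreeValidationError(f"missing branch length on edge above {_node_name(node)!r}")
        return node.edge.length

    pd_sum = 0.0
    stack = list(mrca.child_nodes())
    while stack:
        node = stack.pop()
        if count[node] >= 1:
            pd_sum += edge_len(node)
            stack.extend(node.child_nodes())
    if rooted == "root":
        node = mrca
        while node.parent_node is not None:
            pd_sum += edge_len(node)
            node = node.parent_node
    return pd_sum
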