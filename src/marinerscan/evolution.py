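"""Pairwise identities/distances, neighbor-joining trees, and family
classification of catalytic domains.

Distances default to Kimura two-parameter (K2P), which corrects transition
and transversion fractions separately:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion fractions over the comparable
(pairwise-deletion) columns.  Tree inference is canonical Saitou-Nei
neighbor joining with the Studier-Keppler Q-matrix, with nonparametric
bootstrap support over resampled alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _pairwise
from .io_formats import logger

TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "T"))}


# ---------------------------------------------------------------------------
# Distance and identity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix under a stated model (pairwise deletion)."""

    labels: list[str]
    values: np.ndarray
    model: str = "k2p"
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        expected_diag = 1.0 if self.model == "identity" else 0.0
        if not np.allclose(np.diag(self.values), expected_diag):
            raise ValueError(f"matrix diagonal must be {expected_diag}")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def _comparable_columns(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    for x, y in zip(a, b):
        if x not in "-N" and y not in "-N" and x != "." and y != ".":
            yield x, y


def pairwise_identity(a: str, b: str) -> float:
    """Matches over columns where neither sequence has a gap (or N)."""
    matches = total = 0
    for x, y in _comparable_columns(a, b):
        total += 1
        if x == y:
            matches += 1
    if total == 0:
        raise ValueError("no comparable columns between the aligned pair")
    return matches / total


def p_distance(a: str, b: str) -> float:
    return 1.0 - pairwise_identity(a, b)


@dataclass
class K2PResult:
    distance: float
    saturated: bool
    transitions: float
    transversions: float


def k2p_distance(a: str, b: str) -> K2PResult:
    """Kimura two-parameter distance with pairwise deletion.

    Saturated pairs (log argument <= 0) are flagged rather than returned as
    infinities; callers exclude them downstream.
    """
    ts = tv = total = 0
    for x, y in _comparable_columns(a, b):
        total += 1
        if x == y:
            continue
        if frozenset((x, y)) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if total == 0:
        raise ValueError("no comparable columns between the aligned pair")
    P, Q = ts / total, tv / total
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(distance=math.inf, saturated=True, transitions=P, transversions=Q)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(distance=d, saturated=False, transitions=P, transversions=Q)


def distance_matrix(aligned: dict[str, str], model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix from a dict of aligned sequences."""
    labels = list(aligned)
    n = len(labels)
    values = np.zeros((n, n))
    if model == "identity":
        np.fill_diagonal(values, 1.0)
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[labels[i]], aligned[labels[j]]
            if model == "k2p":
                r = k2p_distance(a, b)
                if r.saturated:
                    saturated.add((labels[i], labels[j]))
                    d = 5.0  # placeholder; flagged pairs are excluded downstream
                else:
                    d = r.distance
            elif model == "p-distance":
                d = p_distance(a, b)
            elif model == "identity":
                d = pairwise_identity(a, b)
            else:
                raise ValueError(f"unknown model {model!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, model=model,
                          saturated=saturated)


def identity_matrix(aligned: dict[str, str]) -> DistanceMatrix:
    return distance_matrix(aligned, model="identity")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree with labeled leaves, branch lengths, optional support."""

    root: TreeNode

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.label)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.label}
            below: set[str] = set()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def support_of(self, bipartition: frozenset[str]) -> float | None:
        found: list[float | None] = []
        all_leaves = set(self.leaves())
        ref = min(all_leaves)

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf():
                return {node.label}
            below: set[str] = set()
            for child, _ in node.children:
                below |= walk(child)
            side = below if ref not in below else all_leaves - below
            if frozenset(side) == bipartition:
                found.append(node.support)
            return below

        walk(self.root)
        return found[0] if found else None

    def newick(self, include_support: bool = False) -> str:
        def fmt_label(label: str) -> str:
            if any(c in label for c in "():;, '\t[]"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def walk(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                text = fmt_label(node.label or "")
            else:
                inner = ",".join(walk(c, l) for c, l in node.children)
                text = f"({inner})"
                if include_support and node.support is not None:
                    text += f"{node.support:g}"
            if length is not None:
                text += f":{length:.6f}"
            return text

        return walk(self.root, None) + ";"

    def as_dendropy(self):
        import dendropy

        from .io_formats import read_newick_string
        return read_newick_string(self.newick(include_support=True))

    def restricted_to(self, keep: set[str]) -> "PhyloTree":
        """Tree restricted to a leaf subset, unifurcations suppressed."""

        def walk(node: TreeNode, length: float) -> tuple[TreeNode, float] | None:
            if node.is_leaf():
                return (node, length) if node.label in keep else None
            kept = []
            for child, l in node.children:
                sub = walk(child, l)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            if len(kept) == 1:
                child, l = kept[0]
                return (child, l + length)
            new = TreeNode(children=kept, support=node.support)
            return (new, length)

        result = walk(self.root, 0.0)
        if result is None:
            return PhyloTree(root=TreeNode())
        return PhyloTree(root=result[0])


def from_dendropy(dtree) -> PhyloTree:
    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(label=node.taxon.label if node.taxon else None)
        out = TreeNode(label=None)
        if node.label is not None:
            try:
                out.support = float(node.label)
            except ValueError:
                pass
        for child in node.child_nodes():
            out.children.append((convert(child), child.edge.length or 0.0))
        return out

    return PhyloTree(root=convert(dtree.seed_node))


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-matrix.

    Negative branch lengths are clamped to zero (the deficit is logged);
    ties in Q are broken by the lexicographically smallest cluster-label
    pair, making the agglomeration deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    names: list[str] = list(dm.labels)  # cluster tie-break labels (min leaf)
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.6g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        best_key = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * D[i, j] - R[i] - R[j]
                pair_names = tuple(sorted((names[i], names[j])))
                key = (q, pair_names)
                if best_key is None or key < best_key:
                    best_key, best = key, (i, j)
        i, j = best
        vi = clamp(D[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2)))
        vj = clamp(D[i, j] - D[i, j] / 2 - (R[i] - R[j]) / (2 * (r - 2)))
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for m in active:
            if m in (i, j):
                continue
            d = (D[i, m] + D[j, m] - D[i, j]) / 2
            D[k, m] = D[m, k] = d
        nodes.append(new)
        names.append(min(names[i], names[j]))
        active = [m for m in active if m not in (i, j)] + [k]

    i, j, k = active
    a = clamp((D[i, j] + D[i, k] - D[j, k]) / 2)
    b = clamp((D[i, j] + D[j, k] - D[i, k]) / 2)
    c = clamp((D[i, k] + D[j, k] - D[i, j]) / 2)
    root = TreeNode(children=[(nodes[i], a), (nodes[j], b), (nodes[k], c)])
    return PhyloTree(root=root)


def bootstrap_support(aligned: dict[str, str],
                      replicates: int = 1000,
                      seed: int | np.random.Generator = 0,
                      model: str = "k2p",
                      tree_builder=neighbor_joining) -> PhyloTree:
    """Nonparametric bootstrap: columns resampled with replacement.

    Support on each internal branch of the full-data tree is the percentage
    of replicate trees containing the same bipartition.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(aligned)
    width = len(aligned[labels[0]])
    if width < 10:
        raise ValueError("alignment must have >= 10 columns")
    arrays = {l: np.frombuffer(aligned[l].encode(), dtype="S1") for l in labels}

    tree = tree_builder(distance_matrix(aligned, model=model))
    target = {bp: 0 for bp in tree.bipartitions()}

    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        sample = {l: arrays[l][cols].tobytes().decode() for l in labels}
        rep_tree = tree_builder(distance_matrix(sample, model=model))
        for bp in rep_tree.bipartitions():
            if bp in target:
                target[bp] += 1

    supports = {bp: 100.0 * c / replicates for bp, c in target.items()}
    _annotate_support(tree, supports)
    return tree


def _annotate_support(tree: PhyloTree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = set(tree.leaves())
    ref = min(all_leaves)

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf():
            return {node.label}
        below: set[str] = set()
        for child, _ in node.children:
            below |= walk(child)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = supports.get(frozenset(side))
        return below

    walk(tree.root)


# ---------------------------------------------------------------------------
# Family classification
# ---------------------------------------------------------------------------

@dataclass
class FamilyCall:
    label: str
    mean_identity: float
    runner_up: str | None
    margin: float
    low_confidence: bool
    per_family_identity: dict[str, float]
    signature_matches: bool | None = None


def classify_family(query: str, references: list[tuple[str, str, str]],
                    query_signature: str | None = None,
                    family_signatures: dict[str, str] | None = None,
                    low_confidence_margin: float = 0.05) -> FamilyCall:
    """Assign a query catalytic domain to the reference family with the
    highest mean pairwise identity (global affine alignments).

    ``references`` is a list of (reference id, family label, protein).
    """
    if len({fam for _, fam, _ in references}) < 2:
        raise ValueError("reference set must contain >= 2 families")
    per_family: dict[str, list[float]] = {}
    for _, fam, seq in references:
        aln = _pairwise.global_protein(seq, query, free_end_gaps=True)
        per_family.setdefault(fam, []).append(
            pairwise_identity(aln.aligned_target, aln.aligned_query))
    means = {fam: float(np.mean(v)) for fam, v in per_family.items()}
    ordered = sorted(means.items(), key=lambda t: (-t[1], t[0]))
    label, best = ordered[0]
    runner_up, second = (ordered[1] if len(ordered) > 1 else (None, 0.0))
    margin = best - second
    signature_matches = None
    if query_signature is not None and family_signatures is not None:
        signature_matches = family_signatures.get(label) == query_signature
    return FamilyCall(label=label, mean_identity=best, runner_up=runner_up,
                      margin=margin, low_confidence=margin < low_confidence_margin,
                      per_family_identity=means,
                      signature_matches=signature_matches)
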