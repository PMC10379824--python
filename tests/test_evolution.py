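import math

import numpy as np
import pytest

from marinerscan import mutate_sequence
from marinerscan.evolution import (DistanceMatrix, PhyloTree, TreeNode,
                                   bootstrap_support, classify_family,
                                   distance_matrix, identity_matrix,
                                   k2p_distance, neighbor_joining, p_distance,
                                   pairwise_identity)
from marinerscan.synthetic_data import random_dna


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == 1.0

    def test_three_quarters(self):
        assert pairwise_identity("ACGT", "ACGA") == 0.75

    def test_gap_columns_excluded(self):
        # 3 comparable columns, all matching
        assert pairwise_identity("AC-T", "ACGT") == 1.0
        assert pairwise_identity("AC-T", "ACGA") == pytest.approx(2 / 3)

    def test_no_comparable_columns(self):
        with pytest.raises(ValueError):
            pairwise_identity("--", "AA")


class TestK2P:
    def test_identical_zero(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10).distance == 0.0

    def test_closed_form_value(self):
        """P=0.1, Q=0.05 evaluates to -0.5*ln(0.75*sqrt(0.9)) ~ 0.17018."""
        n = 200
        a = list("A" * n)
        b = list("A" * n)
        for i in range(20):       # transitions A->G
            b[i] = "G"
        for i in range(20, 30):   # transversions A->C
            b[i] = "C"
        r = k2p_distance("".join(a), "".join(b))
        expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert r.distance == pytest.approx(expected, abs=1e-12)
        assert r.distance == pytest.approx(0.17018, abs=1e-5)

    def test_saturation_flagged(self):
        n = 100
        b = ["G"] * 50 + ["C"] * 25 + ["A"] * 25
        r = k2p_distance("A" * n, "".join(b))
        assert r.saturated

    def test_k2p_at_least_p_distance(self, rng):
        """Jensen-type inequality of the correction on random alignments."""
        for _ in range(30):
            a = random_dna(rng, 300)
            b = mutate_sequence(a, float(rng.uniform(0.01, 0.25)), rng)
            r = k2p_distance(a, b)
            if not r.saturated:
                assert r.distance >= p_distance(a, b) - 1e-12


class TestIdentityMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        seqs = {f"s{i}": random_dna(rng, 100) for i in range(4)}
        m = identity_matrix(seqs)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)


def _tree_distances(newick_lengths):
    """Path-length matrix of a fixed 4-taxon tree ((A,B),(C,D)) with the
    given branch lengths (a, b, c, d, internal)."""
    a, b, c, d, m = newick_lengths
    labels = ["A", "B", "C", "D"]
    dist = {("A", "B"): a + b, ("C", "D"): c + d,
            ("A", "C"): a + m + c, ("A", "D"): a + m + d,
            ("B", "C"): b + m + c, ("B", "D"): b + m + d}
    n = len(labels)
    M = np.zeros((n, n))
    for (x, y), v in dist.items():
        i, j = labels.index(x), labels.index(y)
        M[i, j] = M[j, i] = v
    return DistanceMatrix(labels=labels, values=M)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        M = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(labels=labels, values=M))
        lengths = {child.label: l for child, l in tree.root.children}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_exact(self):
        """A four-point-verified additive matrix reproduces its tree exactly,
        topology and branch lengths."""
        bl = (0.11, 0.23, 0.08, 0.31, 0.17)
        dm = _tree_distances(bl)
        # verify the four-point condition first
        d = dm.values
        s1 = d[0, 1] + d[2, 3]
        s2 = d[0, 2] + d[1, 3]
        s3 = d[0, 3] + d[1, 2]
        assert s1 < s2 == pytest.approx(s3)
        tree = neighbor_joining(dm)
        assert frozenset({"A", "B"}) in tree.bipartitions() or \
            frozenset({"C", "D"}) in tree.bipartitions()
        # recovered path lengths equal the generating ones
        path = _tree_path_lengths(tree)
        for (x, y), v in path.items():
            assert v == pytest.approx(dm.get(x, y))

    def test_ultrametric_five_taxon_topology(self):
        """((A,B),(C,D),E) hierarchy from an ultrametric matrix."""
        labels = ["A", "B", "C", "D", "E"]
        h = {("A", "B"): 0.2, ("C", "D"): 0.3}
        M = np.full((5, 5), 1.0)
        np.fill_diagonal(M, 0.0)
        for (x, y), v in h.items():
            i, j = labels.index(x), labels.index(y)
            M[i, j] = M[j, i] = v
        tree = neighbor_joining(DistanceMatrix(labels=labels, values=M))
        bps = tree.bipartitions()
        assert frozenset({"C", "D"}) in bps or frozenset({"A", "B", "E"}) in bps
        assert any(bp in bps for bp in
                   (frozenset({"A", "B"}), frozenset({"C", "D", "E"})))

    def test_matches_independent_nj_implementation(self, rng):
        """Same topology as scikit-bio's neighbor joining on a random
        perturbed-additive matrix."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        bl = (0.12, 0.27, 0.09, 0.22, 0.3)
        base = _tree_distances(bl).values
        noise = rng.uniform(-0.01, 0.01, size=base.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        values = base + noise
        labels = ["A", "B", "C", "D"]
        ours = neighbor_joining(DistanceMatrix(labels=labels, values=values))
        theirs = skbio_nj(SkbioDM(values, labels))
        def normalize(bp):
            return bp if "A" in bp else frozenset(set(labels) - bp)

        their_bps = set()
        for node in theirs.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels) - 1:
                their_bps.add(normalize(tips))
        our_bps = {normalize(bp) for bp in ours.bipartitions()}
        assert our_bps == their_bps

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [2, 0]]))


def _tree_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    leaves = tree.leaves()
    out = {}

    def paths(node, acc):
        if node.is_leaf():
            yield node.label, acc
        for child, l in node.children:
            yield from paths(child, acc + l)

    # path length via root (valid for additive trees rooted anywhere)
    def depth_map(node):
        return dict(paths(node, 0.0))

    dm = depth_map(tree.root)

    def lca_paths(node):
        if node.is_leaf():
            return {node.label: 0.0}
        maps = []
        for child, l in node.children:
            m = lca_paths(child)
            maps.append({k: v + l for k, v in m.items()})
        merged = {}
        for i, m1 in enumerate(maps):
            for j, m2 in enumerate(maps):
                if i < j:
                    for x in m1:
                        for y in m2:
                            out[tuple(sorted((x, y)))] = m1[x] + m2[y]
            merged.update(m1)
        return merged

    lca_paths(tree.root)
    return out


class TestBootstrap:
    def _clade_alignment(self, rng, within=0.02, between=0.5, cols=400):
        a = random_dna(rng, cols)
        b = mutate_sequence(a, between, rng)
        return {
            "A1": mutate_sequence(a, within, rng),
            "A2": mutate_sequence(a, within, rng),
            "B1": mutate_sequence(b, within, rng),
            "B2": mutate_sequence(b, within, rng),
            "C": mutate_sequence(b, within, rng),
        }

    def test_clear_clades_high_support(self, rng):
        aligned = self._clade_alignment(rng)
        tree = bootstrap_support(aligned, replicates=100, seed=1)
        bp = frozenset({"A1", "A2"})
        support = tree.support_of(bp) or tree.support_of(frozenset({"B1", "B2", "C"}))
        assert support is not None and support >= 95

    def test_star_alignment_low_support(self, rng):
        """All pairs roughly equidistant: no strongly supported branch."""
        root = random_dna(rng, 400)
        aligned = {f"s{i}": mutate_sequence(root, 0.3, rng) for i in range(5)}
        tree = bootstrap_support(aligned, replicates=100, seed=2)
        supports = [tree.support_of(bp) for bp in tree.bipartitions()]
        assert all(s is None or s < 90 for s in supports)

    def test_single_replicate_degenerate(self, rng):
        aligned = self._clade_alignment(rng)
        tree = bootstrap_support(aligned, replicates=1, seed=3)
        for bp in tree.bipartitions():
            s = tree.support_of(bp)
            assert s in (0.0, 100.0)

    def test_deterministic_under_seed(self, rng):
        aligned = self._clade_alignment(rng)
        t1 = bootstrap_support(aligned, replicates=50, seed=9)
        t2 = bootstrap_support(aligned, replicates=50, seed=9)
        for bp in t1.bipartitions():
            assert t1.support_of(bp) == t2.support_of(bp)


class TestClassifyFamily:
    AA = "ACDEFGHIKLMNPQRSTVWY"

    def _protein(self, rng, n=140):
        return "".join(self.AA[i] for i in rng.integers(0, 20, size=n))

    def _mutate(self, rng, seq, rate):
        out = list(seq)
        for i in np.flatnonzero(rng.random(len(out)) < rate):
            out[i] = self.AA[rng.integers(0, 20)]
        return "".join(out)

    def test_own_family_wins_with_margin(self, rng):
        fam_a = self._protein(rng)
        fam_b = self._protein(rng)
        refs = [("a1", "MS", self._mutate(rng, fam_a, 0.1)),
                ("a2", "MS", self._mutate(rng, fam_a, 0.1)),
                ("b1", "TRT", self._mutate(rng, fam_b, 0.1))]
        call = classify_family(self._mutate(rng, fam_a, 0.05), refs)
        assert call.label == "MS" and call.margin > 0 and not call.low_confidence

    def test_identical_reference_full_identity(self, rng):
        fam_a = self._protein(rng)
        fam_b = self._protein(rng)
        refs = [("a1", "MS", fam_a), ("b1", "TRT", fam_b)]
        call = classify_family(fam_a, refs)
        assert call.label == "MS" and call.mean_identity == 1.0

    def test_equidistant_query_low_confidence(self, rng):
        fam_a = self._protein(rng)
        # midpoint: half from each family reference
        fam_b = self._mutate(rng, fam_a, 0.5)
        midpoint = fam_a[:70] + fam_b[70:]
        refs = [("a1", "A", fam_a), ("b1", "B", fam_b)]
        call = classify_family(midpoint, refs)
        assert call.low_confidence

    def test_signature_report(self, rng):
        fam_a = self._protein(rng)
        fam_b = self._protein(rng)
        refs = [("a1", "MS", fam_a), ("b1", "maT", fam_b)]
        call = classify_family(fam_a, refs, query_signature="DD37E",
                               family_signatures={"MS": "DD37E", "maT": "DD37D"})
        assert call.signature_matches is True

    def test_single_family_rejected(self, rng):
        refs = [("a1", "MS", self._protein(rng))]
        with pytest.raises(ValueError):
            classify_family(self._protein(rng), refs)
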