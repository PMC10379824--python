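import numpy as np
import pytest

import oracles
from marinerscan import (CanonicalProfile, build_consensus, center_star_msa,
                         estimate_copy_number, mutate_sequence, pick_representative,
                         plant_copies)
from marinerscan.family import RepresentativeCandidate
from marinerscan.io_formats import GenomeRecord
from marinerscan.synthetic_data import random_dna
from marinerscan import _pairwise


class TestCenterStarMsa:
    def test_two_identical_sequences_gap_free(self):
        rows = center_star_msa(["ACGTACGT", "ACGTACGT"])
        assert rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_placement_matches_oracle(self):
        """{"ACGT", "ACT"}: alignment width 4, one gap in the second row,
        and the induced score equals the brute-force global DP optimum."""
        rows = center_star_msa(["ACGT", "ACT"])
        assert len(rows[0]) == 4
        assert rows[0] == "ACGT" and rows[1].count("-") == 1
        induced = _score_induced(rows[0], rows[1])
        assert induced == oracles.global_msa_score("ACGT", "ACT")

    def test_substitution_only_copies_stay_gap_free(self):
        base = random_dna(np.random.default_rng(3), 60)
        copies = []
        for i in range(5):
            l = list(base)
            l[10 * i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[l[10 * i]]
            copies.append("".join(l))
        rows = center_star_msa(copies)
        assert all("-" not in r for r in rows)
        assert len(rows[0]) == 60

    def test_center_alignments_preserved_exactly(self):
        """Projecting any (center, other) pair out of the MSA and dropping
        double-gap columns recovers the optimal pairwise alignment score."""
        rng = np.random.default_rng(17)
        base = random_dna(rng, 50)
        seqs = [mutate_sequence(base, 0.1, rng) for _ in range(5)]
        # introduce length variation
        seqs[2] = seqs[2][:40]
        seqs[4] = seqs[4] + "ACGT"
        rows = center_star_msa(seqs)
        totals = []
        for i, s in enumerate(seqs):
            assert rows[i].replace("-", "") == s
        # center = row whose pairwise projections all score optimally
        found_center = False
        for ci in range(len(seqs)):
            ok = True
            for j in range(len(seqs)):
                if j == ci:
                    continue
                a, b = _project(rows[ci], rows[j])
                if _score_induced(a, b) != oracles.global_msa_score(seqs[ci], seqs[j]):
                    ok = False
                    break
            if ok:
                found_center = True
        assert found_center

    def test_column_triangle_bound(self):
        """Unit-cost column triangle inequality: for any two rows i, j and
        the center c, cost(i,j) <= cost(i,c) + cost(c,j) column-wise."""
        rng = np.random.default_rng(23)
        base = random_dna(rng, 40)
        seqs = [mutate_sequence(base, 0.15, rng) for _ in range(5)]
        seqs[1] = seqs[1][5:]
        rows = center_star_msa(seqs)

        def cost(a, b):
            c = 0
            for x, y in zip(a, b):
                if x == y:
                    continue
                c += 1
            return c

        for i in range(5):
            for j in range(5):
                for c in range(5):
                    if len({i, j, c}) == 3:
                        assert cost(rows[i], rows[j]) <= \
                            cost(rows[i], rows[c]) + cost(rows[c], rows[j])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            center_star_msa(["ACGT"])


def _project(a: str, b: str) -> tuple[str, str]:
    pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    return "".join(p[0] for p in pairs), "".join(p[1] for p in pairs)


def _score_induced(a: str, b: str) -> float:
    """Score a fixed gapped pair under the center-star parameters."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == "-":
            score += -1 if in_gap_a else -7
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += -1 if in_gap_b else -7
            in_gap_b, in_gap_a = True, False
        else:
            in_gap_a = in_gap_b = False
            score += 2 if x == y else -2
    return score


class TestBuildConsensus:
    def test_identical_rows(self):
        cons, ties = build_consensus(["ACGT"] * 5)
        assert cons == "ACGT" and ties == []

    def test_majority_column(self):
        rows = ["A", "A", "A", "G", "G"]
        cons, _ = build_consensus(rows)
        assert cons == "A"

    def test_gap_majority_column_dropped(self):
        rows = ["-A", "-A", "-A", "AA", "AA"]
        cons, _ = build_consensus(rows)
        assert cons == "A"

    def test_tie_alphabetical_and_flagged(self):
        rows = ["AC", "AC", "AG", "AG", "A-"]
        cons, ties = build_consensus(rows)
        assert cons == "AC" and ties == [1]

    def test_too_few_rows_directs_to_representative(self):
        with pytest.raises(ValueError, match="representative"):
            build_consensus(["ACGT"] * 4)

    def test_consensus_recovery_from_decayed_copies(self, profile):
        """5 copies at 5% decay majority-vote back to >= 99% of the
        canonical sequence."""
        genome, truth = plant_copies(12000, profile, 5, decay_rate=0.05, seed=77)
        copies = [c.planted_sequence for c in truth.copies]
        rows = center_star_msa(copies)
        cons, _ = build_consensus(rows)
        canonical = truth.canonical.sequence
        assert len(cons) == len(canonical)
        identity = sum(a == b for a, b in zip(cons, canonical)) / len(canonical)
        assert identity >= 0.99


class TestPickRepresentative:
    def c(self, gid, seq, score):
        return RepresentativeCandidate(genome_id=gid, sequence=seq, score=score)

    def test_highest_score_wins(self):
        m = pick_representative([self.c("a", "A" * 120, 120),
                                 self.c("b", "A" * 120, 95),
                                 self.c("c", "A" * 120, 80)])
        assert m.species == "a" and m.method == "representative"

    def test_tie_longest_then_lexicographic(self):
        m = pick_representative([self.c("b", "A" * 1250, 100),
                                 self.c("a", "A" * 1300, 100)])
        assert m.species == "a" and len(m.sequence) == 1300
        m2 = pick_representative([self.c("b", "A" * 1300, 100),
                                  self.c("a", "A" * 1300, 100)])
        assert m2.species == "a"

    def test_single_candidate(self):
        m = pick_representative([self.c("x", "A" * 200, 10)])
        assert m.species == "x" and m.n_copies_used == 1


class TestEstimateCopyNumber:
    def test_ten_clean_copies(self, profile):
        genome, truth = plant_copies(14000, profile, 6, seed=88)
        count, hits = estimate_copy_number(truth.canonical.sequence, genome)
        assert count == 6

    def test_heavily_mutated_copy_excluded(self, profile):
        """One copy decayed to ~60% identity among clean ones is not counted."""
        rng = np.random.default_rng(89)
        genome, truth = plant_copies(12000, profile, 5, seed=rng)
        bad = mutate_sequence(truth.canonical.sequence, 0.4, rng)
        extended = GenomeRecord(genome.id, genome.species,
                                genome.sequence + "TA" + bad + "TA")
        count, _ = estimate_copy_number(truth.canonical.sequence, extended)
        assert count == 5

    def test_background_only_zero(self, profile, rng):
        genome = GenomeRecord("bg", "bg", random_dna(rng, 8000))
        model = random_dna(rng, 1300)
        count, _ = estimate_copy_number(model, genome)
        assert count == 0

    def test_low_coverage_fragment_excluded(self, profile):
        """A 30%-length fragment fails the 40% coverage gate; a 60% fragment
        passes it."""
        genome, truth = plant_copies(6000, profile, 1, seed=90)
        canonical = truth.canonical.sequence
        frag30 = canonical[:int(0.30 * len(canonical))]
        frag60 = canonical[:int(0.60 * len(canonical))]
        g = GenomeRecord("g", "g",
                         genome.sequence + "TA" + frag30 + "TACC" + frag60 + "TA")
        count, hits = estimate_copy_number(canonical, g)
        assert count == 2  # full copy + 60% fragment

    def test_threshold_monotonicity(self, profile):
        genome, truth = plant_copies(10000, profile, 3, decay_rate=0.1, seed=91)
        base, _ = estimate_copy_number(truth.canonical.sequence, genome,
                                       min_identity=0.80, min_coverage=0.40)
        looser_id, _ = estimate_copy_number(truth.canonical.sequence, genome,
                                            min_identity=0.70, min_coverage=0.40)
        looser_cov, _ = estimate_copy_number(truth.canonical.sequence, genome,
                                             min_identity=0.80, min_coverage=0.20)
        assert looser_id >= base and looser_cov >= base

    def test_minus_strand_copies_counted(self, profile):
        genome, truth = plant_copies(8000, profile, 2, seed=92)
        flipped = GenomeRecord("rc", "rc", _pairwise.revcomp(genome.sequence))
        count, hits = estimate_copy_number(truth.canonical.sequence, flipped)
        assert count == 2
        assert all(h.strand == "-" for h in hits if h.qualifies(0.8, 0.4))
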