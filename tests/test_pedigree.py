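"""Pedigree reading, inbreeding, relationship matrices, ancestor scores."""

import numpy as np
import pytest

from felhip.pedigree import (
    AncestorScore,
    Pedigree,
    PedigreeError,
    PedigreeRecord,
    inbreeding_coefficients,
    mean_ancestor_score,
    mean_ancestor_scores,
    read_pedigree,
    relationship_inverse,
    relationship_matrix,
    sample_breeding_values,
)

from conftest import coancestry_oracle, random_pedigree


def _trio() -> list[PedigreeRecord]:
    return [
        PedigreeRecord("A", None, None, "male"),
        PedigreeRecord("B", None, None, "female"),
        PedigreeRecord("C", "A", "B", "female"),
    ]


class TestReadAndValidate:
    def test_trio_roundtrip(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,sex\nA,,,m\nB,0,0,f\nC,A,B,f\n")
        ped = read_pedigree(p)
        assert len(ped) == 3
        assert ped.index["C"] > ped.index["A"]
        assert ped["C"].sire_id == "A"
        assert ped["A"].sire_id is None  # "" and "0" both mean unknown

    def test_out_of_order_input_is_resorted(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,sex\nC,A,B,f\nA,,,m\nB,,,f\n")
        ped = read_pedigree(p)
        assert ped.index["A"] < ped.index["C"]
        assert ped.index["B"] < ped.index["C"]
        assert ped.input_order == ("C", "A", "B")

    def test_whitespace_dialect(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("id sire dam sex\nA 0 0 m\nB 0 0 f\nC A B f\n")
        ped = read_pedigree(p)
        assert len(ped) == 3

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            PedigreeRecord("C", "A", "C", "female")

    def test_duplicate_id_named_in_error(self):
        recs = _trio() + [PedigreeRecord("C", None, None, "female")]
        with pytest.raises(PedigreeError, match="'C'"):
            Pedigree(recs)

    def test_unresolved_parent_errors_unless_permissive(self):
        recs = [PedigreeRecord("C", "A", "B", "female")]
        with pytest.raises(PedigreeError, match="parent"):
            Pedigree(recs)
        ped = Pedigree(recs, add_missing_founders=True)
        assert set(ped.ids) == {"A", "B", "C"}
        assert ped["A"].sex == "male"

    def test_cycle_detected_and_listed(self):
        recs = [
            PedigreeRecord("A", "C", None, "male"),
            PedigreeRecord("B", None, None, "female"),
            PedigreeRecord("C", "A", "B", "female"),
        ]
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(recs)

    def test_sire_and_dam_roles_disjoint(self):
        recs = [
            PedigreeRecord("A", None, None, "male"),
            PedigreeRecord("B", None, None, "female"),
            PedigreeRecord("C", "A", "B"),
            PedigreeRecord("D", "A", "C"),
            PedigreeRecord("E", "C", "B"),
        ]
        with pytest.raises(PedigreeError, match="both sire and dam"):
            Pedigree(recs)


class TestInbreedingAndRelationship:
    def test_founders_have_zero_inbreeding(self):
        ped = Pedigree(_trio())
        assert np.allclose(inbreeding_coefficients(ped), 0.0)

    def test_full_sib_mating_gives_quarter(self):
        recs = _trio() + [
            PedigreeRecord("D", "A", "B", "male"),
            PedigreeRecord("E", "D", "C", "female"),
        ]
        F = inbreeding_coefficients(Pedigree(recs))
        assert F[-1] == pytest.approx(0.25)

    def test_parent_offspring_and_sib_relationships(self):
        recs = _trio() + [
            PedigreeRecord("D", "A", "B", "male"),   # full sib of C
            PedigreeRecord("E", "A", "F0", "male"),  # half sib of C
            PedigreeRecord("F0", None, None, "female"),
        ]
        rm = relationship_matrix(Pedigree(recs))
        i = {x: rm.ids.index(x) for x in "ABCDE"}
        A = rm.values
        assert A[i["A"], i["C"]] == pytest.approx(0.5)
        assert A[i["C"], i["D"]] == pytest.approx(0.5)
        assert A[i["C"], i["E"]] == pytest.approx(0.25)

    def test_matches_recursive_coancestry_oracle(self, rng):
        for _ in range(5):
            ped = random_pedigree(rng, n_founders=8, n_extra=22)
            A = relationship_matrix(ped).values
            assert np.allclose(A, 2.0 * coancestry_oracle(ped), atol=1e-12)

    def test_diagonal_is_one_plus_inbreeding(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_extra=40)
        rm = relationship_matrix(ped)
        F = inbreeding_coefficients(ped)
        assert np.allclose(np.diag(rm.values), 1.0 + F, atol=1e-12)
        assert np.allclose(rm.inbreeding, F, atol=1e-12)

    def test_psd_on_larger_pedigree(self, rng):
        ped = random_pedigree(rng, n_founders=20, n_extra=180)
        A = relationship_matrix(ped).values
        evals = np.linalg.eigvalsh(A)
        assert evals.min() >= -1e-8

    def test_inverse_founders_only_is_identity(self):
        ped = Pedigree([PedigreeRecord(f"I{i}") for i in range(5)])
        Ainv = relationship_inverse(ped).toarray()
        assert np.allclose(Ainv, np.eye(5))

    def test_inverse_times_matrix_is_identity(self, rng):
        for _ in range(3):
            ped = random_pedigree(rng, n_founders=10, n_extra=40)
            A = relationship_matrix(ped).values
            Ainv = relationship_inverse(ped).toarray()
            assert np.allclose(Ainv @ A, np.eye(len(ped)), atol=1e-8)

    def test_inverse_sparsity_pattern(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_extra=40)
        Ainv = relationship_inverse(ped).tocoo()
        allowed = set()
        for i in range(len(ped)):
            fam = [i] + [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
            allowed.update((a, b) for a in fam for b in fam)
        nz = {(int(r), int(c)) for r, c, v in
              zip(Ainv.row, Ainv.col, Ainv.data) if abs(v) > 1e-14}
        assert nz <= allowed


class TestBreedingValueSampling:
    def test_founder_variance_matches_g(self):
        rng = np.random.default_rng(7)
        ped = Pedigree([PedigreeRecord(f"I{i}") for i in range(10_000)])
        G = np.array([[1.0, 0.3], [0.3, 0.5]])
        a = sample_breeding_values(ped, G, rng)
        assert np.allclose(np.cov(a.T), G, rtol=0.05, atol=0.02)

    def test_parent_offspring_covariance(self, rng):
        sires = [PedigreeRecord(f"S{i}", None, None, "male") for i in range(2000)]
        dams = [PedigreeRecord(f"D{i}", None, None, "female") for i in range(2000)]
        kids = [PedigreeRecord(f"K{i}", f"S{i}", f"D{i}") for i in range(2000)]
        ped = Pedigree(sires + dams + kids)
        a = sample_breeding_values(ped, 1.0, rng)[:, 0]
        s, k = a[:2000], a[4000:]
        cov = np.cov(s, k)[0, 1]
        assert cov == pytest.approx(0.5, abs=0.06)

    def test_zero_variance_gives_zero_bvs(self, rng):
        ped = random_pedigree(rng, 6, 20)
        a = sample_breeding_values(ped, 0.0, rng)
        assert np.allclose(a, 0.0)


class TestMeanAncestorScore:
    def _ped(self):
        recs = [
            PedigreeRecord("GS1", None, None, "male"),
            PedigreeRecord("GD1", None, None, "female"),
            PedigreeRecord("GS2", None, None, "male"),
            PedigreeRecord("GD2", None, None, "female"),
            PedigreeRecord("S", "GS1", "GD1", "male"),
            PedigreeRecord("D", "GS2", "GD2", "female"),
            PedigreeRecord("X", "S", "D", "female"),
        ]
        return Pedigree(recs)

    def test_no_screened_parents_scores_zero(self):
        sc = mean_ancestor_score(self._ped(), {}, "X", subject_date=10.0)
        assert sc == AncestorScore(0.0, 0.0)
        assert sc.mean_score == 0.0

    def test_parents_screened_grandparents_not(self):
        screened = {"S": 1.0, "D": 2.0}
        sc = mean_ancestor_score(self._ped(), screened, "X", subject_date=10.0)
        assert sc.maternal == 1.0 and sc.paternal == 1.0
        assert sc.mean_score == 1.0

    def test_fully_screened_depth(self):
        # complete screened ancestry to depth 2 on both sides:
        # g(grandparent) = 1, g(parent) = 1 + (1+1)/2 = 2, mean = 2
        screened = {i: 1.0 for i in "S D GS1 GD1 GS2 GD2".split()}
        sc = mean_ancestor_score(self._ped(), screened, "X", subject_date=10.0)
        assert sc.mean_score == 2.0
        strict = mean_ancestor_score(self._ped(), screened, "X",
                                     subject_date=10.0, mode="strict")
        assert strict.mean_score == 2.0

    def test_depth_three_both_sides(self):
        recs = []
        prev_m, prev_f = None, None
        for depth in range(4):
            m, f = f"M{depth}", f"F{depth}"
            recs.append(PedigreeRecord(m, prev_m, prev_f, "male"))
            recs.append(PedigreeRecord(f, prev_m, prev_f, "female"))
            prev_m, prev_f = m, f
        ped = Pedigree(recs, add_missing_founders=True)
        screened = {r.id: 1.0 for r in recs}
        # hand-expansion: g = 1, 2, 3 up the single fully screened chain
        sc = mean_ancestor_score(ped, screened, "M3", subject_date=5.0)
        assert sc.mean_score == 3.0

    def test_tie_counts_as_not_previous(self):
        screened = {"S": 10.0, "D": 1.0}
        sc = mean_ancestor_score(self._ped(), screened, "X", subject_date=10.0)
        assert sc.paternal == 0.0 and sc.maternal == 1.0

    def test_monotone_when_ancestor_becomes_screened(self):
        base = {"S": 1.0, "D": 1.0}
        before = mean_ancestor_score(self._ped(), base, "X", subject_date=10.0)
        after = mean_ancestor_score(self._ped(), {**base, "GS1": 0.5}, "X",
                                    subject_date=10.0)
        assert after.mean_score >= before.mean_score

    def test_strict_mode_breaks_on_gap(self):
        screened = {i: 1.0 for i in ("S", "D", "GS1", "GS2", "GD2")}
        disc = mean_ancestor_score(self._ped(), screened, "X", subject_date=10.0)
        strict = mean_ancestor_score(self._ped(), screened, "X",
                                     subject_date=10.0, mode="strict")
        # paternal side has an unscreened granddam: strict stops at 1
        assert strict.paternal == 1.0 and strict.maternal == 2.0
        assert disc.paternal == 1.5
        assert disc.mean_score >= strict.mean_score

    def test_unknown_subject_errors(self):
        with pytest.raises(KeyError):
            mean_ancestor_score(self._ped(), {}, "nope", subject_date=1.0)

    def test_vectorised_wrapper_matches_scalar(self):
        screened = {"S": 1.0, "D": 2.0, "X": 10.0}
        series = mean_ancestor_scores(self._ped(), screened, ["X"])
        assert series["X"] == 1.0
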