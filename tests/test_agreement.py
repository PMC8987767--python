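"""Fleiss' kappa: formula, oracle equivalence, banding, ingestion."""

import itertools

import numpy as np
import pandas as pd
import pytest

import vagcyto as v


def brute_force_subject_agreement(row: np.ndarray) -> float:
    """Oracle: expand a count row into rater assignments and count ordered
    pairs of raters that agree, divided by n(n-1)."""
    assignments = list(
        itertools.chain.from_iterable([j] * int(c) for j, c in enumerate(row))
    )
    n = len(assignments)
    agree = sum(
        1
        for a, b in itertools.permutations(range(n), 2)
        if assignments[a] == assignments[b]
    )
    return agree / (n * (n - 1))


class TestRatingsToMatrix:
    def test_unanimous_two_subjects(self):
        rows = [(s, r, "A") for s in ("s1", "s2") for r in ("r1", "r2", "r3")]
        m = v.ratings_to_matrix(rows, categories=["A", "B"])
        assert m.counts.tolist() == [[3, 0], [3, 0]]
        assert m.categories == ("A", "B")

    def test_survey_export_row_sums(self, rng):
        cats = ["parabasal", "intermediate", "superficial", "squamous"]
        rows = [
            (f"cell{s}", f"rater{r}", cats[rng.integers(len(cats))])
            for s in range(8)
            for r in range(16)
        ]
        m = v.ratings_to_matrix(rows)
        assert m.n_subjects == 8
        assert m.n_raters == 16
        assert (m.counts.sum(axis=1) == 16).all()

    def test_unequal_raters_rejected(self):
        rows = [("s1", "r1", "A"), ("s1", "r2", "A"), ("s2", "r1", "A"),
                ("s2", "r2", "B"), ("s2", "r3", "B")]
        with pytest.raises(v.ValidationError, match="unequal raters"):
            v.ratings_to_matrix(rows)

    def test_duplicate_pair_rejected(self):
        rows = [("s1", "r1", "A"), ("s1", "r1", "B")]
        with pytest.raises(v.ValidationError, match="duplicate"):
            v.ratings_to_matrix(rows)

    def test_dataframe_input_and_first_appearance_order(self):
        df = pd.DataFrame(
            {"subject_id": ["s1", "s1", "s2", "s2"],
             "rater_id": ["r1", "r2", "r1", "r2"],
             "category": ["B", "A", "B", "B"]}
        )
        m = v.ratings_to_matrix(df)
        assert m.categories == ("B", "A")
        assert m.counts.tolist() == [[1, 1], [2, 0]]


class TestFleissKappa:
    def test_perfect_agreement_is_exactly_one(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:5, 0] = 5
        counts[5:, 1] = 5
        res = v.fleiss_kappa(v.RatingMatrix(counts, ("A", "B")))
        assert res.kappa == 1.0
        assert res.band is v.AgreementBand.PERFECT

    def test_survey_worked_row(self):
        # one cell rated by 16 veterinarians: intermediate 9, parabasal 6,
        # basal 1 -> per-subject agreement 102/240 = 0.425
        m = v.RatingMatrix(np.array([[9, 6, 1, 0, 0]]), ("i", "p", "b", "s", "q"))
        res = v.fleiss_kappa(m)
        assert res.per_subject_agreement[0] == pytest.approx(0.425, abs=1e-12)
        assert res.per_subject_agreement[0] == pytest.approx(
            brute_force_subject_agreement(np.array([9, 6, 1, 0, 0])), abs=1e-12
        )

    def test_oracle_equivalence_on_random_matrices(self, rng):
        for _ in range(300):
            N = rng.integers(1, 7)
            n = rng.integers(2, 6)
            k = rng.integers(2, 5)
            counts = rng.multinomial(n, np.ones(k) / k, size=N)
            try:
                res = v.fleiss_kappa(v.RatingMatrix(counts, tuple(map(str, range(k)))))
            except v.UndefinedKappaError:
                continue
            for i in range(N):
                assert res.per_subject_agreement[i] == pytest.approx(
                    brute_force_subject_agreement(counts[i]), abs=1e-12
                )

    def test_statsmodels_cross_check(self, rng):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa

        counts = rng.multinomial(7, [0.5, 0.3, 0.2], size=25)
        ours = v.fleiss_kappa(v.RatingMatrix(counts, ("a", "b", "c"))).kappa
        assert ours == pytest.approx(sm_kappa(counts, method="fleiss"), abs=1e-10)

    def test_null_kappa_near_zero(self, rng):
        counts = rng.multinomial(4, np.ones(3) / 3, size=2000)
        res = v.fleiss_kappa(v.RatingMatrix(counts, ("a", "b", "c")))
        assert abs(res.kappa) < 0.02

    def test_subject_and_category_permutation_invariance(self, rng):
        counts = rng.multinomial(5, [0.4, 0.4, 0.2], size=12)
        base = v.fleiss_kappa(v.RatingMatrix(counts, ("a", "b", "c"))).kappa
        perm_s = v.fleiss_kappa(
            v.RatingMatrix(counts[rng.permutation(12)], ("a", "b", "c"))
        ).kappa
        cperm = rng.permutation(3)
        perm_c = v.fleiss_kappa(
            v.RatingMatrix(counts[:, cperm], tuple("abc"[i] for i in cperm))
        ).kappa
        assert base == pytest.approx(perm_s, abs=1e-12)
        assert base == pytest.approx(perm_c, abs=1e-12)

    def test_zero_category_column_leaves_kappa_unchanged(self, rng):
        counts = rng.multinomial(5, [0.6, 0.4], size=10)
        base = v.fleiss_kappa(v.RatingMatrix(counts, ("a", "b"))).kappa
        padded = np.hstack([counts, np.zeros((10, 1), dtype=int)])
        assert v.fleiss_kappa(v.RatingMatrix(padded, ("a", "b", "c"))).kappa == pytest.approx(
            base, abs=1e-12
        )

    def test_single_category_raises_undefined(self):
        counts = np.array([[5, 0], [5, 0]])
        with pytest.raises(v.UndefinedKappaError) as exc:
            v.fleiss_kappa(v.RatingMatrix(counts, ("a", "b")))
        assert exc.value.mean_agreement == 1.0

    def test_matrix_invariants(self):
        with pytest.raises(v.ValidationError, match="sum"):
            v.RatingMatrix(np.array([[3, 0], [2, 0]]), ("a", "b"))
        with pytest.raises(v.ValidationError, match="two raters"):
            v.RatingMatrix(np.array([[1, 0]]), ("a", "b"))
        with pytest.raises(v.ValidationError, match="categories"):
            v.RatingMatrix(np.array([[3], [3]]), ("a",))


class TestInterpretKappa:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (0.39, v.AgreementBand.POOR),
            (-0.2, v.AgreementBand.POOR),
            (0.40, v.AgreementBand.MODERATE),
            (0.412, v.AgreementBand.MODERATE),
            (0.533, v.AgreementBand.MODERATE),
            (0.75, v.AgreementBand.MODERATE),
            (0.76, v.AgreementBand.GOOD),
            (0.858, v.AgreementBand.GOOD),
            (1.0, v.AgreementBand.PERFECT),
        ],
    )
    def test_bands(self, kappa, band):
        assert v.interpret_kappa(kappa) is band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(v.ValidationError):
            v.interpret_kappa(1.1)
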