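"""Adduct hypotheses, ppm matching, cosine scoring, best-hit retention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msikit.annotation import (
    ADDUCTS,
    FragmentTolerance,
    adducts_for_polarity,
    annotate,
    cosine_score,
    match_library,
    neutral_hypotheses,
    ppm_error,
)
from msikit.formats_io import LibraryEntry, Scan, ValidationError


def _entry(compound_id, mass, mz, intensity, adduct=None):
    return LibraryEntry(
        compound_id, compound_id, "", mass,
        np.asarray(mz, dtype=float), np.asarray(intensity, dtype=float), adduct=adduct,
    )


def _ms2(mz, intensity, precursor):
    return Scan(0, 0.0, 2, np.asarray(mz, dtype=float), np.asarray(intensity, dtype=float),
                precursor_mz=precursor, isolation_width=1.0)


class TestNeutralHypotheses:
    def test_positive_mode_gives_h_and_na(self):
        hypotheses = neutral_hypotheses(500.0, "positive")
        assert [a.label for a, _ in hypotheses] == ["[M+H]+", "[M+Na]+"]

    def test_negative_mode_gives_h_loss_and_cl(self):
        hypotheses = neutral_hypotheses(500.0, "negative")
        assert [a.label for a, _ in hypotheses] == ["[M-H]-", "[M+Cl]-"]

    def test_degenerate_precursor_drops_nonpositive_masses(self):
        proton = adducts_for_polarity("positive")[0].mass_shift_da
        assert neutral_hypotheses(proton, "positive") == []

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(40.0, 2000.0), st.sampled_from(["positive", "negative"]))
    def test_round_trip_recovers_precursor(self, precursor_mz, polarity):
        """Re-adding the adduct mass shift recovers the precursor to 1e-9 Da."""
        for adduct, neutral in neutral_hypotheses(precursor_mz, polarity):
            assert neutral + adduct.mass_shift_da == pytest.approx(
                precursor_mz, abs=1e-9
            )


class TestPpmError:
    @pytest.mark.parametrize(
        "observed, calculated, expected",
        [
            (500.0, 500.0, 0.0),
            (500.0025, 500.0, +5.0),
            (499.9975, 500.0, -5.0),
        ],
    )
    def test_sign_and_magnitude(self, observed, calculated, expected):
        assert ppm_error(observed, calculated) == pytest.approx(expected)

    def test_nonpositive_calculated_rejected(self):
        with pytest.raises(ValidationError):
            ppm_error(500.0, 0.0)


class TestMatchLibrary:
    def _hyp(self, precursor):
        return neutral_hypotheses(precursor, "positive")

    def test_exact_mass_match_has_zero_ppm(self):
        proton = ADDUCTS[0].mass_shift_da
        library = [_entry("C1", 300.0, [100.0], [1.0])]
        matches = match_library(self._hyp(300.0 + proton), library, tol_ppm=5.0)
        assert len(matches) == 1
        assert matches[0].ppm_err == pytest.approx(0.0, abs=1e-6)

    def test_isomers_both_matched(self):
        proton = ADDUCTS[0].mass_shift_da
        library = [
            _entry("iso_a", 300.0, [100.0], [1.0]),
            _entry("iso_b", 300.0, [150.0], [1.0]),
        ]
        matches = match_library(self._hyp(300.0 + proton), library, tol_ppm=5.0)
        assert {m.entry.compound_id for m in matches} == {"iso_a", "iso_b"}

    def test_outside_tolerance_excluded(self):
        proton = ADDUCTS[0].mass_shift_da
        library = [_entry("far", 300.0 * (1 + 20e-6), [100.0], [1.0])]
        assert match_library(self._hyp(300.0 + proton), library, tol_ppm=5.0) == []

    def test_conflicting_declared_adduct_excluded(self):
        sodium = ADDUCTS[1].mass_shift_da
        library = [_entry("C1", 300.0, [100.0], [1.0], adduct="[M+H]+")]
        hypotheses = [h for h in self._hyp(300.0 + sodium) if h[0].label == "[M+Na]+"]
        assert match_library(hypotheses, library, tol_ppm=5.0) == []

    def test_unspecified_adduct_eligible_for_all(self):
        proton = ADDUCTS[0].mass_shift_da
        library = [_entry("C1", 300.0, [100.0], [1.0], adduct=None)]
        assert len(match_library(self._hyp(300.0 + proton), library, tol_ppm=5.0)) == 1

    def test_agrees_with_exhaustive_double_loop(self):
        """Oracle equivalence against a from-scratch double loop."""
        rng = np.random.default_rng(3)
        library = [
            _entry(f"C{i}", float(rng.uniform(150.0, 800.0)), [100.0], [1.0])
            for i in range(500)
        ]
        tol = 5.0
        for precursor in rng.uniform(160.0, 820.0, size=20):
            hypotheses = neutral_hypotheses(float(precursor), "positive")
            got = {
                (m.entry.compound_id, m.adduct.label)
                for m in match_library(hypotheses, library, tol)
            }
            expected = set()
            for adduct, neutral in hypotheses:
                for entry in library:
                    if abs((neutral - entry.exact_mass) / entry.exact_mass * 1e6) <= tol:
                        expected.add((entry.compound_id, adduct.label))
            assert got == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.5, 5.0), st.floats(0.0, 20.0))
    def test_shrinking_tolerance_never_adds_candidates(self, seed, tight, extra):
        rng = np.random.default_rng(seed)
        library = [
            _entry(f"C{i}", float(rng.uniform(200.0, 400.0)), [100.0], [1.0])
            for i in range(50)
        ]
        hypotheses = neutral_hypotheses(float(rng.uniform(210.0, 410.0)), "positive")
        n_tight = len(match_library(hypotheses, library, tight))
        n_loose = len(match_library(hypotheses, library, tight + extra))
        assert n_tight <= n_loose


class TestCosineScore:
    def test_self_similarity_is_one(self):
        spectrum = (np.array([100.0, 200.0, 300.0]), np.array([5.0, 50.0, 10.0]))
        assert cosine_score(spectrum, spectrum) == pytest.approx(1.0)

    def test_disjoint_spectra_score_zero(self):
        a = (np.array([100.0, 200.0]), np.array([1.0, 1.0]))
        b = (np.array([150.0, 250.0]), np.array([1.0, 1.0]))
        assert cosine_score(a, b) == 0.0

    def test_hand_computed_worked_example(self):
        """(1*2 + 2*1) / (sqrt(5)*sqrt(5)) = 0.8 for exactly matched peaks."""
        a = (np.array([100.0, 200.0]), np.array([1.0, 2.0]))
        b = (np.array([100.0, 200.0]), np.array([2.0, 1.0]))
        assert cosine_score(a, b) == pytest.approx(0.8)

    def test_sqrt_weighting_damps_base_peak_dominance(self):
        a = (np.array([100.0, 200.0]), np.array([1.0, 4.0]))
        b = (np.array([100.0, 200.0]), np.array([2.0, 2.0]))
        plain = cosine_score(a, b)
        weighted = cosine_score(a, b, sqrt_weight=True)
        # sqrt: (1,2)·(sqrt2,sqrt2) / (sqrt5 * 2) = 3*sqrt(2)/(2*sqrt(5))
        assert weighted == pytest.approx(3 * np.sqrt(2) / (2 * np.sqrt(5)))
        assert weighted > plain
        assert cosine_score(a, a, sqrt_weight=True) == pytest.approx(1.0)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            cosine_score((np.empty(0), np.empty(0)), (np.array([1.0]), np.array([1.0])))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_symmetric_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = (np.sort(rng.uniform(100.0, 900.0, 6)), rng.uniform(1.0, 100.0, 6))
        b = (np.sort(rng.uniform(100.0, 900.0, 5)), rng.uniform(1.0, 100.0, 5))
        forward = cosine_score(a, b)
        assert cosine_score(b, a) == pytest.approx(forward, abs=1e-12)
        assert cosine_score((a[0], a[1] * scale), b) == pytest.approx(forward, rel=1e-9)

    def test_agrees_with_matchms_reference(self):
        """Independent cross-check against matchms CosineGreedy on spectra
        whose peaks are separated by more than the pairing window."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(7)
        tol = FragmentTolerance(ppm=0.0, floor_da=0.05)
        reference = CosineGreedy(tolerance=0.05)
        for _ in range(20):
            mz_a = np.sort(rng.choice(np.arange(100.0, 900.0, 1.0), 8, replace=False))
            mz_b = mz_a + rng.uniform(-0.04, 0.04, 8)
            keep = rng.random(8) < 0.7
            mz_b = np.sort(mz_b[keep]) if keep.any() else mz_a[:1]
            int_a = rng.uniform(1.0, 100.0, mz_a.size)
            int_b = rng.uniform(1.0, 100.0, mz_b.size)
            ours = cosine_score((mz_a, int_a), (mz_b, int_b), tol)
            spec_a = matchms.Spectrum(mz=mz_a, intensities=int_a,
                                      metadata={"precursor_mz": 500.0})
            spec_b = matchms.Spectrum(mz=mz_b, intensities=int_b,
                                      metadata={"precursor_mz": 500.0})
            theirs = float(reference.pair(spec_a, spec_b)["score"])
            assert ours == pytest.approx(theirs, abs=1e-9)


class TestAnnotate:
    def _candidates(self, precursor, specs):
        proton = ADDUCTS[0].mass_shift_da
        library = [
            _entry(cid, precursor - proton, mz, intensity)
            for cid, mz, intensity in specs
        ]
        return match_library(neutral_hypotheses(precursor, "positive"), library, 5.0)

    def test_highest_score_retained(self):
        ms2 = _ms2([100.0, 200.0], [1.0, 2.0], precursor=400.0)
        candidates = self._candidates(
            400.0,
            [
                ("low", [500.0], [1.0]),                 # scores 0
                ("best", [100.0, 200.0], [1.0, 2.0]),    # scores 1
                ("mid", [100.0, 200.0], [2.0, 1.0]),     # scores 0.8
            ],
        )
        record = annotate(ms2, candidates)
        assert record.compound_id == "best"
        assert record.cosine_score == pytest.approx(1.0)

    def test_cosine_tie_broken_by_smaller_ppm(self):
        proton = ADDUCTS[0].mass_shift_da
        precursor = 400.0
        neutral = precursor - proton
        library = [
            _entry("far", neutral * (1 - 3e-6), [100.0], [1.0]),
            _entry("near", neutral * (1 + 1e-6), [100.0], [1.0]),
        ]
        candidates = match_library(
            neutral_hypotheses(precursor, "positive"), library, 5.0
        )
        record = annotate(_ms2([100.0], [1.0], precursor), candidates)
        assert record.compound_id == "near"
        assert abs(record.ppm_error) == pytest.approx(1.0, rel=1e-3)

    def test_no_candidates_returns_none(self):
        assert annotate(_ms2([100.0], [1.0], 400.0), []) is None
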