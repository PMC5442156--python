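"""Plate-normalization statistics and hit-calling rules, checked against
hand computations, analytic laws and brute-force evaluators."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import median_abs_deviation

from mitoscreen import fixtures
from mitoscreen.screen_scoring import (
    ZeroSpreadError,
    call_primary,
    call_validation,
    raw_over_mnc,
    robust_z,
    score_plates,
    summarize,
    validation_normalize,
)


class TestRobustZ:
    def test_median_scores_zero(self):
        sample = [3, 9, 4, 8, 5, 7, 6, 10]
        assert robust_z(sample, np.median(sample)) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # median 14, MAD 2 (cross-checked with scipy's estimator)
        sample = [10, 12, 14, 16, 18, 10, 12, 16]
        med, mad = np.median(sample), median_abs_deviation(sample)
        expected = (med - 8) / (1.4826 * mad)
        assert robust_z(sample, 8) == pytest.approx(expected)
        assert robust_z([10, 12, 14, 16, 18] + [12, 14, 16], 8) > 0  # fewer mitoses => positive

    def test_sign_orientation(self):
        """Wells with a reduced MitosisCount score positive."""
        sample = list(range(90, 111))
        assert robust_z(sample, 50) > 0
        assert robust_z(sample, 150) < 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            robust_z([1, 2, 3], 2)

    def test_zero_mad_raises_unless_fallback(self):
        constant_mad = [5, 5, 5, 5, 5, 5, 5, 9]  # MAD 0, SD > 0
        with pytest.raises(ZeroSpreadError):
            robust_z(constant_mad, 4)
        assert np.isfinite(robust_z(constant_mad, 4, fallback_sd=True))

    def test_normal_law_calibration(self):
        """For x drawn from the sample's own law, P(z < 2) is close to the
        normal 97.7% (z uses the MAD-consistent sigma estimate)."""
        rng = np.random.default_rng(42)
        sample = rng.normal(100, 10, size=10_000)
        xs = rng.normal(100, 10, size=10_000)
        z = robust_z(sample, xs)
        assert np.mean(z < 2) == pytest.approx(0.977, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_location_scale_equivariance(self, a, b):
        sample = np.array([10.0, 12, 14, 16, 18, 11, 13, 17])
        x = 8.0
        base = robust_z(sample, x)
        assert robust_z(a * sample + b, a * x + b) == pytest.approx(base, rel=1e-9)


class TestRawOverMnc:
    def test_median_ratio_one(self):
        assert raw_over_mnc(100, [90, 100, 110]) == pytest.approx(1.0)

    def test_direct_division(self):
        assert raw_over_mnc(40, [100, 110, 90]) == pytest.approx(0.4)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            raw_over_mnc(10, [])

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            raw_over_mnc(10, [0, 0, 0])


def sirna_frame(z, scores, target="T1"):
    return pd.DataFrame({
        "target": target, "sirna": [f"{target}_s{i}" for i in range(len(z))],
        "z": z, "manual_score": scores,
    })


class TestCallPrimary:
    def test_two_sirnas_at_z_cut_is_bioinformatic_hit(self):
        calls = call_primary(sirna_frame([2.1, 2.5, 0.3, 0.1, 0.0], [1] * 5))
        assert calls.loc[0, "bioinformatic_hit"]

    def test_manual_rules(self):
        assert not call_primary(sirna_frame([0] * 5, [3, 3, 2, 2, 1])).loc[0, "manual_hit"]
        assert call_primary(sirna_frame([0] * 5, [4, 4, 1, 1, 1])).loc[0, "manual_hit"]
        assert call_primary(sirna_frame([0] * 5, [3, 3, 3, 1, 1])).loc[0, "manual_hit"]

    def test_no_effect_no_hit(self):
        calls = call_primary(sirna_frame([0.5, 1.0, -0.5, 0.0, 1.9], [1] * 5))
        assert not calls.loc[0, "bioinformatic_hit"] and not calls.loc[0, "manual_hit"]

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            call_primary(sirna_frame([0] * 3, [1, 2, 6]))

    def test_exhaustive_against_brute_force(self):
        """Every (z, score) configuration of a 5-siRNA target, z in {0, 3}
        and score in 1..5, agrees with a direct evaluation of the rules."""
        combos = list(itertools.product([(0.0, s) for s in range(1, 6)]
                                        + [(3.0, s) for s in range(1, 6)], repeat=5))
        rows = []
        for ti, combo in enumerate(combos):
            for si, (z, s) in enumerate(combo):
                rows.append((f"T{ti:06d}", f"T{ti:06d}_s{si}", z, s))
        big = pd.DataFrame(rows, columns=["target", "sirna", "z", "manual_score"])
        calls = call_primary(big).sort_values("target").reset_index(drop=True)
        expect_bio = np.array([sum(z >= 2 for z, _ in c) >= 2 for c in combos])
        expect_manual = np.array([
            sum(s >= 3 for _, s in c) >= 3 or sum(s >= 4 for _, s in c) >= 2
            for c in combos])
        assert np.array_equal(calls["bioinformatic_hit"].to_numpy(), expect_bio)
        assert np.array_equal(calls["manual_hit"].to_numpy(), expect_manual)


class TestCallValidation:
    def _primary(self, effects, target="T1"):
        return pd.DataFrame({
            "target": target,
            "sirna": [f"{target}_s{i}" for i in range(len(effects))],
            "primary_effect": effects,
        })

    def _validation(self, sirnas, mnc, manual):
        return pd.DataFrame({"sirna": sirnas, "raw_mnc": mnc, "manual_score": manual})

    def test_two_low_mnc_effect_sirnas_validate(self):
        prim = self._primary([True, True, False])
        val = self._validation(prim["sirna"], [0.7, 0.75, 0.5], [1, 1, 1])
        assert call_validation(prim, val).loc[0, "validated"]

    def test_high_mnc_low_manual_fails(self):
        prim = self._primary([True, True])
        val = self._validation(prim["sirna"], [0.9, 0.95], [1, 1])
        assert not call_validation(prim, val).loc[0, "validated"]

    def test_same_sirnas_requirement(self):
        """A non-primary-effect siRNA cannot contribute to validation even
        with a strong validation phenotype."""
        prim = self._primary([True, False])
        val = self._validation(prim["sirna"], [0.5, 0.5], [1, 1])
        assert not call_validation(prim, val).loc[0, "validated"]

    def test_missing_validation_record_rejected(self):
        prim = self._primary([True, True])
        val = self._validation([prim["sirna"][0]], [0.5], [1])
        with pytest.raises(ValueError, match="missing"):
            call_validation(prim, val)

    def test_exhaustive_small_space_against_brute_force(self):
        options = [(eff, mnc, man) for eff in (True, False)
                   for mnc in (0.5, 0.9) for man in (1, 4)]
        for combo in itertools.product(options, repeat=3):
            prim = self._primary([c[0] for c in combo])
            val = self._validation(prim["sirna"], [c[1] for c in combo],
                                   [c[2] for c in combo])
            got = call_validation(prim, val).loc[0, "validated"]
            want = sum(c[0] and (c[1] <= 0.8 or c[2] >= 3) for c in combo) >= 2
            assert got == want


class TestSummarize:
    def test_disjoint_sets_add(self):
        calls = pd.DataFrame({
            "target": list("ABCD"),
            "bioinformatic_hit": [True, True, False, False],
            "manual_hit": [False, False, True, False],
        })
        s = summarize(calls)
        assert (s.n_bioinformatic, s.n_manual, s.n_overlap, s.n_union) == (2, 1, 0, 3)

    def test_identical_sets(self):
        calls = pd.DataFrame({
            "target": list("AB"),
            "bioinformatic_hit": [True, True],
            "manual_hit": [True, True],
        })
        s = summarize(calls)
        assert s.n_union == s.n_overlap == 2

    def test_union_identity_on_random_flag_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            calls = pd.DataFrame({
                "target": [f"T{i}" for i in range(n)],
                "bioinformatic_hit": rng.random(n) < 0.4,
                "manual_hit": rng.random(n) < 0.4,
            })
            s = summarize(calls)  # the constructor enforces the identity
            assert s.n_union == s.n_bioinformatic + s.n_manual - s.n_overlap

    def test_reference_screen_arithmetic(self):
        prim, val = fixtures.reference_screen_tables()
        calls = call_primary(prim)
        vcalls = call_validation(calls.attrs["sirna_effects"], val)
        s = summarize(calls, vcalls)
        assert (s.n_bioinformatic, s.n_manual, s.n_overlap, s.n_union) == (27, 35, 13, 49)
        assert s.n_validated == 26
        assert s.n_validated_both == 6


class TestPlateScoring:
    def _wells(self, n_sample=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = [{"plate": "P01", "well": f"S{i:02d}", "content": f"LNC_s{i}",
                 "mitosis_count": int(rng.normal(1000, 50))} for i in range(n_sample)]
        rows += [{"plate": "P01", "well": "C01", "content": "NC_A", "mitosis_count": 1000},
                 {"plate": "P01", "well": "C02", "content": "COPB2", "mitosis_count": 200}]
        return pd.DataFrame(rows)

    def test_controls_excluded_from_reference(self):
        wells = self._wells()
        scored = score_plates(wells)
        # a strong positive control must not drag the sample reference down
        pos = scored[scored["content"] == "COPB2"]["z"].iloc[0]
        assert pos > 2

    def test_validation_normalization_uses_negative_controls(self):
        wells = self._wells()
        out = validation_normalize(wells)
        nc = out[out["content"] == "NC_A"]["raw_mnc"].iloc[0]
        assert nc == pytest.approx(1.0)
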