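"""Cell-fate classification and time courses on event sequences."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitoscreen import synthetic_data as sd
from mitoscreen.fate_analysis import (
    DEFAULT_THRESHOLDS,
    FateThresholds,
    arrest_durations,
    classify_fate,
    classify_log,
    fate_profile,
    time_course,
)


def seq(events):
    """events: list of (time_h, event)"""
    return pd.DataFrame({
        "cell_id": 0, "parent_id": -1,
        "time_h": [t for t, _ in events], "event": [e for _, e in events],
        "x_um": 0.0, "y_um": 0.0,
    })


class TestClassifyFate:
    def test_long_arrest_ending_in_death(self):
        s = seq([(4, "birth"), (40, "mitosis_entry"), (46, "mitotic_death")])
        assert classify_fate(s) == "mitotic_death"

    def test_arrest_then_exit_and_failure(self):
        assert classify_fate(seq([(4, "birth"), (30, "mitosis_entry"),
                                  (36, "mitotic_exit")])) == "mitotic_exit"
        assert classify_fate(seq([(4, "birth"), (30, "mitosis_entry"),
                                  (39, "cytokinesis_failure")])) == "cytokinesis_failure"

    def test_early_death_without_arrest_is_direct_apoptosis(self):
        s = seq([(4, "birth"), (14, "interphase_death")])
        assert classify_fate(s) == "direct_apoptosis"

    def test_one_hour_mitosis_is_normal(self):
        s = seq([(4, "birth"), (30, "mitosis_entry"), (31, "division")])
        assert classify_fate(s) == "normal"

    def test_uneventful_cell_is_normal(self):
        assert classify_fate(seq([(4, "birth")])) == "normal"

    def test_threshold_separates_normal_from_arrest(self):
        s = seq([(4, "birth"), (30, "mitosis_entry"), (32.5, "mitotic_exit")])
        assert classify_fate(s, FateThresholds(arrest_h=2.0)) == "mitotic_exit"
        assert classify_fate(s, FateThresholds(arrest_h=3.0)) != "mitotic_exit"

    def test_grammar_violation_rejected(self):
        with pytest.raises(ValueError):
            classify_fate(seq([(4, "birth"), (30, "mitotic_death")]))
        with pytest.raises(ValueError):
            classify_fate(seq([(10, "mitosis_entry")]))

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FateThresholds(normal_mitosis_h=2.0, arrest_h=1.0)


def test_confusion_matrix_identity_on_generator_output():
    """Classifying noiseless generated sequences reproduces the generating
    fate label exactly (identity confusion matrix)."""
    log = sd.assign_fates(500, seed=8)
    truth = {}
    for cid, s in log.sequences():
        terminal = s.iloc[-1]["event"]
        truth[cid] = "direct_apoptosis" if terminal == "interphase_death" else terminal
    labels = classify_log(log).set_index("cell_id")["fate"]
    assert all(labels[cid] == fate for cid, fate in truth.items())


class TestFateProfile:
    def test_point_mass(self):
        assert fate_profile(["mitotic_death"] * 4)["mitotic_death"] == 1.0

    def test_normals_excluded_from_denominator(self):
        labels = ["mitotic_death"] * 3 + ["normal"] * 7 + ["other"] * 2
        prof = fate_profile(labels)
        assert prof["mitotic_death"] == 1.0
        assert prof.sum() == pytest.approx(1.0)

    def test_no_phenotypic_cells_rejected(self):
        with pytest.raises(ValueError):
            fate_profile(["normal", "normal"])

    def test_default_mixture_recovery(self):
        log = sd.assign_fates(2000, seed=9)
        prof = fate_profile(classify_log(log)["fate"])
        for fate, p in [("mitotic_death", 0.42), ("mitotic_exit", 0.28),
                        ("cytokinesis_failure", 0.05)]:
            se = np.sqrt(p * (1 - p) / 2000)
            assert abs(prof[fate] - p) <= 3 * se


class TestArrestDurations:
    def test_cap_and_threshold(self):
        log = sd.assign_fates(400, seed=10)
        d = arrest_durations(log)
        assert len(d) > 0
        assert d.max() <= 10.0
        assert (d > DEFAULT_THRESHOLDS.arrest_h).all()

    def test_no_arrests_empty(self):
        log = sd.assign_fates(20, sd.FateMixture(0, 0, 0, 1.0), seed=0)
        assert arrest_durations(log).size == 0


class TestTimeCourse:
    def test_no_events_zero_mitotic_fraction(self):
        log = sd.simulate_well(n_cells=30, baseline_division_rate=0.0,
                               interphase_death_rate=0.0, seed=0)
        tc = time_course(log, [24.0, 48.0, 72.0])
        assert (tc["mitotic_fraction"] == 0).all()
        assert (tc["apoptotic_fraction"] == 0).all()

    def test_all_cells_arrested_fraction_one(self):
        ev = []
        for cid in range(10):
            ev += [(cid, -1, 4.0, "birth", 0.0, 0.0),
                   (cid, -1, 20.0, "mitosis_entry", 0.0, 0.0),
                   (cid, -1, 28.0, "mitotic_death", 0.0, 0.0)]
        log = sd.CellEventLog(pd.DataFrame(
            ev, columns=["cell_id", "parent_id", "time_h", "event", "x_um", "y_um"]))
        tc = time_course(log, [24.0])
        assert tc.loc[0, "mitotic_fraction"] == 1.0

    def test_timepoint_outside_range_rejected(self):
        log = sd.simulate_well(n_cells=5, seed=0)
        with pytest.raises(ValueError):
            time_course(log, [100.0])

    def test_knockdown_raises_mitotic_fraction_at_60h(self):
        """An arrest phenotype (strongest well after the penetration delay)
        shows a higher mitotic fraction than control at 60 h."""
        arrest = sd.WellPhenotype(0.8, "mitotic_arrest", 12.0)
        kd = sd.simulate_well(arrest, n_cells=150, seed=14)
        ctrl = sd.simulate_well(n_cells=150, seed=14)
        f_kd = time_course(kd, [60.0]).loc[0, "mitotic_fraction"]
        f_ctrl = time_course(ctrl, [60.0]).loc[0, "mitotic_fraction"]
        assert f_kd > f_ctrl

    def test_apoptotic_fraction_cumulative(self):
        log = sd.assign_fates(200, seed=15)
        tc = time_course(log, [24.0, 48.0, 72.0])
        assert tc["apoptotic_fraction"].is_monotonic_increasing
        assert tc["apoptotic_fraction"].iloc[-1] > 0
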