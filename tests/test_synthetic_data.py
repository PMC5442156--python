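"""Generative-model tests: library/plate construction, event-log grammar,
branching-process calibration, fate sequences and manual scores."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitoscreen import synthetic_data as sd


# ---------------------------------------------------------------------------
# library

class TestLibrary:
    def test_default_library_size(self):
        lib = sd.make_library(638, 5, seed=0)
        assert lib.n_targets == 638
        assert lib.total_sirnas > 3100
        assert all(1 <= len(lib.sirnas[t]) <= 5 for t in lib.targets)

    def test_sirna_ids_globally_unique(self):
        lib = sd.make_library(100, 5, seed=3)
        ids = lib.all_sirnas()
        assert len(ids) == len(set(ids))

    def test_empty_library(self):
        assert sd.make_library(0, 5, seed=0).total_sirnas == 0

    def test_max_policy_exact_count(self):
        assert sd.make_library(10, 5, seed=0, policy="max").total_sirnas == 50

    def test_seed_reproducibility(self):
        a = sd.make_library(50, 5, seed=9)
        b = sd.make_library(50, 5, seed=9)
        assert a.sirnas == b.sirnas

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_max_sirnas_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.make_library(10, bad, seed=0)


# ---------------------------------------------------------------------------
# plates

class TestPlates:
    def test_control_complement_per_plate(self):
        lib = sd.make_library(seed=1)
        for plate in sd.make_plates(lib, seed=1):
            counts = pd.Series(list(plate.wells.values())).value_counts()
            for label in sd.POSITIVE_CONTROLS + sd.NEGATIVE_CONTROLS:
                assert counts[label] == 2
            assert counts.get(sd.EMPTY, 0) >= 1

    def test_sample_well_conservation(self):
        lib = sd.make_library(seed=1)
        plates = sd.make_plates(lib, seed=1)
        placed = [c for p in plates for c in p.wells.values() if sd.is_sample(c)]
        assert sorted(placed) == sorted(lib.all_sirnas())
        assert len(placed) == len(set(placed))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sd.make_plates(sd.make_library(0, 5, seed=0))

    def test_format_too_small_rejected(self):
        lib = sd.make_library(10, 5, seed=0)
        with pytest.raises(ValueError, match="format"):
            sd.make_plates(lib, rows=4, cols=4)


# ---------------------------------------------------------------------------
# phenotypes

class TestPhenotype:
    def test_effect_bounds(self):
        with pytest.raises(ValueError):
            sd.WellPhenotype(1.5, "viability")

    def test_zero_effect_matches_null(self):
        ph = sd.WellPhenotype(0.0, "viability", 12.0)
        assert ph.rate_multiplier(50.0) == 1.0
        assert ph.arrest_prob(50.0) == 0.0

    def test_delay_gates_the_effect(self):
        ph = sd.WellPhenotype(0.8, "viability", 12.0)
        assert ph.rate_multiplier(11.9) == 1.0
        assert ph.rate_multiplier(12.0) == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# event-level well simulation

class TestSimulateWell:
    def test_grammar_and_division_conservation(self):
        log = sd.simulate_well(n_cells=60, seed=4)
        log.validate()  # grammar automaton + births == 2*divisions + founders

    def test_seed_determinism(self):
        a = sd.simulate_well(n_cells=40, seed=5)
        b = sd.simulate_well(n_cells=40, seed=5)
        pd.testing.assert_frame_equal(a.events, b.events)
        c = sd.simulate_well(n_cells=40, seed=6)
        assert not a.events.equals(c.events)

    def test_no_cells_empty_log(self):
        log = sd.simulate_well(n_cells=0, seed=0)
        assert len(log.events) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_well(baseline_division_rate=-0.1)

    def test_full_knockdown_stops_divisions_after_delay(self):
        """A complete viability knockdown with a 12 h penetration delay can
        emit no division after ~13 h (entries stop at 12 h; a normal mitosis
        lasts 1 h), well before the 16 h bound."""
        ph = sd.WellPhenotype(1.0, "viability", 12.0)
        log = sd.simulate_well(ph, n_cells=300, baseline_division_rate=0.05, seed=7)
        divisions = log.events[log.events["event"] == "division"]
        assert (divisions["time_h"] <= 16.0).all()

    def test_division_count_within_monte_carlo_band(self):
        """The per-cell simulator's division count falls inside the 99%
        band of an independent aggregate branching simulation."""
        n, rate = 200, 0.02
        spec = sd.MovieSpec()
        dt = spec.interval_h
        rng = np.random.default_rng(123)
        reps = np.zeros(200, dtype=int)
        for r in range(reps.size):  # independent oracle: count recursion with
            alive, total = n, 0     # a 1 h (2-step) mitosis delay line
            pipe = [0, 0]
            for _ in range(spec.n_frames - 1):
                done = pipe.pop(0)
                k = rng.binomial(alive, rate * dt)
                d = rng.binomial(alive - k, 0.001 * dt)
                alive += 2 * done - k - d
                total += done
                pipe.append(k)
            reps[r] = total
        lo, hi = np.quantile(reps, [0.005, 0.995])
        observed = sd.simulate_well(n_cells=n, baseline_division_rate=rate,
                                    seed=11).n_divisions
        assert lo <= observed <= hi

    def test_fast_counts_match_event_level_distribution(self):
        """The aggregate fast path and the per-cell simulator implement the
        same branching law: the event-level count lands in the fast-path
        spread."""
        counts = sd.simulate_well_counts(
            [sd.NULL_PHENOTYPE] * 200, n_cells=100, baseline_division_rate=0.03,
            rate_cv=0.0, seed=21)
        event_level = sd.simulate_well(n_cells=100, baseline_division_rate=0.03,
                                       seed=22).n_divisions
        lo, hi = np.quantile(counts, [0.005, 0.995])
        assert lo <= event_level <= hi


# ---------------------------------------------------------------------------
# fate sequences

class TestAssignFates:
    def test_point_mass_mixture(self):
        mix = sd.FateMixture(1.0, 0.0, 0.0, 0.0)
        log = sd.assign_fates(50, mix, seed=0)
        log.validate()
        counts = log.counts()
        assert counts["mitotic_death"] == 50
        assert counts["mitosis_entry"] == 50

    def test_empty(self):
        assert sd.assign_fates(0, seed=0).n_cells == 0

    def test_mixture_recovery_within_3se(self):
        n = 2000
        log = sd.assign_fates(n, seed=1)
        counts = log.counts()
        for event, p in [("mitotic_death", 0.42), ("mitotic_exit", 0.28),
                         ("cytokinesis_failure", 0.05), ("interphase_death", 0.25)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(event, 0) / n - p) <= 3 * se

    def test_arrest_durations_in_cap(self):
        log = sd.assign_fates(300, seed=2)
        ev = log.events
        entries = ev[ev["event"] == "mitosis_entry"].set_index("cell_id")["time_h"]
        ends = ev[ev["event"].isin(sd.MITOSIS_RESOLUTIONS)].set_index("cell_id")["time_h"]
        durations = (ends - entries).dropna()
        assert ((durations > 2.0) & (durations <= 10.0)).all()

    def test_direct_apoptosis_window(self):
        log = sd.assign_fates(300, seed=3)
        deaths = log.events[log.events["event"] == "interphase_death"]["time_h"]
        assert ((deaths >= 12.0) & (deaths <= 24.0)).all()

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            sd.FateMixture(0.5, 0.5, 0.5, -0.5)
        with pytest.raises(ValueError):
            sd.FateMixture(0.3, 0.3, 0.3, 0.3)


# ---------------------------------------------------------------------------
# manual scores

class TestManualScores:
    def test_noiseless_endpoints(self):
        assert sd.synthesize_manual_scores([0.0], 0.0, seed=0)[0] == 1
        assert sd.synthesize_manual_scores([1.0], 0.0, seed=0)[0] == 5

    def test_scores_monotone_in_effect(self):
        effects = np.linspace(0, 1, 6)
        means = []
        for e in effects:
            scores = sd.synthesize_manual_scores(np.full(10_000, e), 0.5, seed=int(e * 10))
            means.append(scores.mean())
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_out_of_range_effect_rejected(self):
        with pytest.raises(ValueError):
            sd.synthesize_manual_scores([1.2], 0.5, seed=0)


# ---------------------------------------------------------------------------
# pulldown tables

def test_peptide_tables_structure():
    target, controls, n_theo = sd.make_peptide_tables(n_proteins=50, n_enriched=10, seed=0)
    assert len(controls) == 2
    assert set(target["protein_id"]) == set(n_theo)
    assert (target["intensity"] >= 0).all()
    # designated enriched proteins really are brighter in the target pulldown
    t_sum = target.groupby("protein_id")["intensity"].sum()
    c_sum = controls[0].groupby("protein_id")["intensity"].sum()
    enriched = [f"PROT{i:04d}" for i in range(10)]
    ratio = (t_sum[enriched] / c_sum[enriched]).median()
    assert ratio > 4
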