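"""Henderson-Hasselbalch fitting, gating, bootstrap errors, population
profiles."""

import numpy as np
import pandas as pd
import pytest

import titramem as tm
from titramem.pka import (
    GATE_FITTED,
    GATE_MONOTONIC,
    GATE_PH,
    GATE_POINTS,
    GATE_REPLICAS,
    PKaProfiler,
    bayesian_bootstrap_pka,
    hh_fit,
    hh_protonated_fraction,
    ionized_population_profile,
)
from tests.conftest import conditional_records


class TestHHFit:
    @pytest.mark.parametrize(
        "pka,ph_grid",
        [
            (3.94, [3.0, 4.0, 5.0, 6.0]),  # Asp ladder
            (6.54, [4.5, 5.5, 6.5, 7.5]),  # His ladder
        ],
    )
    def test_exact_data_recovers_generating_value(self, pka, ph_grid):
        means = hh_protonated_fraction(np.array(ph_grid), pka)
        assert hh_fit(ph_grid, means) == pytest.approx(pka, abs=1e-6)

    def test_noisy_data_recovery_within_tenth(self):
        # titration means with gaussian noise sd 0.02: the fitted pKa
        # stays within 0.1 of the generating value across 100 draws
        rng = np.random.default_rng(2024)
        ph = np.array([3.0, 4.0, 5.0, 6.0])
        errs = []
        for _ in range(100):
            y = hh_protonated_fraction(ph, 3.94) + rng.normal(0, 0.02, size=4)
            errs.append(abs(hh_fit(ph, np.clip(y, 0.0, 1.0)) - 3.94))
        assert max(errs) < 0.1

    def test_flat_data_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            hh_fit([3, 4, 5, 6], [0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="flat"):
            hh_fit([3, 4, 5, 6], [1.0, 1.0, 1.0, 1.0])

    def test_single_ph_rejected(self):
        with pytest.raises(ValueError, match="2 distinct pH"):
            hh_fit([4.0, 4.0], [0.4, 0.6])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            hh_fit([3.0, np.nan], [0.4, 0.6])

    def test_counts_weighting_pulls_toward_heavier_ph(self):
        ph = [4.0, 6.0]
        y = [hh_protonated_fraction(4.0, 5.0) + 0.05, hh_protonated_fraction(6.0, 5.0)]
        unweighted = hh_fit(ph, y)
        weighted = hh_fit(ph, y, counts=[10000, 1])
        # the heavily weighted (perturbed) point dominates the fit
        assert abs(weighted - unweighted) > 1e-3

    def test_results_summary(self):
        model = tm.HendersonHasselbalch([3, 4, 5, 6],
                                        hh_protonated_fraction(np.array([3, 4, 5, 6.0]), 4.25))
        res = model.fit()
        assert res.pka == pytest.approx(4.25, abs=1e-6)
        assert "pKa = 4.2500" in res.summary()


class TestIonizedProfile:
    def _records(self, insertions, states, ph=4.0):
        n = len(insertions)
        return pd.DataFrame(
            {
                "time": np.arange(n, dtype=float),
                "replica_id": "r",
                "replicate_index": 1,
                "pH": ph,
                "window_id": "",
                "z_nm": np.asarray(insertions) / 10.0,
                "state": states,
                "bias_kJmol": 0.0,
                "equilibration_flag": False,
            }
        )

    def test_grid_has_200_bins(self):
        prof = ionized_population_profile(self._records([0.1], [tm.PROTONATED]), "acid")
        assert len(prof.centers) == 200
        assert prof.bin_edges[0] == -15.0 and prof.bin_edges[-1] == 25.0

    def test_all_neutral_gives_zero_counts(self):
        rec = self._records([0.1, 0.3, 1.0], [tm.PROTONATED] * 3)
        prof = ionized_population_profile(rec, "acid")
        assert prof.ionized.sum() == 0

    def test_fraction_arithmetic(self):
        states = [tm.DEPROTONATED] * 4 + [tm.PROTONATED] * 6
        rec = self._records([0.1] * 10, states)
        prof = ionized_population_profile(rec, "acid")
        i = np.searchsorted(prof.bin_edges, 0.1, side="right") - 1
        assert prof.total[i] == 10
        assert prof.fraction[i] == pytest.approx(0.4)

    def test_half_open_edge_convention(self):
        rec = self._records([0.2], [tm.DEPROTONATED])
        prof = ionized_population_profile(rec, "acid")
        left = np.flatnonzero(prof.total)[0]
        assert prof.bin_edges[left] == pytest.approx(0.2)  # lands in [0.2, 0.4)

    def test_base_counts_protonated_as_ionized(self):
        rec = self._records([0.1, 0.1], [tm.PROTONATED, tm.DEPROTONATED])
        prof = ionized_population_profile(rec, "base")
        assert prof.ionized.sum() == 1

    def test_empty_range_warns(self):
        rec = self._records([100.0], [tm.PROTONATED])
        with pytest.warns(UserWarning, match="no frames"):
            prof = ionized_population_profile(rec, "acid")
        assert prof.total.sum() == 0


def gate_records(n_ionized=100, n_neutral=100, ph_values=(4.0, 5.0), replicas=(1, 2),
                 z_A=0.5, means=None):
    """Construct a record table concentrated in one scan bin with exact
    control over counts, pH spread, replica spread and per-pH means."""
    rows = []
    ph_values = list(ph_values)
    if means is None:
        means = [n_neutral / (n_ionized + n_neutral)] * len(ph_values)
    for j, (ph, m) in enumerate(zip(ph_values, means)):
        total = n_ionized + n_neutral
        n_prot = int(round(m * total))
        states = [tm.PROTONATED] * n_prot + [tm.DEPROTONATED] * (total - n_prot)
        reps = [replicas[i % len(replicas)] for i in range(total)]
        rows.append(
            pd.DataFrame(
                {
                    "time": np.arange(total, dtype=float),
                    "replica_id": "r",
                    "replicate_index": reps,
                    "pH": ph,
                    "window_id": "",
                    "z_nm": z_A / 10.0,
                    "state": states,
                    "bias_kJmol": 0.0,
                    "equilibration_flag": False,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestGates:
    def _profile_status(self, records, **kwargs):
        prof = PKaProfiler(records, "acid", scan_lo=0.0, scan_hi=1.0, stride=1.0,
                           n_boot=10, **kwargs).fit(seed=0)
        return prof.table.iloc[0]["status"]

    def test_49_ionized_points_insufficient(self):
        rec = gate_records(n_ionized=49, n_neutral=200, means=[0.8, 0.8])
        # means chosen so the deprotonated pool stays below 50 in total
        rec.loc[rec["state"] == tm.DEPROTONATED, "state"] = tm.PROTONATED
        rec.loc[rec.index[:49], "state"] = tm.DEPROTONATED
        assert self._profile_status(rec) == GATE_POINTS

    def test_50_points_pass_the_count_gate(self):
        rec = gate_records(n_ionized=50, n_neutral=450, means=None)
        status = self._profile_status(rec)
        assert status != GATE_POINTS

    def test_single_ph_insufficient(self):
        rec = gate_records(ph_values=(4.0,))
        assert self._profile_status(rec) == GATE_PH

    def test_single_replica_insufficient(self):
        rec = gate_records(replicas=(1,))
        assert self._profile_status(rec) == GATE_REPLICAS

    def test_non_monotonic_rejected(self):
        rec = gate_records(ph_values=(4.0, 5.0), means=[0.40, 0.60])
        assert self._profile_status(rec) == GATE_MONOTONIC

    def test_within_slack_still_fits(self):
        rec = gate_records(ph_values=(4.0, 5.0), means=[0.50, 0.51])
        assert self._profile_status(rec, mono_slack=0.02) == GATE_FITTED

    def test_gate_statuses_are_order_independent(self):
        rec = conditional_records(tm.asp_like(), [3, 4, 5, 6], n_per=800, seed=3)
        prof_a = PKaProfiler(rec, "acid", n_boot=5).fit(seed=1)
        shuffled = rec.sample(frac=1.0, random_state=9).reset_index(drop=True)
        prof_b = PKaProfiler(shuffled, "acid", n_boot=5).fit(seed=1)
        pd.testing.assert_series_equal(prof_a.table["status"], prof_b.table["status"])
        np.testing.assert_allclose(prof_a.table["pka"], prof_b.table["pka"], atol=1e-12)

    def test_equilibration_frames_are_ignored(self):
        rec = gate_records()
        junk = gate_records(ph_values=(4.0, 5.0), means=[0.0, 1.0])
        junk["equilibration_flag"] = True
        prof_a = PKaProfiler(rec, "acid", scan_lo=0.0, scan_hi=1.0, stride=1.0,
                             n_boot=10).fit(seed=0)
        prof_b = PKaProfiler(pd.concat([rec, junk], ignore_index=True), "acid",
                             scan_lo=0.0, scan_hi=1.0, stride=1.0, n_boot=10).fit(seed=0)
        pd.testing.assert_frame_equal(prof_a.table, prof_b.table)


class TestScanGrid:
    def test_printed_scan_parameters(self):
        profiler = PKaProfiler(gate_records(), "acid")
        edges = profiler.bin_left_edges()
        assert edges[0] == pytest.approx(-12.0)
        assert edges[1] == pytest.approx(-11.75)
        assert edges[-1] == pytest.approx(21.0)
        assert len(edges) == 133


class TestBayesianBootstrap:
    def _frames(self, n, pka=4.5, ph_values=(3.5, 4.5, 5.5)):
        return {
            ph: np.repeat([1.0, 0.0],
                          [round(n * hh_protonated_fraction(ph, pka)),
                           n - round(n * hh_protonated_fraction(ph, pka))])
            for ph in ph_values
        }

    def test_error_shrinks_with_counts(self):
        sds = [
            bayesian_bootstrap_pka(self._frames(n), n_boot=1000,
                                   rng=np.random.default_rng(7)).error
            for n in (50, 500, 5000)
        ]
        assert sds[0] > sds[1] > sds[2]

    def test_single_bootstrap_degenerate(self):
        res = bayesian_bootstrap_pka(self._frames(100), n_boot=1,
                                     rng=np.random.default_rng(0))
        assert res.error == 0.0
        assert res.degenerate

    def test_fixed_seed_reproducible(self):
        a = bayesian_bootstrap_pka(self._frames(200), n_boot=500,
                                   rng=np.random.default_rng(3))
        b = bayesian_bootstrap_pka(self._frames(200), n_boot=500,
                                   rng=np.random.default_rng(3))
        assert a.error == b.error


class TestProfilePipeline:
    def test_flat_model_profile_is_flat_at_reference(self):
        m = tm.flat_model(pKa_w=4.0, confined=False)
        rec = conditional_records(m, [3, 4, 5, 6], n_per=4000, seed=11)
        prof = PKaProfiler(rec, "acid", n_boot=100).fit(seed=2)
        fitted = prof.fitted
        assert len(fitted) > 100
        assert np.abs(fitted["pka"] - 4.0).max() < 0.2
        assert np.abs(fitted["pka"] - 4.0).median() < 0.05

    def test_insertion_column_preferred_over_z(self):
        rec = gate_records()
        rec["insertion_A"] = rec["z_nm"] * 10.0 + 5.0  # shift by 5 A
        prof = PKaProfiler(rec, "acid", scan_lo=5.0, scan_hi=6.0, stride=1.0,
                           n_boot=5).fit(seed=0)
        assert prof.table.iloc[0]["status"] == GATE_FITTED
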