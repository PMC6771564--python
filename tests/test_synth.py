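"""Synthetic snapshots, time courses and tube meshes; parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from trypocycle.cohorts import CohortComparison
from trypocycle.ergodic import CellCycleMap, age_cdf
from trypocycle.simulate import SimScenario
from trypocycle.synth import (
    SnapshotSpec,
    generate_snapshot,
    generate_tapered_tube,
    generate_timecourse,
    linear_profile_through,
    nfd_like_tube,
    ofd_like_tube,
    recover_windows,
)


class TestSnapshot:
    def test_zero_window_gives_no_marked_cells(self):
        df = generate_snapshot(SnapshotSpec(n_cells=5000, w_tip_u=0.0, seed=1))
        assert df["tip_marker"].sum() == 0

    def test_marked_fractions_match_ergodic_expectation(self):
        n = 50_000
        spec = SnapshotSpec(n_cells=n, seed=2)
        df = generate_snapshot(spec)
        for col, w in (("tip_marker", spec.w_tip_u), ("mid_marker", spec.w_mid_u)):
            p = age_cdf(w) / 2.0
            se = np.sqrt(p * (1 - p) / n)
            assert abs(df[col].mean() - p) < 3 * se

    def test_markers_never_cooccur(self):
        df = generate_snapshot(SnapshotSpec(n_cells=20_000, seed=3))
        assert ((df["tip_marker"] == 1) & (df["mid_marker"] == 1)).sum() == 0

    def test_same_seed_identical(self):
        a = generate_snapshot(SnapshotSpec(n_cells=500, seed=4))
        b = generate_snapshot(SnapshotSpec(n_cells=500, seed=4))
        pd.testing.assert_frame_equal(a, b)

    def test_free_flagellum_never_exceeds_flagellum(self):
        df = generate_snapshot(SnapshotSpec(n_cells=5000, seed=5))
        assert (df["free_flagellum_um"] <= df["flagellum_um"] + 1e-9).all()

    def test_stage_configuration_consistent_with_age(self, cmap):
        df = generate_snapshot(SnapshotSpec(n_cells=2000, seed=6))
        g1 = df["age_u"] < cmap.b_2f
        assert (df.loc[g1, "n_flagella"] == 1).all()
        assert (df.loc[~g1, "n_flagella"] == 2).all()

    def test_missingness_rate(self):
        df = generate_snapshot(SnapshotSpec(n_cells=20_000, missing_rate=0.2, seed=7))
        assert df["faz_um"].isna().mean() == pytest.approx(0.2, abs=0.02)

    def test_invalid_specs_rejected(self, cmap):
        with pytest.raises(ValueError):
            SnapshotSpec(w_tip_u=0.7)  # beyond b_2f
        with pytest.raises(ValueError):
            SnapshotSpec(missing_rate=1.5)
        with pytest.raises(ValueError):
            SnapshotSpec(n_cells=0)


class TestWindowRecovery:
    def test_recovers_generating_windows(self):
        n = 100_000
        spec = SnapshotSpec(n_cells=n, w_tip_u=0.063, w_mid_u=0.020, seed=8)
        df = generate_snapshot(spec)
        w_tip, w_mid = recover_windows(df, spec.cycle_map)
        for w_est, w_true, col in (
            (w_tip, 0.063, "tip_marker"),
            (w_mid, 0.020, "mid_marker"),
        ):
            p = age_cdf(w_true) / 2.0
            se = np.sqrt(p * (1 - p) / n)
            # 3 binomial SEs on the marked fraction, pushed through the
            # inverse CDF slope du/dp = 2 / phi(u)
            from trypocycle.ergodic import age_pdf

            tol = 3 * se * 2.0 / age_pdf(w_true)
            assert abs(w_est - w_true) < tol

    def test_zero_marked_warns_and_returns_zero(self):
        df = generate_snapshot(SnapshotSpec(n_cells=200, w_tip_u=0.0, seed=9))
        with pytest.warns(UserWarning, match="tip"):
            w_tip, _ = recover_windows(df)
        assert w_tip == 0.0


class TestTimecourse:
    def test_initial_timepoint_fully_labelled(self):
        tc = generate_timecourse(
            SimScenario(n_agents=2000, seed=10), sample_size=500, seed=10
        )
        t0 = tc[tc["time_u"] == 0]
        assert t0.loc[t0["old_label_class"] == "affected", "count"].sum() == 0
        assert t0["count"].sum() == 500

    def test_full_sample_returns_exact_tallies(self):
        from trypocycle.simulate import run

        scenario = SimScenario(n_agents=300, seed=11)
        report = run(scenario, CellCycleMap(), seed=11)
        t0_pop = int(report.counts[report.counts["time_u"] == 0]["count"].sum())
        tc = generate_timecourse(
            scenario, sample_size=t0_pop, timepoints=[0.0], seed=11
        )
        exact = report.counts[report.counts["time_u"] == 0]["count"].to_numpy()
        assert np.array_equal(tc["count"].to_numpy(), exact)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_timecourse(
                SimScenario(n_agents=100, seed=12), sample_size=500,
                timepoints=[0.0], seed=12,
            )

    def test_late_equal_rates_sample_near_half(self):
        tc = generate_timecourse(
            SimScenario.equal_rates(n_agents=4000, seed=13),
            sample_size=500,
            timepoints=[1.25],  # 0.95 u post-induction: inside the plateau
            seed=13,
        )
        k1n1 = tc[tc["stage"].isin(["1F1K1N", "2F1K1N"])]
        full = k1n1.loc[k1n1["old_label_class"] == "full", "count"].sum()
        total = k1n1["count"].sum()
        se = np.sqrt(0.25 / total)
        assert abs(full / total - 0.5) < 4 * se


class TestEndToEndCohortOrdering:
    def test_snapshot_reproduces_daughter_cohort_ordering(self):
        """NFDs measure shorter flagellum / cell body / FAZ / K-N distance
        but a longer free flagellum than OFDs, each significant at P<0.05."""
        df = generate_snapshot(SnapshotSpec(n_cells=8000, seed=14))
        res = CohortComparison(df.drop(columns=["age_u", "cohort"])).fit()
        summaries = res.summaries.set_index(["parameter", "cohort"])

        def mean(param, cohort):
            return summaries.loc[(param, cohort), "mean"]

        def significant(param):
            t = res.pairwise
            row = t[(t.parameter == param) & (t.cohort_a == "NFD") & (t.cohort_b == "OFD")]
            return bool(row["significant"].iloc[0])

        for shorter in ("flagellum_um", "cell_body_um", "faz_um", "kn_dist_um"):
            assert mean(shorter, "NFD") < mean(shorter, "OFD")
            assert significant(shorter)
        assert mean("free_flagellum_um", "NFD") > mean("free_flagellum_um", "OFD")
        assert significant("free_flagellum_um")
        assert mean("anterior_angle_deg", "NFD") > mean("anterior_angle_deg", "OFD")
        assert significant("anterior_angle_deg")


class TestTaperedTubeGenerator:
    def test_cylinder_caliber_constant(self):
        from trypocycle.meshes import anterior_caliber

        tube = generate_tapered_tube(lambda z: 300.0, length=8000)
        for s in (2000.0, 4000.0):
            assert anterior_caliber(tube.mesh, tube.path, arclength=s) == pytest.approx(
                600.0, rel=0.01
            )

    def test_linear_taper_expected_caliber(self):
        tube = generate_tapered_tube(linear_profile_through(100.0, 250.0))
        assert tube.expected_caliber_at(2000.0) == pytest.approx(500.0, rel=1e-3)

    def test_daughter_like_profiles_reproduce_caliber_ratio(self):
        """Blunt vs tapered anterior fixtures anchor the 908 vs 403 nm
        calibers; their analytic ratio matches 908/403 within 2%."""
        nfd, ofd = nfd_like_tube(), ofd_like_tube()
        ratio = nfd.expected_caliber_at(2000.0) / ofd.expected_caliber_at(2000.0)
        assert ratio == pytest.approx(908.0 / 403.0, rel=0.02)

    def test_meshes_watertight_with_outward_normals(self):
        tube = generate_tapered_tube(linear_profile_through(120.0, 200.0))
        assert tube.mesh.is_watertight
        assert tube.mesh.volume > 0  # outward orientation

    def test_pointed_tip_profile(self):
        tube = generate_tapered_tube(lambda z: 0.1 * z, length=6000)
        assert tube.mesh.is_watertight
        assert tube.path.points[0] == pytest.approx([0.0, 0.0, 0.0])

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            generate_tapered_tube(lambda z: -1.0)
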