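"""Ground-truth selection, power-law fitting and the study orchestrator."""

import numpy as np
import pandas as pd
import pytest

import petphantomqa as qa
from petphantomqa.simulate import DurationSchedule
from petphantomqa.study import GroundTruthRule, StudyConfig, fit_power_law, run_study

COARSE = dict(voxel_size_mm=(3.3, 3.3, 3.0))


def _fake_frames(covs_or_counts, key):
    frames = []
    for t, v in covs_or_counts:
        f = qa.ScanVolume(
            grid=qa.VoxelGrid(shape=(2, 2, 2)),
            values=np.zeros((2, 2, 2)),
            setup=qa.AcquisitionSetup(),
            duration_s=t,
        )
        if key == "counts":
            f.expected_true_counts = v
        frames.append(f)
    return frames


def test_select_ground_truth_count_target_nearest():
    frames = _fake_frames([(60, 10e6), (180, 34e6), (900, 170e6)], "counts")
    rule = GroundTruthRule(kind="count_target", target=35e6)
    assert qa.select_ground_truth(frames, rule) == 1


def test_select_ground_truth_tie_prefers_longer_duration():
    frames = _fake_frames([(60, 30e6), (180, 40e6)], "counts")
    rule = GroundTruthRule(kind="count_target", target=35e6)
    assert qa.select_ground_truth(frames, rule) == 1


def test_select_ground_truth_fixed_duration():
    frames = _fake_frames([(60, 1.0), (180, 2.0)], "counts")
    assert (
        qa.select_ground_truth(frames, GroundTruthRule(kind="fixed_duration", duration_s=60))
        == 0
    )
    with pytest.raises(ValueError, match="not in schedule"):
        qa.select_ground_truth(frames, GroundTruthRule(kind="fixed_duration", duration_s=70))


def test_select_ground_truth_single_frame_any_rule():
    frames = _fake_frames([(60, 1.0)], "counts")
    assert qa.select_ground_truth(frames, GroundTruthRule(kind="count_target", target=9e9)) == 0


def test_select_ground_truth_cov_target(coarse_labels, background_vois, calibrated_setup, coarse_activity):
    frames = [
        qa.simulate(coarse_activity, calibrated_setup, t, coarse_labels.grid, 4.0, seed=int(t))
        for t in (5.0, 60.0, 900.0)
    ]
    covs = [qa.cov_bg(f.values, background_vois) for f in frames]
    target = covs[1]
    rule = GroundTruthRule(kind="cov_target", target=target)
    assert qa.select_ground_truth(frames, rule, background_vois=background_vois) == 1


def test_fit_power_law_exact():
    t = np.array([5.0, 10.0, 40.0, 160.0, 900.0])
    cov = 50.0 * t**-0.5
    fit = fit_power_law(t, cov)
    assert fit.a == pytest.approx(50.0, rel=1e-12)
    assert fit.b == pytest.approx(-0.5, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_fit_power_law_poisson_series(coarse_labels, background_vois, calibrated_setup, coarse_activity):
    """A simulated 13-frame series recovers the t^(-1/2) Poisson exponent."""
    durations = list(qa.duration_schedule())
    covs = []
    for j, t in enumerate(durations):
        scan = qa.simulate(coarse_activity, calibrated_setup, t, coarse_labels.grid, 4.0, seed=j)
        covs.append(qa.cov_bg(scan.values, background_vois))
    fit = fit_power_law(durations, covs)
    assert -0.55 < fit.b < -0.45
    assert fit.r_squared > 0.999


def test_fit_power_law_degenerate_inputs():
    with pytest.raises(ValueError):
        fit_power_law([10.0, 20.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_power_law([10.0, 20.0, 30.0], [1.0, -2.0, 3.0])
    flat = fit_power_law([10.0, 20.0, 40.0], [5.0, 5.0, 5.0])
    assert flat.b == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(flat.r_squared)


@pytest.fixture(scope="module")
def small_study():
    cfg = StudyConfig(
        **COARSE,
        denoisers=[qa.parse_denoiser_spec("gaussian:5"), qa.parse_denoiser_spec("identity")],
        master_seed=3,
    )
    return run_study(cfg)


def test_run_study_produces_full_grid(small_study):
    raw = small_study.records[small_study.records.variant == "raw"]
    assert len(raw) == 52
    assert raw.groupby("setup").size().eq(13).all()
    assert "error" not in small_study.records.columns


def test_run_study_ground_truth_self_comparison(small_study):
    recs = small_study.records
    for setup, gt_t in small_study.ground_truth_durations.items():
        row = recs[(recs.setup == setup) & (recs.duration_s == gt_t) & (recs.variant == "raw")]
        assert len(row) == 1
        assert row.ssim.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert row.mae.iloc[0] == 0.0
        assert row.psnr_db.iloc[0] == np.inf
        assert row.delta_suv_mean.iloc[0] == 0.0


def test_run_study_identity_variant_equals_raw(small_study):
    recs = small_study.records
    ident = recs[recs.variant == "identity"]
    assert len(ident) >= 1
    for _, row in ident.iterrows():
        raw = recs[
            (recs.setup == row.setup)
            & (recs.duration_s == row.duration_s)
            & (recs.variant == "raw")
        ].iloc[0]
        for col in ("cov_bg_percent", "ssim", "mae", "rc_mean_37mm", "cnr_10mm"):
            assert row[col] == pytest.approx(raw[col], rel=1e-12)


def test_run_study_power_law_r2_rounds_to_one(small_study):
    for name, fit in small_study.power_laws.items():
        assert round(fit.r_squared, 2) == 1.0, name


def test_run_study_qualitative_patterns(small_study):
    """CoV falls with duration; CNR rises; obese is noisier than thin;
    SBR10 has higher CNR than SBR4 at matched duration."""
    raw = small_study.records[small_study.records.variant == "raw"]
    piv_cov = raw.pivot_table(index="duration_s", columns="setup", values="cov_bg_percent")
    for col in piv_cov:
        assert piv_cov[col].is_monotonic_decreasing
    assert (piv_cov["SBR4_obese"] > piv_cov["SBR4_thin"]).all()
    piv_cnr = raw.pivot_table(index="duration_s", columns="setup", values="cnr_22mm")
    assert (piv_cnr["SBR10_thin"] > piv_cnr["SBR4_thin"]).all()
    # CNR grows with statistics (compare shortest vs ground-truth-length frames)
    assert (piv_cnr.loc[180.0] > piv_cnr.loc[5.0]).all()


def test_run_study_tables_and_csv_determinism(tmp_path):
    cfg = StudyConfig(
        **COARSE,
        setups=qa.default_setups()[:2],
        schedule=DurationSchedule((10.0, 60.0, 180.0)),
        denoisers=[qa.parse_denoiser_spec("gaussian:10")],
        master_seed=11,
    )
    res1 = run_study(cfg, out_dir=tmp_path / "a")
    res2 = run_study(cfg, out_dir=tmp_path / "b")
    for name in ("records", "ssim_grid", "power_law", "visibility", "denoiser_comparison"):
        f1 = (tmp_path / "a" / f"{name}.csv").read_bytes()
        f2 = (tmp_path / "b" / f"{name}.csv").read_bytes()
        assert f1 == f2, name
    assert "ssim_grid" in res1.tables
    grid = res1.tables["ssim_grid"]
    assert set(grid.columns) == {"SBR4_thin", "SBR4_obese"}
    assert list(grid.index) == [10.0, 60.0, 180.0]


def test_run_study_gaussian_table_orderings(small_study):
    """The anchor-scan comparison reproduces the post-filter directions:
    CoV monotone decreasing in FWHM."""
    tab = small_study.tables["denoiser_comparison"]
    anchor = tab[(tab.setup == "SBR4_thin") & (tab.duration_s == 10.0)]
    raw_cov = anchor[anchor.variant == "raw"].cov_bg_percent.iloc[0]
    g5_cov = anchor[anchor.variant == "G5"].cov_bg_percent.iloc[0]
    assert g5_cov < raw_cov
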