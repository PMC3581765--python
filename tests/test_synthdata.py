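"""Synthetic session generator: scripting, forward model, EMG synthesis."""

import filecmp

import numpy as np
import pytest

from emgkin import kinematics as km
from emgkin import synthdata as sd
from emgkin.features import WindowSpec, extract_features
from emgkin.io import POSITIONS, RUN_ACTIVE_DOFS, RunDescriptor, read_manifest


def _rd(run, position="POS1", duration=6.0):
    return RunDescriptor(run, position, tuple(sorted(RUN_ACTIVE_DOFS[run])),
                         duration)


class TestScriptAngles:
    def test_run1_leaves_pronosupination_neutral(self):
        left, right = sd.script_angles(_rd(1), seed=0)
        assert np.allclose(left.angles[:, 2], 90.0)
        assert left.angles[:, 0].std() > 5.0  # DoF1 articulated
        assert np.allclose(right.angles, left.angles)

    def test_run2_roles_swap(self):
        left, _ = sd.script_angles(_rd(2), seed=0)
        assert left.angles[:, 1].std() > 5.0  # DoF2 articulated
        assert left.angles[:, 0].std() == 0.0  # DoF1 held

    def test_run7_articulates_all_three(self):
        left, _ = sd.script_angles(_rd(7), seed=0)
        for d in range(3):
            assert left.angles[:, d].std() > 5.0

    def test_angles_within_stated_ranges(self):
        for run in range(1, 8):
            left, _ = sd.script_angles(_rd(run), seed=1)
            a = left.angles
            assert np.all(np.abs(a[:, 0]) <= 90.0)
            assert np.all(np.abs(a[:, 1]) <= 90.0)
            assert np.all((a[:, 2] >= 0.0) & (a[:, 2] <= 180.0))

    def test_held_dof_near_maximal_range(self):
        left, _ = sd.script_angles(_rd(1), seed=0)  # DoF2 held
        assert np.allclose(left.angles[:, 1], 0.9 * 60.0)

    def test_same_seed_identical(self):
        a, _ = sd.script_angles(_rd(3), seed=5)
        b, _ = sd.script_angles(_rd(3), seed=5)
        np.testing.assert_array_equal(a.angles, b.angles)
        c, _ = sd.script_angles(_rd(3), seed=6)
        assert not np.array_equal(a.angles, c.angles)

    def test_invalid_run_rejected(self):
        with pytest.raises(Exception):
            sd.script_angles(RunDescriptor(9, "POS1", (1, 2), 5.0))


class TestForwardModel:
    @pytest.mark.parametrize("position", POSITIONS)
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_noiseless_round_trip(self, position, side):
        trace, tr_r = sd.script_angles(_rd(7, position), seed=2)
        trace = trace if side == "left" else tr_r
        mk = sd.forward_markers(trace, sd.ArmGeometry(side=side), position)
        rec = km.compute_angles(mk, side=side)
        assert np.abs(rec.angles - trace.angles).max() < 1e-6

    def test_position_changes_pose_not_angles(self):
        _, trace = sd.script_angles(_rd(4), seed=3)
        geo = sd.ArmGeometry()
        mk1 = sd.forward_markers(trace, geo, "POS1")
        mk3 = sd.forward_markers(trace, geo, "POS3")
        assert not np.allclose(mk1.coords, mk3.coords)  # pose differs
        a1 = km.compute_angles(mk1, side="right").angles
        a3 = km.compute_angles(mk3, side="right").angles
        np.testing.assert_allclose(a1, a3, atol=1e-9)

    def test_marker_noise_gives_bounded_angle_error(self):
        _, trace = sd.script_angles(_rd(7, duration=10.0), seed=3)
        mk = sd.forward_markers(trace, sd.ArmGeometry(), "POS1",
                                marker_noise_mm=0.5, seed=0)
        rec = km.compute_angles(mk, side="right")
        rms = np.sqrt(np.mean((rec.angles - trace.angles) ** 2))
        assert rms < 1.0

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            sd.ArmGeometry(forearm_mm=-1.0)


class TestEmgSynthesis:
    def _flat_trace(self, n=2560):
        a = np.zeros((n, 3))
        a[:, 2] = 90.0
        return km.AngleTrace(a, 256.0, side="right", run=1, position="POS1")

    def test_zero_gain_mav_matches_gaussian_floor(self):
        """MAV of floor x unit-variance Gaussian carrier is floor*sqrt(2/pi)."""
        cfg = sd.EmgSynthConfig(gains=np.zeros((7, 6)), noise_floor=0.2)
        emg, _, _ = sd.synthesize_emg(self._flat_trace(), cfg, "POS1", seed=0)
        mav = np.mean(np.abs(emg.samples), axis=1)
        expected = 0.2 * np.sqrt(2 / np.pi)
        np.testing.assert_allclose(mav, expected, rtol=0.05)

    def test_gain_doubling_doubles_envelope(self):
        _, trace = sd.script_angles(_rd(1), seed=1)
        g1 = sd._default_gains()
        g2 = g1.copy()
        g2[2, :] *= 2.0
        cfg1 = sd.EmgSynthConfig(gains=g1, noise_floor=0.0, seed=3)
        cfg2 = sd.EmgSynthConfig(gains=g2, noise_floor=0.0, seed=3)
        e1, _, _ = sd.synthesize_emg(trace, cfg1, "POS1", seed=4)
        e2, _, _ = sd.synthesize_emg(trace, cfg2, "POS1", seed=4)
        m1 = np.mean(np.abs(e1.samples), axis=1)
        m2 = np.mean(np.abs(e2.samples), axis=1)
        assert m2[2] == pytest.approx(2 * m1[2], rel=1e-9)  # same carrier
        np.testing.assert_allclose(m2[[0, 1, 3]], m1[[0, 1, 3]], rtol=1e-12)

    def test_position_effect_changes_channel_scaling(self):
        cfg = sd.EmgSynthConfig(sigma_gain=0.3, seed=9)
        m1, b1 = cfg.position_effect("POS1")
        m2, b2 = cfg.position_effect("POS2")
        assert np.all(m1 > 0) and np.all(m2 > 0)
        assert not np.allclose(m1, m2)
        # the effect is a stable property of the position, not re-drawn
        m1b, _ = cfg.position_effect("POS1")
        np.testing.assert_array_equal(m1, m1b)

    def test_zero_sigma_means_no_effect(self):
        cfg = sd.EmgSynthConfig(sigma_gain=0.0, sigma_base=0.0, seed=9)
        for pos in POSITIONS:
            mult, base = cfg.position_effect(pos)
            np.testing.assert_allclose(mult, 1.0)
            np.testing.assert_allclose(base, 0.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.EmgSynthConfig(gains=-np.ones((7, 6)))
        with pytest.raises(ValueError):
            sd.EmgSynthConfig(gains=np.ones((6, 6)))

    def test_carrier_band_limited(self):
        cfg = sd.EmgSynthConfig(gains=np.zeros((7, 6)), noise_floor=1.0)
        emg, _, _ = sd.synthesize_emg(self._flat_trace(), cfg, "POS1", seed=0)
        f = np.fft.rfftfreq(emg.n_samples, 1 / emg.rate_hz)
        spec = np.abs(np.fft.rfft(emg.samples[0])) ** 2
        in_band = spec[(f > 20) & (f < 350)].sum()
        out_band = spec[(f < 10) | (f > 500)].sum()
        assert in_band > 50 * out_band


class TestGenerateSession:
    def test_file_counts_and_validation(self, mini_session):
        d, manifest = mini_session
        n_emg = sum(len(list(d.glob(f"*_{s}_emg.tsv"))) for s in ("left", "right"))
        assert n_emg == 42
        assert len(list(d.glob("*_markers.tsv"))) == 42
        assert len(list(d.glob("*_sync_*.tsv"))) == 42
        manifest.validate(complete=True)

    def test_same_master_seed_byte_identical(self, tmp_path):
        cfg = dict(duration_s=1.0, master_seed=77)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.generate_session(d1, **cfg)
        sd.generate_session(d2, **cfg)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert not mismatch and not errors

    def test_amputee_mode_blurs_control_side_gains(self, tmp_path):
        g = sd._default_gains()
        blurred = sd._amputated_gains(g)
        assert blurred.std() < g.std()  # reduced channel specificity
        np.testing.assert_allclose(blurred.mean(), g.mean())
        d = tmp_path / "amp"
        man = sd.generate_session(d, group="amputee", duration_s=1.0,
                                  control_side="right", master_seed=1)
        assert man.group == "amputee"
        read_manifest(d / "manifest.tsv").validate(complete=True)


class TestEndToEndOrderings:
    """Full-loop identifiability on the shared session fixtures."""

    def test_null_position_effect_equalizes_intra_inter(self, null_results):
        grid = null_results["grid"]
        cells = grid[grid["train"] != "POOLED"].groupby(
            ["scenario", "train", "test"])["r2"].mean().reset_index()
        intra = cells[cells["train"] == cells["test"]].set_index(
            ["scenario", "train"])["r2"]
        inter = cells[cells["train"] != cells["test"]]
        gaps = [
            abs(intra.loc[(row["scenario"], row["train"])] - row["r2"])
            for _, row in inter.iterrows()
        ]
        assert np.mean(gaps) < 0.05

    def test_position_effect_creates_intra_inter_gap(self, effect_results):
        grid = effect_results["grid"]
        intra = grid.loc[grid["kind"] == "intra", "r2"].mean()
        inter = grid.loc[grid["kind"] == "inter", "r2"].mean()
        assert intra - inter > 0.05

    def test_windows_per_run_match_formula(self, effect_results):
        grid = effect_results["grid"]
        assert len(grid) == 4 * (3 * 5 * 3 + 3 * 5)  # scenarios x (single + pooled)
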