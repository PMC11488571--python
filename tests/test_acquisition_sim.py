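"""Phantom generation, quadrature encoding, peak-hold and scan simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metalase import (RawRecord, ScanConfig, emulate_peak_hold,
                      encode_quadrature, generate_phantom, simulate_scan)
from metalase.acquisition_sim import MAP_NAMES
from metalase.trajectory import decode_quadrature


class TestPhantoms:
    def test_uniform_all_maps_constant(self):
        f = generate_phantom("uniform", (100.0, 100.0), 1.0, value=1.0)
        for name in MAP_NAMES:
            np.testing.assert_array_equal(f.maps[name], 1.0)

    def test_edge_is_half_plane_step_in_every_map(self):
        f = generate_phantom("edge", (100.0, 40.0), 0.5, axis="fast",
                             edge_position=50.0)
        x = (np.arange(f.shape[1]) + 0.5) * f.resolution
        for name in MAP_NAMES:
            col = f.maps[name][0]
            assert (col[x < 50.0] == 0.0).all()
            assert (col[x >= 50.0] == 1.0).all()

    def test_cells_deterministic_for_fixed_seed(self):
        f1 = generate_phantom("cells", (80.0, 80.0), 0.5, seed=7, n_cells=10)
        f2 = generate_phantom("cells", (80.0, 80.0), 0.5, seed=7, n_cells=10)
        for name in MAP_NAMES:
            np.testing.assert_array_equal(f1.maps[name], f2.maps[name])

    def test_cells_nuclei_inside_cytoplasm(self):
        f = generate_phantom("cells", (80.0, 80.0), 0.5, seed=1, n_cells=5)
        nuc = f.maps["nuclear_absorption"] > 0
        cyto = f.maps["uv_scattering"] > 0
        assert nuc.any() and (cyto | ~nuc).all()  # nuclei subset of cytoplasm

    def test_gradient_orr_step(self):
        f = generate_phantom("gradient", (40.0, 40.0), 1.0, axis="slow",
                             orr_low=0.3, orr_high=0.7, split_position=20.0)
        orr = f.maps["fad_af"] / (f.maps["fad_af"] + f.maps["nadh_af"])
        assert np.allclose(orr[:19], 0.3) and np.allclose(orr[21:], 0.7)

    @pytest.mark.parametrize("kwargs, match", [
        (dict(pattern="wiggle", extent=(10, 10), resolution=1.0), "pattern"),
        (dict(pattern="uniform", extent=(-1, 10), resolution=1.0), "extent"),
        (dict(pattern="uniform", extent=(10, 10), resolution=0.0), "resolution"),
        (dict(pattern="cells", extent=(10, 10), resolution=1.0, n_cells=0), "n_cells"),
        (dict(pattern="checkerboard", extent=(10, 10), resolution=1.0, period=-2), "period"),
    ])
    def test_invalid_specs_name_the_field(self, kwargs, match):
        pattern = kwargs.pop("pattern")
        extent = kwargs.pop("extent")
        resolution = kwargs.pop("resolution")
        with pytest.raises(ValueError, match=match):
            generate_phantom(pattern, extent, resolution, **kwargs)


class TestQuadrature:
    def test_forward_counts_traverse_gray_cycle(self):
        a, b = encode_quadrature(np.array([0, 1, 2, 3, 4]))
        states = list(zip(a.tolist(), b.tolist()))
        assert states == [(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]

    def test_constant_counts_constant_states(self):
        a, b = encode_quadrature(np.full(10, 3))
        assert len(set(zip(a.tolist(), b.tolist()))) == 1

    def test_round_trip_sinusoidal_counts(self):
        c = np.round(25 * np.sin(np.linspace(0, 20, 4000))).astype(int) + 7
        a, b = encode_quadrature(c)
        pos = decode_quadrature(a, b, 1.0)
        np.testing.assert_array_equal(pos - pos[0], c - c[0])

    def test_skip_rejected(self):
        with pytest.raises(ValueError, match="skip"):
            encode_quadrature(np.array([0, 2]))

    @given(st.lists(st.sampled_from([-1, 0, 1]), max_size=60))
    def test_round_trip_property(self, deltas):
        c = np.concatenate([[0], np.cumsum(deltas)]).astype(int)
        a, b = encode_quadrature(c)
        pos = decode_quadrature(a, b, 1.0)
        np.testing.assert_array_equal(pos - pos[0], c - c[0])


class TestPeakHold:
    def test_running_max_within_window(self):
        held = emulate_peak_hold(np.array([0.0, 3.0, 1.0, 2.0]), [0], [4])
        np.testing.assert_array_equal(held, [0.0, 3.0, 3.0, 3.0])

    def test_all_zero_signal(self):
        held = emulate_peak_hold(np.zeros(20), [2, 10], [6, 14])
        np.testing.assert_array_equal(held, 0.0)

    def test_baseline_outside_windows(self):
        held = emulate_peak_hold(np.ones(10), [2], [5])
        assert (held[:2] == 0).all() and (held[5:] == 0).all()

    @given(st.integers(0, 2**31 - 1))
    def test_held_value_at_reset_is_window_max(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.normal(0, 1, 50)
        trig, rst = [3, 25], [20, 49]
        held = emulate_peak_hold(sig, trig, rst)
        for t, r in zip(trig, rst):
            assert held[r - 1] == sig[t:r].max()

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            emulate_peak_hold(np.zeros(20), [0, 3], [10, 15])
        with pytest.raises(ValueError, match="window"):
            emulate_peak_hold(np.zeros(20), [5], [3])


class TestScanConfig:
    def test_defaults_give_20ns_interval(self):
        cfg = ScanConfig()
        assert cfg.sample_interval == pytest.approx(20e-9)

    @pytest.mark.parametrize("field, value", [
        ("prf", 5e3), ("prf", 3e6), ("fast_frequency", -1.0),
        ("noise_sd", -0.1), ("pars_window", 2),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError, match=field):
            ScanConfig(**{field: value})

    def test_prf_must_be_below_sample_rate(self):
        with pytest.raises(ValueError, match="prf"):
            ScanConfig(prf=2e6, sample_rate=1e6)


class TestSimulateScan:
    def test_sinusoid_quarter_period_amplitude(self):
        # D = 2 mm, f = 100 Hz: x(2.5 ms) - x(0) = 1 mm
        cfg = ScanConfig(fast_scan_distance=2.0, fast_frequency=100.0)
        from metalase.acquisition_sim import trajectory_positions
        f = generate_phantom("uniform", (2500.0, 10.0), 5.0)
        x, _ = trajectory_positions(cfg, f, np.array([0.0, 2.5e-3]))
        assert x[1] - x[0] == pytest.approx(1000.0)

    def test_one_ms_default_record_geometry(self):
        f = generate_phantom("uniform", (2500.0, 10.0), 5.0)
        rec = simulate_scan(f, ScanConfig(noise_sd=0.0))
        assert len(rec.channels) == 8
        assert all(len(c) == 50_000 for c in rec.channels.values())
        assert rec.sample_interval == pytest.approx(20e-9)

    def test_uniform_field_extracted_values_equal_value_times_gain(self):
        from metalase import extract_pulse_values, reconstruct_trajectory
        f = generate_phantom("uniform", (60.0, 10.0), 0.5, value=0.8)
        cfg = ScanConfig(fast_scan_distance=0.05, fast_frequency=50.0,
                         slow_velocity=0.02, prf=2e4, duration=0.1,
                         sample_rate=1e6, noise_sd=0.0, pars_gain=2.5)
        rec = simulate_scan(f, cfg)
        ev = extract_pulse_values(rec, reconstruct_trajectory(rec))
        assert len(ev) > 100
        np.testing.assert_allclose(ev.df["pars"], 0.8 * 2.5, rtol=1e-5)
        for ch in ("uv_refl", "af_collagen", "af_nadh", "af_fad"):
            np.testing.assert_allclose(ev.df[ch], 0.8, rtol=1e-5)

    def test_trigger_count_matches_prf(self, small_record):
        rec, _, cfg = small_record
        from metalase import detect_triggers
        n = detect_triggers(rec.channels["trigger"]).size
        assert abs(n - int(np.floor(cfg.prf * cfg.duration))) <= 1

    def test_fixed_seed_byte_identical(self, tmp_path):
        f = generate_phantom("cells", (40.0, 20.0), 0.5, seed=2, n_cells=3,
                             cyto_radius=5.0)
        cfg = ScanConfig(fast_scan_distance=0.03, fast_frequency=50.0,
                         slow_velocity=0.05, prf=1e4, duration=0.05,
                         sample_rate=1e6, noise_sd=0.02, seed=9)
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        simulate_scan(f, cfg).to_hdf5(p1)
        simulate_scan(f, cfg).to_hdf5(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_trajectory_overshoot_rejected(self):
        f = generate_phantom("uniform", (50.0, 10.0), 1.0)
        with pytest.raises(ValueError, match="overshoot"):
            simulate_scan(f, ScanConfig(fast_scan_distance=2.0, duration=1e-4,
                                        sample_rate=1e6))
        with pytest.raises(ValueError, match="overshoot"):
            simulate_scan(f, ScanConfig(fast_scan_distance=0.04,
                                        slow_velocity=10.0, duration=0.1,
                                        sample_rate=1e6))

    def test_record_roundtrip_hdf5(self, small_record, tmp_path):
        rec, _, cfg = small_record
        p = tmp_path / "rec.h5"
        rec.to_hdf5(p)
        back = RawRecord.from_hdf5(p)
        assert back.config == cfg
        for name, ch in rec.channels.items():
            np.testing.assert_array_equal(back.channels[name],
                                          ch.astype(back.channels[name].dtype))
        np.testing.assert_allclose(back.truth["pulse_x_um"], rec.truth["pulse_x_um"])

    def test_binary_channel_invariant_enforced(self, small_record):
        rec, _, _ = small_record
        bad = dict(rec.channels)
        bad["trigger"] = bad["trigger"].astype(float) + 0.5
        with pytest.raises(ValueError, match="binary"):
            RawRecord(channels=bad, sample_interval=rec.sample_interval,
                      config=rec.config)
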