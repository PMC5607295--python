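"""Virtual probe: channels, analyzer rows, forward model, geometry, fixtures."""

import numpy as np
import pytest

import polarprobe as pp
from polarprobe.mueller import (
    embed_linear,
    linear_polariser,
    linear_retarder,
    rotator,
)
from polarprobe.probe import PAIR_CHANNELS, analyzer_row


class TestChannelsAndAnalyzer:
    def test_ideal_exit_states(self, unpolarised_probe):
        np.testing.assert_allclose(
            unpolarised_probe.channels["H1"].exit_stokes, [1, 1, 0],
            atol=1e-12)
        np.testing.assert_allclose(
            unpolarised_probe.channels["B1"].exit_stokes, [1, 0, -1],
            atol=1e-12)

    def test_exit_dop_is_one_for_partially_polarised_source(self):
        # the source's 15% DOP modulates intensity, not polarisation purity
        probe = pp.ProbeModel.ideal(source_dop=0.15, source_axis_deg=27.0)
        for ch in probe.channels.values():
            assert np.hypot(*ch.exit_stokes[1:]) == pytest.approx(1.0)

    @pytest.mark.parametrize("label, expected", [
        ("H1", [0.5, 0.5, 0.0]),
        ("V2", [0.5, -0.5, 0.0]),
        ("B1", [0.5, 0.0, 0.5]),  # U sign flips on collection
    ])
    def test_analyzer_rows(self, unpolarised_probe, label, expected):
        np.testing.assert_allclose(
            analyzer_row(unpolarised_probe.channels[label]), expected,
            atol=1e-12)

    def test_build_probe_rejects_unknown_keys_and_missing_channels(self):
        config = {"channels": {l: {} for l in pp.CHANNEL_LABELS}}
        pp.build_probe(config)  # minimal config is valid
        with pytest.raises(ValueError, match="unknown"):
            pp.build_probe({**config, "extra": 1})
        broken = {"channels": {l: {} for l in pp.CHANNEL_LABELS if l != "V1"}}
        with pytest.raises(ValueError, match="V1"):
            pp.build_probe(broken)

    def test_build_probe_normalizes_measured_exit_stokes(self):
        config = {"channels": {l: {} for l in pp.CHANNEL_LABELS}}
        config["channels"]["H1"] = {"exit_stokes": [2.0, 1.9, 0.2]}
        probe = pp.build_probe(config)
        np.testing.assert_allclose(probe.channels["H1"].exit_stokes,
                                   [1.0, 0.95, 0.1])
        config["channels"]["H1"] = {"exit_stokes": [0.0, 0.0, 0.0]}
        with pytest.raises(ValueError, match="non-positive"):
            pp.build_probe(config)

    def test_per_fibre_gains_expand_to_pair_products(self):
        config = {
            "channels": {l: {} for l in pp.CHANNEL_LABELS},
            "gains": {"fibres": {l: 2.0 if l == "H1" else 1.0
                                 for l in pp.CHANNEL_LABELS}},
        }
        probe = pp.build_probe(config)
        assert probe.couplings["H1H2"] == pytest.approx(2.0)
        assert probe.couplings["V2H1"] == pytest.approx(2.0)  # collects via H1
        assert probe.couplings["V2V1"] == pytest.approx(1.0)


class TestForwardModel:
    @pytest.mark.parametrize("pair, expected", [
        ("H1H2", 1.0), ("H1V2", 0.0), ("B1B2", 1.0),
    ])
    def test_mirror_intensities(self, unpolarised_probe, pair, expected):
        illum, collect = PAIR_CHANNELS[pair]
        value = pp.simulate_intensity(
            unpolarised_probe.channels[illum],
            unpolarised_probe.channels[collect],
            np.diag([1.0, 1.0, -1.0]))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_identity_sample_pair_pattern(self, unpolarised_probe):
        meas = pp.simulate_measurement_set(unpolarised_probe, np.eye(3))
        assert meas.intensities["H1H2"] == pytest.approx(1.0)
        assert meas.intensities["H1V2"] == pytest.approx(0.0, abs=1e-12)
        assert meas.intensities["H1B1"] == pytest.approx(0.5)

    def test_linearity_in_gains(self, unpolarised_probe):
        sample = pp.make_synthetic_tissue(60.0, 30.0, (0.8, 0.9)).matrix
        base = pp.simulate_measurement_set(unpolarised_probe, sample)
        scaled_probe = unpolarised_probe.with_couplings(
            {p: 3.0 for p in pp.PAIR_SCHEME})
        scaled = pp.simulate_measurement_set(scaled_probe, sample)
        for p in pp.PAIR_SCHEME:
            assert scaled.intensities[p] == pytest.approx(
                3.0 * base.intensities[p])

    def test_intensity_additive_over_sample_sum(self, unpolarised_probe):
        a = pp.make_synthetic_tissue(40.0, 10.0, (0.9, 0.7)).matrix
        b = pp.make_synthetic_tissue(110.0, 70.0, (0.5, 0.6)).matrix
        ch = unpolarised_probe.channels
        for pair in pp.PAIR_SCHEME:
            il, co = PAIR_CHANNELS[pair]
            ia = pp.simulate_intensity(ch[il], ch[co], a)
            ib = pp.simulate_intensity(ch[il], ch[co], b)
            iab = pp.simulate_intensity(ch[il], ch[co], a + b)
            assert iab == pytest.approx(ia + ib, abs=1e-12)

    def test_collection_fibre_does_not_alter_total_intensity(
            self, unpolarised_probe):
        """Full-chain evaluation through an arbitrary non-depolarising
        unit-transmittance collection fibre agrees with the reduced
        analyzer-row form: the fibre reshuffles polarisation, not power."""
        rng = np.random.default_rng(42)
        ch = unpolarised_probe.channels
        for _ in range(30):
            sample = pp.make_synthetic_tissue(
                seed=int(rng.integers(2**31))).matrix
            fibre = (linear_retarder(rng.uniform(0, 180), rng.uniform(0, 360))
                     @ rotator(rng.uniform(0, 180))
                     @ linear_retarder(rng.uniform(0, 180),
                                       rng.uniform(0, 360)))
            pair = pp.PAIR_SCHEME[rng.integers(9)]
            il, co = PAIR_CHANNELS[pair]
            # collection micro-polariser seen by returning light: axis at
            # 180 - alpha in the frame of the travelling light
            pol_c = linear_polariser(180.0 - ch[co].polariser_angle)
            s_in = np.append(ch[il].exit_stokes, 0.0)
            s_out = fibre @ pol_c @ embed_linear(sample) @ s_in
            reduced = pp.simulate_intensity(ch[il], ch[co], sample)
            assert s_out[0] == pytest.approx(reduced, abs=1e-12)

    def test_noise_requires_seed_and_is_reproducible(self, unpolarised_probe):
        sample = np.diag([1.0, 1.0, -1.0])
        noise = pp.NoiseModel(cv=0.05)
        with pytest.raises(ValueError, match="seed"):
            pp.simulate_measurement_set(unpolarised_probe, sample, noise=noise)
        a = pp.simulate_measurement_set(unpolarised_probe, sample,
                                        noise=noise, seed=11)
        b = pp.simulate_measurement_set(unpolarised_probe, sample,
                                        noise=noise, seed=11)
        assert a.intensities == b.intensities
        c = pp.simulate_measurement_set(unpolarised_probe, sample,
                                        noise=noise, seed=12)
        assert a.intensities != c.intensities

    def test_negative_gain_rejected(self, unpolarised_probe):
        ch = unpolarised_probe.channels
        with pytest.raises(ValueError):
            pp.simulate_intensity(ch["H1"], ch["H2"], np.eye(3), gain=-1.0)


class TestFootprint:
    def test_contact_spot_equals_core(self):
        geom = pp.ProbeGeometry()
        out = pp.footprint(0.0, geom)
        assert out["spot_diameter_mm"] == pytest.approx(0.4)

    def test_half_angle_from_na(self):
        out = pp.footprint(1.0, pp.ProbeGeometry(na=0.39, medium_ri=1.0))
        assert out["half_angle_deg"] == pytest.approx(
            np.rad2deg(np.arcsin(0.39)), abs=1e-9)

    def test_monotone_in_working_distance(self):
        geom = pp.ProbeGeometry()
        distances = np.linspace(0.0, 5.0, 11)
        spots = [pp.footprint(d, geom)["spot_diameter_mm"] for d in distances]
        assert np.all(np.diff(spots) > 0)
        overlaps = [
            pp.footprint(d, geom)["pairwise_overlap_fraction"]["H1H2"]
            for d in distances]
        assert np.all(np.diff(overlaps) >= 0)

    def test_full_overlap_at_zero_separation(self):
        from polarprobe.probe import _circle_overlap_fraction
        assert _circle_overlap_fraction(0.0, 1.0) == pytest.approx(1.0)
        assert _circle_overlap_fraction(2.0, 1.0) == 0.0

    def test_invalid_na_rejected(self):
        with pytest.raises(ValueError):
            pp.footprint(1.0, pp.ProbeGeometry(na=1.5, medium_ri=1.0))


class TestSyntheticTissue:
    def test_trivial_parameters_give_identity(self):
        t = pp.make_synthetic_tissue(0.0, 0.0, (1.0, 1.0), 0.0)
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-12)

    def test_reflection_fixture_matches_double_pass(self):
        t = pp.make_synthetic_tissue(60.0, 90.0, (1.0, 1.0), reflection=True)
        np.testing.assert_allclose(t.matrix, np.diag([1.0, 1.0, -0.5]),
                                   atol=1e-12)

    def test_depolarisation_only_fixture(self):
        t = pp.make_synthetic_tissue(0.0, 0.0, (0.5, 0.62))
        result = pp.polar_decompose(t.matrix)
        assert result.depolarisation_pct == pytest.approx(44.0)

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            pp.make_synthetic_tissue(30.0, 0.0, (1.2, 0.5))
        with pytest.raises(ValueError):
            pp.make_synthetic_tissue(30.0, 0.0, (0.5, 0.5), diatten=1.0)

    def test_random_draws_are_seed_deterministic(self):
        a = pp.make_synthetic_tissue(seed=5)
        b = pp.make_synthetic_tissue(seed=5)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        with pytest.raises(ValueError, match="seed"):
            pp.make_synthetic_tissue()
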