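"""Virtual measurement generator: scene factories and frame rendering."""

import numpy as np
import pytest

from halftone_sfdi import (
    NoiseModel,
    OpticalProperties,
    Scene,
    demodulate_ac,
    make_flow_scene,
    make_phantom_array_scene,
    make_vessel_scene,
    render_frame,
    render_sequence,
    rd_frequency,
)
from halftone_sfdi.patterns import PatternSpec, pattern_sequence, sinusoid_pattern, PHASES
from halftone_sfdi.scene import phantom_tile_slices, render_time_series


def homogeneous_scene(mua=0.01, musp=1.0, shape=(120, 120), pitch=0.05, n_wl=1):
    return Scene(
        mua=np.full((*shape, n_wl), mua),
        musp=np.full((*shape, n_wl), musp),
        wavelengths=650.0 + 50.0 * np.arange(n_wl),
        pixel_pitch=pitch,
    )


class TestPhantomArrayScene:
    def test_sixteen_distinct_property_pairs(self):
        scene = make_phantom_array_scene(shape=(80, 80))
        pairs = {
            (scene.mua[rs, cs, 0][0, 0], scene.musp[rs, cs, 0][0, 0])
            for rs, cs in phantom_tile_slices((80, 80))
        }
        assert len(pairs) == 16

    def test_range_endpoints_reproduced_exactly(self):
        scene = make_phantom_array_scene(shape=(80, 80), mua_range=(0.005, 0.04), musp_range=(0.3, 2.0))
        assert scene.mua[..., 0].min() == 0.005
        assert scene.mua[..., 0].max() == 0.04
        assert scene.musp[..., 0].min() == 0.3
        assert scene.musp[..., 0].max() == 2.0

    def test_degenerate_single_tile_is_homogeneous(self):
        scene = make_phantom_array_scene(n_rows=1, n_cols=1, shape=(16, 16))
        assert np.unique(scene.mua[..., 0]).size == 1
        assert np.unique(scene.musp[..., 0]).size == 1

    def test_scattering_power_law_across_wavelengths(self):
        scene = make_phantom_array_scene(shape=(16, 16), wavelengths=(650.0, 850.0), scatter_power=0.6)
        ratio = scene.musp[0, 0, 1] / scene.musp[0, 0, 0]
        assert ratio == pytest.approx((850 / 650) ** -0.6)
        assert scene.mua[0, 0, 1] == scene.mua[0, 0, 0]


class TestVesselAndFlowScenes:
    def test_zero_width_gives_pure_background(self):
        bg = OpticalProperties(0.008, 1.0)
        scene = make_vessel_scene(bg, OpticalProperties(0.05, 1.0), 0.0, shape=(32, 32))
        assert np.all(scene.mua == 0.008)

    def test_stripe_carries_vessel_properties_exactly(self):
        scene = make_vessel_scene(
            OpticalProperties(0.008, 1.0), OpticalProperties(0.05, 1.4), 0.4,
            shape=(32, 32), pixel_pitch=0.05,
        )
        center = scene.mua[:, 16, 0]
        assert np.all(center == 0.05)
        assert np.all(scene.mua[:, 0, 0] == 0.008)
        assert np.all(scene.musp[:, 16, 0] == 1.4)

    def test_modulated_vessel_has_spectral_peak_at_rate(self):
        rate, frame_rate, n = 1.5, 15.0, 128
        scene = make_vessel_scene(
            OpticalProperties(0.008, 1.0), OpticalProperties(0.05, 1.0), 0.4,
            shape=(16, 16), modulation_rate=rate, modulation_amplitude=0.2,
            frame_rate=frame_rate, n_frames=n,
        )
        series = np.array([s.mua[0, 8, 0] for s in scene.time_course])
        spec = np.abs(np.fft.rfft(series - series.mean()))
        freqs = np.fft.rfftfreq(n, d=1 / frame_rate)
        assert freqs[np.argmax(spec)] == pytest.approx(rate, abs=freqs[1])

    def test_flow_scene_has_one_scene_per_frame(self):
        scene = make_flow_scene(shape=(60, 80), n_frames=10, blob_radius=0.4)
        assert len(scene.time_course) == 10
        uniq = np.unique(scene.time_course[0].mua[..., 0])
        assert uniq.size == 2  # background + blob


class TestRenderFrame:
    def test_dark_pattern_renders_to_zero_noise_free(self, mc_table):
        scene = homogeneous_scene()
        dark = sinusoid_pattern(PatternSpec(shape=scene.shape, pixel_pitch=0.05, kind="dark"))
        assert np.all(render_frame(scene, dark, mc_table) == 0)

    def test_planar_on_homogeneous_scene_is_uniform_rd0(self, mc_table):
        props = OpticalProperties(0.012, 1.1)
        scene = homogeneous_scene(props.mua, props.musp)
        planar = sinusoid_pattern(PatternSpec(shape=scene.shape, pixel_pitch=0.05, kind="planar"))
        out = render_frame(scene, planar, mc_table)
        rd0 = rd_frequency(mc_table, props, 0.0)
        assert np.ptp(out) < 1e-9  # no spatial structure
        assert out.mean() == pytest.approx(rd0, rel=1e-3)

    def test_demodulated_sinusoid_recovers_half_rd(self, mc_table):
        # analytic modulation-transfer identity at the standard AC frequency
        props = OpticalProperties(0.01, 1.0)
        scene = homogeneous_scene(props.mua, props.musp, shape=(200, 200))
        frames = [
            render_frame(
                scene,
                sinusoid_pattern(
                    PatternSpec(shape=scene.shape, fx=0.1, pixel_pitch=0.05, phase=ph)
                ),
                mc_table,
            )
            for ph in PHASES
        ]
        ac = demodulate_ac(*frames)
        expected = 0.5 * rd_frequency(mc_table, props, 0.1)
        assert np.median(ac) == pytest.approx(expected, rel=1e-3)

    def test_noise_seeded_and_reproducible(self, mc_table):
        scene = homogeneous_scene()
        planar = sinusoid_pattern(PatternSpec(shape=scene.shape, pixel_pitch=0.05, kind="planar"))
        noise = NoiseModel(seed=5)
        a = render_frame(scene, planar, mc_table, noise=noise)
        b = render_frame(scene, planar, mc_table, noise=noise)
        assert np.array_equal(a, b)
        assert np.std(a) > 0

    def test_out_of_validity_region_names_the_region(self, mc_table):
        scene = homogeneous_scene(musp=500.0)
        planar = sinusoid_pattern(PatternSpec(shape=scene.shape, pixel_pitch=0.05, kind="planar"))
        with pytest.raises(ValueError, match="musp=500"):
            render_frame(scene, planar, mc_table)

    def test_non_piecewise_constant_scene_rejected(self, mc_table):
        rng = np.random.default_rng(0)
        scene = Scene(
            mua=rng.uniform(0.005, 0.02, (32, 32, 1)),
            musp=np.full((32, 32, 1), 1.0),
            wavelengths=[650.0],
            pixel_pitch=0.05,
        )
        planar = sinusoid_pattern(PatternSpec(shape=(32, 32), pixel_pitch=0.05, kind="planar"))
        with pytest.raises(ValueError, match="piecewise"):
            render_frame(scene, planar, mc_table)


class TestRenderSequence:
    def test_five_patterns_give_five_frames_in_order(self, mc_table):
        scene = homogeneous_scene(shape=(64, 64))
        pats = pattern_sequence([650.0], 0.1, scene.shape, 0.05)
        seq = render_sequence(scene, pats, mc_table, fx=0.1)
        assert len(seq.frames) == 5
        assert np.all(seq.dark == 0)
        assert seq.fx == 0.1

    def test_static_scene_renders_identically_under_same_seed(self, mc_table):
        scene = homogeneous_scene(shape=(64, 64))
        pats = pattern_sequence([650.0], 0.1, scene.shape, 0.05)
        noise = NoiseModel(seed=11)
        a = render_sequence(scene, pats, mc_table, noise=noise)
        b = render_sequence(scene, pats, mc_table, noise=noise)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa, fb)

    def test_dynamic_two_wavelength_run_frame_count(self, mc_table):
        n_frames = 30  # 3 time points x 2 wavelengths x 5 patterns
        scene = make_flow_scene(shape=(24, 32), n_frames=n_frames, pixel_pitch=0.05)
        out = render_time_series(scene, 0.1, mc_table)
        assert len(out) == 3
        total = sum(len(seqs) * 5 for seqs in out)
        assert total == n_frames

    def test_wrong_pattern_count_rejected(self, mc_table):
        scene = homogeneous_scene(shape=(64, 64))
        pats = pattern_sequence([650.0], 0.1, scene.shape, 0.05)[:4]
        with pytest.raises(ValueError):
            render_sequence(scene, pats, mc_table)
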