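import numpy as np
import pytest

from pumpprobe.fitting import (
    FitConfig,
    TADecayFit,
    classify_pigment,
    fit_decay,
    fit_image,
    noise_floor,
)
from pumpprobe.synthetic import (
    AcquisitionMetadata,
    PhantomSpec,
    generate_phantom,
    render_stack,
)
from pumpprobe.ta_model import (
    PigmentModel,
    TAComponent,
    convolved_trace,
    default_models,
)

GRID = np.array(AcquisitionMetadata().delays_ps)


class TestFitDecay:
    def test_single_exponential_self_consistency(self, irf):
        model = PigmentModel("one", (TAComponent(1.0, 0.15),))
        delays = np.linspace(-0.5, 2.0, 40)
        trace = convolved_trace(model, irf, delays)
        fit = fit_decay(delays, trace, irf, FitConfig(n_components=1))
        assert fit.converged
        assert fit.lifetimes_ps[0] == pytest.approx(0.15, rel=1e-4)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-4)

    def test_two_component_eumelanin_recovery(self, irf, models):
        eu, _ = models
        trace = convolved_trace(eu, irf, GRID)
        fit = fit_decay(GRID, trace, irf, FitConfig(n_components=2))
        assert fit.converged
        assert fit.lifetimes_ps[1] == pytest.approx(9.4, rel=0.05)
        assert fit.amplitudes[1] < 0  # GSB component is negative

    def test_components_sorted_by_lifetime(self, irf, models):
        eu, _ = models
        fit = fit_decay(GRID, convolved_trace(eu, irf, GRID), irf, FitConfig())
        assert fit.lifetimes_ps[0] < fit.lifetimes_ps[1]

    def test_all_zero_trace_yields_zero_amplitudes(self, irf):
        fit = fit_decay(GRID, np.zeros_like(GRID), irf, FitConfig())
        if fit.converged:
            assert np.allclose(fit.amplitudes, 0.0, atol=1e-12)

    def test_too_few_points_rejected(self, irf):
        with pytest.raises(ValueError):
            fit_decay([0.0, 0.5, 1.0], [1.0, 0.5, 0.2], irf, FitConfig(n_components=2))

    def test_scaling_invariance(self, irf, models):
        eu, _ = models
        trace = convolved_trace(eu, irf, GRID)
        base = fit_decay(GRID, trace, irf, FitConfig())
        scaled = fit_decay(GRID, 7.5 * trace, irf, FitConfig())
        assert scaled.lifetimes_ps == pytest.approx(base.lifetimes_ps, rel=1e-4)
        assert scaled.amplitudes == pytest.approx(
            tuple(7.5 * a for a in base.amplitudes), rel=1e-4
        )

    def test_mixture_recovery_both_lifetimes(self, irf, models):
        # mixtures of the two pigments with weight >= 0.2 each resolve both lifetimes
        eu, ph = models
        for w in (0.2, 0.5, 0.8):
            comps = (
                TAComponent(w * 1.0 + (1 - w) * 1.0, 0.15),  # shared fast ESA
                TAComponent(w * -0.35, 9.4),
            )
            trace = convolved_trace(PigmentModel("mix", comps), irf, GRID)
            fit = fit_decay(GRID, trace, irf, FitConfig())
            assert fit.lifetimes_ps[0] == pytest.approx(0.15, rel=0.05)
            assert fit.lifetimes_ps[1] == pytest.approx(9.4, rel=0.05)

    def test_deterministic_across_runs(self, irf, models):
        eu, _ = models
        rng = np.random.default_rng(0)
        trace = convolved_trace(eu, irf, GRID) + rng.normal(0, 0.01, GRID.shape)
        a = fit_decay(GRID, trace, irf, FitConfig())
        b = fit_decay(GRID, trace, irf, FitConfig())
        assert a == b


class TestNoiseFloor:
    def test_recovers_injected_noise_scale(self, irf):
        rng = np.random.default_rng(5)
        delays = np.concatenate([np.linspace(-3, -0.5, 200), GRID[GRID >= 0]])
        trace = rng.normal(0, 0.02, delays.shape)
        est = noise_floor(delays, trace, irf)
        assert est == pytest.approx(0.02, rel=0.2)

    def test_zero_without_baseline_frames(self, irf):
        assert noise_floor([0.0, 1.0], [1.0, 0.5], irf) == 0.0


class TestClassifyPigment:
    def _fit(self, amplitudes, lifetimes, converged=True):
        return TADecayFit(
            amplitudes=tuple(amplitudes),
            lifetimes_ps=tuple(lifetimes),
            t0_ps=0.0,
            irf_sigma_fs=81.6,
            residual_rms=0.0,
            reduced_chi_sq=0.0,
            converged=converged,
            n_points_used=13,
        )

    def test_eumelanin_from_slow_negative_component(self):
        call = classify_pigment(self._fit((1.0, -0.35), (0.15, 9.4)), 1.0, (0.05, 0.05))
        assert call.label == "eumelanin"
        assert call.slow_negative_fraction == pytest.approx(0.35 / 1.35)

    def test_pheomelanin_from_fast_positive_component(self):
        call = classify_pigment(self._fit((1.0,), (0.15,)), 1.0, (0.05, 0.05))
        assert call.label == "pheomelanin"
        assert call.slow_negative_fraction == 0.0

    def test_zero_peak_is_unpigmented(self):
        call = classify_pigment(self._fit((0.0,), (0.15,)), 0.0, (0.05, 0.05))
        assert call.label == "unpigmented"

    def test_nonconverged_fit_is_ambiguous(self):
        call = classify_pigment(self._fit((1.0,), (0.15,), converged=False), 1.0, (0.05, 0.05))
        assert call.label == "ambiguous"

    def test_slow_positive_component_is_not_eumelanin(self):
        call = classify_pigment(self._fit((0.2, 0.8), (0.15, 5.0)), 1.0, (0.05, 0.05))
        assert call.label != "eumelanin"


class TestFitImage:
    def test_uniform_pheomelanin_blocks_all_pheomelanin(self, irf):
        md = AcquisitionMetadata(width_px=32, height_px=32)
        spec = PhantomSpec(layout="uniform", uniform_label="paracancer", metadata=md)
        stack = render_stack(generate_phantom(spec), metadata=md)
        result = fit_image(stack, irf, FitConfig(n_components=1), binning=8)
        assert np.all(result.labels == "pheomelanin")

    def test_two_region_blocks_match_phantom_labels(self, irf):
        md = AcquisitionMetadata(width_px=32, height_px=32)
        phantom = generate_phantom(PhantomSpec(metadata=md, seed=1))
        stack = render_stack(phantom, metadata=md)
        result = fit_image(stack, irf, FitConfig(), binning=8)
        blocks = phantom.labels.reshape(4, 8, 4, 8)
        expected = {2: "eumelanin", 1: "pheomelanin"}
        for i in range(4):
            for j in range(4):
                block = blocks[i, :, j, :]
                first = block.flat[0]
                if np.all(block == first):  # only blocks fully inside a region
                    assert result.labels[i, j] == expected[first]

    def test_full_binning_reduces_to_mean_trace_fit(self, irf, two_region_stack):
        result = fit_image(two_region_stack, irf, FitConfig(), binning=64)
        assert result.labels.shape == (1, 1)
        mean_trace = two_region_stack.ac.mean(axis=(0, 1))
        direct = fit_decay(two_region_stack.delays_ps, mean_trace, irf, FitConfig())
        assert result.tau_slow_ps[0, 0] == pytest.approx(direct.lifetimes_ps[1], rel=1e-9)

    def test_zero_stack_is_unpigmented_everywhere(self, irf, small_metadata):
        spec = PhantomSpec(layout="uniform", uniform_label="background", metadata=small_metadata)
        stack = render_stack(generate_phantom(spec), metadata=small_metadata)
        result = fit_image(stack, irf, FitConfig(), binning=16)
        assert np.all(result.labels == "unpigmented")

    def test_dataframe_export_schema(self, irf, two_region_stack):
        result = fit_image(two_region_stack, irf, FitConfig(), binning=32)
        df = result.to_dataframe()
        assert list(df.columns) == [
            "row", "col", "label", "A_fast", "tau_fast_ps", "A_slow",
            "tau_slow_ps", "t0_ps", "residual_rms", "converged",
        ]
        assert len(df) == result.labels.size
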