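import dataclasses

import numpy as np
import pytest
from scipy.ndimage import binary_dilation, label

from pumpprobe.errors import ConfigurationError
from pumpprobe.synthetic import (
    LABEL_BACKGROUND,
    LABEL_MELANOMA,
    LABEL_PARACANCER,
    LAYOUTS,
    AcquisitionMetadata,
    NoiseSpec,
    PhantomSpec,
    generate_phantom,
    default_acquisition_metadata,
    render_stack,
)


class TestAcquisitionMetadata:
    def test_default_geometry(self):
        md = default_acquisition_metadata()
        assert md.width_px == 512
        assert md.height_px == 512
        assert md.fov_um == pytest.approx(212.0)

    def test_default_delays_cover_the_unmixing_frames(self):
        delays = default_acquisition_metadata().delays_ps
        assert 0.0 in delays and 0.5 in delays
        assert min(delays) < 0  # baseline frames before time zero

    def test_delays_must_increase(self):
        with pytest.raises(ValueError):
            AcquisitionMetadata(delays_ps=(0.0, 0.5, 0.2))

    def test_pixel_size(self):
        assert default_acquisition_metadata().pixel_size_um == pytest.approx(212.0 / 512.0)


class TestGeneratePhantom:
    def test_unknown_layout_rejected(self, small_metadata):
        with pytest.raises(ConfigurationError):
            PhantomSpec(layout="spiral", metadata=small_metadata)

    def test_uniform_paracancer_has_only_pheomelanin(self, small_metadata):
        spec = PhantomSpec(layout="uniform", uniform_label="paracancer", metadata=small_metadata)
        ph = generate_phantom(spec)
        assert np.all(ph.conc_eu == 0.0)
        assert np.all(ph.conc_ph > 0.0)
        assert not ph.truth_tumor_mask.any()

    def test_choroid_belt_cores_are_melanin_free_and_ringed(self):
        md = AcquisitionMetadata(width_px=128, height_px=128)
        ph = generate_phantom(PhantomSpec(layout="choroid_belt", metadata=md, seed=2))
        cores = ph.labels == LABEL_BACKGROUND
        assert cores.any()
        assert np.all(ph.conc_eu[cores] == 0.0)
        assert np.all(ph.conc_ph[cores] == 0.0)
        # the pixels immediately surrounding the cores form a pheomelanin ring
        ring = binary_dilation(cores, np.ones((3, 3), bool)) & ~cores
        assert np.all(ph.conc_ph[ring] > 0.0)

    def test_scattered_cells_are_eumelanin_rich_disks(self):
        md = AcquisitionMetadata(width_px=128, height_px=128)
        ph = generate_phantom(PhantomSpec(layout="scattered_cells", metadata=md, seed=4))
        cells = ph.labels == LABEL_MELANOMA
        assert cells.any()
        assert np.all(ph.conc_eu[cells] > ph.conc_ph[cells])
        assert np.all(ph.conc_eu[~cells] == 0.0)

    def test_seed_changes_texture_not_two_region_topology(self, small_metadata):
        a = generate_phantom(PhantomSpec(metadata=small_metadata, seed=10))
        b = generate_phantom(PhantomSpec(metadata=small_metadata, seed=11))
        assert np.array_equal(a.labels, b.labels)  # boundary geometry is seed-free
        assert not np.array_equal(a.conc_eu, b.conc_eu)

    @pytest.mark.parametrize("layout", LAYOUTS)
    def test_truth_mask_is_eumelanin_dominance(self, layout, small_metadata):
        ph = generate_phantom(PhantomSpec(layout=layout, metadata=small_metadata, seed=3))
        assert np.array_equal(ph.truth_tumor_mask, ph.conc_eu > ph.conc_ph)
        assert np.all(ph.conc_eu >= 0) and np.all(ph.conc_ph >= 0)

    def test_region_mean_dominance(self, two_region_phantom):
        ph = two_region_phantom
        melanoma = ph.labels == LABEL_MELANOMA
        paracancer = ph.labels == LABEL_PARACANCER
        assert ph.conc_eu[melanoma].mean() > ph.conc_ph[melanoma].mean()
        assert ph.conc_ph[paracancer].mean() > ph.conc_eu[paracancer].mean()


class TestRenderStack:
    def test_pigment_free_phantom_renders_dark(self, small_metadata):
        spec = PhantomSpec(layout="uniform", uniform_label="background", metadata=small_metadata)
        stack = render_stack(generate_phantom(spec), metadata=small_metadata)
        assert np.all(stack.ac == 0.0)
        assert np.all(stack.dc == 1.0)

    def test_melanoma_pixel_sign_flip(self, two_region_phantom, two_region_stack):
        delays = two_region_stack.delays_ps
        i0 = int(np.argmin(np.abs(delays)))
        i500 = int(np.argmin(np.abs(delays - 0.5)))
        melanoma = two_region_phantom.labels == LABEL_MELANOMA
        assert np.all(two_region_stack.ac[:, :, i0][melanoma] > 0)
        assert np.all(two_region_stack.ac[:, :, i500][melanoma] < 0)

    def test_linearity_in_concentration_without_absorption(self, two_region_phantom, small_metadata):
        ph = two_region_phantom
        doubled = dataclasses.replace(ph, conc_eu=2 * ph.conc_eu, conc_ph=2 * ph.conc_ph)
        a = render_stack(ph, metadata=small_metadata, k_abs=0.0)
        b = render_stack(doubled, metadata=small_metadata, k_abs=0.0)
        assert b.ac == pytest.approx(2 * a.ac, rel=1e-12)

    def test_dc_in_unit_interval_and_decreasing_in_concentration(self, two_region_phantom, small_metadata):
        stack = render_stack(two_region_phantom, metadata=small_metadata)
        assert np.all(stack.dc > 0) and np.all(stack.dc <= 1)
        total = two_region_phantom.conc_eu + two_region_phantom.conc_ph
        order = np.argsort(total.ravel())
        dc_sorted = stack.dc.ravel()[order]
        assert np.all(np.diff(dc_sorted) <= 1e-12)

    def test_noise_seed_changes_noise_only(self, two_region_phantom, small_metadata):
        noiseless = render_stack(two_region_phantom, metadata=small_metadata)
        n1 = render_stack(
            two_region_phantom, metadata=small_metadata, noise=NoiseSpec(0.05, 0.01, seed=1)
        )
        n2 = render_stack(
            two_region_phantom, metadata=small_metadata, noise=NoiseSpec(0.05, 0.01, seed=2)
        )
        assert not np.array_equal(n1.ac, n2.ac)
        # both share the same noiseless component
        r1 = n1.ac - noiseless.ac
        r2 = n2.ac - noiseless.ac
        sigma = 0.05 * np.max(np.abs(noiseless.ac))
        for r in (r1, r2):
            assert abs(r.mean()) < 0.05 * sigma
            assert r.std() == pytest.approx(sigma, rel=0.05)

    def test_render_is_deterministic(self, two_region_phantom, small_metadata):
        noise = NoiseSpec(0.05, 0.01, seed=7)
        a = render_stack(two_region_phantom, metadata=small_metadata, noise=noise)
        b = render_stack(two_region_phantom, metadata=small_metadata, noise=noise)
        assert np.array_equal(a.ac, b.ac) and np.array_equal(a.dc, b.dc)

    def test_grid_mismatch_rejected(self, two_region_phantom):
        other = AcquisitionMetadata(width_px=32, height_px=32)
        with pytest.raises(ValueError):
            render_stack(two_region_phantom, metadata=other)
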