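"""Ground-truthed tissue phantoms and synthetic pump-probe delay stacks.

The generator emulates the statistical structure of choroidal melanoma
imagery: a eumelanin-dominated tumor region abutting a pheomelanin-dominated
paracancerous region, choroid vessels appearing as melanin-free cores ringed
by a pheomelanin belt, and sparse eumelanin-rich single cells on a
pheomelanin background.  Each phantom carries per-pixel ground truth (label
map and pigment concentration maps) so downstream unmixing and delineation
can be scored exactly.

Rendering composes the pigment transient models into a delay stack
S(x, y, τ): the AC channel is the concentration-weighted sum of the
IRF-convolved pigment responses, attenuated by a Beer-Lambert DC
transmission map that mimics heterogeneous melanin absorption; acquisition
noise is additive Gaussian on AC and multiplicative Gaussian on DC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .ta_model import InstrumentResponse, PigmentModel, default_irf, default_models

__all__ = [
    "AcquisitionMetadata",
    "PhantomSpec",
    "TissuePhantom",
    "NoiseSpec",
    "DelayStack",
    "default_acquisition_metadata",
    "generate_phantom",
    "render_stack",
    "LAYOUTS",
]

#: Default delay grid in ps: dense around time zero (where the fast ESA
#: component lives), sparse at long delays; includes the 0 and 0.5 ps frames
#: required by two-delay unmixing and two pre-time-zero baseline frames.
DEFAULT_DELAYS_PS = (-0.5, -0.25, 0.0, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)

LAYOUTS = ("two_region_interface", "choroid_belt", "scattered_cells", "uniform")

LABEL_BACKGROUND = 0
LABEL_PARACANCER = 1
LABEL_MELANOMA = 2
LABEL_NAMES = {LABEL_BACKGROUND: "background", LABEL_PARACANCER: "paracancer", LABEL_MELANOMA: "melanoma"}


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition geometry and (informational) instrument settings."""

    width_px: int = 512
    height_px: int = 512
    fov_um: float = 212.0
    delays_ps: tuple[float, ...] = DEFAULT_DELAYS_PS
    pump_wavelength_nm: float = 1040.0
    probe_wavelength_nm: float = 860.0
    pump_power_mw: float = 10.0
    probe_power_mw: float = 5.0
    pixel_dwell_us: float = 2.0
    modulation_frequency_mhz: float = 20.0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be >= 1 px")
        if not self.fov_um > 0:
            raise ValueError("fov_um must be positive")
        delays = tuple(float(d) for d in self.delays_ps)
        if len(delays) == 0 or np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be a non-empty strictly increasing sequence")
        object.__setattr__(self, "delays_ps", delays)

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.width_px


def default_acquisition_metadata() -> AcquisitionMetadata:
    """512×512 px over a 212 µm field with the default delay grid."""
    return AcquisitionMetadata()


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and seed for one synthetic phantom."""

    layout: str = "two_region_interface"
    metadata: AcquisitionMetadata = field(default_factory=default_acquisition_metadata)
    boundary_waviness: float = 0.5
    cell_density: float = 3.0  # cells per 100×100 µm (scattered_cells)
    belt_width_um: float = 6.0  # choroid_belt ring width
    concentration_smoothness_um: float = 4.0
    uniform_label: str = "paracancer"
    melanoma_pheo_fraction: float = 0.3  # pheomelanin carried inside tumor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ConfigurationError(
                f"unknown layout {self.layout!r}; expected one of {LAYOUTS}"
            )
        for name in ("cell_density", "belt_width_um", "concentration_smoothness_um"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"PhantomSpec.{name} must be positive")
        if self.boundary_waviness < 0:
            raise ConfigurationError("boundary_waviness must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition-noise model.

    ``additive_sigma`` is the Gaussian noise standard deviation on the AC
    channel, as a fraction of the stack's peak |AC| signal;
    ``dc_relative_sigma`` is relative multiplicative noise on DC.
    """

    additive_sigma: float = 0.05
    dc_relative_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0 or self.dc_relative_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class TissuePhantom:
    """Ground truth: label map and per-pigment concentration maps."""

    labels: np.ndarray  # int map, values in LABEL_NAMES
    conc_eu: np.ndarray
    conc_ph: np.ndarray

    @property
    def truth_tumor_mask(self) -> np.ndarray:
        return self.labels == LABEL_MELANOMA


@dataclass(frozen=True)
class DelayStack:
    """S(x, y, τ): AC signal cube plus DC transmission image plus metadata."""

    ac: np.ndarray  # (rows, cols, n_delays), differential-absorption units
    dc: np.ndarray  # (rows, cols), transmission in (0, 1]
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        if self.ac.shape[-1] != len(self.metadata.delays_ps):
            raise ValueError("AC delay axis length does not match metadata delays")
        if self.ac.shape[:2] != self.dc.shape:
            raise ValueError("AC and DC pixel grids differ")
        if not np.all(self.dc > 0):
            raise ValueError("DC transmission must be strictly positive")

    @property
    def delays_ps(self) -> np.ndarray:
        return np.asarray(self.metadata.delays_ps)


def _texture(shape: tuple[int, int], smoothness_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean positive log-normal texture with the given correlation length."""
    g = gaussian_filter(rng.standard_normal(shape), smoothness_px, mode="reflect")
    std = g.std()
    if std > 0:
        g = g / std
    log_sigma = 0.4
    return np.exp(log_sigma * g - 0.5 * log_sigma**2)


def _pixel_centers_um(n: int, pixel_size: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pixel_size


def generate_phantom(spec: PhantomSpec) -> TissuePhantom:
    """Build the ground-truth label and concentration maps for one layout.

    Concentrations are the product of the label indicator with a positive
    log-normal texture.  Tumor pixels additionally carry pheomelanin at
    ``melanoma_pheo_fraction`` of their local eumelanin concentration, so
    eumelanin strictly dominates inside the tumor; paracancer pixels carry
    pheomelanin only.  Consequently ``truth_tumor_mask`` coincides with the
    set of pixels where conc_eu exceeds conc_ph.
    """
    md = spec.metadata
    h, w = md.height_px, md.width_px
    px = md.pixel_size_um
    rng = np.random.default_rng(spec.seed)
    smooth_px = max(spec.concentration_smoothness_um / px, 0.5)

    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    conc_eu = np.zeros((h, w))
    conc_ph = np.zeros((h, w))

    ys = _pixel_centers_um(h, px)[:, None]
    xs = _pixel_centers_um(w, px)[None, :]

    tex_eu = _texture((h, w), smooth_px, rng)
    tex_ph = _texture((h, w), smooth_px, rng)

    if spec.layout == "two_region_interface":
        amp = 0.1 * spec.boundary_waviness * md.fov_um
        wavelength = md.fov_um / 2.0
        boundary_x = md.fov_um / 2.0 + amp * np.sin(2.0 * np.pi * ys / wavelength)
        melanoma = xs < boundary_x  # broadcast to (h, w)
        melanoma = np.broadcast_to(melanoma, (h, w))
        labels[melanoma] = LABEL_MELANOMA
        labels[~melanoma] = LABEL_PARACANCER
        conc_eu = np.where(melanoma, tex_eu, 0.0)
        conc_ph = np.where(melanoma, spec.melanoma_pheo_fraction * conc_eu, tex_ph)
    elif spec.layout == "choroid_belt":
        labels[:] = LABEL_PARACANCER
        conc_ph = tex_ph.copy()
        n_cores = max(1, int(round((md.fov_um / 100.0) ** 2 * 2)))
        for _ in range(n_cores):
            cy = rng.uniform(0.2, 0.8) * md.fov_um
            cx = rng.uniform(0.2, 0.8) * md.fov_um
            a = rng.uniform(10.0, 20.0)  # core semi-axes in µm
            b = rng.uniform(10.0, 20.0)
            r = np.sqrt(((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2)
            core = r <= 1.0
            ring = (r > 1.0) & (r <= 1.0 + spec.belt_width_um / min(a, b))
            labels[core] = LABEL_BACKGROUND
            conc_ph[core] = 0.0
            conc_ph[ring] *= 2.0  # pheomelanin-rich belt
        conc_eu[:] = 0.0
    elif spec.layout == "scattered_cells":
        labels[:] = LABEL_PARACANCER
        conc_ph = tex_ph.copy()
        area_factor = (md.fov_um / 100.0) ** 2
        n_cells = rng.poisson(spec.cell_density * area_factor)
        n_cells = max(int(n_cells), 1)
        cell_radius_um = 5.0  # ~10 µm diameter melanocyte
        profile = np.zeros((h, w))
        cell_mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_cells):
            cy = rng.uniform(0.05, 0.95) * md.fov_um
            cx = rng.uniform(0.05, 0.95) * md.fov_um
            r = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
            disk = r <= cell_radius_um
            cell_mask |= disk
            profile = np.maximum(profile, np.where(disk, 1.0, 0.0))
        # 1 px Gaussian feather on the intensity profile only; labels stay hard
        profile = gaussian_filter(profile, 1.0, mode="reflect")
        labels[cell_mask] = LABEL_MELANOMA
        conc_eu = np.where(cell_mask, 2.0 * np.maximum(profile, 1e-3) * tex_eu, 0.0)
        conc_ph = np.where(cell_mask, spec.melanoma_pheo_fraction * conc_eu, conc_ph)
    elif spec.layout == "uniform":
        name_to_label = {v: k for k, v in LABEL_NAMES.items()}
        try:
            lab = name_to_label[spec.uniform_label]
        except KeyError:
            raise ConfigurationError(f"unknown uniform_label {spec.uniform_label!r}")
        labels[:] = lab
        if lab == LABEL_MELANOMA:
            conc_eu = tex_eu
            conc_ph = spec.melanoma_pheo_fraction * conc_eu
        elif lab == LABEL_PARACANCER:
            conc_ph = tex_ph
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise ConfigurationError(f"unknown layout {spec.layout!r}")

    return TissuePhantom(labels=labels, conc_eu=conc_eu, conc_ph=conc_ph)


def render_stack(
    phantom: TissuePhantom,
    models: tuple[PigmentModel, PigmentModel] | None = None,
    irf: InstrumentResponse | None = None,
    noise: NoiseSpec | None = None,
    metadata: AcquisitionMetadata | None = None,
    k_abs: float = 0.5,
    t0_ps: float = 0.0,
) -> DelayStack:
    """Render a phantom into a noisy delay stack.

    Noiseless model: AC(x,y,τ) = dc(x,y)·[c_eu·M_eu(τ) + c_ph·M_ph(τ)] with
    M_p the IRF-convolved pigment response, and
    dc(x,y) = exp(−k_abs·(c_eu+c_ph)) (Beer-Lambert with a lumped extinction
    coefficient), so pigmented regions transmit less light.  Additive
    Gaussian noise (scaled to the peak |AC|) is then added to AC and
    multiplicative Gaussian noise to DC; everything is deterministic given
    the seeds.
    """
    metadata = metadata if metadata is not None else default_acquisition_metadata()
    if phantom.labels.shape != (metadata.height_px, metadata.width_px):
        raise ValueError(
            f"phantom grid {phantom.labels.shape} does not match metadata "
            f"({metadata.height_px}, {metadata.width_px})"
        )
    if models is None:
        models = default_models()
    if irf is None:
        irf = default_irf()
    noise = noise if noise is not None else NoiseSpec(additive_sigma=0.0, dc_relative_sigma=0.0)

    delays = np.asarray(metadata.delays_ps)
    m_eu = models[0].convolved(irf, delays, t0_ps)
    m_ph = models[1].convolved(irf, delays, t0_ps)

    dc = np.exp(-k_abs * (phantom.conc_eu + phantom.conc_ph))
    ac = dc[:, :, None] * (
        phantom.conc_eu[:, :, None] * m_eu[None, None, :]
        + phantom.conc_ph[:, :, None] * m_ph[None, None, :]
    )

    rng = np.random.default_rng(noise.seed)
    if noise.additive_sigma > 0:
        peak = float(np.max(np.abs(ac)))
        ac = ac + rng.normal(0.0, noise.additive_sigma * peak, ac.shape)
    if noise.dc_relative_sigma > 0:
        dc = dc * (1.0 + rng.normal(0.0, noise.dc_relative_sigma, dc.shape))
    dc = np.clip(dc, 1e-6, 1.0)

    return DelayStack(ac=ac.astype(np.float64), dc=dc.astype(np.float64), metadata=metadata)
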