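"""Transient-absorption (TA) signal models for melanin pump-probe microscopy.

A femtosecond pump pulse promotes melanin to an electronic excited state; a
delayed probe pulse then experiences either increased absorption
(excited-state absorption, ESA) or decreased absorption (ground-state
bleaching, GSB).  The measured differential absorption Δα = −ΔT/T is
therefore signed: positive for ESA, negative for GSB and stimulated emission
(SE).  SE is absent whenever the probe photon carries more energy than the
pump photon, which is the case for the near-infrared pump/probe pair used
here (1040 nm pump, 860 nm probe).

Relaxation is modelled as a sum of signed exponential decays.  Pheomelanin
shows a single short-lived ESA component (lifetime well under 200 fs);
eumelanin additionally shows a long-lived negative GSB component with a
lifetime of roughly 9.4 ps — this extra component is the contrast mechanism
that separates the two pigments.

The finite pump-probe cross-correlation (the instrument response function,
IRF) smears the ideal decay.  For a Gaussian IRF the convolution of each
exponential component has the closed exponentially-modified-Gaussian form
implemented in :func:`convolved_trace`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "HC_EV_NM",
    "PulsePair",
    "TAComponent",
    "InstrumentResponse",
    "PigmentModel",
    "photon_energy",
    "stimulated_emission_absent",
    "decay_trace",
    "convolved_trace",
    "default_irf",
    "default_models",
]

#: CODATA value of h*c in eV·nm.
HC_EV_NM = 1239.841984

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548


@dataclass(frozen=True)
class PulsePair:
    """Pump/probe wavelengths (nm) and pulse duration FWHMs (fs)."""

    pump_wavelength: float = 1040.0
    probe_wavelength: float = 860.0
    pump_duration: float = 150.0
    probe_duration: float = 120.0

    def __post_init__(self) -> None:
        for name in ("pump_wavelength", "probe_wavelength", "pump_duration", "probe_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PulsePair.{name} must be strictly positive")

    def cross_correlation_fwhm_fs(self) -> float:
        """FWHM of the Gaussian pump-probe cross-correlation, in fs."""
        return math.hypot(self.pump_duration, self.probe_duration)


@dataclass(frozen=True)
class TAComponent:
    """One signed exponential component of a transient-absorption response.

    ``amplitude`` is in differential-absorption units: positive means ESA,
    negative means GSB.  The sign is physical and is never flipped
    internally.  ``lifetime_ps`` is the 1/e decay time in ps.
    """

    amplitude: float
    lifetime_ps: float

    def __post_init__(self) -> None:
        if not self.lifetime_ps > 0:
            raise ValueError("TAComponent.lifetime_ps must be strictly positive")


@dataclass(frozen=True)
class InstrumentResponse:
    """Gaussian IRF: standard deviation of the cross-correlation, in fs."""

    sigma_fs: float

    def __post_init__(self) -> None:
        if not self.sigma_fs > 0:
            raise ValueError("InstrumentResponse.sigma_fs must be strictly positive")

    @property
    def sigma_ps(self) -> float:
        return self.sigma_fs / 1000.0


@dataclass(frozen=True)
class PigmentModel:
    """A pigment's transient response as an ordered tuple of components.

    A model with zero components evaluates to zero everywhere (empty sum);
    the shipped defaults always carry at least one component.
    """

    name: str
    components: tuple[TAComponent, ...]

    def __init__(self, name: str, components: Sequence[TAComponent]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "components", tuple(components))

    def decay(self, delays_ps: Sequence[float]) -> np.ndarray:
        return decay_trace(self, delays_ps)

    def convolved(
        self, irf: InstrumentResponse, delays_ps: Sequence[float], t0_ps: float = 0.0
    ) -> np.ndarray:
        return convolved_trace(self, irf, delays_ps, t0_ps)

    # --- JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "components": [
                {"amplitude": c.amplitude, "lifetime_ps": c.lifetime_ps}
                for c in self.components
            ],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PigmentModel":
        doc = json.loads(text)
        comps = [TAComponent(c["amplitude"], c["lifetime_ps"]) for c in doc["components"]]
        return cls(doc["name"], comps)


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy hc/λ in eV for a wavelength in nm."""
    if not wavelength_nm > 0:
        raise ValueError("wavelength must be strictly positive")
    return HC_EV_NM / wavelength_nm


def stimulated_emission_absent(pulses: PulsePair) -> bool:
    """Whether SE cannot contribute: probe photon energy exceeds pump's."""
    return photon_energy(pulses.probe_wavelength) > photon_energy(pulses.pump_wavelength)


def _as_delay_array(delays_ps: Sequence[float]) -> np.ndarray:
    delays = np.asarray(delays_ps, dtype=float)
    if delays.size == 0:
        raise ValueError("delay sequence is empty")
    if not np.all(np.isfinite(delays)):
        raise ValueError("delays must be finite")
    return delays


def decay_trace(model: PigmentModel, delays_ps: Sequence[float]) -> np.ndarray:
    """Ideal (IRF-free) multiexponential trace: Σ A_i exp(−τ/λ_i), 0 for τ<0."""
    delays = _as_delay_array(delays_ps)
    out = np.zeros_like(delays)
    pos = delays >= 0
    for comp in model.components:
        out[pos] += comp.amplitude * np.exp(-delays[pos] / comp.lifetime_ps)
    return out


def _emg_component(amplitude: float, lifetime: float, sigma: float, d: np.ndarray) -> np.ndarray:
    # Exponentially-modified Gaussian, evaluated in a log-stabilised split:
    # erfc(x) = erfcx(x)·exp(−x²) collapses the exponent to −d²/2σ² for x ≥ 0,
    # while the direct form is already decaying (and erfc bounded by 2) for x < 0.
    x = (sigma / lifetime - d / sigma) / math.sqrt(2.0)
    out = np.empty_like(d)
    pos = x >= 0
    out[pos] = 0.5 * amplitude * erfcx(x[pos]) * np.exp(-(d[pos] ** 2) / (2.0 * sigma**2))
    out[~pos] = (
        0.5
        * amplitude
        * erfc(x[~pos])
        * np.exp(sigma**2 / (2.0 * lifetime**2) - d[~pos] / lifetime)
    )
    return out


def convolved_trace(
    model: PigmentModel,
    irf: InstrumentResponse,
    delays_ps: Sequence[float],
    t0_ps: float = 0.0,
) -> np.ndarray:
    """Analytic convolution of the decay with a unit-area Gaussian IRF.

    Each component contributes
    (A/2)·exp(σ²/2λ² − (τ−t0)/λ)·erfc((σ/λ − (τ−t0)/σ)/√2),
    which is continuous and finite for all delays.
    """
    delays = _as_delay_array(delays_ps)
    sigma = irf.sigma_ps
    d = delays - t0_ps
    out = np.zeros_like(delays)
    for comp in model.components:
        out += _emg_component(comp.amplitude, comp.lifetime_ps, sigma, d)
    return out


def default_irf(pulses: PulsePair | None = None) -> InstrumentResponse:
    """IRF derived from the pulse durations: FWHM = √(pump²+probe²), σ = FWHM/2.3548.

    For the default 150/120 fs pulses this gives FWHM ≈ 192 fs, σ ≈ 81.6 fs.
    """
    pulses = pulses if pulses is not None else PulsePair()
    return InstrumentResponse(pulses.cross_correlation_fwhm_fs() / _FWHM_PER_SIGMA)


#: Default eumelanin GSB lifetime in ps.
EUMELANIN_SLOW_LIFETIME_PS = 9.4
#: Default fast ESA lifetime in ps, shared by both pigments (below the 0.2 ps bound).
FAST_ESA_LIFETIME_PS = 0.15
#: Default GSB amplitude relative to the unit ESA amplitude.
EUMELANIN_GSB_AMPLITUDE = -0.35


def default_models() -> tuple[PigmentModel, PigmentModel]:
    """Default (eumelanin, pheomelanin) transient models.

    Pheomelanin: one ESA component, lifetime 0.15 ps, amplitude +1.
    Eumelanin: the same ESA component plus a GSB component (9.4 ps, −0.35),
    so the trace is positive at τ=0 and clearly negative by 0.5 ps.
    Amplitudes are package defaults, freely overridable.
    """
    eumelanin = PigmentModel(
        "eumelanin",
        (
            TAComponent(1.0, FAST_ESA_LIFETIME_PS),
            TAComponent(EUMELANIN_GSB_AMPLITUDE, EUMELANIN_SLOW_LIFETIME_PS),
        ),
    )
    pheomelanin = PigmentModel("pheomelanin", (TAComponent(1.0, FAST_ESA_LIFETIME_PS),))
    return eumelanin, pheomelanin
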