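"""Per-trace and per-pixel fitting of IRF-convolved multiexponential decays.

A measured transient-absorption trace is modelled as the sum of one or two
signed exponential components convolved with a Gaussian instrument response
(see :mod:`pumpprobe.ta_model`).  Fitting is bounded nonlinear least squares
(trust-region reflective via lmfit) restarted from a small grid of initial
lifetime guesses; the restart with the lowest residual RMS wins, ties going
to the first in grid order, so results are fully deterministic.

A fitted trace is then classified as eumelanin (a slow negative GSB
component is present), pheomelanin (a fast positive ESA component dominates),
unpigmented (no signal above the noise floor) or ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .synthetic import DelayStack
from .ta_model import InstrumentResponse, PigmentModel, TAComponent, convolved_trace

__all__ = [
    "FitConfig",
    "TADecayFit",
    "PigmentCall",
    "fit_decay",
    "classify_pigment",
    "fit_image",
    "FitImageResult",
    "noise_floor",
]

logger = logging.getLogger(__name__)

#: Multistart initial lifetime tuples (ps), per component count.
DEFAULT_MULTISTART = {
    1: ((0.1,), (0.2,)),
    2: ((0.1, 5.0), (0.2, 10.0), (0.15, 20.0)),
}

#: Lifetime below which a dominant positive component is called pheomelanin (ps).
FAST_LIFETIME_CUTOFF_PS = 0.5
#: Lifetime above which a negative component is called a eumelanin GSB (ps).
SLOW_LIFETIME_CUTOFF_PS = 1.0


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the multistart bounded least-squares fit."""

    n_components: int = 2
    lifetime_bounds: tuple[float, float] = (0.02, 100.0)
    amplitude_bounds: tuple[float, float] = (-np.inf, np.inf)
    fit_t0: bool = False
    fit_irf_sigma: bool = False
    multistart_grid: tuple[tuple[float, ...], ...] | None = None
    max_iterations: int = 2000
    convergence_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if not self.lifetime_bounds[0] < self.lifetime_bounds[1]:
            raise ValueError("lifetime_bounds must be a nonempty interval")
        if not self.amplitude_bounds[0] < self.amplitude_bounds[1]:
            raise ValueError("amplitude_bounds must be a nonempty interval")
        grid = self.multistart_grid
        if grid is None:
            grid = DEFAULT_MULTISTART[self.n_components]
        grid = tuple(tuple(float(v) for v in start) for start in grid)
        if len(grid) == 0 or any(len(s) != self.n_components for s in grid):
            raise ValueError("multistart grid must be nonempty, one lifetime per component")
        object.__setattr__(self, "multistart_grid", grid)

    @property
    def n_free_parameters(self) -> int:
        return 2 * self.n_components + int(self.fit_t0) + int(self.fit_irf_sigma)


@dataclass(frozen=True)
class TADecayFit:
    """Result of one trace fit; components sorted by ascending lifetime."""

    amplitudes: tuple[float, ...]
    lifetimes_ps: tuple[float, ...]
    t0_ps: float
    irf_sigma_fs: float
    residual_rms: float
    reduced_chi_sq: float
    converged: bool
    n_points_used: int

    def model(self) -> PigmentModel:
        comps = [TAComponent(a, t) for a, t in zip(self.amplitudes, self.lifetimes_ps)]
        return PigmentModel("fit", comps)


@dataclass(frozen=True)
class PigmentCall:
    """Pigment classification of one fitted trace."""

    label: str  # eumelanin | pheomelanin | unpigmented | ambiguous
    slow_negative_fraction: float
    peak_signal: float


def _model_trace(params: Parameters, delays: np.ndarray, n: int) -> np.ndarray:
    comps = [
        TAComponent(params[f"amp{i}"].value, params[f"tau{i}"].value) for i in range(n)
    ]
    irf = InstrumentResponse(params["irf_sigma_fs"].value)
    return convolved_trace(PigmentModel("fit", comps), irf, delays, params["t0_ps"].value)


def _residual(params: Parameters, delays: np.ndarray, trace: np.ndarray, n: int) -> np.ndarray:
    return _model_trace(params, delays, n) - trace


def _initial_amplitudes(
    delays: np.ndarray, trace: np.ndarray, n: int
) -> tuple[float, ...]:
    # Peak near τ=0 carries the fast ESA; the frame nearest 0.5 ps is
    # dominated by the slow component once the fast one has decayed.
    i0 = int(np.argmin(np.abs(delays)))
    s0 = float(trace[i0])
    if n == 1:
        return (2.0 * s0,)
    i500 = int(np.argmin(np.abs(delays - 0.5)))
    s500 = float(trace[i500])
    return (2.0 * s0 - s500, s500)


def fit_decay(
    delays_ps: Sequence[float],
    trace: Sequence[float],
    irf: InstrumentResponse,
    config: FitConfig | None = None,
) -> TADecayFit:
    """Fit an IRF-convolved multiexponential to one trace.

    Runs every multistart, keeps the restart with the smallest residual RMS
    (ties broken by grid order).  A fit where no restart converges is
    returned with ``converged=False`` rather than raising.
    """
    config = config if config is not None else FitConfig()
    delays = np.asarray(delays_ps, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if delays.shape != trace.shape or delays.ndim != 1:
        raise ValueError("delays and trace must be 1-D arrays of equal length")
    if delays.size < config.n_free_parameters + 2:
        raise ValueError(
            f"need at least {config.n_free_parameters + 2} points for "
            f"{config.n_free_parameters} free parameters"
        )

    n = config.n_components
    amp0 = _initial_amplitudes(delays, trace, n)
    lo_t, hi_t = config.lifetime_bounds
    lo_a, hi_a = config.amplitude_bounds

    best = None
    best_rms = np.inf
    for start in config.multistart_grid:
        params = Parameters()
        for i in range(n):
            tau0 = float(np.clip(start[i], lo_t, hi_t))
            a0 = float(np.clip(amp0[i], lo_a, hi_a))
            params.add(f"amp{i}", value=a0, min=lo_a, max=hi_a)
            params.add(f"tau{i}", value=tau0, min=lo_t, max=hi_t)
        params.add("t0_ps", value=0.0, vary=config.fit_t0, min=-1.0, max=1.0)
        params.add(
            "irf_sigma_fs",
            value=irf.sigma_fs,
            vary=config.fit_irf_sigma,
            min=1.0,
            max=10.0 * irf.sigma_fs,
        )
        try:
            # errstate: lmfit's correlation bookkeeping divides 0/0 on
            # perfect (zero-residual) fits; the correlations are unused here
            with np.errstate(invalid="ignore", divide="ignore"):
                result = minimize(
                    _residual,
                    params,
                    args=(delays, trace, n),
                    method="least_squares",
                    calc_covar=False,
                    max_nfev=config.max_iterations,
                    ftol=config.convergence_tolerance,
                    xtol=config.convergence_tolerance,
                    gtol=config.convergence_tolerance,
                )
        except Exception:  # a diverged restart is not fatal
            logger.debug("multistart %s failed", start, exc_info=True)
            continue
        rms = float(np.sqrt(np.mean(result.residual**2)))
        if result.success and rms < best_rms:
            best, best_rms = result, rms

    if best is None:
        return TADecayFit(
            amplitudes=(0.0,) * n,
            lifetimes_ps=tuple(config.multistart_grid[0]),
            t0_ps=0.0,
            irf_sigma_fs=irf.sigma_fs,
            residual_rms=float(np.sqrt(np.mean(trace**2))),
            reduced_chi_sq=np.nan,
            converged=False,
            n_points_used=delays.size,
        )

    amps = [best.params[f"amp{i}"].value for i in range(n)]
    taus = [best.params[f"tau{i}"].value for i in range(n)]
    order = np.argsort(taus)
    dof = max(delays.size - best.nvarys, 1)
    return TADecayFit(
        amplitudes=tuple(float(amps[i]) for i in order),
        lifetimes_ps=tuple(float(taus[i]) for i in order),
        t0_ps=float(best.params["t0_ps"].value),
        irf_sigma_fs=float(best.params["irf_sigma_fs"].value),
        residual_rms=best_rms,
        reduced_chi_sq=float(np.sum(best.residual**2) / dof),
        converged=True,
        n_points_used=delays.size,
    )


def noise_floor(delays_ps: Sequence[float], trace: Sequence[float], irf: InstrumentResponse) -> float:
    """Robust noise estimate: 1.4826 × MAD of pre-time-zero trace values.

    Uses frames earlier than −3σ of the IRF, where the convolved signal is
    negligible; returns 0 when no such baseline frames exist.
    """
    delays = np.asarray(delays_ps, dtype=float)
    trace = np.asarray(trace, dtype=float)
    baseline = trace[delays < -3.0 * irf.sigma_ps]
    if baseline.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(baseline - np.median(baseline))))


def classify_pigment(
    fit: TADecayFit,
    trace_peak: float,
    floors: tuple[float, float] = (0.0, 0.0),
) -> PigmentCall:
    """Label a fitted trace as eumelanin / pheomelanin / unpigmented / ambiguous.

    ``floors`` is ``(amp_floor, peak_floor)``: amplitudes below ``amp_floor``
    in magnitude are treated as noise, and a trace whose peak is below
    ``peak_floor`` is unpigmented.  The rule, in priority order: unpigmented
    if peak < peak_floor; eumelanin if any component slower than 1 ps has
    amplitude < −amp_floor; pheomelanin if the dominant component is positive
    above amp_floor with lifetime < 0.5 ps; otherwise ambiguous.
    """
    amp_floor, peak_floor = floors
    slow_neg = 0.0
    total = sum(abs(a) for a in fit.amplitudes)
    for a, t in zip(fit.amplitudes, fit.lifetimes_ps):
        if t > SLOW_LIFETIME_CUTOFF_PS and a < 0 and total > 0:
            slow_neg = abs(a) / total
            break
    if trace_peak < peak_floor:
        return PigmentCall("unpigmented", slow_neg, trace_peak)
    if not fit.converged:
        return PigmentCall("ambiguous", slow_neg, trace_peak)
    for a, t in zip(fit.amplitudes, fit.lifetimes_ps):
        if t > SLOW_LIFETIME_CUTOFF_PS and a < -amp_floor:
            return PigmentCall("eumelanin", slow_neg, trace_peak)
    i_dom = int(np.argmax(np.abs(fit.amplitudes)))
    if (
        fit.amplitudes[i_dom] > amp_floor
        and fit.lifetimes_ps[i_dom] < FAST_LIFETIME_CUTOFF_PS
    ):
        return PigmentCall("pheomelanin", slow_neg, trace_peak)
    return PigmentCall("ambiguous", slow_neg, trace_peak)


@dataclass(frozen=True)
class FitImageResult:
    """Binned per-pixel fit summaries and pigment labels."""

    labels: np.ndarray  # str map at binned resolution
    amp_fast: np.ndarray
    tau_fast_ps: np.ndarray
    amp_slow: np.ndarray
    tau_slow_ps: np.ndarray
    t0_ps: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    binning: int

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.indices(self.labels.shape)
        return pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "label": self.labels.ravel(),
                "A_fast": self.amp_fast.ravel(),
                "tau_fast_ps": self.tau_fast_ps.ravel(),
                "A_slow": self.amp_slow.ravel(),
                "tau_slow_ps": self.tau_slow_ps.ravel(),
                "t0_ps": self.t0_ps.ravel(),
                "residual_rms": self.residual_rms.ravel(),
                "converged": self.converged.ravel(),
            }
        )


def _block_mean(ac: np.ndarray, binning: int) -> np.ndarray:
    h, w, nd = ac.shape
    hb, wb = h // binning, w // binning
    if h % binning or w % binning:
        logger.warning(
            "image %dx%d not divisible by binning %d; truncating edges", h, w, binning
        )
        ac = ac[: hb * binning, : wb * binning]
    return ac.reshape(hb, binning, wb, binning, nd).mean(axis=(1, 3))


def fit_image(
    stack: DelayStack,
    irf: InstrumentResponse,
    config: FitConfig | None = None,
    binning: int = 1,
    floors: tuple[float, float] | None = None,
) -> FitImageResult:
    """Fit every binning×binning block of a delay stack and classify it.

    Traces are block-averaged before fitting (noise averages down, and the
    pixel count drops by binning²).  Blocks whose peak |signal| falls below
    the peak floor are labelled unpigmented without fitting.  When ``floors``
    is not given, the amplitude floor is 3× and the peak floor 5× the robust
    pre-time-zero noise estimate of each block trace (with a tiny absolute
    floor so an identically-zero stack is unpigmented everywhere).
    """
    config = config if config is not None else FitConfig()
    if binning < 1:
        raise ValueError("binning must be >= 1")
    delays = stack.delays_ps
    binned = _block_mean(stack.ac, binning)
    hb, wb = binned.shape[:2]
    global_peak = float(np.max(np.abs(binned))) if binned.size else 0.0
    tiny = 1e-12 * max(global_peak, 1.0)

    labels = np.full((hb, wb), "unpigmented", dtype="<U11")
    nanmap = np.full((hb, wb), np.nan)
    out = {
        "amp_fast": nanmap.copy(),
        "tau_fast_ps": nanmap.copy(),
        "amp_slow": nanmap.copy(),
        "tau_slow_ps": nanmap.copy(),
        "t0_ps": nanmap.copy(),
        "residual_rms": nanmap.copy(),
    }
    converged = np.zeros((hb, wb), dtype=bool)

    for i in range(hb):
        for j in range(wb):
            trace = binned[i, j]
            peak = float(np.max(np.abs(trace)))
            if floors is None:
                est = noise_floor(delays, trace, irf)
                blk_floors = (3.0 * est, max(5.0 * est, tiny))
            else:
                blk_floors = floors
            if peak < blk_floors[1]:
                continue  # labelled unpigmented, no fit
            fit = fit_decay(delays, trace, irf, config)
            call = classify_pigment(fit, peak, blk_floors)
            labels[i, j] = call.label
            converged[i, j] = fit.converged
            out["amp_fast"][i, j] = fit.amplitudes[0]
            out["tau_fast_ps"][i, j] = fit.lifetimes_ps[0]
            if config.n_components == 2:
                out["amp_slow"][i, j] = fit.amplitudes[1]
                out["tau_slow_ps"][i, j] = fit.lifetimes_ps[1]
            out["t0_ps"][i, j] = fit.t0_ps
            out["residual_rms"][i, j] = fit.residual_rms

    return FitImageResult(
        labels=labels,
        amp_fast=out["amp_fast"],
        tau_fast_ps=out["tau_fast_ps"],
        amp_slow=out["amp_slow"],
        tau_slow_ps=out["tau_slow_ps"],
        t0_ps=out["t0_ps"],
        residual_rms=out["residual_rms"],
        converged=converged,
        binning=binning,
    )
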