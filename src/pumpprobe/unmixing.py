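"""Two-delay eumelanin/pheomelanin unmixing and DC normalization.

The separation exploits the sign structure of the two melanin transients at
two delays: at τ = 0 both pigments show positive ESA, while at τ = 500 fs
the pheomelanin signal has decayed to (near) zero and the eumelanin signal
has turned negative (GSB).  The eumelanin map is therefore the 500 fs frame
with a sign reversal, S_eu = −S(500 fs), and the pheomelanin map is the
residual S_ph = S(0) + S(500 fs); negative values in either map are clamped
to zero.  Frames are first normalized by the DC transmission image to
correct for heterogeneous light absorption by melanin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingFrameError
from .synthetic import DelayStack

__all__ = [
    "PigmentMaps",
    "select_delay_frames",
    "unmix_two_delay",
    "dc_normalize",
    "unmix_stack",
    "DEFAULT_DELAY_TOLERANCE_PS",
]

DEFAULT_DELAY_TOLERANCE_PS = 0.05
DEFAULT_DC_FLOOR = 0.01


@dataclass(frozen=True)
class PigmentMaps:
    """Nonnegative per-pixel eumelanin and pheomelanin signal maps."""

    eumelanin: np.ndarray
    pheomelanin: np.ndarray
    source_delays_ps: tuple[float, float]
    dc_normalized: bool

    def __post_init__(self) -> None:
        if self.eumelanin.shape != self.pheomelanin.shape:
            raise ValueError("pigment maps must share dimensions")


def select_delay_frames(
    stack: DelayStack,
    targets_ps: tuple[float, float] = (0.0, 0.5),
    tolerance_ps: float = DEFAULT_DELAY_TOLERANCE_PS,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Pick the frames nearest each target delay, within tolerance.

    Returns (S0 image, S500 image, actual delays used).  The nominal 0 and
    500 fs positions are stage settings; a small tolerance absorbs grid
    jitter.  A target with no frame inside the tolerance raises
    :class:`MissingFrameError` naming the target.
    """
    delays = stack.delays_ps
    frames = []
    actual = []
    for target in targets_ps:
        idx = int(np.argmin(np.abs(delays - target)))
        if abs(delays[idx] - target) > tolerance_ps:
            raise MissingFrameError(
                f"no delay frame within {tolerance_ps} ps of target {target} ps "
                f"(available delays: {np.round(delays, 4).tolist()})"
            )
        frames.append(stack.ac[:, :, idx])
        actual.append(float(delays[idx]))
    return frames[0], frames[1], (actual[0], actual[1])


def unmix_two_delay(s0: np.ndarray, s500: np.ndarray) -> PigmentMaps:
    """Apply the two-delay separation: eu = max(−S500, 0), ph = max(S0+S500, 0)."""
    s0 = np.asarray(s0, dtype=float)
    s500 = np.asarray(s500, dtype=float)
    if s0.shape != s500.shape:
        raise ValueError(f"frame shapes differ: {s0.shape} vs {s500.shape}")
    eumelanin = np.maximum(-s500, 0.0)
    pheomelanin = np.maximum(s0 + s500, 0.0)
    return PigmentMaps(eumelanin, pheomelanin, (0.0, 0.5), dc_normalized=False)


def dc_normalize(
    ac_image: np.ndarray,
    dc_image: np.ndarray,
    dc_floor: float = DEFAULT_DC_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide an AC frame by the DC transmission image, with a floor.

    Returns ``(normalized, valid_mask)``; pixels where dc < dc_floor are
    computed with the floor and flagged invalid in the mask.
    """
    if ac_image.shape != dc_image.shape:
        raise ValueError("AC and DC image dimensions differ")
    if not dc_floor > 0:
        raise ValueError("dc_floor must be positive")
    valid = dc_image >= dc_floor
    return ac_image / np.maximum(dc_image, dc_floor), valid


def unmix_stack(
    stack: DelayStack,
    normalize: bool = True,
    tolerance_ps: float = DEFAULT_DELAY_TOLERANCE_PS,
    dc_floor: float = DEFAULT_DC_FLOOR,
) -> PigmentMaps:
    """Full unmixing chain: select frames → (DC-normalize) → two-delay unmix."""
    s0, s500, actual = select_delay_frames(stack, (0.0, 0.5), tolerance_ps)
    if normalize:
        s0, valid0 = dc_normalize(s0, stack.dc, dc_floor)
        s500, valid500 = dc_normalize(s500, stack.dc, dc_floor)
        n_invalid = int(np.count_nonzero(~(valid0 & valid500)))
        if n_invalid:
            import logging

            logging.getLogger(__name__).info(
                "%d pixels below dc_floor=%g flagged invalid", n_invalid, dc_floor
            )
    maps = unmix_two_delay(s0, s500)
    return PigmentMaps(
        maps.eumelanin, maps.pheomelanin, actual, dc_normalized=normalize
    )
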