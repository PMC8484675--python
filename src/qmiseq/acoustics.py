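"""Echo-sounder backscatter processing.

A calibrated echo sounder records volume backscattering strength S_V on a
ping (time) × depth grid in dB re 1 m⁻¹.  Before backscatter can be compared
with eDNA concentrations the grid needs: (i) exclusion of the acoustic dead
zone within 1 m of the sea bottom and of instrument/bubble artefacts, (ii) a
−70 dB noise threshold below which a cell is treated as containing no fish
(linear S_V = 0, not "missing"), and (iii) averaging of the *linear* S_V over
the ten minutes following each water sampling.  Averaging must happen in the
linear domain: dB values are log-transformed powers and their arithmetic
mean underestimates the mean backscatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_DB = -70.0
DEFAULT_WINDOW_S = 600.0  # ten minutes
DEAD_ZONE_M = 1.0


@dataclass(frozen=True)
class Echogram:
    """Time × depth grid of S_V (dB) with a validity mask.

    ``times`` are seconds (float, any epoch) with one entry per ping;
    ``depths`` are metres, increasing downward; ``sv_db`` has shape
    (n_pings, n_depths); −inf encodes linear zero.  Masked cells stay in the
    grid but are flagged invalid.  ``bottom_depth`` is per-ping seabed depth.
    """

    times: np.ndarray
    depths: np.ndarray
    sv_db: np.ndarray
    valid: np.ndarray
    bottom_depth: np.ndarray | None = None
    station_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_db.shape != (len(self.times), len(self.depths)):
            raise ValueError("sv_db shape must be (n_times, n_depths)")
        if self.valid.shape != self.sv_db.shape:
            raise ValueError("valid mask shape must match sv_db")
        if self.bottom_depth is not None and len(self.bottom_depth) != len(self.times):
            raise ValueError("bottom_depth must have one entry per ping")


@dataclass(frozen=True)
class EchoSummary:
    station_id: str
    window_start: float
    window_end: float
    mean_sv_linear: float  # dimensionless volume backscattering coefficient
    n_cells_used: int
    flagged: bool = False


def db_to_linear(sv_db):
    """dB re 1 m⁻¹ → linear volume backscattering coefficient (10^(dB/10))."""
    return np.power(10.0, np.asarray(sv_db, dtype=float) / 10.0)


def linear_to_db(sv_linear):
    """Linear S_V → dB; zero maps to −inf (handled downstream as 'no fish')."""
    sv = np.asarray(sv_linear, dtype=float)
    if (sv < 0).any():
        raise ValueError("linear S_V must be non-negative")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(sv)


def apply_masks(
    eg: Echogram,
    extra_masks: Sequence[np.ndarray] = (),
    dead_zone_m: float = DEAD_ZONE_M,
) -> Echogram:
    """Invalidate the bottom dead zone and any supplied artefact masks.

    Cells deeper than (bottom − dead_zone_m) on each ping are excluded to
    avoid confounding with the acoustic dead zone; ``extra_masks`` are
    boolean grids (True = exclude) for instrument signals and bubble noise.
    """
    if eg.bottom_depth is None:
        raise ValueError("bottom depth profile required to mask the dead zone")
    valid = eg.valid.copy()
    cutoff = eg.bottom_depth[:, None] - dead_zone_m
    valid &= ~(eg.depths[None, :] > cutoff)
    for mask in extra_masks:
        if mask.shape != valid.shape:
            raise ValueError("extra mask shape must match the grid")
        valid &= ~mask
    n_removed = int(eg.valid.sum() - valid.sum())
    logger.info("masking invalidated %d cells on %s", n_removed, eg.station_id or "grid")
    return replace(eg, valid=valid)


def threshold_echogram(eg: Echogram, threshold_db: float = DEFAULT_THRESHOLD_DB) -> Echogram:
    """Zero out (linear) valid cells below the noise threshold.

    Cells strictly below ``threshold_db`` are assumed to contain no fish and
    are set to linear zero (−inf dB); cells at or above the threshold are
    kept unchanged, so an exact −70 dB cell survives.  Zeroed cells remain
    *valid* — they contribute zeros to window means, which is what lets a
    station mean fall below the threshold's linear equivalent.
    """
    sv = eg.sv_db.copy()
    below = eg.valid & (sv < threshold_db)
    sv[below] = -np.inf
    return replace(eg, sv_db=sv)


def window_mean_sv(
    eg: Echogram,
    start: float,
    duration_s: float = DEFAULT_WINDOW_S,
    depth_band: tuple[float, float] | None = None,
) -> EchoSummary:
    """Mean linear S_V over valid cells in the half-open window [start, start+duration).

    Thresholded zeros count as zeros.  ``depth_band`` (min_m, max_m)
    optionally restricts the average to the sampled layer's depth band.
    A window with no valid cells yields a flagged summary.
    """
    end = start + duration_s
    in_window = (eg.times >= start) & (eg.times < end)
    use = eg.valid & in_window[:, None]
    if depth_band is not None:
        lo, hi = depth_band
        use &= (eg.depths[None, :] >= lo) & (eg.depths[None, :] <= hi)
    n = int(use.sum())
    if n == 0:
        return EchoSummary(eg.station_id, start, end, float("nan"), 0, flagged=True)
    linear = db_to_linear(eg.sv_db[use])
    return EchoSummary(eg.station_id, start, end, float(linear.mean()), n)
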