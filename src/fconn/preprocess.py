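"""Time-series conditioning: volume discard, detrending, band-pass
filtering, nuisance regression and head-motion summaries.

The canonical order is discard -> detrend -> band-pass -> nuisance
regression; ``preprocess_timeseries`` applies it end to end (a flag swaps
the last two stages for sensitivity analyses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceSet",
    "MotionSummary",
    "condition_timeseries",
    "bandpass_filter",
    "expand_motion_24",
    "regress_nuisance",
    "fd_summaries",
    "motion_exclusion_flag",
    "build_nuisance_set",
    "preprocess_timeseries",
]


@dataclass
class NuisanceSet:
    """Confound regressors: columns of `matrix` named by `names`."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")


@dataclass
class MotionSummary:
    max_fd: float
    rms_fd: float
    mean_fd: float


def condition_timeseries(ts: np.ndarray, n_discard: int = 5) -> np.ndarray:
    """Drop the first `n_discard` volumes, then remove per-column linear trends."""
    ts = np.asarray(ts, dtype=float)
    if n_discard >= ts.shape[0]:
        raise ValueError("cannot discard all volumes")
    out = ts[n_discard:]
    if out.shape[0] < 10:
        raise ValueError("fewer than 10 volumes remain after discard")
    return signal.detrend(out, axis=0, type="linear")


def _band_mask(n: int, tr: float, low: float, high: float, n_taper: int = 2) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    mask = ((freqs >= low) & (freqs <= high)).astype(float)
    df = freqs[1] - freqs[0] if n > 1 else 1.0
    # raised-cosine roll-off over n_taper bins on each side of the band
    for k in range(len(freqs)):
        if mask[k] == 1.0 or freqs[k] == 0.0:
            continue
        dist = min(
            abs(freqs[k] - low) if freqs[k] < low else np.inf,
            abs(freqs[k] - high) if freqs[k] > high else np.inf,
        )
        bins = dist / df
        if bins <= n_taper:
            mask[k] = 0.5 * (1.0 + np.cos(np.pi * bins / (n_taper + 1)))
    mask[0] = 0.0  # DC always removed
    return mask


def bandpass_filter(
    ts: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Zero-phase frequency-domain band-pass (0.01-0.1 Hz by default).

    Implemented by masking the rFFT with a 2-bin raised-cosine roll-off at
    each band edge; output length equals input length and the DC component
    is always removed.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist:.4f}")
    n = ts.shape[0]
    spec = np.fft.rfft(ts, axis=0)
    mask = _band_mask(n, tr_seconds, low_hz, high_hz)
    return np.fft.irfft(spec * mask[:, None] if ts.ndim == 2 else spec * mask,
                        n=n, axis=0)


def expand_motion_24(motion: np.ndarray) -> np.ndarray:
    """Friston-style 24-parameter motion expansion.

    Column order: the 6 raw parameters, their one-volume backward shifts
    (first row zero-padded), the squares of the raw parameters, and the
    squares of the shifted parameters.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have exactly 6 columns")
    shifted = np.zeros_like(motion)
    shifted[1:] = motion[:-1]
    return np.hstack([motion, shifted, motion**2, shifted**2])


def regress_nuisance(ts: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Replace each column by its OLS residual on [intercept | nuisance].

    Rank-deficient designs are handled by the pseudoinverse (equivalent to
    dropping collinear columns) with a logged warning; residuals remain
    orthogonal to the design's column space, so the operation is idempotent.
    """
    ts = np.asarray(ts, dtype=float)
    if nuisance.matrix.shape[0] != ts.shape[0]:
        raise ValueError("row counts of series and nuisance must match")
    x = np.column_stack([np.ones(ts.shape[0]), nuisance.matrix])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        logger.warning(
            "nuisance design rank-deficient (%d < %d); collinear columns "
            "effectively dropped", rank, x.shape[1],
        )
    beta = np.linalg.pinv(x) @ ts
    return ts - x @ beta


def fd_summaries(motion: np.ndarray, head_radius_mm: float = 50.0) -> MotionSummary:
    """Power-style framewise displacement summaries.

    FD at volume t (t >= 1) is the sum of absolute backward differences of
    the 3 translations (mm) plus the 3 rotations (degrees) converted to arc
    length at `head_radius_mm`.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + np.deg2rad(d[:, 3:]).sum(axis=1) * head_radius_mm
    return MotionSummary(
        max_fd=float(fd.max()),
        rms_fd=float(np.sqrt((fd**2).mean())),
        mean_fd=float(fd.mean()),
    )


def motion_exclusion_flag(
    motion: np.ndarray,
    trans_thresh_mm: float = 1.5,
    rot_thresh_deg: float = 1.5,
) -> bool:
    """True if motion exceeds the excessive-head-motion QC rule."""
    motion = np.asarray(motion, dtype=float)
    return bool(
        np.any(np.abs(motion[:, :3]) > trans_thresh_mm)
        or np.any(np.abs(motion[:, 3:]) > rot_thresh_deg)
    )


def build_nuisance_set(
    motion: np.ndarray,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    expand_motion: bool = True,
) -> NuisanceSet:
    """Assemble the standard confound regressor matrix."""
    cols, names = [], []
    for name, sig in (("wm", wm), ("csf", csf), ("global", global_signal)):
        if sig is not None:
            cols.append(np.asarray(sig, dtype=float).reshape(-1, 1))
            names.append(name)
    if expand_motion:
        cols.append(expand_motion_24(motion))
        names += [f"motion_{k}" for k in range(6)]
        names += [f"motion_shift_{k}" for k in range(6)]
        names += [f"motion_sq_{k}" for k in range(6)]
        names += [f"motion_shift_sq_{k}" for k in range(6)]
    else:
        cols.append(np.asarray(motion, dtype=float))
        names += [f"motion_{k}" for k in range(6)]
    return NuisanceSet(matrix=np.hstack(cols), names=names)


def preprocess_timeseries(
    ts: np.ndarray,
    motion: np.ndarray,
    tr_seconds: float,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    n_discard: int = 5,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    expand_motion: bool = True,
    regress_before_filter: bool = False,
) -> np.ndarray:
    """Full conditioning pipeline for one subject's ROI-by-time matrix.

    Default order: discard -> detrend -> band-pass -> nuisance regression.
    Nuisance signals are truncated to match the discarded volumes.
    """
    if motion.shape[0] != np.asarray(ts).shape[0]:
        raise ValueError("motion table must have one row per volume")
    out = condition_timeseries(ts, n_discard=n_discard)

    def trunc(x):
        return None if x is None else np.asarray(x, dtype=float)[n_discard:]

    nuis = build_nuisance_set(
        motion=np.asarray(motion, dtype=float)[n_discard:],
        wm=trunc(wm), csf=trunc(csf), global_signal=trunc(global_signal),
        expand_motion=expand_motion,
    )
    if regress_before_filter:
        out = regress_nuisance(out, nuis)
        out = bandpass_filter(out, tr_seconds, low_hz, high_hz)
    else:
        out = bandpass_filter(out, tr_seconds, low_hz, high_hz)
        out = regress_nuisance(out, nuis)
    return out
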