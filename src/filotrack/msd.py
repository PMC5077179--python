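"""Mean-squared-displacement analysis of single-molecule tracks.

The per-track, time-averaged MSD is evaluated over all same-track pairs at
each lag, up to one quarter of the track duration; the short-range lateral
diffusion coefficient D_lat is one quarter of the slope of an unweighted
least-squares line through the origin over the first few curve points (2D
diffusion: MSD = 4 D dt).  The curve always includes the constructed point
MSD(0) = 0.  The static localization-noise offset (4 sigma_loc^2) is *not*
subtracted by default, matching how D_lat is usually reported from raw MSD
initial gradients; pass ``noise_sigma_um`` to ``fit_dlat`` to remove it.

Curve shape is classified by the anomalous-diffusion exponent alpha of
MSD = 4 D dt^alpha: concave-down (sub-diffusive / confined) for alpha < 0.8,
linear (free Brownian) for 0.8 <= alpha <= 1.2, concave-up (directed) above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Track

CONCAVE_DOWN = "CONCAVE_DOWN"
LINEAR = "LINEAR"
CONCAVE_UP = "CONCAVE_UP"
UNCLASSIFIED = "UNCLASSIFIED"

MIN_TRACK_FRAMES = 5
STATIONARY_THRESHOLD = 0.02  # um^2/s; boundary value is retained


@dataclass
class MSDCurve:
    dt_s: np.ndarray  # includes dt = 0
    msd_um2: np.ndarray  # msd[0] = 0 by construction
    n_pairs: np.ndarray
    D_lat: float | None = None
    shape_class: str | None = None
    dlat_flagged: bool = False

    @property
    def n_lags(self) -> int:
        return len(self.dt_s)


def compute_msd(track_or_positions, frame_interval_s: float | None = None) -> MSDCurve:
    """Time-averaged MSD of one track (lags up to 1/4 of the track duration).

    Accepts either a :class:`Track` (requires ``frame_interval_s``) or an
    (N, d) position array sampled at uniform intervals.
    """
    frames = None
    if isinstance(track_or_positions, Track):
        if frame_interval_s is None:
            raise ValueError("frame_interval_s required with a Track input")
        pos = track_or_positions.positions_um
        frames = track_or_positions.frames  # gap-aware lags
    else:
        pos = np.asarray(track_or_positions, dtype=float)
        if frame_interval_s is None:
            raise ValueError("frame_interval_s required")
    n = len(pos)
    if n < MIN_TRACK_FRAMES:
        raise ValueError(
            f"track of {n} frames rejected: need >= {MIN_TRACK_FRAMES} for MSD")
    if frames is None:
        frames = np.arange(n)
    span = int(frames[-1] - frames[0])
    max_lag = max(1, span // 4)
    msd = np.zeros(max_lag + 1)
    npairs = np.zeros(max_lag + 1, dtype=int)
    npairs[0] = n
    # pair positions by frame separation, honouring any skipped frames
    index_of = {int(f): i for i, f in enumerate(frames)}
    for k in range(1, max_lag + 1):
        ii = [index_of[int(f)] for f in frames if int(f) + k in index_of]
        if not ii:
            continue
        jj = [index_of[int(frames[i]) + k] for i in ii]
        d = pos[jj] - pos[ii]
        msd[k] = float(np.mean(np.sum(d * d, axis=1)))
        npairs[k] = len(ii)
    dts = np.arange(max_lag + 1) * frame_interval_s
    return MSDCurve(dt_s=dts, msd_um2=msd, n_pairs=npairs)


def fit_dlat(curve: MSDCurve, n_initial_points: int = 4,
             noise_sigma_um: float | None = None) -> float:
    """D_lat from the initial MSD gradient (slope/4 through the origin).

    ``n_initial_points`` counts curve points including the constructed origin.
    A negative fitted slope is clamped to zero and flagged on the curve.
    """
    if curve.n_lags < n_initial_points:
        raise ValueError(
            f"curve has {curve.n_lags} points; need >= {n_initial_points}")
    x = curve.dt_s[:n_initial_points]
    y = curve.msd_um2[:n_initial_points].copy()
    if noise_sigma_um is not None:
        y[1:] = y[1:] - 4.0 * noise_sigma_um ** 2
    denom = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / denom if denom > 0 else 0.0
    d = slope / 4.0
    if d < 0:
        curve.dlat_flagged = True
        d = 0.0
    curve.D_lat = d
    return d


CLASSIFY_MAX_LAGS = 10


def classify_shape(curve: MSDCurve, alpha_bounds=(0.8, 1.2)) -> str:
    """Classify the MSD-vs-dt shape via the exponent of MSD = 4 D dt^alpha.

    The exponent is fitted over at most the first ``CLASSIFY_MAX_LAGS``
    non-zero lags: beyond ~10% of the track duration a time-averaged MSD is
    so noisy that the exponent estimate degrades rather than improves.
    """
    mask = (curve.dt_s > 0) & (curve.msd_um2 > 0)
    if int(mask.sum()) < 6:
        raise ValueError("need >= 6 positive lags to classify shape")
    mask &= np.arange(curve.n_lags) <= CLASSIFY_MAX_LAGS
    lx = np.log(curve.dt_s[mask])
    ly = np.log(curve.msd_um2[mask])
    # weight lags by sqrt(pair count): long lags of a time-averaged MSD are
    # noisy (few pairs) and would otherwise dominate the exponent estimate
    wts = np.sqrt(curve.n_pairs[mask].astype(float))
    try:
        alpha = float(np.polyfit(lx, ly, 1, w=wts)[0])
    except np.linalg.LinAlgError:
        curve.shape_class = UNCLASSIFIED
        return UNCLASSIFIED
    if not np.isfinite(alpha):
        curve.shape_class = UNCLASSIFIED
        return UNCLASSIFIED
    lo, hi = alpha_bounds
    cls = CONCAVE_DOWN if alpha < lo else (LINEAR if alpha <= hi else CONCAVE_UP)
    curve.shape_class = cls
    return cls


def filter_stationary(dlat_values, threshold: float = STATIONARY_THRESHOLD):
    """Drop stationary objects (D_lat < threshold); boundary value retained.

    Returns (retained array, number excluded).
    """
    arr = np.asarray(list(dlat_values), dtype=float)
    keep = arr >= threshold
    return arr[keep], int((~keep).sum())


@dataclass
class MobilitySummary:
    """Box-and-whisker style population summary of per-track D_lat values."""

    n: int
    n_excluded_stationary: int
    median: float
    q1: float
    q3: float
    min: float
    max: float
    degenerate: bool = False

    @classmethod
    def from_dlat(cls, dlat_values, threshold: float = STATIONARY_THRESHOLD):
        retained, n_exc = filter_stationary(dlat_values, threshold)
        if retained.size == 0:
            return cls(0, n_exc, np.nan, np.nan, np.nan, np.nan, np.nan,
                       degenerate=True)
        q1, med, q3 = np.percentile(retained, [25, 50, 75])
        return cls(int(retained.size), n_exc, float(med), float(q1), float(q3),
                   float(retained.min()), float(retained.max()))


def ensemble_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Pairs-weighted pooled MSD across tracks (for pooled-curve figures)."""
    if not curves:
        raise ValueError("no curves")
    max_len = max(c.n_lags for c in curves)
    num = np.zeros(max_len)
    den = np.zeros(max_len)
    dt = None
    for c in curves:
        n = c.n_lags
        num[:n] += c.msd_um2 * c.n_pairs
        den[:n] += c.n_pairs
        if dt is None or n == max_len:
            dt = c.dt_s
    msd = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return MSDCurve(dt_s=dt, msd_um2=msd, n_pairs=den.astype(int))
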