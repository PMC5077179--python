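"""Filopodial straightening, kymographs and intrafilopodial velocimetry.

A filopodium is traced as a spline through user (or ground-truth) control
points; a 5-pixel-wide stripe along the path is resampled perpendicular to the
local axis, and a kymograph (position along the filopodium vs time, tip on
top) is built from the straightened profiles.  Directed-run velocity is the
slope of a streak's per-column intensity-weighted centroid positions (total
least squares).  Instantaneous velocities are signed axial speeds from a
least-squares slope over a sliding 10-frame (500 ms at 50-ms frames) window;
their histogram is fitted with a sum of two Gaussians: a near-zero component
(stalled + diffusive episodes) and a positive, tip-directed component.
Constructs are compared with a one-tailed Welch t test whose sample size is
reduced in proportion to the moving fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, stats
from scipy.optimize import curve_fit

from .config import SimConfig
from .render import FrameStack
from .tracking import Track

DEFAULT_STRIPE_PX = 5
DEFAULT_WINDOW_FRAMES = 10  # 500 ms at 50-ms frames
DEFAULT_BIN_WIDTH = 0.1  # um/s


class FilopodiumPath:
    """Spline-parameterized filopodial backbone; the tip is the last point."""

    def __init__(self, control_points_um, n_dense: int = 2000,
                 smoothing: float = 0.0):
        pts = np.asarray(control_points_um, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("control points must be (N>=2, 2)")
        if pts.shape[0] == 2 or smoothing == 0.0:
            k = min(3, pts.shape[0] - 1)
            tck, _u = interpolate.splprep(pts.T, k=k, s=smoothing)
        else:
            tck, _u = interpolate.splprep(pts.T, s=smoothing)
        self._tck = tck
        u = np.linspace(0, 1, n_dense)
        xy = np.array(interpolate.splev(u, tck)).T
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        self._dense_xy = xy
        self._dense_s = np.concatenate([[0.0], np.cumsum(seg)])
        if self.length_um <= 0:
            raise ValueError("degenerate path (zero arc length)")

    @property
    def length_um(self) -> float:
        return float(self._dense_s[-1])

    @property
    def control_tck(self):
        return self._tck

    def point_at(self, s) -> np.ndarray:
        s = np.clip(np.asarray(s, dtype=float), 0, self.length_um)
        x = np.interp(s, self._dense_s, self._dense_xy[:, 0])
        y = np.interp(s, self._dense_s, self._dense_xy[:, 1])
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s) -> np.ndarray:
        eps = max(self.length_um * 1e-4, 1e-6)
        p0 = self.point_at(np.asarray(s) - eps)
        p1 = self.point_at(np.asarray(s) + eps)
        d = p1 - p0
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        return d / np.maximum(n, 1e-12)

    def normal_at(self, s) -> np.ndarray:
        t = self.tangent_at(s)
        return np.stack([-t[..., 1], t[..., 0]], axis=-1)

    def project(self, points_um) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length coordinate (tipward positive) and distance to the axis."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        d2 = ((pts[:, None, :] - self._dense_xy[None, :, :]) ** 2).sum(axis=-1)
        idx = np.argmin(d2, axis=1)
        return self._dense_s[idx], np.sqrt(d2[np.arange(len(pts)), idx])

    def reversed(self) -> "FilopodiumPath":
        rev = FilopodiumPath.__new__(FilopodiumPath)
        rev._tck = self._tck
        rev._dense_xy = self._dense_xy[::-1].copy()
        seg = np.linalg.norm(np.diff(rev._dense_xy, axis=0), axis=1)
        rev._dense_s = np.concatenate([[0.0], np.cumsum(seg)])
        return rev


def straighten_frame(frame: np.ndarray, path: FilopodiumPath,
                     config: SimConfig, stripe_px: int = DEFAULT_STRIPE_PX,
                     reduce: bool = True) -> np.ndarray:
    """Resample a frame along the path at pixel pitch.

    Returns the (n_arc, stripe_px) strip, or its stripe-averaged (n_arc,)
    profile if ``reduce``.  Samples outside the field are truncated by the
    bilinear interpolation (constant-padded with the frame median).
    """
    if stripe_px % 2 == 0:
        raise ValueError("stripe_px must be odd")
    px = config.pixel_size_um
    s = np.arange(0.0, path.length_um + 0.5 * px, px)
    centers = path.point_at(s)
    normals = path.normal_at(s)
    offsets = (np.arange(stripe_px) - stripe_px // 2) * px
    pts = centers[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    # image row index = y/px - 0.5, col index = x/px - 0.5 (pixel-centre grid)
    rows = pts[..., 1] / px - 0.5
    cols = pts[..., 0] / px - 0.5
    strip = ndimage.map_coordinates(frame, [rows.ravel(), cols.ravel()],
                                    order=1, mode="constant",
                                    cval=float(np.median(frame)))
    strip = strip.reshape(len(s), stripe_px)
    return strip.mean(axis=1) if reduce else strip


def straighten(stack: FrameStack, path: FilopodiumPath,
               stripe_px: int = DEFAULT_STRIPE_PX) -> np.ndarray:
    """Straightened profiles for every frame: (n_frames, n_arc)."""
    return np.array([
        straighten_frame(stack.data[k], path, stack.config, stripe_px)
        for k in range(stack.n_frames)
    ])


@dataclass
class Kymograph:
    """Position along the filopodium (rows, tip at top) vs time (columns)."""

    data: np.ndarray  # (n_arc, n_frames)
    pixel_pitch_um: float
    frame_interval_s: float
    stripe_px: int = DEFAULT_STRIPE_PX

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def arc_of_row(self, rows) -> np.ndarray:
        """Arc-length coordinate (um, from the root) of given row indices."""
        n = self.data.shape[0]
        return (n - 1 - np.asarray(rows, dtype=float)) * self.pixel_pitch_um


def build_kymograph(profiles: np.ndarray, config: SimConfig,
                    stripe_px: int = DEFAULT_STRIPE_PX) -> Kymograph:
    """Kymograph from straightened per-frame profiles (tip row on top)."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need >= 2 frames of straightened profiles")
    data = profiles.T[::-1]  # rows: arc bins, tip (largest s) on top
    return Kymograph(data=data.copy(), pixel_pitch_um=config.pixel_size_um,
                     frame_interval_s=config.frame_interval_s)


def measure_kymo_velocity(kymo: Kymograph, col_start: int = 0,
                          col_stop: int | None = None,
                          min_snr: float = 2.0) -> float:
    """Velocity (um/s, tipward positive) of a streak in a kymograph segment.

    Per-column intensity-weighted centroid positions (background = column
    median) are fitted with a total-least-squares line.  Segments without a
    detectable streak (peak SNR < ``min_snr``) are rejected.
    """
    if col_stop is None:
        col_stop = kymo.n_cols
    if col_stop - col_start < 5:
        raise ValueError("segment must span >= 5 time columns")
    seg = kymo.data[:, col_start:col_stop]
    bg = np.median(seg, axis=0, keepdims=True)
    resid = seg - bg
    noise = 1.4826 * np.median(np.abs(resid)) or 1e-12
    if resid.max() < min_snr * noise:
        raise ValueError("no detectable streak in segment (peak SNR < threshold)")
    # centroid within a PSF-sized window around each column's peak: a whole-
    # column centroid would be dragged toward mid-shaft by residual background
    halfwin = 3  # rows (~2 PSF sigma at 100 nm arc bins)
    rows = np.arange(seg.shape[0], dtype=float)
    cent_rows, cols_ok = [], []
    for c in range(seg.shape[1]):
        col = resid[:, c]
        peak = int(np.argmax(col))
        if col[peak] < min_snr * noise:
            continue
        lo, hi = max(0, peak - halfwin), min(len(col), peak + halfwin + 1)
        wts = np.clip(col[lo:hi], 0.0, None)
        if wts.sum() <= 0:
            continue
        cent_rows.append(float(np.sum(wts * rows[lo:hi]) / wts.sum()))
        cols_ok.append(c)
    if len(cols_ok) < 5:
        raise ValueError("fewer than 5 columns with a detectable streak")
    s = kymo.arc_of_row(np.array(cent_rows))
    t = (np.asarray(cols_ok) + col_start) * kymo.frame_interval_s
    slope = _tls_slope(t, s)
    # coherence gate: noise maxima scatter across the whole position axis,
    # whereas a real streak's centroids hug the fitted line
    pred = s.mean() + slope * (t - t.mean())
    span = seg.shape[0] * kymo.pixel_pitch_um
    if np.sqrt(np.mean((s - pred) ** 2)) > 0.1 * span:
        raise ValueError("no coherent streak in segment (centroids scatter)")
    return slope


def _tls_slope(t: np.ndarray, s: np.ndarray) -> float:
    tc = t - t.mean()
    sc = s - s.mean()
    cov = np.cov(np.vstack([tc, sc]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-12:
        return float(np.inf) * np.sign(v[1])
    return float(v[1] / v[0])


@dataclass
class VelocitySample:
    """Sliding-window signed axial velocities (um/s, tipward positive)."""

    velocities: np.ndarray
    window_frames: int = DEFAULT_WINDOW_FRAMES

    @property
    def n(self) -> int:
        return len(self.velocities)


def instantaneous_velocities(track: Track, path: FilopodiumPath,
                             config: SimConfig,
                             window_frames: int = DEFAULT_WINDOW_FRAMES,
                             shaft_radius_nm: float = 58.25) -> VelocitySample:
    """Windowed axial velocities of one track projected on the path.

    Each sliding window's velocity is the least-squares slope of arc length vs
    time (more robust to localization noise than an endpoint difference).
    Samples whose projection distance exceeds shaft radius + 2 PSF sigma are
    dropped.
    """
    if track.n_spots < window_frames:
        raise ValueError("track shorter than the velocity window")
    s, dist = path.project(track.positions_um)
    max_dist = shaft_radius_nm / 1000.0 + 2.0 * config.psf_sigma_um
    t = track.times_s(config.frame_interval_s)
    keep = dist <= max_dist
    return VelocitySample(
        velocities=windowed_slopes(t[keep], s[keep], window_frames),
        window_frames=window_frames,
    )


def windowed_slopes(t: np.ndarray, s: np.ndarray, window: int) -> np.ndarray:
    out = []
    for i in range(len(t) - window + 1):
        tw = t[i:i + window]
        sw = s[i:i + window]
        tc = tw - tw.mean()
        denom = float(np.sum(tc * tc))
        if denom <= 0:
            continue
        out.append(float(np.sum(tc * (sw - sw.mean())) / denom))
    return np.asarray(out)


@dataclass
class MixtureFit:
    """Two-Gaussian velocity-histogram fit: near-zero (1) + directed (2)."""

    V1: float
    sigma1: float
    A1: float
    V2: float | None
    sigma2: float | None
    A2: float | None
    n_total: int
    n_V2: int
    pct_V2: float  # fraction in [0, 1]
    single_component: bool = False
    sse: float = np.nan


def _two_gauss(x, a1, m1, s1, a2, m2, s2):
    return (a1 * np.exp(-(x - m1) ** 2 / (2 * s1 ** 2))
            + a2 * np.exp(-(x - m2) ** 2 / (2 * s2 ** 2)))


def fit_two_gaussians(velocities, bin_width: float = DEFAULT_BIN_WIDTH,
                      min_samples: int = 100,
                      min_weight: float = 0.01) -> MixtureFit:
    """Least-squares fit of the velocity histogram to two Gaussians.

    The fit is restarted from five deterministic initializations of the
    directed component's mean and the best-SSE solution kept.  The component
    whose mean is nearer zero is labelled 1; the directed fraction comes from
    the fitted component weights (A * sigma products).  Degenerate fits
    (vanishing width or component weight below 1%) fall back to a single
    Gaussian with V2 undefined.
    """
    v = np.asarray(list(velocities), dtype=float)
    n = len(v)
    if n < min_samples:
        raise ValueError(f"need >= {min_samples} velocity samples, got {n}")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    peak = counts.max()
    spread = max(v.std(), bin_width)
    m_lo, m_hi = float(v.min()) - spread, float(v.max()) + spread
    best = None
    # deterministic restarts: directed-component mean seeded at upper
    # quantiles of the sample
    for m2_init in np.quantile(v, [0.55, 0.70, 0.85, 0.95, 0.99]):
        p0 = [peak, float(np.median(v)), 0.5 * spread,
              0.3 * peak, float(m2_init), spread]
        try:
            popt, _ = curve_fit(
                _two_gauss, centers, counts, p0=p0,
                bounds=([0, m_lo, bin_width / 4, 0, m_lo, bin_width / 4],
                        [5 * peak, m_hi, 10 * spread,
                         5 * peak, m_hi, 10 * spread]),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((_two_gauss(centers, *popt) - counts) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return _single_gaussian_fallback(v, centers, counts, n)
    sse, (a1, m1, s1, a2, m2, s2) = best
    if abs(m2) < abs(m1):  # label the component nearer zero as 1
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    w1 = a1 * s1
    w2 = a2 * s2
    frac2 = w2 / (w1 + w2) if (w1 + w2) > 0 else 0.0
    degenerate = frac2 < min_weight or frac2 > 1 - min_weight
    if not degenerate:
        # parsimony check: keep the second component only if it improves the
        # fit significantly over a single Gaussian (F-test on 3 extra params)
        single = _single_gaussian_fallback(v, centers, counts, n)
        dof = len(centers) - 6
        if np.isfinite(single.sse) and dof > 0 and sse > 0:
            f_stat = max(single.sse - sse, 0.0) / 3.0 / (sse / dof)
            degenerate = stats.f.sf(f_stat, 3, dof) > 0.01
    if degenerate:
        return _single_gaussian_fallback(v, centers, counts, n)
    return MixtureFit(V1=float(m1), sigma1=float(s1), A1=float(a1),
                      V2=float(m2), sigma2=float(s2), A2=float(a2),
                      n_total=n, n_V2=int(round(frac2 * n)),
                      pct_V2=float(frac2), sse=sse)


def _single_gaussian_fallback(v, centers, counts, n) -> MixtureFit:
    def g(x, a, m, s):
        return a * np.exp(-(x - m) ** 2 / (2 * s ** 2))
    try:
        popt, _ = curve_fit(g, centers, counts,
                            p0=[counts.max(), float(np.median(v)), max(v.std(), 1e-3)],
                            maxfev=2000)
        a, m, s = popt
        sse = float(np.sum((g(centers, *popt) - counts) ** 2))
    except RuntimeError:
        a, m, s, sse = float(counts.max()), float(np.mean(v)), float(v.std()), np.nan
    return MixtureFit(V1=float(m), sigma1=float(abs(s)), A1=float(a),
                      V2=None, sigma2=None, A2=None, n_total=n, n_V2=0,
                      pct_V2=0.0, single_component=True, sse=sse)


def compare_velocities(fit_a, fit_b) -> float:
    """One-tailed Welch t test on the directed-component means.

    Accepts MixtureFit objects or (V2, sigma2, n) tuples; for fits the
    effective n is n_total * pct_V2 (sample size reduced in proportion to the
    moving fraction).  Returns the p-value for the alternative V2_a > V2_b.
    """
    v1, s1, n1 = _v2_stats(fit_a)
    v2, s2, n2 = _v2_stats(fit_b)
    if n1 < 3 or n2 < 3:
        raise ValueError("effective n < 3: comparison refused")
    se2 = s1 ** 2 / n1 + s2 ** 2 / n2
    t = (v1 - v2) / np.sqrt(se2)
    df = se2 ** 2 / ((s1 ** 2 / n1) ** 2 / (n1 - 1) + (s2 ** 2 / n2) ** 2 / (n2 - 1))
    return float(stats.t.sf(t, df))


def _v2_stats(fit):
    if isinstance(fit, MixtureFit):
        if fit.V2 is None:
            raise ValueError("fit has no directed component (V2 undefined)")
        return fit.V2, fit.sigma2, fit.n_total * fit.pct_V2
    v, s, n = fit
    return float(v), float(s), float(n)
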