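"""Per-pixel temporal autocorrelation mobility mapping.

Molecules too fast to track leave intensity fluctuations at each pixel whose
characteristic decay time tau shortens as local mobility rises (tau reflects
the dwell of a molecule in the optical volume: PSF x pixel x evanescent
depth).  tau is mapped to a diffusion coefficient through an *empirical*
calibration built by running the identical pipeline on simulated movies of
uniformly diffusing emitters across a D grid; the raw tau(D) table is made
monotone by isotonic regression before inversion.  Mapped values are capped
at 2 um^2/s — faster motion decorrelates within a frame or two and cannot be
determined reliably — and flagged as saturated.

tau is defined as the first 1/e crossing of the normalized autocorrelation,
linearly interpolated between bracketing lags (robust to the non-exponential
ACF shapes produced by the evanescent-field convolution); a single-exponential
fit is available as an alternative estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from .config import SimConfig
from .render import FrameStack, render_stack
from .simulate import uniform_2d_ensemble, apply_photobleaching

D_CAP = 2.0  # um^2/s
LOCAL_WINDOW = 8  # px
MIN_RESOLVED_FRACTION = 0.25
INV_E = 1.0 / np.e


@dataclass
class PixelACF:
    lags_s: np.ndarray
    acf: np.ndarray  # normalized, acf[0] = 1
    resolved: bool = True
    tau_s: float | None = None
    saturated: bool = False


@dataclass
class MobilityMap:
    tau_s: np.ndarray  # locally averaged
    D: np.ndarray  # um^2/s, capped at D_CAP
    resolved: np.ndarray  # bool grid
    saturated: np.ndarray  # bool grid (D at or above the cap)


MIN_SIGNAL_VARIANCE_FRACTION = 0.12


def stack_autocorrelation(data: np.ndarray, max_lag: int | None = None,
                          noise_corrected: bool = False):
    """Normalized mean-subtracted temporal ACF for every pixel at once.

    Returns (acf array of shape (max_lag+1, h, w), resolved mask).  Lags run
    to one quarter of the record length by default.  Mean subtraction makes
    the estimate invariant to any constant offset.

    With ``noise_corrected`` (used by the mobility-mapping pipeline) the
    zero-lag value — which carries the uncorrelated shot/read-noise spike on
    top of the molecular signal variance — is replaced by the signal variance
    extrapolated from the first lags before normalization, the standard
    image-correlation treatment.  Pixels whose extrapolated signal variance
    is a small fraction of the total (noise-only pixels never visited by a
    molecule) are marked unresolved.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 8:
        raise ValueError("need >= 8 frames for autocorrelation")
    if max_lag is None:
        max_lag = max(1, n // 4)
    x = data - data.mean(axis=0)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, n=nfft, axis=0)
    corr = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[: max_lag + 1]
    counts = (n - np.arange(max_lag + 1))[:, None, None]
    corr /= counts
    total_var = corr[0].copy()
    resolved = total_var > 1e-12 * max(float(data.max()) ** 2, 1.0)
    if noise_corrected:
        # linear extrapolation of lags 1..2 back to zero lag
        sig_var = np.maximum(2.0 * corr[1] - corr[2], corr[1])
        resolved &= sig_var > MIN_SIGNAL_VARIANCE_FRACTION * np.maximum(total_var, 1e-300)
        norm = sig_var
    else:
        norm = total_var
    acf = corr / np.where(resolved, norm, 1.0)
    acf[0] = np.where(resolved, 1.0, acf[0])
    return acf, resolved


def pixel_autocorrelation(stack: FrameStack, pixel: tuple[int, int]) -> PixelACF:
    """ACF of a single pixel's intensity series (spec'd single-pixel view)."""
    if stack.n_frames < 50:
        raise ValueError("need >= 50 frames for a mobility-grade ACF")
    acf, resolved = stack_autocorrelation(stack.data)
    i, j = pixel
    lags = np.arange(acf.shape[0]) * stack.config.frame_interval_s
    if not resolved[i, j]:
        return PixelACF(lags_s=lags, acf=np.full(acf.shape[0], np.nan),
                        resolved=False)
    return PixelACF(lags_s=lags, acf=acf[:, i, j])


def extract_tau(acf_obj: PixelACF) -> float:
    """tau = first 1/e crossing of the ACF, linearly interpolated.

    If the ACF never falls below 1/e within the computed lags, tau is set to
    the maximum lag and the ACF is flagged saturated (slow decay, e.g. an
    immobile spot whose decay is dominated by bleaching).
    """
    if not acf_obj.resolved:
        raise ValueError("ACF unresolved (zero-variance series)")
    tau, sat = _tau_from_series(acf_obj.acf, acf_obj.lags_s)
    acf_obj.tau_s = tau
    acf_obj.saturated = sat
    return tau


def _tau_from_series(acf: np.ndarray, lags: np.ndarray):
    below = np.nonzero(acf < INV_E)[0]
    if below.size == 0:
        return float(lags[-1]), True
    k = int(below[0])
    if k == 0:  # ACF(0) is 1 by normalization; cannot happen for resolved pixels
        return float(lags[0]), False
    a0, a1 = acf[k - 1], acf[k]
    frac = (a0 - INV_E) / (a0 - a1)
    return float(lags[k - 1] + frac * (lags[k] - lags[k - 1])), False


def extract_tau_expfit(acf_obj: PixelACF) -> float:
    """Alternative tau estimator: single-exponential least-squares fit."""
    if not acf_obj.resolved:
        raise ValueError("ACF unresolved")
    lags, acf = acf_obj.lags_s, acf_obj.acf
    try:
        popt, _ = curve_fit(lambda t, tau: np.exp(-t / tau), lags, acf,
                            p0=[max(lags[1], lags[-1] / 4)],
                            bounds=(1e-6, np.inf), maxfev=200)
        tau = float(popt[0])
    except RuntimeError:
        tau = float(lags[-1])
    acf_obj.tau_s = tau
    return tau


def tau_grid(stack: FrameStack):
    """tau at every pixel (noise-corrected ACF): (tau, resolved, saturated)."""
    acf, resolved = stack_autocorrelation(stack.data, noise_corrected=True)
    lags = np.arange(acf.shape[0]) * stack.config.frame_interval_s
    h, w = resolved.shape
    taus = np.full((h, w), np.nan)
    sat = np.zeros((h, w), dtype=bool)
    below = acf < INV_E
    any_below = below.any(axis=0)
    first = np.argmax(below, axis=0)
    for i in range(h):
        for j in range(w):
            if not resolved[i, j]:
                continue
            if not any_below[i, j]:
                taus[i, j] = lags[-1]
                sat[i, j] = True
                continue
            k = first[i, j]
            a0, a1 = acf[k - 1, i, j], acf[k, i, j]
            taus[i, j] = lags[k - 1] + (a0 - INV_E) / (a0 - a1) * (lags[k] - lags[k - 1])
    return taus, resolved, sat


def local_average_tau(taus: np.ndarray, resolved: np.ndarray,
                      window: int = LOCAL_WINDOW):
    """Sliding-window mean of tau ignoring unresolved pixels.

    Windows with fewer than 25% resolved pixels are marked unresolved.
    """
    if taus.shape[0] <= window or taus.shape[1] <= window:
        raise ValueError("grid must be larger than the averaging window")
    vals = np.where(resolved, taus, 0.0)
    num = ndimage.uniform_filter(vals, size=window, mode="constant")
    den = ndimage.uniform_filter(resolved.astype(float), size=window, mode="constant")
    ok = den >= MIN_RESOLVED_FRACTION * _coverage(taus.shape, window)
    avg = np.where(ok & (den > 0), num / np.maximum(den, 1e-12), np.nan)
    return avg, ok


def _coverage(shape, window):
    """Fraction of a centred window lying inside the grid (1 in the interior)."""
    ones = np.ones(shape)
    return ndimage.uniform_filter(ones, size=window, mode="constant")


@dataclass
class TauDCalibration:
    """Monotone empirical tau(D) table with its generating conditions."""

    D_grid: np.ndarray
    tau_s: np.ndarray  # isotonic (strictly non-increasing in D)
    density_per_um2: float
    config: SimConfig | None = None
    n_reps: int = 1
    tau_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tau_s) > 0):
            raise ValueError("tau must be non-increasing in D")

    def tau_to_D(self, tau) -> tuple[np.ndarray, np.ndarray]:
        """Invert the table: returns (D, saturated mask).

        tau below the fastest calibrated point maps to the cap and is flagged
        saturated; tau above the slowest point maps to the smallest D.
        """
        tau = np.asarray(tau, dtype=float)
        # np.interp needs increasing x: reverse the (decreasing) tau axis
        d = np.interp(tau, self.tau_s[::-1], self.D_grid[::-1],
                      left=self.D_grid[-1], right=self.D_grid[0])
        saturated = tau < self.tau_s[-1]
        d = np.minimum(d, D_CAP)
        saturated |= d >= D_CAP
        return d, saturated

    def to_json(self, path) -> None:
        payload = {
            "D_grid": self.D_grid.tolist(),
            "tau_s": self.tau_s.tolist(),
            "density_per_um2": self.density_per_um2,
            "n_reps": self.n_reps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TauDCalibration":
        with open(path) as fh:
            p = json.load(fh)
        return cls(np.array(p["D_grid"]), np.array(p["tau_s"]),
                   p["density_per_um2"], n_reps=p.get("n_reps", 1))


def stack_tau(stack: FrameStack) -> float:
    """Pipeline tau summary of a movie: median locally-averaged tau.

    The median (not the mean) is used because the window-tau distribution is
    right-skewed by windows a molecule happened to linger in; the same
    statistic is used when a map is reduced to a single mobility, so the
    calibration and its application agree.
    """
    taus, resolved, _sat = tau_grid(stack)
    avg, ok = local_average_tau(taus, resolved)
    if not ok.any():
        raise ValueError("no resolved windows in movie")
    return float(np.nanmedian(avg[ok]))


def simulate_movie(D: float, config: SimConfig, n_frames: int,
                   density_per_um2: float, seed: int,
                   bleach_rate_per_s: float | None = None) -> FrameStack:
    """A calibration-style movie: uniform in-plane diffusers at set density."""
    rng = np.random.default_rng(seed)
    area = config.field_w_um * config.field_h_um
    n_mol = max(1, int(round(density_per_um2 * area)))
    trajs = uniform_2d_ensemble(D, n_mol, n_frames, config, rng)
    rate = config.bleach_rate_per_s if bleach_rate_per_s is None else bleach_rate_per_s
    if rate > 0:
        trajs = apply_photobleaching(trajs, rate, seed=seed + 1)
    return render_stack(trajs, config, n_frames=n_frames, seed=seed + 2)


def build_calibration(config: SimConfig, D_grid, n_reps: int = 3,
                      seed: int = 0, density_per_um2: float = 0.15,
                      n_frames: int = 300) -> TauDCalibration:
    """Empirical tau->D conversion from simulated movies across a D grid.

    For each D the identical ACF pipeline is run on ``n_reps`` independently
    seeded movies; mean tau per D is made monotone by (decreasing) isotonic
    regression before inversion.  Bleaching is included at the config rate so
    its tau bias cancels between calibration and data.
    """
    D_grid = np.sort(np.asarray(D_grid, dtype=float))
    if D_grid[0] <= 0:
        raise ValueError("calibration D grid must be positive")
    taus = np.empty((len(D_grid), n_reps))
    for i, D in enumerate(D_grid):
        for r in range(n_reps):
            movie = simulate_movie(D, config, n_frames, density_per_um2,
                                   seed=seed + 1000 * i + r)
            taus[i, r] = stack_tau(movie)
    mean_tau = taus.mean(axis=1)
    se = taus.std(axis=1, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros(len(D_grid))
    if np.any(se / np.maximum(mean_tau, 1e-12) > 0.10):
        import warnings
        warnings.warn("tau calibration SE exceeds 10% of tau; increase n_reps")
    iso = IsotonicRegression(increasing=False)
    tau_mono = iso.fit_transform(D_grid, mean_tau)
    # break exact plateaus so the inverse is single-valued
    for k in range(1, len(tau_mono)):
        if tau_mono[k] >= tau_mono[k - 1]:
            tau_mono[k] = tau_mono[k - 1] * (1 - 1e-9)
    return TauDCalibration(D_grid=D_grid, tau_s=tau_mono,
                           density_per_um2=density_per_um2, config=config,
                           n_reps=n_reps, tau_se=se)


def mobility_map(stack: FrameStack, calibration: TauDCalibration) -> MobilityMap:
    """Locally averaged tau grid mapped to a capped D grid."""
    taus, resolved, _ = tau_grid(stack)
    avg, ok = local_average_tau(taus, resolved)
    d = np.full_like(avg, np.nan)
    sat = np.zeros(avg.shape, dtype=bool)
    dvals, satvals = calibration.tau_to_D(avg[ok])
    d[ok] = dvals
    sat[ok] = satvals
    return MobilityMap(tau_s=avg, D=d, resolved=ok, saturated=sat)


def render_mobility_map(mob: MobilityMap, stack: FrameStack, alpha: float = 0.55):
    """Pseudo-color overlay (red = 0 -> magenta/crimson >= 2 um^2/s) on the
    time-averaged fluorescence image.  Returns (rgb array, matplotlib figure).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    cmap = LinearSegmentedColormap.from_list(
        "mobility", ["red", "orange", "yellow", "green", "cyan", "blue", "magenta"])
    norm = Normalize(vmin=0.0, vmax=D_CAP)
    base = stack.mean_image()
    base = (base - base.min()) / max(np.ptp(base), 1e-12)
    rgb = np.stack([base] * 3, axis=-1)
    colored = cmap(norm(np.nan_to_num(mob.D, nan=0.0)))[..., :3]
    m = mob.resolved
    rgb[m] = (1 - alpha) * rgb[m] + alpha * colored[m]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rgb, interpolation="nearest")
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    cb = fig.colorbar(sm, ax=ax, fraction=0.046)
    cb.set_label(r"$D$ ($\mu$m$^2$ s$^{-1}$)")
    ax.set_axis_off()
    return rgb, fig
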