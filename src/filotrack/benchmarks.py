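"""End-to-end parameter-recovery experiments on synthetic data.

Each function generates data at a known ground-truth value of a quantity the
live-cell study reports, runs the corresponding analysis pipeline, and
returns the recovered estimate.  They are the single implementation behind
the acceptance checks and the analysis drivers, so every reported number is
recomputed from scratch at call time.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig, Filopodium
from .simulate import brownian_track_2d, directed_filopodial_run
from .render import render_stack, gaussian_spot_pixels
from .msd import compute_msd, fit_dlat
from .acf import build_calibration, simulate_movie, mobility_map
from .kinetics import (FilopodiumPath, straighten, build_kymograph,
                       measure_kymo_velocity, fit_two_gaussians)
from .superres import (SuperResCanvas, accumulate_localizations,
                       transverse_profile, psf_sigma_for_measured_width,
                       upsample_average_image)

FWHM_FACTOR = 2.3548

# Table-style mixture of intrafilopodial window velocities for the
# full-length construct: 65% near-zero + 35% directed (um/s)
FL_MIXTURE = dict(frac2=0.35, m1=-0.06, s1=0.21, m2=0.28, s2=0.69, n=425)


def dlat_recovery(seed: int, D_true: float = 0.2, n_tracks: int = 200,
                  n_frames: int = 100, frame_interval_s: float = 0.05,
                  noise_sigma_um: float = 0.03) -> float:
    """Median D_lat recovered from noisy synthetic membrane tracks."""
    rng = np.random.default_rng(seed)
    dlats = []
    for _ in range(n_tracks):
        pos = brownian_track_2d(D_true, n_frames, frame_interval_s, rng)
        pos = pos + rng.normal(0.0, noise_sigma_um, size=pos.shape)
        dlats.append(fit_dlat(compute_msd(pos, frame_interval_s)))
    return float(np.median(dlats))


def kymograph_velocity_recovery(seed: int, v_true: float = 1.4,
                                n_runs: int = 20) -> float:
    """Median streak velocity from rendered directed runs re-measured via
    straightening + kymograph slope analysis."""
    cfg = SimConfig(field_w_px=80, field_h_px=24)
    filo = Filopodium(np.array([[1.0, 1.2], [6.0, 1.2]]))
    path = FilopodiumPath(filo.axis_um)
    vs = []
    for run in range(n_runs):
        rng = np.random.default_rng(seed + 17 * run + 1)
        traj = directed_filopodial_run(filo, v_true, 50, cfg, rng, s0_um=0.2,
                                       molecule_id=run)
        stack = render_stack([traj], cfg, seed=seed + 31 * run + 2)
        kymo = build_kymograph(straighten(stack, path), cfg)
        vs.append(measure_kymo_velocity(kymo, 0, 45))
    return float(np.median(vs))


def draw_fl_mixture(rng, n: int | None = None) -> np.ndarray:
    """Velocity samples from the full-length construct's two-component mix."""
    p = FL_MIXTURE
    n = n or p["n"]
    directed = rng.random(n) < p["frac2"]
    return np.where(directed, rng.normal(p["m2"], p["s2"], n),
                    rng.normal(p["m1"], p["s1"], n))


def mixture_recovery(seed: int, n_replicates: int = 50):
    """Median (V2, %V2) recovered by the two-Gaussian histogram fit over
    independently drawn replicates of the velocity mixture."""
    v2s, pcts = [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + 101 * rep + 3)
        fit = fit_two_gaussians(draw_fl_mixture(rng), bin_width=0.1)
        if fit.V2 is None:
            continue  # rare unresolved replicate
        v2s.append(fit.V2)
        pcts.append(100.0 * fit.pct_V2)
    return float(np.median(v2s)), float(np.median(pcts))


def superres_fwhm_recovery(seed: int, true_fwhm_nm: float = 116.5,
                           n_localizations: int = 10000,
                           diffraction_fwhm_nm: float = 357.0):
    """(super-res FWHM, diffraction-limited FWHM) of a synthetic shaft.

    Localizations with Gaussian transverse spread of the true FWHM are
    accumulated on a 16x canvas with a near-delta kernel and profiled; the
    diffraction channel renders the same positions as PSF-blurred spots on
    the camera grid, upsamples 16x and profiles the averaged image.
    """
    rng = np.random.default_rng(seed)
    sigma_t_um = true_fwhm_nm / FWHM_FACTOR / 1000.0
    x = rng.uniform(0.5, 5.5, n_localizations)
    y = 1.0 + rng.normal(0.0, sigma_t_um, n_localizations)
    intensity = 3000.0

    canvas = SuperResCanvas(20, 64, 100.0)
    accumulate_localizations(zip(x, y, np.full(n_localizations, intensity)),
                             canvas, c_amp=1.0 / intensity,
                             c_sigma=5.0 * np.sqrt(intensity))
    path = FilopodiumPath(np.array([[0.5, 1.0], [5.5, 1.0]]))
    sr = transverse_profile(canvas.data, path, (0.5, 4.5), canvas.pitch_um,
                            half_width_nm=300.0)

    psf_nm = psf_sigma_for_measured_width(diffraction_fwhm_nm, true_fwhm_nm,
                                          100.0)
    img = np.zeros((20, 64))
    for xi, yi in zip(x[:4000], y[:4000]):
        gaussian_spot_pixels(20, 64, xi / 0.1, yi / 0.1, psf_nm / 100.0, 1.0,
                             out=img)
    dl = transverse_profile(upsample_average_image(img, 16), path,
                            (0.5, 4.5), 0.1 / 16.0, half_width_nm=600.0)
    return float(sr.fwhm_nm), float(dl.fwhm_nm)


ACF_CAL_GRID = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)


def acf_round_trip(seed: int, D_values=(0.05, 0.2, 1.0), n_frames: int = 400,
                   density_per_um2: float = 0.15, n_test_movies: int = 3,
                   field_px: int = 96):
    """Calibrate tau->D, then map independently seeded movies.

    Each true D is assessed as the median over ``n_test_movies`` independent
    movies of the per-movie median mapped D (a single short movie carries
    only a handful of molecules, so a lone movie is a noisy probe of the
    mapping).  Returns (dict D_true -> recovered D, saturated fraction of a
    movie above the 2 um^2/s cap).
    """
    cfg = SimConfig(field_w_px=field_px, field_h_px=field_px,
                    frame_interval_s=0.02, exposure_s=0.02,
                    background_photons_per_px=2.0)
    cal = build_calibration(cfg, ACF_CAL_GRID, n_reps=4, seed=seed,
                            n_frames=n_frames,
                            density_per_um2=density_per_um2)
    recovered = {}
    for D in D_values:
        meds = []
        for rep in range(n_test_movies):
            movie = simulate_movie(
                D, cfg, n_frames, density_per_um2,
                seed=seed + 50000 + int(D * 1000) + 7919 * rep)
            mob = mobility_map(movie, cal)
            meds.append(float(np.nanmedian(mob.D[mob.resolved])))
        recovered[D] = float(np.median(meds))
    fast = simulate_movie(4.0, cfg, 200, density_per_um2, seed=seed + 99991)
    mob = mobility_map(fast, cal)
    sat_frac = float(mob.saturated[mob.resolved].mean())
    return recovered, sat_frac
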