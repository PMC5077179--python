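"""Rendering of ground-truth trajectories into calibrated EMCCD-like video.

The expected photon count of a molecule is attenuated by the evanescent
excitation, ``N(z) = N0 * exp(-z / d)``, and spread over pixels as a
pixel-integrated 2D Gaussian of the PSF width.  Camera counts are
``offset + gain * Poisson(photons) + read noise``; the EMCCD excess-noise
factor is not modelled (gain plus read noise suffices at the SNR regime the
package is tested in).  Motion blur is reproduced by splitting each frame's
photons over >= 5 sub-frame positions taken from the sub-step trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .config import SimConfig
from .simulate import GroundTruthTrajectory, BLEACHED

MIN_BLUR_SUBFRAMES = 5
PATCH_HALF_SIGMAS = 5.0


@dataclass
class FrameStack:
    """Calibrated video: (n_frames, h, w) float counts plus its SimConfig."""

    data: np.ndarray
    config: SimConfig

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_frames, h, w)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def mean_image(self) -> np.ndarray:
        return self.data.mean(axis=0)


def gaussian_spot_pixels(h: int, w: int, x_px: float, y_px: float,
                         sigma_px: float, photons: float,
                         out: np.ndarray | None = None) -> np.ndarray:
    """Add a pixel-integrated Gaussian of total mass ``photons`` to a grid.

    Pixel (i, j) covers [j, j+1] x [i, i+1] in pixel units, so a molecule at
    pixel-centre coordinates contributes symmetrically.
    """
    if out is None:
        out = np.zeros((h, w))
    half = int(np.ceil(PATCH_HALF_SIGMAS * sigma_px)) + 1
    j0, j1 = int(np.floor(x_px)) - half, int(np.floor(x_px)) + half + 1
    i0, i1 = int(np.floor(y_px)) - half, int(np.floor(y_px)) + half + 1
    j0, j1 = max(j0, 0), min(j1, w)
    i0, i1 = max(i0, 0), min(i1, h)
    if j0 >= j1 or i0 >= i1:
        return out
    root2s = np.sqrt(2.0) * sigma_px
    ex = 0.5 * (erf((np.arange(j0, j1 + 1) - x_px) / root2s))
    ey = 0.5 * (erf((np.arange(i0, i1 + 1) - y_px) / root2s))
    out[i0:i1, j0:j1] += photons * np.outer(np.diff(ey), np.diff(ex))
    return out


def expected_photon_image(trajectories, config: SimConfig, frame: int) -> np.ndarray:
    """Noise-free expected photon counts for one frame (no background)."""
    h, w = config.field_h_px, config.field_w_px
    img = np.zeros((h, w))
    t0 = frame * config.frame_interval_s
    t1 = t0 + config.exposure_s
    px = config.pixel_size_um
    for tr in trajectories:
        positions, states = _subframe_samples(tr, t0, t1)
        if positions is None:
            continue
        n_sub = len(positions)
        for (x, y, z), st in zip(positions, states):
            if st == BLEACHED:
                continue
            photons = (config.photons_per_frame_at_z0 / n_sub
                       * np.exp(-z / config.evanescent_depth_um))
            gaussian_spot_pixels(h, w, x / px, y / px, config.psf_sigma_px,
                                 photons, out=img)
    return img


def _subframe_samples(tr: GroundTruthTrajectory, t0: float, t1: float):
    """>= MIN_BLUR_SUBFRAMES positions within [t0, t1] from the sub-step path,
    falling back to linear interpolation of the per-frame path."""
    ts = np.linspace(t0, t1, MIN_BLUR_SUBFRAMES, endpoint=False) + (t1 - t0) / (
        2 * MIN_BLUR_SUBFRAMES)
    if tr.t_sub is not None:
        src_t, src_xyz, src_state = tr.t_sub, tr.xyz_sub, tr.state_sub
    else:
        src_t, src_xyz, src_state = tr.t, tr.xyz, tr.state
    if t0 > src_t[-1] + 1e-12 or t1 < src_t[0] - 1e-12:
        return None, None
    idx = np.clip(np.searchsorted(src_t, ts), 0, len(src_t) - 1)
    xyz = np.column_stack([np.interp(ts, src_t, src_xyz[:, k]) for k in range(3)])
    states = src_state[idx]
    return xyz, states


def render_stack(trajectories, config: SimConfig, n_frames: int | None = None,
                 seed: int = 0, noise: bool = True) -> FrameStack:
    """Render trajectories into an EMCCD-like stack.

    An empty trajectory list yields a background-only stack.  With
    ``noise=False`` the stack is the noise-free expectation (offset +
    gain * expected photons), useful for calibration oracles.
    """
    if n_frames is None:
        if not trajectories:
            raise ValueError("n_frames required when rendering background only")
        n_frames = max(tr.n_frames for tr in trajectories)
    rng = np.random.default_rng(seed)
    h, w = config.field_h_px, config.field_w_px
    frames = np.empty((n_frames, h, w))
    for k in range(n_frames):
        expected = expected_photon_image(trajectories, config, k)
        expected += config.background_photons_per_px
        if noise:
            counts = (config.camera_offset
                      + config.camera_gain * rng.poisson(expected)
                      + rng.normal(0.0, config.read_noise_sd, size=(h, w)))
        else:
            counts = config.camera_offset + config.camera_gain * expected
        frames[k] = np.clip(counts, 0.0, config.saturation_level)
    return FrameStack(frames, config)
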