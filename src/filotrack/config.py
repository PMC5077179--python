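"""Calibration and simulation parameter containers.

Physical conventions used throughout the package:

* lateral positions in micrometres, in a coordinate frame whose origin is the
  top-left corner of the camera field; ``x`` runs along image columns and ``y``
  along rows,
* ``z`` in micrometres measured away from the coverslip (``z = 0`` is the
  glass-water interface where the evanescent excitation is strongest),
* times in seconds, diffusion coefficients in um^2/s, velocities in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

NM_PER_UM = 1000.0


@dataclass
class SimConfig:
    """Camera + optics calibration for simulated (and analysed) TIRF video.

    Defaults describe the imaging regime of the study being emulated: EMCCD at
    100 nm/pixel, 50-ms frames, a ~100 nm evanescent depth and a photon budget
    chosen so a single in-focus eGFP is localized with ~30 nm precision.
    """

    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.05  # 20 frames/s; 0.02, 0.03 and 0.1 s also used
    exposure_s: float = 0.05
    field_w_px: int = 128
    field_h_px: int = 128
    evanescent_depth_nm: float = 100.0
    psf_sigma_nm: float = 150.0
    camera_gain: float = 20.0  # counts per detected photon
    camera_offset: float = 100.0  # counts
    read_noise_sd: float = 10.0  # counts
    photons_per_frame_at_z0: float = 180.0
    background_photons_per_px: float = 15.0  # diffuse cytosolic background
    bleach_rate_per_s: float = 0.0
    saturation_level: float = 65535.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_nm",
            "frame_interval_s",
            "exposure_s",
            "evanescent_depth_nm",
            "psf_sigma_nm",
            "camera_gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("read_noise_sd", "photons_per_frame_at_z0",
                     "background_photons_per_px", "bleach_rate_per_s",
                     "camera_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.field_w_px < 8 or self.field_h_px < 8:
            raise ValueError("field must be at least 8x8 pixels")
        if self.exposure_s > self.frame_interval_s + 1e-12:
            raise ValueError("exposure_s cannot exceed frame_interval_s")
        # Sub-pixel Gaussian fitting needs >= 2 pixels across the PSF FWHM.
        fwhm_px = 2.3548 * self.psf_sigma_nm / self.pixel_size_nm
        if fwhm_px < 2.0:
            raise ValueError(
                f"PSF FWHM spans {fwhm_px:.2f} px; need >= 2 px for sub-pixel fitting"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / NM_PER_UM

    @property
    def psf_sigma_um(self) -> float:
        return self.psf_sigma_nm / NM_PER_UM

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def evanescent_depth_um(self) -> float:
        return self.evanescent_depth_nm / NM_PER_UM

    @property
    def field_w_um(self) -> float:
        return self.field_w_px * self.pixel_size_um

    @property
    def field_h_um(self) -> float:
        return self.field_h_px * self.pixel_size_um

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class KineticParams:
    """Rate constants of the intermittent 3D/2D/1D targeting kinetics.

    ``D_cyto`` and ``D_mem`` are the cytosolic and membrane diffusion
    coefficients; ``f`` and ``g`` the membrane binding and detachment rates;
    ``v_directed`` the processive intrafilopodial speed.  Within a filopodium a
    molecule switches among directed, stalled and diffusive episodes with the
    (per-second) rates in ``filo_switch_rate``; only the directed speed and the
    population fractions are constrained by measurement, so the switch rates
    default to symmetric 1 /s transitions.
    """

    D_cyto: float = 5.0
    D_mem: float = 0.2
    f: float = 2.5
    g: float = 0.1
    v_directed: float = 1.4
    D_filo_diffusive: float = 0.2
    filo_switch_rate: float = 1.0
    filo_entry_rate: float = 5.0
    tip_escape_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f", "g", "filo_switch_rate", "filo_entry_rate",
                     "tip_escape_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("D_cyto", "D_mem", "D_filo_diffusive", "v_directed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.D_mem < self.D_cyto:
            raise ValueError("expected D_mem < D_cyto")


@dataclass
class Filopodium:
    """A filopodium: an axis polyline from root (first vertex) to tip (last).

    ``shaft_radius_nm`` is the half-width of the transverse confinement; the
    default reproduces a 116.5 nm full shaft diameter.
    """

    axis_um: np.ndarray  # (N, 2) polyline, root -> tip
    shaft_radius_nm: float = 58.25

    def __post_init__(self) -> None:
        self.axis_um = np.asarray(self.axis_um, dtype=float)
        if self.axis_um.ndim != 2 or self.axis_um.shape[0] < 2 or self.axis_um.shape[1] != 2:
            raise ValueError("axis_um must be an (N>=2, 2) polyline")
        if self.shaft_radius_nm <= 0:
            raise ValueError("shaft_radius_nm must be > 0")
        seg = np.diff(self.axis_um, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(self._seg_len <= 0):
            raise ValueError("degenerate axis segment")
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])

    @property
    def root_um(self) -> np.ndarray:
        return self.axis_um[0]

    @property
    def tip_um(self) -> np.ndarray:
        return self.axis_um[-1]

    @property
    def length_um(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at arc length ``s`` (clamped to [0, length])."""
        s = float(np.clip(s, 0.0, self.length_um))
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self._seg_len) - 1)
        frac = (s - self._cum[i]) / self._seg_len[i]
        return self.axis_um[i] + frac * (self.axis_um[i + 1] - self.axis_um[i])

    def normal_at(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length_um))
        i = int(np.searchsorted(self._cum, s, side="right") - 1)
        i = min(i, len(self._seg_len) - 1)
        t = (self.axis_um[i + 1] - self.axis_um[i]) / self._seg_len[i]
        return np.array([-t[1], t[0]])


@dataclass
class CellGeometry:
    """Simplified cell footprint: a membrane region at z=0 with filopodia.

    ``membrane_mask`` is an optional boolean grid aligned with the camera
    pixels (True where the basal membrane is available for binding); ``None``
    means the whole field.  ``cytosol_height_um`` bounds the 3D diffusion in z.
    """

    width_um: float
    height_um: float
    filopodia: list = field(default_factory=list)
    membrane_mask: Optional[np.ndarray] = None
    cytosol_height_um: float = 3.0
    root_radius_um: float = 0.5

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("cell extents must be positive")
        if self.cytosol_height_um <= 0:
            raise ValueError("cytosol_height_um must be positive")
        for f in self.filopodia:
            if not isinstance(f, Filopodium):
                raise TypeError("filopodia entries must be Filopodium")

    def in_membrane(self, x: float, y: float, pixel_size_um: float = 0.1) -> bool:
        if self.membrane_mask is None:
            return 0.0 <= x <= self.width_um and 0.0 <= y <= self.height_um
        j = int(x / pixel_size_um)
        i = int(y / pixel_size_um)
        h, w = self.membrane_mask.shape
        if 0 <= i < h and 0 <= j < w:
            return bool(self.membrane_mask[i, j])
        return False
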