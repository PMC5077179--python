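"""Ground-truth trajectory simulation for the intermittent 3D/2D/1D search.

A molecule alternates between rapid 3D diffusion in the cytosol, slower 2D
diffusion on the basal plasma membrane (binding with effective rate ``f`` when
it comes within one sub-step diffusion length of the membrane plane, detaching
with rate ``g``) and, once it enters a filopodium through its root region, 1D
motion along the filopodial axis consisting of directed, stalled and diffusive
episodes.  Reaching the end of the axis traps the molecule at the tip, where it
jitters within roughly one PSF width, optionally escaping back into the shaft.

State switching uses exponential waiting times discretised on a kinetic
sub-step of one tenth of a frame interval; displacement steps are Gaussian with
per-axis variance 2*D*dt in the active dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import SimConfig, KineticParams, CellGeometry, Filopodium

# Kinetic states -----------------------------------------------------------
CYTO3D = "CYTO3D"
MEM2D = "MEM2D"
FILO_DIRECTED = "FILO_DIRECTED"
FILO_STALLED = "FILO_STALLED"
FILO_DIFFUSIVE = "FILO_DIFFUSIVE"
TIP = "TIP"
BLEACHED = "BLEACHED"

FILO_STATES = (FILO_DIRECTED, FILO_STALLED, FILO_DIFFUSIVE)

N_SUBSTEPS = 10  # kinetic sub-steps per frame interval
MAX_SWITCH_PROB = 1.0  # refuse rates whose per-sub-step probability exceeds this


@dataclass
class GroundTruthTrajectory:
    """Per-frame (and per-sub-step) true position and kinetic state.

    ``t``, ``xyz`` and ``state`` are sampled at frame boundaries; the
    sub-step-resolution path (``t_sub``, ``xyz_sub``) is retained so the
    renderer can reproduce motion blur within the camera exposure.
    """

    molecule_id: int
    t: np.ndarray  # (F,) seconds
    xyz: np.ndarray  # (F, 3) micrometres
    state: np.ndarray  # (F,) object array of state names
    t_sub: np.ndarray | None = None
    xyz_sub: np.ndarray | None = None
    state_sub: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "frame": np.arange(self.n_frames),
                "t_s": self.t,
                "x_um": self.xyz[:, 0],
                "y_um": self.xyz[:, 1],
                "z_um": self.xyz[:, 2],
                "state": self.state,
            }
        )


def trajectories_to_frame(trajectories) -> pd.DataFrame:
    if not trajectories:
        return pd.DataFrame(
            columns=["molecule_id", "frame", "t_s", "x_um", "y_um", "z_um", "state"]
        )
    return pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True)


def _check_rates(kinetics: KineticParams, dt_sub: float) -> None:
    worst = max(
        kinetics.f,
        kinetics.g,
        2 * kinetics.filo_switch_rate,  # competing exits from one filo state
        kinetics.filo_entry_rate,
        kinetics.tip_escape_rate,
    )
    if worst * dt_sub > MAX_SWITCH_PROB:
        raise ValueError(
            f"switching probability {worst * dt_sub:.2f} per sub-step exceeds 1; "
            "use a finer frame interval / sub-step"
        )


def simulate_trajectories(
    kinetics: KineticParams,
    geometry: CellGeometry,
    config: SimConfig,
    duration_s: float,
    n_molecules: int,
    seed: int = 0,
    initial_state: str | None = None,
) -> list[GroundTruthTrajectory]:
    """Simulate ``n_molecules`` through the 3D/2D/1D kinetic state machine.

    ``initial_state`` forces the starting state (e.g. ``MEM2D`` for a pure
    membrane ensemble); by default molecules start in the cytosol at uniform
    random positions.  Fixed seed gives bit-identical output.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    n_frames = int(round(duration_s / config.frame_interval_s))
    if n_frames == 0 or n_molecules == 0:
        return []

    dt = config.frame_interval_s / N_SUBSTEPS
    _check_rates(kinetics, dt)
    rng = np.random.default_rng(seed)
    capture_um = np.sqrt(2.0 * kinetics.D_cyto * dt)

    out = []
    for mid in range(n_molecules):
        out.append(
            _simulate_one(mid, kinetics, geometry, config, n_frames, dt, rng,
                          capture_um, initial_state)
        )
    return out


def _switch(rng, rate, dt) -> bool:
    return rate > 0 and rng.random() < -np.expm1(-rate * dt)


def _simulate_one(mid, kin, geom, cfg, n_frames, dt, rng, capture_um,
                  initial_state) -> GroundTruthTrajectory:
    n_sub = n_frames * N_SUBSTEPS
    t_sub = np.arange(n_sub + 1) * dt
    xyz = np.empty((n_sub + 1, 3))
    states = np.empty(n_sub + 1, dtype=object)

    state = initial_state or CYTO3D
    x = rng.uniform(0, geom.width_um)
    y = rng.uniform(0, geom.height_um)
    z = rng.uniform(0, geom.cytosol_height_um) if state == CYTO3D else 0.0
    filo: Filopodium | None = None
    s_arc = 0.0
    if state in FILO_STATES or state == TIP:
        filo = geom.filopodia[0]
        x, y = filo.point_at(s_arc)

    sd_cyto = np.sqrt(2.0 * kin.D_cyto * dt)
    sd_mem = np.sqrt(2.0 * kin.D_mem * dt)
    sd_filo = np.sqrt(2.0 * kin.D_filo_diffusive * dt)
    tip_halfwidth = cfg.psf_sigma_um

    xyz[0] = (x, y, z)
    states[0] = state

    for k in range(1, n_sub + 1):
        if state == CYTO3D:
            dx, dy, dz = rng.normal(0.0, sd_cyto, size=3)
            x = _reflect(x + dx, 0.0, geom.width_um)
            y = _reflect(y + dy, 0.0, geom.height_um)
            z = _reflect(z + dz, 0.0, geom.cytosol_height_um)
            if z < capture_um and geom.in_membrane(x, y, cfg.pixel_size_um):
                if _switch(rng, kin.f, dt):
                    state, z = MEM2D, 0.0
        elif state == MEM2D:
            dx, dy = rng.normal(0.0, sd_mem, size=2)
            x = _reflect(x + dx, 0.0, geom.width_um)
            y = _reflect(y + dy, 0.0, geom.height_um)
            if _switch(rng, kin.g, dt):
                state = CYTO3D
            else:
                for fp in geom.filopodia:
                    r = np.hypot(x - fp.root_um[0], y - fp.root_um[1])
                    if r < geom.root_radius_um and _switch(rng, kin.filo_entry_rate, dt):
                        state, filo, s_arc = FILO_DIRECTED, fp, 0.0
                        x, y = fp.point_at(s_arc)
                        break
        elif state in FILO_STATES:
            if state == FILO_DIRECTED:
                s_arc += kin.v_directed * dt
            elif state == FILO_DIFFUSIVE:
                s_arc += rng.normal(0.0, sd_filo)
            if s_arc < 0.0:
                s_arc = -s_arc
            if s_arc >= filo.length_um:
                s_arc = filo.length_um
                state = TIP
            elif _switch(rng, 2.0 * kin.filo_switch_rate, dt):
                others = [s for s in FILO_STATES if s != state]
                state = others[rng.integers(len(others))]
            x, y = _filo_position(filo, s_arc, rng)
        elif state == TIP:
            lo = max(0.0, filo.length_um - tip_halfwidth)
            s_arc = _reflect(s_arc + rng.normal(0.0, sd_mem), lo, filo.length_um)
            if kin.tip_escape_rate > 0 and _switch(rng, kin.tip_escape_rate, dt):
                state = FILO_DIFFUSIVE
            x, y = _filo_position(filo, s_arc, rng)
        xyz[k] = (x, y, z)
        states[k] = state

    frame_idx = np.arange(n_frames) * N_SUBSTEPS
    return GroundTruthTrajectory(
        molecule_id=mid,
        t=t_sub[frame_idx],
        xyz=xyz[frame_idx],
        state=states[frame_idx],
        t_sub=t_sub,
        xyz_sub=xyz,
        state_sub=states,
    )


def _filo_position(filo: Filopodium, s_arc: float, rng) -> tuple[float, float]:
    p = filo.point_at(s_arc)
    n = filo.normal_at(s_arc)
    # transverse confinement: Gaussian whose FWHM equals the shaft diameter
    sigma_t = 2.0 * filo.shaft_radius_nm / 2.3548 / 1000.0
    off = rng.normal(0.0, sigma_t)
    off = float(np.clip(off, -3 * sigma_t, 3 * sigma_t))
    return p[0] + off * n[0], p[1] + off * n[1]


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return v + lo


def apply_photobleaching(trajectories, bleach_rate_per_s: float, seed: int = 0):
    """Terminate each molecule's emission at an exponential random time.

    Emission stops in a single step: all frames at or after the bleach time
    are relabelled ``BLEACHED`` (the renderer emits no photons for them).
    """
    if bleach_rate_per_s < 0:
        raise ValueError("bleach_rate_per_s must be >= 0")
    if bleach_rate_per_s == 0:
        return [replace(tr) for tr in trajectories]
    rng = np.random.default_rng(seed)
    out = []
    for tr in trajectories:
        t_bleach = rng.exponential(1.0 / bleach_rate_per_s)
        state = tr.state.copy()
        state[tr.t >= t_bleach] = BLEACHED
        state_sub = None
        if tr.state_sub is not None:
            state_sub = tr.state_sub.copy()
            state_sub[tr.t_sub >= t_bleach] = BLEACHED
        out.append(replace(tr, state=state, state_sub=state_sub))
    return out


# -- direct generators used by the estimator benchmarks --------------------

def brownian_track_2d(D: float, n_frames: int, frame_interval_s: float,
                      rng, origin=(0.0, 0.0)) -> np.ndarray:
    """A plain 2D Brownian track (n_frames, 2) in um; per-axis var 2*D*dt."""
    steps = rng.normal(0.0, np.sqrt(2.0 * D * frame_interval_s), size=(n_frames - 1, 2))
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return pos + np.asarray(origin)


def uniform_2d_ensemble(D: float, n_molecules: int, n_frames: int,
                        config: SimConfig, rng) -> list[GroundTruthTrajectory]:
    """Uniformly seeded in-plane diffusers with reflecting field boundaries.

    The fast path behind the tau->D autocorrelation calibration: membrane-like
    emitters at z=0 covering the field at a controlled density.
    """
    w, h = config.field_w_um, config.field_h_um
    dt = config.frame_interval_s
    out = []
    for mid in range(n_molecules):
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, 2)) if D > 0 \
            else np.zeros((n_frames - 1, 2))
        pos = np.vstack([rng.uniform([0, 0], [w, h]), steps]).cumsum(axis=0)
        pos[:, 0] = [_reflect(v, 0.0, w) for v in pos[:, 0]]
        pos[:, 1] = [_reflect(v, 0.0, h) for v in pos[:, 1]]
        t = np.arange(n_frames) * dt
        xyz = np.column_stack([pos, np.zeros(n_frames)])
        state = np.full(n_frames, MEM2D, dtype=object)
        out.append(GroundTruthTrajectory(mid, t, xyz, state))
    return out


def directed_filopodial_run(filo: Filopodium, v_um_s: float, n_frames: int,
                            config: SimConfig, rng, s0_um: float = 0.0,
                            molecule_id: int = 0) -> GroundTruthTrajectory:
    """A single processive run along a filopodial axis at constant speed."""
    dt = config.frame_interval_s
    t = np.arange(n_frames) * dt
    s = np.minimum(s0_um + v_um_s * t, filo.length_um)
    xy = np.array([filo.point_at(si) for si in s])
    xyz = np.column_stack([xy, np.zeros(n_frames)])
    state = np.where(s < filo.length_um, FILO_DIRECTED, TIP).astype(object)
    return GroundTruthTrajectory(molecule_id, t, xyz, state)
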