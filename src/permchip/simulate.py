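"""Forward model: membrane-limited diffusion into a gel, rendered as camera frames.

The physical picture is the two-channel device: at injection the media
channel (lumen) fills with fluorescent tracer over a short ramp and is then
held at constant concentration (the feed reservoir is ~µL, the gel ~nL, so
lumen depletion is negligible). Tracer crosses the endothelial monolayer,
modeled as a zero-thickness membrane with flux

    J = P_d · (C_lumen − C_gel(0⁺, t))        [Robin boundary condition]

and then diffuses freely in the fibrin gel (coefficient D_gel) toward the
device midline, where symmetry with the opposite channel imposes zero flux.
The transverse direction is treated as independent 1-D columns (the
measured quantities are gap-wise averages, and focal leaks are injected as
a locally elevated P_d over a sub-segment of one gap).

Rendering maps concentration to expected camera counts
(``photon_gain·C + offset``) and adds EMCCD-like shot + read noise:
``Poisson(gain·C) + offset + N(0, read_noise_sd)``, clipped at zero.

The closed-form half-space solution (:func:`robin_halfspace_solution`) is
the analytic oracle against which the finite-difference solver is verified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from scipy.constants import k as BOLTZMANN_K
from scipy.special import erfc, erfcx

from .image_io import ImageStack
from .roi import DeviceGeometry

__all__ = [
    "LeakSpec",
    "NoiseModel",
    "SimulationConfig",
    "DiffusionField",
    "SyntheticTruth",
    "stokes_einstein_D",
    "robin_halfspace_solution",
    "solve_diffusion",
    "render_stack",
    "inject_focal_leak",
    "simulate_device",
]

CM_PER_UM = 1e-4
UM2_PER_CM2 = 1e8


def stokes_einstein_D(d_H: float, temperature: float = 310.15, viscosity: float = 6.9e-4) -> float:
    """Stokes–Einstein diffusivity of a sphere, in cm²/s.

    Parameters
    ----------
    d_H : float
        Hydrodynamic diameter in nm.
    temperature : float
        Absolute temperature in K (default: incubator, 37 °C).
    viscosity : float
        Dynamic viscosity of the solvent in Pa·s (default: water at 37 °C).
    """
    if not (d_H > 0 and temperature > 0 and viscosity > 0):
        raise ValueError("d_H, temperature and viscosity must all be > 0")
    d_m = d_H * 1e-9
    D_m2_s = BOLTZMANN_K * temperature / (3.0 * math.pi * viscosity * d_m)
    return D_m2_s * 1e4  # m²/s → cm²/s


def robin_halfspace_solution(
    y: np.ndarray,
    t: float,
    D: float,
    Pd: float,
    C0: float = 1.0,
) -> np.ndarray:
    """Concentration in a semi-infinite gel behind a membrane, closed form.

    Initially empty half-space ``y > 0`` with surface resistance at ``y = 0``:
    ``−D ∂C/∂y = P_d (C0 − C(0, t))``, reservoir concentration ``C0`` applied
    as a step at ``t = 0``. With ``h = P_d / D``:

        C(y, t) = C0 [ erfc(u) − exp(h y + h² D t) · erfc(u + h √(D t)) ],
        u = y / (2 √(D t)).

    All arguments in consistent units (µm, s, µm²/s, µm/s). Evaluated with
    the scaled complementary error function for numerical stability.
    """
    y = np.asarray(y, dtype=float)
    if t <= 0:
        return np.zeros_like(y)
    h = Pd / D
    u = y / (2.0 * np.sqrt(D * t))
    s = h * np.sqrt(D * t)
    # exp(hy + h²Dt)·erfc(u+s) = exp(-u²)·erfcx(u+s)
    return C0 * (erfc(u) - np.exp(-np.square(u)) * erfcx(u + s))


@dataclass(frozen=True)
class LeakSpec:
    """A focal leak: locally elevated permeability over part of one gap."""

    gap_index: int = 0
    start_frac: float = 0.45
    width_frac: float = 0.10
    multiplier: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width_frac < 1.0:
            raise ValueError("width_frac must be in (0, 1)")
        if not 0.0 <= self.start_frac <= 1.0 - self.width_frac:
            raise ValueError("leak must lie within the gap")
        if not self.multiplier >= 1.0:
            raise ValueError("multiplier must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """EMCCD-like camera noise: shot noise on the signal plus read noise."""

    photon_gain: float = 500.0  # counts per concentration unit
    read_noise_sd: float = 20.0  # counts
    offset: float = 100.0  # counts

    def __post_init__(self) -> None:
        if self.photon_gain < 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SimulationConfig:
    """Ground-truth physics and imaging parameters for one synthetic device.

    Geometry defaults are the package's reference device: a 1300 µm central
    gel (half-width 650 µm to the symmetry midline) flanked by two media
    channels, monolayer exposed over three 120 µm post gaps, imaged at
    2 µm/px every 30 s.
    """

    Pd_true: float = 3.5e-5  # cm/s (untreated monolayer, 10 kDa dextran scale)
    D_gel: float = 1.0e-6  # cm²/s (~6 nm probe at 37 °C via Stokes–Einstein)
    C_lumen: float = 1.0  # arbitrary concentration units
    gel_half_width: float = 650.0  # µm, membrane to symmetry midline
    lumen_width: float = 120.0  # µm of channel rendered behind each monolayer
    n_monolayers: int = 2
    gap_width: float = 120.0  # µm, exposed monolayer between posts
    n_gaps: int = 3
    post_width: float = 60.0  # µm between gaps
    edge_width: float = 30.0  # µm of post at each end of the field of view
    grid_dx: float = 2.0  # µm, solver cell size
    pixel_size: float = 2.0  # µm/px, must be an integer multiple of grid_dx
    frame_interval: float = 30.0  # s
    duration: float = 1800.0  # s (30 min dextran-like; use 2700 for pNP-like)
    fill_time: float = 60.0  # s, lumen concentration ramp 0 → C_lumen
    n_pre_frames: int = 0  # blank frames prepended before injection
    noise: NoiseModel = field(default_factory=NoiseModel)
    leak: Optional[LeakSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        if isinstance(self.leak, dict):
            self.leak = LeakSpec(**self.leak)
        if self.Pd_true < 0:
            raise ValueError("Pd_true must be >= 0")
        if self.D_gel <= 0:
            raise ValueError("D_gel must be > 0")
        if self.n_monolayers not in (1, 2):
            raise ValueError("n_monolayers must be 1 or 2")
        if self.frame_interval <= 0 or self.duration < 2 * self.frame_interval:
            raise ValueError("need a positive frame interval and >= 2 frames")
        if self.pixel_size % self.grid_dx:
            raise ValueError("pixel_size must be an integer multiple of grid_dx")
        if self.leak is not None and not 0 <= self.leak.gap_index < self.n_gaps:
            raise ValueError("leak gap_index out of range")

    # -- derived quantities ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.n_pre_frames + int(self.duration // self.frame_interval) + 1

    @property
    def true_t0_frame(self) -> int:
        """First frame at/after the lumen is completely filled."""
        return self.n_pre_frames + math.ceil(self.fill_time / self.frame_interval)

    @property
    def Pd_um_s(self) -> float:
        return self.Pd_true / CM_PER_UM

    @property
    def D_um2_s(self) -> float:
        return self.D_gel * UM2_PER_CM2

    def lumen_concentration(self, t: float) -> float:
        """Lumen fill schedule: linear ramp over ``fill_time``, then constant."""
        if t <= 0:
            return 0.0
        if self.fill_time <= 0:
            return self.C_lumen
        return self.C_lumen * min(t / self.fill_time, 1.0)

    # -- pixel-space geometry ---------------------------------------------
    @property
    def lumen_px(self) -> int:
        return int(round(self.lumen_width / self.pixel_size))

    @property
    def gel_px(self) -> int:
        width = self.gel_half_width * self.n_monolayers
        return int(round(width / self.pixel_size))

    def gap_layout_px(self) -> list[tuple[int, int]]:
        """Half-open transverse pixel intervals of the post gaps."""
        px = self.pixel_size
        gaps = []
        pos = self.edge_width
        for _ in range(self.n_gaps):
            gaps.append((int(round(pos / px)), int(round((pos + self.gap_width) / px))))
            pos += self.gap_width + self.post_width
        return gaps

    @property
    def frame_width_px(self) -> int:
        total = 2 * self.edge_width + self.n_gaps * self.gap_width + (self.n_gaps - 1) * self.post_width
        return int(round(total / self.pixel_size))

    @property
    def frame_height_px(self) -> int:
        return self.gel_px + self.n_monolayers * self.lumen_px

    def device_geometry(self) -> DeviceGeometry:
        """Pixel-space geometry of the rendered frames (diffusion along rows)."""
        m1 = self.lumen_px
        gel_span = (m1, m1 + self.gel_px)
        positions = [m1]
        lumens = [(0, m1)]
        if self.n_monolayers == 2:
            m2 = gel_span[1] - 1
            positions.append(m2)
            lumens.append((gel_span[1], gel_span[1] + self.lumen_px))
        return DeviceGeometry(
            axis=0,
            monolayer_positions=positions,
            gel_span=gel_span,
            lumen_spans=lumens,
            post_gaps=self.gap_layout_px(),
            pixel_size=self.pixel_size,
        )

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class DiffusionField:
    """1-D solver output: gel concentration profile at each frame time.

    ``C[k, i]`` is the concentration in gel cell ``i`` (center ``y[i]`` µm
    from the membrane) at frame time ``times[k]`` (seconds from injection).
    ``C_lumen[k]`` is the lumen concentration, ``influx[k]`` the cumulative
    mass per unit membrane area that has crossed the membrane.
    """

    times: np.ndarray
    y: np.ndarray
    C: np.ndarray
    C_lumen: np.ndarray
    influx: np.ndarray
    dx: float

    def gel_mass(self) -> np.ndarray:
        """Mass per unit membrane area in the gel at each frame."""
        return self.C.sum(axis=1) * self.dx


def solve_diffusion(config: SimulationConfig, Pd_cm_s: Optional[float] = None) -> DiffusionField:
    """Explicit finite-volume solution of the lumen→membrane→gel transport.

    Domain: gel cells of width ``grid_dx`` from the membrane (y = 0) to the
    symmetry midline (y = gel_half_width), zero flux at the far end.
    Membrane flux ``J = P_d (C_lumen(t) − C₀)`` feeds the first cell. The
    internal time step is sub-stepped to satisfy the diffusion stability
    bound ``dt ≤ 0.4 dx²/D``.
    """
    Pd = (config.Pd_true if Pd_cm_s is None else Pd_cm_s) / CM_PER_UM  # µm/s
    D = config.D_um2_s
    dx = config.grid_dx
    n_cells = max(2, int(round(config.gel_half_width / dx)))
    dt_max = 0.4 * dx * dx / D
    n_sub = max(1, math.ceil(config.frame_interval / dt_max))
    dt = config.frame_interval / n_sub

    n_frames = int(config.duration // config.frame_interval) + 1
    times = np.arange(n_frames) * config.frame_interval
    C = np.zeros((n_frames, n_cells))
    C_lum = np.zeros(n_frames)
    influx = np.zeros(n_frames)

    c = np.zeros(n_cells)
    cum = 0.0
    t = 0.0
    r = D * dt / (dx * dx)
    for k in range(1, n_frames):
        for _ in range(n_sub):
            # midpoint lumen concentration over the sub-step (ramp is linear)
            clum = config.lumen_concentration(t + 0.5 * dt)
            J = Pd * (clum - c[0])  # µm·conc/s per unit area
            lap = np.empty_like(c)
            lap[1:-1] = c[2:] - 2.0 * c[1:-1] + c[:-2]
            lap[0] = c[1] - c[0]
            lap[-1] = c[-2] - c[-1]
            c += r * lap
            c[0] += dt / dx * J
            cum += J * dt
            t += dt
        np.clip(c, 0.0, None, out=c)
        C[k] = c
        C_lum[k] = config.lumen_concentration(t)
        influx[k] = cum
    return DiffusionField(times=times, y=(np.arange(n_cells) + 0.5) * dx, C=C, C_lumen=C_lum, influx=influx, dx=dx)


@dataclass
class SyntheticTruth:
    """A rendered synthetic device with its ground truth."""

    config: SimulationConfig
    stack: ImageStack
    noise_free_stack: ImageStack
    true_Pd: float
    true_t0_frame: int

    def truth_dict(self) -> dict:
        return {
            "true_Pd_cm_s": self.true_Pd,
            "true_t0_frame": self.true_t0_frame,
            "config": self.config.to_dict(),
        }


def _expected_frames(field: DiffusionField, config: SimulationConfig, leak_field: Optional[DiffusionField]) -> np.ndarray:
    """Noise-free expected counts, frame by frame (float64, without offset)."""
    gain = config.noise.photon_gain
    px_per_cell = int(round(config.pixel_size / config.grid_dx))
    n_frames_solved = field.C.shape[0]
    H, W = config.frame_height_px, config.frame_width_px
    gaps = config.gap_layout_px()

    def cell_to_px(profile: np.ndarray) -> np.ndarray:
        if px_per_cell == 1:
            prof = profile
        else:
            prof = profile.reshape(-1, px_per_cell).mean(axis=1)
        return prof[: config.gel_px // config.n_monolayers]

    out = np.zeros((config.n_pre_frames + n_frames_solved, H, W))
    m1 = config.lumen_px
    half_px = config.gel_px // config.n_monolayers
    leak = config.leak
    for k in range(n_frames_solved):
        img = out[config.n_pre_frames + k]
        clum = field.C_lumen[k]
        img[:m1, :] = gain * clum  # lumen band A spans the whole field of view
        base_prof = gain * cell_to_px(field.C[k])
        leak_prof = gain * cell_to_px(leak_field.C[k]) if leak_field is not None else None
        for gi, (g0, g1) in enumerate(gaps):
            cols = np.arange(g0, g1)
            prof = np.tile(base_prof[:, None], (1, cols.size))
            if leak is not None and leak_prof is not None and gi == leak.gap_index:
                w = g1 - g0
                l0 = g0 + int(round(leak.start_frac * w))
                l1 = l0 + max(1, int(round(leak.width_frac * w)))
                sel = (cols >= l0) & (cols < l1)
                prof[:, sel] = leak_prof[:, None]
            img[m1 : m1 + half_px, g0:g1] = prof
            if config.n_monolayers == 2:
                img[m1 + half_px : m1 + 2 * half_px, g0:g1] = prof[::-1]
        if config.n_monolayers == 2:
            img[m1 + config.gel_px :, :] = gain * clum  # lumen band B
    return out


def render_stack(
    field: DiffusionField,
    config: SimulationConfig,
    leak_field: Optional[DiffusionField] = None,
    seed: Optional[int] = None,
) -> SyntheticTruth:
    """Render a solved field into noisy and noise-free camera stacks.

    The noise-free stack is the pixelwise expectation of the noisy one
    (``gain·C + offset``); the noisy stack adds Poisson shot noise on the
    signal and Gaussian read noise, clipped at zero. Reproducible from
    ``seed`` (default: ``config.seed``).
    """
    if config.leak is not None and leak_field is None:
        raise ValueError("config declares a leak; pass the leak_field solved at the elevated P_d")
    expected_signal = _expected_frames(field, config, leak_field)
    offset = config.noise.offset
    noise_free = expected_signal + offset

    rng = np.random.default_rng(config.seed if seed is None else seed)
    noisy = rng.poisson(expected_signal).astype(np.float64) + offset
    if config.noise.read_noise_sd > 0:
        noisy += rng.normal(0.0, config.noise.read_noise_sd, size=noisy.shape)
    np.clip(noisy, 0.0, None, out=noisy)

    cal = dict(pixel_size=config.pixel_size, frame_interval=config.frame_interval)
    return SyntheticTruth(
        config=config,
        stack=ImageStack(frames=noisy.astype(np.float32), label="synthetic", **cal),
        noise_free_stack=ImageStack(frames=noise_free.astype(np.float32), label="synthetic noise-free", **cal),
        true_Pd=config.Pd_true,
        true_t0_frame=config.true_t0_frame,
    )


def inject_focal_leak(
    config: SimulationConfig,
    gap_index: int = 0,
    start_frac: float = 0.45,
    width_frac: float = 0.10,
    multiplier: float = 10.0,
) -> SimulationConfig:
    """Return a config with a focal leak over a sub-segment of one gap."""
    return replace(
        config,
        leak=LeakSpec(gap_index=gap_index, start_frac=start_frac, width_frac=width_frac, multiplier=multiplier),
    )


def simulate_device(config: SimulationConfig, seed: Optional[int] = None) -> SyntheticTruth:
    """Solve the transport problem and render one synthetic device.

    With a leak configured, the gap is split into independent 1-D columns:
    the leak sub-segment uses a second solve at ``multiplier × P_d`` (valid
    at early times, before transverse diffusion couples the columns).
    """
    base = solve_diffusion(config)
    leak_field = None
    if config.leak is not None:
        if config.leak.multiplier == 1.0:
            leak_field = base
        else:
            leak_field = solve_diffusion(config, Pd_cm_s=config.Pd_true * config.leak.multiplier)
    return render_stack(base, config, leak_field=leak_field, seed=seed)
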