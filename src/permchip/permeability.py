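"""P_d estimation from ROI traces: the measurement at the heart of the package.

For each ROI triple the per-frame, background-subtracted mean intensities
I_lumen(t), I_y=0(t) and I_ave,gel(t) are extracted. Once the lumen is
completely filled (frame t0), mass balance over the gel control volume of
area A_gel behind a monolayer of exposed width w_monolayer gives

    P_d = A_gel · (dI_ave,gel/dt) / (w_monolayer · ΔI),      ΔI = I_lumen − I_y=0,

with the derivative taken at t0 (channel height cancels between the gel
volume and the membrane area, so it never enters). A finite fit window is
unavoidable with 30-s frames, and over such a window ΔI itself decays as
the gel side of the membrane loads up. Because the instantaneous membrane
flux obeys J(t) = P_d·ΔC(t) at *every* time, integrating once gives the
exact finite-window identity

    I_ave,gel(t) = I_ave,gel(t0) + (w/A_gel) · P_d · ∫_{t0}^{t} ΔI dt′

as long as the gel region captures the diffusive front. The slope β of the
OLS regression of I_ave,gel on X(t) = ∫ΔI dt′ therefore estimates
P_d·w/A_gel without the early-saturation bias of a naive slope/ΔI(t0)
ratio, and reduces to it as the window shrinks to zero. The reported
``delta_I`` is the window-effective value ``slope/β`` (→ ΔI(t0) as the
window → 0), so ``P_d = A_gel·slope/(w·delta_I)`` holds exactly in every
output record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_io import BackgroundModel, ImageStack
from .roi import Rect, RoiTriple, mean_intensity

__all__ = [
    "IntensityTrace",
    "PdMeasurement",
    "MeasureConfig",
    "detect_t0",
    "extract_traces",
    "fit_initial_slope",
    "compute_pd",
    "detect_focal_leak",
    "measure_device",
    "measurements_to_frame",
]

CM_PER_UM = 1e-4


@dataclass
class IntensityTrace:
    """Per-frame ROI means for one data point, background-subtracted."""

    times: np.ndarray  # s from acquisition start, uniform spacing
    I_ave_gel: np.ndarray
    I_lumen: np.ndarray
    I_y0: np.ndarray
    t0_index: int

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.I_ave_gel) == len(self.I_lumen) == len(self.I_y0) == n):
            raise ValueError("trace arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def delta_I(self) -> np.ndarray:
        """Transmembrane intensity difference I_lumen − I_y=0 per frame."""
        return self.I_lumen - self.I_y0


@dataclass
class PdMeasurement:
    """One data point's permeability estimate with QC diagnostics.

    ``P_d = A_gel·slope/(w_monolayer·delta_I)`` (unit-converted to cm/s)
    holds exactly; ``delta_I`` is the fit-window effective transmembrane
    intensity difference (→ the t0 value for an instantaneous window).
    """

    slope: float  # d(I_ave,gel)/dt over the fit window, intensity/s
    delta_I: float  # effective I_lumen − I_y=0, intensity
    A_gel: float  # µm²
    w_monolayer: float  # µm
    P_d: float  # cm/s
    r_squared: float
    focal_leak: bool
    leak_score: float
    t0_index: int
    n_fit_frames: int
    triple_id: str = ""
    device_id: str = ""
    error: str = ""

    @property
    def ok(self) -> bool:
        return not self.error


@dataclass
class MeasureConfig:
    """Tunable parameters of the measurement pipeline."""

    fit_window: int = 10  # frames at/after t0 (5 min at 30 s)
    plateau_fraction: float = 0.95  # lumen-filling detection
    t0_index: Optional[int] = None  # explicit override of detection
    leak_window: int = 20  # frames after t0 for the leak profile (10 min)
    leak_threshold: float = 1.0
    r2_warn: float = 0.9
    device_id: str = ""


def detect_t0(I_lumen: np.ndarray, plateau_fraction: float = 0.95) -> int:
    """First frame at which the lumen is completely filled.

    The plateau level is the median of the top quartile of the lumen trace;
    t0 is the first frame reaching ``plateau_fraction`` of it.
    """
    I = np.asarray(I_lumen, dtype=float)
    if I.size < 2:
        raise ValueError("need at least 2 frames")
    top = np.sort(I)[-max(1, I.size // 4) :]
    plateau = float(np.median(top))
    if plateau <= 0:
        raise ValueError("lumen never fills: trace is zero")
    hits = np.nonzero(I >= plateau_fraction * plateau)[0]
    if hits.size == 0:
        raise ValueError("lumen never reaches the filling plateau")
    return int(hits[0])


def extract_traces(
    stack: ImageStack,
    triple: RoiTriple,
    background: Optional[BackgroundModel] = None,
    plateau_fraction: float = 0.95,
    t0_index: Optional[int] = None,
) -> IntensityTrace:
    """Per-frame background-subtracted ROI means for one triple."""
    n = stack.n_frames

    def series(region: Rect) -> np.ndarray:
        return np.array([mean_intensity(stack, region, k, background) for k in range(n)])

    I_lum = series(triple.lumen_region)
    I_gel = series(triple.gel_region)
    I_y0 = series(triple.interface_line)
    t0 = detect_t0(I_lum, plateau_fraction) if t0_index is None else int(t0_index)
    return IntensityTrace(times=stack.times, I_ave_gel=I_gel, I_lumen=I_lum, I_y0=I_y0, t0_index=t0)


def fit_initial_slope(trace: IntensityTrace, fit_window: int = 10) -> tuple[float, float]:
    """OLS slope of I_ave,gel vs time over [t0, t0 + fit_window), with r².

    This is the reported early-time rate of rise of the gel signal; the
    permeability estimate pairs it with the window-effective ΔI (see
    :func:`measure_triple`).
    """
    t, I = _window(trace, fit_window)
    slope, _ = _ols(t, I)
    return slope, _r_squared(t, I)


def _window(trace: IntensityTrace, fit_window: int) -> tuple[np.ndarray, np.ndarray]:
    if fit_window < 3:
        raise ValueError("fit_window must be >= 3 frames")
    k0, k1 = trace.t0_index, trace.t0_index + fit_window
    if k1 > len(trace.times):
        raise ValueError(
            f"fit window [{k0}, {k1}) exceeds the {len(trace.times)}-frame acquisition"
        )
    return trace.times[k0:k1], trace.I_ave_gel[k0:k1]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate regressor")
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    return b, ym - b * xm


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    b, a = _ols(x, y)
    ss_res = float(np.sum((y - (a + b * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def compute_pd(slope: float, delta_I: float, A_gel: float, w_monolayer: float) -> float:
    """P_d = A_gel·slope / (w_monolayer·ΔI), converted from µm/s to cm/s."""
    if delta_I <= 0:
        raise ValueError(
            "delta_I must be > 0 (non-positive values signal a saturated "
            "interface or mis-detected t0)"
        )
    if A_gel <= 0 or w_monolayer <= 0:
        raise ValueError("A_gel and w_monolayer must be > 0")
    return (A_gel * slope) / (w_monolayer * delta_I) * CM_PER_UM


def _effective_delta_I(trace: IntensityTrace, fit_window: int) -> tuple[float, float, float]:
    """Window slope, effective ΔI and r² for one trace.

    Regresses I_ave,gel on the running integral X(t) = ∫ΔI dt′ (trapezoid
    over the frames in the window); the regression slope β estimates
    P_d·w/A_gel exactly for membrane-limited uptake. Returns
    ``(slope, slope/β, r²)`` where ``slope`` is the plain OLS-vs-time
    slope, so that A·slope/(w·ΔI_eff) = (A/w)·β.
    """
    t, I = _window(trace, fit_window)
    k0, k1 = trace.t0_index, trace.t0_index + fit_window
    dI = trace.delta_I[k0:k1]
    X = np.concatenate([[0.0], np.cumsum(0.5 * (dI[1:] + dI[:-1]) * np.diff(t))])
    slope, _ = _ols(t, I)
    r2 = _r_squared(t, I)
    sxx = float(np.sum((X - X.mean()) ** 2))
    if sxx == 0:  # ΔI identically zero: no transmembrane gradient
        raise ValueError("delta_I vanishes over the fit window")
    beta, _ = _ols(X, I)
    if beta <= 0 or slope <= 0:
        # no measurable uptake: fall back to ΔI at t0 so the sign of the
        # (near-zero or negative) slope is preserved in P_d
        dI0 = float(trace.delta_I[k0])
        return slope, dI0, r2
    return slope, slope / beta, r2


def detect_focal_leak(
    stack: ImageStack,
    triple: RoiTriple,
    background: Optional[BackgroundModel] = None,
    t0_index: int = 0,
    window: int = 20,
    threshold: float = 1.0,
) -> tuple[bool, float]:
    """Flag localized bright plumes along the interface line.

    The spatial intensity profile along the interface line is averaged over
    ``window`` frames after t0; the leak score is (max − median)/median of
    that profile. A uniform monolayer scores ≈ 0; a focal leak produces a
    localized peak and a score above ``threshold``. A zero-median profile
    (no signal) scores +inf and is flagged for manual review.
    """
    k0 = t0_index
    k1 = min(stack.n_frames, k0 + window)
    if k1 - k0 < 2:
        raise ValueError("need at least 2 frames after t0 for leak detection")
    rs, cs = triple.interface_line.slices
    prof = np.zeros(triple.interface_line.n_pixels)
    for k in range(k0, k1):
        prof += stack.frames[k][rs, cs].astype(float).ravel()
    prof /= k1 - k0
    if background is not None:
        bg = background.value if background.mode == "scalar" else np.asarray(background.value)[rs, cs].ravel()
        prof = prof - bg
    med = float(np.median(prof))
    if med <= 0:
        return True, math.inf
    score = (float(prof.max()) - med) / med
    return bool(score > threshold), score


def measure_triple(
    stack: ImageStack,
    triple: RoiTriple,
    background: Optional[BackgroundModel] = None,
    config: Optional[MeasureConfig] = None,
) -> PdMeasurement:
    """Full per-data-point pipeline: traces → t0 → slope → P_d → QC."""
    cfg = config or MeasureConfig()
    trace = extract_traces(
        stack, triple, background, plateau_fraction=cfg.plateau_fraction, t0_index=cfg.t0_index
    )
    slope, dI_eff, r2 = _effective_delta_I(trace, cfg.fit_window)
    if slope > 0:
        pd_val = compute_pd(slope, dI_eff, triple.A_gel, triple.w_monolayer)
    else:  # zero/negative uptake: report the (non-positive) value as-is
        pd_val = (triple.A_gel * slope) / (triple.w_monolayer * max(dI_eff, 1e-300)) * CM_PER_UM
    flag, score = detect_focal_leak(
        stack,
        triple,
        background,
        t0_index=trace.t0_index,
        window=cfg.leak_window,
        threshold=cfg.leak_threshold,
    )
    return PdMeasurement(
        slope=slope,
        delta_I=dI_eff,
        A_gel=triple.A_gel,
        w_monolayer=triple.w_monolayer,
        P_d=pd_val,
        r_squared=r2,
        focal_leak=flag,
        leak_score=score,
        t0_index=trace.t0_index,
        n_fit_frames=cfg.fit_window,
        triple_id=triple.triple_id,
        device_id=cfg.device_id,
    )


def measure_device(
    stack: ImageStack,
    triples: Sequence[RoiTriple],
    background: Optional[BackgroundModel] = None,
    config: Optional[MeasureConfig] = None,
) -> list[PdMeasurement]:
    """One :class:`PdMeasurement` per triple; per-triple failures are recorded,
    not raised, so one bad ROI does not abort a device."""
    cfg = config or MeasureConfig()
    out = []
    for triple in triples:
        try:
            out.append(measure_triple(stack, triple, background, cfg))
        except (ValueError, IndexError) as exc:
            out.append(
                PdMeasurement(
                    slope=math.nan,
                    delta_I=math.nan,
                    A_gel=triple.A_gel,
                    w_monolayer=triple.w_monolayer,
                    P_d=math.nan,
                    r_squared=math.nan,
                    focal_leak=True,
                    leak_score=math.nan,
                    t0_index=-1,
                    n_fit_frames=cfg.fit_window,
                    triple_id=triple.triple_id,
                    device_id=cfg.device_id,
                    error=str(exc),
                )
            )
    return out


def measurements_to_frame(measurements: Sequence[PdMeasurement]) -> pd.DataFrame:
    """Tabulate measurements with the standard output column names."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "device_id": m.device_id,
                "triple_id": m.triple_id,
                "slope": m.slope,
                "delta_I": m.delta_I,
                "A_gel_um2": m.A_gel,
                "w_um": m.w_monolayer,
                "Pd_cm_s": m.P_d,
                "r2": m.r_squared,
                "focal_leak": m.focal_leak,
                "leak_score": m.leak_score,
                "t0_index": m.t0_index,
                "n_fit_frames": m.n_fit_frames,
                "error": m.error,
            }
        )
    return pd.DataFrame(rows)
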