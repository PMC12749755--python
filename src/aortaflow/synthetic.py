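"""Synthetic velocity-encoded phantoms and paired regurgitation cohorts.

Everything downstream of acquisition is testable against these generators:
aortic flow waveforms with controllable regurgitant volume/fraction and
reversal shape, rendered magnitude + phase image series with VENC wrapping,
planar eddy-current offsets and Gaussian velocity noise, and paired
patient cohorts drawn from a linear ascending-to-descending relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow import FlowCurve, encode_phase

__all__ = [
    "AcquisitionParams",
    "VesselSpec",
    "WaveformSpec",
    "PhantomTruth",
    "PhantomSeries",
    "CohortModel",
    "InfeasibleWaveformError",
    "COHORT_PRESETS",
    "build_waveform",
    "render_phantom",
    "simulate_cohort",
]

# Magnitude-image intensity levels (arbitrary units).
_LUMEN_MAGNITUDE = 1.0
_TISSUE_MAGNITUDE = 0.1
_AIR_MAGNITUDE = 0.02
_MAGNITUDE_NOISE_SD = 0.01
_AIR_BORDER_PX = 2
_SUPERSAMPLE = 4


class InfeasibleWaveformError(ValueError):
    """The requested waveform shape cannot satisfy its volume constraints."""


@dataclass
class AcquisitionParams:
    """Acquisition metadata for a rendered phantom series.

    ``offset_coeffs`` are the planar background-offset coefficients
    ``(c0, c_row, c_col)`` in cm/s and cm/s per pixel (0-based indices),
    applied to all tissue pixels before phase wrapping.
    """

    venc: float = 180.0
    n_phases: int = 40
    pixel_spacing: float = 2.5
    grid_size: int = 64
    rr_interval: float = 1000.0
    noise_sd: float = 0.0
    offset_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 90.0 <= self.venc <= 480.0:
            raise ValueError(f"venc must be in [90, 480] cm/s, got {self.venc}")
        if self.n_phases < 8:
            raise ValueError("n_phases must be >= 8")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def pixel_area(self) -> float:
        """Pixel area in mm^2."""
        return self.pixel_spacing**2

    @property
    def times_ms(self) -> np.ndarray:
        """Phase-centre trigger times in ms."""
        dt = self.rr_interval / self.n_phases
        return (np.arange(self.n_phases) + 0.5) * dt


@dataclass
class VesselSpec:
    """Circular vessel crossed by the image plane at a given angulation.

    The in-plane cross-section is an ellipse with semi-axes ``radius`` and
    ``radius / cos(angulation)``; the measured through-plane velocity is
    reduced by ``cos(angulation)``, leaving the integrated flow invariant.
    """

    center: tuple[float, float]  # (row, col) in pixels
    radius: float  # mm, orthogonal to flow
    angulation: float = 0.0  # degrees
    profile: str = "plug"

    def __post_init__(self) -> None:
        if not 0.0 <= self.angulation < 90.0:
            raise ValueError("angulation must be in [0, 90) degrees")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.profile not in ("plug", "parabolic"):
            raise ValueError("profile must be 'plug' or 'parabolic'")

    @property
    def cos_angle(self) -> float:
        return float(np.cos(np.deg2rad(self.angulation)))

    @property
    def lumen_area_mm2(self) -> float:
        """True lumen area orthogonal to flow, mm^2."""
        return float(np.pi * self.radius**2)


@dataclass
class WaveformSpec:
    """Ground-truth volumes and reversal shape of one cardiac cycle."""

    forward_volume: float  # mL per cycle
    rvol_true: float = 0.0  # mL, diastolic backward volume
    systolic_fraction: float = 0.35
    reversal_shape: str = "none"  # none | holodiastolic | early_only
    systolic_backward_volume: float = 0.0  # mL, <= 0

    def __post_init__(self) -> None:
        if self.forward_volume <= 0:
            raise ValueError("forward_volume must be positive")
        if self.rvol_true < 0:
            raise ValueError("rvol_true must be non-negative")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must be in (0, 1)")
        if self.reversal_shape not in ("none", "holodiastolic", "early_only"):
            raise ValueError(f"unknown reversal_shape {self.reversal_shape!r}")
        if self.systolic_backward_volume > 0:
            raise ValueError("systolic_backward_volume must be <= 0")
        if self.rf_true >= 100.0:
            raise ValueError("implied regurgitant fraction must be < 100%")

    @property
    def rf_true(self) -> float:
        """Implied regurgitant fraction, percent."""
        return 100.0 * self.rvol_true / self.forward_volume


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a rendered phantom."""

    waveform: WaveformSpec
    flow_curve: FlowCurve
    lumen_fraction: np.ndarray  # (ny, nx) lumen area fraction per pixel
    lumen_mask: np.ndarray  # fraction > 0 (any lumen signal)
    core_mask: np.ndarray  # fraction >= 0.5 (pixel centre inside lumen)
    static_mask: np.ndarray
    air_mask: np.ndarray
    hfr: bool
    dfr_velocity: float  # cm/s
    peak_velocity: float  # cm/s, max |pre-wrap tissue velocity|
    aliased: bool


@dataclass
class PhantomSeries:
    """Magnitude + velocity-encoded phase stacks with carried ground truth."""

    magnitude: np.ndarray
    phase: np.ndarray
    params: AcquisitionParams
    vessel: VesselSpec
    truth: PhantomTruth

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase stacks must share a shape")
        if np.any(self.phase > np.pi) or np.any(self.phase <= -np.pi):
            raise ValueError("phase values must lie in (-pi, pi]")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


@dataclass
class CohortModel:
    """Generative model for paired ascending/descending metric cohorts.

    ``x`` (ascending metric) is Normal(mean_x, sd_x) without truncation —
    draws are abstract metric values, so negatives are retained — and
    ``y = slope * x + intercept + Normal(0, resid_sd)``.
    """

    n: int
    mean_x: float
    sd_x: float
    slope: float
    intercept: float
    resid_sd: float
    metric_name: str = "RVol (mL)"

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("cohort size must be >= 3 (downstream fit undefined)")
        if self.sd_x <= 0:
            raise ValueError("sd_x must be positive")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")

    @property
    def population_r(self) -> float:
        """Population Pearson correlation implied by the model."""
        sy = np.hypot(self.slope * self.sd_x, self.resid_sd)
        return float(np.sign(self.slope) * abs(self.slope) * self.sd_x / sy)


#: Cohort-1 generative presets: printed moments and linear relations.
COHORT_PRESETS: dict[str, CohortModel] = {
    "cohort1-rvol": CohortModel(
        n=41, mean_x=61.0, sd_x=37.0, slope=0.59, intercept=-7.43,
        resid_sd=9.0, metric_name="RVol (mL)",
    ),
    "cohort1-rf": CohortModel(
        n=41, mean_x=38.0, sd_x=16.0, slope=1.01, intercept=-10.04,
        resid_sd=9.0, metric_name="RF (%)",
    ),
}


def _scale_to(samples: np.ndarray, dt_s: float, target: float) -> np.ndarray:
    """Scale a single-signed lobe so its Riemann sum equals ``target`` exactly."""
    total = samples.sum() * dt_s
    if total == 0.0:
        if target != 0.0:
            raise InfeasibleWaveformError("cannot scale an empty lobe to a nonzero volume")
        return samples
    return samples * (target / total)


def build_waveform(spec: WaveformSpec, params: AcquisitionParams) -> FlowCurve:
    """Construct a per-phase volumetric flow curve realising ``spec`` exactly.

    Systole is a half-sine forward pulse; the diastolic reversal lobe is
    shaped by ``spec.reversal_shape``:

    * ``none`` — zero diastolic flow (requires ``rvol_true == 0``);
    * ``early_only`` — half-sine reversal confined to the first half of
      diastole, returning to zero by mid-diastole;
    * ``holodiastolic`` — a reversal plateau never shallower than
      ``hfr_floor`` (10 mL/s, the holodiastolic detection floor) with the
      remaining volume distributed as a raised half-sine.

    Discrete positive/negative lobes are renormalised so their Riemann
    sums equal ``forward_volume``, ``rvol_true`` and
    ``systolic_backward_volume`` to machine precision.

    Raises
    ------
    InfeasibleWaveformError
        If the shape cannot realise the requested volumes (e.g. a
        holodiastolic plateau with ``rvol_true`` below the floor integral,
        or ``reversal_shape='none'`` with ``rvol_true > 0``).
    """
    hfr_floor = 10.0
    n = params.n_phases
    period_s = params.rr_interval / 1000.0
    dt = period_s / n
    t = (np.arange(n) + 0.5) * dt
    t_sys = spec.systolic_fraction * period_s

    flow = np.zeros(n)
    systole = t < t_sys
    diastole = ~systole
    if not systole.any() or not diastole.any():
        raise InfeasibleWaveformError("systolic_fraction leaves an empty phase interval")

    # Forward half-sine; an early-systolic window is carved out for the
    # complex-flow (systolic backward) lobe when one is requested.  The lobe
    # precedes the forward pulse so the end-systole boundary (first downward
    # zero crossing after the peak) stays at the true systolic fraction.
    t_fwd_start = 0.0 if spec.systolic_backward_volume == 0.0 else 0.15 * t_sys
    fwd = systole & (t >= t_fwd_start)
    if not fwd.any():
        raise InfeasibleWaveformError("no samples left for the forward pulse")
    flow[fwd] = np.sin(np.pi * (t[fwd] - t_fwd_start) / (t_sys - t_fwd_start))
    flow[fwd] = np.maximum(flow[fwd], 1e-9)  # keep the lobe strictly positive
    flow[fwd] = _scale_to(flow[fwd], dt, spec.forward_volume)

    if spec.systolic_backward_volume < 0.0:
        sbw = systole & (t < t_fwd_start)
        if not sbw.any():
            raise InfeasibleWaveformError(
                "no systolic samples available for the backward-flow lobe"
            )
        lobe = -np.sin(np.pi * t[sbw] / t_fwd_start)
        lobe = np.minimum(lobe, -1e-9)  # keep strictly negative before scaling
        flow[sbw] = _scale_to(lobe, dt, spec.systolic_backward_volume)

    t_dia = period_s - t_sys
    if spec.reversal_shape == "none":
        if spec.rvol_true > 0:
            raise InfeasibleWaveformError(
                "reversal_shape='none' is inconsistent with rvol_true > 0"
            )
    elif spec.reversal_shape == "early_only":
        early = diastole & (t < t_sys + 0.5 * t_dia)
        if spec.rvol_true > 0:
            lobe = -np.sin(np.pi * (t[early] - t_sys) / (0.5 * t_dia))
            lobe = np.minimum(lobe, 0.0)
            flow[early] = _scale_to(lobe, dt, -spec.rvol_true)
    else:  # holodiastolic
        n_dia = int(diastole.sum())
        floor_volume = hfr_floor * n_dia * dt
        extra = spec.rvol_true - floor_volume
        if extra < 0:
            raise InfeasibleWaveformError(
                f"holodiastolic reversal needs rvol_true >= {floor_volume:.2f} mL "
                f"to hold a {hfr_floor} mL/s floor over the whole diastole"
            )
        hump = np.sin(np.pi * (t[diastole] - t_sys) / t_dia)
        hump_sum = hump.sum() * dt
        flow[diastole] = -(hfr_floor + (extra / hump_sum) * hump if hump_sum > 0 else hfr_floor)

    return FlowCurve(flow=flow, times=params.times_ms)


def _elliptical_rho2(params: AcquisitionParams, vessel: VesselSpec) -> np.ndarray:
    """Supersampled squared elliptical radius, shape (ny, nx, ss*ss)."""
    g, ss = params.grid_size, _SUPERSAMPLE
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    rows = np.arange(g)[:, None, None, None] + sub[None, None, :, None]
    cols = np.arange(g)[None, :, None, None] + sub[None, None, None, :]
    a = vessel.radius / params.pixel_spacing  # semi-axis along columns, px
    b = a / vessel.cos_angle  # elongated semi-axis along rows, px
    cr, cc = vessel.center
    rho2 = ((rows - cr) / b) ** 2 + ((cols - cc) / a) ** 2
    return rho2.reshape(g, g, ss * ss)


def render_phantom(
    waveform: FlowCurve,
    vessel: VesselSpec,
    params: AcquisitionParams,
    waveform_spec: WaveformSpec | None = None,
) -> PhantomSeries:
    """Render a magnitude + phase series realising a flow waveform.

    The through-plane velocity inside the lumen follows the vessel profile,
    scaled so the lumen-integrated flow equals the waveform at every phase:
    angulation reduces velocity by ``cos(theta)`` while the elliptical
    cross-section grows by ``1 / cos(theta)``.  Boundary pixels are
    area-weighted (partial volume).  The phase image is
    ``wrap(pi * v / venc)`` with the planar background offset added before
    wrapping; Gaussian velocity noise is added inside tissue, and air
    border pixels get low magnitude with uniform-random phase.

    If the peak pre-wrap velocity reaches VENC the series is still rendered
    but flagged ``aliased=True`` in the truth record.
    """
    if waveform.n_phases != params.n_phases:
        raise ValueError("waveform length must equal n_phases")
    g = params.grid_size
    rng = np.random.default_rng(params.seed)

    rho2 = _elliptical_rho2(params, vessel)
    inside = rho2 < 1.0
    frac = inside.mean(axis=2)
    if vessel.profile == "plug":
        shape_weight = frac
    else:  # parabolic: v(rho) = 2 * v_mean * (1 - rho^2)
        shape_weight = np.mean(2.0 * (1.0 - rho2) * inside, axis=2)

    lumen_mask = frac > 0.0
    core_mask = frac >= 0.5
    border = np.zeros((g, g), dtype=bool)
    border[:_AIR_BORDER_PX, :] = border[-_AIR_BORDER_PX:, :] = True
    border[:, :_AIR_BORDER_PX] = border[:, -_AIR_BORDER_PX:] = True
    air_mask = border & ~lumen_mask
    static_mask = ~lumen_mask & ~air_mask
    tissue_mask = ~air_mask

    # Mean measured (through-plane) lumen velocity per phase, cm/s:
    # v_mean = 100 * Q * cos(theta) / (pi r^2)  [Q in mL/s, r in mm].
    v_mean = 100.0 * waveform.flow * vessel.cos_angle / vessel.lumen_area_mm2
    velocity = v_mean[:, None, None] * shape_weight[None, :, :]

    c0, c_row, c_col = params.offset_coeffs
    rows, cols = np.mgrid[0:g, 0:g]
    offset_plane = c0 + c_row * rows + c_col * cols
    velocity = velocity + offset_plane[None, :, :]
    velocity[:, air_mask] = 0.0

    peak_velocity = float(np.max(np.abs(velocity[:, tissue_mask]))) if tissue_mask.any() else 0.0
    aliased = peak_velocity >= params.venc

    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=velocity.shape)
        noise[:, air_mask] = 0.0
        velocity = velocity + noise

    phase = np.asarray(encode_phase(velocity, params.venc))
    n_air = int(air_mask.sum())
    if n_air:
        # uniform phase in (-pi, pi]
        air_phase = np.pi - rng.uniform(0.0, 2.0 * np.pi, size=(params.n_phases, n_air))
        phase[:, air_mask] = air_phase

    magnitude_2d = frac * _LUMEN_MAGNITUDE + (1.0 - frac) * _TISSUE_MAGNITUDE
    magnitude_2d[air_mask] = _AIR_MAGNITUDE
    magnitude = np.broadcast_to(magnitude_2d, phase.shape).copy()
    magnitude += rng.normal(0.0, _MAGNITUDE_NOISE_SD, size=magnitude.shape)
    np.clip(magnitude, 0.0, None, out=magnitude)

    dt_s = params.rr_interval / 1000.0 / params.n_phases
    t_sys = (waveform_spec.systolic_fraction if waveform_spec else 0.35) * (
        params.rr_interval / 1000.0
    )
    t = (np.arange(params.n_phases) + 0.5) * dt_s
    diastolic = t >= t_sys
    hfr = bool(diastolic.any() and np.all(waveform.flow[diastolic] <= -10.0))
    dfr_velocity = float(max(0.0, -v_mean[-1]))

    truth = PhantomTruth(
        waveform=waveform_spec
        if waveform_spec is not None
        else WaveformSpec(forward_volume=max(waveform.flow.sum() * dt_s, 1e-9)),
        flow_curve=waveform,
        lumen_fraction=frac,
        lumen_mask=lumen_mask,
        core_mask=core_mask,
        static_mask=static_mask,
        air_mask=air_mask,
        hfr=hfr,
        dfr_velocity=dfr_velocity,
        peak_velocity=peak_velocity,
        aliased=aliased,
    )
    return PhantomSeries(
        magnitude=magnitude, phase=phase, params=params, vessel=vessel, truth=truth
    )


def simulate_cohort(
    model: CohortModel,
    seed: int,
    repeat_sd: float | None = None,
) -> pd.DataFrame:
    """Draw a paired cohort table from a linear generative model.

    Returns a DataFrame with columns ``patient_id``, ``x_aao`` (ascending
    metric) and ``y_da`` (descending metric); when ``repeat_sd`` is given,
    repeat measurements ``x_aao_repeat`` / ``y_da_repeat`` (the same true
    value plus independent Normal(0, repeat_sd) noise) are appended.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(model.mean_x, model.sd_x, size=model.n)
    y = model.slope * x + model.intercept + rng.normal(0.0, model.resid_sd, size=model.n)
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(model.n)],
            "x_aao": x,
            "y_da": y,
        }
    )
    if repeat_sd is not None:
        if repeat_sd < 0:
            raise ValueError("repeat_sd must be non-negative")
        table["x_aao_repeat"] = x + rng.normal(0.0, repeat_sd, size=model.n)
        table["y_da_repeat"] = y + rng.normal(0.0, repeat_sd, size=model.n)
    return table
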