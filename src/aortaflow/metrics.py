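"""Per-patient regurgitation metrics from a volumetric flow curve.

Implements regurgitant volume (RVol, the diastolic backward flow volume in
mL), regurgitant fraction (RF, RVol as a percentage of the positive flow
volume), the systolic backward flow volume (complex-flow surrogate),
holodiastolic flow reversal (HFR) detection, diastolic flow-reversal (DFR)
velocity, strict-threshold severity calls and test–retest reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .flow import FlowCurve, RoiMaskSeries, VelocitySeries

__all__ = [
    "CardiacPhaseSplit",
    "RegurgitationMetrics",
    "SeverityThresholds",
    "SeverityCall",
    "NoForwardEjectionError",
    "PhaseSplitWarning",
    "split_phases",
    "compute_metrics",
    "detect_hfr",
    "compute_dfr_velocity",
    "classify_severity",
    "reproducibility_pct",
]

#: Reversal-flow floor for holodiastolic flow reversal, mL/s.
HFR_FLOW_FLOOR_ML_S = 10.0
#: DFR velocity cut-off for predicting severe regurgitation, cm/s.
DFR_VELOCITY_THRESHOLD_CM_S = 19.5


class NoForwardEjectionError(ValueError):
    """Flow curve has no positive peak; systole cannot be located."""


class PhaseSplitWarning(UserWarning):
    """A fallback rule was used to locate end-systole."""


@dataclass
class CardiacPhaseSplit:
    """Systole/diastole boundary: systole is ``[0, end_systole_index)``."""

    end_systole_index: int
    n_phases: int
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.end_systole_index < self.n_phases:
            raise ValueError("end_systole_index must split the cycle non-trivially")

    @property
    def systole(self) -> slice:
        return slice(0, self.end_systole_index)

    @property
    def diastole(self) -> slice:
        return slice(self.end_systole_index, self.n_phases)


@dataclass
class RegurgitationMetrics:
    """Regurgitation metrics for one site of one patient."""

    rvol: float  # mL
    rf: float  # %
    forward_volume: float  # mL
    systolic_backward_volume: float  # mL, <= 0
    hfr: bool
    dfr_velocity: float | None  # cm/s; None when no velocity data supplied
    site: str = "ascending"

    def __post_init__(self) -> None:
        if self.rvol < 0:
            raise ValueError("rvol must be non-negative")
        if self.systolic_backward_volume > 1e-12:
            raise ValueError("systolic_backward_volume must be <= 0")
        if self.site not in ("ascending", "descending"):
            raise ValueError("site must be 'ascending' or 'descending'")


@dataclass
class SeverityThresholds:
    """Strict-'>' severity cut-offs at both measurement sites."""

    reference_rvol: float = 42.0  # mL, ascending aorta
    reference_rf: float = 33.0  # %, ascending aorta
    da_rvol: float = 17.0  # mL, descending aorta
    da_rf: float = 23.0  # %, descending aorta
    dfr_velocity: float = DFR_VELOCITY_THRESHOLD_CM_S  # cm/s
    hfr_floor: float = HFR_FLOW_FLOOR_ML_S  # mL/s
    diameter_dilated: float = 40.0  # mm, '>=' convention

    def __post_init__(self) -> None:
        for name in ("reference_rvol", "reference_rf", "da_rvol", "da_rf",
                     "dfr_velocity", "hfr_floor", "diameter_dilated"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SeverityCall:
    """Per-patient severity flags; thresholds applied strictly ('>')."""

    significant_aao: bool | None
    significant_da_rvol: bool | None
    significant_da_rf: bool | None
    dfr_positive: bool | None
    hfr_positive: bool | None
    diameter_class: str | None  # 'normal' | 'dilated'


def split_phases(curve: FlowCurve) -> CardiacPhaseSplit:
    """Locate end-systole on a flow curve.

    End-systole is the first downward zero crossing after the global
    maximum.  If the curve never crosses zero, the first phase after the
    maximum with flow below 10% of the peak is used; failing that, the
    phase at 40% of the cycle — both fallbacks emit a
    :class:`PhaseSplitWarning`.
    """
    flow = curve.flow
    n = flow.size
    peak_idx = int(np.argmax(flow))
    if flow[peak_idx] <= 0:
        raise NoForwardEjectionError("flow curve has no positive peak (no forward ejection)")

    after = np.arange(peak_idx + 1, n)
    crossing = after[flow[after] <= 0.0]
    if crossing.size:
        return CardiacPhaseSplit(end_systole_index=int(crossing[0]), n_phases=n)

    below = after[flow[after] < 0.1 * flow[peak_idx]]
    if below.size:
        warnings.warn(
            "no downward zero crossing after peak; using 10%-of-peak fallback",
            PhaseSplitWarning, stacklevel=2,
        )
        return CardiacPhaseSplit(end_systole_index=int(below[0]), n_phases=n, fallback_used=True)

    warnings.warn(
        "no zero crossing or sub-10% phase after peak; splitting at 40% of cycle",
        PhaseSplitWarning, stacklevel=2,
    )
    idx = min(max(int(round(0.4 * n)), 1), n - 1)
    return CardiacPhaseSplit(end_systole_index=idx, n_phases=n, fallback_used=True)


def compute_metrics(
    curve: FlowCurve,
    split: CardiacPhaseSplit,
    dfr_velocity: float | None = None,
) -> RegurgitationMetrics:
    """Compute RVol, RF and the systolic backward volume from a flow curve.

    ``rvol = |sum_diastole min(Q, 0) * dt|``, ``forward_volume =
    sum_cycle max(Q, 0) * dt`` and ``rf = 100 * rvol / forward_volume``,
    with the uniform phase duration ``dt`` taken from the curve's times.
    """
    if split.n_phases != curve.n_phases:
        raise ValueError("split does not match curve length")
    dt = curve.dt_s
    flow = curve.flow
    forward = float(np.maximum(flow, 0.0).sum() * dt)
    if forward == 0.0:
        raise ValueError("forward volume is zero; regurgitant fraction undefined")
    rvol = float(-np.minimum(flow[split.diastole], 0.0).sum() * dt)
    sbv = float(np.minimum(flow[split.systole], 0.0).sum() * dt)
    return RegurgitationMetrics(
        rvol=rvol,
        rf=100.0 * rvol / forward,
        forward_volume=forward,
        systolic_backward_volume=sbv,
        hfr=detect_hfr(curve, split),
        dfr_velocity=dfr_velocity,
        site=curve.site_label,
    )


def detect_hfr(
    curve: FlowCurve,
    split: CardiacPhaseSplit,
    flow_floor: float = HFR_FLOW_FLOOR_ML_S,
) -> bool:
    """Holodiastolic flow reversal: reversed flow of at least ``flow_floor``
    mL/s persisting through the entire diastole (boundary inclusive:
    exactly -10 mL/s counts)."""
    diastolic = curve.flow[split.diastole]
    return bool(diastolic.size and np.all(diastolic <= -flow_floor))


def compute_dfr_velocity(
    vel: VelocitySeries,
    masks: RoiMaskSeries,
    split: CardiacPhaseSplit,
    threshold: float = DFR_VELOCITY_THRESHOLD_CM_S,
    definition: str = "end_diastole",
) -> tuple[float, bool]:
    """Diastolic flow-reversal velocity and its strict-threshold flag.

    ``definition='end_diastole'`` (default): magnitude of the spatial-mean
    reversal velocity at the final diastolic phase.
    ``definition='mean_diastole'``: magnitude of the time-averaged
    diastolic spatial-mean reversal velocity.
    The flag is ``velocity > threshold`` (strictly greater).
    """
    if split.end_systole_index >= vel.n_phases:
        raise ValueError("no diastolic phases")
    spatial_means = np.array(
        [vel.velocity[p][masks.masks[p]].mean() for p in range(vel.n_phases)]
    )
    if definition == "end_diastole":
        value = max(0.0, float(-spatial_means[-1]))
    elif definition == "mean_diastole":
        value = max(0.0, float(-spatial_means[split.diastole].mean()))
    else:
        raise ValueError(f"unknown DFR definition {definition!r}")
    return value, value > threshold


def classify_severity(
    aao: RegurgitationMetrics | None = None,
    da: RegurgitationMetrics | None = None,
    diameter_mm: float | None = None,
    thresholds: SeverityThresholds | None = None,
) -> SeverityCall:
    """Apply strict-'>' severity thresholds at both sites.

    The ascending-aorta reference is positive if either RVol or RF exceeds
    its outcome-based cut-off (42 mL / 33%); the descending-aorta flags use
    the transferred cut-offs (17 mL / 23% by default).  A diameter of
    exactly 40 mm classifies as dilated ('>=' convention).
    """
    t = thresholds or SeverityThresholds()
    sig_aao = None
    if aao is not None:
        sig_aao = bool(aao.rvol > t.reference_rvol or aao.rf > t.reference_rf)
    sig_da_rvol = sig_da_rf = dfr_pos = hfr_pos = None
    if da is not None:
        sig_da_rvol = bool(da.rvol > t.da_rvol)
        sig_da_rf = bool(da.rf > t.da_rf)
        hfr_pos = bool(da.hfr)
        if da.dfr_velocity is not None:
            dfr_pos = bool(da.dfr_velocity > t.dfr_velocity)
    diameter_class = None
    if diameter_mm is not None:
        diameter_class = "dilated" if diameter_mm >= t.diameter_dilated else "normal"
    return SeverityCall(
        significant_aao=sig_aao,
        significant_da_rvol=sig_da_rvol,
        significant_da_rf=sig_da_rf,
        dfr_positive=dfr_pos,
        hfr_positive=hfr_pos,
        diameter_class=diameter_class,
    )


def reproducibility_pct(m1: float, m2: float) -> float:
    """Test–retest reproducibility as ``100 * |m1 - m2| / mean(m1, m2)``."""
    mean = 0.5 * (m1 + m2)
    if mean == 0.0:
        raise ValueError("reproducibility undefined when the pair mean is zero")
    return 100.0 * abs(m1 - m2) / abs(mean)
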