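"""Velocity decoding and volumetric flow quantification for PC-MR series.

Turns a magnitude + velocity-encoded phase image series into a calibrated
volumetric flow curve: phase-to-velocity decoding, aliasing unwrap,
planar background-offset correction, threshold-based lumen segmentation
with phase-to-phase propagation, and ROI integration.

Conventions
-----------
* Phase values live in ``(-pi, pi]``; velocity ``v = venc * phi / pi`` (cm/s).
* Pixel coordinates are 0-based ``(row, col)``; images are row-major.
* 1 cm/s over 1 mm^2 equals 0.01 mL/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "VelocitySeries",
    "RoiMaskSeries",
    "FlowCurve",
    "OffsetModel",
    "VencSelection",
    "UnrecoverableAliasingError",
    "TrackingLostError",
    "OffsetResidualWarning",
    "RESIDUAL_OFFSET_LIMIT_CM_S",
    "wrap_phase",
    "encode_phase",
    "decode_velocity",
    "unwrap_aliasing",
    "estimate_background_offset",
    "segment_lumen",
    "compute_flow_curve",
    "select_venc",
]

#: Acceptance limit for the residual static-tissue velocity offset (cm/s).
RESIDUAL_OFFSET_LIMIT_CM_S = 0.6


class UnrecoverableAliasingError(RuntimeError):
    """More lumen pixels are wrapped than single-order unwrapping can repair."""


class TrackingLostError(RuntimeError):
    """Lumen mask area changed too abruptly between adjacent phases."""


class OffsetResidualWarning(UserWarning):
    """Residual static-tissue offset exceeds the acceptance limit."""


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the half-open interval ``(-pi, pi]``.

    Values already inside the interval are returned unchanged (bitwise),
    so encoding below VENC is the identity up to the scale factor.
    """
    out = np.array(phi, dtype=float, copy=True)
    need = (out <= -np.pi) | (out > np.pi)
    out[need] = np.pi - np.mod(np.pi - out[need], 2.0 * np.pi)
    if out.ndim == 0:
        return float(out)
    return out


def encode_phase(velocity_cm_s: np.ndarray | float, venc: float) -> np.ndarray | float:
    """Forward phase-contrast encoding ``phi = wrap(pi * v / venc)``."""
    if venc <= 0:
        raise ValueError(f"venc must be positive, got {venc}")
    return wrap_phase(np.pi * np.asarray(velocity_cm_s, dtype=float) / venc)


@dataclass
class VelocitySeries:
    """Decoded through-plane velocity stack.

    Attributes
    ----------
    velocity : ndarray, shape (n_phases, ny, nx)
        Through-plane velocity in cm/s.
    times : ndarray, shape (n_phases,)
        Trigger time of each cardiac phase in ms, strictly increasing.
    pixel_area : float
        In-plane pixel area in mm^2.
    venc : float
        Velocity-encoding limit in cm/s.
    corrected : bool
        True once background-offset correction has been applied.
    """

    velocity: np.ndarray
    times: np.ndarray
    pixel_area: float
    venc: float
    corrected: bool = False

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.velocity.ndim != 3:
            raise ValueError("velocity must be a (n_phases, ny, nx) stack")
        if self.times.shape != (self.velocity.shape[0],):
            raise ValueError("times length must equal number of phases")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]


@dataclass
class RoiMaskSeries:
    """Per-phase boolean lumen masks with centroids and areas (mm^2)."""

    masks: np.ndarray
    pixel_area: float
    centroids: np.ndarray = field(default=None)  # type: ignore[assignment]
    areas: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_phases, ny, nx) stack")
        counts = self.masks.sum(axis=(1, 2))
        if np.any(counts == 0):
            raise ValueError("every phase must have a non-empty mask")
        if self.areas is None:
            self.areas = counts * self.pixel_area
        if self.centroids is None:
            cents = [ndimage.center_of_mass(m) for m in self.masks]
            self.centroids = np.asarray(cents, dtype=float)

    @property
    def n_phases(self) -> int:
        return self.masks.shape[0]


@dataclass
class FlowCurve:
    """Volumetric flow per cardiac phase.

    ``flow`` is in mL/s, ``times`` in ms, one sample per cardiac phase.
    """

    flow: np.ndarray
    times: np.ndarray
    site_label: str = "ascending"

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.flow.shape != self.times.shape or self.flow.ndim != 1:
            raise ValueError("flow and times must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow values must be finite")
        if self.site_label not in ("ascending", "descending"):
            raise ValueError("site_label must be 'ascending' or 'descending'")

    @property
    def n_phases(self) -> int:
        return self.flow.size

    @property
    def dt_s(self) -> float:
        """Uniform phase duration in seconds."""
        return float(self.times[1] - self.times[0]) / 1000.0


@dataclass
class OffsetModel:
    """First-order spatial background-offset model.

    ``offset(row, col) = c0 + c_row * row + c_col * col`` in cm/s with 0-based
    pixel indices.  ``residual_static_mean`` is the mean over phases of the
    absolute spatial-mean corrected velocity in the static-tissue region.
    """

    c0: float
    c_row: float
    c_col: float
    residual_static_mean: float

    def __post_init__(self) -> None:
        if self.residual_static_mean < 0:
            raise ValueError("residual_static_mean must be non-negative")

    def plane(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.c0 + self.c_row * rows + self.c_col * cols


@dataclass
class VencSelection:
    """Outcome of the VENC selection rule."""

    venc: float
    headroom: float
    rule_satisfied: bool
    warning: str | None = None


def decode_velocity(
    phase_stack: np.ndarray,
    venc: float,
    times: np.ndarray,
    pixel_area: float,
) -> VelocitySeries:
    """Decode a phase stack into velocity, ``v = venc * phi / pi`` (cm/s).

    Parameters
    ----------
    phase_stack : ndarray, shape (n_phases, ny, nx)
        Phase images in radians, values in ``(-pi, pi]``.
    venc : float
        Velocity-encoding limit in cm/s (must be positive).
    times : ndarray
        Trigger times in ms.
    pixel_area : float
        Pixel area in mm^2.
    """
    if venc <= 0:
        raise ValueError(f"venc must be positive, got {venc}")
    phase_stack = np.asarray(phase_stack, dtype=float)
    if np.any(phase_stack > np.pi) or np.any(phase_stack <= -np.pi):
        raise ValueError("phase values must lie in (-pi, pi]")
    velocity = venc * phase_stack / np.pi
    return VelocitySeries(velocity=velocity, times=times, pixel_area=pixel_area, venc=venc)


def unwrap_aliasing(
    vel: VelocitySeries,
    lumen_hint: RoiMaskSeries,
    max_wrapped_fraction: float = 0.2,
) -> tuple[VelocitySeries, bool]:
    """Correct single-order VENC wrapping inside the lumen.

    For each phase, pixels whose velocity differs from the lumen spatial
    median by more than VENC are shifted by ``+/- 2 * venc``, whichever
    brings them closer to the median.  Only one wrap order is corrected.

    Returns the corrected series and a flag that is True if residual
    discontinuities (still > VENC from the median) remain.

    Raises
    ------
    UnrecoverableAliasingError
        If more than ``max_wrapped_fraction`` of lumen pixels are wrapped
        in any phase.
    """
    if lumen_hint.masks.shape != vel.velocity.shape:
        raise ValueError("lumen mask stack must match velocity stack shape")
    venc = vel.venc
    out = vel.velocity.copy()
    residual = False
    for p in range(vel.n_phases):
        mask = lumen_hint.masks[p]
        v = out[p]
        med = np.median(v[mask])
        wrapped = mask & (np.abs(v - med) > venc)
        n_wrapped = int(wrapped.sum())
        if n_wrapped == 0:
            continue
        if n_wrapped > max_wrapped_fraction * mask.sum():
            raise UnrecoverableAliasingError(
                f"phase {p}: {n_wrapped}/{int(mask.sum())} lumen pixels wrapped "
                f"(> {max_wrapped_fraction:.0%}); series unrecoverable"
            )
        up = v[wrapped] + 2.0 * venc
        down = v[wrapped] - 2.0 * venc
        v[wrapped] = np.where(np.abs(up - med) <= np.abs(down - med), up, down)
        if np.any(np.abs(v[wrapped] - med) > venc):
            residual = True
    return replace(vel, velocity=out), residual


def estimate_background_offset(
    vel: VelocitySeries,
    static_mask: np.ndarray,
    min_static_pixels: int = 50,
    acceptance_limit: float = RESIDUAL_OFFSET_LIMIT_CM_S,
) -> tuple[OffsetModel, VelocitySeries]:
    """Fit and subtract a planar eddy-current velocity offset.

    A first-order spatial polynomial is least-squares fitted to the
    time-averaged velocity of static-tissue pixels and subtracted from
    every phase.  Warns with :class:`OffsetResidualWarning` if the residual
    static-tissue offset exceeds ``acceptance_limit`` (0.6 cm/s default).
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != vel.velocity.shape[1:]:
        raise ValueError("static mask shape must match image shape")
    n_static = int(static_mask.sum())
    if n_static < min_static_pixels:
        raise ValueError(
            f"static mask has {n_static} pixels; at least {min_static_pixels} required"
        )
    mean_map = vel.velocity.mean(axis=0)
    rows, cols = np.nonzero(static_mask)
    design = np.column_stack([np.ones(rows.size), rows, cols])
    coeffs, *_ = np.linalg.lstsq(design, mean_map[static_mask], rcond=None)
    c0, c_row, c_col = (float(c) for c in coeffs)

    all_rows, all_cols = np.mgrid[0 : mean_map.shape[0], 0 : mean_map.shape[1]]
    plane = c0 + c_row * all_rows + c_col * all_cols
    corrected = vel.velocity - plane[None, :, :]

    per_phase_mean = corrected[:, static_mask].mean(axis=1)
    residual = float(np.mean(np.abs(per_phase_mean)))
    if residual > acceptance_limit:
        warnings.warn(
            f"residual static-tissue offset {residual:.3f} cm/s exceeds "
            f"acceptance limit {acceptance_limit} cm/s",
            OffsetResidualWarning,
            stacklevel=2,
        )
    model = OffsetModel(c0=c0, c_row=c_row, c_col=c_col, residual_static_mean=residual)
    corrected_series = replace(vel, velocity=corrected, corrected=True)
    return model, corrected_series


def _grow_mask(
    image: np.ndarray,
    seed_point: tuple[int, int],
    threshold_fraction: float,
) -> np.ndarray:
    """Connected component above a seed-relative intensity threshold."""
    r, c = int(round(seed_point[0])), int(round(seed_point[1]))
    ny, nx = image.shape
    if not (0 <= r < ny and 0 <= c < nx):
        raise ValueError(f"seed point {seed_point} outside image")
    neigh = image[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
    threshold = threshold_fraction * float(np.median(neigh))
    labels = measure.label(image >= threshold, connectivity=1)
    lab = labels[r, c]
    if lab == 0:
        raise ValueError(f"seed point {seed_point} below segmentation threshold")
    return labels == lab


def segment_lumen(
    magnitude_stack: np.ndarray,
    seed_point: tuple[int, int],
    pixel_area: float,
    reference_phase: int = 0,
    threshold_fraction: float = 0.5,
    max_area_change: float = 0.5,
) -> RoiMaskSeries:
    """Segment the vessel lumen and propagate it through all phases.

    The reference mask is the connected component of pixels brighter than
    ``threshold_fraction`` times the median intensity of the seed's 3x3
    neighbourhood that contains the seed.  Subsequent phases are seeded
    from the previous phase's centroid and re-grown, cycling through the
    series starting at ``reference_phase``.

    Raises
    ------
    TrackingLostError
        If the mask area changes by more than ``max_area_change`` between
        adjacent phases.
    """
    magnitude_stack = np.asarray(magnitude_stack, dtype=float)
    n_phases = magnitude_stack.shape[0]
    if not 0 <= reference_phase < n_phases:
        raise ValueError("reference_phase out of range")
    masks = np.zeros(magnitude_stack.shape, dtype=bool)

    order = [(reference_phase + k) % n_phases for k in range(n_phases)]
    seed = (float(seed_point[0]), float(seed_point[1]))
    prev_area = None
    for p in order:
        mask = _grow_mask(magnitude_stack[p], seed, threshold_fraction)
        area = int(mask.sum())
        if prev_area is not None:
            change = abs(area - prev_area) / prev_area
            if change > max_area_change:
                raise TrackingLostError(
                    f"phase {p}: mask area changed by {change:.0%} "
                    f"(limit {max_area_change:.0%}); tracking lost"
                )
        masks[p] = mask
        seed = ndimage.center_of_mass(mask)
        prev_area = area
    return RoiMaskSeries(masks=masks, pixel_area=pixel_area)


def compute_flow_curve(
    vel: VelocitySeries,
    masks: RoiMaskSeries,
    site_label: str = "ascending",
) -> FlowCurve:
    """Integrate velocity over the ROI into volumetric flow (mL/s).

    ``flow(t) = sum_{pixels in mask} v * pixel_area * 0.01`` where v is in
    cm/s and pixel_area in mm^2.
    """
    if masks.masks.shape != vel.velocity.shape:
        raise ValueError("mask stack shape must match velocity stack shape")
    flow = np.array(
        [vel.velocity[p][masks.masks[p]].sum() for p in range(vel.n_phases)]
    )
    flow *= vel.pixel_area * 0.01
    return FlowCurve(flow=flow, times=vel.times, site_label=site_label)


def select_venc(
    expected_peak: float,
    candidates: np.ndarray,
    max_headroom: float = 0.20,
) -> VencSelection:
    """Pick the smallest VENC candidate strictly above the expected peak.

    The selected VENC should also satisfy ``(venc - peak) / venc <= 0.20``;
    if no candidate above the peak does, the smallest one is returned with
    a "rule unsatisfiable" warning attached.

    Raises
    ------
    ValueError
        If the expected peak is not below the largest candidate (flow
        unmeasurable at any allowed VENC).
    """
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if expected_peak <= 0:
        raise ValueError("expected peak velocity must be positive")
    above = candidates[candidates > expected_peak]
    if above.size == 0:
        raise ValueError(
            f"expected peak {expected_peak} cm/s is not below any candidate VENC "
            f"(max {candidates[-1]}); unmeasurable"
        )
    venc = float(above[0])
    headroom = (venc - expected_peak) / venc
    if headroom <= max_headroom:
        return VencSelection(venc=venc, headroom=headroom, rule_satisfied=True)
    msg = (
        f"VENC rule unsatisfiable: smallest candidate {venc} cm/s leaves "
        f"{headroom:.1%} headroom above peak {expected_peak} cm/s (> {max_headroom:.0%})"
    )
    warnings.warn(msg, UserWarning, stacklevel=2)
    return VencSelection(venc=venc, headroom=headroom, rule_satisfied=False, warning=msg)
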