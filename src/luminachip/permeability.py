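"""Image-based diffusive-permeability quantification and calibration.

The assay measures leakage of a fluorescent tracer from a vessel lumen
into the surrounding matrix.  A line profile is drawn from the vessel
edge outward into the matrix; with ``TI`` the trapezoidal integral of
intensity along that line (intensity·μm), the diffusive permeability is

    P = (1 / ΔI₀) · ((TI_f − TI_0) / (t_f − t_0)) · (f · D / 4)

where ΔI₀ is the initial intensity step across the lumen wall (taken as
the mean lumen intensity at t₀), D the vessel diameter, and f the
fraction of the vessel perimeter exposed to the matrix.  P is reported
in μm/s; ``PermeabilityResult.P_cm_per_s`` converts to cm/s.

The module also calibrates the transport model's interface partition
coefficient k against observed profiles (or a target permeability) by a
bounded scalar search over forward simulations.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .geometry import ChipGeometry, DomainMask, LUMEN_LEFT, LUMEN_RIGHT, exposed_perimeter_fraction
from .transport import (
    ConcentrationField,
    SimulationConfig,
    SimulationResult,
    Species,
    simulate_transport,
)

DEFAULT_LINE_LENGTH = 200.0  # μm into the matrix
DEFAULT_T0 = 0.0  # s
DEFAULT_TF = 900.0  # s (15 min)


@dataclass
class IntensityProfile:
    """Fluorescence readout along a line from the vessel edge outward."""

    positions: np.ndarray  # μm, strictly increasing, starting at 0
    intensities: np.ndarray  # arbitrary units, ≥ 0
    time: float  # s
    pixel_pitch: float  # μm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have the same shape")
        if self.positions.size == 0:
            raise ValueError("profile must be non-empty")
        if abs(self.positions[0]) > 1e-9:
            raise ValueError("positions must start at 0 (vessel edge)")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PermeabilityInputs:
    """Ingredients of the permeability formula."""

    delta_I0: float  # intensity
    TI_0: float  # intensity · μm
    TI_f: float  # intensity · μm
    t_0: float  # s
    t_f: float  # s
    vessel_diameter: float  # μm
    exposed_fraction: float  # dimensionless

    def __post_init__(self):
        if self.t_f <= self.t_0:
            raise ValueError("t_f must exceed t_0")
        if self.delta_I0 <= 0:
            raise ValueError("delta_I0 must be positive")
        if not (0 < self.exposed_fraction <= 1):
            raise ValueError("exposed_fraction must lie in (0, 1]")
        if self.vessel_diameter <= 0:
            raise ValueError("vessel_diameter must be positive")


@dataclass
class PermeabilityResult:
    P: float  # μm/s
    inputs: PermeabilityInputs
    provenance: str = ""

    @property
    def P_cm_per_s(self) -> float:
        return self.P * 1e-4


def extract_profile(
    stack: np.ndarray,
    origin,
    direction,
    length: float,
    time_index: int,
    pixel_pitch: float,
) -> IntensityProfile:
    """Bilinear line profile from an image time-series.

    ``origin`` is a (row, col) pixel coordinate, ``direction`` a (drow,
    dcol) vector (normalized internally); samples are taken at 1-pixel
    spacing along the line for ``length`` μm.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if not (0 <= time_index < stack.shape[0]):
        raise IndexError(f"time_index {time_index} outside stack of {stack.shape[0]} frames")
    if not np.isfinite(pixel_pitch) or pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be a positive, known value")
    d = np.asarray(direction, dtype=float)
    norm = math.hypot(*d)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    d = d / norm
    n = int(math.floor(length / pixel_pitch)) + 1
    s = np.arange(n)
    rows = origin[0] + s * d[0]
    cols = origin[1] + s * d[1]
    h, w = stack.shape[1:]
    if rows.min() < 0 or cols.min() < 0 or rows.max() > h - 1 or cols.max() > w - 1:
        raise ValueError("profile line exits the image bounds")
    frame = stack[time_index].astype(float)
    intensities = ndimage.map_coordinates(frame, np.vstack([rows, cols]), order=1, mode="nearest")
    return IntensityProfile(
        positions=s * pixel_pitch,
        intensities=np.maximum(intensities, 0.0),
        time=float(time_index),
        pixel_pitch=pixel_pitch,
    )


def normalize_profiles(profiles, reference: float):
    """Divide all intensities by the t₀ lumen reference (maps it to 1)."""
    if reference <= 0:
        raise ValueError("reference intensity must be positive")
    return [
        IntensityProfile(
            positions=p.positions.copy(),
            intensities=p.intensities / reference,
            time=p.time,
            pixel_pitch=p.pixel_pitch,
        )
        for p in profiles
    ]


def total_intensity(profile: IntensityProfile) -> float:
    """Trapezoidal integral of intensity over position, intensity·μm."""
    if profile.positions.size < 2:
        raise ValueError("total intensity needs at least two samples")
    return float(np.trapezoid(profile.intensities, profile.positions))


def estimate_delta_I0(lumen_profile_t0: IntensityProfile) -> float:
    """ΔI₀ under the step assumption: mean lumen intensity at t₀."""
    return float(lumen_profile_t0.intensities.mean())


def lumen_roi_mean(frame: np.ndarray, mask: DomainMask, side: str = "left", erosion_px: int = 2) -> float:
    """Mean intensity over a lumen-interior disk eroded from the wall."""
    label = LUMEN_LEFT if side == "left" else LUMEN_RIGHT
    roi = mask.labels == label
    if erosion_px > 0:
        eroded = ndimage.binary_erosion(roi, iterations=erosion_px)
        if eroded.any():
            roi = eroded
    return float(np.asarray(frame, dtype=float)[roi].mean())


def compute_permeability(inputs: PermeabilityInputs, provenance: str = "") -> PermeabilityResult:
    """Evaluate the permeability formula exactly; P in μm/s."""
    P = (
        (1.0 / inputs.delta_I0)
        * ((inputs.TI_f - inputs.TI_0) / (inputs.t_f - inputs.t_0))
        * (inputs.exposed_fraction * inputs.vessel_diameter / 4.0)
    )
    return PermeabilityResult(P=float(P), inputs=inputs, provenance=provenance)


# ---------------------------------------------------------------------------
# assay-level helpers shared by the estimator and the calibration


def profile_line_origin(mask: DomainMask, side: str = "left"):
    """(row, col) pixel origin and direction of the measurement line.

    The line starts at the matrix-side cell of the central interface
    pair (the outer vessel edge at the slit) and runs perpendicular to
    the interface into the matrix.
    """
    pairs = mask.interface_left if side == "left" else mask.interface_right
    if not pairs:
        raise ValueError(f"mask has no {side} interface; cannot place the line")
    central = min(pairs, key=lambda pr: abs(mask.z[pr[0][0]]))
    (iz, _), (_, ix_m) = central
    direction = (0.0, 1.0) if side == "left" else (0.0, -1.0)
    return (float(iz), float(ix_m)), direction


def profile_from_frame(
    frame: np.ndarray,
    mask: DomainMask,
    side: str = "left",
    line_length: float = DEFAULT_LINE_LENGTH,
    time: float = 0.0,
) -> IntensityProfile:
    """Extract the assay line profile from a single rendered frame."""
    origin, direction = profile_line_origin(mask, side)
    prof = extract_profile(
        np.asarray(frame)[None], origin, direction, line_length, 0, mask.grid_pitch
    )
    prof.time = time
    return prof


def permeability_from_frames(
    frame_t0: np.ndarray,
    frame_tf: np.ndarray,
    mask: DomainMask,
    geometry: ChipGeometry,
    t_0: float = DEFAULT_T0,
    t_f: float = DEFAULT_TF,
    side: str = "left",
    line_length: float = DEFAULT_LINE_LENGTH,
    provenance: str = "",
) -> PermeabilityResult:
    """Full estimator path on two frames: ROI ΔI₀, line profiles, formula."""
    p0 = profile_from_frame(frame_t0, mask, side, line_length, time=t_0)
    pf = profile_from_frame(frame_tf, mask, side, line_length, time=t_f)
    delta_I0 = lumen_roi_mean(frame_t0, mask, side=side)
    inputs = PermeabilityInputs(
        delta_I0=delta_I0,
        TI_0=total_intensity(p0),
        TI_f=total_intensity(pf),
        t_0=t_0,
        t_f=t_f,
        vessel_diameter=geometry.lumen_diameter,
        exposed_fraction=exposed_perimeter_fraction(geometry),
    )
    return compute_permeability(inputs, provenance=provenance)


def permeability_from_simulation(
    result: SimulationResult,
    mask: DomainMask,
    geometry: ChipGeometry,
    t_0: float = DEFAULT_T0,
    t_f: float = DEFAULT_TF,
    side: str = "left",
    line_length: float = DEFAULT_LINE_LENGTH,
) -> PermeabilityResult:
    """Ideal (noiseless, unrendered) permeability of a simulated assay.

    Applies the same formula directly to the simulated concentration
    fields; this is the operational ground-truth permeability recorded
    by the synthetic-assay generator.
    """
    f0 = result.field_at(t_0)
    ff = result.field_at(t_f)
    return permeability_from_frames(
        f0.values, ff.values, mask, geometry, t_0=t_0, t_f=t_f, side=side,
        line_length=line_length, provenance="ideal-simulated",
    )


class CalibrationError(RuntimeError):
    """Scalar search for the partition coefficient failed."""


def fit_partition_coefficient(
    mask: DomainMask,
    species: Species,
    observed=None,
    target_P: float | None = None,
    geometry: ChipGeometry | None = None,
    config: SimulationConfig | None = None,
    bounds=(0.01, 1.0),
    tolerance: float = 1e-4,
    side: str = "left",
    line_length: float = DEFAULT_LINE_LENGTH,
    t_f: float = DEFAULT_TF,
) -> float:
    """Calibrate the partition coefficient k against observations.

    Either ``observed`` (a list of :class:`IntensityProfile`, normalized,
    whose ``time`` attributes name the sample instants of the assay) or
    ``target_P`` (μm/s, requires ``geometry``) must be given.  The
    objective — squared mismatch of simulated vs observed profiles, or of
    simulated vs target permeability — is minimized by bounded scalar
    search; when several observed profiles are passed (noisy replicates
    at the same times), the objective averages over them.
    """
    if (observed is None) == (target_P is None):
        raise ValueError("provide exactly one of `observed` or `target_P`")
    lo, hi = bounds
    if not (0 < lo < hi <= 1):
        raise ValueError("bounds must satisfy 0 < lo < hi ≤ 1")

    if observed is not None:
        times = sorted({p.time for p in observed if p.time > 0})
        if not times:
            raise ValueError("observed profiles must include at least one t > 0 instant")
        sim_t_end = max(times)
    else:
        if geometry is None:
            raise ValueError("target_P calibration requires the chip geometry")
        times = [t_f]
        sim_t_end = t_f

    base = config if config is not None else SimulationConfig()
    base = dataclasses.replace(
        base, t_end=sim_t_end, sample_times=tuple([0.0] + list(times))
    )

    def objective(k: float) -> float:
        sp_k = dataclasses.replace(species, partition_k=float(k))
        result = simulate_transport(mask, sp_k, base)
        if observed is not None:
            sse = 0.0
            for obs in observed:
                if obs.time <= 0:
                    continue
                sim_prof = profile_from_frame(
                    result.field_at(obs.time).values, mask, side,
                    line_length=obs.positions[-1], time=obs.time,
                )
                m = min(sim_prof.intensities.size, obs.intensities.size)
                sse += float(np.mean((sim_prof.intensities[:m] - obs.intensities[:m]) ** 2))
            return sse / len(observed)
        res = permeability_from_simulation(
            result, mask, geometry, t_f=t_f, side=side, line_length=line_length
        )
        return (res.P - target_P) ** 2

    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": tolerance, "maxiter": 60})
    if not res.success:
        raise CalibrationError(f"scalar search did not converge: {res.message}; best k = {res.x}")
    k_hat = float(res.x)
    # diagnose an unbracketed optimum: interior fit should not beat the
    # returned point at either bound by a large margin
    if min(abs(k_hat - lo), abs(hi - k_hat)) < 2 * tolerance:
        edge = lo if abs(k_hat - lo) < abs(hi - k_hat) else hi
        warnings.warn(
            f"fitted partition coefficient {k_hat:.4f} sits at the {edge:g} bound; "
            "the optimum may lie outside the bracket", stacklevel=2,
        )
    return k_hat
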