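"""Synthetic inputs with serialized ground truth for every pipeline stage.

Each generator draws from a seeded ``numpy.random.Generator`` so that
regeneration with the same seed is bit-identical, and records the
parameters it used (including derived ground-truth quantities) in a
``ground_truth`` dictionary that downstream tests read instead of
re-deriving.

The permeability-stack generator emulates a widefield fluorescence
time-lapse of tracer leakage: the forward transport model is rendered on
its own lattice (no resampling), scaled by a detector gain, and
corrupted by additive Gaussian read noise (default sd 2 % of the lumen
intensity) plus optional Poisson shot noise.  Cell shapes, optics and
photobleaching are not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .geometry import ChipGeometry, DomainMask, build_domain_mask
from .transport import (
    SimulationConfig,
    Species,
    simulate_transport,
)
from .permeability import DEFAULT_TF, permeability_from_simulation
from .quantify import CellPoints, HeightProfile, InterfaceLine
from .group_stats import GroupSamples

DEFAULT_GRID_PITCH = 5.0  # μm
ASSAY_FRAME_TIMES = (0.0, 900.0, 1800.0)  # s: t = 0, 15 min, 30 min


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise: Gaussian read noise plus optional Poisson shot noise.

    ``gaussian_sd`` is a fraction of the rendered lumen intensity
    (i.e. of the gain); ``poisson_gain`` is the expected photon count per
    unit intensity (0 disables shot noise).
    """

    gaussian_sd: float = 0.02
    poisson_gain: float = 0.0

    def __post_init__(self):
        if self.gaussian_sd < 0 or self.poisson_gain < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SyntheticAssay:
    """Rendered permeability time-lapse plus its generating truth."""

    stack: np.ndarray  # (T, H, W) float32
    frame_times: np.ndarray  # s
    pixel_pitch: float  # μm
    mask: DomainMask
    ground_truth: dict


def synth_permeability_stack(
    geometry: ChipGeometry | None = None,
    species: Species | None = None,
    config: SimulationConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    grid_pitch: float = DEFAULT_GRID_PITCH,
    gain: float = 1.0,
) -> SyntheticAssay:
    """Simulate a leakage assay and render it as a noisy image stack.

    Frames are sampled at t = 0, 15 and 30 min (plus any extra times in
    ``config.sample_times``); the recorded ground truth includes the
    ideal diffusive permeability of the noiseless simulation.
    """
    from .transport import dextran_10kda

    geometry = geometry or ChipGeometry()
    species = species or dextran_10kda()
    noise = noise or NoiseModel()
    if gain <= 0:
        raise ValueError("gain must be positive")
    mask = build_domain_mask(geometry, grid_pitch)
    base = config or SimulationConfig()
    times = sorted(set(ASSAY_FRAME_TIMES) | set(base.sample_times))
    t_end = max(max(times), base.t_end if not base.sample_times else max(times))
    config = dataclasses.replace(base, t_end=t_end, sample_times=tuple(times))

    result = simulate_transport(mask, species, config)
    truth_P = permeability_from_simulation(result, mask, geometry, t_f=DEFAULT_TF)

    rng = np.random.default_rng(seed)
    frames = []
    frame_times = []
    for f in result.fields:
        signal = f.values * gain
        if noise.poisson_gain > 0:
            signal = rng.poisson(np.clip(signal, 0, None) * noise.poisson_gain) / noise.poisson_gain
        if noise.gaussian_sd > 0:
            signal = signal + rng.normal(0.0, noise.gaussian_sd * gain, size=signal.shape)
        frames.append(np.maximum(signal, 0.0).astype(np.float32))
        frame_times.append(f.time)

    ground_truth = {
        "species": asdict(species),
        "partition_k": species.partition_k,
        "interface_transmission_um_per_s": config.interface_transmission,
        "true_P_um_per_s": truth_P.P,
        "geometry": asdict(geometry),
        "grid_pitch_um": grid_pitch,
        "gain": gain,
        "noise": asdict(noise),
        "seed": seed,
        "frame_times_s": list(map(float, frame_times)),
        "lumen_mode": config.lumen_mode,
    }
    return SyntheticAssay(
        stack=np.stack(frames),
        frame_times=np.asarray(frame_times, dtype=float),
        pixel_pitch=grid_pitch,
        mask=mask,
        ground_truth=ground_truth,
    )


def calibrate_transmission_for_target_P(
    target_P: float,
    geometry: ChipGeometry | None = None,
    D: float = 100.0,
    grid_pitch: float = DEFAULT_GRID_PITCH,
    t_f: float = DEFAULT_TF,
    bracket=(1e-4, 1e3),
    rtol: float = 1e-3,
) -> float:
    """Interface transmission T (μm/s) whose ideal assay permeability is ``target_P``.

    The assay-reported permeability is a saturating function of the
    membrane transmission (matrix diffusion limits the readout once the
    wall is effectively transparent), so only targets below that ceiling
    are reachable; unreachable targets raise a ValueError quoting the
    ceiling.
    """
    geometry = geometry or ChipGeometry()
    if target_P <= 0:
        raise ValueError("target_P must be positive")
    mask = build_domain_mask(geometry, grid_pitch)
    species = Species("tracer", 10.0, D, D, 1.0)

    def ideal_P(T: float) -> float:
        config = SimulationConfig(
            t_end=t_f, sample_times=(0.0, t_f), interface_transmission=T
        )
        result = simulate_transport(mask, species, config)
        return permeability_from_simulation(result, mask, geometry, t_f=t_f).P

    lo, hi = bracket
    p_hi = ideal_P(hi)
    if target_P >= p_hi:
        raise ValueError(
            f"target P = {target_P:g} μm/s exceeds the assay ceiling "
            f"≈ {p_hi:.3g} μm/s at D = {D:g} μm²/s (matrix-diffusion limited)"
        )
    p_lo = ideal_P(lo)
    if target_P <= p_lo:
        raise ValueError(f"target P = {target_P:g} μm/s below the bracket floor {p_lo:.3g}")

    logT = brentq(
        lambda u: ideal_P(10.0**u) - target_P, np.log10(lo), np.log10(hi), rtol=1e-12,
        xtol=rtol,
    )
    return float(10.0**logT)


@dataclass
class SyntheticScene:
    """Invasion scene: centroid table, matching label image, ground truth."""

    points: CellPoints
    label_image: np.ndarray
    pixel_pitch: float
    interface: InterfaceLine
    ground_truth: dict


def synth_invasion_scene(
    n_cells: int,
    distance_distribution=("exponential", 100.0),
    seed: int = 0,
    x_interface: float = 0.0,
    pixel_pitch: float = 2.0,
    cell_radius: float = 6.0,
    row_spacing: float = 30.0,
) -> SyntheticScene:
    """Cells at controlled depths beyond the lumen–matrix interface.

    ``distance_distribution`` is either ``("exponential", mean_μm)`` or
    ``("fixed", [d1, d2, ...])``.  Centres are snapped to pixel centres
    and laid out on separated rows so the rendered nuclei stay disjoint,
    keeping the label-image → centroid round trip exact.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    kind = distance_distribution[0]
    rng = np.random.default_rng(seed)
    if kind == "exponential":
        mean = float(distance_distribution[1])
        if mean <= 0:
            raise ValueError("exponential mean must be positive")
        distances = rng.exponential(mean, size=n_cells)
    elif kind == "fixed":
        distances = np.asarray(distance_distribution[1], dtype=float)
        if distances.size != n_cells:
            raise ValueError("fixed distance list must have n_cells entries")
        if np.any(distances < 0):
            raise ValueError("fixed distances must be non-negative")
    else:
        raise ValueError(f"unknown distance distribution {kind!r}")

    # snap to pixel centres (image row i / col j centre at i·pitch, j·pitch)
    margin_px = int(np.ceil((cell_radius + 2 * pixel_pitch) / pixel_pitch))
    xs_px = np.round((x_interface + distances) / pixel_pitch).astype(int) + margin_px
    ys_px = (margin_px + np.arange(n_cells) * int(np.ceil(row_spacing / pixel_pitch)))
    x_interface_px = x_interface / pixel_pitch + margin_px

    width = int(xs_px.max() + margin_px + 1) if n_cells else 2 * margin_px
    height = int(ys_px.max() + margin_px + 1) if n_cells else 2 * margin_px
    label_image = np.zeros((height, width), dtype=np.int32)
    r_px = cell_radius / pixel_pitch
    for i, (cx, cy) in enumerate(zip(xs_px, ys_px), start=1):
        rr, cc = np.ogrid[:height, :width]
        label_image[(rr - cy) ** 2 + (cc - cx) ** 2 <= r_px**2] = i

    coords = np.column_stack([xs_px * pixel_pitch, ys_px * pixel_pitch]) if n_cells else np.empty((0, 2))
    points = CellPoints(coordinates=coords, label="synthetic-cancer-cell")
    interface = InterfaceLine(x_interface=x_interface_px * pixel_pitch, orientation=1)
    snapped = xs_px * pixel_pitch - x_interface_px * pixel_pitch
    ground_truth = {
        "distances_um": snapped.tolist(),
        "d_max_um": float(snapped.max()) if n_cells else 0.0,
        "x_interface_um": interface.x_interface,
        "seed": seed,
        "distribution": [kind, distance_distribution[1] if kind == "exponential"
                         else list(map(float, np.atleast_1d(distance_distribution[1])))],
        "pixel_pitch_um": pixel_pitch,
        "cell_radius_um": cell_radius,
    }
    return SyntheticScene(
        points=points,
        label_image=label_image,
        pixel_pitch=pixel_pitch,
        interface=interface,
        ground_truth=ground_truth,
    )


@dataclass
class SyntheticProfile:
    profile: HeightProfile
    ground_truth: dict


def synth_height_profile(
    waveform: str,
    n_samples: int,
    seed: int = 0,
    amplitude: float = 50.0,
    period: float = 10.0,
    sd: float = 10.0,
    spacing: float = 0.1,
) -> SyntheticProfile:
    """1-D height trace with closed-form roughness where applicable.

    ``sine`` gives Ra = 2A/π and Rq = A/√2 (exact in the continuum,
    approached for many samples per period); ``square`` alternates ±A
    every sample (Ra = Rq = A, Rz = 2A); ``white`` is Gaussian noise of
    standard deviation ``sd`` (Rq → sd for large n).  Heights in nm,
    positions in μm.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    positions = np.arange(n_samples) * spacing
    truth: dict = {"waveform": waveform, "seed": seed, "n_samples": n_samples}
    if waveform == "sine":
        if amplitude <= 0 or period <= 0:
            raise ValueError("sine needs positive amplitude and period")
        heights = amplitude * np.sin(2 * np.pi * positions / period)
        truth.update(amplitude_nm=amplitude, period_um=period,
                     Ra_nm=2 * amplitude / np.pi, Rq_nm=amplitude / np.sqrt(2))
    elif waveform == "square":
        if amplitude <= 0:
            raise ValueError("square needs a positive amplitude")
        heights = amplitude * np.where(np.arange(n_samples) % 2 == 0, 1.0, -1.0)
        truth.update(amplitude_nm=amplitude, Ra_nm=amplitude, Rq_nm=amplitude,
                     Rz_nm=2 * amplitude)
    elif waveform == "white":
        if sd <= 0:
            raise ValueError("white noise needs a positive sd")
        rng = np.random.default_rng(seed)
        heights = rng.normal(0.0, sd, size=n_samples)
        truth.update(sd_nm=sd, Rq_nm=sd)
    else:
        raise ValueError(f"unknown waveform {waveform!r}")
    return SyntheticProfile(
        profile=HeightProfile(positions=positions, heights=heights), ground_truth=truth
    )


def synth_group_data(
    n_groups: int,
    n_per_group: int,
    effect_sizes,
    sd: float = 1.0,
    seed: int = 0,
) -> GroupSamples:
    """Normal samples with specified group means (``effect_sizes``) and common sd."""
    if n_groups < 2 or n_per_group < 2:
        raise ValueError("need at least two groups of at least two samples")
    if sd <= 0:
        raise ValueError("sd must be positive")
    effects = np.asarray(effect_sizes, dtype=float)
    if effects.size == 1:
        effects = np.full(n_groups, float(effects))
    if effects.size != n_groups:
        raise ValueError("effect_sizes must have one entry per group (or a scalar)")
    rng = np.random.default_rng(seed)
    groups = {
        f"group{i + 1}": rng.normal(effects[i], sd, size=n_per_group)
        for i in range(n_groups)
    }
    return GroupSamples(groups=groups)
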