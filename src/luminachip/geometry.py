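"""Chip cross-section geometry and its discretization.

The chip cross-section (x lateral, z vertical, origin at the centre of the
hydrogel channel) consists of a rectangular matrix channel flanked by two
circular lumens.  Each lumen communicates with the matrix only through a
narrow slit (``gap_width``) centred on the tangent plane; everywhere else
the compartments are separated by solid wall.

Lengths are micrometres unless a field name says otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

# lattice label values
SOLID = 0
LUMEN_LEFT = 1
LUMEN_RIGHT = 2
MATRIX = 3

_EPS = 1e-9


class ResolutionError(ValueError):
    """Grid pitch too coarse to resolve a geometric feature."""


@dataclass(frozen=True)
class ChipGeometry:
    """Physical dimensions of the chip cross-section and lumens.

    Parameters
    ----------
    lumen_diameter : float
        Diameter of each tubular lumen, μm.
    matrix_channel_width : float
        Width of the central hydrogel channel between the two lumen
        edges, μm.
    lumen_center_spacing : float
        Distance between the two lumen centres, μm.  Defaults to
        ``matrix_channel_width + lumen_diameter`` (lumens tangent to the
        matrix channel).
    gap_width : float
        Height of the open slit connecting each lumen to the matrix, μm.
        May be zero (isolated compartments).
    channel_half_height : float
        Half-height of the matrix channel (one mould half), μm.
    lumen_length : float
        Axial length of the lumens, mm.  Needed only for shear-stress
        and quasi-3D bookkeeping; no manufacturer default exists, so the
        default here is an arbitrary 10 mm placeholder.
    reservoir_diameter : float
        Diameter of the punched media reservoirs, mm.
    """

    lumen_diameter: float = 300.0
    matrix_channel_width: float = 800.0
    lumen_center_spacing: float | None = None
    gap_width: float = 30.0
    channel_half_height: float = 150.0
    lumen_length: float = 10.0
    reservoir_diameter: float = 5.0

    def __post_init__(self):
        if self.lumen_center_spacing is None:
            object.__setattr__(
                self, "lumen_center_spacing", self.matrix_channel_width + self.lumen_diameter
            )
        for name in (
            "lumen_diameter",
            "matrix_channel_width",
            "lumen_center_spacing",
            "channel_half_height",
            "lumen_length",
            "reservoir_diameter",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.gap_width) or self.gap_width < 0:
            raise ValueError(f"gap_width must be non-negative, got {self.gap_width!r}")
        if self.gap_width >= self.lumen_diameter:
            raise ValueError("gap_width must be smaller than lumen_diameter")
        if self.gap_width > math.pi * self.lumen_diameter:
            raise ValueError("gap_width exceeds the lumen perimeter")

    @property
    def lumen_radius(self) -> float:
        return self.lumen_diameter / 2.0

    @property
    def matrix_channel_height(self) -> float:
        """Full height of the bonded matrix channel (two mould halves), μm."""
        return 2.0 * self.channel_half_height

    def to_yaml(self, path) -> None:
        data = {f"{k}_um": v for k, v in asdict(self).items()}
        # lumen_length and reservoir_diameter are millimetres
        data["lumen_length_mm"] = data.pop("lumen_length_um")
        data["reservoir_diameter_mm"] = data.pop("reservoir_diameter_um")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChipGeometry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        kwargs = {}
        for key, value in data.items():
            if key.endswith("_um"):
                kwargs[key[:-3]] = value
            elif key.endswith("_mm"):
                kwargs[key[:-3]] = value
            else:
                raise ValueError(f"geometry key {key!r} lacks a unit suffix (_um/_mm)")
        return cls(**kwargs)


def exposed_perimeter_fraction(geometry, lumen_diameter: float | None = None) -> float:
    """Fraction of the lumen perimeter open to the diffusive matrix.

    The slit of height ``gap_width`` subtends an arc of approximately the
    same length on the lumen circle, so the exposed fraction is
    ``gap_width / (π · lumen_diameter)``.  Accepts either a
    :class:`ChipGeometry` or the raw ``(gap_width, lumen_diameter)`` pair
    (the raw form also covers hypothetical exposures up to the full
    perimeter, which no slit geometry can realize).
    """
    if lumen_diameter is None:
        gap, diameter = geometry.gap_width, geometry.lumen_diameter
    else:
        gap, diameter = float(geometry), float(lumen_diameter)
        if diameter <= 0 or gap < 0 or gap > math.pi * diameter:
            raise ValueError("need 0 ≤ gap_width ≤ π · lumen_diameter and a positive diameter")
    return gap / (math.pi * diameter)


@dataclass
class DomainMask:
    """Labelled lattice over the chip cross-section.

    ``labels`` has shape ``(nz, nx)`` with values SOLID / LUMEN_LEFT /
    LUMEN_RIGHT / MATRIX; cell centres are at ``x[ix], z[iz]``.
    ``interface_left`` / ``interface_right`` list the membrane pairs
    ``((iz, ix_lumen), (iz, ix_matrix))`` spanning each slit; flux between
    lumen and matrix passes only through these pairs.
    """

    grid_pitch: float
    labels: np.ndarray
    x: np.ndarray
    z: np.ndarray
    interface_left: list = field(default_factory=list)
    interface_right: list = field(default_factory=list)
    geometry: ChipGeometry | None = None

    @property
    def shape(self):
        return self.labels.shape

    def area(self, label: int) -> float:
        """Lattice area of one compartment, μm²."""
        return float(np.count_nonzero(self.labels == label)) * self.grid_pitch**2

    @property
    def interface_pairs(self):
        return self.interface_left + self.interface_right

    def interface_arc_length(self, side: str) -> float:
        pairs = self.interface_left if side == "left" else self.interface_right
        return len(pairs) * self.grid_pitch


def build_domain_mask(geometry: ChipGeometry, grid_pitch: float) -> DomainMask:
    """Discretize the cross-section on a cell-centred lattice.

    Lumens are full circles (bonded device), the matrix channel a
    rectangle; interface pairs are marked during construction as the
    lumen/matrix cell pairs lying in rows within the slit band
    ``|z| < gap_width / 2``, which keeps the slit arc length exact to one
    pitch.

    Raises
    ------
    ResolutionError
        If the pitch cannot resolve a non-zero gap at all
        (``grid_pitch > gap_width``).
    """
    if not np.isfinite(grid_pitch) or grid_pitch <= 0:
        raise ValueError("grid_pitch must be strictly positive")
    g = geometry
    if g.gap_width > 0 and grid_pitch > g.gap_width:
        raise ResolutionError(
            f"grid_pitch {grid_pitch} μm cannot resolve the {g.gap_width} μm gap; "
            f"use a pitch of at most {g.gap_width} μm (ideally ≤ {g.gap_width / 3:g})"
        )
    if g.gap_width > 0 and grid_pitch > g.gap_width / 3:
        warnings.warn(
            f"grid_pitch {grid_pitch} μm resolves the {g.gap_width} μm gap with "
            "fewer than 3 cells; interface arc length is coarse",
            stacklevel=2,
        )

    half_width = g.lumen_center_spacing / 2.0 + g.lumen_radius
    half_height = max(g.channel_half_height, g.lumen_radius)
    nx = int(math.ceil(2 * half_width / grid_pitch - _EPS))
    nz = int(math.ceil(2 * half_height / grid_pitch - _EPS))
    x = (np.arange(nx) - (nx - 1) / 2.0) * grid_pitch
    z = (np.arange(nz) - (nz - 1) / 2.0) * grid_pitch
    X, Z = np.meshgrid(x, z)

    labels = np.full((nz, nx), SOLID, dtype=np.uint8)
    in_matrix = (np.abs(X) < g.matrix_channel_width / 2.0 - _EPS) & (
        np.abs(Z) < g.channel_half_height - _EPS
    )
    labels[in_matrix] = MATRIX
    xc = g.lumen_center_spacing / 2.0
    r2 = g.lumen_radius**2 + _EPS
    labels[(X + xc) ** 2 + Z**2 <= r2] = LUMEN_LEFT
    labels[(X - xc) ** 2 + Z**2 <= r2] = LUMEN_RIGHT

    mask = DomainMask(
        grid_pitch=grid_pitch, labels=labels, x=x, z=z, geometry=geometry
    )
    if g.gap_width > 0:
        band = np.abs(z) < g.gap_width / 2.0 - _EPS
        for iz in np.flatnonzero(band):
            row = labels[iz]
            lum_l = np.flatnonzero(row == LUMEN_LEFT)
            lum_r = np.flatnonzero(row == LUMEN_RIGHT)
            mat = np.flatnonzero(row == MATRIX)
            if lum_l.size and mat.size:
                mask.interface_left.append(((iz, int(lum_l.max())), (iz, int(mat.min()))))
            if lum_r.size and mat.size:
                mask.interface_right.append(((iz, int(lum_r.min())), (iz, int(mat.max()))))
    return mask


def build_slab_mask(length: float, grid_pitch: float, held_cells: int = 1) -> DomainMask:
    """Single-row 1-D slab: ``held_cells`` lumen cells followed by matrix.

    A convenience domain for validating the solver against the
    semi-infinite-slab closed form; the lumen cell(s) act as the held
    concentration boundary.
    """
    if grid_pitch <= 0 or length <= 0:
        raise ValueError("length and grid_pitch must be positive")
    n = int(round(length / grid_pitch))
    if n < held_cells + 2:
        raise ValueError("slab too short for the requested pitch")
    labels = np.full((1, n), MATRIX, dtype=np.uint8)
    labels[0, :held_cells] = LUMEN_LEFT
    x = (np.arange(n) - (held_cells - 1)) * grid_pitch  # x=0 at last held-cell centre
    z = np.zeros(1)
    mask = DomainMask(grid_pitch=grid_pitch, labels=labels, x=x, z=z, geometry=None)
    mask.interface_left.append(((0, held_cells - 1), (0, held_cells)))
    return mask
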