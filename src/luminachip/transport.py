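"""Finite-volume diffusion solver for the chip cross-section.

The model solves the transport equation of a dilute species,

    ∂C/∂t + u·∇C = ∇·(D ∇C) + R,      R ≡ 0,

on the labelled lattice of a :class:`~luminachip.geometry.DomainMask`,
with no-flux conditions on all solid walls and a partition condition at
the endothelialized lumen–matrix interface: the membrane carries a flux

    q = T · (k · C_lumen − C_matrix)        [conc · μm / s]

per unit arc length, so the two sides equilibrate at the concentration
jump C_matrix = k · C_lumen while the flux itself is continuous.  The
partition coefficient k ∈ (0, 1] measures barrier tightness (smaller k,
tighter barrier); T is the interface transmission in μm/s, defaulting to
D_matrix / pitch (a membrane one cell thick).

Discretization: cell-centred finite volumes, harmonic-mean face
diffusivities, backward Euler by default (an explicit scheme is provided
for teaching and cross-checks).  The axial dimension is not resolved;
reservoir replenishment by slow axial flow is emulated by the
``held_constant`` / ``replenished_flow`` lumen modes.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import erfc

from .geometry import DomainMask, SOLID, LUMEN_LEFT, LUMEN_RIGHT, MATRIX

logger = logging.getLogger(__name__)

#: concentration this negative is treated as a solver failure
_NEGATIVITY_FAILURE = 1e-6
#: concentration negativity clamped with a warning
_NEGATIVITY_WARN = 1e-12

LUMEN_MODES = ("held_constant", "replenished_flow", "closed")
SCHEMES = ("implicit", "explicit")
SCENARIOS = ("moderate", "high_concentration_gel", "low_concentration_gel", "extra_right_source")


class SolverError(RuntimeError):
    """Raised when the time integration produces invalid concentrations."""


class StabilityError(ValueError):
    """Explicit time step violates the diffusion stability bound."""


@dataclass(frozen=True)
class Species:
    """Solute descriptor.

    Diffusivities are in μm²/s.  The defaults used for the two dextran
    tracers are order-of-magnitude values typical for dextran in dilute
    collagen gels; they are configuration values, not measured constants.
    """

    name: str
    molecular_weight: float  # kDa
    D_lumen: float  # μm²/s
    D_matrix: float  # μm²/s
    partition_k: float = 1.0

    def __post_init__(self):
        if self.D_lumen <= 0 or self.D_matrix <= 0:
            raise ValueError("diffusivities must be strictly positive")
        if not (0 < self.partition_k <= 1):
            raise ValueError("partition_k must lie in (0, 1]")


def dextran_10kda(k: float = 0.85) -> Species:
    """10 kDa FITC-dextran with its fitted endothelial partition coefficient."""
    return Species("dextran-10kDa", 10.0, 100.0, 100.0, k)


def dextran_70kda(k: float = 0.05) -> Species:
    """70 kDa FITC-dextran with its fitted endothelial partition coefficient."""
    return Species("dextran-70kDa", 70.0, 35.0, 35.0, k)


@dataclass(frozen=True)
class SimulationConfig:
    """Time-integration settings.

    ``interface_transmission`` (μm/s) overrides the default membrane
    transmission T = D_matrix / pitch; it is the dial used when a
    synthetic assay is generated for a target diffusive permeability.
    ``hold_left`` / ``hold_right`` are the lumen concentrations enforced
    in ``held_constant`` mode (the asymmetric source scenario holds the
    right lumen at 0.5).
    """

    dt: float = 5.0  # s
    t_end: float = 1800.0  # s
    sample_times: tuple = ()
    lumen_mode: str = "held_constant"
    axial_velocity: float = 0.0  # μm/s, feeds the replenishment rate
    replenishment_rate: float = 0.05  # 1/s
    reaction_rate: float = 0.0  # fixed at zero
    scheme: str = "implicit"
    seed: int | None = None
    interface_transmission: float | None = None  # μm/s
    hold_left: float = 1.0
    hold_right: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.lumen_mode not in LUMEN_MODES:
            raise ValueError(f"lumen_mode must be one of {LUMEN_MODES}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.reaction_rate != 0.0:
            raise ValueError("the reaction term is identically zero in this model")

    def resolved_sample_times(self) -> tuple:
        if self.sample_times:
            return tuple(sorted(set(float(t) for t in self.sample_times) | {0.0}))
        return (0.0, float(self.t_end))


@dataclass
class ConcentrationField:
    """Normalized concentration on the mask lattice at one instant.

    Values in SOLID cells are kept at zero and carry no meaning.
    """

    values: np.ndarray
    time: float
    mask: DomainMask

    def compartment_mean(self, label: int) -> float:
        sel = self.mask.labels == label
        return float(self.values[sel].mean())

    def compartment_mass(self, label: int) -> float:
        sel = self.mask.labels == label
        return float(self.values[sel].sum()) * self.mask.grid_pitch**2


@dataclass
class SimulationResult:
    """Sampled fields plus the conserved-mass and interface-flux ledgers."""

    fields: list
    times: np.ndarray  # ledger times, s
    total_mass: np.ndarray  # dimensionless · μm²
    flux_left: np.ndarray  # conc · μm²/s per unit axial length
    flux_right: np.ndarray
    config: SimulationConfig
    species: Species

    def field_at(self, t: float) -> ConcentrationField:
        i = int(np.argmin([abs(f.time - t) for f in self.fields]))
        return self.fields[i]

    @property
    def mass_drift(self) -> float:
        """Max relative drift of total mass over the run."""
        m0 = self.total_mass[0]
        if m0 == 0:
            return float(np.max(np.abs(self.total_mass)))
        return float(np.max(np.abs(self.total_mass - m0)) / abs(m0))


def analytic_slab_solution(x, t: float, D: float):
    """Semi-infinite slab with a unit held boundary: C = erfc(x / (2√(Dt)))."""
    if t <= 0:
        raise ValueError("t must be positive")
    if D <= 0:
        raise ValueError("D must be positive")
    return erfc(np.asarray(x, dtype=float) / (2.0 * math.sqrt(D * t)))


def partition_flux(c_lumen: float, c_matrix: float, k: float, D_eff: float, pitch: float):
    """Membrane flux per unit interface arc length, conc·μm/s.

    q = (D_eff / pitch) · (k · c_lumen − c_matrix): zero exactly at the
    partition equilibrium c_matrix = k · c_lumen, positive into the
    matrix when the lumen side is overconcentrated.
    """
    if k <= 0:
        raise ValueError("partition coefficient k must be positive")
    if D_eff <= 0 or pitch <= 0:
        raise ValueError("D_eff and pitch must be positive")
    return (D_eff / pitch) * (k * np.asarray(c_lumen, dtype=float) - np.asarray(c_matrix, dtype=float))


def initial_field(
    mask: DomainMask,
    lumen_left: float = 1.0,
    lumen_right: float = 1.0,
    matrix: float = 0.0,
) -> ConcentrationField:
    """Standard assay start: lumens loaded, matrix empty."""
    values = np.zeros(mask.shape, dtype=float)
    values[mask.labels == LUMEN_LEFT] = lumen_left
    values[mask.labels == LUMEN_RIGHT] = lumen_right
    values[mask.labels == MATRIX] = matrix
    return ConcentrationField(values=values, time=0.0, mask=mask)


def _assemble(mask: DomainMask, species: Species, config: SimulationConfig):
    """Build the spatial operator L (dc/dt = L c + s) over active cells."""
    labels = mask.labels
    p = mask.grid_pitch
    active = labels != SOLID
    n = int(active.sum())
    ids = np.full(labels.shape, -1, dtype=np.int64)
    ids[active] = np.arange(n)

    Dcell = np.where(labels == MATRIX, species.D_matrix, species.D_lumen).astype(float)

    rows, cols, vals = [], [], []

    # faces between lattice-adjacent cells of the same compartment
    for axis in (0, 1):
        a = (slice(None), slice(None, -1)) if axis == 1 else (slice(None, -1), slice(None))
        b = (slice(None), slice(1, None)) if axis == 1 else (slice(1, None), slice(None))
        same = (labels[a] == labels[b]) & active[a]
        ia = ids[a][same]
        ib = ids[b][same]
        Da = Dcell[a][same]
        Db = Dcell[b][same]
        w = (2.0 * Da * Db / (Da + Db)) / p**2
        rows.append(ia)
        cols.append(ib)
        vals.append(w)
        rows.append(ib)
        cols.append(ia)
        vals.append(w)
        rows.append(ia)
        cols.append(ia)
        vals.append(-w)
        rows.append(ib)
        cols.append(ib)
        vals.append(-w)

    rows = [np.atleast_1d(r) for r in rows]
    cols = [np.atleast_1d(c) for c in cols]
    vals = [np.atleast_1d(v) for v in vals]

    # membrane pairs: flux q = T (k c_L - c_M) per unit arc length
    T = config.interface_transmission
    if T is None:
        T = species.D_matrix / p
    k = species.partition_k
    beta = T / p  # 1/s
    for (lz, lx), (mz, mx) in mask.interface_pairs:
        il, im = int(ids[lz, lx]), int(ids[mz, mx])
        if il < 0 or im < 0:
            raise ValueError("interface pair references a SOLID cell")
        rows.append(np.array([im, im, il, il]))
        cols.append(np.array([il, im, il, im]))
        vals.append(np.array([beta * k, -beta, -beta * k, beta]))

    source = np.zeros(n)
    held = np.zeros(n, dtype=bool)
    lumen_sel = (labels == LUMEN_LEFT) | (labels == LUMEN_RIGHT)
    if config.lumen_mode == "held_constant":
        held[ids[lumen_sel]] = True
    elif config.lumen_mode == "replenished_flow":
        rate = config.replenishment_rate
        if config.axial_velocity > 0 and mask.geometry is not None:
            # fresh medium advected through the lumen length by creeping flow
            rate = config.axial_velocity / (mask.geometry.lumen_length * 1000.0)
        for lab, hold in ((LUMEN_LEFT, config.hold_left), (LUMEN_RIGHT, config.hold_right)):
            sel = ids[labels == lab]
            rows.append(sel)
            cols.append(sel)
            vals.append(np.full(sel.size, -rate))
            source[sel] += rate * hold

    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    if held.any():
        # held cells have dc/dt = 0: zero their rows
        diag = sp.diags((~held).astype(float))
        L = diag @ L
        source[held] = 0.0
    return L, source, ids, active, T


def simulate_transport(
    mask: DomainMask,
    species: Species,
    config: SimulationConfig,
    initial: ConcentrationField | None = None,
) -> SimulationResult:
    """Integrate the diffusion problem and return sampled fields and ledgers.

    In ``held_constant`` mode the lumen cells are Dirichlet-held at their
    initial values (overridden to ``hold_left`` / ``hold_right`` when the
    default initial field is used); ``closed`` runs conserve total mass to
    solver tolerance.
    """
    if initial is None:
        initial = initial_field(mask, lumen_left=config.hold_left, lumen_right=config.hold_right)
    if initial.values.shape != mask.shape:
        raise ValueError("initial field shape does not match mask")

    p = mask.grid_pitch
    maxD = max(species.D_lumen, species.D_matrix)
    if config.scheme == "explicit":
        dt_max = p**2 / (4.0 * maxD)
        if config.dt > dt_max:
            raise StabilityError(
                f"explicit scheme requires dt ≤ {dt_max:.6g} s at pitch {p} μm "
                f"(got dt = {config.dt} s)"
            )

    L, source, ids, active, T = _assemble(mask, species, config)
    c = initial.values[active].astype(float).copy()

    n_steps = int(math.ceil(config.t_end / config.dt - 1e-12))
    times = np.empty(n_steps + 1)
    mass = np.empty(n_steps + 1)
    flux_l = np.empty(n_steps + 1)
    flux_r = np.empty(n_steps + 1)
    cell_area = p**2
    k = species.partition_k

    def side_flux(cvec, pairs):
        if not pairs:
            return 0.0
        il = np.array([ids[a] for a, _ in pairs])
        im = np.array([ids[b] for _, b in pairs])
        return float(np.sum(T * (k * cvec[il] - cvec[im])) * p)

    sample_times = config.resolved_sample_times()
    fields = []

    def record_field(t, cvec):
        full = np.zeros(mask.shape)
        full[active] = cvec
        fields.append(ConcentrationField(values=full, time=t, mask=mask))

    times[0] = 0.0
    mass[0] = c.sum() * cell_area
    flux_l[0] = side_flux(c, mask.interface_left)
    flux_r[0] = side_flux(c, mask.interface_right)

    next_sample = 0
    if abs(sample_times[0]) < 1e-12:
        record_field(0.0, c)
        next_sample = 1

    lu = None
    if config.scheme == "implicit":
        A = (sp.identity(L.shape[0], format="csr") - config.dt * L).tocsc()
        lu = splu(A)

    t = 0.0
    warned = False
    for step in range(1, n_steps + 1):
        dt = min(config.dt, config.t_end - t)
        if config.scheme == "implicit":
            if dt != config.dt:
                A = (sp.identity(L.shape[0], format="csr") - dt * L).tocsc()
                lu = splu(A)
            c = lu.solve(c + dt * source)
        else:
            c = c + dt * (L @ c + source)
        t += dt

        if not np.all(np.isfinite(c)):
            raise SolverError(f"non-finite concentration at t = {t:.6g} s")
        cmin = c.min()
        if cmin < -_NEGATIVITY_FAILURE:
            raise SolverError(f"concentration {cmin:.3e} below failure tolerance at t = {t:.6g} s")
        if cmin < 0:
            if cmin < -_NEGATIVITY_WARN and not warned:
                logger.warning("clamping negative concentration %.3e at t = %.6g s", cmin, t)
                warned = True
            c = np.maximum(c, 0.0)

        times[step] = t
        mass[step] = c.sum() * cell_area
        flux_l[step] = side_flux(c, mask.interface_left)
        flux_r[step] = side_flux(c, mask.interface_right)

        while next_sample < len(sample_times) and t >= sample_times[next_sample] - dt / 2:
            record_field(t, c)
            next_sample += 1

    while next_sample < len(sample_times):  # sample times beyond t_end clamp to final state
        record_field(t, c)
        next_sample += 1

    return SimulationResult(
        fields=fields,
        times=times,
        total_mass=mass,
        flux_left=flux_l,
        flux_right=flux_r,
        config=config,
        species=species,
    )


def run_scenario(
    mask: DomainMask,
    species: Species,
    config: SimulationConfig,
    scenario: str = "moderate",
    initial: ConcentrationField | None = None,
) -> SimulationResult:
    """Run one of the named what-if variants of the transport model.

    ``high_concentration_gel`` halves the matrix diffusivity (denser
    gel), ``low_concentration_gel`` doubles it, and
    ``extra_right_source`` holds the right lumen at concentration 0.5
    while the left stays at 1.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "high_concentration_gel":
        species = dataclasses.replace(species, D_matrix=0.5 * species.D_matrix)
    elif scenario == "low_concentration_gel":
        species = dataclasses.replace(species, D_matrix=2.0 * species.D_matrix)
    elif scenario == "extra_right_source":
        config = dataclasses.replace(config, lumen_mode="held_constant", hold_right=0.5)
        if initial is not None:
            warnings.warn("extra_right_source overrides the initial lumen values", stacklevel=2)
            initial = None
    return simulate_transport(mask, species, config, initial)
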