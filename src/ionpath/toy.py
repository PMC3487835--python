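"""Analytic toy model of a K+ selectivity filter and its Brownian surrogate.

The toy system replaces an all-atom channel with a one-dimensional pore
axis (z, increasing toward the extracellular side) carrying a sequence of
binding sites.  Each site is a Gaussian well; adjacent sites are separated
by Gaussian barriers centered at the midpoints.  Up to three ions move in
single file and interact through a screened Coulomb-like repulsion
``A/r * exp(-r/kappa)``, which diverges at contact and therefore forbids
ion crossing, exactly as in a real single-file pore.

Because the potential is analytic, exact free-energy surfaces can be
computed by direct Boltzmann integration (:func:`exact_fes`), which serves
as the oracle for every free-energy estimator in the package.  Dynamics is
overdamped (position) Langevin: the conclusions downstream depend on the
free-energy landscape and the collective-variable machinery, not on a
force field, so inertia and explicit solvent are deliberately absent.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, thermal_energy
from .grids import FESGrid, GridAxis

__all__ = [
    "SITE_NAMES",
    "ToyFilterSystem",
    "build_toy_system",
    "DoubleWell",
    "HarmonicWell",
    "SingleParticleSystem",
    "Trajectory",
    "generate_trajectory",
    "exact_fes",
    "exact_fes_1d",
    "toy_frame",
    "scaffold_coordinates",
    "generate_reference_path",
    "DEFAULT_PERMEATION_CYCLE",
]

#: Canonical site names from the intracellular cavity (Sint) to the
#: extracellular solution (Sext).  S1-S4 are the filter sites numbered
#: from the extracellular side, so along +z the order is S4 < S3 < S2 < S1.
SITE_NAMES = ("Sint", "S5", "S4", "S3", "S2", "S1", "S0", "Sext")

#: Typical spacing of carbonyl cages in a K+ filter (angstrom).
DEFAULT_SITE_SPACING = 3.1


class CoverageWarning(UserWarning):
    """Raised when an integration grid does not cover the Boltzmann support."""


@dataclasses.dataclass
class ToyFilterSystem:
    """Multi-site, multi-ion single-file pore with an analytic potential.

    Parameters
    ----------
    site_centers:
        Axial site positions (angstrom), strictly increasing toward the
        extracellular side.
    well_depths:
        Positive well depths per site (kcal/mol).  The single-ion
        potential at a site center equals minus that depth (up to the
        negligible tails of neighboring Gaussians).
    barrier_heights:
        Positive Gaussian barrier heights between adjacent sites
        (kcal/mol), centered at the midpoints.
    repulsion_strength:
        ``A`` in the pair term ``A/r * exp(-r/kappa)`` (kcal*angstrom/mol).
    screening_length:
        ``kappa`` (angstrom).
    boundary_margin, boundary_k:
        Harmonic confinement beyond the outermost sites, standing in for
        the boundary potentials that keep ions near the filter region.
    """

    site_centers: np.ndarray
    well_depths: np.ndarray
    barrier_heights: np.ndarray
    site_names: tuple[str, ...] = SITE_NAMES
    well_sigma: float = 0.45
    barrier_sigma: float = 0.35
    repulsion_strength: float = 20.0
    screening_length: float = 2.0
    n_ions: int = 3
    temperature: float = DEFAULT_TEMPERATURE
    boundary_margin: float = 2.0
    boundary_k: float = 5.0

    def __post_init__(self) -> None:
        self.site_centers = np.asarray(self.site_centers, dtype=float)
        self.well_depths = np.asarray(self.well_depths, dtype=float)
        self.barrier_heights = np.asarray(self.barrier_heights, dtype=float)
        n = self.site_centers.size
        if n < 4:
            raise ValueError("need at least four binding sites")
        if not np.all(np.diff(self.site_centers) > 0):
            raise ValueError("site_centers must be strictly increasing along z")
        if self.well_depths.size != n:
            raise ValueError("one well depth per site required")
        if self.barrier_heights.size != n - 1:
            raise ValueError("one barrier height per adjacent site pair required")
        if np.any(self.well_depths <= 0) or np.any(self.barrier_heights <= 0):
            raise ValueError("well depths and barrier heights must be positive")
        if len(self.site_names) != n:
            raise ValueError("one site name per site required")
        if self.n_ions < 1:
            raise ValueError("need at least one ion")
        self._barrier_centers = 0.5 * (self.site_centers[:-1] + self.site_centers[1:])

    # -- geometry ---------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.site_centers.size

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def z_bounds(self) -> tuple[float, float]:
        return (
            float(self.site_centers[0] - self.boundary_margin),
            float(self.site_centers[-1] + self.boundary_margin),
        )

    def site_center(self, name: str) -> float:
        try:
            return float(self.site_centers[self.site_names.index(name)])
        except ValueError as exc:
            raise KeyError(f"unknown site {name!r}") from exc

    # -- energies ---------------------------------------------------------

    def single_ion_potential(self, z):
        """Potential of one ion at axial position(s) z (kcal/mol)."""
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        two_sw2 = 2.0 * self.well_sigma**2
        two_sb2 = 2.0 * self.barrier_sigma**2
        for c, d in zip(self.site_centers, self.well_depths):
            u -= d * np.exp(-((z - c) ** 2) / two_sw2)
        for c, h in zip(self._barrier_centers, self.barrier_heights):
            u += h * np.exp(-((z - c) ** 2) / two_sb2)
        lo, hi = self.z_bounds
        u += np.where(z < lo, self.boundary_k * (z - lo) ** 2, 0.0)
        u += np.where(z > hi, self.boundary_k * (z - hi) ** 2, 0.0)
        return u if u.ndim else float(u)

    def single_ion_force(self, z: float) -> float:
        """-dU/dz for a single ion (kcal/mol/angstrom); scalar fast path."""
        du = 0.0
        sw2 = self.well_sigma**2
        sb2 = self.barrier_sigma**2
        for c, d in zip(self.site_centers, self.well_depths):
            dz = z - c
            du += d * dz / sw2 * math.exp(-dz * dz / (2.0 * sw2))
        for c, h in zip(self._barrier_centers, self.barrier_heights):
            dz = z - c
            du -= h * dz / sb2 * math.exp(-dz * dz / (2.0 * sb2))
        lo, hi = self.z_bounds
        if z < lo:
            du += 2.0 * self.boundary_k * (z - lo)
        elif z > hi:
            du += 2.0 * self.boundary_k * (z - hi)
        return -du

    def pair_potential(self, r):
        """Screened ion-ion repulsion at separation r > 0 (kcal/mol)."""
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore"):
            u = self.repulsion_strength / r * np.exp(-r / self.screening_length)
        return u if u.ndim else float(u)

    def pair_force_mag(self, r: float) -> float:
        """Magnitude of the repulsive force -du/dr at separation r."""
        a, k = self.repulsion_strength, self.screening_length
        return a * math.exp(-r / k) * (1.0 / r**2 + 1.0 / (r * k))

    def total_energy(self, positions) -> float | np.ndarray:
        """Total potential of an ion configuration.

        ``positions`` is an array of shape (n_ions,) or (n_frames, n_ions).
        """
        pos = np.asarray(positions, dtype=float)
        single = self.single_ion_potential(pos)
        u = single.sum(axis=-1) if pos.ndim else float(single)
        if pos.ndim == 1:
            u = float(single.sum())
        n = pos.shape[-1]
        for i in range(n):
            for j in range(i + 1, n):
                r = np.abs(pos[..., i] - pos[..., j])
                u = u + self.pair_potential(r)
        return float(u) if np.ndim(u) == 0 else u

    def forces(self, positions: Sequence[float]) -> list[float]:
        """Per-ion axial forces for a single configuration (list of floats)."""
        n = len(positions)
        f = [self.single_ion_force(z) for z in positions]
        for i in range(n):
            for j in range(i + 1, n):
                dz = positions[i] - positions[j]
                mag = self.pair_force_mag(abs(dz))
                if dz >= 0:
                    f[i] += mag
                    f[j] -= mag
                else:
                    f[i] -= mag
                    f[j] += mag
        return f

    def default_ion_positions(self) -> list[float]:
        """Default start: ions on alternating filter sites (S4, S2, S0, ...)."""
        idx_s4 = self.site_names.index("S4") if "S4" in self.site_names else 0
        out = []
        i = idx_s4
        for _ in range(self.n_ions):
            out.append(float(self.site_centers[min(i, self.n_sites - 1)]))
            i += 2
        return out


def build_toy_system(config: dict | None = None, **overrides) -> ToyFilterSystem:
    """Build a :class:`ToyFilterSystem` from a parameter mapping.

    Recognized keys: ``n_sites`` (default 8, named Sint..Sext),
    ``site_spacing`` or explicit ``site_centers``, ``well_depths`` (scalar
    or per-site), ``barrier_heights`` (scalar or per-pair) and any field of
    :class:`ToyFilterSystem`.
    """
    params = dict(config or {})
    params.update(overrides)
    n_sites = int(params.pop("n_sites", 8))
    spacing = float(params.pop("site_spacing", DEFAULT_SITE_SPACING))
    if "site_centers" in params:
        centers = np.asarray(params.pop("site_centers"), dtype=float)
        n_sites = centers.size
    else:
        # place S4 (index 2 of the canonical ladder) at the origin when the
        # canonical eight sites are used; otherwise start at zero
        offset = -2 * spacing if n_sites == len(SITE_NAMES) else 0.0
        centers = offset + spacing * np.arange(n_sites)
    names = params.pop("site_names", None)
    if names is None:
        names = SITE_NAMES if n_sites == len(SITE_NAMES) else tuple(
            f"site{i}" for i in range(n_sites)
        )
    depths = params.pop("well_depths", 3.0)
    depths = np.broadcast_to(np.asarray(depths, dtype=float), (n_sites,)).copy()
    barriers = params.pop("barrier_heights", 2.5)
    barriers = np.broadcast_to(
        np.asarray(barriers, dtype=float), (n_sites - 1,)
    ).copy()
    return ToyFilterSystem(
        site_centers=centers,
        well_depths=depths,
        barrier_heights=barriers,
        site_names=tuple(names),
        **params,
    )


# ---------------------------------------------------------------------------
# simple 1D potentials used as oracles and test beds
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DoubleWell:
    """Quartic double well ``U = h * ((z/a)^2 - 1)^2``.

    Minima at z = +-a with U = 0; the barrier at z = 0 is exactly ``h``.
    """

    barrier: float = 3.0
    half_separation: float = 1.55

    def potential(self, z):
        a = self.half_separation
        return self.barrier * (np.square(np.asarray(z) / a) - 1.0) ** 2

    def force(self, z: float) -> float:
        a = self.half_separation
        return -4.0 * self.barrier * z * ((z / a) ** 2 - 1.0) / a**2

    @property
    def bounds(self) -> tuple[float, float]:
        a = self.half_separation
        return (-2.2 * a, 2.2 * a)


@dataclasses.dataclass
class HarmonicWell:
    """``U = k/2 (z - z0)^2``; equilibrium variance is kT/k."""

    k: float = 1.0
    z0: float = 0.0

    def potential(self, z):
        return 0.5 * self.k * np.square(np.asarray(z) - self.z0)

    def force(self, z: float) -> float:
        return -self.k * (z - self.z0)

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.z0 - 20.0, self.z0 + 20.0)


@dataclasses.dataclass
class SingleParticleSystem:
    """Adapter giving a bare 1D potential the multi-ion system interface."""

    potential_1d: object
    temperature: float = DEFAULT_TEMPERATURE

    n_ions: int = 1

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def z_bounds(self) -> tuple[float, float]:
        return self.potential_1d.bounds

    def single_ion_potential(self, z):
        return self.potential_1d.potential(z)

    def total_energy(self, positions) -> float:
        pos = np.asarray(positions, dtype=float)
        return float(np.sum(self.potential_1d.potential(pos)))

    def forces(self, positions: Sequence[float]) -> list[float]:
        return [self.potential_1d.force(z) for z in positions]

    def default_ion_positions(self) -> list[float]:
        lo, hi = self.z_bounds
        if isinstance(self.potential_1d, DoubleWell):
            return [-self.potential_1d.half_separation]
        if isinstance(self.potential_1d, HarmonicWell):
            return [self.potential_1d.z0]
        return [0.5 * (lo + hi)]


# ---------------------------------------------------------------------------
# exact free energies by direct Boltzmann integration
# ---------------------------------------------------------------------------


def exact_fes_1d(
    potential: Callable[[np.ndarray], np.ndarray] | object,
    axis: GridAxis,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FESGrid:
    """Exact FES of a 1D system: the potential itself, min-shifted to zero."""
    fn = potential.potential if hasattr(potential, "potential") else potential
    values = np.asarray(fn(axis.centers), dtype=float)
    return FESGrid((axis,), values, temperature).normalize()


def exact_fes(
    system: ToyFilterSystem,
    axis: GridAxis,
    ion: int = 0,
    n_quad: int = 161,
    temperature: float | None = None,
    ordered: bool = True,
) -> FESGrid:
    """Exact marginal free energy of one ion's axial position.

    Integrates the Boltzmann factor of the analytic toy potential over the
    positions of the remaining ions by brute-force quadrature on a regular
    grid of ``n_quad`` points per integrated coordinate.  With
    ``ordered=True`` (the default, matching single-file dynamics that
    cannot swap ions) the integral runs over the sector where ion labels
    are sorted by ascending z.

    The marginal converges to the exact result as ``n_quad`` grows; a
    :class:`CoverageWarning` is emitted if the integration box truncates
    non-negligible Boltzmann weight.
    """
    kT = thermal_energy(temperature) if temperature else system.kT
    n = system.n_ions
    if not 0 <= ion < n:
        raise ValueError(f"ion index {ion} out of range for {n} ions")
    lo, hi = system.z_bounds
    lo -= 1.5
    hi += 1.5
    quad = np.linspace(lo, hi, n_quad)
    grids: list[np.ndarray] = []
    for i in range(n):
        g = axis.centers if i == ion else quad
        shape = [1] * n
        shape[i] = g.size
        grids.append(g.reshape(shape))
    u_single = [system.single_ion_potential(g) for g in grids]
    U = u_single[0]
    for u in u_single[1:]:
        U = U + u
    for i in range(n):
        for j in range(i + 1, n):
            r = np.abs(grids[i] - grids[j])
            U = U + system.pair_potential(r)
    if ordered and n > 1:
        mask = np.ones(np.broadcast_shapes(*(g.shape for g in grids)), dtype=bool)
        for i in range(n - 1):
            mask = mask & (grids[i] < grids[i + 1])
        U = np.where(mask, U, np.inf)
    B = np.exp(-(U - np.min(U)) / kT)
    other_axes = tuple(i for i in range(n) if i != ion)
    marg = B.sum(axis=other_axes) if other_axes else B
    # coverage diagnostic: Boltzmann weight at the box edges
    if n > 1:
        edge = 0.0
        for i in other_axes:
            sl_lo = [slice(None)] * n
            sl_lo[i] = slice(0, 1)
            sl_hi = [slice(None)] * n
            sl_hi[i] = slice(-1, None)
            edge += float(B[tuple(sl_lo)].sum() + B[tuple(sl_hi)].sum())
        if edge > 1e-6 * float(B.sum()):
            warnings.warn(
                "integration box may truncate Boltzmann support", CoverageWarning
            )
    with np.errstate(divide="ignore"):
        F = -kT * np.log(marg)
    F[~np.isfinite(F)] = np.nan
    return FESGrid((axis,), F, temperature or system.temperature).normalize()


# ---------------------------------------------------------------------------
# overdamped Langevin surrogate for MD
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Trajectory:
    """Recorded Langevin trajectory: times (ps) and per-frame ion positions."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_ions)
    bias_energies: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def generate_trajectory(
    system,
    n_steps: int,
    dt: float = 0.01,
    seed: int = 0,
    x0: Sequence[float] | None = None,
    bias=None,
    stride: int = 10,
    diffusion: float = 0.1,
    hard_bound: float = 60.0,
) -> Trajectory:
    """Overdamped Langevin dynamics of the toy ions.

    Euler-Maruyama integration of ``dz = (D/kT) F dt + sqrt(2 D dt) xi``;
    time in ps, ``diffusion`` in angstrom^2/ps.  The step size must keep
    the stiffest mode stable: for a harmonic well of stiffness k the
    scheme requires ``D k dt / kT < 1`` and adds a relative equilibrium-
    variance bias of ``(D k dt)/(2 kT)``, which is the documented check
    behind the default dt.

    ``bias``, when given, must provide ``energy(positions) -> float`` and
    ``forces(positions) -> sequence``; the instantaneous bias energy is
    recorded per frame.  Trajectories are bit-reproducible for a fixed
    seed.  An ion leaving ``[-hard_bound, hard_bound]`` raises a
    RuntimeError naming the offending step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    pos = list(map(float, x0 if x0 is not None else system.default_ion_positions()))
    n_ions = len(pos)
    kT = system.kT
    c = diffusion * dt / kT
    g = math.sqrt(2.0 * diffusion * dt)
    n_frames = n_steps // stride + 1
    out = np.empty((n_frames, n_ions))
    times = np.empty(n_frames)
    biases = np.empty(n_frames) if bias is not None else None
    out[0] = pos
    times[0] = 0.0
    if biases is not None:
        biases[0] = bias.energy(pos)
    frame = 1
    chunk = 65536
    step = 0
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = rng.standard_normal((m, n_ions))
        for k in range(m):
            f = system.forces(pos)
            if bias is not None:
                bf = bias.forces(pos)
                for i in range(n_ions):
                    f[i] += bf[i]
            row = noise[k]
            for i in range(n_ions):
                z = pos[i] + c * f[i] + g * row[i]
                if z < -hard_bound or z > hard_bound:
                    raise RuntimeError(
                        f"trajectory diverged at step {step + k + 1} (ion {i}, z={z:.2f})"
                    )
                pos[i] = z
            if (step + k + 1) % stride == 0:
                out[frame] = pos
                times[frame] = (step + k + 1) * dt
                if biases is not None:
                    biases[frame] = bias.energy(pos)
                frame += 1
        step += m
    return Trajectory(times[:frame], out[:frame], biases[:frame] if biases is not None else None)


# ---------------------------------------------------------------------------
# reference permeation path
# ---------------------------------------------------------------------------

#: Occupancy-state waypoints of one full permeation cycle: both endpoints
#: carry two filter-bound ions, and one K+ is moved from the intracellular
#: to the extracellular side through the knock-on intermediate.
DEFAULT_PERMEATION_CYCLE = (
    "Sint,[S4,S2]",
    "S5,[S4,S2]",
    "S5,[S3,S1]",
    "[S4,S3,S1]",
    "[S4,S2],S0",
    "[S4,S2],Sext",
)

#: Scaffold atoms shared by every path frame: two squares of four pseudo
#: C-alpha atoms bracketing the filter, enough for a non-degenerate
#: least-squares superposition.
_SCAFFOLD_RADIUS = 4.0


def scaffold_coordinates(system) -> np.ndarray:
    lo, hi = system.z_bounds
    coords = []
    for zlev in (lo - 1.0, hi + 1.0):
        for kx, ky in ((1, 0), (0, 1), (-1, 0), (0, -1)):
            coords.append((_SCAFFOLD_RADIUS * kx, _SCAFFOLD_RADIUS * ky, zlev))
    return np.asarray(coords, dtype=float)


def toy_frame(system, ion_z: Sequence[float]) -> np.ndarray:
    """Full 3D coordinates of a toy configuration: scaffold + ions on the axis."""
    scaffold = scaffold_coordinates(system)
    ions = np.column_stack(
        [np.zeros(len(ion_z)), np.zeros(len(ion_z)), np.asarray(ion_z, float)]
    )
    return np.vstack([scaffold, ions])


def _state_to_ion_z(system, state_code: str) -> np.ndarray:
    from .fes import parse_occupancy_state  # local import avoids a cycle

    state = parse_occupancy_state(state_code)
    return np.asarray([system.site_center(s) for s in state.sites_in_order()])


def generate_reference_path(
    system,
    n_frames: int = 16,
    state_sequence: Sequence[str] = DEFAULT_PERMEATION_CYCLE,
    lam: float | None = None,
):
    """Reference permeation path through a sequence of occupancy states.

    The ion triplet is interpolated piecewise-linearly through the state
    waypoints and resampled at equal arc length in ion-configuration
    space, which equalizes adjacent-frame MSDs (to within the small
    inhomogeneity introduced at waypoint kinks, < 10 %).  By default
    ``lambda`` is set so that ``lambda * <adjacent MSD> = 9.21``, i.e. the
    weight of a neighboring frame is 1e-4.

    Returns a :class:`ionpath.cv.PathDefinition` whose fit selection is
    the rigid scaffold and whose measure selection is the ions only, with
    ions relabeled by ascending z in the metric (ions are
    indistinguishable).
    """
    from .cv import PathDefinition

    states = list(state_sequence)
    if len(states) < 2:
        raise ValueError("need at least two occupancy states")
    if n_frames < len(states):
        raise ValueError(
            f"n_frames={n_frames} is fewer than the {len(states)} states"
        )
    waypoints = np.asarray([_state_to_ion_z(system, s) for s in states])
    if waypoints.shape[1] != system.n_ions:
        raise ValueError(
            "state sequence ion count does not match the system's n_ions"
        )
    # arc-length reparameterization in ion-configuration space, then a
    # fixed-point iteration that equalizes the chord (adjacent-frame)
    # distances, which the raw arc-length spacing shortens at waypoint kinks
    seg = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("consecutive states must differ")
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def frames_at(tvals: np.ndarray) -> np.ndarray:
        out = np.empty((tvals.size, system.n_ions))
        for d in range(system.n_ions):
            out[:, d] = np.interp(tvals, cum, waypoints[:, d])
        return out

    targets = np.linspace(0.0, cum[-1], n_frames)
    for _ in range(200):
        pts = frames_at(targets)
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        spread = (chords.max() - chords.min()) / chords.mean()
        if spread < 1e-3:
            break
        c_cum = np.concatenate([[0.0], np.cumsum(chords)])
        even = np.linspace(0.0, c_cum[-1], n_frames)
        targets = np.interp(even, c_cum, targets)
    ion_frames = frames_at(targets)
    frames = [toy_frame(system, zrow) for zrow in ion_frames]
    n_scaffold = scaffold_coordinates(system).shape[0]
    fit_sel = np.arange(n_scaffold)
    measure_sel = np.arange(n_scaffold, n_scaffold + system.n_ions)
    # adjacent MSD of the measured ions (scaffold is identical in all frames)
    adj_msd = np.sum(np.diff(ion_frames, axis=0) ** 2, axis=1) / system.n_ions
    if lam is None:
        lam = 9.21 / float(np.mean(adj_msd))
    state_to_frame = {
        s: int(np.argmin(np.abs(targets - c))) for s, c in zip(states, cum)
    }
    return PathDefinition(
        frames=frames,
        lam=float(lam),
        fit_selection=fit_sel,
        measure_selection=measure_sel,
        sort_measure_by_z=True,
        state_labels=state_to_frame,
    )
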