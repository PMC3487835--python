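"""History-dependent Gaussian biasing (metadynamics) on the toy system.

Standard (non-well-tempered) metadynamics: Gaussians of fixed height are
deposited along 1-3 collective variables at a fixed period, and the free
energy is estimated as minus the accumulated bias.  Multiple walkers
share one hill history (every walker feels the union of all hills, merged
by deposition time), one-sided harmonic walls confine the CVs, and the
biasing force on the ion coordinates is obtained by the chain rule with
analytic CV gradients where available and centered finite differences
otherwise.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .grids import FESGrid, GridAxis
from .toy import generate_trajectory  # noqa: F401  (re-exported convenience)

__all__ = [
    "Hill",
    "Wall",
    "MetadSchedule",
    "bias_energy",
    "wall_energy",
    "AxialIonPosition",
    "PathProgressCV",
    "PathDistanceCV",
    "MetadResult",
    "run_metadynamics",
    "fes_from_hills",
]


@dataclasses.dataclass(frozen=True)
class Hill:
    """One deposited Gaussian in CV space."""

    center: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    time: float
    walker_id: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if len(self.center) != len(self.widths):
            raise ValueError("center and widths must share a dimensionality")


@dataclasses.dataclass(frozen=True)
class Wall:
    """One-sided harmonic wall on a CV axis.

    ``side='upper'`` penalizes values above ``bound`` with k*(excess)^2,
    ``side='lower'`` penalizes values below it; the potential and its
    derivative are continuous at the bound.
    """

    axis: int
    bound: float
    side: str
    k: float

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise ValueError("wall side must be 'upper' or 'lower'")
        if self.k < 0:
            raise ValueError("wall force constant must be non-negative")

    def energy(self, value: float) -> float:
        if self.side == "upper":
            excess = value - self.bound
        else:
            excess = self.bound - value
        return self.k * excess * excess if excess > 0 else 0.0

    def derivative(self, value: float) -> float:
        if self.side == "upper":
            excess = value - self.bound
            return 2.0 * self.k * excess if excess > 0 else 0.0
        excess = self.bound - value
        return -2.0 * self.k * excess if excess > 0 else 0.0


def wall_energy(value: float, wall: Wall) -> float:
    """Energy of a CV value under a one-sided harmonic wall (kcal/mol)."""
    return wall.energy(value)


@dataclasses.dataclass
class MetadSchedule:
    """Deposition schedule for one metadynamics run.

    ``height`` in kcal/mol, ``deposition_period`` in ps, ``widths`` one
    Gaussian sigma per CV axis.
    """

    height: float = 0.06
    deposition_period: float = 2.0
    widths: tuple[float, ...] = (0.2,)
    walls: tuple[Wall, ...] = ()
    n_walkers: int = 1

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if self.deposition_period <= 0:
            raise ValueError("deposition period must be positive")
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")
        self.widths = tuple(float(w) for w in self.widths)
        self.walls = tuple(self.walls)


def _hill_arrays(hills: Sequence[Hill]):
    centers = np.asarray([h.center for h in hills], dtype=float)
    widths = np.asarray([h.widths for h in hills], dtype=float)
    heights = np.asarray([h.height for h in hills], dtype=float)
    return centers, widths, heights


def bias_energy(point: Sequence[float], hills: Sequence[Hill]) -> float:
    """Total bias at a CV-space point: sum of deposited Gaussians (kcal/mol)."""
    if not hills:
        return 0.0
    point = np.atleast_1d(np.asarray(point, dtype=float))
    centers, widths, heights = _hill_arrays(hills)
    if centers.shape[1] != point.size:
        raise ValueError(
            f"point has {point.size} dimensions but hills have {centers.shape[1]}"
        )
    arg = ((point - centers) / widths) ** 2
    return float(np.sum(heights * np.exp(-0.5 * arg.sum(axis=1))))


# ---------------------------------------------------------------------------
# collective variables evaluated on toy ion configurations
# ---------------------------------------------------------------------------


class AxialIonPosition:
    """CV: the axial position of one ion (angstrom); analytic gradient."""

    def __init__(self, ion: int = 0, name: str | None = None):
        self.ion = ion
        self.name = name or f"z{ion + 1}"

    def value(self, positions: Sequence[float]) -> float:
        return float(positions[self.ion])

    def gradient(self, positions: Sequence[float]) -> np.ndarray:
        g = np.zeros(len(positions))
        g[self.ion] = 1.0
        return g


class _PathCVBase:
    """Path CVs evaluated on toy ion z-configurations via full 3D frames."""

    def __init__(self, path, system, name: str, fd_step: float = 1e-4):
        from .toy import toy_frame

        self._toy_frame = toy_frame
        self.path = path
        self.system = system
        self.name = name
        self.fd_step = fd_step

    def _config(self, positions) -> np.ndarray:
        return self._toy_frame(self.system, list(positions))

    def value(self, positions: Sequence[float]) -> float:  # pragma: no cover
        raise NotImplementedError

    def gradient(self, positions: Sequence[float]) -> np.ndarray:
        # centered finite differences in the ion coordinates
        base = list(map(float, positions))
        g = np.zeros(len(base))
        for i in range(len(base)):
            up = list(base)
            dn = list(base)
            up[i] += self.fd_step
            dn[i] -= self.fd_step
            g[i] = (self.value(up) - self.value(dn)) / (2.0 * self.fd_step)
        return g


class PathProgressCV(_PathCVBase):
    """Progress S along a reference permeation path, in [0, 1]."""

    def __init__(self, path, system, name: str = "s", fd_step: float = 1e-4):
        super().__init__(path, system, name, fd_step)

    def value(self, positions: Sequence[float]) -> float:
        from .cv import path_s

        return path_s(self._config(positions), self.path)


class PathDistanceCV(_PathCVBase):
    """Distance Z from a reference permeation path (angstrom^2)."""

    def __init__(self, path, system, name: str = "z", fd_step: float = 1e-4):
        super().__init__(path, system, name, fd_step)

    def value(self, positions: Sequence[float]) -> float:
        from .cv import path_z

        return path_z(self._config(positions), self.path)


# ---------------------------------------------------------------------------
# the metadynamics driver
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetadResult:
    """Merged hill list plus per-walker CV time series."""

    hills: list[Hill]
    times: list[np.ndarray]
    cv_values: list[np.ndarray]  # per walker: (n_frames, n_cvs)
    positions: list[np.ndarray]  # per walker: (n_frames, n_ions)
    bias_energies: list[np.ndarray]
    cv_names: tuple[str, ...]

    @property
    def n_hills(self) -> int:
        return len(self.hills)


class _RunningBias:
    """Incrementally grown hill sum with analytic CV-space derivatives."""

    def __init__(self, ndim: int, capacity: int):
        self.ndim = ndim
        self.n = 0
        self.centers = np.empty((capacity, ndim))
        self.inv_w2 = np.empty((capacity, ndim))
        self.heights = np.empty(capacity)

    def add(self, center, widths, height) -> None:
        i = self.n
        if i >= self.heights.size:
            grow = max(256, self.heights.size)
            self.centers = np.vstack([self.centers, np.empty((grow, self.ndim))])
            self.inv_w2 = np.vstack([self.inv_w2, np.empty((grow, self.ndim))])
            self.heights = np.concatenate([self.heights, np.empty(grow)])
        self.centers[i] = center
        self.inv_w2[i] = 1.0 / np.square(widths)
        self.heights[i] = height
        self.n += 1

    def energy_and_gradient(self, point: np.ndarray):
        if self.n == 0:
            return 0.0, np.zeros(self.ndim)
        d = point - self.centers[: self.n]
        e = self.heights[: self.n] * np.exp(
            -0.5 * np.sum(d * d * self.inv_w2[: self.n], axis=1)
        )
        energy = float(e.sum())
        grad = -np.sum(e[:, None] * d * self.inv_w2[: self.n], axis=0)
        return energy, grad


def run_metadynamics(
    system,
    cvs: Sequence,
    schedule: MetadSchedule,
    n_steps: int,
    dt: float = 0.01,
    seeds: Sequence[int] = (0,),
    x0s: Sequence[Sequence[float]] | None = None,
    stride: int = 10,
    diffusion: float = 0.1,
    hard_bound: float = 60.0,
) -> MetadResult:
    """Multiple-walker metadynamics on the toy Langevin system.

    All walkers march synchronously; every ``deposition_period`` of
    simulated time each walker deposits one hill at its current CV point,
    and from that moment on every walker feels the merged hill history
    (sorted by time, then walker id).  Hill count per walker equals
    ``floor(simulated_time / deposition_period)``.  Reproducible for a
    fixed seed tuple.
    """
    n_cv = len(cvs)
    if len(schedule.widths) != n_cv:
        raise ValueError("schedule widths must match the number of CVs")
    if len(seeds) != schedule.n_walkers:
        raise ValueError("need one seed per walker")
    for wall in schedule.walls:
        if not 0 <= wall.axis < n_cv:
            raise ValueError("wall axis outside CV dimensionality")
    rngs = [np.random.default_rng(s) for s in seeds]
    if x0s is None:
        x0s = [system.default_ion_positions() for _ in range(schedule.n_walkers)]
    positions = [list(map(float, x0)) for x0 in x0s]
    n_ions = len(positions[0])
    kT = system.kT
    c = diffusion * dt / kT
    gaus = math.sqrt(2.0 * diffusion * dt)
    dep_every = max(1, int(round(schedule.deposition_period / dt)))
    n_dep = n_steps // dep_every
    bias = _RunningBias(n_cv, capacity=max(16, n_dep * schedule.n_walkers))
    hills: list[Hill] = []

    n_frames = n_steps // stride + 1
    rec_t = [np.empty(n_frames) for _ in range(schedule.n_walkers)]
    rec_cv = [np.empty((n_frames, n_cv)) for _ in range(schedule.n_walkers)]
    rec_pos = [np.empty((n_frames, n_ions)) for _ in range(schedule.n_walkers)]
    rec_bias = [np.empty(n_frames) for _ in range(schedule.n_walkers)]

    def cv_point(pos) -> np.ndarray:
        return np.asarray([cv.value(pos) for cv in cvs])

    def record(w: int, frame: int, t: float, pos, point, vbias: float) -> None:
        rec_t[w][frame] = t
        rec_cv[w][frame] = point
        rec_pos[w][frame] = pos
        rec_bias[w][frame] = vbias

    for w in range(schedule.n_walkers):
        pt = cv_point(positions[w])
        e, _ = bias.energy_and_gradient(pt)
        record(w, 0, 0.0, positions[w], pt, e)
    frame = 1

    noise_chunk = 8192
    noise = [None] * schedule.n_walkers
    noise_at = [0] * schedule.n_walkers

    for step in range(1, n_steps + 1):
        for w in range(schedule.n_walkers):
            pos = positions[w]
            if noise[w] is None or noise_at[w] >= noise_chunk:
                noise[w] = rngs[w].standard_normal((noise_chunk, n_ions))
                noise_at[w] = 0
            row = noise[w][noise_at[w]]
            noise_at[w] += 1
            point = cv_point(pos)
            _, dV = bias.energy_and_gradient(point)
            for wall in schedule.walls:
                dV[wall.axis] += wall.derivative(point[wall.axis])
            f = system.forces(pos)
            if np.any(dV):
                for k, cv in enumerate(cvs):
                    if dV[k] == 0.0:
                        continue
                    g = cv.gradient(pos)
                    for i in range(n_ions):
                        f[i] -= dV[k] * g[i]
            for i in range(n_ions):
                z = pos[i] + c * f[i] + gaus * row[i]
                if z < -hard_bound or z > hard_bound:
                    raise RuntimeError(
                        f"walker {w} diverged at step {step} (ion {i}, z={z:.2f})"
                    )
                pos[i] = z
        t = step * dt
        if step % dep_every == 0:
            for w in range(schedule.n_walkers):
                point = cv_point(positions[w])
                bias.add(point, schedule.widths, schedule.height)
                hills.append(
                    Hill(tuple(point), schedule.widths, schedule.height, t, w)
                )
        if step % stride == 0:
            for w in range(schedule.n_walkers):
                point = cv_point(positions[w])
                e, _ = bias.energy_and_gradient(point)
                record(w, frame, t, positions[w], point, e)
            frame += 1

    hills.sort(key=lambda h: (h.time, h.walker_id))
    return MetadResult(
        hills=hills,
        times=[a[:frame] for a in rec_t],
        cv_values=[a[:frame] for a in rec_cv],
        positions=[a[:frame] for a in rec_pos],
        bias_energies=[a[:frame] for a in rec_bias],
        cv_names=tuple(cv.name for cv in cvs),
    )


def fes_from_hills(
    hills: Sequence[Hill],
    axes: Sequence[GridAxis],
    temperature: float = 310.0,
    average_last_fraction: float | None = None,
) -> FESGrid:
    """Free-energy estimate from a hill list: F = -(accumulated bias).

    With ``average_last_fraction`` the estimate is the time average of
    -V_bias(t) over the final fraction of the deposition history (each
    snapshot taken after one more hill), which damps the oscillation of
    plain metadynamics around the converged profile.  The result is
    shifted so its minimum is zero.
    """
    hills = list(hills)
    if not hills:
        raise ValueError("cannot build a free-energy estimate from zero hills")
    axes = tuple(axes)
    mesh = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    centers, widths, heights = _hill_arrays(hills)
    if centers.shape[1] != len(axes):
        raise ValueError("hill dimensionality does not match the grid axes")

    def _bias_of(sel: slice) -> np.ndarray:
        c, w, h = centers[sel], widths[sel], heights[sel]
        out = np.zeros(pts.shape[0])
        chunk = 256
        for start in range(0, c.shape[0], chunk):
            d = (pts[:, None, :] - c[None, start : start + chunk, :]) / w[
                None, start : start + chunk, :
            ]
            out += np.sum(
                h[None, start : start + chunk] * np.exp(-0.5 * np.sum(d * d, axis=2)),
                axis=1,
            )
        return out

    if average_last_fraction is None:
        total = _bias_of(slice(None))
        F = -total
    else:
        if not 0.0 < average_last_fraction <= 1.0:
            raise ValueError("average_last_fraction must lie in (0, 1]")
        n = len(hills)
        first = max(1, int(math.ceil(n * (1.0 - average_last_fraction))))
        base = _bias_of(slice(0, first))
        acc = np.zeros_like(base)
        running = base.copy()
        count = 0
        # add hills one at a time and average the successive estimates
        for i in range(first, n):
            d = (pts - centers[i]) / widths[i]
            running = running + heights[i] * np.exp(-0.5 * np.sum(d * d, axis=1))
            acc += running
            count += 1
        if count == 0:
            F = -running
        else:
            F = -(acc / count)
    F = F.reshape([ax.n_bins for ax in axes])
    grid = FESGrid(axes, F, temperature)
    return grid.normalize()
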