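"""Histogram reweighting to a 1D permeation profile and a kinetic Monte
Carlo Brownian-dynamics conductance model.

The permeation model is a single-ion, one-dimensional discrete-state
Markov chain on a uniform axial grid.  Nearest-neighbor hopping rates use
the symmetric split-barrier rule

    k(i -> j) = (D / delta^2) * exp( -(G_j - G_i) / (2 kT) ),

which satisfies detailed balance exactly with respect to the
voltage-tilted profile G(z) = W(z) + q*phi(z) and converges to
Smoluchowski diffusion as the spacing delta -> 0.  The membrane potential
enters through the constant-field approximation: phi falls linearly from
V (intracellular entrance, z_in) to 0 (extracellular exit, z_out), so a
positive V (intracellular side positive) drives K+ outward.

Boundary bins exchange ions with the two reservoirs: entry is
concentration-proportional (rate = entry_rate_scale * concentration) and
exit rates are fixed by detailed balance against the reservoir
electrochemical potentials, which makes the zero-current voltage of the
chain the Nernst potential (kT/q) ln(c_out/c_in) exactly.  Conductance is
obtained by counting completed translocations (enter on one side, exit on
the other) over the simulated time.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_TEMPERATURE,
    ELEMENTARY_CHARGE,
    thermal_energy,
    voltage_to_kcal,
)
from .grids import GridAxis
from .metad import Hill

__all__ = [
    "PermeationProfile",
    "KMCConfig",
    "KMCResult",
    "reweight_to_z",
    "RateTable",
    "build_rates",
    "run_kmc",
    "run_closed_chain",
    "first_passage_times",
    "mfpt_quadrature",
    "mfpt_discrete",
    "iv_curve",
]


@dataclasses.dataclass
class PermeationProfile:
    """1D permeation free energy W(z) with a diffusion coefficient.

    ``z`` must be uniformly spaced (angstrom); ``free_energy`` in
    kcal/mol with min 0; ``diffusion`` scalar or per-bin (angstrom^2/ns);
    ``channel_span`` is (z_in, z_out), defaulting to the grid ends.
    """

    z: np.ndarray
    free_energy: np.ndarray
    diffusion: float | np.ndarray = 0.5
    temperature: float = DEFAULT_TEMPERATURE
    channel_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.z.ndim != 1 or self.z.size < 2:
            raise ValueError("profile needs at least two grid points")
        steps = np.diff(self.z)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
            raise ValueError("profile grid must be uniformly spaced")
        if self.free_energy.shape != self.z.shape:
            raise ValueError("free_energy must match the z grid")
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("free energy must be finite on the channel span")
        self.free_energy = self.free_energy - self.free_energy.min()
        if self.channel_span is None:
            self.channel_span = (float(self.z[0]), float(self.z[-1]))

    @property
    def spacing(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)

    def diffusion_per_bin(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.diffusion, dtype=float), self.z.shape
        ).astype(float)


@dataclasses.dataclass
class KMCConfig:
    """Conditions of one KMC conductance run.

    ``voltage`` is the potential of the intracellular side relative to
    the extracellular side (mV); concentrations in mM; ``total_time`` in
    microseconds; ``entry_rate_scale`` in 1/(ns mM).
    """

    voltage: float = 0.0
    conc_in: float = 100.0
    conc_out: float = 100.0
    total_time: float = 1.0
    seed: int = 0
    entry_rate_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be non-negative")
        if self.entry_rate_scale <= 0:
            raise ValueError("entry_rate_scale must be positive")


@dataclasses.dataclass
class KMCResult:
    """Event counts and derived electrical observables of one KMC run."""

    n_outward: int
    n_inward: int
    simulated_time: float  # microseconds
    voltage: float  # mV

    @property
    def net_outward(self) -> int:
        return self.n_outward - self.n_inward

    @property
    def current(self) -> float:
        """Current in pA; outward (intra -> extra) positive."""
        return (
            ELEMENTARY_CHARGE
            * self.net_outward
            / (self.simulated_time * 1e-6)
            * 1e12
        )

    @property
    def chord_conductance(self) -> float:
        """I/V in pS; NaN at V = 0 where the chord is undefined."""
        if self.voltage == 0.0:
            return float("nan")
        return self.current / self.voltage * 1e3


# ---------------------------------------------------------------------------
# histogram reweighting
# ---------------------------------------------------------------------------


def _bias_at_points(
    points: np.ndarray, hills: Sequence[Hill], height_scale: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized hill-sum evaluation at many CV points."""
    if not hills:
        return np.zeros(points.shape[0])
    centers = np.asarray([h.center for h in hills], dtype=float)
    widths = np.asarray([h.widths for h in hills], dtype=float)
    heights = np.asarray([h.height for h in hills], dtype=float)
    if height_scale is not None:
        heights = heights * height_scale
    out = np.zeros(points.shape[0])
    chunk = max(1, 20_000_000 // max(points.shape[0], 1))
    for start in range(0, centers.shape[0], chunk):
        d = (points[:, None, :] - centers[None, start : start + chunk, :]) / widths[
            None, start : start + chunk, :
        ]
        out += np.sum(
            heights[None, start : start + chunk] * np.exp(-0.5 * np.sum(d * d, axis=2)),
            axis=1,
        )
    return out


def reweight_to_z(
    cv_values: np.ndarray,
    z_positions: np.ndarray,
    hills: Sequence[Hill],
    bins: GridAxis,
    temperature: float = DEFAULT_TEMPERATURE,
    burn_in: float = 0.5,
    diffusion: float | np.ndarray = 0.5,
    min_ess: float = 10.0,
    mode: str = "averaged",
) -> PermeationProfile:
    """Unbiased 1D permeation profile from a biased trajectory.

    Histogram reweighting: each retained frame gets a weight proportional
    to exp(+V_bias(CV_t)/kT) and the permeation free energy is
    W(z) = -kT ln (weighted z-histogram), min-shifted to zero.
    ``cv_values`` holds the CVs the bias acts on, frame by frame;
    ``z_positions`` the ion axial positions of the same frames (all ions
    pooled).  The first ``burn_in`` fraction of frames, sampled while the
    bias was still filling the wells, is discarded.

    ``mode`` selects the reweighting potential.  ``"final"`` uses the
    terminal hill sum; ``"averaged"`` (default) uses the bias time-
    averaged over the retained window, which is the effective potential
    the retained frames actually sampled and suppresses the
    standard-metadynamics ripple that the terminal sum carries.  Because
    each averaging snapshot is the hill sum truncated at a later time,
    the average reduces to scaling hill i deposited inside the window by
    the fraction of the window it was active, so it costs one hill-sum
    evaluation in any dimension.

    Raises ValueError when the weights degenerate (effective sample size
    below ``min_ess``).
    """
    cv_values = np.atleast_2d(np.asarray(cv_values, dtype=float))
    if cv_values.shape[0] == 1 and cv_values.shape[1] > 1 and np.ndim(z_positions) == 1:
        cv_values = cv_values.T
    z_positions = np.asarray(z_positions, dtype=float)
    if z_positions.ndim == 1:
        z_positions = z_positions[:, None]
    if cv_values.shape[0] != z_positions.shape[0]:
        raise ValueError("cv_values and z_positions must have equal frame counts")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must lie in [0, 1)")
    if mode not in ("averaged", "final"):
        raise ValueError("mode must be 'averaged' or 'final'")
    n_frames_total = cv_values.shape[0]
    first = int(n_frames_total * burn_in)
    cv_values = cv_values[first:]
    z_positions = z_positions[first:]
    kT = thermal_energy(temperature)
    hills = list(hills)
    scale = None
    if mode == "averaged" and hills:
        times = np.asarray([h.time for h in hills])
        t_end = times.max()
        t_burn = t_end * burn_in
        in_window = times > t_burn
        k_window = int(in_window.sum())
        scale = np.ones(len(hills))
        if k_window > 0:
            # hill m of the window is active in (K - m) of the K snapshots
            # taken after each window hill; the last hill never acts
            order = np.argsort(times[in_window], kind="stable")
            frac = (k_window - 1.0 - np.arange(k_window)) / max(k_window, 1)
            tmp = np.empty(k_window)
            tmp[order] = frac
            scale[in_window] = tmp
    vbias = _bias_at_points(cv_values, hills, scale)
    logw = (vbias - vbias.max()) / kT
    w = np.exp(logw)
    ess = float(w.sum() ** 2 / np.sum(w * w))
    if ess < min_ess:
        raise ValueError(
            f"reweighting weights are degenerate (effective sample size {ess:.1f})"
        )
    n_ions = z_positions.shape[1]
    hist, _ = np.histogram(
        z_positions.ravel(), bins=bins.edges, weights=np.repeat(w, n_ions)
    )
    with np.errstate(divide="ignore"):
        W = -kT * np.log(hist)
    if not np.all(np.isfinite(W)):
        finite = np.isfinite(W)
        if finite.sum() < 2:
            raise ValueError("too few sampled bins for a permeation profile")
        # interpolate across empty interior bins; they are genuinely rare
        W = np.interp(bins.centers, bins.centers[finite], W[finite])
    W -= W.min()
    return PermeationProfile(
        z=bins.centers,
        free_energy=W,
        diffusion=diffusion,
        temperature=temperature,
    )


def reweight_weights(
    cv_values: np.ndarray,
    hills: Sequence[Hill],
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Per-frame reweighting factors exp(+V_bias/kT), normalized to sum 1."""
    cv_values = np.atleast_2d(np.asarray(cv_values, dtype=float))
    kT = thermal_energy(temperature)
    vbias = _bias_at_points(cv_values, list(hills))
    w = np.exp((vbias - vbias.max()) / kT)
    return w / w.sum()


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RateTable:
    """Nearest-neighbor hopping rates (1/ns) on the tilted profile."""

    z: np.ndarray
    tilted: np.ndarray  # G = W + q*phi(z), kcal/mol
    up: np.ndarray  # k(i -> i+1), length M-1
    down: np.ndarray  # k(i+1 -> i), length M-1
    voltage: float
    temperature: float
    spacing: float

    @property
    def n_bins(self) -> int:
        return self.z.size

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)


def build_rates(profile: PermeationProfile, voltage: float = 0.0) -> RateTable:
    """Hopping rates on the voltage-tilted profile.

    The tilt is the constant-field electrostatic energy
    ``q * V * (z_out - z) / (z_out - z_in)`` added to W, so the
    intracellular entrance is raised by qV relative to the extracellular
    exit for positive V.  Detailed balance,
    ``k(i->j)/k(j->i) = exp(-(G_j - G_i)/kT)``, holds exactly.
    """
    z = profile.z
    z_in, z_out = profile.channel_span
    if z_out == z_in:
        raise ValueError("channel span is degenerate")
    qv = voltage_to_kcal(voltage)
    phi = (z_out - z) / (z_out - z_in)  # 1 at the intracellular end, 0 outside
    G = profile.free_energy + qv * phi
    kT = profile.kT
    D = profile.diffusion_per_bin()
    d2 = profile.spacing**2
    Dedge = 0.5 * (D[:-1] + D[1:])
    dG = np.diff(G)
    up = Dedge / d2 * np.exp(-dG / (2.0 * kT))
    down = Dedge / d2 * np.exp(dG / (2.0 * kT))
    return RateTable(
        z=z,
        tilted=G,
        up=up,
        down=down,
        voltage=voltage,
        temperature=profile.temperature,
        spacing=profile.spacing,
    )


# ---------------------------------------------------------------------------
# kinetic Monte Carlo
# ---------------------------------------------------------------------------


def _boundary_rates(rates: RateTable, config: KMCConfig):
    """Entry and exit rates consistent with reservoir electrochemistry.

    Entry: rate = entry_rate_scale * concentration (mass action).  Exit
    rates follow from detailed balance against the reservoir
    electrochemical potential mu = kT ln(c / 1 mM) + q*phi, evaluated
    with the same 1/(ns mM) scale, so the chain reverses exactly at the
    Nernst voltage.
    """
    kT = rates.kT
    s = config.entry_rate_scale
    qv = voltage_to_kcal(rates.voltage)
    enter_in = s * config.conc_in
    enter_out = s * config.conc_out
    # Exit attempt frequency referenced to 100 mM so that entries and exits
    # balance at physiological concentration and a flat profile; the
    # reference cancels from the cycle affinity, so the reversal voltage
    # stays exactly Nernstian.  Reservoir potentials: phi_in = V, phi_out = 0.
    c_ref = 100.0
    exit_in = s * c_ref * math.exp((rates.tilted[0] - qv) / kT)
    exit_out = s * c_ref * math.exp(rates.tilted[-1] / kT)
    return enter_in, enter_out, exit_in, exit_out


def run_kmc(rates: RateTable, config: KMCConfig) -> KMCResult:
    """Residence-time (Gillespie) simulation of the open channel.

    The channel holds at most one ion.  From the empty state an ion
    enters at either boundary bin at the concentration-proportional rate;
    inside, it hops with the split-barrier rates; from a boundary bin it
    can leave to the adjacent reservoir.  A translocation is counted when
    an ion that entered from one reservoir exits to the other.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    enter_in, enter_out, exit_in, exit_out = _boundary_rates(rates, config)
    up = rates.up
    down = rates.down
    M = rates.n_bins
    t = 0.0
    horizon = config.total_time * 1e3  # ns
    state = -1  # -1: empty, otherwise bin index
    entered_from = 0  # +1: intracellular, -1: extracellular
    n_out = 0
    n_in = 0
    exp = rng.exponential
    uni = rng.random
    while True:
        if state == -1:
            total = enter_in + enter_out
            if total <= 0:
                raise ValueError("zero total rate: no ions can enter")
            t += exp(1.0 / total)
            if t >= horizon:
                break
            if uni() * total < enter_in:
                state = 0
                entered_from = 1
            else:
                state = M - 1
                entered_from = -1
        else:
            k_up = up[state] if state < M - 1 else exit_out
            k_down = down[state - 1] if state > 0 else exit_in
            total = k_up + k_down
            t += exp(1.0 / total)
            if t >= horizon:
                break
            if uni() * total < k_up:
                if state == M - 1:
                    if entered_from == 1:
                        n_out += 1
                    state = -1
                else:
                    state += 1
            else:
                if state == 0:
                    if entered_from == -1:
                        n_in += 1
                    state = -1
                else:
                    state -= 1
    return KMCResult(
        n_outward=n_out,
        n_inward=n_in,
        simulated_time=config.total_time,
        voltage=rates.voltage,
    )


def run_closed_chain(
    rates: RateTable,
    n_events: int,
    start: int = 0,
    seed: int = 0,
    record_states: bool = False,
):
    """Sojourn times (ns) per bin of a single ion with no reservoir exchange.

    Boundary bins reflect.  The time-fraction spent in each bin converges
    to the Boltzmann weights of the tilted profile.  With
    ``record_states`` the visited state sequence is returned as well.
    """
    rng = np.random.default_rng(seed)
    up = rates.up
    down = rates.down
    M = rates.n_bins
    times = np.zeros(M)
    state = start
    states = np.empty(n_events, dtype=np.int64) if record_states else None
    exp = rng.exponential
    uni = rng.random
    for k in range(n_events):
        if states is not None:
            states[k] = state
        k_up = up[state] if state < M - 1 else 0.0
        k_down = down[state - 1] if state > 0 else 0.0
        total = k_up + k_down
        times[state] += exp(1.0 / total)
        state = state + 1 if uni() * total < k_up else state - 1
    if record_states:
        return times, states
    return times


def first_passage_times(
    rates: RateTable,
    start: int,
    absorb: int,
    n_replicas: int = 256,
    seed: int = 0,
    max_events: int = 50_000_000,
) -> np.ndarray:
    """First-passage times (ns) from ``start`` to ``absorb``.

    The boundary opposite the absorbing bin reflects.  Replicas are
    propagated in lockstep with vectorized KMC moves; results match the
    sequential residence-time algorithm in distribution.
    """
    if start == absorb:
        return np.zeros(n_replicas)
    rng = np.random.default_rng(seed)
    M = rates.n_bins
    up = np.concatenate([rates.up, [0.0]])
    down = np.concatenate([[0.0], rates.down])
    pos = np.full(n_replicas, start, dtype=np.int64)
    t = np.zeros(n_replicas)
    alive = np.ones(n_replicas, dtype=bool)
    out = np.empty(n_replicas)
    events = 0
    while alive.any():
        idx = pos[alive]
        ku = up[idx]
        kd = down[idx]
        total = ku + kd
        t_alive = t[alive] + rng.exponential(1.0, idx.size) / total
        step_up = rng.random(idx.size) * total < ku
        newpos = np.where(step_up, idx + 1, idx - 1)
        t[alive] = t_alive
        pos[alive] = newpos
        done = newpos == absorb
        if done.any():
            alive_idx = np.flatnonzero(alive)
            finished = alive_idx[done]
            out[finished] = t[finished]
            alive[finished] = False
        events += idx.size
        if events > max_events:
            raise RuntimeError("first-passage simulation exceeded the event budget")
    return out


def mfpt_quadrature(
    profile: PermeationProfile, a: float, b: float, n_quad: int = 4001
) -> float:
    """Analytic 1D mean first-passage time (ns) from a to b, reflecting at a.

    T = (1/D) * int_a^b dy e^{W(y)/kT} int_a^y dx e^{-W(x)/kT}
    evaluated by composite trapezoidal quadrature on the interpolated
    profile (scalar diffusion only).
    """
    D = float(np.asarray(profile.diffusion, dtype=float).mean())
    kT = profile.kT
    lo, hi = (a, b) if a < b else (b, a)
    y = np.linspace(lo, hi, n_quad)
    W = np.interp(y, profile.z, profile.free_energy)
    inner = np.concatenate(
        [[0.0], np.cumsum(0.5 * (np.exp(-W[1:] / kT) + np.exp(-W[:-1] / kT)))]
    ) * (y[1] - y[0])
    if a > b:
        # mirror: reflecting boundary at a on the right
        inner = inner[-1] - inner
    integrand = np.exp(W / kT) * inner
    outer = np.trapezoid(integrand, y)
    return float(outer / D)


def mfpt_discrete(rates: RateTable, start: int, absorb: int) -> float:
    """Exact mean first-passage time (ns) of the discrete chain.

    Closed-form birth-death expression with a reflecting boundary
    opposite the absorbing bin; the oracle against which the stochastic
    estimate is validated independently of any discretization error.
    """
    kT = rates.kT
    G = rates.tilted
    if start < absorb:
        up, down, g = rates.up, rates.down, G
        s, ab = start, absorb
    else:
        # mirror the chain so the walk always moves "up"
        up = rates.down[::-1]
        down = rates.up[::-1]
        g = G[::-1]
        M = rates.n_bins
        s, ab = M - 1 - start, M - 1 - absorb
    pi = np.exp(-(g - g.min()) / kT)
    total = 0.0
    for j in range(s, ab):
        total += np.sum(pi[: j + 1]) / (up[j] * pi[j])
    return float(total)


# ---------------------------------------------------------------------------
# current-voltage relation
# ---------------------------------------------------------------------------


def iv_curve(
    profile: PermeationProfile,
    voltages: Sequence[float],
    config: KMCConfig,
    slope_fit_max_abs_v: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Current-voltage table and slope conductance.

    Runs one KMC simulation per voltage (seed offset per row for
    independence), reports current (pA) and chord conductance
    g = I/V (pS, flagged NaN at V = 0), and fits the slope conductance
    (pS) through the rows with |V| <= ``slope_fit_max_abs_v`` (all rows
    by default) by least squares through the origin-free line I = g V + b.
    """
    if len(voltages) < 2:
        raise ValueError("need at least two voltages for an I-V curve")
    rows = []
    for i, v in enumerate(voltages):
        rates = build_rates(profile, voltage=v)
        cfg = dataclasses.replace(config, voltage=v, seed=config.seed + 1000 * i)
        res = run_kmc(rates, cfg)
        rows.append(
            {
                "voltage_mV": v,
                "current_pA": res.current,
                "chord_pS": res.chord_conductance,
                "n_outward": res.n_outward,
                "n_inward": res.n_inward,
            }
        )
    table = pd.DataFrame(rows)
    sel = table
    if slope_fit_max_abs_v is not None:
        sel = table[table["voltage_mV"].abs() <= slope_fit_max_abs_v]
        if len(sel) < 2:
            raise ValueError("fewer than two voltages inside the slope-fit window")
    coeffs = np.polyfit(sel["voltage_mV"], sel["current_pA"], 1)
    slope_ps = float(coeffs[0] * 1e3)  # pA/mV -> pS
    return table, slope_ps
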