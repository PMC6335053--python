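"""Mass-action kinetics of the G-protein turnover cycle driving GIRK.

The model couples a receptor-catalyzed G-protein cycle to cooperative
binding of up to four Gβγ subunits to a GIRK channel, all expressed as
2D membrane densities (molecules µm⁻²):

    R* + Gα(GDP)βγ  ⇌  R*·Gα(GDP)βγ          (k12 / k21)
    R*·Gα(GDP)βγ    →  R* + Gα(GTP) + Gβγ     (k23; lumped exchange+dissociation)
    Gα(GTP)         →  Gα(GDP)                (k34; hydrolysis, Pi implicit)
    Gα(GDP) + Gβγ   ⇌  Gα(GDP)βγ              (k45 / k54)
    GIRK·βγ_{n-1} + Gβγ ⇌ GIRK·βγ_n           (forward (5−n)·k56, backward n·µ^{n−1}·k65)

Agonist stimulation is modeled as a piecewise-constant k12 protocol
(k12 = 0 at rest, stepping to its full value at t = 0). The channel
readout is the fully liganded state GIRK·βγ₄.

Four linear combinations are conserved exactly: total receptor, total
Gα, total Gβγ and total GIRK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .units import GeometryParams, ParameterSet

SPECIES = (
    "R_star", "RT", "T", "Ga_GTP", "Ga_GDP", "Gbg",
    "girk0", "girk1", "girk2", "girk3", "girk4",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10  # µm⁻²


class InvalidStateError(ValueError):
    pass


class InvalidProtocolError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


def state_vector(**densities: float) -> np.ndarray:
    """Assemble a state array from named species densities (others zero)."""
    y = np.zeros(N_SPECIES)
    for name, value in densities.items():
        y[_IDX[name]] = value
    return y


def initial_state(geometry: GeometryParams, receptor_density: float | None = None) -> np.ndarray:
    """Naive pre-stimulus state: all receptor active-free, all Gα in trimer,
    all GIRK unliganded."""
    rd = geometry.receptor_density if receptor_density is None else receptor_density
    return state_vector(R_star=rd, T=geometry.trimer_density, girk0=geometry.girk_density)


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant k12(t): ordered (start, end, k12) segments
    contiguous from t = 0."""

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise InvalidProtocolError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise InvalidProtocolError("protocol must start at t = 0")
        prev_end = 0.0
        for start, end, k12 in segs:
            if start != prev_end:
                raise InvalidProtocolError("segments must be contiguous and non-overlapping")
            if end <= start:
                raise InvalidProtocolError("segment end must exceed its start")
            if k12 < 0:
                raise InvalidProtocolError(f"k12 must be >= 0, got {k12}")
            prev_end = end

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def k12_at(self, t: float) -> float:
        for start, end, k12 in self.segments:
            if start <= t < end:
                return k12
        if t == self.t_end:
            return self.segments[-1][2]
        raise InvalidProtocolError(f"t = {t} outside protocol [0, {self.t_end}]")

    @classmethod
    def step(cls, k12_on: float, t_end: float, t_on: float = 0.0,
             k12_off: float = 0.0) -> "StimulusProtocol":
        """Rest at ``k12_off`` until ``t_on``, then ``k12_on`` until ``t_end``."""
        if t_on <= 0.0:
            return cls(((0.0, t_end, k12_on),))
        return cls(((0.0, t_on, k12_off), (t_on, t_end, k12_on)))

    @classmethod
    def constant(cls, k12: float, t_end: float) -> "StimulusProtocol":
        return cls(((0.0, t_end, k12),))


@dataclass
class TimeCourse:
    """A simulated trajectory: time grid, per-species densities, optional
    scalar observable (e.g. GIRK·βγ₄ scaled to a current)."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), N_SPECIES)
    observable: np.ndarray | None = None

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "t", self.t)
        if self.observable is not None:
            df["observable"] = self.observable
        return df

    def conservation_drift(self, geometry: GeometryParams | None = None) -> float:
        """Max relative drift of the four conserved sums along the trajectory."""
        sums = conserved_sums(self.states)
        ref = sums[0]
        drift = np.abs(sums - ref) / np.maximum(np.abs(ref), 1e-300)
        return float(drift.max())


def conserved_sums(states: np.ndarray) -> np.ndarray:
    """The four conserved totals (receptor, Gα, Gβγ, GIRK) per row."""
    s = np.atleast_2d(states)
    receptor = s[:, _IDX["R_star"]] + s[:, _IDX["RT"]]
    galpha = s[:, _IDX["T"]] + s[:, _IDX["RT"]] + s[:, _IDX["Ga_GTP"]] + s[:, _IDX["Ga_GDP"]]
    n_bound = sum(n * s[:, _IDX[f"girk{n}"]] for n in range(1, 5))
    gbg = s[:, _IDX["T"]] + s[:, _IDX["RT"]] + s[:, _IDX["Gbg"]] + n_bound
    girk = sum(s[:, _IDX[f"girk{n}"]] for n in range(5))
    return np.column_stack([receptor, galpha, gbg, girk])


def derivatives(state: np.ndarray, params: ParameterSet, k12_now: float,
                deplete_gbg: bool = True) -> np.ndarray:
    """Mass-action time derivatives of all species at a given k12.

    With ``deplete_gbg=False`` the GIRK binding reactions read the free
    Gβγ pool without consuming it ("non-depleting probe" mode).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise InvalidStateError(f"state must have shape ({N_SPECIES},)")
    if np.any(state < 0):
        raise InvalidStateError("state densities must be non-negative")
    return _rhs(state, params, k12_now, deplete_gbg)


def _rhs(y: np.ndarray, p: ParameterSet, k12: float, deplete: bool = True) -> np.ndarray:
    R, RT, T, GT, GD, B = y[0], y[1], y[2], y[3], y[4], y[5]
    g = y[6:11]

    v_bind = k12 * R * T            # receptor–trimer association
    v_unbind = p.k21 * RT
    v_exch = p.k23 * RT             # Gβγ generation
    v_hyd = p.k34 * GT
    v_assoc = p.k45 * GD * B        # trimer re-formation
    v_dissoc = p.k54 * T

    dy = np.empty(N_SPECIES)
    dy[0] = -v_bind + v_unbind + v_exch          # R*
    dy[1] = v_bind - v_unbind - v_exch           # RT
    dy[2] = -v_bind + v_unbind + v_assoc - v_dissoc  # T
    dy[3] = v_exch - v_hyd                       # Ga_GTP
    dy[4] = v_hyd - v_assoc + v_dissoc           # Ga_GDP

    # GIRK ladder: statistical factors (5−n) forward, n·µ^{n−1} backward
    fwd = np.array([(5 - n) * p.k56 * B * g[n - 1] for n in range(1, 5)])
    bwd = np.array([n * p.mu ** (n - 1) * p.k65 * g[n] for n in range(1, 5)])
    net = fwd - bwd
    dg = np.zeros(5)
    dg[:4] -= net
    dg[1:] += net
    dy[6:11] = dg

    dy[5] = v_exch + v_dissoc - v_assoc          # free Gβγ
    if deplete:
        dy[5] -= net.sum()
    return dy


def _jac(y: np.ndarray, p: ParameterSet, k12: float, deplete: bool = True) -> np.ndarray:
    R, RT, T, GT, GD, B = y[0], y[1], y[2], y[3], y[4], y[5]
    g = y[6:11]
    J = np.zeros((N_SPECIES, N_SPECIES))

    # cycle reactions
    # v_bind = k12 R T
    for i, sgn in ((0, -1), (1, +1), (2, -1)):
        J[i, 0] += sgn * k12 * T
        J[i, 2] += sgn * k12 * R
    # v_unbind = k21 RT
    for i, sgn in ((0, +1), (1, -1), (2, +1)):
        J[i, 1] += sgn * p.k21
    # v_exch = k23 RT -> R*, GT, B
    J[0, 1] += p.k23
    J[1, 1] += -p.k23
    J[3, 1] += p.k23
    J[5, 1] += p.k23
    # v_hyd = k34 GT
    J[3, 3] += -p.k34
    J[4, 3] += p.k34
    # v_assoc = k45 GD B
    for i, sgn in ((2, +1), (4, -1), (5, -1)):
        J[i, 4] += sgn * p.k45 * B
        J[i, 5] += sgn * p.k45 * GD
    # v_dissoc = k54 T
    for i, sgn in ((2, -1), (4, +1), (5, +1)):
        J[i, 2] += sgn * p.k54

    # GIRK ladder
    for n in range(1, 5):
        kf = (5 - n) * p.k56
        kb = n * p.mu ** (n - 1) * p.k65
        lo, hi = 6 + n - 1, 6 + n
        # forward kf * B * g[n-1]
        J[lo, 5] += -kf * g[n - 1]
        J[lo, lo] += -kf * B
        J[hi, 5] += kf * g[n - 1]
        J[hi, lo] += kf * B
        # backward kb * g[n]
        J[lo, hi] += kb
        J[hi, hi] += -kb
        if deplete:
            J[5, 5] += -kf * g[n - 1]
            J[5, lo] += -kf * B
            J[5, hi] += kb
    return J


def simulate(
    params: ParameterSet,
    geometry: GeometryParams,
    protocol: StimulusProtocol,
    t_end: float,
    output_grid: Sequence[float] | None = None,
    initial: str | np.ndarray = "naive",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    deplete_gbg: bool = True,
) -> TimeCourse:
    """Integrate the cycle + binding ODEs under a k12 stimulus protocol.

    Parameters
    ----------
    initial : "naive" (all receptor free, all Gα in trimer, GIRK empty),
        "basal" (pre-equilibrated rest state from :func:`basal_equilibrium`),
        or an explicit state array.
    output_grid : time points for the returned trajectory; defaults to
        400 uniform points on [0, t_end].

    Uses the implicit BDF method with an analytic Jacobian; the four
    conservation laws drift by < 1e-6 (relative) at default tolerances.
    """
    if t_end <= 0:
        raise InvalidProtocolError(f"t_end must be positive, got {t_end}")
    if protocol.t_end < t_end:
        raise InvalidProtocolError(
            f"protocol covers [0, {protocol.t_end}] but t_end = {t_end}"
        )
    if output_grid is None:
        t_out = np.linspace(0.0, t_end, 401)
    else:
        t_out = np.asarray(output_grid, dtype=float)
        if t_out.ndim != 1 or len(t_out) < 2 or np.any(np.diff(t_out) <= 0) or t_out[0] != 0.0:
            raise InvalidProtocolError("output grid must be strictly increasing from 0")
        if t_out[-1] > t_end:
            raise InvalidProtocolError("output grid extends past t_end")

    if isinstance(initial, str):
        if initial == "naive":
            y0 = initial_state(geometry)
        elif initial == "basal":
            y0 = basal_equilibrium(params, geometry)
        else:
            raise InvalidStateError(f"unknown initial condition {initial!r}")
    else:
        y0 = np.asarray(initial, dtype=float)
        if y0.shape != (N_SPECIES,):
            raise InvalidStateError(f"initial state must have shape ({N_SPECIES},)")

    states = np.empty((len(t_out), N_SPECIES))
    states[0] = y0
    y = y0.copy()
    cursor = 1  # next output index to fill
    for start, end, k12 in protocol.segments:
        if start >= t_end:
            break
        seg_end = min(end, t_end)
        in_seg = (t_out > start) & (t_out <= seg_end)
        t_eval = t_out[in_seg]
        # always integrate to the segment end so the next segment starts clean
        t_span_end = seg_end
        t_eval_full = t_eval if len(t_eval) and t_eval[-1] == t_span_end else None
        sol = solve_ivp(
            lambda t, yy: _rhs(yy, params, k12, deplete_gbg),
            (start, t_span_end),
            y,
            method="BDF",
            jac=lambda t, yy: _jac(yy, params, k12, deplete_gbg),
            t_eval=np.concatenate([t_eval, [t_span_end]]) if (len(t_eval) == 0 or t_eval[-1] < t_span_end) else t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on segment [{start}, {seg_end}] (k12={k12}): {sol.message}"
            )
        seg_states = sol.y.T
        n_keep = len(t_eval)
        if n_keep:
            states[cursor:cursor + n_keep] = seg_states[:n_keep]
            cursor += n_keep
        y = seg_states[-1]
        if seg_end >= t_end:
            break

    # tiny negative excursions within solver tolerance are clamped for reporting
    np.clip(states, 0.0, None, out=states)
    return TimeCourse(t=t_out, states=states)


def girk_occupancy_closed_form(gbg_free: float, params: ParameterSet) -> np.ndarray:
    """Equilibrium occupancy fractions of GIRK states 0..4 at clamped free Gβγ.

    Detailed balance along the ladder gives weights
    w_n = w_0 · Π_{m=1..n} [(5−m)·k56·Gβγ / (m·µ^{m−1}·k65)], normalized.
    At µ = 1 this reduces to a binomial over four independent sites.
    """
    if gbg_free < 0:
        raise InvalidStateError("free Gβγ must be non-negative")
    w = np.ones(5)
    for n in range(1, 5):
        step = (5 - n) * params.k56 * gbg_free / (n * params.mu ** (n - 1) * params.k65)
        w[n] = w[n - 1] * step
    return w / w.sum()


def _basal_free_gbg(params: ParameterSet, geometry: GeometryParams) -> float:
    """Free Gβγ at the k12 = 0 fixed point (root of the trimer/GIRK balance)."""
    g_tot = geometry.trimer_density
    if params.k54 == 0.0:
        return 0.0
    girk_tot = geometry.girk_density

    def bound(b: float) -> float:
        occ = girk_occupancy_closed_form(b, params)
        return girk_tot * float(np.dot(np.arange(5), occ))

    def balance(b: float) -> float:
        # Gα(GDP) = b + bound(b); trimer T = g_tot − b − bound(b)
        t = g_tot - b - bound(b)
        return params.k45 * (b + bound(b)) * b - params.k54 * t

    hi = g_tot
    if balance(hi) < 0:  # all Gβγ free still below equilibrium — degenerate
        return hi
    return brentq(balance, 0.0, hi, xtol=1e-14, rtol=1e-14)


def basal_equilibrium(params: ParameterSet, geometry: GeometryParams) -> np.ndarray:
    """Rest state (k12 = 0 fixed point) of the cycle + binding system.

    All receptor is free R*; Gα partitions between trimer and Gα(GDP)
    according to the 2D dissociation constant K_2d = k54/k45, with GIRK
    occupancy at the resulting free Gβγ. With negligible GIRK, free Gβγ
    is the positive root of x² + K_2d·x − K_2d·G_total = 0.
    """
    b = _basal_free_gbg(params, geometry)
    occ = girk_occupancy_closed_form(b, params)
    bound = geometry.girk_density * float(np.dot(np.arange(5), occ))
    t = geometry.trimer_density - b - bound
    y = state_vector(
        R_star=geometry.receptor_density,
        T=max(t, 0.0),
        Ga_GDP=b + bound,
        Gbg=b,
    )
    y[6:11] = geometry.girk_density * occ
    return y


def steady_state(
    params: ParameterSet,
    geometry: GeometryParams,
    k12: float,
    initial: str | np.ndarray = "naive",
    rel_tol: float = 1e-8,
    t_cap: float = 1e5,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Fixed point at constant k12, found by integration to convergence.

    Convergence: relative state change over 1 s of model time below
    ``rel_tol``, verified by a small derivative norm. Raises
    ConvergenceError if not reached within ``t_cap`` model seconds.
    """
    if isinstance(initial, str):
        y = basal_equilibrium(params, geometry) if initial == "basal" else initial_state(geometry)
    else:
        y = np.asarray(initial, dtype=float).copy()

    t_done = 0.0
    chunk = 5.0
    scale = max(geometry.trimer_density, geometry.receptor_density, geometry.girk_density)
    while t_done < t_cap:
        sol = solve_ivp(
            lambda t, yy: _rhs(yy, params, k12),
            (0.0, chunk),
            y,
            method="BDF",
            jac=lambda t, yy: _jac(yy, params, k12),
            t_eval=[chunk - 1.0, chunk] if chunk > 1.0 else [chunk],
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"steady-state integration failed: {sol.message}")
        ys = sol.y.T
        y_new = ys[-1]
        t_done += chunk
        if chunk > 1.0:
            delta = np.abs(y_new - ys[0]) / (np.abs(y_new) + atol * scale)
            if delta.max() < rel_tol:
                resid = np.abs(_rhs(y_new, params, k12)).max()
                if resid < 1e-6 * scale:
                    return np.clip(y_new, 0.0, None)
        y = y_new
        chunk = min(chunk * 2.0, t_cap - t_done) if t_cap - t_done > 0 else 0.0
        if chunk <= 1.0 and t_done < t_cap:
            chunk = min(5.0, t_cap - t_done)
    raise ConvergenceError(f"no steady state within {t_cap} s of model time (k12={k12})")


def sweep_k12(
    params: ParameterSet,
    geometry: GeometryParams,
    k12_grid: Sequence[float],
    initial: str = "naive",
) -> pd.DataFrame:
    """Steady-state GIRK·βγ₄ density across a grid of k12 values.

    The grid must be sorted ascending; successive solves are warm-started
    from the previous steady state. Returns a DataFrame (k12, girk4).
    """
    grid = np.asarray(k12_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise InvalidProtocolError("k12 grid must be non-negative and sorted ascending")
    rows = []
    y = None
    for k12 in grid:
        start = initial if y is None else y
        try:
            y = steady_state(params, geometry, k12, initial=start)
        except (ConvergenceError, IntegrationError) as err:
            raise ConvergenceError(f"sweep failed at k12 = {k12}: {err}") from err
        rows.append((k12, y[_IDX["girk4"]]))
    return pd.DataFrame(rows, columns=["k12", "girk4"])
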