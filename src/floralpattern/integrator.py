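"""Fixed-step Euler predictor-corrector (Heun) integration of the full model.

The published scheme is an explicit fixed-step "Euler predictor-corrector":
a forward-Euler predictor followed by a trapezoidal corrector (Heun's
method, second order).  The default run takes 1,200,000 steps of 0.05 s
(16.6 simulated hours) on the 15-cell lattice.  Concentrations are clipped
at zero after each corrector step; the predictor sees the raw dynamics.

The hot loop is compiled with numba; a pure-numpy right-hand side composed
from the public rate functions (:func:`full_rhs`) is kept as a reference
and is cross-checked against the kernel in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple

import numba
import numpy as np

from .model_core import (
    FIELD_NAMES,
    FieldState,
    GridSpec,
    KineticParams,
    ModelOptions,
    ag_rate,
    ap1_rate,
    lfy_rate,
    tfl1_rate,
)
from .wus_prepattern import BoundaryConfig, WusParams, wus_rate, y_rate

__all__ = [
    "RunConfig",
    "Trajectory",
    "IntegrationError",
    "heun_step",
    "full_rhs",
    "simulate",
    "steady_state_time",
    "SteadyState",
]

METHODS = ("heun", "euler")


class IntegrationError(RuntimeError):
    """The explicit scheme produced non-finite values (instability)."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run.

    Defaults are the published study conditions: dt = 0.05 s for 1,200,000
    steps (16.6 h), 15 cells, wide boundary signal, homogeneous initial
    state (lfy = 1, ap1 = 0, ag = 0, tfl1 = 0.1, wus = 1; y follows the
    boundary configuration), sampling every 2,000 steps (100 s).

    ``epsilon_schedule`` optionally overrides the constant LFY coupling:
    a (n_intervals, n_cells) array applied piecewise-constantly, switching
    every ``epsilon_interval`` seconds (a single row gives a static
    per-cell profile).  ``wus_enabled=False`` freezes the wus/y fields at
    their initial values (used by the fixed-point oracle experiments).
    """

    dt: float = 0.05
    n_steps: int = 1_200_000
    sample_every: int = 2000
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)
    kinetics: KineticParams = field(default_factory=KineticParams)
    wus: WusParams = field(default_factory=WusParams)
    boundary: BoundaryConfig | None = None
    options: ModelOptions = field(default_factory=ModelOptions)
    initial_state: FieldState | None = None
    method: str = "heun"
    wus_enabled: bool = True
    epsilon_schedule: np.ndarray | None = None
    epsilon_interval: float = 50.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not self.epsilon_interval > 0:
            raise ValueError("epsilon_interval must be > 0")
        if self.boundary is None:
            self.boundary = BoundaryConfig.wide(self.grid.n_cells)
        if self.boundary.n_cells != self.grid.n_cells:
            raise ValueError(
                f"boundary has {self.boundary.n_cells} cells, grid has "
                f"{self.grid.n_cells}"
            )
        if self.initial_state is None:
            self.initial_state = FieldState.uniform(
                self.grid.n_cells, y=self.boundary.y0
            )
        if self.initial_state.n_cells != self.grid.n_cells:
            raise ValueError("initial state does not match the grid")
        if self.epsilon_schedule is not None:
            sched = np.atleast_2d(np.asarray(self.epsilon_schedule, dtype=float))
            if sched.shape[1] == 1:
                sched = np.repeat(sched, self.grid.n_cells, axis=1)
            if sched.shape[1] != self.grid.n_cells:
                raise ValueError(
                    "epsilon_schedule columns must match n_cells (or be 1)"
                )
            if (sched < 0).any():
                raise ValueError("epsilon values must be >= 0")
            self.epsilon_schedule = sched

    @property
    def total_time(self) -> float:
        """Simulated duration in seconds."""
        return self.dt * self.n_steps

    def replace(self, **changes) -> "RunConfig":
        return replace(self, **changes)


@dataclass
class Trajectory:
    """Sampled time series of one run: times (s) and a (m, 6, n) data block."""

    times: np.ndarray
    data: np.ndarray
    config: RunConfig

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.times.ndim != 1 or self.data.ndim != 3:
            raise ValueError("times must be 1D and data (m, 6, n)")
        if self.data.shape[0] != self.times.shape[0] or self.data.shape[1] != 6:
            raise ValueError("data shape does not match times")
        if self.times.shape[0] >= 2 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def times_hours(self) -> np.ndarray:
        return self.times / 3600.0

    def field(self, name: str) -> np.ndarray:
        """(m, n_cells) time series of one field."""
        return self.data[:, FIELD_NAMES.index(name), :]

    def ap1_T(self) -> np.ndarray:
        """(m, n_cells) series of the effective AP1 level, using the
        configured beta1 and exclusion driver."""
        p, opts = self.config.kinetics, self.config.options
        driver = self.field("ag") if opts.exclusion_driver == "AG" else self.field("wus")
        return self.field("ap1") * (1.0 - driver / (driver + p.beta1))

    def state(self, i: int) -> FieldState:
        return FieldState.from_array(float(self.times[i]), self.data[i])

    @property
    def final_state(self) -> FieldState:
        return self.state(-1)


# ---------------------------------------------------------------------------
# reference (numpy) right-hand side and single-step operations


def full_rhs(state: FieldState, config: RunConfig) -> np.ndarray:
    """(6, n) time derivative of the full coupled system, composed from the
    public per-field rate functions.  Reference implementation; the numba
    kernel must agree with it to roundoff."""
    p, wp, opts = config.kinetics, config.wus, config.options
    out = np.zeros((6, state.n_cells))
    out[0] = lfy_rate(state, p, opts)
    out[1] = ap1_rate(state, p, opts)
    out[2] = ag_rate(state, p, opts)
    out[3] = tfl1_rate(state, p, opts)
    if config.wus_enabled:
        out[4] = wus_rate(state, wp)
        out[5] = y_rate(state, config.boundary.L, wp)
    return out


def heun_step(
    x: np.ndarray,
    t: float,
    dt: float,
    rhs: Callable[[float, np.ndarray], np.ndarray],
    clip_negative: bool = True,
) -> np.ndarray:
    """One Euler predictor / trapezoidal corrector step of ``dx/dt = rhs(t, x)``.

    Predictor ``x~ = x + dt f(t, x)``; corrector
    ``x' = x + dt/2 [f(t, x) + f(t + dt, x~)]``; the result is clipped at
    zero afterwards if ``clip_negative`` (the predictor is never clipped).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    x = np.asarray(x, dtype=float)
    f0 = np.asarray(rhs(t, x), dtype=float)
    xp = x + dt * f0
    f1 = np.asarray(rhs(t + dt, xp), dtype=float)
    out = x + 0.5 * dt * (f0 + f1)
    if not np.all(np.isfinite(out)):
        raise IntegrationError(f"non-finite state after step at t={t}")
    if clip_negative:
        out = np.maximum(out, 0.0)
    return out


def step_state(state: FieldState, config: RunConfig) -> FieldState:
    """Advance a :class:`FieldState` by one dt with the configured scheme
    (numpy reference path; the production loop is the numba kernel)."""

    def rhs(t: float, arr: np.ndarray) -> np.ndarray:
        return full_rhs(FieldState.from_array(t, arr), config)

    clip = config.options.clip_negative
    if config.method == "heun":
        arr = heun_step(state.as_array(), state.t, config.dt, rhs, clip)
    else:
        arr = state.as_array() + config.dt * rhs(state.t, state.as_array())
        if clip:
            arr = np.maximum(arr, 0.0)
    return FieldState.from_array(state.t + config.dt, arr)


# ---------------------------------------------------------------------------
# compiled kernel

_GATE_SCOPE = {"all_production": 0, "wus_term_only": 1}
_DEN_SCOPE = {"shared": 0, "lfy_term_only": 1}
_FEEDBACK = {"raw": 0, "effective": 1}
_DRIVER = {"AG": 0, "WUS": 1}
_SIGMOID = {"mjolsness": 0, "literal_ratio": 1, "literal_sum": 2}


@numba.njit(cache=True)
def _rhs_into(dF, F, t, k, b1, b2, b3, gate_t, eps_row, wpar, L, flags):
    lfy, ap1v, ag, tfl, wus, y = F[0], F[1], F[2], F[3], F[4], F[5]
    n = lfy.shape[0]
    k17e, d_w, h_w, T_wy, k_y, d_y, D_y, ts = (
        wpar[0], wpar[1], wpar[2], wpar[3], wpar[4], wpar[5], wpar[6], wpar[7],
    )
    gate_scope, den_scope, feedback, driver, wus_on, sigv = (
        flags[0], flags[1], flags[2], flags[3], flags[4], flags[5],
    )
    g = 1.0 if t >= gate_t else 0.0
    for j in range(n):
        jm = j - 1 if j > 0 else j
        jp = j + 1 if j < n - 1 else j
        lap_l = lfy[jp] - 2.0 * lfy[j] + lfy[jm]
        lap_y = y[jp] - 2.0 * y[j] + y[jm]
        if feedback == 0:
            ap1_dyn = ap1v[j]
        else:
            d = ag[j] if driver == 0 else wus[j]
            ap1_dyn = ap1v[j] * (1.0 - d / (d + b1))
        dF[0, j] = (
            k[0] + k[1] * ap1_dyn - k[2] * tfl[j] - k[3] * lfy[j]
            + eps_row[j] * lap_l
        )
        dF[1, j] = k[4] + k[5] * lfy[j] - k[6] * tfl[j] - k[7] * ap1v[j]
        term_w = k[8] * wus[j]
        term_l = k[9] * lfy[j]
        den = b2 + b3 * ap1_dyn
        if gate_scope == 0:
            if den_scope == 0:
                production = g * (term_w + term_l) / den
            else:
                production = g * (term_w + term_l / den)
        else:
            if den_scope == 0:
                production = (g * term_w + term_l) / den
            else:
                production = g * term_w + term_l / den
        dF[2, j] = production - k[10] * tfl[j] - k[11] * ag[j]
        dF[3, j] = k[12] - k[13] * lfy[j] - k[14] * ap1_dyn - k[15] * tfl[j]
        if wus_on == 1:
            u = h_w + T_wy * y[j]
            if sigv == 0:
                sig = 0.5 * (1.0 + u / np.sqrt(1.0 + u * u))
            elif sigv == 1:
                sig = (1.0 + u) / (1.0 + u * u)
            else:
                sig = 1.0 + u / (1.0 + u * u)
            dF[4, j] = (k17e * sig - d_w * wus[j]) / ts
            dF[5, j] = (k_y * L[j] - d_y * y[j] + D_y * lap_y) / ts
        else:
            dF[4, j] = 0.0
            dF[5, j] = 0.0


@numba.njit(cache=True)
def _integrate(
    F0, k, b1, b2, b3, gate_t, eps_sched, steps_per_interval, wpar, L,
    flags, clip, use_heun, dt, n_steps, sample_every,
):
    n = F0.shape[1]
    n_rec = (n_steps - 1) // sample_every + 2
    times = np.empty(n_rec)
    out = np.empty((n_rec, 6, n))
    F = F0.copy()
    dF1 = np.empty((6, n))
    dF2 = np.empty((6, n))
    Fp = np.empty((6, n))
    m = eps_sched.shape[0]
    r = 0
    bad_step = -1
    for step in range(n_steps):
        if step % sample_every == 0:
            times[r] = step * dt
            out[r] = F
            r += 1
            if not np.all(np.isfinite(F)):
                bad_step = step
                break
        idx = step // steps_per_interval
        if idx >= m:
            idx = m - 1
        eps_row = eps_sched[idx]
        t = step * dt
        _rhs_into(dF1, F, t, k, b1, b2, b3, gate_t, eps_row, wpar, L, flags)
        if use_heun == 1:
            for i in range(6):
                for j in range(n):
                    Fp[i, j] = F[i, j] + dt * dF1[i, j]
            _rhs_into(dF2, Fp, t + dt, k, b1, b2, b3, gate_t, eps_row, wpar, L, flags)
            for i in range(6):
                for j in range(n):
                    F[i, j] += 0.5 * dt * (dF1[i, j] + dF2[i, j])
        else:
            for i in range(6):
                for j in range(n):
                    F[i, j] += dt * dF1[i, j]
        if clip == 1:
            for i in range(6):
                for j in range(n):
                    if F[i, j] < 0.0:
                        F[i, j] = 0.0
    if bad_step < 0:
        times[r] = n_steps * dt
        out[r] = F
        r += 1
        if not np.all(np.isfinite(F)):
            bad_step = n_steps
    return times[:r], out[:r], bad_step


def simulate(config: RunConfig) -> Trajectory:
    """Integrate the full coupled system and return the sampled trajectory.

    Samples are recorded at step 0, every ``sample_every`` steps, and at
    the final step.  The run is deterministic given its configuration.
    Raises :class:`IntegrationError` if the state becomes non-finite.
    """
    p, wp, opts = config.kinetics, config.wus, config.options
    n = config.grid.n_cells
    if config.epsilon_schedule is not None:
        sched = np.ascontiguousarray(config.epsilon_schedule)
        steps_per_interval = max(1, int(round(config.epsilon_interval / config.dt)))
    else:
        sched = np.full((1, n), p.epsilon)
        steps_per_interval = config.n_steps + 1
    wpar = np.array(
        [wp.k17_effective, wp.d_w, wp.h_w, wp.T_wy, wp.k_y, wp.d_y, wp.D_y,
         wp.time_scale]
    )
    flags = np.array(
        [
            _GATE_SCOPE[opts.gate_scope],
            _DEN_SCOPE[opts.denominator_scope],
            _FEEDBACK[opts.ap1_feedback],
            _DRIVER[opts.exclusion_driver],
            1 if config.wus_enabled else 0,
            _SIGMOID[wp.sigmoid_variant],
        ],
        dtype=np.int64,
    )
    times, data, bad_step = _integrate(
        config.initial_state.as_array(),
        p.rate_array(),
        p.beta1,
        p.beta2,
        p.beta3,
        p.gate_time,
        sched,
        steps_per_interval,
        wpar,
        np.asarray(config.boundary.L, dtype=float),
        flags,
        1 if opts.clip_negative else 0,
        1 if config.method == "heun" else 0,
        config.dt,
        config.n_steps,
        config.sample_every,
    )
    if bad_step >= 0:
        raise IntegrationError(
            f"non-finite state at step {bad_step} (t = {bad_step * config.dt} s); "
            "the explicit scheme is unstable for this configuration"
        )
    return Trajectory(times=times, data=data, config=config)


# ---------------------------------------------------------------------------
# steady-state detection


class SteadyState(NamedTuple):
    time: float  # seconds
    reached: bool

    @property
    def time_hours(self) -> float:
        return self.time / 3600.0


def steady_state_time(traj: Trajectory, tol: float = 1e-3) -> SteadyState:
    """First sampled time after which every field stops changing.

    A field counts as changing between consecutive samples when its maximal
    per-cell change, relative to the field's overall scale (its maximum
    absolute value over the whole trajectory), exceeds ``tol`` per
    simulated hour.  Returns the first sample time from which no field
    changes through the end; if the last interval is still changing,
    returns the end time with ``reached=False``.
    """
    if traj.n_samples < 2:
        raise ValueError("need at least 2 samples to detect a steady state")
    scales = np.abs(traj.data).max(axis=(0, 2))  # per field
    scales[scales == 0.0] = 1.0
    dt_h = np.diff(traj.times) / 3600.0
    step_change = np.abs(np.diff(traj.data, axis=0)).max(axis=2)  # (m-1, 6)
    rates = step_change / scales[None, :] / dt_h[:, None]
    changing = (rates >= tol).any(axis=1)
    if changing[-1]:
        return SteadyState(float(traj.times[-1]), False)
    idx = np.nonzero(changing)[0]
    first = 0 if idx.size == 0 else int(idx[-1]) + 1
    return SteadyState(float(traj.times[first]), True)
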