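"""Core kinetics of the floral-meristem patterning model.

The model describes a transect of idealized L1-layer cells across the four
whorls of an early *Arabidopsis* floral meristem.  Each cell j carries the
protein levels of five regulators -- LFY, AP1, AG, TFL1 and WUS -- plus a
diffusible repressor signal y.  The rate laws here implement the regulatory
logic of the ABC flowering network:

* ``lfy``   is activated by AP1, repressed by TFL1, and couples to its
  neighbours through a discrete no-flux Laplacian (coefficient ``epsilon``,
  the discretized diffusion rate D/dx**2).
* ``ap1``   is activated by LFY and repressed by TFL1.  AG does not change
  the ap1 state variable itself; instead the *effective* (AG-excluded)
  level ``ap1_T = ap1 * (1 - ag/(ag + beta1))`` describes where AP1
  activity survives.
* ``ag``    production is licensed by WUS and LFY, noncompetitively
  inhibited by AP1 through a ``(beta2 + beta3*ap1)`` denominator, and held
  silent by a unit step gate until ``gate_time`` (5 h by default).
* ``tfl1``  has a constant source opposed by LFY, AP1 and first-order decay.

All concentrations are in uM, all times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FIELD_NAMES",
    "GridSpec",
    "KineticParams",
    "ModelOptions",
    "FieldState",
    "TABLE_INTERVALS",
    "effective_ap1",
    "heaviside_gate",
    "noflux_laplacian",
    "laplacian_matrix",
    "lfy_rate",
    "ap1_rate",
    "ag_rate",
    "tfl1_rate",
    "uniform_fixed_point",
]

#: Order of the six dynamic fields wherever they are packed into one array.
FIELD_NAMES = ("lfy", "ap1", "ag", "tfl1", "wus", "y")

#: Published robustness intervals for the rate constants (uM/s or 1/s).
#: The k5 interval is inconsistent with the k5 point value (it excludes it
#: by a factor of ten) and is therefore exempt from interval validation;
#: see ``experiments.run_robustness_scan`` for how the scan handles it.
TABLE_INTERVALS: dict[str, tuple[float, float]] = {
    "k1": (0.03, 0.035),
    "k2": (0.02, 0.023),
    "k3": (0.015, 0.02),
    "k4": (0.035, 0.04),
    "k5": (0.9, 1.5),
    "k6": (0.05, 0.07),
    "k7": (0.01, 0.02),
    "k8": (0.04, 0.05),
    "k9": (0.08, 0.5),
    "k10": (0.025, 0.05),
    "k11": (0.01, 0.03),
    "k12": (0.01, 0.05),
    "k13": (0.7, 0.9),
    "k14": (0.07, 0.08),
    "k15": (0.03, 0.08),
    "k16": (0.55, 0.75),
}

#: Parameters exempt from interval validation (printed interval contradicts
#: the printed point value).
INTERVAL_EXEMPT = ("k5",)


@dataclass(frozen=True)
class GridSpec:
    """The 1D lattice of idealized L1 cells spanning the meristem diameter.

    Parameters
    ----------
    n_cells
        Number of cells across the transect (default 15).
    cell_length
        Cell diameter in micrometres (default 4.4 um, giving a 66 um
        meristem diameter with the default cell count).
    """

    n_cells: int = 15
    cell_length: float = 4.4

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError(f"n_cells must be >= 3, got {self.n_cells}")
        if not self.cell_length > 0:
            raise ValueError(f"cell_length must be > 0, got {self.cell_length}")

    @property
    def diameter(self) -> float:
        """Meristem diameter in micrometres."""
        return self.n_cells * self.cell_length

    @property
    def center_cell(self) -> int:
        """1-based index of the central cell (8 for the default grid)."""
        return (self.n_cells + 1) // 2


_RATE_NAMES = tuple(f"k{i}" for i in range(1, 17))


@dataclass
class KineticParams:
    """Rate constants of the LFY/AP1/AG/TFL1 subsystem.

    ``k1``, ``k5``, ``k13`` are zero-order production rates (uM/s); the
    remaining ``k``s are first-order rates (1/s).  ``beta1`` (uM) sets the
    AG level at which AP1 exclusion is half-maximal, ``beta2`` (uM) and
    ``beta3`` (dimensionless) parameterize the noncompetitive inhibition of
    AG production by AP1.  ``gate_time`` (s) is when the AG step gate
    opens; ``epsilon`` (1/s) is the intercellular LFY coupling coefficient.
    """

    k1: float = 0.03
    k2: float = 0.02
    k3: float = 0.02
    k4: float = 0.04
    k5: float = 0.09
    k6: float = 0.05
    k7: float = 0.02
    k8: float = 0.05
    k9: float = 0.08
    k10: float = 0.025
    k11: float = 0.03
    k12: float = 0.05
    k13: float = 0.9
    k14: float = 0.08
    k15: float = 0.03
    k16: float = 0.55
    beta1: float = 0.05
    beta2: float = 1.0
    beta3: float = 0.55
    gate_time: float = 18000.0  # 5 h
    epsilon: float = 5.0

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.beta1 > 0:
            raise ValueError("beta1 must be > 0")
        if not self.beta2 > 0:
            raise ValueError("beta2 must be > 0")
        if self.beta3 < 0:
            raise ValueError("beta3 must be >= 0")
        if self.gate_time < 0:
            raise ValueError("gate_time must be >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def rate_array(self) -> np.ndarray:
        """The sixteen rate constants as a flat array (k1..k16)."""
        return np.array([getattr(self, n) for n in _RATE_NAMES], dtype=float)

    def interval_violations(
        self, exempt: tuple[str, ...] = INTERVAL_EXEMPT
    ) -> dict[str, tuple[float, tuple[float, float]]]:
        """Rate constants lying outside their published robustness interval.

        Returns a mapping ``name -> (value, (lo, hi))``; exempt parameters
        (by default the inconsistent k5 interval) are skipped.
        """
        out = {}
        for name, (lo, hi) in TABLE_INTERVALS.items():
            if name in exempt:
                continue
            v = getattr(self, name)
            if not lo <= v <= hi:
                out[name] = (v, (lo, hi))
        return out

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)


GATE_SCOPES = ("all_production", "wus_term_only")
DENOMINATOR_SCOPES = ("shared", "lfy_term_only")
AP1_FEEDBACKS = ("raw", "effective")
EXCLUSION_DRIVERS = ("AG", "WUS")


@dataclass(frozen=True)
class ModelOptions:
    """Explicit choices for the ambiguous readings of the AG rate law.

    ``gate_scope``
        whether the step gate multiplies all AG production
        (``all_production``, default) or only the WUS term.
    ``denominator_scope``
        whether the AP1 inhibition denominator divides the combined
        activation (``shared``, default) or only the LFY term.
    ``ap1_feedback``
        whether AP1 feeds back on LFY, AG and TFL1 as the raw state
        variable (``raw``, default) or as the AG-excluded ``ap1_T``.
    ``exclusion_driver``
        which field drives AP1 exclusion in ``ap1_T`` (``AG`` default,
        ``WUS`` for the swap variant).
    ``clip_negative``
        clip every field at zero after each corrector step (default on;
        concentrations are physical).
    """

    gate_scope: str = "all_production"
    denominator_scope: str = "shared"
    ap1_feedback: str = "raw"
    exclusion_driver: str = "AG"
    clip_negative: bool = True

    def __post_init__(self) -> None:
        _check_enum("gate_scope", self.gate_scope, GATE_SCOPES)
        _check_enum("denominator_scope", self.denominator_scope, DENOMINATOR_SCOPES)
        _check_enum("ap1_feedback", self.ap1_feedback, AP1_FEEDBACKS)
        _check_enum("exclusion_driver", self.exclusion_driver, EXCLUSION_DRIVERS)

    def replace(self, **changes) -> "ModelOptions":
        return replace(self, **changes)


def _check_enum(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


@dataclass
class FieldState:
    """Per-cell concentrations of all six fields at one time point."""

    t: float
    lfy: np.ndarray
    ap1: np.ndarray
    ag: np.ndarray
    tfl1: np.ndarray
    wus: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        for name in FIELD_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, np.atleast_1d(arr))
        n = self.lfy.shape[0]
        for name in FIELD_NAMES:
            if getattr(self, name).shape != (n,):
                raise ValueError(
                    f"field {name!r} has shape {getattr(self, name).shape}, "
                    f"expected ({n},)"
                )

    @property
    def n_cells(self) -> int:
        return self.lfy.shape[0]

    def ap1_T(self, beta1: float = 0.05, exclusion_driver: str = "AG") -> np.ndarray:
        """Effective (exclusion-corrected) AP1 level per cell."""
        driver = self.ag if exclusion_driver == "AG" else self.wus
        return effective_ap1(self.ap1, driver, beta1)

    def as_array(self) -> np.ndarray:
        """Pack the six fields into a (6, n_cells) array, FIELD_NAMES order."""
        return np.stack([getattr(self, name) for name in FIELD_NAMES])

    @classmethod
    def from_array(cls, t: float, arr: np.ndarray) -> "FieldState":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != 6:
            raise ValueError(f"expected a (6, n_cells) array, got {arr.shape}")
        return cls(t, *(arr[i].copy() for i in range(6)))

    @classmethod
    def uniform(
        cls,
        n_cells: int,
        t: float = 0.0,
        *,
        lfy: float = 1.0,
        ap1: float = 0.0,
        ag: float = 0.0,
        tfl1: float = 0.1,
        wus: float = 1.0,
        y: float | np.ndarray = 0.0,
    ) -> "FieldState":
        """Spatially uniform state (the model's homogeneous initial condition),
        optionally with a non-uniform y profile."""
        full = lambda v: np.full(n_cells, float(v))
        y_arr = np.asarray(y, dtype=float)
        if y_arr.ndim == 0:
            y_arr = full(y_arr)
        return cls(t, full(lfy), full(ap1), full(ag), full(tfl1), full(wus), y_arr.copy())

    def copy(self) -> "FieldState":
        return FieldState.from_array(self.t, self.as_array())


# ---------------------------------------------------------------------------
# elementary operations


def effective_ap1(ap1: np.ndarray, driver: np.ndarray, beta1: float) -> np.ndarray:
    """AG-excluded AP1 distribution: ``ap1 * (1 - d/(d + beta1))``.

    ``driver`` is the excluding field (AG in the default model, WUS in the
    swap variant).  The result is bounded by ``0 <= out <= ap1`` elementwise.
    """
    ap1 = np.asarray(ap1, dtype=float)
    driver = np.asarray(driver, dtype=float)
    if ap1.shape != driver.shape:
        raise ValueError(f"shape mismatch: ap1 {ap1.shape} vs driver {driver.shape}")
    if not beta1 > 0:
        raise ValueError(f"beta1 must be > 0, got {beta1}")
    return ap1 * (1.0 - driver / (driver + beta1))


def heaviside_gate(t: float, gate_time: float = 18000.0) -> float:
    """Unit step that opens AG production at ``gate_time``.

    Right-continuous: returns 1.0 at exactly ``t == gate_time``.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return 1.0 if t >= gate_time else 0.0


def noflux_laplacian(v: np.ndarray) -> np.ndarray:
    """Discrete 1D Laplacian with mirrored ghost cells (no-flux ends).

    Interior cells get ``v[j+1] - 2 v[j] + v[j-1]``; at each end the missing
    neighbour is replaced by the end cell itself, so the output sums to zero
    exactly (material is conserved under pure coupling).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.shape[0] < 3:
        raise ValueError("profile must be 1D with length >= 3")
    out = np.empty_like(v)
    out[1:-1] = v[2:] - 2.0 * v[1:-1] + v[:-2]
    out[0] = v[1] - v[0]
    out[-1] = v[-2] - v[-1]
    return out


def laplacian_matrix(n: int) -> np.ndarray:
    """Dense matrix form of :func:`noflux_laplacian` on ``n`` cells."""
    if n < 3:
        raise ValueError("need at least 3 cells")
    m = np.diag(np.full(n, -2.0)) + np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
    m[0, 0] = -1.0
    m[-1, -1] = -1.0
    return m


def _ap1_for_dynamics(
    state: FieldState, p: KineticParams, opts: ModelOptions
) -> np.ndarray:
    """The AP1 signal that other rate laws see (raw or exclusion-corrected)."""
    if opts.ap1_feedback == "raw":
        return state.ap1
    return state.ap1_T(p.beta1, opts.exclusion_driver)


def lfy_rate(
    state: FieldState, p: KineticParams, opts: ModelOptions = ModelOptions()
) -> np.ndarray:
    """d(lfy)/dt: AP1 activation, TFL1 repression, turnover, cell coupling."""
    ap1 = _ap1_for_dynamics(state, p, opts)
    return (
        p.k1
        + p.k2 * ap1
        - p.k3 * state.tfl1
        - p.k4 * state.lfy
        + p.epsilon * noflux_laplacian(state.lfy)
    )


def ap1_rate(
    state: FieldState, p: KineticParams, opts: ModelOptions = ModelOptions()
) -> np.ndarray:
    """d(ap1)/dt: LFY activation, TFL1 repression, turnover.

    The ap1 state variable evolves independently of AG; exclusion acts only
    through the derived ``ap1_T``.
    """
    return p.k5 + p.k6 * state.lfy - p.k7 * state.tfl1 - p.k8 * state.ap1


def ag_rate(
    state: FieldState, p: KineticParams, opts: ModelOptions = ModelOptions()
) -> np.ndarray:
    """d(ag)/dt: gated, WUS/LFY-driven production under noncompetitive AP1
    inhibition, opposed by TFL1 and first-order decay."""
    g = heaviside_gate(state.t, p.gate_time)
    ap1 = _ap1_for_dynamics(state, p, opts)
    term_wus = p.k9 * state.wus
    term_lfy = p.k10 * state.lfy
    den = p.beta2 + p.beta3 * ap1
    if opts.gate_scope == "all_production":
        if opts.denominator_scope == "shared":
            production = g * (term_wus + term_lfy) / den
        else:
            production = g * (term_wus + term_lfy / den)
    else:  # gate only the WUS term
        if opts.denominator_scope == "shared":
            production = (g * term_wus + term_lfy) / den
        else:
            production = g * term_wus + term_lfy / den
    return production - p.k11 * state.tfl1 - p.k12 * state.ag


def tfl1_rate(
    state: FieldState, p: KineticParams, opts: ModelOptions = ModelOptions()
) -> np.ndarray:
    """d(tfl1)/dt: constant source opposed by LFY, AP1 and turnover."""
    ap1 = _ap1_for_dynamics(state, p, opts)
    return p.k13 - p.k14 * state.lfy - p.k15 * ap1 - p.k16 * state.tfl1


def uniform_fixed_point(p: KineticParams) -> tuple[float, float, float]:
    """Steady state of the uniform, pre-gate (AG-free) LFY/AP1/TFL1 subsystem.

    Solves the 3x3 linear system obtained by setting the three rates to
    zero with ag = 0 and spatially uniform fields.  If the unconstrained
    solution has negative components, the offending variables are pinned at
    zero (the clipped dynamics cannot sustain negative concentrations) and
    the reduced system is re-solved.

    Returns ``(lfy*, ap1*, tfl1*)``.
    """
    A = np.array(
        [
            [-p.k4, p.k2, -p.k3],
            [p.k6, -p.k8, -p.k7],
            [-p.k14, -p.k15, -p.k16],
        ]
    )
    b = -np.array([p.k1, p.k5, p.k13])
    active = [0, 1, 2]
    x = np.zeros(3)
    for _ in range(3):
        if not active:
            break
        sub = A[np.ix_(active, active)]
        try:
            sol = np.linalg.solve(sub, b[active])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular kinetic system; no unique uniform fixed point"
            ) from exc
        x[:] = 0.0
        x[active] = sol
        negative = [i for i in active if x[i] < 0]
        if not negative:
            break
        active = [i for i in active if i not in negative]
        x[:] = 0.0
    return float(x[0]), float(x[1]), float(x[2])
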