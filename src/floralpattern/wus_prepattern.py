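"""WUS pre-pattern subsystem.

WUSCHEL expression is restricted to the meristem center by a repressor
cascade: an imposed boundary signal L (high at the lattice ends) drives
production of a diffusible repressor y, and y shuts WUS production down
through a steep sigmoidal response,

    d(wus)/dt = k17 * g(h_w + T_wy * y) - d_w * wus
    d(y)/dt   = k_y * L - d_y * y + D_y * Lap(y)

with a no-flux Laplacian for y.  Because T_wy is large and negative, cells
that see the boundary signal (y high) have g ~ 0 and lose WUS, while
interior cells keep g(h_w) ~ 1 -- a centered WUS dome, the pre-pattern that
later licenses AG in the flower center.

The subsystem runs on a slower clock than the second-scale kinetics of the
ABC fields: its rates are interpreted per ``time_scale`` seconds (one hour
by default), which puts pattern emergence at ~1 h of simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import FieldState, GridSpec, laplacian_matrix, noflux_laplacian

__all__ = [
    "WusParams",
    "BoundaryConfig",
    "repressor_input",
    "activation_sigmoid",
    "wus_rate",
    "y_rate",
    "wus_steady_profile",
]

SIGMOID_VARIANTS = ("mjolsness", "literal_ratio", "literal_sum")
AMPLITUDE_MODES = ("normalized", "literal")


@dataclass
class WusParams:
    """Constants of the WUS repressor subsystem.

    Rates (``k17``, ``d_w``, ``k_y``, ``d_y``, ``D_y``) are per WUS time
    unit; ``time_scale`` converts that unit to seconds (default 3600, i.e.
    per-hour rates).  ``h_w`` and ``T_wy`` shape the sigmoid input
    ``u = h_w + T_wy * y``; ``T_wy`` is negative (y represses WUS).

    ``sigmoid_variant`` selects the activation nonlinearity:

    * ``mjolsness`` (default): ``g(u) = (1 + u / sqrt(1 + u^2)) / 2``, the
      saturating 0..1 sigmoid of the connectionist gene-network formalism
      the repressor subsystem is adapted from;
    * ``literal_ratio``: ``(1 + u) / (1 + u^2)``;
    * ``literal_sum``: ``1 + u / (1 + u^2)``.

    With ``amplitude_mode="normalized"`` (default) the production constant
    is taken equal to ``d_w`` so the derepressed steady WUS level is
    ~``g_max`` ~ 1 uM, commensurate with the O(1) initial condition and
    large enough to drive the AG switch; ``literal`` uses ``k17`` as
    printed.
    """

    k17: float = 0.05
    d_w: float = 1.75
    h_w: float = 2.0
    T_wy: float = -30.0
    k_y: float = 0.2
    d_y: float = 2.0
    D_y: float = 0.1
    time_scale: float = 3600.0
    sigmoid_variant: str = "mjolsness"
    amplitude_mode: str = "normalized"

    def __post_init__(self) -> None:
        for name in ("k17", "d_w", "k_y", "d_y", "D_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.time_scale > 0:
            raise ValueError("time_scale must be > 0")
        if self.sigmoid_variant not in SIGMOID_VARIANTS:
            raise ValueError(
                f"sigmoid_variant must be one of {SIGMOID_VARIANTS}, "
                f"got {self.sigmoid_variant!r}"
            )
        if self.amplitude_mode not in AMPLITUDE_MODES:
            raise ValueError(
                f"amplitude_mode must be one of {AMPLITUDE_MODES}, "
                f"got {self.amplitude_mode!r}"
            )

    @property
    def k17_effective(self) -> float:
        """Production constant actually used (``d_w`` in normalized mode)."""
        return self.d_w if self.amplitude_mode == "normalized" else self.k17

    def replace(self, **changes) -> "WusParams":
        return replace(self, **changes)


@dataclass
class BoundaryConfig:
    """Spatial extent of the boundary signal L and the initial y profile.

    The canonical configurations are

    * ``wide``   -- L = 1 (and y(0) = 1) in the three outermost cells at
      each end of the lattice, 0 elsewhere;
    * ``narrow`` -- L = 1 (and y(0) = 1) only in the single end cells.
    """

    L: np.ndarray
    y0: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.L = np.atleast_1d(np.asarray(self.L, dtype=float))
        self.y0 = np.atleast_1d(np.asarray(self.y0, dtype=float))
        if self.L.shape != self.y0.shape:
            raise ValueError(
                f"L and y0 must have the same length, got {self.L.shape} "
                f"and {self.y0.shape}"
            )
        if self.L.shape[0] < 3:
            raise ValueError("boundary profiles need at least 3 cells")
        if not set(np.unique(self.L)) <= {0.0, 1.0}:
            raise ValueError("L must be a binary (0/1) vector")

    @property
    def n_cells(self) -> int:
        return self.L.shape[0]

    @classmethod
    def wide(cls, n_cells: int = 15) -> "BoundaryConfig":
        """Signal in the three outermost cells at each end."""
        if n_cells < 7:
            raise ValueError("wide boundary needs at least 7 cells")
        L = np.zeros(n_cells)
        L[:3] = 1.0
        L[-3:] = 1.0
        return cls(L=L, y0=L.copy(), name="wide")

    @classmethod
    def narrow(cls, n_cells: int = 15) -> "BoundaryConfig":
        """Signal only in the two end cells."""
        L = np.zeros(n_cells)
        L[0] = 1.0
        L[-1] = 1.0
        return cls(L=L, y0=L.copy(), name="narrow")

    @classmethod
    def named(cls, name: str, n_cells: int = 15) -> "BoundaryConfig":
        if name == "wide":
            return cls.wide(n_cells)
        if name == "narrow":
            return cls.narrow(n_cells)
        raise ValueError(f"unknown boundary name {name!r} (use wide/narrow)")


def repressor_input(y: np.ndarray, wp: WusParams) -> np.ndarray:
    """Sigmoid input ``u = h_w + T_wy * y`` per cell."""
    return wp.h_w + wp.T_wy * np.asarray(y, dtype=float)


def activation_sigmoid(u, variant: str = "mjolsness"):
    """WUS production nonlinearity g(u); see :class:`WusParams`."""
    u = np.asarray(u, dtype=float)
    if variant == "mjolsness":
        out = 0.5 * (1.0 + u / np.sqrt(1.0 + u * u))
    elif variant == "literal_ratio":
        out = (1.0 + u) / (1.0 + u * u)
    elif variant == "literal_sum":
        out = 1.0 + u / (1.0 + u * u)
    else:
        raise ValueError(f"unknown sigmoid variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def wus_rate(state: FieldState, wp: WusParams) -> np.ndarray:
    """d(wus)/dt in 1/s: sigmoidal production minus first-order decay."""
    g = activation_sigmoid(repressor_input(state.y, wp), wp.sigmoid_variant)
    return (wp.k17_effective * g - wp.d_w * state.wus) / wp.time_scale


def y_rate(state: FieldState, L: np.ndarray, wp: WusParams) -> np.ndarray:
    """d(y)/dt in 1/s: boundary-driven production, decay, no-flux diffusion."""
    L = np.asarray(L, dtype=float)
    if L.shape != state.y.shape:
        raise ValueError(f"L shape {L.shape} does not match grid {state.y.shape}")
    return (wp.k_y * L - wp.d_y * state.y + wp.D_y * noflux_laplacian(state.y)) / wp.time_scale


def wus_steady_profile(
    wp: WusParams, bc: BoundaryConfig, grid: GridSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form steady state of the repressor subsystem.

    The y equation is linear, so its steady state solves
    ``(d_y I - D_y Lap) y = k_y L`` exactly; WUS then follows pointwise as
    ``wus = k17_eff * g(h_w + T_wy * y) / d_w``.  Used as an independent
    oracle for the time-stepped subsystem.

    Returns ``(y_ss, wus_ss)``.
    """
    n = grid.n_cells if grid is not None else bc.n_cells
    if bc.n_cells != n:
        raise ValueError(
            f"boundary has {bc.n_cells} cells but grid has {n}"
        )
    A = wp.d_y * np.eye(n) - wp.D_y * laplacian_matrix(n)
    y_ss = np.linalg.solve(A, wp.k_y * bc.L)
    g = activation_sigmoid(repressor_input(y_ss, wp), wp.sigmoid_variant)
    wus_ss = wp.k17_effective * g / wp.d_w
    return y_ss, wus_ss
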