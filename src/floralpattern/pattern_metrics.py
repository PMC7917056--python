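"""Quantification of the emergent expression pattern.

The steady pattern is summarized by where AG and (effective) AP1 peak, how
wide the AG domain is, how mirror-symmetric the profiles are about the
center cell, and a per-cell A/B/C zone classification:

* C where AG is at least ``half_fraction`` of its spatial maximum
  (carpel/stamen territory, the flower center),
* A where not C and effective AP1 (``ap1_T``) is at least
  ``half_fraction`` of its maximum (sepal territory, the periphery),
* B otherwise (residual).

Half-max thresholding keeps the labels invariant under rescaling of the
profiles.  Because the model's WUS transition is sharp, the exclusive B
label can be empty at the default threshold; overlap-style B membership is
available through :func:`zone_membership`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import FieldState

__all__ = [
    "PatternSummary",
    "peak_cell",
    "zone_classify",
    "zone_membership",
    "zone_ordering",
    "halfmax_width",
    "symmetry_error",
    "profile_distance",
    "summarize_trajectory",
    "classification_stable_from",
]

#: Fields compared by :func:`profile_distance` (ap1 enters via ap1_T).
DISTANCE_FIELDS = ("lfy", "ap1_T", "ag", "tfl1", "wus")


def peak_cell(profile: np.ndarray) -> int:
    """1-based index of the profile maximum; ties break to the lowest index."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    return int(np.argmax(profile)) + 1


def zone_classify(
    state: FieldState,
    half_fraction: float = 0.5,
    *,
    beta1: float = 0.05,
    exclusion_driver: str = "AG",
) -> np.ndarray:
    """Per-cell A/B/C labels from the AG and effective-AP1 profiles.

    Raises ``ValueError`` when both profiles are identically zero (the
    classification is undefined there).
    """
    if not 0 < half_fraction <= 1:
        raise ValueError("half_fraction must be in (0, 1]")
    ag = state.ag
    ap1t = state.ap1_T(beta1, exclusion_driver)
    if ag.max() == 0.0 and ap1t.max() == 0.0:
        raise ValueError("zone classification undefined: ag and ap1_T are all zero")
    is_c = ag >= half_fraction * ag.max() if ag.max() > 0 else np.zeros_like(ag, bool)
    is_a = (
        ap1t >= half_fraction * ap1t.max()
        if ap1t.max() > 0
        else np.zeros_like(ap1t, bool)
    )
    labels = np.full(state.n_cells, "B", dtype="<U1")
    labels[is_a & ~is_c] = "A"
    labels[is_c] = "C"
    return labels


def zone_membership(
    state: FieldState,
    half_fraction: float = 0.5,
    *,
    beta1: float = 0.05,
    exclusion_driver: str = "AG",
) -> tuple[np.ndarray, np.ndarray]:
    """Soft (non-exclusive) A and C membership booleans per cell.

    Cells can belong to both (the overlap region read as the B zone
    spanning adjacent whorls) or to neither.
    """
    ag = state.ag
    ap1t = state.ap1_T(beta1, exclusion_driver)
    c_member = ag >= half_fraction * ag.max() if ag.max() > 0 else np.zeros_like(ag, bool)
    a_member = (
        ap1t >= half_fraction * ap1t.max()
        if ap1t.max() > 0
        else np.zeros_like(ap1t, bool)
    )
    return a_member, c_member


def zone_ordering(labels: np.ndarray) -> str:
    """Run-length ordering of a label vector, e.g. ``"ACA"`` or ``"ABCBA"``."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return ""
    order = [str(labels[0])]
    for lab in labels[1:]:
        if str(lab) != order[-1]:
            order.append(str(lab))
    return "".join(order)


def halfmax_width(profile: np.ndarray) -> int:
    """Number of cells at or above half the profile maximum."""
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0 or profile.max() <= 0:
        raise ValueError("halfmax_width needs a profile with a positive maximum")
    if (profile < 0).any():
        raise ValueError("profile must be non-negative")
    return int((profile >= 0.5 * profile.max()).sum())


def symmetry_error(profile: np.ndarray) -> float:
    """Maximal deviation from mirror symmetry about the center cell (uM).

    Requires an odd-length profile (a unique center cell).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size % 2 == 0:
        raise ValueError("symmetry_error needs an odd-length 1D profile")
    return float(np.abs(profile - profile[::-1]).max())


def profile_distance(
    a: FieldState,
    b: FieldState,
    *,
    beta1: float = 0.05,
    exclusion_driver: str = "AG",
) -> float:
    """Max-norm distance between two states over lfy, ap1_T, ag, tfl1, wus."""
    if a.n_cells != b.n_cells:
        raise ValueError(f"grid mismatch: {a.n_cells} vs {b.n_cells} cells")
    d = 0.0
    for name in DISTANCE_FIELDS:
        if name == "ap1_T":
            va = a.ap1_T(beta1, exclusion_driver)
            vb = b.ap1_T(beta1, exclusion_driver)
        else:
            va = getattr(a, name)
            vb = getattr(b, name)
        d = max(d, float(np.abs(va - vb).max()))
    return d


@dataclass
class PatternSummary:
    """Digest of one run's final pattern and its establishment timing."""

    zone_labels: list[str]
    ag_peak_cell: int
    ap1T_min_cell: int
    wus_peak_cell: int
    ag_halfmax_width: int
    symmetry_error: float
    steady_time_hours: float
    steady_reached: bool
    classification_stable_from_hours: float
    a_membership: list[bool] = field(default_factory=list)
    c_membership: list[bool] = field(default_factory=list)

    @property
    def zone_string(self) -> str:
        return "".join(self.zone_labels)

    @property
    def ordering(self) -> str:
        return zone_ordering(np.array(self.zone_labels))

    def to_dict(self) -> dict:
        return {
            "zone_labels": list(self.zone_labels),
            "ag_peak_cell": self.ag_peak_cell,
            "ap1T_min_cell": self.ap1T_min_cell,
            "wus_peak_cell": self.wus_peak_cell,
            "ag_halfmax_width": self.ag_halfmax_width,
            "symmetry_error": self.symmetry_error,
            "steady_time_hours": self.steady_time_hours,
            "steady_reached": self.steady_reached,
            "classification_stable_from_hours": self.classification_stable_from_hours,
            "a_membership": [bool(v) for v in self.a_membership],
            "c_membership": [bool(v) for v in self.c_membership],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatternSummary":
        return cls(**d)


def _labels_or_none(state, half_fraction, beta1, driver):
    try:
        return zone_classify(
            state, half_fraction, beta1=beta1, exclusion_driver=driver
        )
    except ValueError:
        return None


def classification_stable_from(
    traj, half_fraction: float = 0.5
) -> tuple[float, np.ndarray]:
    """Earliest sampled time from which the zone labels equal the final ones.

    Samples where the classification is undefined (all-zero profiles) never
    match.  Returns ``(time_seconds, final_labels)``.
    """
    beta1 = traj.config.kinetics.beta1
    driver = traj.config.options.exclusion_driver
    final = _labels_or_none(traj.final_state, half_fraction, beta1, driver)
    if final is None:
        raise ValueError("final state has no defined zone classification")
    stable_idx = traj.n_samples - 1
    for i in range(traj.n_samples - 2, -1, -1):
        labels = _labels_or_none(traj.state(i), half_fraction, beta1, driver)
        if labels is None or not np.array_equal(labels, final):
            break
        stable_idx = i
    return float(traj.times[stable_idx]), final


def summarize_trajectory(traj, half_fraction: float = 0.5) -> PatternSummary:
    """Build a :class:`PatternSummary` for a finished run."""
    from .integrator import steady_state_time  # local import to avoid a cycle

    beta1 = traj.config.kinetics.beta1
    driver = traj.config.options.exclusion_driver
    final = traj.final_state
    stable_t, labels = classification_stable_from(traj, half_fraction)
    ap1t = final.ap1_T(beta1, driver)
    ag = final.ag
    sym = max(
        symmetry_error(final.lfy),
        symmetry_error(ap1t),
        symmetry_error(ag),
        symmetry_error(final.tfl1),
        symmetry_error(final.wus),
    ) if final.n_cells % 2 == 1 else float("nan")
    steady = steady_state_time(traj)
    a_mem, c_mem = zone_membership(
        final, half_fraction, beta1=beta1, exclusion_driver=driver
    )
    return PatternSummary(
        zone_labels=[str(v) for v in labels],
        ag_peak_cell=peak_cell(ag),
        ap1T_min_cell=int(np.argmin(ap1t)) + 1,
        wus_peak_cell=peak_cell(final.wus),
        ag_halfmax_width=halfmax_width(ag) if ag.max() > 0 else 0,
        symmetry_error=sym,
        steady_time_hours=steady.time_hours,
        steady_reached=steady.reached,
        classification_stable_from_hours=stable_t / 3600.0,
        a_membership=[bool(v) for v in a_mem],
        c_membership=[bool(v) for v in c_mem],
    )
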