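"""Open-population projection and the coral-cover proxy.

The population of a habitat advances one year at a time under the affine
recurrence

    n(t+1) = A . n(t) + nu(t)

where ``A`` is a stage-transition matrix and ``nu(t)`` is a vector of zeros
with the year's externally supplied spat count in its first position.
Recruitment can be *closed* (local fertility in A only, ``nu == 0``),
*mixed* (both), or *imported_only* (zero fertility, positive ``nu``) — the
last reflecting a fully open population whose larvae arrive from elsewhere.

When the matrix is subcritical (``lambda < 1``) and ``nu`` is constant the
trajectory converges to the affine fixed point ``n* = (I - A)^-1 nu``.

Cover is approximated by treating each colony as a disc at the median
radius of its size class (1, 3, 5 and 10 cm for classes 2-5 by default) and
summing the disc areas; spat (class 1) are too small to detect in
phototransects and are excluded from cover by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrices import N_STAGES, TransitionMatrix

__all__ = [
    "SizeDistribution",
    "RecruitmentSeries",
    "CoverProxyConfig",
    "project_one_step",
    "project_series",
    "affine_fixed_point",
    "cover_from_distribution",
]

RECRUITMENT_MODES = ("closed", "mixed", "imported_only")


@dataclass(frozen=True)
class SizeDistribution:
    """Colony counts in the five size classes, with habitat/time tags.

    Counts are kept real-valued: the matrix model is an expectation model
    and integer rounding would break its fixed-point structure.
    """

    n: np.ndarray
    habitat: str = ""
    depth_zone: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        if n.shape != (N_STAGES,):
            raise ValueError("a size distribution has exactly five classes")
        if np.any(n < 0):
            raise ValueError("colony counts must be nonnegative")
        object.__setattr__(self, "n", n)

    @property
    def total(self) -> float:
        return float(self.n.sum())


@dataclass(frozen=True)
class RecruitmentSeries:
    """External larval supply entering size class 1 each year.

    ``nu`` may be a scalar (constant supply) or a per-year sequence.  In
    ``closed`` mode the supply must be identically zero.
    """

    nu: "float | np.ndarray"
    mode: str = "imported_only"

    def __post_init__(self) -> None:
        if self.mode not in RECRUITMENT_MODES:
            raise ValueError(f"mode must be one of {RECRUITMENT_MODES}")
        nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        if np.any(nu < 0):
            raise ValueError("recruitment must be nonnegative")
        if self.mode == "closed" and np.any(nu != 0):
            raise ValueError("closed mode forces zero external recruitment")
        object.__setattr__(self, "nu", nu)

    def as_array(self, years: int) -> np.ndarray:
        """Per-year supply for ``years`` steps (scalar broadcast, series
        must be at least as long)."""
        if self.nu.size == 1:
            return np.full(years, float(self.nu[0]))
        if self.nu.size < years:
            raise ValueError(
                f"recruitment series of length {self.nu.size} cannot cover "
                f"{years} projection years"
            )
        return self.nu[:years].copy()


def _as_matrix(A: "TransitionMatrix | np.ndarray") -> np.ndarray:
    arr = A.A if isinstance(A, TransitionMatrix) else np.asarray(A, dtype=float)
    if arr.shape != (N_STAGES, N_STAGES):
        raise ValueError("transition matrix must be 5x5")
    return arr


def project_one_step(
    A: "TransitionMatrix | np.ndarray",
    n_t: "SizeDistribution | np.ndarray",
    nu_t: float = 0.0,
) -> SizeDistribution:
    """One year of the affine recurrence ``n(t+1) = A n(t) + nu``."""
    if nu_t < 0:
        raise ValueError("recruitment must be nonnegative")
    arr = _as_matrix(A)
    if isinstance(n_t, SizeDistribution):
        vec, habitat, depth, year = n_t.n, n_t.habitat, n_t.depth_zone, n_t.year
    else:
        vec = np.asarray(n_t, dtype=float)
        habitat, depth, year = "", "", None
        if vec.shape != (N_STAGES,):
            raise ValueError("size distribution must have five classes")
    out = arr @ vec
    out[0] += nu_t
    return SizeDistribution(
        n=out,
        habitat=habitat,
        depth_zone=depth,
        year=None if year is None else year + 1,
    )


def project_series(
    A: "TransitionMatrix | np.ndarray",
    n_0: "SizeDistribution | np.ndarray",
    recruitment: RecruitmentSeries,
    years: int,
) -> list[SizeDistribution]:
    """Project ``years`` steps; returns ``years + 1`` states including n_0.

    In ``imported_only`` mode the matrix must carry no fertility (the
    combination is contradictory and rejected); in ``closed`` mode the
    recruitment series is identically zero by construction.
    """
    if years < 0:
        raise ValueError("years must be >= 0")
    arr = _as_matrix(A)
    if recruitment.mode == "imported_only" and np.any(arr[0, 3:] != 0):
        raise ValueError(
            "imported_only recruitment contradicts nonzero fertility in A; "
            "zero A[1,4] and A[1,5] or use mode='mixed'"
        )
    if not isinstance(n_0, SizeDistribution):
        n_0 = SizeDistribution(n=np.asarray(n_0, dtype=float))
    nus = recruitment.as_array(years) if years else np.empty(0)
    traj = [n_0]
    for t in range(years):
        traj.append(project_one_step(arr, traj[-1], float(nus[t])))
    return traj


def affine_fixed_point(
    A: "TransitionMatrix | np.ndarray", nu: float
) -> np.ndarray:
    """Stationary distribution ``(I - A)^-1 nu`` under constant supply.

    Only meaningful when the spectral radius of ``A`` is below one.
    """
    arr = _as_matrix(A)
    v = np.zeros(N_STAGES)
    v[0] = nu
    return np.linalg.solve(np.eye(N_STAGES) - arr, v)


@dataclass(frozen=True)
class CoverProxyConfig:
    """Disc-area cover proxy: representative radius per class (cm) and the
    subset of classes that contribute.  Class 1 (spat, undetectable in
    phototransects) is excluded by default; its nominal radius is only a
    placeholder."""

    radii: tuple[float, ...] = (0.5, 1.0, 3.0, 5.0, 10.0)
    classes_included: frozenset[int] = field(
        default_factory=lambda: frozenset({2, 3, 4, 5})
    )

    def __post_init__(self) -> None:
        if len(self.radii) != N_STAGES:
            raise ValueError("one radius per size class")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if not set(self.classes_included) <= set(range(1, N_STAGES + 1)):
            raise ValueError("classes_included must be a subset of 1..5")
        object.__setattr__(self, "classes_included", frozenset(self.classes_included))

    @property
    def areas(self) -> np.ndarray:
        """Per-class disc area (cm^2), zero for excluded classes."""
        a = np.pi * np.asarray(self.radii, dtype=float) ** 2
        mask = np.array([c in self.classes_included for c in range(1, N_STAGES + 1)])
        return np.where(mask, a, 0.0)


def cover_from_distribution(
    n: "SizeDistribution | np.ndarray", cfg: CoverProxyConfig | None = None
) -> float:
    """Total cover proxy in cm^2: counts times median-radius disc areas."""
    cfg = cfg or CoverProxyConfig()
    vec = n.n if isinstance(n, SizeDistribution) else np.asarray(n, dtype=float)
    if vec.shape != (N_STAGES,):
        raise ValueError("size distribution must have five classes")
    return float(vec @ cfg.areas)
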