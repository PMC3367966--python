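"""Eigenvalue elasticity and global model-sensitivity analysis.

The elasticity of the asymptotic growth rate to a matrix entry is

    e_ij = (a_ij / lambda) * v_i w_j / <v, w>

with ``w`` and ``v`` the right and left eigenvectors of the dominant
eigenvalue.  Elasticities are proportional sensitivities and always sum to
one over the matrix, so they can be compared across entries and matrices.
Because coral fertilities are poorly known, elasticities are averaged over
a logarithmic grid of fertility values substituted into A[1,4] and A[1,5]
(all pairwise combinations), and reported as entrywise mean and standard
deviation.

Global sensitivity is assessed at the level of whole projection runs:
each factor (fertility values, external recruitment level, timing of larval
import, or the starting vector) is varied over a set of alternatives while
the others are held at control values, and the mean total proportional
deviation of the final population vector from the control run, measured in
the L1 norm, is reported per factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrices import N_STAGES, TransitionMatrix, dominant_eigenvalue
from .projection import RecruitmentSeries, project_series

__all__ = [
    "ElasticityResult",
    "ControlRun",
    "SensitivityReport",
    "elasticity_matrix",
    "elasticity_over_fertility_grid",
    "global_sensitivity",
    "DEFAULT_FERTILITY_GRID",
]

DEFAULT_FERTILITY_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


def elasticity_matrix(A: "TransitionMatrix | np.ndarray") -> np.ndarray:
    """Elasticity of the dominant eigenvalue to every matrix entry.

    The right eigenvector is scaled to sum to one and the left eigenvector
    so that ``<v, w> = 1``; entries are zero wherever ``a_ij`` is zero and
    the whole matrix sums to one.
    """
    arr = A.A if isinstance(A, TransitionMatrix) else np.asarray(A, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    lam = dominant_eigenvalue(arr)
    if lam <= 0:
        raise ValueError("elasticity undefined for a matrix with lambda = 0")
    if arr.shape == (1, 1):
        return np.ones((1, 1))

    evals, evecs = np.linalg.eig(arr)
    k = int(np.argmin(np.abs(evals - lam)))
    w = np.real(evecs[:, k])
    levals, levecs = np.linalg.eig(arr.T)
    kl = int(np.argmin(np.abs(levals - lam)))
    v = np.real(levecs[:, kl])
    # fix signs so both eigenvectors are nonnegative (Perron vectors)
    if w.sum() < 0:
        w = -w
    if v.sum() < 0:
        v = -v
    w = w / w.sum()
    v = v / (v @ w)
    return (arr / lam) * np.outer(v, w)


@dataclass(frozen=True)
class ElasticityResult:
    """Entrywise mean/sd elasticity over a fertility grid."""

    mean_elasticity: np.ndarray
    sd_elasticity: np.ndarray
    fertility_grid: tuple[float, ...]
    n_combinations: int


def elasticity_over_fertility_grid(
    A_base: "TransitionMatrix | np.ndarray",
    grid: Sequence[float] = DEFAULT_FERTILITY_GRID,
) -> ElasticityResult:
    """Average elasticities over all fertility combinations.

    Every pair from ``grid`` x ``grid`` is substituted into A[1,4] and
    A[1,5] of a copy of the base matrix and the elasticity matrix computed;
    the entrywise mean and (population) standard deviation over all
    ``len(grid)**2`` combinations are returned.
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("fertility grid must be nonempty")
    if any(g <= 0 for g in grid):
        raise ValueError("fertility grid values must be positive")
    base = A_base.A if isinstance(A_base, TransitionMatrix) else np.asarray(
        A_base, dtype=float
    )
    mats = []
    for f4 in grid:
        for f5 in grid:
            arr = base.copy()
            arr[0, 3] = f4
            arr[0, 4] = f5
            mats.append(elasticity_matrix(arr))
    stack = np.stack(mats)
    return ElasticityResult(
        mean_elasticity=stack.mean(axis=0),
        sd_elasticity=stack.std(axis=0),
        fertility_grid=grid,
        n_combinations=len(mats),
    )


@dataclass(frozen=True)
class ControlRun:
    """Reference parameterization for the global sensitivity analysis."""

    n_0: np.ndarray
    nu_series: np.ndarray
    fertility: tuple[float, float] = (0.0, 0.0)
    years: int | None = None

    def __post_init__(self) -> None:
        n0 = np.asarray(self.n_0, dtype=float)
        nu = np.atleast_1d(np.asarray(self.nu_series, dtype=float))
        if n0.shape != (N_STAGES,):
            raise ValueError("control start vector must have five classes")
        object.__setattr__(self, "n_0", n0)
        object.__setattr__(self, "nu_series", nu)

    @property
    def horizon(self) -> int:
        return self.years if self.years is not None else int(self.nu_series.size)


@dataclass(frozen=True)
class SensitivityReport:
    """Per-factor mean total proportional deviation from the control run."""

    factor_deviation: Mapping[str, float]

    @property
    def ranking(self) -> list[str]:
        """Factors ordered from most to least influential."""
        return sorted(
            self.factor_deviation, key=self.factor_deviation.__getitem__, reverse=True
        )


def _final_vector(
    base: np.ndarray,
    n_0: np.ndarray,
    nu_series: np.ndarray,
    fertility: tuple[float, float],
    years: int,
) -> np.ndarray:
    arr = base.copy()
    arr[0, 3], arr[0, 4] = fertility
    mode = "mixed" if (fertility[0] or fertility[1]) else "imported_only"
    nu = np.resize(np.asarray(nu_series, dtype=float), years)
    traj = project_series(arr, n_0, RecruitmentSeries(nu=nu, mode=mode), years)
    return traj[-1].n


def global_sensitivity(
    A: "TransitionMatrix | np.ndarray",
    control: ControlRun,
    fertility_variants: Sequence[tuple[float, float]] = (),
    recruitment_level_variants: Sequence["float | np.ndarray"] = (),
    timing_variants: Sequence[np.ndarray] = (),
    n_0_variants: Sequence[np.ndarray] = (),
    classes_evaluated: Sequence[int] | None = None,
) -> SensitivityReport:
    """Rank model factors by deviation of the final vector from control.

    For each factor the projection is re-run once per variant with the
    other factors at control values; the deviation of a run is
    ``sum |modeled - control| / sum control`` over the final vector, and a
    factor's score is the mean deviation over its variants.  Factors with
    no variants are omitted from the report.

    ``classes_evaluated`` restricts the comparison to a subset of size
    classes (1-based); pass ``(2, 3, 4, 5)`` to score against
    field-observable classes only, since spat cannot be censused in
    phototransects.  Default is all five classes.
    """
    base = A.A if isinstance(A, TransitionMatrix) else np.asarray(A, dtype=float)
    years = control.horizon
    if classes_evaluated is None:
        sel = np.arange(N_STAGES)
    else:
        sel = np.asarray(sorted(classes_evaluated), dtype=int) - 1
        if sel.size == 0 or sel.min() < 0 or sel.max() >= N_STAGES:
            raise ValueError("classes_evaluated must be a nonempty subset of 1..5")
    ref = _final_vector(base, control.n_0, control.nu_series, control.fertility, years)
    denom = float(np.abs(ref[sel]).sum())
    if denom == 0:
        raise ValueError("control run ends at an all-zero vector")

    def dev(final: np.ndarray) -> float:
        return float(np.abs(final[sel] - ref[sel]).sum()) / denom

    report: dict[str, float] = {}
    if fertility_variants:
        report["fertility"] = float(
            np.mean(
                [
                    dev(_final_vector(base, control.n_0, control.nu_series, f, years))
                    for f in fertility_variants
                ]
            )
        )
    if recruitment_level_variants:
        report["recruitment_level"] = float(
            np.mean(
                [
                    dev(_final_vector(base, control.n_0, nu, control.fertility, years))
                    for nu in recruitment_level_variants
                ]
            )
        )
    if timing_variants:
        report["recruitment_timing"] = float(
            np.mean(
                [
                    dev(_final_vector(base, control.n_0, nu, control.fertility, years))
                    for nu in timing_variants
                ]
            )
        )
    if n_0_variants:
        report["start_vector"] = float(
            np.mean(
                [
                    dev(
                        _final_vector(
                            base, np.asarray(n0, float), control.nu_series,
                            control.fertility, years,
                        )
                    )
                    for n0 in n_0_variants
                ]
            )
        )
    if not report:
        raise ValueError("at least one factor needs a nonempty variant set")
    return SensitivityReport(factor_deviation=report)
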