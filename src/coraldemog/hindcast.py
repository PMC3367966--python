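"""Hindcast calibration: grid search over recruitment histories.

After a mass-mortality anchor year, the model is run forward for a fixed
number of years under every combination of (i) fertility assumptions, (ii)
per-year external spat supply drawn from a logarithmic candidate grid, and
(iii) fractions of the pre-disturbance population that survived the anchor
event.  A combination is *accepted* when the projected size distribution
deviates from the observed end-of-period distribution by strictly less than
10% in every evaluated size class; a Pearson chi-square statistic on the
evaluated classes accompanies each fit.  The per-year spat numbers of the
accepted solutions are summarized as max / min / mode, and the modal values
feed the forecast scenarios.

The parameter space is combinatorially large (a per-year grid of six spat
levels over eight years alone yields ~1.7 million recruitment histories),
so full enumeration is used up to a configurable cap and seeded uniform
subsampling beyond it.  The projection over all candidate parameterizations
is vectorized, evaluating millions of trajectories in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .matrices import N_STAGES, TransitionMatrix
from .projection import SizeDistribution

__all__ = [
    "HindcastConfig",
    "Parameterization",
    "FitResult",
    "HindcastResult",
    "RecruitmentSummary",
    "evaluate_fit",
    "enumerate_and_fit",
    "summarize_recruitment",
]

DEFAULT_NU_GRID = (0.0, 10.0, 100.0, 1000.0, 10000.0, 20000.0)
DEFAULT_FERTILITY_GRID = (0.0, 10.0, 100.0, 1000.0, 10000.0)
DEFAULT_START_SURVIVAL_GRID = (0.0, 0.01, 0.05, 0.25)


@dataclass(frozen=True)
class HindcastConfig:
    """Grids and settings for the hindcast grid search.

    ``start_survival_grid`` holds candidate fractions of the
    pre-disturbance distribution surviving the anchor event in classes 1-4;
    ``class5_survival_grid`` the analogous fractions for the largest class,
    enumerated separately because individual large colonies (notably
    massives) are known to survive events that kill smaller corals.  In
    ``mode='imported_only'`` the fertility grid collapses to zero.
    """

    fertility_grid: tuple[float, ...] = DEFAULT_FERTILITY_GRID
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID
    start_survival_grid: tuple[float, ...] = DEFAULT_START_SURVIVAL_GRID
    class5_survival_grid: tuple[float, ...] | None = None
    years: int = 8
    exclude_largest_class: bool = False
    mode: str = "imported_only"
    nu_constant: bool = False
    deviation_threshold: float = 0.10
    max_combinations: int = 1_000_000
    subsample: bool = True
    keep_all_threshold: int = 10_000

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for name in ("fertility_grid", "nu_grid", "start_survival_grid"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")
        if self.mode not in ("imported_only", "mixed"):
            raise ValueError("mode must be 'imported_only' or 'mixed'")
        if self.class5_survival_grid is None:
            object.__setattr__(
                self, "class5_survival_grid", self.start_survival_grid
            )

    @property
    def fertility_pairs(self) -> list[tuple[float, float]]:
        if self.mode == "imported_only":
            return [(0.0, 0.0)]
        return [(f4, f5) for f4 in self.fertility_grid for f5 in self.fertility_grid]


@dataclass(frozen=True)
class Parameterization:
    """One candidate model configuration in the grid search."""

    fertility: tuple[float, float]
    nu_series: tuple[float, ...]
    start_fractions: tuple[float, float]  # (classes 1-4, class 5)
    start_vector: tuple[float, ...]


@dataclass(frozen=True)
class FitResult:
    """Fit of one parameterization against the observed distribution."""

    accepted: bool
    per_class_deviation: np.ndarray  # NaN where a class was not evaluated
    chi_square: float
    p_value: float
    parameterization: Parameterization


@dataclass(frozen=True)
class HindcastResult:
    """Accepted solutions plus bookkeeping of the search."""

    accepted: list[FitResult]
    n_evaluated: int
    n_total: int
    exhaustive: bool
    config: HindcastConfig
    rng_seed: int
    all_results: list[FitResult] | None = None


def _evaluated_mask(
    observed: np.ndarray, exclude_largest: bool
) -> np.ndarray:
    mask = np.ones(N_STAGES, dtype=bool)
    if exclude_largest:
        mask[-1] = False
    zero = mask & (observed == 0)
    if np.any(zero):
        warnings.warn(
            "observed count is zero in class(es) "
            f"{[int(i) + 1 for i in np.flatnonzero(zero)]}; relative deviation "
            "is undefined there and the class(es) are dropped from evaluation",
            stacklevel=3,
        )
        mask &= observed != 0
    if not np.any(mask):
        raise ValueError("no evaluable size classes remain")
    return mask


def _chi_square(modeled: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square with modeled counts as expected values.

    Cells with expected count below 5 are pooled into the neighbouring cell
    (standard small-expected-count practice); degrees of freedom are the
    number of remaining cells minus one.
    """
    exp = list(modeled.astype(float))
    obs = list(observed.astype(float))
    i = 0
    while i < len(exp):
        if exp[i] < 5.0 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            i = 0
        else:
            i += 1
    exp_a, obs_a = np.asarray(exp), np.asarray(obs)
    valid = exp_a > 0
    stat = float(np.sum((obs_a[valid] - exp_a[valid]) ** 2 / exp_a[valid]))
    df = int(valid.sum()) - 1
    p = float(stats.chi2.sf(stat, df)) if df >= 1 else float("nan")
    return stat, p


def evaluate_fit(
    modeled: "SizeDistribution | np.ndarray",
    observed: "SizeDistribution | np.ndarray",
    exclude_largest: bool = False,
    deviation_threshold: float = 0.10,
    parameterization: Parameterization | None = None,
) -> FitResult:
    """Score a modeled distribution against the observed one.

    Acceptance requires the relative deviation ``|modeled - observed| /
    observed`` to be strictly below the threshold in *every* evaluated
    class.  Classes with zero observed count cannot be scored relatively
    and are dropped with a warning; the largest class can be excluded
    explicitly (needed where asexual reproduction generates large colonies
    faster than stage transitions allow).
    """
    mvec = modeled.n if isinstance(modeled, SizeDistribution) else np.asarray(
        modeled, dtype=float
    )
    ovec = observed.n if isinstance(observed, SizeDistribution) else np.asarray(
        observed, dtype=float
    )
    if mvec.shape != (N_STAGES,) or ovec.shape != (N_STAGES,):
        raise ValueError("size distributions must have five classes")
    mask = _evaluated_mask(ovec, exclude_largest)
    dev = np.full(N_STAGES, np.nan)
    dev[mask] = np.abs(mvec[mask] - ovec[mask]) / ovec[mask]
    accepted = bool(np.all(dev[mask] < deviation_threshold))
    stat, p = _chi_square(mvec[mask], ovec[mask])
    if parameterization is None:
        parameterization = Parameterization(
            fertility=(0.0, 0.0),
            nu_series=(),
            start_fractions=(float("nan"), float("nan")),
            start_vector=(),
        )
    return FitResult(
        accepted=accepted,
        per_class_deviation=dev,
        chi_square=stat,
        p_value=p,
        parameterization=parameterization,
    )


def _decode(
    indices: np.ndarray, dims: Sequence[int]
) -> list[np.ndarray]:
    """Mixed-radix decomposition of flat combination indices."""
    out = []
    rem = indices.copy()
    for d in reversed(dims):
        out.append(rem % d)
        rem //= d
    return out[::-1]


def enumerate_and_fit(
    A_mean: "TransitionMatrix | np.ndarray",
    observed: "SizeDistribution | np.ndarray",
    pre_disturbance: "SizeDistribution | np.ndarray",
    cfg: HindcastConfig | None = None,
    rng_seed: int = 0,
) -> HindcastResult:
    """Run the grid search and return the accepted parameterizations.

    Candidate start vectors apply a surviving fraction from
    ``start_survival_grid`` to classes 1-4 of ``pre_disturbance`` and an
    independently enumerated fraction from ``class5_survival_grid`` to
    class 5.  Recruitment histories draw each year's spat number from
    ``nu_grid`` (independently per year, or one constant level when
    ``nu_constant``).  When the total number of combinations exceeds
    ``max_combinations`` a seeded uniform subsample of that size is
    evaluated instead (rejected if ``subsample`` is disabled).

    Trajectories for all candidates are computed in one vectorized sweep;
    chi-square statistics are attached to the (typically few) accepted
    solutions.  All individual results are retained only when the search is
    small (``n_total <= keep_all_threshold``).
    """
    cfg = cfg or HindcastConfig()
    arr = A_mean.A if isinstance(A_mean, TransitionMatrix) else np.asarray(
        A_mean, dtype=float
    )
    ovec = observed.n if isinstance(observed, SizeDistribution) else np.asarray(
        observed, dtype=float
    )
    pvec = (
        pre_disturbance.n
        if isinstance(pre_disturbance, SizeDistribution)
        else np.asarray(pre_disturbance, dtype=float)
    )
    mask = _evaluated_mask(ovec, cfg.exclude_largest_class)

    fert_pairs = cfg.fertility_pairs
    s_small = np.asarray(cfg.start_survival_grid, dtype=float)
    s_large = np.asarray(cfg.class5_survival_grid, dtype=float)
    nu_vals = np.asarray(cfg.nu_grid, dtype=float)
    n_nu_axes = 1 if cfg.nu_constant else cfg.years
    dims = [len(fert_pairs), len(s_small), len(s_large)] + [len(nu_vals)] * n_nu_axes
    n_total = int(np.prod([float(d) for d in dims]))

    if n_total <= cfg.max_combinations:
        indices = np.arange(n_total, dtype=np.int64)
        exhaustive = True
    else:
        if not cfg.subsample:
            raise ValueError(
                f"{n_total} combinations exceed the cap of "
                f"{cfg.max_combinations} and subsampling is disabled"
            )
        rng = np.random.default_rng(rng_seed)
        indices = rng.integers(0, n_total, size=cfg.max_combinations, dtype=np.int64)
        exhaustive = False

    parts = _decode(indices, dims)
    fi, si, li = parts[0], parts[1], parts[2]
    nu_digits = parts[3:]
    if cfg.nu_constant:
        nu_digits = nu_digits * cfg.years

    start = np.empty((indices.size, N_STAGES))
    start[:, :4] = s_small[si, None] * pvec[:4]
    start[:, 4] = s_large[li] * pvec[4]

    fert_arr = np.asarray(fert_pairs, dtype=float)  # (F, 2)
    dev_max = np.full(indices.size, np.inf)
    modeled_all = np.empty((indices.size, N_STAGES))
    for f_idx in range(len(fert_pairs)):
        sel = fi == f_idx
        if not np.any(sel):
            continue
        Af = arr.copy()
        Af[0, 3], Af[0, 4] = fert_arr[f_idx]
        n = start[sel]
        for t in range(cfg.years):
            n = n @ Af.T
            n[:, 0] += nu_vals[nu_digits[t][sel]]
        modeled_all[sel] = n
        d = np.abs(n[:, mask] - ovec[mask]) / ovec[mask]
        dev_max[sel] = d.max(axis=1)

    accepted_idx = np.flatnonzero(dev_max < cfg.deviation_threshold)

    def make_result(k: int) -> FitResult:
        nu_series = tuple(float(nu_vals[dig[k]]) for dig in nu_digits)
        par = Parameterization(
            fertility=(float(fert_arr[fi[k], 0]), float(fert_arr[fi[k], 1])),
            nu_series=nu_series,
            start_fractions=(float(s_small[si[k]]), float(s_large[li[k]])),
            start_vector=tuple(start[k]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return evaluate_fit(
                modeled_all[k],
                ovec,
                exclude_largest=cfg.exclude_largest_class,
                deviation_threshold=cfg.deviation_threshold,
                parameterization=par,
            )

    accepted = [make_result(int(k)) for k in accepted_idx]
    all_results = None
    if n_total <= cfg.keep_all_threshold:
        all_results = [make_result(int(k)) for k in range(indices.size)]
    return HindcastResult(
        accepted=accepted,
        n_evaluated=int(indices.size),
        n_total=n_total,
        exhaustive=exhaustive,
        config=cfg,
        rng_seed=rng_seed,
        all_results=all_results,
    )


@dataclass(frozen=True)
class RecruitmentSummary:
    """Per-year max/min/mode of spat supply over accepted solutions."""

    max_nu: np.ndarray
    min_nu: np.ndarray
    mode_nu: np.ndarray
    n_solutions: int
    habitat: str = ""
    depth_zone: str = ""

    @property
    def no_solution(self) -> bool:
        return self.n_solutions == 0


def summarize_recruitment(
    accepted: Sequence[FitResult], habitat: str = "", depth_zone: str = ""
) -> RecruitmentSummary:
    """Summarize the spat histories of accepted hindcast solutions.

    The mode is taken over the exact grid values, ties broken toward the
    smaller value for reproducibility.  An empty accepted set yields an
    explicit no-solution summary rather than an error.
    """
    if not accepted:
        return RecruitmentSummary(
            max_nu=np.empty(0),
            min_nu=np.empty(0),
            mode_nu=np.empty(0),
            n_solutions=0,
            habitat=habitat,
            depth_zone=depth_zone,
        )
    series = np.asarray([f.parameterization.nu_series for f in accepted], dtype=float)
    modes = np.empty(series.shape[1])
    for t in range(series.shape[1]):
        vals, counts = np.unique(series[:, t], return_counts=True)
        modes[t] = vals[np.argmax(counts)]  # np.unique sorts: ties -> smaller
    return RecruitmentSummary(
        max_nu=series.max(axis=0),
        min_nu=series.min(axis=0),
        mode_nu=modes,
        n_solutions=len(accepted),
        habitat=habitat,
        depth_zone=depth_zone,
    )
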