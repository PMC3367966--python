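"""Stage-structured transition matrices for coral growth forms.

Corals are classified into five radius-defined size classes (spat <1 cm,
recruits <5 cm, juveniles <10 cm, medium 10-20 cm, large >20 cm open-ended)
and three growth-form guilds (arborescent, branching/encrusting, massive).
Annual dynamics of each guild are described by a 5x5 Lefkovitch matrix ``A``
whose diagonal holds stage-retention ("loop") probabilities ``P_i``, whose
sub-diagonal holds stage-advance ("growth") probabilities ``G_i``, and whose
first row may hold fertility entries at columns 4 and 5 (only mature corals
reproduce).

Given an annual within-stage survival probability ``sigma_i`` and a fixed
stage duration ``T_i`` (years spent in stage *i* before advancing, given
survival), the conditional probability ``gamma_i`` that a surviving colony
advances out of stage *i* in a given year follows the fixed-stage-duration
rule of classical matrix demography:

    gamma_i = (sigma_i**T_i - sigma_i**(T_i - 1)) / (sigma_i**T_i - 1)
            = sigma_i**(T_i - 1) / (1 + sigma_i + ... + sigma_i**(T_i - 1))

with the limit ``1 / T_i`` as ``sigma_i -> 1``.  The matrix entries are then

    G_i = sigma_i * gamma_i        (advance to stage i+1)
    P_i = sigma_i * (1 - gamma_i)  (remain in stage i)

and the open-ended last stage is absorbing: ``P_5 = sigma_5``, no ``G_5``.

Because literature life tables disagree, matrices are built by Monte-Carlo
resampling: each trial draws every stage's (sigma, T) pair independently
from a pool of life-table samples, and the arithmetic mean matrix over all
trials is used as the generalized transition model for a guild.  The
asymptotic growth rate ``lambda`` (dominant eigenvalue) of every trial is
retained as an uncertainty diagnostic; with fertilities at zero each trial
matrix is column-substochastic and lower-triangular, so every ``lambda`` is
below one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GROWTH_FORMS",
    "N_STAGES",
    "LifeTableSample",
    "TransitionMatrix",
    "MonteCarloResult",
    "gamma_from_survival",
    "build_transition_matrix",
    "build_matrix_lambda_iterated",
    "monte_carlo_mean_matrix",
    "dominant_eigenvalue",
]

GROWTH_FORMS = ("arborescent", "branching_encrusting", "massive")
N_STAGES = 5


@dataclass(frozen=True)
class LifeTableSample:
    """One literature-style life-table sample for a growth form.

    Parameters
    ----------
    growth_form
        One of :data:`GROWTH_FORMS`.
    sigma
        Per-stage annual survival probabilities, length 5, each in [0, 1].
    duration
        Fixed stage durations in years, length 5, positive integers.  The
        last stage is open-ended (absorbing), so its duration is never used;
        it is kept for tabular round-tripping and conventionally set to 1.
    source_label
        Free-text provenance of the sample (e.g. a literature citation key).
    """

    growth_form: str
    sigma: np.ndarray
    duration: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.growth_form not in GROWTH_FORMS:
            raise ValueError(f"unknown growth form {self.growth_form!r}")
        sigma = np.asarray(self.sigma, dtype=float)
        duration = np.asarray(self.duration)
        if sigma.shape != (N_STAGES,) or duration.shape != (N_STAGES,):
            raise ValueError("sigma and duration must have length 5")
        if np.any(sigma < 0) or np.any(sigma > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if not np.all(duration == np.round(duration)) or np.any(duration < 1):
            raise ValueError("stage durations must be positive integers")
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "duration", duration.astype(int))


def gamma_from_survival(sigma_i: float, T_i: int) -> float:
    """Probability that a surviving colony advances out of its stage.

    Uses the fixed-stage-duration rule in its numerically stable
    geometric-sum form ``sigma**(T-1) / sum_{k=0}^{T-1} sigma**k``, which is
    algebraically identical to ``(sigma**T - sigma**(T-1)) / (sigma**T - 1)``
    for ``sigma < 1`` and evaluates exactly to the limit ``1/T`` at
    ``sigma == 1`` and to 1 at ``T == 1``.

    Parameters
    ----------
    sigma_i
        Annual within-stage survival probability, in [0, 1].
    T_i
        Stage duration in whole years, >= 1.
    """
    if not 0.0 <= sigma_i <= 1.0:
        raise ValueError(f"sigma must lie in [0, 1], got {sigma_i}")
    if T_i != int(T_i) or T_i < 1:
        raise ValueError(f"stage duration must be a positive integer, got {T_i}")
    T_i = int(T_i)
    if T_i == 1:
        return 1.0
    powers = sigma_i ** np.arange(T_i)
    return float(powers[-1] / powers.sum())


def _gamma_vectorized(sigma: np.ndarray, duration: np.ndarray) -> np.ndarray:
    """Vectorized gamma for arrays of (sigma, T) pairs (Monte-Carlo path)."""
    sigma = np.asarray(sigma, dtype=float)
    T = np.asarray(duration, dtype=int)
    # geometric sum 1 + s + ... + s**(T-1), stable at s == 1
    near_one = np.abs(sigma - 1.0) < 1e-12
    s = np.where(near_one, 0.5, sigma)  # dummy to avoid 0/0; overwritten below
    geo = (s**T - 1.0) / (s - 1.0)
    geo = np.where(near_one, T.astype(float), geo)
    return np.where(T == 1, 1.0, sigma ** (T - 1) / geo)


@dataclass(frozen=True)
class TransitionMatrix:
    """A 5x5 stage-transition matrix with derived views.

    ``A`` stores loops on the diagonal, growth on the sub-diagonal and
    fertility at positions (1,4) and (1,5) (1-based).  ``lambda_`` is the
    spectral radius, computed on construction.
    """

    A: np.ndarray
    growth_form: str = "branching_encrusting"
    lambda_: float = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.shape != (N_STAGES, N_STAGES):
            raise ValueError("A must be 5x5")
        if np.any(A < 0):
            raise ValueError("transition matrix entries must be nonnegative")
        allowed = np.zeros_like(A, dtype=bool)
        np.fill_diagonal(allowed, True)
        allowed[np.arange(1, N_STAGES), np.arange(N_STAGES - 1)] = True  # growth
        allowed[0, np.arange(1, N_STAGES)] = True  # fertility / retrogression row 1
        allowed[np.arange(N_STAGES - 1), np.arange(1, N_STAGES)] = True  # shrinkage
        if np.any(A[~allowed] != 0):
            raise ValueError(
                "nonzero entry outside the loop/growth/fertility/shrinkage "
                "positions of a size-structured matrix"
            )
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "lambda_", dominant_eigenvalue(A))

    @property
    def P(self) -> np.ndarray:
        """Diagonal loop entries (probability of remaining in stage)."""
        return np.diag(self.A).copy()

    @property
    def G(self) -> np.ndarray:
        """Sub-diagonal growth entries, length 4."""
        return self.A[np.arange(1, N_STAGES), np.arange(N_STAGES - 1)].copy()

    @property
    def fertility(self) -> tuple[float, float]:
        """Fertility entries at (1,4) and (1,5), 1-based indexing."""
        return float(self.A[0, 3]), float(self.A[0, 4])

    @property
    def sigma(self) -> np.ndarray:
        """Per-stage survival implied by the matrix: column sums of P and G
        (fertility excluded; exact when no shrinkage entries are present)."""
        out = self.P
        out[:-1] = out[:-1] + self.G
        return out


def dominant_eigenvalue(A: "TransitionMatrix | np.ndarray") -> float:
    """Spectral radius of a nonnegative matrix (asymptotic growth rate).

    For a nonnegative matrix the dominant eigenvalue is real and equals the
    long-run annual multiplication factor of a closed population governed by
    ``A`` (Perron-Frobenius).
    """
    arr = A.A if isinstance(A, TransitionMatrix) else np.asarray(A, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(arr < 0):
        raise ValueError("matrix must be nonnegative")
    return float(np.max(np.abs(np.linalg.eigvals(arr))))


def build_transition_matrix(
    life_table: LifeTableSample,
    fertility_4: float = 0.0,
    fertility_5: float | None = None,
    shrinkage: Sequence[float] | None = None,
    gamma_lambda: float | None = None,
) -> TransitionMatrix:
    """Assemble the 5x5 matrix from one life-table sample.

    Parameters
    ----------
    life_table
        Per-stage survivals and durations.
    fertility_4, fertility_5
        Fertility entries placed at A[1,4] and A[1,5].  Fertility is assumed
        to increase steeply with colony size, so when ``fertility_5`` is not
        given it defaults to ``10 * fertility_4``, and ``fertility_5 >=
        fertility_4`` is enforced.
    shrinkage
        Optional per-stage retrogression fractions for stages 2..5 (length
        4): the fraction of survivors of stage *i* that lose enough tissue
        to drop one class, placed on the super-diagonal.  By default tissue
        loss is absorbed into the diagonal loops (no explicit retrogression),
        which is the baseline reading of partial-mortality dynamics; explicit
        entries exist for increased-shrinkage impact scenarios.
    gamma_lambda
        If given, compute gamma with survival discounted by this growth rate
        (``sigma/lambda`` replacing ``sigma``), the form appropriate when a
        population-level growth rate is already known.  ``None`` (default)
        uses the lambda-free fixed-duration form.
    """
    if fertility_4 < 0:
        raise ValueError("fertility must be nonnegative")
    if fertility_5 is None:
        fertility_5 = 10.0 * fertility_4
    if fertility_5 < 0:
        raise ValueError("fertility must be nonnegative")
    if fertility_5 < fertility_4:
        raise ValueError(
            "fertility must not decrease with size: require A[1,5] >= A[1,4]"
        )
    sigma = life_table.sigma
    if gamma_lambda is not None:
        if gamma_lambda <= 0:
            raise ValueError("gamma_lambda must be positive")
        eff = np.clip(sigma / gamma_lambda, 0.0, 1.0)
    else:
        eff = sigma
    gamma = _gamma_vectorized(eff, life_table.duration)

    A = np.zeros((N_STAGES, N_STAGES))
    if shrinkage is not None:
        shr = np.asarray(shrinkage, dtype=float)
        if shr.shape != (N_STAGES - 1,):
            raise ValueError("shrinkage needs one fraction per stage 2..5")
        if np.any(shr < 0) or np.any(gamma[1:-1] + shr[:-1] > 1.0 + 1e-12):
            raise ValueError("shrinkage fractions incompatible with gamma")
    else:
        shr = np.zeros(N_STAGES - 1)

    for i in range(N_STAGES - 1):  # stages 1..4
        A[i + 1, i] = sigma[i] * gamma[i]
        loss = shr[i - 1] if i >= 1 else 0.0
        A[i, i] = sigma[i] * (1.0 - gamma[i] - loss)
    A[N_STAGES - 1, N_STAGES - 1] = sigma[-1] * (1.0 - shr[-1])  # absorbing
    for i in range(1, N_STAGES):  # retrogression entries, super-diagonal
        if shr[i - 1] > 0:
            A[i - 1, i] += sigma[i] * shr[i - 1]
    A[0, 3] += fertility_4
    A[0, 4] += fertility_5
    return TransitionMatrix(A=A, growth_form=life_table.growth_form)


def build_matrix_lambda_iterated(
    life_table: LifeTableSample,
    fertility_4: float = 0.0,
    fertility_5: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> TransitionMatrix:
    """Self-consistent variant: gamma computed with the matrix's own lambda.

    Fixed-point iteration starting from the lambda-free matrix; each round
    rebuilds the matrix with ``gamma_lambda`` set to the previous round's
    dominant eigenvalue.  Converges rapidly for substochastic matrices.
    """
    tm = build_transition_matrix(life_table, fertility_4, fertility_5)
    lam = tm.lambda_
    for _ in range(max_iter):
        if lam <= 0:
            break
        tm = build_transition_matrix(
            life_table, fertility_4, fertility_5, gamma_lambda=lam
        )
        if abs(tm.lambda_ - lam) < tol:
            break
        lam = tm.lambda_
    return tm


@dataclass(frozen=True)
class MonteCarloResult:
    """Mean matrix and per-trial growth rates from life-table resampling."""

    mean_matrix: TransitionMatrix
    lambda_samples: np.ndarray
    n_trials: int
    rng_seed: int

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_samples, dtype=float)
        if lam.shape != (self.n_trials,):
            raise ValueError("need one lambda sample per trial")
        object.__setattr__(self, "lambda_samples", lam)


def monte_carlo_mean_matrix(
    life_table_pool: Sequence[LifeTableSample],
    n_trials: int = 10_000,
    rng_seed: int = 0,
    fertility_4: float = 0.0,
    fertility_5: float | None = None,
) -> MonteCarloResult:
    """Mean transition matrix over Monte-Carlo resampled life tables.

    Each trial draws, for every stage independently, a (sigma, T) pair
    uniformly from the pool entries for that stage, builds the trial matrix
    and records its dominant eigenvalue.  The arithmetic mean of the trial
    matrices (appropriate because samples are unrelated repeat estimates of
    the same rates) is returned as the generalized matrix for the guild.

    Deterministic for a given ``rng_seed``.
    """
    pool = list(life_table_pool)
    if not pool:
        raise ValueError("life-table pool must be nonempty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    forms = {lt.growth_form for lt in pool}
    if len(forms) > 1:
        raise ValueError(f"pool mixes growth forms: {sorted(forms)}")
    if fertility_4 < 0:
        raise ValueError("fertility must be nonnegative")
    f5 = 10.0 * fertility_4 if fertility_5 is None else fertility_5
    if f5 < fertility_4:
        raise ValueError("require A[1,5] >= A[1,4]")

    rng = np.random.default_rng(rng_seed)
    sigmas = np.stack([lt.sigma for lt in pool])  # (n_pool, 5)
    durs = np.stack([lt.duration for lt in pool])
    idx = rng.integers(0, len(pool), size=(n_trials, N_STAGES))
    cols = np.arange(N_STAGES)
    sig = sigmas[idx, cols]  # (n_trials, 5)
    dur = durs[idx, cols]
    gam = _gamma_vectorized(sig, dur)

    A = np.zeros((n_trials, N_STAGES, N_STAGES))
    rows = np.arange(N_STAGES - 1)
    A[:, rows, rows] = sig[:, :-1] * (1.0 - gam[:, :-1])
    A[:, rows + 1, rows] = sig[:, :-1] * gam[:, :-1]
    A[:, N_STAGES - 1, N_STAGES - 1] = sig[:, -1]
    A[:, 0, 3] += fertility_4
    A[:, 0, 4] += f5

    lam = np.max(np.abs(np.linalg.eigvals(A)), axis=1)
    mean = TransitionMatrix(A=A.mean(axis=0), growth_form=pool[0].growth_form)
    return MonteCarloResult(
        mean_matrix=mean, lambda_samples=lam, n_trials=n_trials, rng_seed=rng_seed
    )
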