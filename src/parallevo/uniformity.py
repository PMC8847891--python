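"""Tests of the uniform-direction null for multiple change vectors.

All three tests address the same null hypothesis — the n direction vectors
are independent with no preferred direction (population correlation matrix
Gamma = I) — but differ in their alternatives:

* Schott's high-dimensional test uses the sum of squared pairwise vector
  correlations, S = sum_{i<j} r_ij^2, standardized by its closed-form null
  moments.  It detects any concentration (unimodal, antipodal or girdle)
  but cannot tell those patterns apart.
* The Rayleigh test uses the mean resultant length of the unit vectors and
  is powerful against unimodal concentration only; antipodal or girdle
  patterns leave it blind.
* The Monte Carlo mean-pairwise-angle test compares the observed mean of
  the n(n-1)/2 pairwise angles with its simulated null distribution.  The
  statistic lacks a clear interpretation beyond this null because pairwise
  angles are mutually dependent; it is retained as a descriptive companion.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .eigenstructure import sum_squared_correlations
from .result import TestResult
from .trajectories import (CorrelationMatrix, TrajectorySet, UnitTrajectorySet,
                           angle_matrix, correlation_matrix, normalize)

__all__ = [
    "schott_moments",
    "schott_test",
    "rayleigh_test",
    "mean_pairwise_angle_test",
    "SMALL_SAMPLE_THRESHOLD",
]

#: below this min(n, k) the asymptotic Schott test runs slightly liberal
#: and the auto mode switches to Monte Carlo
SMALL_SAMPLE_THRESHOLD = 16

_DEFAULT_MC_REPS = 10_000


def schott_moments(n: int, p: int) -> tuple[float, float]:
    """Null mean and variance of S = sum_{i<j} r_ij^2 under uniformity.

    Each squared pairwise correlation is Beta(1/2, (p-1)/2) with mean 1/p
    and variance 2(p-1)/(p^2 (p+2)), and the pairs are mutually
    uncorrelated under the null, so over the n(n-1)/2 pairs

        E(S) = n(n-1) / (2p),
        Var(S) = n(n-1)(p-1) / (p^2 (p+2)).
    """
    if int(n) != n or n < 2:
        raise ValueError(f"n must be an integer >= 2, got {n}")
    if int(p) != p or p < 2:
        raise ValueError(f"p must be an integer >= 2, got {p}")
    expectation = n * (n - 1) / (2.0 * p)
    variance = n * (n - 1) * (p - 1) / (p * p * (p + 2.0))
    return expectation, variance


def _simulate_null_S(n: int, k: int, reps: int, rng: np.random.Generator,
                     generator: str = "gaussian") -> np.ndarray:
    """Null replicates of S for n uniform directions in k dims.

    Two interchangeable constructions: row-normalized Gaussian matrices
    ("gaussian"), or Wishart(k, I_n) draws rescaled to correlation matrices
    ("wishart").  Both realize the same null law of C.
    """
    if generator == "gaussian":
        X = rng.standard_normal((reps, n, k))
        Z = X / np.linalg.norm(X, axis=2, keepdims=True)
        C = np.einsum("rik,rjk->rij", Z, Z)
    elif generator == "wishart":
        W = stats.wishart.rvs(df=k, scale=np.eye(n), size=reps, random_state=rng)
        W = W.reshape(reps, n, n)
        d = 1.0 / np.sqrt(np.einsum("rii->ri", W))
        C = W * d[:, :, None] * d[:, None, :]
    else:
        raise ValueError("generator must be 'gaussian' or 'wishart'")
    return (np.einsum("rij,rij->r", C, C) - n) / 2.0


def schott_test(cm: CorrelationMatrix, k: int, mode: str = "auto",
                mc_reps: int = _DEFAULT_MC_REPS,
                seed: int | None = None,
                null_generator: str = "gaussian",
                alternative: str = "greater") -> TestResult:
    """High-dimensional test of Gamma = I from squared pairwise correlations.

    Parameters
    ----------
    cm : CorrelationMatrix
        Observed inter-lineage vector correlation matrix.
    k : int
        Effective trait-space dimensionality (the null's degrees of freedom).
    mode : {"auto", "asymptotic", "monte_carlo"}
        "asymptotic" refers Z = (S - E) / sqrt(Var) to the standard normal;
        valid as n and k grow jointly, slightly liberal when min(n, k) is
        small.  "auto" switches to Monte Carlo below min(n, k) = 16.
    null_generator : {"gaussian", "wishart"}
        Monte Carlo null construction; the two are distributionally
        equivalent and kept as a cross-check.
    alternative : {"greater", "two_sided"}
        Large S signals concentration of directions; "greater" is the
        standard usage.

    Notes
    -----
    S is sign-blind: it cannot distinguish unimodal from antipodal
    concentration.  Inspect C or the ordination scores to tell them apart.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("auto", "asymptotic", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = cm.n
    S = sum_squared_correlations(cm)
    E, V = schott_moments(n, k)
    z = (S - E) / np.sqrt(V)
    notes = []
    if min(n, k) < SMALL_SAMPLE_THRESHOLD:
        notes.append("small-sample regime: min(n, k) < 16, asymptotic "
                     "normal reference is slightly liberal")
    if mode == "auto":
        mode = "monte_carlo" if min(n, k) < SMALL_SAMPLE_THRESHOLD else "asymptotic"
    if mode == "asymptotic":
        p_upper = float(stats.norm.sf(z))
        p = min(1.0, 2 * min(p_upper, 1 - p_upper)) if alternative == "two_sided" else p_upper
        return TestResult(method="schott", statistic=S, p_value=p, n=n, k=k,
                          null_mean=E, null_sd=float(np.sqrt(V)),
                          alternative=alternative,
                          details={"z": float(z), "mode": "asymptotic"},
                          notes=notes)
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
        notes.append("seed auto-drawn")
    rng = np.random.default_rng(seed)
    # chunked so memory stays modest at large reps * n * k
    chunk = max(1, int(2e7 // max(n * k, n * n)))
    sims = np.concatenate([
        _simulate_null_S(n, k, min(chunk, mc_reps - i), rng, null_generator)
        for i in range(0, mc_reps, chunk)])
    p_upper = (1.0 + np.sum(sims >= S)) / (1.0 + mc_reps)
    if alternative == "two_sided":
        p_lower = (1.0 + np.sum(sims <= S)) / (1.0 + mc_reps)
        p = min(1.0, 2 * min(p_upper, p_lower))
    else:
        p = p_upper
    return TestResult(method="schott", statistic=S, p_value=float(p), n=n, k=k,
                      null_mean=E, null_sd=float(np.sqrt(V)),
                      alternative=alternative, mc_iterations=mc_reps, seed=seed,
                      details={"z": float(z), "mode": "monte_carlo",
                               "null_generator": null_generator,
                               "rng": "numpy PCG64"},
                      notes=notes)


def rayleigh_test(uz: UnitTrajectorySet, k: int | None = None,
                  mode: str = "asymptotic", mc_reps: int = _DEFAULT_MC_REPS,
                  seed: int | None = None) -> TestResult:
    """Rayleigh test for unimodal concentration of directions.

    The statistic is T = n * k * ||mean of the unit vectors||^2, referred
    to chi-square with k df (asymptotic mode) or to its simulated null
    (monte_carlo mode).  T is driven by the mean resultant length, so
    antipodal or girdle patterns — which cancel in the mean — are invisible
    to this test; use the Schott test for those.
    """
    if mode not in ("asymptotic", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    k = uz.k_effective if k is None else k
    if k < 2:
        raise ValueError("k must be >= 2")
    n = uz.n
    if n < 2:
        raise ValueError("need at least 2 directions")
    rbar = np.linalg.norm(uz.Z.mean(axis=0))
    T = n * k * rbar**2
    notes = []
    if mode == "asymptotic":
        p = float(stats.chi2.sf(T, df=k))
        return TestResult(method="rayleigh", statistic=float(T), p_value=p,
                          n=n, k=k, null_mean=float(k),
                          null_sd=float(np.sqrt(2 * k)),
                          alternative="unimodal_concentration",
                          details={"mean_resultant_length": float(rbar),
                                   "mode": "asymptotic", "df": k},
                          notes=notes)
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
        notes.append("seed auto-drawn")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((mc_reps, n, k))
    Zs = X / np.linalg.norm(X, axis=2, keepdims=True)
    sims = n * k * np.sum(Zs.mean(axis=1) ** 2, axis=1)
    p = float((1.0 + np.sum(sims >= T)) / (1.0 + mc_reps))
    return TestResult(method="rayleigh", statistic=float(T), p_value=p, n=n,
                      k=k, null_mean=float(sims.mean()),
                      null_sd=float(sims.std(ddof=1)),
                      alternative="unimodal_concentration",
                      mc_iterations=mc_reps, seed=seed,
                      details={"mean_resultant_length": float(rbar),
                               "mode": "monte_carlo", "rng": "numpy PCG64"},
                      notes=notes)


def mean_pairwise_angle_test(ts: TrajectorySet | UnitTrajectorySet,
                             iterations: int = 100_000,
                             seed: int | None = None,
                             alternative: str = "parallel") -> TestResult:
    """Monte Carlo test of the mean pairwise angle against uniformity.

    The observed statistic is the mean of the n(n-1)/2 pairwise angles.
    Null replicates regenerate n independent uniform directions in
    k_effective dimensions; the p-value is tail-counted with the +1
    correction.  ``alternative="parallel"`` treats small means as extreme.

    The mean pairwise angle has no clear interpretation away from the
    uniformity null (pairwise angles are mutually dependent), which is
    recorded as a note on the result.
    """
    if iterations < 1000:
        raise ValueError("need at least 1000 Monte Carlo iterations")
    if alternative not in ("parallel", "antiparallel", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    uz = ts if isinstance(ts, UnitTrajectorySet) else normalize(ts)
    n, k = uz.n, uz.k_effective
    if n < 2:
        raise ValueError("need at least 2 directions")
    iu = np.triu_indices(n, 1)
    observed = float(angle_matrix(correlation_matrix(uz))[iu].mean())
    notes = ["mean pairwise angle lacks a clear interpretation beyond the "
             "uniform-direction null (pairwise angles are dependent)"]
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
        notes.append("seed auto-drawn")
    rng = np.random.default_rng(seed)
    chunk = max(1, int(2e7 // (n * k)))
    sims = np.empty(iterations)
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        X = rng.standard_normal((m, n, k))
        Z = X / np.linalg.norm(X, axis=2, keepdims=True)
        C = np.clip(np.einsum("rik,rjk->rij", Z, Z), -1.0, 1.0)
        sims[done:done + m] = np.arccos(C[:, iu[0], iu[1]]).mean(axis=1)
        done += m
    p_low = (1.0 + np.sum(sims <= observed)) / (1.0 + iterations)
    p_high = (1.0 + np.sum(sims >= observed)) / (1.0 + iterations)
    if alternative == "parallel":
        p = p_low
    elif alternative == "antiparallel":
        p = p_high
    else:
        p = min(1.0, 2.0 * min(p_low, p_high))
    return TestResult(method="mean_pairwise_angle", statistic=observed,
                      p_value=float(p), n=n, k=k,
                      null_mean=float(sims.mean()),
                      null_sd=float(sims.std(ddof=1)),
                      alternative=alternative, mc_iterations=iterations,
                      seed=seed,
                      details={"mean_angle_deg": float(np.degrees(observed)),
                               "n_pairs": len(iu[0]), "rng": "numpy PCG64"},
                      notes=notes)
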