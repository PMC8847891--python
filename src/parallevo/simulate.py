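"""Synthetic direction and specimen generators.

Samplers for unit vectors on the hypersphere S^(k-1) under the regimes the
uniformity tests are meant to separate:

* ``uniform`` — no preferred direction (the shared null of every test);
* ``vmf`` — von Mises–Fisher unimodal concentration around a mean
  direction mu with concentration kappa (kappa = 0 reduces to uniform);
* ``antipodal_vmf`` — a vMF draw whose sign is flipped with probability
  1/2: an axial pattern with two opposite modes and zero mean resultant;
* ``girdle`` — mass concentrated near the great (hyper)circle orthogonal
  to a given normal vector.

The girdle parameterization is a package convention: an isotropic Gaussian
draw has its component along the girdle normal shrunk by 1/sqrt(1 + kappa)
before renormalization, so kappa = 0 is uniform and kappa -> inf collapses
onto the equatorial hyperplane.

A specimen-level generator produces ancestor/descendant Gaussian samples
around programmed lineage means, for bootstrap demonstrations and
round-trip tests of the change-vector computation.

Every sampler is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trajectories import SpecimenTable, UnitTrajectorySet

__all__ = [
    "DirectionModel",
    "SpecimenModel",
    "sample_uniform_directions",
    "sample_directions",
    "sample_specimens",
    "power_study",
]

KINDS = ("uniform", "vmf", "antipodal_vmf", "girdle")


@dataclass
class DirectionModel:
    """Specification of a distribution of directions on S^(k-1)."""

    kind: str
    k: int
    mu: np.ndarray | None = None  # mean direction (vmf/antipodal_vmf)
    kappa: float = 0.0  # concentration, >= 0
    girdle_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.kind in ("vmf", "antipodal_vmf"):
            if self.mu is None:
                mu = np.zeros(self.k)
                mu[0] = 1.0
                self.mu = mu
            self.mu = np.asarray(self.mu, dtype=float)
            if abs(np.linalg.norm(self.mu) - 1.0) > 1e-10:
                raise ValueError("mu must be a unit vector")
        if self.kind == "girdle":
            if self.girdle_normal is None:
                g = np.zeros(self.k)
                g[0] = 1.0
                self.girdle_normal = g
            self.girdle_normal = np.asarray(self.girdle_normal, dtype=float)
            if abs(np.linalg.norm(self.girdle_normal) - 1.0) > 1e-10:
                raise ValueError("girdle_normal must be a unit vector")


@dataclass
class SpecimenModel:
    """Programmed lineage means plus within-group Gaussian noise."""

    ancestor_means: np.ndarray  # n x p
    descendant_means: np.ndarray  # n x p
    sd: float = 1.0
    n_specimens: int = 10  # per lineage x role cell
    lineage_ids: list | None = None
    trait_names: list | None = None

    def __post_init__(self) -> None:
        self.ancestor_means = np.atleast_2d(np.asarray(self.ancestor_means, float))
        self.descendant_means = np.atleast_2d(np.asarray(self.descendant_means, float))
        if self.ancestor_means.shape != self.descendant_means.shape:
            raise ValueError("ancestor and descendant mean arrays must match")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n_specimens < 1:
            raise ValueError("need at least one specimen per group")
        n, p = self.ancestor_means.shape
        if self.lineage_ids is None:
            self.lineage_ids = [f"lineage_{i+1}" for i in range(n)]
        if self.trait_names is None:
            self.trait_names = [f"trait_{j+1}" for j in range(p)]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def sample_uniform_directions(n: int, k: int,
                              seed: int | np.random.Generator | None = None
                              ) -> UnitTrajectorySet:
    """n independent directions uniform on S^(k-1).

    Realized by normalizing rows of an isotropic standard Gaussian matrix —
    the canonical construction of the uniform law on the hypersphere.
    """
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 and k >= 2")
    rng = np.random.default_rng(seed)
    Z = _unit_rows(rng.standard_normal((n, k)))
    return UnitTrajectorySet(
        lineage_ids=[f"sim_{i+1}" for i in range(n)],
        trait_names=[f"trait_{j+1}" for j in range(k)],
        Z=Z, k_effective=k)


def sample_directions(model: DirectionModel, n: int,
                      seed: int | np.random.Generator | None = None
                      ) -> UnitTrajectorySet:
    """Sample n directions from the given model; deterministic under seed.

    vMF draws use rejection sampling of the cosine component (Wood's
    algorithm, via scipy); the sampler name is recorded in the result's
    ``provenance`` attribute.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = model.k
    algorithm = "gaussian-normalization"
    if model.kind == "uniform" or model.kappa == 0.0:
        Z = _unit_rows(rng.standard_normal((n, k)))
    elif model.kind in ("vmf", "antipodal_vmf"):
        vmf = stats.vonmises_fisher(model.mu, model.kappa)
        Z = np.atleast_2d(vmf.rvs(n, random_state=rng))
        algorithm = "wood-rejection-vmf"
        if model.kind == "antipodal_vmf":
            flips = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            Z = Z * flips[:, None]
    else:  # girdle
        X = rng.standard_normal((n, k))
        g = model.girdle_normal
        along = X @ g
        X = X + np.outer(along * (1.0 / np.sqrt(1.0 + model.kappa) - 1.0), g)
        Z = _unit_rows(X)
        algorithm = "gaussian-equatorial-shrinkage"
    out = UnitTrajectorySet(
        lineage_ids=[f"sim_{i+1}" for i in range(n)],
        trait_names=[f"trait_{j+1}" for j in range(k)],
        Z=Z, k_effective=k)
    out.provenance = {"kind": model.kind, "kappa": model.kappa,
                      "algorithm": algorithm}
    return out


def sample_specimens(model: SpecimenModel,
                     seed: int | np.random.Generator | None = None
                     ) -> SpecimenTable:
    """Specimen table with Gaussian noise of the stated sd around each mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, lid in enumerate(model.lineage_ids):
        for role, means in (("ancestor", model.ancestor_means[i]),
                            ("descendant", model.descendant_means[i])):
            vals = means + model.sd * rng.standard_normal(
                (model.n_specimens, len(model.trait_names)))
            for s in range(model.n_specimens):
                rows.append({"specimen_id": f"{lid}_{role[:3]}_{s+1}",
                             "lineage_id": lid, "role": role,
                             **dict(zip(model.trait_names, vals[s]))})
    return SpecimenTable(pd.DataFrame(rows))


def power_study(model: DirectionModel, n: int, replicates: int,
                alpha: float = 0.05, tests: tuple = ("schott", "rayleigh"),
                seed: int | None = None) -> pd.DataFrame:
    """Rejection rates of the uniformity tests under a direction model.

    Runs each requested test on ``replicates`` independent datasets of n
    directions and reports the rejection proportion at ``alpha`` with its
    binomial standard error.  Uses the asymptotic form of each test.
    """
    from .uniformity import rayleigh_test, schott_test
    from .trajectories import correlation_matrix

    if replicates < 100:
        raise ValueError("need at least 100 replicates for a stable estimate")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rejections = {t: 0 for t in tests}
    for _ in range(replicates):
        uz = sample_directions(model, n, seed=rng)
        for t in tests:
            if t == "schott":
                res = schott_test(correlation_matrix(uz), k=model.k,
                                  mode="asymptotic")
            elif t == "rayleigh":
                res = rayleigh_test(uz, k=model.k, mode="asymptotic")
            else:
                raise ValueError(f"unknown test {t!r}")
            rejections[t] += res.p_value < alpha
    recs = []
    for t in tests:
        power = rejections[t] / replicates
        recs.append({"test": t, "kind": model.kind, "kappa": model.kappa,
                     "n": n, "k": model.k, "alpha": alpha,
                     "replicates": replicates, "power": power,
                     "se": np.sqrt(power * (1 - power) / replicates),
                     "seed": seed})
    return pd.DataFrame.from_records(recs)
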