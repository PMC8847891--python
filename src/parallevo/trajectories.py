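"""Phenotypic change vectors and their pairwise comparison.

A phenotypic change vector is the p-dimensional difference between
descendant and ancestor trait means for one lineage.  Stacking the n
lineages' vectors as rows gives the n x p matrix X; row-normalizing yields
Z, and C = Z Z^T is the inter-lineage vector correlation matrix whose
(i, j) entry is the cosine of the angle between lineages i and j.  Rows are
deliberately NOT mean-centred across traits: direction vectors retain the
full effective dimensionality of the trait space unless the traits
themselves are linearly dependent, which the caller declares through
``k_effective``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nulldist import AngleNull, angle_cdf, angle_test, clip_correlation

__all__ = [
    "TrajectorySet",
    "UnitTrajectorySet",
    "CorrelationMatrix",
    "SpecimenTable",
    "change_vectors",
    "normalize",
    "correlation_matrix",
    "angle_matrix",
    "pairwise_angle_report",
]

ROLES = ("ancestor", "descendant")


@dataclass
class TrajectorySet:
    """n lineages' phenotypic change vectors in a p-trait space.

    ``k_effective`` defaults to p and should be lowered when traits are
    linearly dependent (e.g. Procrustes shape coordinates).
    """

    lineage_ids: list
    trait_names: list
    X: np.ndarray
    k_effective: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if n < 1 or p < 2:
            raise ValueError(f"need >= 1 lineages and >= 2 traits, got {n} x {p}")
        if len(self.lineage_ids) != n or len(set(self.lineage_ids)) != n:
            raise ValueError("lineage_ids must be unique and match rows of X")
        if len(self.trait_names) != p or len(set(self.trait_names)) != p:
            raise ValueError("trait_names must be unique and match columns of X")
        if self.k_effective is None:
            self.k_effective = p
        if not 2 <= self.k_effective <= p:
            raise ValueError(f"k_effective must be in [2, {p}], got {self.k_effective}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=pd.Index(self.lineage_ids, name="lineage"),
                            columns=self.trait_names)


@dataclass
class UnitTrajectorySet:
    """Row-normalized change vectors: each row of Z is a unit direction."""

    lineage_ids: list
    trait_names: list
    Z: np.ndarray
    k_effective: int | None = None
    source: TrajectorySet | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        norms = np.linalg.norm(self.Z, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-10):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise ValueError(
                f"row {self.lineage_ids[bad]!r} has norm {norms[bad]!r}, not unit")
        if self.k_effective is None:
            self.k_effective = self.Z.shape[1]

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric n x n matrix of pairwise vector correlations (cosines)."""

    lineage_ids: list
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if np.max(np.abs(C - C.T)) > 1e-12:
            raise ValueError("C must be symmetric")
        C = clip_correlation(C)
        np.fill_diagonal(C, 1.0)
        self.C = C

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass
class SpecimenTable:
    """Specimen-level trait data: one row per specimen with lineage and role.

    Every lineage must have at least one ancestor and one descendant
    specimen; missing trait values are rejected (no imputation).
    """

    data: pd.DataFrame  # columns: specimen_id, lineage_id, role, traits...

    def __post_init__(self) -> None:
        required = {"specimen_id", "lineage_id", "role"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"SpecimenTable missing columns: {sorted(missing)}")
        bad_roles = set(self.data["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        traits = self.trait_names
        if len(traits) < 2:
            raise ValueError("need at least 2 trait columns")
        block = self.data[traits]
        if block.isna().any().any():
            loc = np.argwhere(block.isna().to_numpy())[0]
            raise ValueError(
                f"missing trait value at row {loc[0]}, trait {traits[loc[1]]!r}")
        if not all(np.issubdtype(block[c].dtype, np.number) for c in traits):
            raise ValueError("trait columns must be numeric")
        for lid, grp in self.data.groupby("lineage_id", sort=False):
            for role in ROLES:
                if (grp["role"] == role).sum() < 1:
                    raise ValueError(f"lineage {lid!r} has no {role} specimens")

    @property
    def trait_names(self) -> list:
        return [c for c in self.data.columns
                if c not in ("specimen_id", "lineage_id", "role")]

    @property
    def lineage_ids(self) -> list:
        return list(dict.fromkeys(self.data["lineage_id"]))


def change_vectors(specimens: SpecimenTable,
                   k_effective: int | None = None) -> TrajectorySet:
    """Per-lineage change vectors: descendant trait means minus ancestor means.

    Lineage order follows first appearance in the specimen table.
    """
    traits = specimens.trait_names
    rows = []
    lids = specimens.lineage_ids
    for lid in lids:
        grp = specimens.data[specimens.data["lineage_id"] == lid]
        anc = grp.loc[grp["role"] == "ancestor", traits].mean(axis=0).to_numpy()
        des = grp.loc[grp["role"] == "descendant", traits].mean(axis=0).to_numpy()
        rows.append(des - anc)
    return TrajectorySet(lineage_ids=lids, trait_names=list(traits),
                         X=np.vstack(rows), k_effective=k_effective)


def normalize(ts: TrajectorySet, zero_tol: float = 1e-12) -> UnitTrajectorySet:
    """Scale each change vector to unit length, preserving its direction.

    A zero-length trajectory has no direction and raises, naming the lineage.
    """
    norms = np.linalg.norm(ts.X, axis=1)
    if np.any(norms <= zero_tol):
        bad = int(np.argmin(norms))
        raise ValueError(
            f"lineage {ts.lineage_ids[bad]!r} has a zero-length change vector; "
            "its direction is undefined")
    Z = ts.X / norms[:, None]
    Z /= np.linalg.norm(Z, axis=1)[:, None]  # second pass tightens rounding
    return UnitTrajectorySet(lineage_ids=list(ts.lineage_ids),
                             trait_names=list(ts.trait_names),
                             Z=Z, k_effective=ts.k_effective, source=ts)


def correlation_matrix(uz: UnitTrajectorySet) -> CorrelationMatrix:
    """Inter-lineage vector correlation matrix C = Z Z^T."""
    return CorrelationMatrix(lineage_ids=list(uz.lineage_ids), C=uz.Z @ uz.Z.T)


def angle_matrix(cm: CorrelationMatrix, units: str = "radians") -> np.ndarray:
    """Element-wise arccosine of C: the symmetric matrix of pairwise angles."""
    if units not in ("radians", "degrees"):
        raise ValueError("units must be 'radians' or 'degrees'")
    theta = np.arccos(cm.C)
    np.fill_diagonal(theta, 0.0)
    return np.degrees(theta) if units == "degrees" else theta


def pairwise_angle_report(ts: TrajectorySet | UnitTrajectorySet,
                          alpha: float = 0.05,
                          bonferroni: bool = False) -> pd.DataFrame:
    """Two-sided angle test for every unordered lineage pair.

    Each pair is flagged ``parallel`` when its angle falls below the
    alpha/2 null quantile, ``antiparallel`` above the 1 - alpha/2 quantile,
    and ``null-consistent`` otherwise (boundary equality is non-extreme).

    Pairwise p-values share vectors and are NOT independent, so flag counts
    are descriptive; no error-rate control is applied by default.  The
    optional Bonferroni adjustment is conservative but not exact under this
    dependence.  The caveat is recorded in ``DataFrame.attrs["caveat"]``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    uz = ts if isinstance(ts, UnitTrajectorySet) else normalize(ts)
    k = uz.k_effective
    cm = correlation_matrix(uz)
    theta = angle_matrix(cm)
    n = uz.n
    m = n * (n - 1) // 2
    thr = alpha / (2 * m) if bonferroni else alpha / 2
    null = AngleNull(k)
    recs = []
    for i in range(n):
        for j in range(i + 1, n):
            res = angle_test(theta[i, j], k, alternative="two_sided")
            cdf_val = float(angle_cdf(null, theta[i, j]))
            if cdf_val < thr:
                flag = "parallel"
            elif cdf_val > 1 - thr:
                flag = "antiparallel"
            else:
                flag = "null-consistent"
            recs.append({
                "lineage_i": uz.lineage_ids[i],
                "lineage_j": uz.lineage_ids[j],
                "angle_rad": theta[i, j],
                "angle_deg": np.degrees(theta[i, j]),
                "r": cm.C[i, j],
                "p_value": res.p_value,
                "flag": flag,
            })
    out = pd.DataFrame.from_records(recs)
    out.attrs["k_effective"] = k
    out.attrs["alpha"] = alpha
    out.attrs["bonferroni"] = bonferroni
    out.attrs["caveat"] = (
        "pairwise angles share vectors and their p-values are not "
        "independent; flag counts are descriptive, not a joint test")
    return out
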