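"""Exploratory summaries of trajectory sets.

Ordination biplots of the standardized change vectors, specimen-level
bootstrap clouds with confidence ellipses for the directional sampling
error of each lineage, and k-means clustering of directions.  Tests come
after these: the uniformity tests cannot distinguish unimodal, antipodal
and girdle departures, so looking at the ordination first is part of the
method, not decoration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .eigenstructure import EigenResult, eigen_A
from .trajectories import (SpecimenTable, UnitTrajectorySet, change_vectors,
                           normalize)

__all__ = [
    "BiplotLayout",
    "BootstrapCloud",
    "biplot",
    "bootstrap_directions",
    "kmeans_grouping",
    "plot_biplot",
]


@dataclass
class BiplotLayout:
    """Joint 2-D layout of lineage scores and trait coefficients.

    From the SVD Z = U S V^T restricted to the two leading components,
    scores are U S^(1-alpha) and coefficients V S^alpha, so their product
    always reconstructs the rank-2 part of Z regardless of alpha.
    alpha = 1 puts the full singular values on the trait coefficients.
    """

    scores: pd.DataFrame  # lineage x (comp1, comp2)
    coefficients: pd.DataFrame  # trait x (comp1, comp2)
    alpha_scaling: float
    singular_values: np.ndarray
    eigenvalues: np.ndarray  # of A, all components

    @property
    def explained_proportion(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues[:2] / tot


@dataclass
class BootstrapCloud:
    """Bootstrap replicate scores and normal-theory confidence ellipses."""

    replicate_scores: pd.DataFrame  # columns: lineage, replicate, comp1, comp2
    ellipses: pd.DataFrame  # per lineage: center, semi-axes, orientation
    replicates: int
    seed: int | None
    coverage: float
    notes: list


def biplot(uz: UnitTrajectorySet, alpha_scaling: float = 1.0,
           n_components: int = 2) -> BiplotLayout:
    """SVD biplot of the unit change vectors.

    alpha_scaling in [0, 1] allocates singular values between lineage
    scores (exponent 1 - alpha) and trait coefficients (exponent alpha).
    """
    if not 0.0 <= alpha_scaling <= 1.0:
        raise ValueError("alpha_scaling must lie in [0, 1]")
    er = eigen_A(uz)
    lam = er.eigenvalues
    s = np.sqrt(lam[:n_components])
    # rank-deficient inputs: degenerate components carry zero scores so the
    # reconstruction identity still holds at the actual rank
    nonzero = s > 1e-10 * max(s[0], 1.0)
    V = er.eigenvectors[:, :n_components]
    G = er.scores[:, :n_components]  # = U S
    U = np.where(nonzero, G / np.where(nonzero, s, 1.0), 0.0)
    cols = [f"comp{i+1}" for i in range(n_components)]
    scores = pd.DataFrame(U * s**(1.0 - alpha_scaling),
                          index=pd.Index(uz.lineage_ids, name="lineage"),
                          columns=cols)
    coeffs = pd.DataFrame(V * s**alpha_scaling,
                          index=pd.Index(uz.trait_names, name="trait"),
                          columns=cols)
    return BiplotLayout(scores=scores, coefficients=coeffs,
                        alpha_scaling=alpha_scaling, singular_values=s,
                        eigenvalues=lam)


def _ellipse_params(points: np.ndarray, coverage: float) -> dict:
    """Normal-theory ellipse of 2-D points: chi-square(2) quantile of the
    replicate covariance."""
    center = points.mean(axis=0)
    if len(points) < 2 or np.allclose(points, points[0]):
        return {"center_1": center[0], "center_2": center[1],
                "semi_major": 0.0, "semi_minor": 0.0, "orientation_rad": 0.0}
    cov = np.cov(points.T)
    lam, vec = np.linalg.eigh(cov)
    lam = np.clip(lam[::-1], 0.0, None)
    vec = vec[:, ::-1]
    q = stats.chi2.ppf(coverage, df=2)
    return {"center_1": center[0], "center_2": center[1],
            "semi_major": float(np.sqrt(lam[0] * q)),
            "semi_minor": float(np.sqrt(lam[1] * q)),
            "orientation_rad": float(np.arctan2(vec[1, 0], vec[0, 0]))}


def bootstrap_directions(specimens: SpecimenTable, reference: EigenResult,
                         replicates: int = 5000, seed: int | None = None,
                         coverage: float = 0.95) -> BootstrapCloud:
    """Directional sampling error of each lineage via specimen bootstrap.

    Per replicate, specimens are resampled with replacement within each
    lineage x role cell, change vectors recomputed, renormalized (the
    direction is the object of study) and projected onto the FIRST TWO
    trait-space eigenvectors of the observed data's decomposition, which
    stay fixed across replicates.  Ellipses are normal-theory at the given
    coverage.  Lineages with short trajectories relative to the noise show
    visibly larger directional scatter.
    """
    if replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if reference.source != "trait_crossproduct_A":
        raise ValueError("reference must be the trait-side decomposition")
    rng = np.random.default_rng(seed)
    V2 = reference.eigenvectors[:, :2]
    traits = specimens.trait_names
    lids = specimens.lineage_ids
    notes = []
    # pre-split trait blocks per cell for speed
    cells = {}
    for lid in lids:
        grp = specimens.data[specimens.data["lineage_id"] == lid]
        for role in ("ancestor", "descendant"):
            block = grp.loc[grp["role"] == role, traits].to_numpy(dtype=float)
            if block.shape[0] < 2:
                notes.append(f"lineage {lid!r} has < 2 {role} specimens: "
                             "bootstrap resampling is degenerate for this cell")
            cells[(lid, role)] = block
    recs = []
    for r in range(replicates):
        for lid in lids:
            anc = cells[(lid, "ancestor")]
            des = cells[(lid, "descendant")]
            anc_mean = anc[rng.integers(len(anc), size=len(anc))].mean(axis=0)
            des_mean = des[rng.integers(len(des), size=len(des))].mean(axis=0)
            d = des_mean - anc_mean
            nrm = np.linalg.norm(d)
            if nrm <= 1e-12:
                continue  # zero replicate trajectory: no direction to project
            sc = (d / nrm) @ V2
            recs.append({"lineage": lid, "replicate": r,
                         "comp1": sc[0], "comp2": sc[1]})
    rep_scores = pd.DataFrame.from_records(recs)
    ell = []
    for lid in lids:
        pts = rep_scores.loc[rep_scores["lineage"] == lid,
                             ["comp1", "comp2"]].to_numpy()
        ell.append({"lineage": lid, **_ellipse_params(pts, coverage)})
    return BootstrapCloud(replicate_scores=rep_scores,
                          ellipses=pd.DataFrame.from_records(ell),
                          replicates=replicates, seed=seed,
                          coverage=coverage, notes=notes)


def kmeans_grouping(uz: UnitTrajectorySet, k_range=(2, 3, 4, 5),
                    restarts: int = 50, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-means clustering of unit change vectors over a range of k.

    Returns (labels, summary): cluster labels per lineage for each k, and
    the within-group sum of squares per k.  No automatic choice of k is
    made — inspect the summary and the ordination.
    """
    k_range = [int(k) for k in np.atleast_1d(k_range)]
    n = uz.n
    for k in k_range:
        if not 1 <= k <= n:
            raise ValueError(f"cluster count {k} must satisfy 1 <= k <= n={n}")
    labels = pd.DataFrame(index=pd.Index(uz.lineage_ids, name="lineage"))
    recs = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(uz.Z)
        labels[f"k={k}"] = lab
        recs.append({"k": k, "within_group_ss": float(km.inertia_),
                     "restarts": restarts, "seed": seed})
    return labels, pd.DataFrame.from_records(recs)


def plot_biplot(layout: BiplotLayout, path=None, max_arrows: int = 20):
    """Optional matplotlib rendering of a biplot layout.

    Side-effect-free except for the optional file write; all plotted
    quantities live in the layout's tables, so nothing here is load-bearing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    sc = layout.scores
    ax.scatter(sc["comp1"], sc["comp2"], s=25, zorder=3)
    for lid, row in sc.iterrows():
        ax.annotate(str(lid), (row["comp1"], row["comp2"]), fontsize=8)
    co = layout.coefficients
    mags = np.hypot(co["comp1"], co["comp2"])
    for t in mags.sort_values(ascending=False).index[:max_arrows]:
        ax.arrow(0, 0, co.loc[t, "comp1"], co.loc[t, "comp2"],
                 color="tab:orange", alpha=0.6, head_width=0.01)
    ev = layout.explained_proportion * 100
    ax.set_xlabel(f"Component 1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"Component 2 ({ev[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
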