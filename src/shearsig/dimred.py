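"""Similarity and spatial metrics in reduced dimensions.

Two complementary views of group similarity:

* canonical correlation analysis (CCA) between the control and PAH sample
  blocks of one flow condition, with genes as observations and samples as
  variables — the mean of the first three canonical correlations is the
  similarity score;
* three-component PCA of all samples, with a 95% confidence ellipsoid
  (Gaussian, chi-square(3)-scaled sample covariance) per (group, condition),
  pairwise centroid distances quantifying transcriptional shifts, and an
  intra-group dispersion (RMS distance of members to their centroid)
  quantifying inter-patient heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import ExpressionMatrix, SampleAnnotation, ValidationError


@dataclass
class CcaSimilarity:
    condition: str
    canonical_correlations: tuple[float, ...]
    similarity: float
    n_components: int = 3


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("a sample column is constant; cannot standardize")
    return (M - mean) / sd


def canonical_correlations(
    X: np.ndarray, Y: np.ndarray, n_components: int
) -> np.ndarray:
    """First ``n_components`` canonical correlations between the column
    spaces of X and Y (rows are shared observations).

    Solved as the generalized symmetric eigenproblem
    ``Sxy Syy^-1 Syx v = rho^2 Sxx v``; eigenvalues are the squared
    canonical correlations, which makes the result symmetric in X and Y.
    """
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = Sxy @ linalg.solve(Syy, Sxy.T, assume_a="pos")
    rho2 = linalg.eigh(M, Sxx, eigvals_only=True)
    rho2 = np.clip(rho2, 0.0, 1.0)
    rho = np.sqrt(rho2)[::-1]  # non-increasing
    return rho[:n_components]


def cca_similarity(
    X: ExpressionMatrix | np.ndarray,
    Y: ExpressionMatrix | np.ndarray,
    n_components: int = 3,
    condition: str = "",
) -> CcaSimilarity:
    """Canonical-correlation similarity between two sample blocks.

    Genes are observations; each block's sample columns are standardized to
    zero mean and unit variance over genes before fitting.  The similarity
    score is the mean of the first three canonical correlations.
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    Yv = Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, float)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValidationError("X and Y must cover the same genes (rows)")
    if Xv.shape[1] < n_components or Yv.shape[1] < n_components:
        raise ValidationError(
            f"need >= {n_components} samples on each side, got "
            f"{Xv.shape[1]} and {Yv.shape[1]}"
        )
    Xs = _standardize_columns(Xv)
    Ys = _standardize_columns(Yv)
    rho = canonical_correlations(Xs, Ys, n_components)
    return CcaSimilarity(
        condition=condition,
        canonical_correlations=tuple(float(r) for r in rho),
        similarity=float(rho.mean()),
        n_components=n_components,
    )


@dataclass
class EllipsoidSummary:
    """95% confidence ellipsoid of one (group, condition) in 3D PC space."""

    label: str
    group: str
    condition: str
    n_members: int
    centroid: np.ndarray
    covariance: np.ndarray
    scale95: float
    dispersion: float
    degenerate: bool = False

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each point (rows) lies inside the 95% ellipsoid."""
        pts = np.atleast_2d(points) - self.centroid
        if self.degenerate:
            return np.all(pts == 0, axis=1)
        sol = linalg.solve(self.covariance, pts.T, assume_a="pos")
        d2 = np.einsum("ij,ji->i", pts, sol)
        return d2 <= self.scale95


def pca3(
    E: ExpressionMatrix,
    ann: SampleAnnotation,
    n_components: int = 3,
    scale: bool = False,
    dispersion_metric: str = "rms",
) -> tuple[pd.DataFrame, list[EllipsoidSummary], np.ndarray]:
    """PCA of samples with per-(group, condition) ellipsoid summaries.

    Genes are centered (and optionally unit-scaled) before decomposition;
    scores are the projections of samples on the top right singular
    directions of the centered samples x genes matrix.  Returns the score
    table, ellipsoid summaries (singleton groups are flagged degenerate
    with a zero covariance), and the explained variance ratio.
    """
    if E.n_genes < n_components or len(E.sample_ids) < n_components + 1:
        raise ValidationError("too few genes or samples for a 3-component PCA")
    if dispersion_metric not in ("rms", "mean"):
        raise ValidationError("dispersion_metric must be 'rms' or 'mean'")
    M = E.values.T.astype(float)  # samples x genes
    M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    # deterministic sign: largest-magnitude loading of each axis positive
    for j in range(n_components):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1.0
    evr = S**2 / np.sum(S**2)
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(E.sample_ids, name="sample"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )

    summaries: list[EllipsoidSummary] = []
    groups = ann.table[ann.table["sample_id"].isin(E.sample_ids)]
    for (g, c), block in groups.groupby(["group", "condition"], sort=True):
        members = [s for s in block["sample_id"] if s in score_df.index]
        pts = score_df.loc[members].to_numpy()
        centroid = pts.mean(axis=0)
        degenerate = len(members) < 2
        if degenerate:
            cov = np.zeros((n_components, n_components))
        else:
            cov = np.cov(pts, rowvar=False, ddof=1)
        d = np.linalg.norm(pts - centroid, axis=1)
        dispersion = float(np.sqrt(np.mean(d**2)) if dispersion_metric == "rms"
                           else np.mean(d))
        summaries.append(
            EllipsoidSummary(
                label=f"{g}_{c}",
                group=str(g),
                condition=str(c),
                n_members=len(members),
                centroid=centroid,
                covariance=cov,
                scale95=float(stats.chi2.ppf(0.95, df=n_components)),
                dispersion=dispersion,
                degenerate=degenerate,
            )
        )
    return score_df, summaries, evr[:n_components]


def centroid_metrics(summaries: list[EllipsoidSummary]) -> pd.DataFrame:
    """Symmetric table of pairwise Euclidean distances between centroids."""
    if len(summaries) < 2:
        raise ValidationError("need >= 2 ellipsoid summaries")
    labels = [s.label for s in summaries]
    n = len(summaries)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(summaries[i].centroid - summaries[j].centroid))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=pd.Index(labels, name="label"), columns=labels)


def dispersion_table(summaries: list[EllipsoidSummary]) -> pd.DataFrame:
    rows = [
        {"label": s.label, "group": s.group, "condition": s.condition,
         "n_members": s.n_members, "dispersion": s.dispersion,
         "degenerate": s.degenerate}
        for s in summaries
    ]
    return pd.DataFrame(rows).set_index("label")
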