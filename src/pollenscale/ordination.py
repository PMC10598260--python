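"""Per-record PCA on square-rooted assemblages.

The principal components are the eigenvectors of the column-centred
covariance matrix of the sqrt-proportion assemblage; projecting the centred
matrix on them yields score time series.  Only PC1 — the locally dominant
mode of compositional variability — is analysed downstream, but all
components are returned.

Sign convention: each eigenvector is oriented so that its largest-|loading|
entry is positive.  This is deterministic and record-local; the Haar
analysis is sign-invariant, so it only affects reporting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, InsufficientDataError
from .records import AssemblageMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, >= 0
    loadings: np.ndarray           # (k, p), unit-norm rows
    scores: np.ndarray             # (n, k)
    explained_fraction: np.ndarray
    taxa: list[str]
    times: np.ndarray


@dataclass
class ScoreSeries:
    """A univariate score time series (PC1 or a biome difference axis)."""

    times: np.ndarray
    values: np.ndarray
    source: str = "PC1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")


def pca_pc1(sqrt_assemblage: AssemblageMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the column-centred sqrt-proportion matrix (covariance scaling).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 samples.
    DegenerateInputError
        Constant assemblage (zero total variance) or fewer than 2 taxa with
        non-zero variance.
    """
    if sqrt_assemblage.transform_state != "sqrt_proportion":
        raise DegenerateInputError(
            "pca_pc1 expects a sqrt-proportion assemblage; apply sqrt_transform first"
        )
    X = sqrt_assemblage.values
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError(f"need >= 3 samples, got {n}")
    col_var = X.var(axis=0, ddof=1)
    if np.count_nonzero(col_var > 0) < 2:
        raise DegenerateInputError(
            "need at least 2 taxa with non-zero variance (constant assemblage?)"
        )
    k = min(n - 1, p) if n_components is None else min(n_components, n - 1, p)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    eigenvalues = model.explained_variance_

    # orient: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]

    return PCAResult(
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        explained_fraction=model.explained_variance_ratio_,
        taxa=list(sqrt_assemblage.taxa),
        times=sqrt_assemblage.times.copy(),
    )


def pc1_series(pca_result: PCAResult) -> ScoreSeries:
    return ScoreSeries(
        times=pca_result.times, values=pca_result.scores[:, 0], source="PC1"
    )


def best_correlated_taxon(
    pca_result: PCAResult, sqrt_assemblage: AssemblageMatrix
) -> tuple[str, float]:
    """Taxon whose sqrt-proportion column best tracks the PC1 scores.

    Returns the taxon name and its squared Pearson correlation with the PC1
    score series.  Zero-variance columns are skipped; exact ties resolve to
    the first column in taxon order (logged).
    """
    X = sqrt_assemblage.values
    pc1 = pca_result.scores[:, 0]
    r2 = np.full(X.shape[1], -np.inf)
    pc1c = pc1 - pc1.mean()
    denom_s = float(pc1c @ pc1c)
    for j in range(X.shape[1]):
        col = X[:, j] - X[:, j].mean()
        denom_c = float(col @ col)
        if denom_c <= 0 or denom_s <= 0:
            continue
        r2[j] = (float(col @ pc1c) ** 2) / (denom_c * denom_s)
    if not np.isfinite(r2).any():
        raise DegenerateInputError("no taxon column with non-zero variance")
    best = int(np.argmax(r2))
    ties = np.flatnonzero(np.isclose(r2, r2[best], rtol=0, atol=1e-12))
    if ties.size > 1:
        logger.info(
            "best_correlated_taxon: tie among %s, keeping first",
            [sqrt_assemblage.taxa[t] for t in ties],
        )
    return sqrt_assemblage.taxa[best], float(r2[best])
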