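"""PCA composite baseline: eigendecomposition of the sample covariance.

Because the battery is standardized before fitting, this is
correlation-matrix PCA.  The first principal component score is the
linear composite; its variance fraction (eigenvalue / trace) is the
linear analogue of the autoencoder's explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import StandardizedMatrix
from .errors import InsufficientDataError

__all__ = ["PCAResult", "fit_pca", "pca_composite", "stability_check"]


@dataclass
class PCAResult:
    """Loadings (measures x components, orthonormal), variance fractions
    for all measures (sorted, non-negative, summing to 1), and component
    scores of the fitted records."""

    loadings: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray
    n_components: int
    mean: np.ndarray
    eigenvalues: np.ndarray


def _as_matrix(data) -> np.ndarray:
    x = data.matrix if isinstance(data, StandardizedMatrix) else np.asarray(data)
    return np.asarray(x, dtype=float)


def fit_pca(
    data: StandardizedMatrix | np.ndarray,
    n_components: int = 2,
    directions: np.ndarray | None = None,
) -> PCAResult:
    """Principal components of the sample covariance (n-1 denominator).

    Components are eigenvectors ordered by decreasing eigenvalue; the
    variance fraction of a component is its eigenvalue over the trace.
    Each loading column's sign is fixed so its inner product with the
    direction-of-improvement vector ``d`` is non-negative (measures that
    should rise with health then load positively on an aligned PC1);
    without ``directions``, the largest-magnitude coordinate is made
    positive.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError("covariance undefined for n < 2 records")
    if not 1 <= n_components <= k:
        raise InsufficientDataError(
            f"n_components must be in [1, {k}], got {n_components}"
        )
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(k):
        if directions is not None:
            ref = float(np.asarray(directions, dtype=float) @ eigvecs[:, j])
        else:
            ref = eigvecs[np.argmax(np.abs(eigvecs[:, j])), j]
        if ref < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    loadings = eigvecs[:, :n_components]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(
        loadings=loadings,
        variance_fractions=fractions,
        scores=xc @ loadings,
        n_components=n_components,
        mean=mean,
        eigenvalues=eigvals,
    )


def pca_composite(result: PCAResult) -> np.ndarray:
    """PC1 scores — the linear composite, one per record (mean 0)."""
    return result.scores[:, 0]


def stability_check(
    data: StandardizedMatrix | np.ndarray,
    directions: np.ndarray | None = None,
    gap_tol: float = 1e-8,
) -> tuple[bool, dict]:
    """Check that PC1 is invariant to how many components are extracted.

    Fits with 1 and with 2 components and compares the PC1 loading
    vectors up to sign.  When the top two eigenvalues are (numerically)
    tied the component pair is rotationally degenerate, so the report
    flags instability instead of asserting loading equality.
    """
    x = _as_matrix(data)
    if x.shape[0] < 3:
        raise InsufficientDataError("stability check needs >= 3 records")
    one = fit_pca(x, n_components=1, directions=directions)
    two = fit_pca(x, n_components=2, directions=directions)
    l1 = one.loadings[:, 0]
    l2 = two.loadings[:, 0]
    if float(l1 @ l2) < 0:
        l2 = -l2
    discrepancy = float(np.max(np.abs(l1 - l2)))
    gap = float(one.eigenvalues[0] - one.eigenvalues[1])
    rel_gap = gap / max(float(one.eigenvalues[0]), np.finfo(float).tiny)
    degenerate = rel_gap < gap_tol
    stable = degenerate is False and discrepancy < 1e-8
    return stable, {
        "max_loading_discrepancy": discrepancy,
        "eigenvalue_gap": gap,
        "relative_gap": rel_gap,
        "degenerate_top_pair": degenerate,
    }
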