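"""Sample-level quality control: replicate correlation and PCA.

Replicates of the same stage should correlate strongly and the stages
should separate along the leading principal components.  Peak areas span
orders of magnitude, so both checks default to a log2(x+1) transform.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix

__all__ = ["QcReport", "sample_correlation_matrix", "pca_variance"]


@dataclasses.dataclass
class QcReport:
    """PCA summary: per-component variance fractions and sample scores."""

    pc_variance_fractions: np.ndarray
    pc_scores: pd.DataFrame  # samples x components


def _transformed(data: AbundanceMatrix, transform: str) -> np.ndarray:
    arr = data.values.to_numpy(dtype=float)
    if transform == "log":
        return np.log2(arr + 1.0)
    if transform == "none":
        return arr
    raise ValueError(f"unknown transform {transform!r}")


def sample_correlation_matrix(data: AbundanceMatrix, transform: str = "log") -> pd.DataFrame:
    """Pairwise Pearson r between sample columns across features.

    Entries involving a constant sample column are NaN (flagged undefined,
    never silently zero); the diagonal is exactly 1.
    """
    arr = _transformed(data, transform)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 features for sample correlation")
    sd = arr.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(arr.T)
    corr = np.asarray(corr, dtype=float)
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    cols = data.values.columns
    return pd.DataFrame(corr, index=cols, columns=cols)


def pca_variance(
    data: AbundanceMatrix,
    transform: str = "log",
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> QcReport:
    """Principal component analysis of the samples-by-features matrix.

    Variance fraction of component k is sigma_k^2 / sum(sigma^2) from the
    SVD of the centred (optionally unit-variance scaled) matrix; fractions
    over all components sum to 1.
    """
    if data.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = _transformed(data, transform).T  # samples x features
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    fractions = (s**2) / total if total > 0 else np.zeros_like(s)
    scores = U * s
    k = len(s) if n_components is None else min(n_components, len(s))
    score_frame = pd.DataFrame(
        scores[:, :k],
        index=data.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return QcReport(pc_variance_fractions=fractions, pc_scores=score_frame)
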