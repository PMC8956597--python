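"""PCA quality control of the normalized quantitative matrix.

Samples are observations, phosphosites are variables; features are centered
but not scaled to unit variance. Used to check that biological grouping
(tissue, HER2 status, treatment) rather than TMT batch dominates the
corrected data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .normalize import QuantMatrix

__all__ = ["PCAResult", "pca"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # sample × component
    loadings: pd.DataFrame  # feature × component
    explained_variance_ratio: np.ndarray

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.scores.to_csv(prefix.with_suffix(".scores.tsv"), sep="\t", float_format="%.8g")
        self.loadings.to_csv(prefix.with_suffix(".loadings.tsv"), sep="\t", float_format="%.8g")
        pd.Series(self.explained_variance_ratio, name="explained_variance_ratio").to_csv(
            prefix.with_suffix(".variance.tsv"), sep="\t", index_label="component"
        )


def pca(matrix: QuantMatrix, samples: list[str] | None = None, n_components: int = 2) -> PCAResult:
    """PCA of selected samples (centered, unscaled features).

    Features with any missing value over the selected samples are dropped
    (complete-case) so the decomposition is well defined on partially
    normalized matrices. Loading signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    cols = samples if samples is not None else list(matrix.data.columns)
    if len(cols) < 2:
        raise ValueError("PCA needs at least 2 samples")
    sub = matrix.data[cols].dropna(axis=0, how="any")
    X = sub.to_numpy(float).T  # samples × features
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(n_samples-1, n_features)={max_comp}")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # feature × component
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=cols, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=sub.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
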