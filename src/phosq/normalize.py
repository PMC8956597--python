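"""Normalization of TMT reporter intensities to a batch-corrected log2 matrix.

Two routes mirror the two kinds of comparison downstream:

* group route: log2 → subtract the within-batch mean of the pooled cell-line
  reference channels → median-center each channel → keep features quantified
  in every batch → impute each feature's minimum → empirical-Bayes
  location/scale batch correction (ComBat);
* individual route: log2 → median-center each clinical channel, nothing else.

The reference channels bridge batches: subtracting them within batch cancels
batch-specific labeling/loading efficiency before the residual batch effect
is removed model-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_sitetable import DesignError, SiteRecord, StudyDesign

__all__ = [
    "QuantMatrix",
    "BatchModel",
    "STAGES",
    "records_to_matrix",
    "log2_transform",
    "reference_subtract",
    "median_center",
    "batch_presence_filter",
    "impute_min",
    "combat_correct",
    "normalize_for_individual",
    "group_route",
]

STAGES = ("raw", "raw_log2", "ref_subtracted", "median_centered", "imputed", "batch_corrected")


@dataclass
class QuantMatrix:
    """A feature × sample quantitative matrix on log2 scale.

    ``data`` rows are site keys "GENE_R###" (or protein ids), columns are
    sample ids; NaN marks a missing (unquantified) value. ``stage`` records
    the processing stage and may only advance along :data:`STAGES`.
    """

    data: pd.DataFrame
    stage: str
    sample_batches: pd.Series  # sample_id -> batch_id for the current columns

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [s for s in self.data.columns if s not in self.sample_batches.index]
        if missing:
            raise ValueError(f"samples without batch assignment: {missing}")
        vals = self.data.to_numpy(float)
        if np.isinf(vals).any():
            raise ValueError("non-finite present values in matrix")

    def _advance(self, data: pd.DataFrame, stage: str, samples: pd.Series | None = None) -> "QuantMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not go back from {self.stage!r} to {stage!r}")
        return QuantMatrix(data, stage, self.sample_batches if samples is None else samples)

    def write(self, path: str | Path, design_hash: str | None = None) -> None:
        """TSV of the matrix plus a JSON sidecar with stage metadata."""
        path = Path(path)
        out = self.data.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        sidecar = {
            "stage": self.stage,
            "n_features": int(self.data.shape[0]),
            "n_samples": int(self.data.shape[1]),
        }
        if design_hash is not None:
            sidecar["design_hash"] = design_hash
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch-effect model.

    Per batch: the moment-matched priors (normal for the additive effect
    gamma, inverse-gamma for the squared scale effect delta^2) and the
    posterior estimates gamma_star / delta_star per feature. Per feature: the
    grand mean and pooled variance used for standardization.
    """

    batches: list[str]
    features: list[str]
    grand_mean: np.ndarray
    pooled_var: np.ndarray
    gamma_hat: dict[str, np.ndarray] = field(default_factory=dict)
    delta2_hat: dict[str, np.ndarray] = field(default_factory=dict)
    gamma_star: dict[str, np.ndarray] = field(default_factory=dict)
    delta2_star: dict[str, np.ndarray] = field(default_factory=dict)
    priors: dict[str, dict[str, float]] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        obj = {
            "batches": self.batches,
            "features": self.features,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "priors": self.priors,
            "gamma_star": {b: v.tolist() for b, v in self.gamma_star.items()},
            "delta2_star": {b: v.tolist() for b, v in self.delta2_star.items()},
        }
        Path(path).write_text(json.dumps(obj) + "\n")


def records_to_matrix(records: list[SiteRecord], design: StudyDesign) -> QuantMatrix:
    """Assemble raw (linear-scale) intensities into a feature × sample matrix.

    Feature ids are "GENE_R<pos>" site keys; all design channels (clinical
    and reference) become columns keyed by sample_id.
    """
    key_to_sample = design.table.set_index(["batch_id", "channel_id"])["sample_id"]
    sample_order = design.table["sample_id"].tolist()
    rows, index = [], []
    for r in records:
        g, res, pos = r.site_key
        index.append(f"{g}_{res}{pos}")
        row = dict.fromkeys(sample_order, np.nan)
        for k, v in r.intensities.items():
            if k in key_to_sample.index:
                row[key_to_sample.loc[k]] = v
        rows.append(row)
    data = pd.DataFrame(rows, index=index, columns=sample_order, dtype=float)
    batches = design.table.set_index("sample_id")["batch_id"]
    return QuantMatrix(data, "raw", batches)


def log2_transform(matrix: QuantMatrix) -> QuantMatrix:
    """Elementwise log2 of the reporter intensities; missing stays missing."""
    vals = matrix.data.to_numpy(float)
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValueError("non-positive intensity: log2 undefined")
    return matrix._advance(np.log2(matrix.data), "raw_log2")


def reference_subtract(matrix: QuantMatrix, design: StudyDesign) -> QuantMatrix:
    """Subtract the within-batch mean of the reference channels per feature.

    Output contains clinical samples only. Where no reference value was
    observed for a feature in a batch, that batch's clinical values become
    missing (the ratio to the reference is undefined).
    """
    if matrix.stage != "raw_log2":
        raise ValueError(f"reference_subtract expects stage raw_log2, got {matrix.stage!r}")
    meta = design.sample_meta()
    out = {}
    for b in design.batches:
        refs = meta.index[(meta["batch_id"] == b) & meta["is_reference"]].tolist()
        refs = [s for s in refs if s in matrix.data.columns]
        if not refs:
            raise DesignError(f"batch {b!r} has no reference channel in the matrix")
        ref_mean = matrix.data[refs].mean(axis=1)  # NaN where no ref observed
        clin = meta.index[(meta["batch_id"] == b) & ~meta["is_reference"]].tolist()
        for s in clin:
            if s in matrix.data.columns:
                out[s] = matrix.data[s] - ref_mean
    clinical_order = [s for s in matrix.data.columns if s in out]
    data = pd.DataFrame(out)[clinical_order]
    batches = matrix.sample_batches.loc[clinical_order]
    return matrix._advance(data, "ref_subtracted", batches)


def median_center(matrix: QuantMatrix) -> QuantMatrix:
    """Subtract each sample column's median of observed values."""
    data = matrix.data.copy()
    for s in data.columns:
        col = data[s]
        if col.notna().sum() == 0:
            warnings.warn(f"sample {s!r} has no observed values; left unchanged")
            continue
        data[s] = col - col.median()
    return matrix._advance(data, "median_centered")


def batch_presence_filter(matrix: QuantMatrix, design: StudyDesign | None = None) -> QuantMatrix:
    """Keep features observed in at least one sample of every batch."""
    batches = matrix.sample_batches.loc[matrix.data.columns]
    keep = pd.Series(True, index=matrix.data.index)
    for _, cols in batches.groupby(batches).groups.items():
        keep &= matrix.data[list(cols)].notna().any(axis=1)
    return matrix._advance(matrix.data.loc[keep], matrix.stage)


def impute_min(matrix: QuantMatrix, per_sample: bool = False) -> QuantMatrix:
    """Replace each missing cell with the feature's minimum observed value.

    ``per_sample=True`` switches to the per-sample (column) minimum instead,
    an alternative left-censoring surrogate.
    """
    data = matrix.data.copy()
    if per_sample:
        data = data.apply(lambda col: col.fillna(col.min()))
    else:
        if data.isna().all(axis=1).any():
            raise RuntimeError("fully missing feature at imputation stage (presence filter violated)")
        row_min = data.min(axis=1)
        data = data.T.fillna(row_min).T
    return matrix._advance(data, "imputed")


def _moment_match_inverse_gamma(d2: np.ndarray) -> tuple[float, float]:
    """Method-of-moments inverse-gamma (shape, scale) for the delta^2 prior."""
    m = float(np.mean(d2))
    s2 = float(np.var(d2, ddof=1))
    a = (2.0 * s2 + m * m) / s2
    b = (m * s2 + m**3) / s2
    return a, b


def combat_correct(
    matrix: QuantMatrix,
    design: StudyDesign | None = None,
    parametric: bool = True,
    shrink: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[QuantMatrix, BatchModel]:
    """Parametric empirical-Bayes location/scale batch correction (ComBat).

    Per feature g and batch b the model is x = alpha_g + gamma_bg +
    delta_bg * eps. The data are standardized with the per-feature grand mean
    (batch-size-weighted mean of batch means) and the pooled residual
    variance; per-batch location gamma_hat and scale delta2_hat estimates are
    shrunk toward moment-matched priors (normal for gamma, inverse-gamma for
    delta^2) via iterated conditional posterior means; the adjusted value is
    pooled_sd * (z - gamma*) / delta* + grand mean.

    With ``shrink=False`` the EB step is skipped (gamma* = gamma_hat,
    delta2* = delta2_hat), which reduces to per-batch standardization.
    A single-batch matrix is returned unchanged with an identity model.
    """
    if not parametric:
        raise NotImplementedError("non-parametric priors are not supported")
    data = matrix.data
    if data.isna().any().any():
        raise ValueError("batch correction requires a complete (imputed) matrix")
    batches = matrix.sample_batches.loc[data.columns]
    batch_ids = sorted(batches.unique())
    X = data.to_numpy(float)
    G, N = X.shape

    if len(batch_ids) == 1:
        model = BatchModel(
            batches=batch_ids,
            features=list(data.index),
            grand_mean=X.mean(axis=1),
            pooled_var=np.zeros(G),
            gamma_star={batch_ids[0]: np.zeros(G)},
            delta2_star={batch_ids[0]: np.ones(G)},
        )
        return matrix._advance(data, "batch_corrected"), model

    idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in batch_ids}
    n_b = {b: len(v) for b, v in idx.items()}
    for b, n in n_b.items():
        if n < 2:
            raise ValueError(f"batch {b!r} has {n} sample(s); scale not estimable")

    batch_means = {b: X[:, idx[b]].mean(axis=1) for b in batch_ids}
    grand_mean = sum((n_b[b] / N) * batch_means[b] for b in batch_ids)
    fitted = np.empty_like(X)
    for b in batch_ids:
        fitted[:, idx[b]] = batch_means[b][:, None]
    pooled_var = ((X - fitted) ** 2).mean(axis=1)
    pooled_var = np.maximum(pooled_var, 1e-30)
    pooled_sd = np.sqrt(pooled_var)
    Z = (X - grand_mean[:, None]) / pooled_sd[:, None]

    gamma_hat, delta2_hat = {}, {}
    for b in batch_ids:
        Zb = Z[:, idx[b]]
        gamma_hat[b] = Zb.mean(axis=1)
        delta2_hat[b] = Zb.var(axis=1, ddof=1)

    gamma_star, delta2_star, priors = {}, {}, {}
    for b in batch_ids:
        g_hat, d2_hat = gamma_hat[b], delta2_hat[b]
        if not shrink:
            gamma_star[b] = g_hat.copy()
            # a feature constant within the batch has no estimable scale;
            # leave it unscaled rather than dividing by zero
            delta2_star[b] = np.where(d2_hat > 0, d2_hat, 1.0)
            continue
        gbar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        a_pr, b_pr = _moment_match_inverse_gamma(d2_hat)
        priors[b] = {"gamma_bar": gbar, "tau2": t2, "a_prior": a_pr, "b_prior": b_pr}
        n = n_b[b]
        Zb = Z[:, idx[b]]
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        for _ in range(max_iter):
            g_new = (n * t2 * g_hat + d2_star * gbar) / (n * t2 + d2_star)
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (b_pr + 0.5 * sse) / (n / 2.0 + a_pr - 1.0)
            change = max(
                np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
                np.max(np.abs(d2_new - d2_star) / np.maximum(d2_star, 1e-12)),
            )
            g_star, d2_star = g_new, d2_new
            if change < tol:
                break
        else:
            raise RuntimeError(f"EB conditional updates did not converge for batch {b!r} within {max_iter} iterations")
        gamma_star[b] = g_star
        delta2_star[b] = d2_star

    Xadj = np.empty_like(X)
    for b in batch_ids:
        j = idx[b]
        Xadj[:, j] = (Z[:, j] - gamma_star[b][:, None]) / np.sqrt(delta2_star[b])[:, None]
        Xadj[:, j] = Xadj[:, j] * pooled_sd[:, None] + grand_mean[:, None]

    model = BatchModel(
        batches=batch_ids,
        features=list(data.index),
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        priors=priors,
    )
    out = pd.DataFrame(Xadj, index=data.index, columns=data.columns)
    return matrix._advance(out, "batch_corrected"), model


def normalize_for_individual(matrix: QuantMatrix, design: StudyDesign) -> QuantMatrix:
    """Individual-comparison route: median-center clinical channels only.

    No reference subtraction, imputation or batch correction: single-patient
    fold changes are taken within one batch, where those steps cancel or do
    not apply.
    """
    if matrix.stage != "raw_log2":
        raise ValueError(f"normalize_for_individual expects stage raw_log2, got {matrix.stage!r}")
    clinical = [s for s in matrix.data.columns if not design.sample_meta().loc[s, "is_reference"]]
    sub = QuantMatrix(matrix.data[clinical], matrix.stage, matrix.sample_batches.loc[clinical])
    return median_center(sub)


def group_route(
    matrix: QuantMatrix, design: StudyDesign, shrink: bool = True
) -> tuple[QuantMatrix, BatchModel, dict[str, int]]:
    """Full group-comparison normalization with per-stage feature counts."""
    counts = {"raw": matrix.data.shape[0]}
    m = log2_transform(matrix) if matrix.stage == "raw" else matrix
    m = reference_subtract(m, design)
    m = median_center(m)
    m = batch_presence_filter(m, design)
    counts["presence_filtered"] = m.data.shape[0]
    m = impute_min(m)
    m, model = combat_correct(m, design, shrink=shrink)
    counts["batch_corrected"] = m.data.shape[0]
    return m, model, counts
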