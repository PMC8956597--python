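"""Per-phosphosite contrasts and pathway node overlays.

Group contrasts use a two-sided Welch t-test (unpaired, unequal variances,
Satterthwaite degrees of freedom) or a paired t-test on per-patient
differences. Sites are classed by the joint fold-change / p-value rule:
|log2FC| > 1 with p < 0.05 is significant, with 0.05 <= p < 0.1 a tendency.
Individual (single-patient) comparisons are fold-change-only, |log2FC| > 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_sitetable import DesignError, StudyDesign
from .normalize import QuantMatrix

__all__ = [
    "ComparisonResult",
    "group_compare",
    "classify_sites",
    "individual_compare",
    "pathway_overlay",
    "select_samples",
]

CLASSES = ("significant_up", "significant_down", "tendency_up", "tendency_down", "ns", "not_testable")


@dataclass
class ComparisonResult:
    """Per-site statistics for one named contrast (A vs B, FC = mean A − mean B)."""

    contrast: str
    table: pd.DataFrame  # index: site key; columns: log2FC, t, df, p, class

    def counts(self) -> dict[str, int]:
        c = self.table["class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in CLASSES}

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "site", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def select_samples(
    design: StudyDesign,
    tissue: str | None = None,
    her2: str | None = None,
    timepoint: str | None = None,
) -> list[str]:
    """Sample ids of clinical channels matching the given metadata filters."""
    t = design.clinical()
    m = pd.Series(True, index=t.index)
    if tissue is not None:
        m &= t["tissue"] == tissue
    if her2 is not None:
        m &= t["her2"] == her2
    if timepoint is not None:
        m &= t["timepoint"] == timepoint
    return t.loc[m, "sample_id"].tolist()


def group_compare(
    matrix: QuantMatrix,
    design: StudyDesign,
    group_a: list[str],
    group_b: list[str],
    mode: str = "welch",
    contrast: str = "A_vs_B",
    fc_cut: float = 1.0,
    p_sig: float = 0.05,
    p_tend: float = 0.1,
) -> ComparisonResult:
    """Per-site group contrast: log2FC = mean(A) − mean(B), two-sided t-test.

    ``mode='welch'`` is the unpaired unequal-variance test; ``mode='paired'``
    pairs samples by patient_id and tests the per-patient differences.
    """
    if mode not in ("welch", "paired"):
        raise ValueError(f"mode must be 'welch' or 'paired', got {mode!r}")
    A = matrix.data[group_a].to_numpy(float)
    B_cols = group_b
    if mode == "paired":
        meta = design.sample_meta()
        pat_a = {meta.loc[s, "patient_id"]: s for s in group_a}
        pat_b = {meta.loc[s, "patient_id"]: s for s in group_b}
        unpaired = set(pat_a) ^ set(pat_b)
        if unpaired:
            raise DesignError(f"unpairable patients in paired comparison: {sorted(unpaired)}")
        patients = sorted(pat_a)
        if len(patients) < 2:
            raise DesignError("paired test needs at least 2 pairs")
        A = matrix.data[[pat_a[p] for p in patients]].to_numpy(float)
        B_cols = [pat_b[p] for p in patients]
    elif len(group_a) < 2 or len(group_b) < 2:
        raise DesignError("Welch test needs at least 2 samples per group")
    B = matrix.data[B_cols].to_numpy(float)

    fc = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows (imputed to a single value) trip scipy's
        # catastrophic-cancellation warning; they are handled as degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        if mode == "welch":
            t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
            v_a, v_b = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
            n_a = np.sum(~np.isnan(A), axis=1)
            n_b = np.sum(~np.isnan(B), axis=1)
            num = (v_a / n_a + v_b / n_b) ** 2
            den = (v_a / n_a) ** 2 / (n_a - 1) + (v_b / n_b) ** 2 / (n_b - 1)
            df = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        else:
            diff = A - B
            t, p = stats.ttest_rel(A, B, axis=1, nan_policy="omit")
            df = np.sum(~np.isnan(diff), axis=1) - 1.0

    # degenerate zero-variance limit: p=1 when the means coincide, otherwise
    # the test is not computable and the site is flagged not_testable
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    degenerate = ~np.isfinite(t)
    equal_means = degenerate & np.isclose(fc, 0.0)
    t = np.where(equal_means, 0.0, np.where(degenerate, np.nan, t))
    p = np.where(equal_means, 1.0, np.where(degenerate, np.nan, p))

    table = pd.DataFrame(
        {"log2FC": fc, "t": t, "df": df, "p": p},
        index=matrix.data.index,
    )
    result = ComparisonResult(contrast=contrast, table=table)
    return classify_sites(result, fc_cut=fc_cut, p_sig=p_sig, p_tend=p_tend)


def classify_sites(
    result: ComparisonResult,
    fc_cut: float = 1.0,
    p_sig: float = 0.05,
    p_tend: float = 0.1,
    bh_correct: bool = False,
) -> ComparisonResult:
    """Assign significance classes from the joint |FC| / p-value rule.

    Both cuts are strict on the fold change (|FC| > fc_cut, not >=) and the
    significant band is p < p_sig; p in [p_sig, p_tend) is a tendency.
    ``bh_correct`` optionally replaces raw p-values with Benjamini–Hochberg
    adjusted ones before classing (off by default).
    """
    if not (0 < p_sig < p_tend <= 1):
        raise ValueError(f"need 0 < p_sig < p_tend <= 1, got {p_sig}, {p_tend}")
    if fc_cut <= 0:
        raise ValueError(f"fc_cut must be > 0, got {fc_cut}")
    t = result.table
    p = t["p"].to_numpy(float)
    if bh_correct:
        finite = np.isfinite(p)
        p = p.copy()
        p[finite] = multipletests(p[finite], method="fdr_bh")[1]
    fc = t["log2FC"].to_numpy(float)
    cls = np.full(len(t), "ns", dtype=object)
    cls[~np.isfinite(p) | ~np.isfinite(fc)] = "not_testable"
    testable = np.isfinite(p) & np.isfinite(fc)
    big = np.abs(fc) > fc_cut
    sig = testable & big & (p < p_sig)
    tend = testable & big & (p >= p_sig) & (p < p_tend)
    cls[sig & (fc > 0)] = "significant_up"
    cls[sig & (fc < 0)] = "significant_down"
    cls[tend & (fc > 0)] = "tendency_up"
    cls[tend & (fc < 0)] = "tendency_down"
    out = t.copy()
    out["class"] = cls
    return ComparisonResult(contrast=result.contrast, table=out)


def individual_compare(
    matrix: QuantMatrix, sample_a: str, sample_b: str, fc_cut: float = 1.0
) -> pd.DataFrame:
    """Single-patient contrast: per-site FC = value(A) − value(B), |FC| > cut.

    Sites missing in either sample get class ``no_quantitative_value``.
    Expects the individually normalized (median-centered) matrix.
    """
    for s in (sample_a, sample_b):
        if s not in matrix.data.columns:
            raise KeyError(f"unknown sample id {s!r}")
    a = matrix.data[sample_a]
    b = matrix.data[sample_b]
    fc = a - b
    quantified = a.notna() & b.notna()
    flagged = quantified & (fc.abs() > fc_cut)
    cls = np.where(~quantified, "no_quantitative_value", np.where(flagged, "differential", "ns"))
    return pd.DataFrame({"log2FC": fc.where(quantified), "class": cls}, index=matrix.data.index)


_STATE_RANK = {"significant": 3, "tendency": 2, "quantified_only": 1, "not_quantified": 0}


def pathway_overlay(
    table: pd.DataFrame | ComparisonResult, pathway_genes: list[str], pathway_id: str = "pathway"
) -> pd.DataFrame:
    """Summarize per-site classes into per-node (gene) pathway states.

    A node takes the strongest state among its quantified sites
    (significant > tendency > quantified_only); genes without any quantified
    site are reported not_quantified. Site keys are "GENE_R<pos>" strings.
    """
    t = table.table if isinstance(table, ComparisonResult) else table
    genes = t.index.str.rsplit("_", n=1).str[0].to_numpy()
    rows = []
    for node in pathway_genes:
        sites = t[genes == node]
        if isinstance(table, ComparisonResult):
            quant = sites[sites["class"] != "not_testable"]
        else:
            quant = sites[sites["class"] != "no_quantitative_value"]
        if len(quant) == 0:
            state = "not_quantified"
            contributing = []
        else:
            labels = quant["class"].astype(str)
            if labels.str.startswith("significant").any() or (labels == "differential").any():
                state = "significant"
            elif labels.str.startswith("tendency").any():
                state = "tendency"
            else:
                state = "quantified_only"
            contributing = [
                f"{site}:{fc:.3g}" for site, fc in zip(quant.index, quant["log2FC"]) if np.isfinite(fc)
            ]
        rows.append(
            {
                "pathway_id": pathway_id,
                "gene": node,
                "state": state,
                "sites": ";".join(contributing),
            }
        )
    return pd.DataFrame(rows, columns=["pathway_id", "gene", "state", "sites"])
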