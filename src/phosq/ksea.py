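"""Kinase-substrate enrichment analysis (KSEA).

A kinase's activity change between two conditions is inferred from the log2
fold changes of its annotated substrate phosphosites: with mean_all and
sd_all the mean and standard deviation of all quantified site fold changes
(the background) and mean_sub the mean over the kinase's m matched substrate
sites,

    z = (mean_sub - mean_all) * sqrt(m) / sd_all

with a two-sided normal p-value. Kinases with fewer than two quantified
substrate sites in a comparison are not scored.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .differential import group_compare, select_samples
from .io_sitetable import StudyDesign
from .normalize import QuantMatrix

__all__ = ["KSNetwork", "read_ks_network", "ksea_scores", "ksea_profile"]

_SITE_TOKEN = re.compile(r"^([STY])(\d+)$")


@dataclass
class KSNetwork:
    """Deduplicated kinase -> substrate-site edges.

    ``edges`` columns: kinase, substrate_gene, residue, position. A substrate
    site may be annotated to several kinases; autophosphorylation edges
    (kinase == substrate gene) are retained.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.edges = self.edges.drop_duplicates().reset_index(drop=True)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.edges["kinase"].unique())

    def substrate_map(self) -> dict[str, set[str]]:
        """kinase -> set of substrate site keys ("GENE_R<pos>")."""
        keys = self.edges["substrate_gene"] + "_" + self.edges["residue"] + self.edges["position"].astype(str)
        out: dict[str, set[str]] = {}
        for kinase, key in zip(self.edges["kinase"], keys):
            out.setdefault(kinase, set()).add(key)
        return out

    def substrate_keys(self, kinase: str) -> set[str]:
        e = self.edges[self.edges["kinase"] == kinase]
        return {f"{g}_{r}{p}" for g, r, p in zip(e["substrate_gene"], e["residue"], e["position"])}

    def write(self, path: str | Path) -> None:
        out = self.edges.copy()
        out["site"] = out["residue"] + out["position"].astype(str)
        out[["kinase", "substrate_gene", "site"]].to_csv(path, sep="\t", index=False)


def read_ks_network(
    path: str | Path,
    kinase_col: str = "kinase",
    substrate_col: str = "substrate_gene",
    site_col: str = "site",
) -> KSNetwork:
    """Read a kinase-substrate TSV with a combined site token column ("S473")."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (kinase_col, substrate_col, site_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    residues, positions = [], []
    for i, tok in enumerate(df[site_col], start=2):  # line 1 is the header
        m = _SITE_TOKEN.match(str(tok).strip())
        if not m:
            raise ValueError(f"{path}:{i}: malformed site token {tok!r} (expected e.g. 'S473')")
        residues.append(m.group(1))
        positions.append(int(m.group(2)))
    edges = pd.DataFrame(
        {
            "kinase": df[kinase_col].str.upper(),
            "substrate_gene": df[substrate_col].str.upper(),
            "residue": residues,
            "position": positions,
        }
    )
    return KSNetwork(edges)


def ksea_scores(
    fc: pd.Series,
    network: KSNetwork,
    min_substrates: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every kinase with >= min_substrates quantified substrate sites.

    ``fc`` maps site keys ("GENE_R<pos>") to log2 fold changes for one
    comparison; NaN entries are dropped. Returns one row per scored kinase:
    m, mean_sub, mean_all, sd_all, z, p, significant, substrate sites.
    """
    fc = fc.dropna()
    if len(fc) < 2:
        raise ValueError("need at least 2 finite fold-change entries")
    values = fc.to_numpy(float)
    mean_all = float(values.mean())
    sd_all = float(values.std(ddof=1))
    if sd_all == 0:
        raise ValueError("degenerate background: all fold changes identical")
    site_index = set(fc.index)
    substrate_map = network.substrate_map()
    rows = []
    for kinase in network.kinases:
        subs = sorted(substrate_map[kinase] & site_index)
        m = len(subs)
        if m < min_substrates:
            continue
        mean_sub = float(fc.loc[subs].mean())
        z = (mean_sub - mean_all) * np.sqrt(m) / sd_all
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "kinase": kinase,
                "m": m,
                "mean_sub": mean_sub,
                "mean_all": mean_all,
                "sd_all": sd_all,
                "z": z,
                "p": p,
                "significant": p < alpha,
                "substrates": ";".join(subs),
            }
        )
    cols = ["kinase", "m", "mean_sub", "mean_all", "sd_all", "z", "p", "significant", "substrates"]
    if not rows:
        warnings.warn("no kinase has enough quantified substrates; empty score table")
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values("p", kind="mergesort").reset_index(drop=True)


def _individual_fc(matrix: QuantMatrix, sample_a: str, sample_b: str) -> pd.Series:
    a, b = matrix.data[sample_a], matrix.data[sample_b]
    return (a - b).where(a.notna() & b.notna())


def ksea_profile(
    matrix: QuantMatrix,
    design: StudyDesign,
    comparisons: list[dict],
    network: KSNetwork,
    min_substrates: int = 2,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kinase × comparison activity profile (z-scores + significance mask).

    Each comparison is either individual — {'name', 'sample_a', 'sample_b'},
    per-site FC over co-quantified sites on the individually normalized
    matrix — or group — {'name', 'group_a', 'group_b'} with sample-id lists,
    FC = difference of group means. Kinases unscorable in a comparison
    (fewer than min_substrates quantified substrates) are NaN in the z matrix
    and blank in the mask (the "no information" state).
    """
    z_cols, sig_cols = {}, {}
    for comp in comparisons:
        name = comp["name"]
        if "sample_a" in comp:
            fc = _individual_fc(matrix, comp["sample_a"], comp["sample_b"])
        else:
            a = matrix.data[comp["group_a"]].mean(axis=1)
            b = matrix.data[comp["group_b"]].mean(axis=1)
            fc = a - b
        scores = ksea_scores(fc, network, min_substrates=min_substrates, alpha=alpha)
        scores = scores.set_index("kinase")
        z_cols[name] = scores["z"]
        sig_cols[name] = scores["significant"]
    kinases = sorted(network.kinases)
    z = pd.DataFrame(z_cols).reindex(kinases)
    sig = pd.DataFrame(sig_cols).reindex(kinases)
    # keep only kinases scored in at least one comparison
    scored = z.notna().any(axis=1)
    return z[scored], sig[scored]
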