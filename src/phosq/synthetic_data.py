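"""Ground-truthed synthetic multi-batch TMT phosphoproteomics datasets.

Emulates the study layout this pipeline targets: four TMT 10-plex batches,
each carrying six clinical channels and two pooled cell-line reference
channels; 24 clinical samples — four HER2-positive patients sampled pre- and
post-treatment in tumor (T) and adjacent tissue (NAT), four HER2-negative
patients in T and NAT. On the log2 scale each value is

    base_f + biological effects + gamma_{b,f} + delta_{b,f} * eps

with per-(batch, feature) additive (gamma) and multiplicative (delta) batch
effects; reference channels carry only base + batch effect + noise.
Biological effects are concentrated on the substrate sites of designated
"active" kinases (tumor-vs-NAT, HER2-status and treatment contrasts) plus a
set of extra differential sites per contrast. Missingness is
missing-not-at-random: low-abundance log2 values are left-censored through a
logistic censoring curve, and censored reporter intensities are written as 0.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_sitetable import StudyDesign, write_design
from .ksea import KSNetwork

__all__ = ["SimConfig", "SyntheticDataset", "generate", "batch_r2", "truth_report"]

TMT_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the emulated design: 4 batches of a TMT 10-plex with
    6 clinical + 2 reference channels, 3,000 phosphosites, additive batch
    effects of sd 1 and multiplicative effects in [0.7, 1.4], reporter noise
    sd 0.5 on the log2 scale, kinase activity shifts of 1 log2 unit on 6
    active kinases per contrast, and 150 extra differential sites per group
    contrast with |effect| 2.
    """

    n_features: int = 3000
    n_batches: int = 4
    channels_per_batch: int = 10
    n_reference_per_batch: int = 2
    clinical_per_batch: int = 6
    base_mean: float = 23.0
    base_sd: float = 2.0
    batch_tau: float = 1.0
    delta_range: tuple[float, float] = (0.7, 1.4)
    noise_sd: float = 0.5
    group_effect_size: float = 2.0
    n_diff_sites: int = 150
    n_kinases: int = 60
    n_active_kinases: int = 6
    activity_shift: float = 1.0
    substrate_geom_p: float = 0.15
    missing_midpoint: float = 21.0
    missing_slope: float = 0.8
    frac_reverse: float = 0.01
    frac_contaminant: float = 0.01
    frac_class1: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.batch_tau < 0:
            raise ValueError("batch_tau must be >= 0")
        used = self.clinical_per_batch + self.n_reference_per_batch
        if used > self.channels_per_batch:
            raise ValueError(
                f"design infeasible: {used} used channels > {self.channels_per_batch} per batch"
            )
        if self.clinical_per_batch * self.n_batches != 24:
            raise ValueError("the emulated layout requires 24 clinical channels in total")


@dataclass
class SyntheticDataset:
    """Paths of the generated files plus the in-memory ground truth."""

    site_table: Path
    protein_table: Path
    design: Path
    network: Path
    gmt: Path
    truth: Path
    truth_data: dict = field(repr=False, default_factory=dict)


def _clinical_samples() -> list[dict]:
    """The 24-sample layout: 4 HER2+ × {pre,post} × {T,NAT}; 4 HER2− × {T,NAT}."""
    rows = []
    for i in range(1, 5):
        for tp in ("pre", "post"):
            for tissue in ("T", "NAT"):
                rows.append(
                    {
                        "sample_id": f"HP{i}_{tp}_{tissue}",
                        "patient_id": f"HP{i}",
                        "tissue": tissue,
                        "her2": "positive",
                        "timepoint": tp,
                    }
                )
    for i in range(1, 5):
        for tissue in ("T", "NAT"):
            rows.append(
                {
                    "sample_id": f"HN{i}_pre_{tissue}",
                    "patient_id": f"HN{i}",
                    "tissue": tissue,
                    "her2": "negative",
                    "timepoint": "pre",
                }
            )
    return rows


def _build_design(config: SimConfig) -> StudyDesign:
    """Assign samples round-robin to batches so groups are not confounded."""
    samples = _clinical_samples()
    batches = [f"B{b + 1}" for b in range(config.n_batches)]
    per_batch_count = {b: 0 for b in batches}
    rows = []
    for i, s in enumerate(samples):
        b = batches[i % config.n_batches]
        ch = TMT_CHANNELS[per_batch_count[b]]
        per_batch_count[b] += 1
        rows.append({"batch_id": b, "channel_id": ch, **s, "is_reference": False})
    for b in batches:
        for j in range(config.n_reference_per_batch):
            ch = TMT_CHANNELS[config.channels_per_batch - 1 - j]
            rows.append(
                {
                    "batch_id": b,
                    "channel_id": ch,
                    "sample_id": f"REF_{b}_{j + 1}",
                    "patient_id": "none",
                    "tissue": "REF",
                    "her2": "none",
                    "timepoint": "none",
                    "is_reference": True,
                }
            )
    return StudyDesign(pd.DataFrame(rows))


def _make_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Feature annotations: genes with 1–5 sites, residues at pS/pT/pY-like rates."""
    n = config.n_features
    genes, positions = [], []
    gi = 0
    while len(genes) < n:
        gi += 1
        gene = f"GENE{gi:04d}"
        k = int(rng.integers(1, 6))
        pos = sorted(rng.choice(np.arange(1, 2000), size=k, replace=False).tolist())
        for p in pos:
            genes.append(gene)
            positions.append(int(p))
    genes, positions = genes[:n], positions[:n]
    residues = rng.choice(["S", "T", "Y"], size=n, p=[0.825, 0.158, 0.017]).tolist()
    is_class1 = rng.random(n) < config.frac_class1
    loc_prob = np.where(
        is_class1, rng.uniform(0.7501, 1.0, size=n), rng.uniform(0.0, 0.75, size=n)
    )
    is_reverse = rng.random(n) < config.frac_reverse
    is_contaminant = rng.random(n) < config.frac_contaminant
    return pd.DataFrame(
        {
            "site_id": [f"site{i + 1:05d}" for i in range(n)],
            "protein": [f"P{g[4:]}" for g in genes],
            "gene": genes,
            "residue": residues,
            "position": positions,
            "localization_prob": np.round(loc_prob, 6),
            "is_reverse": is_reverse,
            "is_contaminant": is_contaminant,
        }
    )


def _make_network(
    config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> KSNetwork:
    """Kinase-substrate edges with shifted-geometric substrate counts (min 1).

    Roughly 20% of edges point at sites outside the measured feature set, as
    a curated database would.
    """
    usable = sites[~(sites["is_reverse"] | sites["is_contaminant"])].reset_index(drop=True)
    rows = []
    for k in range(1, config.n_kinases + 1):
        kinase = f"KINASE{k:02d}"
        m = min(int(rng.geometric(config.substrate_geom_p)), 30)  # shifted geometric, min 1
        picks = rng.choice(len(usable), size=m, replace=False)
        for i in picks:
            row = usable.iloc[int(i)]
            rows.append(
                {
                    "kinase": kinase,
                    "substrate_gene": row["gene"],
                    "residue": row["residue"],
                    "position": int(row["position"]),
                }
            )
        for _ in range(max(1, m // 5)):
            rows.append(
                {
                    "kinase": kinase,
                    "substrate_gene": f"OFFGENE{int(rng.integers(1, 500)):03d}",
                    "residue": str(rng.choice(["S", "T", "Y"])),
                    "position": int(rng.integers(1, 1500)),
                }
            )
    return KSNetwork(pd.DataFrame(rows))


def _site_keys(sites: pd.DataFrame) -> pd.Series:
    return sites["gene"] + "_" + sites["residue"] + sites["position"].astype(str)


def generate(config: SimConfig, outdir: str | Path) -> SyntheticDataset:
    """Write site/protein/design/network files plus the ground truth.

    Deterministic given ``config.seed``: every draw comes from one seeded
    generator and files are written with fixed formatting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    design = _build_design(config)
    sites = _make_sites(config, rng)
    network = _make_network(config, sites, rng)
    keys = _site_keys(sites)
    key_to_idx = {k: i for i, k in enumerate(keys)}
    n = config.n_features

    # active kinases per contrast: disjoint draws among kinases with >= 2
    # measured substrates, each with a random activity direction
    counts = {
        k: len(network.substrate_keys(k) & set(keys)) for k in network.kinases
    }
    eligible = [k for k in network.kinases if counts[k] >= 2]
    rng.shuffle(eligible)
    na = config.n_active_kinases
    active = {
        "tumor": eligible[:na],
        "her2": eligible[na : 2 * na],
        "treatment": eligible[2 * na : 3 * na],
    }
    directions = {
        contrast: {k: int(rng.choice([-1, 1])) for k in kin} for contrast, kin in active.items()
    }

    effects = {c: np.zeros(n) for c in active}
    for contrast, kin in active.items():
        for k in kin:
            for key in network.substrate_keys(k) & set(keys):
                effects[contrast][key_to_idx[key]] += directions[contrast][k] * config.activity_shift
    # extra differential sites per group contrast, ±group_effect_size
    diff_sites = {}
    free = np.flatnonzero(sum(np.abs(e) for e in effects.values()) == 0)
    for contrast in ("her2", "treatment"):
        picks = rng.choice(free, size=min(config.n_diff_sites, len(free)), replace=False)
        free = np.setdiff1d(free, picks)
        signs = rng.choice([-1.0, 1.0], size=len(picks))
        effects[contrast][picks] += signs * config.group_effect_size
        diff_sites[contrast] = {keys.iloc[int(i)]: float(s * config.group_effect_size) for i, s in zip(picks, signs)}

    base = rng.normal(config.base_mean, config.base_sd, size=n)
    batches = design.batches
    gamma = {b: rng.normal(0.0, config.batch_tau, size=n) if config.batch_tau > 0 else np.zeros(n) for b in batches}
    delta = {b: rng.uniform(*config.delta_range, size=n) for b in batches}

    meta = design.table
    values = {}
    for row in meta.to_dict("records"):
        b, sid = row["batch_id"], row["sample_id"]
        v = base + gamma[b] + delta[b] * rng.normal(0.0, config.noise_sd, size=n)
        if not row["is_reference"]:
            if row["tissue"] == "T":
                v = v + effects["tumor"]
                if row["her2"] == "positive":
                    v = v + effects["her2"]
                    if row["timepoint"] == "post":
                        v = v + effects["treatment"]
        values[sid] = v

    # logistic left-censoring on the log2 value (MNAR)
    log2 = pd.DataFrame(values, index=keys)
    p_missing = 1.0 / (1.0 + np.exp(config.missing_slope * (log2.to_numpy() - config.missing_midpoint)))
    censored = rng.random(log2.shape) < p_missing
    intensity = np.where(censored, 0.0, np.exp2(log2.to_numpy()))

    # site table in the reader's dialect
    table = sites.copy()
    table["localization_prob"] = table["localization_prob"].map(repr)
    table["reverse"] = np.where(sites["is_reverse"], "+", "")
    table["contaminant"] = np.where(sites["is_contaminant"], "+", "")
    table = table.drop(columns=["is_reverse", "is_contaminant"])
    sid_to_key = {row["sample_id"]: (row["batch_id"], row["channel_id"]) for row in meta.to_dict("records")}
    for j, sid in enumerate(log2.columns):
        b, ch = sid_to_key[sid]
        table[f"intensity.{b}.{ch}"] = [repr(float(x)) for x in intensity[:, j]]
    site_path = outdir / "sites.tsv"
    table.to_csv(site_path, sep="\t", index=False)

    # small protein-group table exercising the peptide-count and flag filters
    prot_genes = sites["gene"].unique()
    n_prot = len(prot_genes)
    pep = 1 + rng.poisson(4, size=n_prot)
    pep[rng.random(n_prot) < 0.15] = 1  # some one-hit groups to filter
    prot = pd.DataFrame(
        {
            "protein_group_id": [f"PG{i + 1:04d}" for i in range(n_prot)],
            "accessions": [f"P{g[4:]}" for g in prot_genes],
            "peptide_count": pep,
            "reverse": np.where(rng.random(n_prot) < config.frac_reverse, "+", ""),
            "contaminant": np.where(rng.random(n_prot) < config.frac_contaminant, "+", ""),
        }
    )
    prot_base = rng.normal(config.base_mean + 2, config.base_sd, size=n_prot)
    for sid in log2.columns:
        b, ch = sid_to_key[sid]
        v = np.exp2(prot_base + rng.normal(0, config.noise_sd, size=n_prot))
        prot[f"intensity.{b}.{ch}"] = [repr(float(x)) for x in v]
    prot_path = outdir / "proteins.tsv"
    prot.to_csv(prot_path, sep="\t", index=False)

    design_path = outdir / "design.tsv"
    write_design(design, design_path)
    network_path = outdir / "network.tsv"
    network.write(network_path)

    # gene sets: one set per contrast enriched in its differential genes,
    # plus random background sets
    gmt_lines = []
    all_genes = sites["gene"].unique()
    for contrast in ("her2", "treatment"):
        genes = sorted({k.rsplit("_", 1)[0] for k in diff_sites[contrast]})
        picked = [str(g) for g in rng.choice(genes, size=min(30, len(genes)), replace=False)]
        filler = [str(g) for g in rng.choice(all_genes, size=10, replace=False)]
        gmt_lines.append("\t".join([f"SET_{contrast.upper()}", f"{contrast} signature"] + picked + filler))
    for i in range(1, 13):
        members = [str(g) for g in rng.choice(all_genes, size=int(rng.integers(20, 60)), replace=False)]
        gmt_lines.append("\t".join([f"SET_RANDOM{i:02d}", "random set"] + members))
    gmt_path = outdir / "genesets.gmt"
    gmt_path.write_text("\n".join(gmt_lines) + "\n")

    truth = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "base_abundance": {k: round(float(v), 6) for k, v in zip(keys, base)},
        "gamma": {b: [round(float(x), 6) for x in g] for b, g in gamma.items()},
        "delta": {b: [round(float(x), 6) for x in d] for b, d in delta.items()},
        "active_kinases": {c: {k: directions[c][k] for k in kin} for c, kin in active.items()},
        "differential_sites": {
            c: {
                **diff_sites.get(c, {}),
                **{
                    keys.iloc[i]: float(effects[c][i])
                    for i in np.flatnonzero(effects[c])
                    if keys.iloc[i] not in diff_sites.get(c, {})
                },
            }
            for c in effects
        },
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, sort_keys=True) + "\n")

    return SyntheticDataset(
        site_table=site_path,
        protein_table=prot_path,
        design=design_path,
        network=network_path,
        gmt=gmt_path,
        truth=truth_path,
        truth_data=truth,
    )


def batch_r2(data: pd.DataFrame, sample_batches: pd.Series) -> float:
    """Mean per-feature R² of a batch-indicator one-way fit (complete rows)."""
    X = data.dropna(axis=0, how="any")
    batches = sample_batches.loc[X.columns]
    vals = X.to_numpy(float)
    grand = vals.mean(axis=1, keepdims=True)
    sst = ((vals - grand) ** 2).sum(axis=1)
    ssb = np.zeros(len(X))
    for b in batches.unique():
        cols = np.flatnonzero((batches == b).to_numpy())
        bm = vals[:, cols].mean(axis=1)
        ssb += len(cols) * (bm - grand[:, 0]) ** 2
    ok = sst > 0
    return float(np.mean(ssb[ok] / sst[ok]))


def truth_report(
    truth: dict,
    comparison_tables: dict | None = None,
    kinase_tables: dict | None = None,
    r2_before: float | None = None,
    r2_after: float | None = None,
) -> dict:
    """Recovery metrics of pipeline outputs against the generating truth.

    ``comparison_tables`` maps contrast name ('her2', 'treatment') to a
    classified ComparisonResult table; ``kinase_tables`` maps contrast name to
    a KSEA score table. Reports differential-site recall/precision, kinase
    recovery rate and sign agreement, and the batch-variance reduction.
    """
    report: dict = {}
    if comparison_tables:
        for contrast, table in comparison_tables.items():
            true_sites = set(truth["differential_sites"].get(contrast, {}))
            called = set(table.index[table["class"].astype(str).str.startswith(("significant", "tendency"))])
            called &= set(table.index)
            tp = len(called & true_sites)
            report[f"{contrast}_recall"] = tp / len(true_sites) if true_sites else float("nan")
            report[f"{contrast}_precision"] = tp / len(called) if called else float("nan")
    if kinase_tables:
        for contrast, table in kinase_tables.items():
            truth_dirs = truth["active_kinases"].get(contrast, {})
            scored = table.set_index("kinase") if "kinase" in table.columns else table
            hits, signs = 0, 0
            for k, d in truth_dirs.items():
                if k in scored.index and bool(scored.loc[k, "significant"]):
                    hits += 1
                    if np.sign(scored.loc[k, "z"]) == d:
                        signs += 1
            n_active = len(truth_dirs)
            report[f"{contrast}_kinase_recovery"] = hits / n_active if n_active else float("nan")
            report[f"{contrast}_kinase_sign_agreement"] = signs / hits if hits else float("nan")
    if r2_before is not None and r2_after is not None:
        report["batch_r2_before"] = r2_before
        report["batch_r2_after"] = r2_after
        report["batch_r2_reduction"] = 1.0 - r2_after / r2_before if r2_before > 0 else float("nan")
    return report
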