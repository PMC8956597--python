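"""End-to-end orchestration of the analysis stages.

Each stage reads the artifacts of the previous one, writes its own TSV/JSON
outputs under the run directory, and appends row counts to ``run.log``. The
log records package version, a hash of the resolved configuration and the
feature counts at every filter, and contains no timestamps so that reruns
with the same seed and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, differential, enrich, io_sitetable, ksea, normalize, ordination
from . import synthetic_data as synth

__all__ = ["RunConfig", "PipelineRun", "load_config", "run"]

SUBCOMMANDS = ("simulate", "normalize", "compare", "ksea", "enrich", "pca", "all")

DEFAULT_THRESHOLDS = {
    "class1_cut": 0.75,
    "min_peptides": 2,
    "fc_cut": 1.0,
    "p_sig": 0.05,
    "p_tend": 0.1,
    "min_substrates": 2,
    "alpha": 0.05,
}

_THRESHOLD_RANGES = {
    "class1_cut": (0.0, 1.0),
    "fc_cut": (0.0, 100.0),
    "p_sig": (0.0, 1.0),
    "p_tend": (0.0, 1.0),
    "alpha": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Paths, thresholds and route flags for one pipeline run."""

    outdir: Path
    site_table: Path | None = None
    protein_table: Path | None = None
    design: Path | None = None
    network: Path | None = None
    gmt: Path | None = None
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    group_route: bool = True
    individual_route: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = self.thresholds[key]
            if not lo <= v <= hi:
                raise ValueError(f"threshold {key}={v} outside [{lo}, {hi}]")
        if not self.thresholds["p_sig"] < self.thresholds["p_tend"]:
            raise ValueError("need p_sig < p_tend")
        if int(self.thresholds["min_peptides"]) < 1 or int(self.thresholds["min_substrates"]) < 1:
            raise ValueError("min_peptides and min_substrates must be >= 1")

    def require_inputs(self) -> None:
        for name in ("site_table", "design", "network"):
            p = getattr(self, name)
            if p is None:
                raise FileNotFoundError(f"config is missing the {name} path")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    def config_hash(self) -> str:
        payload = {
            # basenames only: the hash identifies the run recipe, not the
            # directory it happens to live in
            "paths": {
                k: Path(getattr(self, k)).name if getattr(self, k) else None
                for k in ("site_table", "protein_table", "design", "network", "gmt")
            },
            "thresholds": self.thresholds,
            "group_route": self.group_route,
            "individual_route": self.individual_route,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path, outdir: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration, with CLI overrides for outdir/seed."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - {
        "outdir", "site_table", "protein_table", "design", "network", "gmt",
        "thresholds", "group_route", "individual_route", "seed",
    }
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if outdir is not None:
        raw["outdir"] = outdir
    if "outdir" not in raw:
        raise ValueError("config must declare an outdir")
    if seed is not None:
        raw["seed"] = seed
    for key in ("site_table", "protein_table", "design", "network", "gmt"):
        if raw.get(key):
            raw[key] = Path(raw[key])
    return RunConfig(**raw)


class PipelineRun:
    """Stateful runner holding intermediate artifacts across stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_lines: list[str] = []
        self.counts: dict[str, int] = {}
        self._log(f"phosq {__version__}")
        self._log(f"config_hash {config.config_hash()}")
        self._log(f"seed {config.seed}")

    def _log(self, line: str) -> None:
        self.log_lines.append(line)

    def _count(self, label: str, n: int) -> None:
        self.counts[label] = n
        self._log(f"count {label} {n}")

    def write_log(self) -> None:
        (self.outdir / "run.log").write_text("\n".join(self.log_lines) + "\n")

    # stages ---------------------------------------------------------------

    def simulate(self) -> None:
        ds = synth.generate(synth.SimConfig(seed=self.config.seed), self.outdir / "sim")
        self.config.site_table = ds.site_table
        self.config.protein_table = ds.protein_table
        self.config.design = ds.design
        self.config.network = ds.network
        self.config.gmt = ds.gmt
        self._log(f"simulate seed={self.config.seed} -> {ds.site_table.parent.name}/")

    def load_and_filter(self) -> None:
        cfg = self.config
        cfg.require_inputs()
        self.design = io_sitetable.read_design(cfg.design)
        records = io_sitetable.read_site_table(cfg.site_table, self.design)
        self._count("sites_read", len(records))
        records = io_sitetable.filter_class1(records, cfg.thresholds["class1_cut"])
        self._count("sites_class1", len(records))
        records = io_sitetable.filter_artifacts(records)
        self._count("sites_artifact_filtered", len(records))
        self.records = records
        comp = io_sitetable.residue_composition(records)
        io_sitetable.write_summary(comp, self.outdir / "composition.json")
        io_sitetable.write_summary(
            io_sitetable.quantified_summary(records, self.design), self.outdir / "presence.json"
        )
        if cfg.protein_table and Path(cfg.protein_table).exists():
            prots = io_sitetable.read_protein_table(cfg.protein_table, self.design)
            self._count("proteins_read", len(prots))
            prots = io_sitetable.filter_artifacts(prots)
            prots = io_sitetable.filter_protein_groups(prots, int(cfg.thresholds["min_peptides"]))
            self._count("proteins_filtered", len(prots))

    def normalize(self) -> None:
        if not hasattr(self, "records"):
            self.load_and_filter()
        raw = normalize.records_to_matrix(self.records, self.design)
        if self.config.group_route:
            corrected, model, counts = normalize.group_route(raw, self.design)
            self._count("sites_presence_filtered", counts["presence_filtered"])
            self._count("sites_batch_corrected", counts["batch_corrected"])
            corrected.write(self.outdir / "matrix_group.tsv", self.config.config_hash())
            model.write(self.outdir / "batch_model.json")
            self.matrix_group = corrected
        if self.config.individual_route:
            log2 = normalize.log2_transform(raw)
            indiv = normalize.normalize_for_individual(log2, self.design)
            indiv.write(self.outdir / "matrix_individual.tsv", self.config.config_hash())
            self.matrix_individual = indiv

    def _need(self, attr: str, stage: str) -> None:
        if not hasattr(self, attr):
            self.normalize()
        if not hasattr(self, attr):
            raise RuntimeError(f"stage {stage} requires the {attr} route to be enabled")

    def compare(self) -> None:
        """Group contrasts: HER2+ pre-T vs HER2− T (Welch), post vs pre T (paired)."""
        self._need("matrix_group", "compare")
        th = self.config.thresholds
        d = self.design
        kw = dict(fc_cut=th["fc_cut"], p_sig=th["p_sig"], p_tend=th["p_tend"])
        her2 = differential.group_compare(
            self.matrix_group, d,
            differential.select_samples(d, tissue="T", her2="positive", timepoint="pre"),
            differential.select_samples(d, tissue="T", her2="negative"),
            mode="welch", contrast="her2pos_preT_vs_her2neg_T", **kw,
        )
        treat = differential.group_compare(
            self.matrix_group, d,
            differential.select_samples(d, tissue="T", her2="positive", timepoint="post"),
            differential.select_samples(d, tissue="T", her2="positive", timepoint="pre"),
            mode="paired", contrast="her2pos_postT_vs_preT", **kw,
        )
        self.comparisons = {"her2": her2, "treatment": treat}
        for name, res in self.comparisons.items():
            res.write(self.outdir / f"comparison_{name}.tsv")
            for cls, n in res.counts().items():
                self._count(f"{name}_{cls}", n)

    def enrich(self) -> None:
        if self.config.gmt is None:
            self._log("enrich skipped: no gene-set collection configured")
            return
        if not hasattr(self, "comparisons"):
            self.compare()
        collection = enrich.read_gmt(self.config.gmt)
        universe = {k.rsplit("_", 1)[0] for k in self.matrix_group.data.index}
        for name, res in self.comparisons.items():
            sig = res.table["class"].astype(str).str.startswith("significant")
            hits = {k.rsplit("_", 1)[0] for k in res.table.index[sig]}
            table = enrich.ora(hits, universe, collection, alpha=self.config.thresholds["alpha"])
            table.to_csv(self.outdir / f"ora_{name}.tsv", sep="\t", index=False, float_format="%.6g")
            self._count(f"ora_{name}_significant", int(table["significant"].sum()))

    def ksea(self) -> None:
        """Per-patient kinome profiles: post-vs-pre T, and T-vs-NAT per timepoint."""
        self._need("matrix_individual", "ksea")
        network = ksea.read_ks_network(self.config.network)
        meta = self.design.clinical()
        comparisons = []
        her2pos = sorted(meta.loc[meta["her2"] == "positive", "patient_id"].unique())
        for p in her2pos:
            comparisons.append(
                {"name": f"{p}_postT_vs_preT",
                 "sample_a": f"{p}_post_T", "sample_b": f"{p}_pre_T"}
            )
        for p in sorted(meta["patient_id"].unique()):
            a, b = f"{p}_pre_T", f"{p}_pre_NAT"
            if a in self.matrix_individual.data.columns and b in self.matrix_individual.data.columns:
                comparisons.append({"name": f"{p}_T_vs_NAT", "sample_a": a, "sample_b": b})
        th = self.config.thresholds
        z, sig = ksea.ksea_profile(
            self.matrix_individual, self.design, comparisons, network,
            min_substrates=int(th["min_substrates"]), alpha=th["alpha"],
        )
        z.to_csv(self.outdir / "ksea_z.tsv", sep="\t", float_format="%.6g", na_rep="NA")
        sig.to_csv(self.outdir / "ksea_significant.tsv", sep="\t", na_rep="NA")
        self._count("ksea_kinases_scored", int(z.shape[0]))
        self.ksea_z = z

    def pca(self) -> None:
        self._need("matrix_group", "pca")
        d = self.design
        for label, samples in (
            ("T", differential.select_samples(d, tissue="T")),
            ("NAT", differential.select_samples(d, tissue="NAT")),
        ):
            samples = [s for s in samples if s in self.matrix_group.data.columns]
            res = ordination.pca(self.matrix_group, samples, n_components=2)
            res.write(self.outdir / f"pca_{label}.tsv")
            self._log(
                f"pca {label} explained "
                + " ".join(f"{v:.4f}" for v in res.explained_variance_ratio)
            )


def run(config: RunConfig, subcommand: str = "all") -> PipelineRun:
    """Execute one stage (or the whole pipeline) and write artifacts + log."""
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}; choose from {SUBCOMMANDS}")
    runner = PipelineRun(config)
    try:
        if subcommand in ("simulate", "all") and (subcommand == "simulate" or config.site_table is None):
            runner.simulate()
        if subcommand in ("normalize", "all"):
            runner.normalize()
        if subcommand in ("compare", "all"):
            runner.compare()
        if subcommand in ("enrich", "all"):
            runner.enrich()
        if subcommand in ("ksea", "all"):
            runner.ksea()
        if subcommand in ("pca", "all"):
            runner.pca()
    except Exception:
        runner._log("FAILED")
        runner.write_log()
        (runner.outdir / "FAILED").write_text("pipeline stage failed; see run.log\n")
        raise
    runner.write_log()
    return runner
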