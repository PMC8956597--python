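"""Reading and filtering of search-engine phosphosite / protein-group tables.

The expected inputs are tab-separated exports in the MaxQuant style: one row
per phosphosite (or protein group) with annotation columns plus one reporter
intensity column per (TMT batch, channel). A reporter intensity of 0 means
the feature was not quantified in that channel and is stored as missing.
"""

from __future__ import annotations

import decimal
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SiteRecord",
    "ProteinRecord",
    "StudyDesign",
    "CompositionSummary",
    "FormatError",
    "DesignError",
    "read_design",
    "read_site_table",
    "read_protein_table",
    "write_site_table",
    "filter_class1",
    "filter_artifacts",
    "filter_protein_groups",
    "residue_composition",
    "composition_from_counts",
    "percentage",
    "quantified_summary",
]

RESIDUES = ("S", "T", "Y")

#: default column names for site/protein tables; override via a column map
DEFAULT_COLUMNS = {
    "site_id": "site_id",
    "protein": "protein",
    "gene": "gene",
    "residue": "residue",
    "position": "position",
    "localization_prob": "localization_prob",
    "reverse": "reverse",
    "contaminant": "contaminant",
    "protein_group_id": "protein_group_id",
    "accessions": "accessions",
    "peptide_count": "peptide_count",
    # reporter columns are "<intensity_prefix><batch>.<channel>"
    "intensity_prefix": "intensity.",
    # marker dialect: flag column contains this token when the flag is set
    "flag_marker": "+",
}


class FormatError(ValueError):
    """Input file violates the expected tabular format."""


class DesignError(ValueError):
    """Data and study design disagree (unknown channel, missing reference...)."""


@dataclass
class SiteRecord:
    """One phosphosite with annotations and per-(batch, channel) intensities."""

    site_id: str
    protein: str
    gene: str
    residue: str
    position: int
    localization_prob: float
    is_reverse: bool = False
    is_contaminant: bool = False
    intensities: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue not in RESIDUES:
            raise ValueError(f"residue must be one of {RESIDUES}, got {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 0.0 <= self.localization_prob <= 1.0:
            raise ValueError(f"localization_prob must be in [0,1], got {self.localization_prob}")
        for key, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"negative intensity {v} at {key}")

    @property
    def site_key(self) -> tuple[str, str, int]:
        """Join key used across tables: (gene symbol, residue, position).

        Falls back to the protein accession when the gene symbol is absent.
        """
        return (self.gene or self.protein, self.residue, self.position)


@dataclass
class ProteinRecord:
    """One protein group with accessions and per-channel intensities."""

    protein_group_id: str
    accessions: list[str]
    peptide_count: int
    is_reverse: bool = False
    is_contaminant: bool = False
    intensities: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.peptide_count < 0:
            raise ValueError(f"peptide_count must be >= 0, got {self.peptide_count}")


DESIGN_COLUMNS = [
    "batch_id",
    "channel_id",
    "sample_id",
    "patient_id",
    "tissue",
    "her2",
    "timepoint",
    "is_reference",
]


@dataclass
class StudyDesign:
    """Mapping of (batch, channel) to sample metadata.

    ``tissue`` is T (tumor), NAT (non-tumor adjacent tissue) or REF (pooled
    cell-line reference); ``is_reference`` is true exactly for REF rows.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"study design missing columns: {missing}")
        t = self.table
        dup = t.duplicated(subset=["batch_id", "channel_id"])
        if dup.any():
            raise DesignError(f"duplicate (batch, channel) rows: {t[dup][['batch_id','channel_id']].values.tolist()}")
        bad = t[(t["tissue"] == "REF") != t["is_reference"]]
        if len(bad):
            raise DesignError("is_reference must hold exactly for tissue == REF rows")
        for b, grp in t.groupby("batch_id"):
            if not grp["is_reference"].any():
                raise DesignError(f"batch {b!r} has no reference channel")

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch_id"].unique())

    def channels(self, batch_id: str) -> list[str]:
        return self.table.loc[self.table["batch_id"] == batch_id, "channel_id"].tolist()

    def reference_channels(self, batch_id: str) -> list[str]:
        t = self.table
        m = (t["batch_id"] == batch_id) & t["is_reference"]
        return t.loc[m, "channel_id"].tolist()

    def clinical(self) -> pd.DataFrame:
        return self.table[~self.table["is_reference"]].reset_index(drop=True)

    def sample_meta(self) -> pd.DataFrame:
        """Design table indexed by sample_id."""
        return self.table.set_index("sample_id")

    def keys(self) -> set[tuple[str, str]]:
        return set(zip(self.table["batch_id"], self.table["channel_id"]))


def read_design(path: str | Path) -> StudyDesign:
    """Read a study-design TSV (one row per TMT channel)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"study design {path} missing columns: {missing}")
    df["is_reference"] = df["is_reference"].str.lower().isin(("true", "1", "yes"))
    for col in ("patient_id", "her2", "timepoint"):
        df[col] = df[col].replace("", "none")
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path) -> None:
    df = design.table.copy()
    df["is_reference"] = df["is_reference"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


_INTENSITY_RE_TEMPLATE = r"^{prefix}(?P<batch>[^.]+)\.(?P<channel>.+)$"


def _intensity_columns(header: Iterable[str], prefix: str) -> dict[str, tuple[str, str]]:
    pat = re.compile(_INTENSITY_RE_TEMPLATE.format(prefix=re.escape(prefix)))
    out: dict[str, tuple[str, str]] = {}
    for col in header:
        m = pat.match(col)
        if m:
            out[col] = (m.group("batch"), m.group("channel"))
    return out


def _parse_intensities(
    row: Mapping[str, str], cols: Mapping[str, tuple[str, str]], path: str | Path
) -> dict[tuple[str, str], float]:
    vals: dict[tuple[str, str], float] = {}
    for col, key in cols.items():
        cell = row[col]
        if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
            continue
        try:
            v = float(cell)
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable intensity {cell!r} in column {col!r}") from exc
        if v < 0:
            raise FormatError(f"{path}: negative intensity {v} in column {col!r}")
        if v > 0:  # zero reporter intensity = not quantified
            vals[key] = v
    return vals


def _flag(cell: str, marker: str) -> bool:
    return str(cell).strip() == marker


def read_site_table(
    path: str | Path,
    design: StudyDesign,
    columns: Mapping[str, str] | None = None,
) -> list[SiteRecord]:
    """Parse a phosphosite TSV into records, validating against the design.

    Raises :class:`FormatError` for a missing mandatory column and
    :class:`DesignError` when the file carries a (batch, channel) absent from
    the design.
    """
    cmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = ["site_id", "protein", "gene", "residue", "position", "localization_prob", "reverse", "contaminant"]
    for logical in mandatory:
        if cmap[logical] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[logical]!r} ({logical})")
    icols = _intensity_columns(df.columns, cmap["intensity_prefix"])
    unknown = set(icols.values()) - design.keys()
    if unknown:
        raise DesignError(f"{path}: (batch, channel) not in study design: {sorted(unknown)}")
    marker = cmap["flag_marker"]
    records = []
    for row in df.to_dict("records"):
        records.append(
            SiteRecord(
                site_id=row[cmap["site_id"]],
                protein=row[cmap["protein"]],
                gene=row[cmap["gene"]],
                residue=row[cmap["residue"]],
                position=int(row[cmap["position"]]),
                localization_prob=float(row[cmap["localization_prob"]]),
                is_reverse=_flag(row[cmap["reverse"]], marker),
                is_contaminant=_flag(row[cmap["contaminant"]], marker),
                intensities=_parse_intensities(row, icols, path),
            )
        )
    return records


def read_protein_table(
    path: str | Path,
    design: StudyDesign,
    columns: Mapping[str, str] | None = None,
) -> list[ProteinRecord]:
    """Parse a protein-group TSV (accessions, razor+unique peptide counts)."""
    cmap = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in ("protein_group_id", "accessions", "peptide_count", "reverse", "contaminant"):
        if cmap[logical] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[logical]!r} ({logical})")
    icols = _intensity_columns(df.columns, cmap["intensity_prefix"])
    unknown = set(icols.values()) - design.keys()
    if unknown:
        raise DesignError(f"{path}: (batch, channel) not in study design: {sorted(unknown)}")
    marker = cmap["flag_marker"]
    out = []
    for row in df.to_dict("records"):
        out.append(
            ProteinRecord(
                protein_group_id=row[cmap["protein_group_id"]],
                accessions=[a for a in str(row[cmap["accessions"]]).split(";") if a],
                peptide_count=int(row[cmap["peptide_count"]]),
                is_reverse=_flag(row[cmap["reverse"]], marker),
                is_contaminant=_flag(row[cmap["contaminant"]], marker),
                intensities=_parse_intensities(row, icols, path),
            )
        )
    return out


def write_site_table(
    records: list[SiteRecord],
    design: StudyDesign,
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    """Write records in the same dialect ``read_site_table`` consumes.

    Missing intensities are written as 0 (the unquantified-reporter
    convention), so a round trip preserves the missingness pattern.
    """
    cmap = {**DEFAULT_COLUMNS, **(columns or {})}
    marker = cmap["flag_marker"]
    keys = sorted(design.keys())
    rows = []
    for r in records:
        row = {
            cmap["site_id"]: r.site_id,
            cmap["protein"]: r.protein,
            cmap["gene"]: r.gene,
            cmap["residue"]: r.residue,
            cmap["position"]: r.position,
            cmap["localization_prob"]: repr(r.localization_prob),
            cmap["reverse"]: marker if r.is_reverse else "",
            cmap["contaminant"]: marker if r.is_contaminant else "",
        }
        for b, c in keys:
            row[f"{cmap['intensity_prefix']}{b}.{c}"] = repr(r.intensities.get((b, c), 0.0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_class1(records: list[SiteRecord], threshold: float = 0.75) -> list[SiteRecord]:
    """Keep class-1 sites: localization probability strictly above threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    return [r for r in records if r.localization_prob > threshold]


def filter_artifacts(records):
    """Drop decoy ("reverse") hits and potential contaminants."""
    return [r for r in records if not (r.is_reverse or r.is_contaminant)]


def filter_protein_groups(records: list[ProteinRecord], min_peptides: int = 2) -> list[ProteinRecord]:
    """Keep protein groups identified with at least ``min_peptides`` razor+unique peptides."""
    if min_peptides < 1:
        raise ValueError(f"min_peptides must be >= 1, got {min_peptides}")
    return [r for r in records if r.peptide_count >= min_peptides]


def percentage(count: int, total: int) -> float:
    """Percentage to one decimal, round-half-up (reporting convention)."""
    pct = decimal.Decimal(100 * count) / decimal.Decimal(total)
    return float(pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


@dataclass
class CompositionSummary:
    """pS/pT/pY counts and percentages among class-1 sites."""

    n_class1: int
    n_S: int
    n_T: int
    n_Y: int
    pct_S: float
    pct_T: float
    pct_Y: float

    def to_dict(self) -> dict:
        return {
            "n_class1": self.n_class1,
            "n_S": self.n_S,
            "n_T": self.n_T,
            "n_Y": self.n_Y,
            "pct_S": self.pct_S,
            "pct_T": self.pct_T,
            "pct_Y": self.pct_Y,
        }


def composition_from_counts(n_s: int, n_t: int, n_y: int) -> CompositionSummary:
    """Residue composition from raw per-residue site counts."""
    total = n_s + n_t + n_y
    if total == 0:
        raise ValueError("residue composition of an empty site set is undefined")
    return CompositionSummary(
        n_class1=total,
        n_S=n_s,
        n_T=n_t,
        n_Y=n_y,
        pct_S=percentage(n_s, total),
        pct_T=percentage(n_t, total),
        pct_Y=percentage(n_y, total),
    )


def residue_composition(records: list[SiteRecord]) -> CompositionSummary:
    """pS/pT/pY composition of a (class-1 filtered) site list."""
    if not records:
        raise ValueError("residue composition of an empty site set is undefined")
    counts = {res: 0 for res in RESIDUES}
    for r in records:
        counts[r.residue] += 1
    return composition_from_counts(counts["S"], counts["T"], counts["Y"])


def quantified_summary(records: list[SiteRecord], design: StudyDesign) -> dict:
    """Presence summary over the three tissue groups (REF, T, NAT).

    Returns the number of features quantified in at least one sample, the
    percentage of all features that is, and the breakdown of quantified
    features by presence category: observed in all three groups, only in the
    reference (cell-line) channels, or some other combination.
    """
    meta = design.table.set_index(["batch_id", "channel_id"])["tissue"]
    n_total = len(records)
    n_quant = 0
    cats = {"all_three_groups": 0, "cell_line_only": 0, "other": 0}
    for r in records:
        groups = {meta.get(k) for k in r.intensities}
        groups.discard(None)
        if not groups:
            continue
        n_quant += 1
        if groups >= {"REF", "T", "NAT"}:
            cats["all_three_groups"] += 1
        elif groups == {"REF"}:
            cats["cell_line_only"] += 1
        else:
            cats["other"] += 1
    out = {
        "n_features": n_total,
        "n_quantified": n_quant,
        "pct_quantified": percentage(n_quant, n_total) if n_total else 0.0,
    }
    for k, v in cats.items():
        out[f"pct_{k}"] = percentage(v, n_quant) if n_quant else 0.0
        out[f"n_{k}"] = v
    return out


def write_summary(summary: dict | CompositionSummary, path: str | Path) -> None:
    data = summary.to_dict() if isinstance(summary, CompositionSummary) else summary
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
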