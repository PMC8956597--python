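"""Identification-level QC: class-1 / artifact filters and composition.

Reads results/data/, applies the localization-probability cutoff (> 0.75),
removes decoy and contaminant hits, filters one-peptide protein groups, and
reports the pS/pT/pY composition and the presence breakdown across the three
tissue groups (cell-line reference, tumor, adjacent tissue).

Writes results/qc/{composition.json,presence.json,filter_counts.json}.
"""

import json
from pathlib import Path

from phosq import io_sitetable as io

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "qc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = io.read_design(DATA / "design.tsv")
    records = io.read_site_table(DATA / "sites.tsv", design)
    counts = {"sites_read": len(records)}
    records = io.filter_class1(records)
    counts["sites_class1"] = len(records)
    records = io.filter_artifacts(records)
    counts["sites_artifact_filtered"] = len(records)

    comp = io.residue_composition(records)
    io.write_summary(comp, OUT / "composition.json")
    presence = io.quantified_summary(records, design)
    io.write_summary(presence, OUT / "presence.json")

    prots = io.read_protein_table(DATA / "proteins.tsv", design)
    counts["proteins_read"] = len(prots)
    prots = io.filter_protein_groups(io.filter_artifacts(prots))
    counts["proteins_filtered"] = len(prots)
    (OUT / "filter_counts.json").write_text(json.dumps(counts, indent=2) + "\n")

    print(f"class-1 sites: {comp.n_class1} "
          f"(pS {comp.pct_S}%, pT {comp.pct_T}%, pY {comp.pct_Y}%)")
    print(f"quantified in >=1 sample: {presence['n_quantified']} "
          f"({presence['pct_quantified']}%), all three groups: {presence['pct_all_three_groups']}%")
    print(f"protein groups kept (>=2 peptides, no artifacts): {counts['proteins_filtered']}")


if __name__ == "__main__":
    main()
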