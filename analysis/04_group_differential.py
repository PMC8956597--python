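"""Group-level differential phosphosites and recovery against the truth.

Two contrasts on the batch-corrected matrix:
  * HER2-status: pre-treatment HER2+ tumors vs HER2− tumors (Welch t);
  * treatment: post- vs pre-treatment HER2+ tumors (paired t by patient).
Sites with |log2FC| > 1 and p < 0.05 are significant; p in [0.05, 0.1) is a
tendency. A node-status overlay is written for the genes of the planted
HER2-signature set, standing in for a curated signaling-pathway gene list.

Writes results/differential/.
"""

import json
from pathlib import Path

import pandas as pd

from phosq import differential as diff
from phosq import io_sitetable as io
from phosq.enrich import read_gmt
from phosq.normalize import QuantMatrix
from phosq.synthetic_data import truth_report

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
NORM = ROOT / "results" / "normalized"
OUT = ROOT / "results" / "differential"


def load_matrix(path: Path, design: io.StudyDesign) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    stage = json.loads(path.with_suffix(".tsv.json").read_text())["stage"]
    return QuantMatrix(df, stage, design.sample_meta()["batch_id"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = io.read_design(DATA / "design.tsv")
    matrix = load_matrix(NORM / "matrix_group.tsv", design)

    her2 = diff.group_compare(
        matrix, design,
        diff.select_samples(design, tissue="T", her2="positive", timepoint="pre"),
        diff.select_samples(design, tissue="T", her2="negative"),
        mode="welch", contrast="her2pos_preT_vs_her2neg_T",
    )
    treat = diff.group_compare(
        matrix, design,
        diff.select_samples(design, tissue="T", her2="positive", timepoint="post"),
        diff.select_samples(design, tissue="T", her2="positive", timepoint="pre"),
        mode="paired", contrast="her2pos_postT_vs_preT",
    )
    truth = json.loads((DATA / "truth.json").read_text())
    report = truth_report(truth, comparison_tables={"her2": her2.table, "treatment": treat.table})
    for name, res in (("her2", her2), ("treatment", treat)):
        res.write(OUT / f"comparison_{name}.tsv")
        c = res.counts()
        print(f"{res.contrast}: {c['significant_up']} up / {c['significant_down']} down "
              f"significant, {c['tendency_up'] + c['tendency_down']} tendency; "
              f"precision {report[f'{name}_precision']:.2f}, recall {report[f'{name}_recall']:.2f}")

    # node-status overlay on the planted HER2-signature genes
    gmt = read_gmt(DATA / "genesets.gmt")
    nodes = gmt.sets["SET_HER2"]["genes"]
    overlay = diff.pathway_overlay(her2, nodes, "SET_HER2")
    overlay.to_csv(OUT / "overlay_her2_signature.tsv", sep="\t", index=False)
    state_counts = overlay["state"].value_counts().to_dict()
    print(f"overlay ({len(nodes)} nodes): {state_counts}")
    (OUT / "recovery.json").write_text(json.dumps(report, indent=2) + "\n")


if __name__ == "__main__":
    main()
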