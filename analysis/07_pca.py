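"""PCA of the batch-corrected matrix: does biology dominate batch?

Separate decompositions of tumor and NAT samples (centered, unscaled
features). On this design the tumor samples should separate by HER2 status
and treatment on the leading components while NAT samples stay mixed.

Writes results/pca/.
"""

import json
from pathlib import Path

import pandas as pd

from phosq import io_sitetable as io
from phosq.differential import select_samples
from phosq.normalize import QuantMatrix
from phosq.ordination import pca

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "pca"


def separation(scores: pd.Series, groups: pd.Series) -> float:
    """Distance between group centroids on PC1 in pooled-SD units."""
    g = sorted(groups.unique())
    a, b = scores[groups == g[0]], scores[groups == g[1]]
    pooled = ((a.var(ddof=1) + b.var(ddof=1)) / 2) ** 0.5
    return abs(a.mean() - b.mean()) / pooled


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = io.read_design(ROOT / "results" / "data" / "design.tsv")
    data = pd.read_csv(ROOT / "results" / "normalized" / "matrix_group.tsv",
                       sep="\t", index_col=0, na_values="NA")
    matrix = QuantMatrix(data, "batch_corrected", design.sample_meta()["batch_id"])
    meta = design.sample_meta()

    stats = {}
    for label, samples in (("T", select_samples(design, tissue="T")),
                           ("NAT", select_samples(design, tissue="NAT"))):
        res = pca(matrix, samples, n_components=2)
        res.write(OUT / f"pca_{label}.tsv")
        her2 = meta.loc[samples, "her2"]
        sep = separation(res.scores["PC1"], her2)
        stats[label] = {
            "explained_pc1": round(float(res.explained_variance_ratio[0]), 4),
            "explained_pc2": round(float(res.explained_variance_ratio[1]), 4),
            "her2_separation_pc1_sd": round(sep, 2),
        }
        print(f"{label}: PC1 {stats[label]['explained_pc1']:.1%}, "
              f"HER2 centroid separation on PC1 = {sep:.2f} pooled SDs")
    (OUT / "pca_stats.json").write_text(json.dumps(stats, indent=2) + "\n")


if __name__ == "__main__":
    main()
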