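"""Over-representation of differential phosphosite genes in gene sets.

For each contrast the hit list is the set of genes carrying at least one
significant site; the universe is every gene with a quantified site in the
batch-corrected matrix. Enrichment is the upper-tail hypergeometric test;
sets with p < 0.05 are reported as significant.

Writes results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from phosq.enrich import ora, read_gmt

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "enrichment"


def genes_of(index: pd.Index) -> set[str]:
    return {k.rsplit("_", 1)[0] for k in index}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    collection = read_gmt(DATA / "genesets.gmt")
    matrix = pd.read_csv(ROOT / "results" / "normalized" / "matrix_group.tsv",
                         sep="\t", index_col=0, na_values="NA")
    universe = genes_of(matrix.index)
    for name in ("her2", "treatment"):
        comp = pd.read_csv(ROOT / "results" / "differential" / f"comparison_{name}.tsv",
                           sep="\t", index_col=0, na_values="NA")
        hits = genes_of(comp.index[comp["class"].astype(str).str.startswith("significant")])
        table = ora(hits, universe, collection)
        table.to_csv(OUT / f"ora_{name}.tsv", sep="\t", index=False, float_format="%.6g")
        sig = table[table["significant"]]
        print(f"{name}: {len(hits)} hit genes over a universe of {len(universe)}; "
              f"{len(sig)} significant sets, top: "
              f"{table.iloc[0]['set_id']} (p={table.iloc[0]['p']:.3g})")


if __name__ == "__main__":
    main()
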