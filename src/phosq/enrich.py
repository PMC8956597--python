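"""Local over-representation analysis (ORA) against gene-set collections.

The test is the upper-tail hypergeometric: given a universe of N genes of
which m belong to a set, the probability of drawing at least k set members in
a hit list of size n. The universe defaults to all genes carrying at least
one quantified phosphosite in the analyzed matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

__all__ = ["GeneSetCollection", "read_gmt", "ora", "hypergeom_upper_tail"]


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n) — the ORA p-value."""
    if k <= 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, m, n), 1.0))


class GMTFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (set_id -> {name, genes}), symbols upper-cased."""

    sets: dict[str, dict]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated id, description, genes."""
    sets: dict[str, dict] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTFormatError(f"{path}:{i}: GMT line needs >= 3 tab-separated fields, got {len(fields)}")
        set_id, name = fields[0], fields[1]
        genes = list(dict.fromkeys(g.strip().upper() for g in fields[2:] if g.strip()))
        if not genes:
            raise GMTFormatError(f"{path}:{i}: gene set {set_id!r} has no genes")
        sets[set_id] = {"name": name, "genes": genes}
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, source=str(path))


def ora(
    hits: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``hits`` within each set, over ``universe``.

    Returns one row per set with k (overlap), m (set size in universe),
    n (hit-list size), N (universe size), the upper-tail p-value
    P(X >= k), a significance flag (p < alpha) and the overlapping genes,
    sorted by p.
    """
    hits = {g.upper() for g in hits}
    universe = {g.upper() for g in universe}
    stray = hits - universe
    if stray:
        raise ValueError(f"hit genes not in universe: {sorted(stray)}")
    N, n = len(universe), len(hits)
    rows = []
    for set_id, entry in collection.sets.items():
        members = set(entry["genes"]) & universe
        m = len(members)
        overlap = sorted(members & hits)
        k = len(overlap)
        p = hypergeom_upper_tail(k, N, m, n) if m else 1.0
        rows.append(
            {
                "set_id": set_id,
                "name": entry["name"],
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "significant": p < alpha,
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["set_id", "name", "k", "m", "n", "N", "p", "significant", "genes"])
    return out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
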