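"""Hypergeometric over-representation analysis (ORA) of gene lists.

Gene-set collections are read and written in the tab-separated GMT
format (set name, description, member genes). The test is the one-sided
hypergeometric upper tail on the overlap between the query list and each
set, with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclass
class GeneSetCollection:
    """Named gene sets with per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members are deduplicated, empty lines skipped."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, against ``universe``.

    Sets are intersected with the universe before testing. For each set,
    p_raw = P(X >= n_overlap) with X ~ Hypergeometric(N=n_universe,
    K=n_set, n=n_query); FDR is BH across all tested sets and a set is
    significant when fdr < fdr_cut (strict).

    Returns a DataFrame sorted by p_raw with columns set_name, n_universe,
    n_set, n_query, n_overlap, p_raw, fdr, significant.
    """
    from tkiscreen.diffexpr import bh_adjust

    universe_set = set(universe)
    query_set = set(query)
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes not in universe: {sorted(stray)[:10]}")
    n_universe, n_query = len(universe_set), len(query_set)
    rows = []
    for name, members in sets.sets.items():
        in_universe = universe_set.intersection(members)
        n_set = len(in_universe)
        n_overlap = len(query_set & in_universe)
        # upper tail P(X >= k) = sf(k-1)
        p = float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_set, n_query))
        rows.append((name, n_universe, n_set, n_query, n_overlap, min(p, 1.0)))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "n_universe", "n_set", "n_query", "n_overlap", "p_raw"],
    )
    out["fdr"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < fdr_cut
    return out.sort_values(["p_raw", "set_name"], kind="stable").reset_index(drop=True)
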