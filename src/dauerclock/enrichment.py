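"""Gene-set over-representation analysis (ORA).

Given a query gene list (e.g. the differentially expressed genes of a
time course), a universe (all genes that entered the test) and a GMT
collection of gene sets, each set is scored with the hypergeometric
upper-tail probability

    p = sum_{i=k}^{min(m, n)} C(m, i) C(N-m, n-i) / C(N, n)

where N is the universe size, m the set size within the universe, n the
query size and k the observed overlap. P-values are adjusted with
Benjamini-Hochberg across tested sets. Only over-representation (the
upper tail) is tested. Two effect-size summaries are reported: the gene
ratio k/n and the rich factor k/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated member ids).

    Duplicate member ids within a set are deduplicated (keeping first
    occurrence); a duplicated set name or a line with fewer than three
    fields is an error reported with its line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
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
                    f"{path}:{lineno}: malformed GMT line (needs name, "
                    f"description and at least one member)"
                )
            name, description, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m and m not in seen:
                    seen[m] = None
            sets[name] = list(seen)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(
    query_genes: Iterable[str],
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    universe: Iterable[str],
    min_set_size: int = 3,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    Query genes outside the universe are dropped with a warning; each
    set is intersected with the universe and skipped (with a warning)
    when fewer than ``min_set_size`` members remain. Returns one row per
    tested set sorted by p, with columns ``set``, ``k`` (overlap), ``m``
    (set size in universe), ``n`` (query size), ``N`` (universe size),
    ``gene_ratio``, ``rich_factor``, ``p``, ``q`` and ``significant``
    (q <= cutoff).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query = set(query_genes)
    outside = query - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= universe_set

    if isinstance(sets, GeneSetCollection):
        items = list(sets)
    else:
        items = list(sets.items())

    N, n = len(universe_set), len(query)
    rows = []
    for name, members in items:
        in_universe = universe_set.intersection(members)
        m = len(in_universe)
        if m < min_set_size:
            warnings.warn(
                f"gene set {name!r} has {m} members in the universe "
                f"(< {min_set_size}); skipped",
                stacklevel=2,
            )
            continue
        k = len(query & in_universe)
        # upper tail P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(hypergeom.sf(k - 1, N, m, n))
        rows.append(
            {
                "set": name,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "gene_ratio": k / n if n else float("nan"),
                "rich_factor": k / m,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set", "k", "m", "n", "N", "gene_ratio", "rich_factor", "p"]
    )
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["q"] <= cutoff
        result = result.sort_values(["p", "set"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
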