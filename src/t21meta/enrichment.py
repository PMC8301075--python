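"""Over-representation analysis (ORA) of gene lists against GMT collections.

For a gene set of ``size`` annotated members inside the background universe
of ``N`` genes, and a dysregulated list of ``n`` genes of which ``observed``
fall in the set, the report row carries::

    expected = size * n / N           # expected-by-chance overlap
    ratio    = observed / expected    # enrichment ratio
    p        = P(X >= observed),  X ~ Hypergeometric(N, size, n)

with BH adjustment across all sets of the collection.  This is the local,
reproducible arithmetic behind web-service enrichment reports; no
permutation-based combined scores are computed.

The background universe is a modelling choice.  The default policy restricts
it to genes that entered the meta-analysis *and* are annotated somewhere in
the collection (web tools typically do the same, which is why their printed
"Expected" columns imply a background smaller than the full gene list); the
full measured universe is available via ``universe_policy="all_measured"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import fdr_bh
from .exceptions import ContractError, GMTParseError

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora",
    "directional_enrichment",
]


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        # dedupe preserving order
        seen: set[str] = set()
        self.members = [m for m in self.members if not (m in seen or seen.add(m))]
        if not self.members:
            raise GMTParseError(f"gene set {self.name!r}: no members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise GMTParseError("gene set collection: duplicate set names")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.members)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file (name, description, tab-separated members).

    Duplicate members within a line are deduplicated; empty trailing fields
    are ignored.  Malformed lines raise :class:`GMTParseError` with the line
    number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = [f for f in fields[2:] if f.strip()]
            if len(fields) < 3 or not members:
                raise GMTParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            sets.append(GeneSet(fields[0], fields[1], members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def hypergeom_upper_tail(observed: int, universe: int, set_size: int, n_drawn: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(N=universe, K=set_size, n=n_drawn)."""
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe, set_size, n_drawn))


def ora(
    deg_genes,
    universe,
    collection: GeneSetCollection,
    on_outside: str = "error",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``deg_genes`` in each gene set.

    ``universe`` is the background gene list; ``deg_genes`` must be a subset
    of it (``on_outside="drop"`` silently intersects instead).  Returns one
    row per set — columns ``set, description, size, expected, observed,
    ratio, p, adjusted_p`` — sorted by p ascending (ties by set name).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ContractError("ora: empty universe")
    degs = set(deg_genes)
    outside = degs - universe_set
    if outside:
        if on_outside == "drop":
            degs &= universe_set
        else:
            raise ContractError(
                f"ora: {len(outside)} dysregulated genes outside the universe "
                f"(e.g. {sorted(outside)[:3]})"
            )
    n_universe = len(universe_set)
    n_deg = len(degs)

    rows = []
    for s in collection.sets:
        members = set(s.members) & universe_set
        size = len(members)
        observed = len(members & degs)
        expected = size * n_deg / n_universe
        ratio = observed / expected if expected > 0 else 0.0
        p = hypergeom_upper_tail(observed, n_universe, size, n_deg)
        rows.append(
            {
                "set": s.name,
                "description": s.description,
                "size": size,
                "expected": expected,
                "observed": observed,
                "ratio": ratio,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = np.maximum(fdr_bh(table["p"].to_numpy()), table["p"].to_numpy())
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        table["adjusted_p"] = []
    return table


def directional_enrichment(
    meta_records: pd.DataFrame,
    collection: GeneSetCollection,
    universe_policy: str = "annotated",
) -> dict[str, pd.DataFrame]:
    """ORA of the up, down, and combined included gene lists.

    ``meta_records`` is the meta-analysis record table (``gene``,
    ``included``, ``direction`` columns).  The background is every gene that
    entered the meta-analysis, optionally intersected with the collection's
    annotated genes (default policy ``"annotated"``).  Each result table
    additionally carries ``n_up_members`` / ``n_down_members``, the split of
    the combined observed overlap by direction.
    """
    measured = list(meta_records["gene"])
    if universe_policy == "annotated":
        annotated = collection.annotated_genes
        universe = [g for g in measured if g in annotated]
    elif universe_policy == "all_measured":
        universe = measured
    else:
        raise ContractError(
            f"universe_policy: {universe_policy!r} not in ('annotated', 'all_measured')"
        )
    uni_set = set(universe)

    inc = meta_records[meta_records["included"]]
    up = [g for g in inc.loc[inc["direction"] == "up", "gene"] if g in uni_set]
    down = [g for g in inc.loc[inc["direction"] == "down", "gene"] if g in uni_set]
    both = up + down

    out: dict[str, pd.DataFrame] = {}
    split = {
        s.name: (
            len(set(s.members) & set(up)),
            len(set(s.members) & set(down)),
        )
        for s in collection.sets
    }
    for key, genes in (("up", up), ("down", down), ("all", both)):
        table = ora(genes, universe, collection)
        table["n_up_members"] = [split[n][0] for n in table["set"]]
        table["n_down_members"] = [split[n][1] for n in table["set"]]
        out[key] = table
    return out
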