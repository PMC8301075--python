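"""Map platform-native feature ids to a shared gene-symbol namespace.

Cross-platform meta-analysis needs every study keyed by the same identifiers.
Array studies arrive keyed by probe ids and RNA-seq studies by gene-model ids;
a :class:`ProbeMap` translates either to official gene symbols.  Symbols are
opaque, case-sensitive strings here — alias resolution against a live
annotation database is out of scope, so inputs must use consistent symbols.

When several probes map to one symbol the ``collapse_rule`` picks a single
row.  The default ``max_mean`` keeps the probe with the highest mean
expression, the common array practice (a high-intensity probe is usually the
best-behaved one); ``median`` takes the element-wise median across probes and
``first`` keeps the first probe in input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, HarmonizationError
from .studies import ExpressionStudy

logger = logging.getLogger(__name__)

COLLAPSE_RULES = ("max_mean", "median", "first")


@dataclass
class ProbeMap:
    """Probe id -> gene symbol map; empty-string symbol means unmapped."""

    entries: pd.Series  # index: probe_id (unique), values: symbol or ""

    def __post_init__(self) -> None:
        if not self.entries.index.is_unique:
            raise DataError("probe map: duplicate probe ids")
        self.entries = self.entries.fillna("").astype(str)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_mapped(self) -> int:
        return int((self.entries != "").sum())

    @property
    def n_unmapped(self) -> int:
        return int((self.entries == "").sum())

    @property
    def symbols(self) -> set[str]:
        return set(self.entries[self.entries != ""])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"probe_id": self.entries.index, "symbol": self.entries.to_numpy()})
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if not {"probe_id", "symbol"} <= set(df.columns):
            raise DataError(f"{path}: probe map needs probe_id and symbol columns")
        return cls(entries=pd.Series(df["symbol"].to_numpy(), index=df["probe_id"].to_numpy()))

    @classmethod
    def identity(cls, symbols: list[str]) -> "ProbeMap":
        return cls(entries=pd.Series(list(symbols), index=list(symbols)))


def harmonize_study(
    study: ExpressionStudy,
    probe_map: ProbeMap,
    collapse_rule: str = "max_mean",
) -> ExpressionStudy:
    """Re-key a study by gene symbol, dropping unmapped probes and
    collapsing multi-probe genes with ``collapse_rule``.

    The sample axis is untouched.  Raises :class:`HarmonizationError` when no
    study feature has a mapped symbol.
    """
    if collapse_rule not in COLLAPSE_RULES:
        raise DataError(f"collapse_rule: {collapse_rule!r} not in {COLLAPSE_RULES}")

    symbols = probe_map.entries.reindex(study.values.index)
    known = symbols.notna() & (symbols != "")
    n_dropped = int((~known).sum())
    if not known.any():
        raise HarmonizationError(
            f"{study.study_id}: no study feature maps to a gene symbol"
        )
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d features without a mapped symbol",
            study.study_id, n_dropped, len(symbols),
        )

    mat = study.values.loc[known.to_numpy()]
    sym = symbols[known.to_numpy()].to_numpy()

    if collapse_rule == "median":
        collapsed = mat.groupby(sym, sort=True).median()
    elif collapse_rule == "first":
        keep = ~pd.Index(sym).duplicated(keep="first")
        collapsed = mat.loc[keep].set_axis(sym[keep], axis=0).sort_index()
    else:  # max_mean
        means = mat.to_numpy().mean(axis=1)
        order = pd.DataFrame({"symbol": sym, "mean": means, "pos": np.arange(len(sym))})
        # highest mean wins; ties broken by input order for determinism
        best = (
            order.sort_values(["symbol", "mean", "pos"], ascending=[True, False, True])
            .drop_duplicates("symbol", keep="first")
        )
        collapsed = mat.iloc[best["pos"].to_numpy()].set_axis(
            best["symbol"].to_numpy(), axis=0
        )

    n_collapsed = len(mat) - len(collapsed)
    if n_collapsed:
        logger.info(
            "%s: collapsed %d duplicate probe rows into %d symbols (%s)",
            study.study_id, n_collapsed, len(collapsed), collapse_rule,
        )
    if study.platform == "rnaseq":
        collapsed = collapsed.round().astype(np.int64)
    return ExpressionStudy(
        study_id=study.study_id,
        platform=study.platform,
        values=collapsed,
        group=study.group,
    )


def gene_universe(studies: list[ExpressionStudy]) -> tuple[list[str], pd.Series]:
    """Union of symbols across harmonized studies and per-symbol study counts.

    The count feeds the "assayed in at least two datasets" inclusion
    criterion downstream; single-study genes are kept (and flagged), not
    dropped here.
    """
    counts: dict[str, int] = {}
    for study in studies:
        for g in study.values.index:
            counts[g] = counts.get(g, 0) + 1
    union = sorted(counts)
    return union, pd.Series([counts[g] for g in union], index=union, dtype=int)
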