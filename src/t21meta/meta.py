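"""Signed, sample-size-weighted Stouffer Z meta-analysis with heterogeneity
filtering.

Each study contributes, per gene, a signed Z-score

    Z_i = sign(log2FC_i) * Phi^{-1}(1 - p_i / 2)

which is combined across the k studies measuring the gene as

    Z_meta = sum(w_i * Z_i) / sqrt(sum(w_i^2)),      w_i = sqrt(n_i)

(the sample-size weighting scheme of classical GWAS meta-analysis tools;
an effective-sample-size variant ``w_i = sqrt(4 / (1/n_case + 1/n_control))``
is available).  ``p_meta`` is the two-sided normal tail of ``Z_meta`` and
q-values are BH over every gene entering the meta-analysis (k >= 1).

A gene is reported as dysregulated when it passes all three criteria:
q_meta <= 0.01, measured in at least two studies, and not significantly
heterogeneous across studies (HetP > 0.05).  Heterogeneity is Cochran's Q of
the signed Z-scores around their weighted fit (see
:func:`heterogeneity_test`), referred to chi-square with k - 1 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import P_FLOOR, fdr_bh
from .exceptions import ContractError, DataError

__all__ = [
    "signed_z",
    "combine_stouffer",
    "heterogeneity_test",
    "run_meta",
    "WEIGHT_SCHEMES",
]

WEIGHT_SCHEMES = ("sqrt_n", "effective_n")

#: default inclusion thresholds (two-sided meta q, minimum study count,
#: heterogeneity p); ties resolved as q <= and HetP > exactly
META_Q = 0.01
MIN_STUDIES = 2
HETP = 0.05


def signed_z(p_two_sided, log2fc):
    """Signed Z-score: ``sign(log2FC) * Phi^{-1}(1 - p/2)``.

    A zero fold change has sign 0 and therefore Z = 0.  Accepts scalars or
    arrays; p must lie in (0, 1].
    """
    p = np.asarray(p_two_sided, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p > 1)):
        raise DataError("signed_z: p-values must be in (0, 1]")
    if np.any(~np.isfinite(lfc)):
        raise DataError("signed_z: log2FC must be finite")
    z = np.sign(lfc) * stats.norm.isf(np.clip(p, P_FLOOR, 1.0) / 2.0)
    if np.ndim(p_two_sided) == 0 and np.ndim(log2fc) == 0:
        return float(z)
    return z


def _weights(n_list=None, weights=None):
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    else:
        w = np.sqrt(np.asarray(n_list, dtype=float))
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise DataError("weights must be positive and finite")
    return w


def combine_stouffer(z_list, n_list=None, weights=None):
    """Weighted Stouffer combination of signed Z-scores.

    By default ``w_i = sqrt(n_i)``; pass ``weights`` to override.  Returns
    ``(Z_meta, p_meta)`` with ``p_meta = 2 * (1 - Phi(|Z_meta|))``.  The
    result is invariant to study order and to rescaling all weights by a
    common factor.
    """
    z = np.asarray(z_list, dtype=float)
    if z.size == 0:
        raise ContractError("combine_stouffer: empty input")
    if n_list is None and weights is None:
        raise ContractError("combine_stouffer: provide n_list or weights")
    w = _weights(n_list, weights)
    if w.shape != z.shape:
        raise ContractError("combine_stouffer: length mismatch")
    z_meta = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p_meta = float(np.clip(2.0 * stats.norm.sf(abs(z_meta)), P_FLOOR, 1.0))
    return z_meta, p_meta


def heterogeneity_test(z_list, weights=None):
    """Cochran's Q for between-study inconsistency of signed Z-scores.

    With no ``weights`` (the default) each Z is treated as unit-variance
    with a common mean, giving the textbook ``Q = sum((Z_i - Zbar)^2)``.
    With combination weights the common-mean model becomes ``E[Z_i] =
    lambda * w_i`` (a shared standardized effect scaled by study size), and
    Q is the residual sum of squares around the weighted fit::

        lambda_hat = sum(w_i Z_i) / sum(w_i^2)
        Q = sum((Z_i - w_i * lambda_hat)^2)

    which reduces exactly to the unweighted form for equal weights.  Under
    homogeneity Q ~ chi-square(k - 1); HetP is its upper tail.  k = 1
    returns (0, 1) by convention.
    """
    z = np.asarray(z_list, dtype=float)
    k = z.size
    if k == 0:
        raise ContractError("heterogeneity_test: empty input")
    if k == 1:
        return 0.0, 1.0
    if weights is None:
        resid = z - z.mean()
    else:
        w = _weights(weights=weights)
        if w.shape != z.shape:
            raise ContractError("heterogeneity_test: length mismatch")
        lam = np.sum(w * z) / np.sum(w**2)
        resid = z - w * lam
    q = float(np.sum(resid**2))
    het_p = float(stats.chi2.sf(q, df=k - 1))
    return q, het_p


def _study_weights(table: pd.DataFrame, scheme: str) -> np.ndarray:
    if scheme == "sqrt_n":
        return np.sqrt(table["n_total"].to_numpy(dtype=float))
    if scheme == "effective_n":
        n1 = table["n_case"].to_numpy(dtype=float)
        n2 = table["n_control"].to_numpy(dtype=float)
        return np.sqrt(4.0 / (1.0 / n1 + 1.0 / n2))
    raise DataError(f"weight_scheme: {scheme!r} not in {WEIGHT_SCHEMES}")


def run_meta(
    de_tables: list[pd.DataFrame],
    q_threshold: float = META_Q,
    min_studies: int = MIN_STUDIES,
    hetp_threshold: float = HETP,
    weight_scheme: str = "sqrt_n",
    fdr_scope: str = "all",
) -> tuple[pd.DataFrame, dict]:
    """Assemble per-gene meta-analysis records across studies.

    Parameters
    ----------
    de_tables
        Per-study DE tables (``gene, log2fc, p, n_case, n_control, n_total,
        study_id`` columns) from harmonized studies.
    q_threshold, min_studies, hetp_threshold
        The three inclusion criteria: q_meta <= q_threshold, measured in >=
        min_studies datasets, HetP > hetp_threshold.
    weight_scheme
        ``sqrt_n`` (default) or ``effective_n``.
    fdr_scope
        ``all`` computes BH over every gene with k >= 1 (criteria applied
        afterwards); ``min_studies`` restricts the BH universe to genes with
        k >= min_studies first.

    Returns the per-gene record table (one row per gene, sorted by p_meta)
    and a summary dict with entered/included/up/down counts and
    per-criterion exclusion tallies.
    """
    if not de_tables:
        raise ContractError("run_meta: no DE tables")
    rows = pd.concat(de_tables, ignore_index=True)
    if rows.duplicated(subset=["study_id", "gene"]).any():
        dup = rows[rows.duplicated(subset=["study_id", "gene"])].iloc[0]
        raise ContractError(
            f"run_meta: duplicate record for gene {dup['gene']!r} in study "
            f"{dup['study_id']!r} (harmonization bug upstream?)"
        )

    rows = rows.copy()
    rows["z"] = signed_z(rows["p"].to_numpy(), rows["log2fc"].to_numpy())
    rows["w"] = _study_weights(rows, weight_scheme)
    rows["wz"] = rows["w"] * rows["z"]
    rows["w2"] = rows["w"] ** 2

    g = rows.groupby("gene", sort=True)
    agg = g.agg(
        k=("z", "size"),
        sum_wz=("wz", "sum"),
        sum_w2=("w2", "sum"),
    )
    agg["z_meta"] = agg["sum_wz"] / np.sqrt(agg["sum_w2"])
    agg["p_meta"] = np.clip(2.0 * stats.norm.sf(np.abs(agg["z_meta"])), P_FLOOR, 1.0)

    # heterogeneity: residuals around the weighted per-gene fit
    lam = (agg["sum_wz"] / agg["sum_w2"]).reindex(rows["gene"]).to_numpy()
    rows["het_resid2"] = (rows["z"].to_numpy() - rows["w"].to_numpy() * lam) ** 2
    agg["q_het"] = rows.groupby("gene", sort=True)["het_resid2"].sum()
    single = agg["k"] == 1
    agg.loc[single, "q_het"] = 0.0
    agg["het_p"] = stats.chi2.sf(agg["q_het"], df=np.maximum(agg["k"] - 1, 1))
    agg.loc[single, "het_p"] = 1.0

    if fdr_scope == "min_studies":
        scope = agg["k"] >= min_studies
        agg["q_meta"] = np.nan
        agg.loc[scope, "q_meta"] = fdr_bh(agg.loc[scope, "p_meta"].to_numpy())
    elif fdr_scope == "all":
        agg["q_meta"] = fdr_bh(agg["p_meta"].to_numpy())
    else:
        raise DataError(f"fdr_scope: {fdr_scope!r} not in ('all', 'min_studies')")

    pass_q = agg["q_meta"] <= q_threshold
    pass_k = agg["k"] >= min_studies
    pass_het = agg["het_p"] > hetp_threshold
    agg["included"] = pass_q & pass_k & pass_het
    agg["direction"] = np.select(
        [agg["z_meta"] > 0, agg["z_meta"] < 0], ["up", "down"], default="none"
    )

    reasons = []
    for okq, okk, okh in zip(pass_q, pass_k, pass_het):
        r = []
        if not okq:
            r.append(f"q>{q_threshold}")
        if not okk:
            r.append("fewer than two datasets" if min_studies == 2 else f"k<{min_studies}")
        if not okh:
            r.append(f"HetP<={hetp_threshold}")
        reasons.append(";".join(r))
    agg["reason_excluded"] = reasons

    records = (
        agg.drop(columns=["sum_wz", "sum_w2"])
        .reset_index()
        .sort_values(["p_meta", "gene"], kind="mergesort")
        .reset_index(drop=True)
    )

    inc = records[records["included"]]
    summary = {
        "genes_entered": int(len(records)),
        "included": int(len(inc)),
        "up": int((inc["direction"] == "up").sum()),
        "down": int((inc["direction"] == "down").sum()),
        "excluded_q": int((~pass_q).sum()),
        "excluded_min_studies": int((~pass_k).sum()),
        "excluded_heterogeneity": int((~pass_het).sum()),
        "weight_scheme": weight_scheme,
        "thresholds": {
            "q_meta": q_threshold,
            "min_studies": min_studies,
            "het_p": hetp_threshold,
        },
    }
    return records, summary


def per_study_entries(de_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Long-format per-(study, gene) table with signed Z's, for reporting."""
    rows = pd.concat(de_tables, ignore_index=True).copy()
    rows["z"] = signed_z(rows["p"].to_numpy(), rows["log2fc"].to_numpy())
    return rows[["study_id", "gene", "log2fc", "p", "z", "n_total"]]
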