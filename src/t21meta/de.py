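"""Per-study differential expression: moderated t for arrays, NB LRT for counts.

Both engines emit the same per-gene contract — a log2 fold change (case minus
control), a two-sided p-value, and the study sample size — which is all the
downstream signed-Z meta-analysis consumes.

Array engine
    Classical empirical-Bayes moderated t.  Per-gene residual variances
    ``s_g^2`` (pooled two-group, ``d_g = n - 2`` df) are shrunk toward a
    prior ``s0^2`` with prior df ``d0``::

        s_tilde^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
        t = log2FC / sqrt(s_tilde^2 * (1/n1 + 1/n2)),   df = d0 + d_g

    ``(d0, s0^2)`` are estimated by moment matching on ``log s_g^2`` using
    the scaled-F model (log-chi-square mean/variance identities with digamma
    and trigamma); an observed log-variance spread at or below the sampling
    floor gives ``d0 = infinity`` (capped at 1e6, normal reference).

Count engine
    A deliberately simple negative-binomial likelihood-ratio test.  Library
    sizes are normalized as column-sum ratios to their geometric mean; a
    per-gene method-of-moments dispersion is shrunk toward the all-gene
    median; group means are fitted by Newton iterations on the NB likelihood
    with fixed dispersion, and the group effect is tested by LRT against
    chi-square(1).  This is not a re-implementation of quasi-likelihood
    F-tests — it is a documented simplification with the same input/output
    contract, calibrated by simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, DesignError
from .studies import ExpressionStudy

__all__ = ["moderated_t_de", "nb_count_de", "fdr_bh", "moderated_fit", "ModeratedFit"]

#: prior df value used to represent "infinite" shrinkage
D0_CAP = 1e6
#: p-values are clamped here so downstream normal quantiles stay finite
P_FLOOR = 1e-300


from dataclasses import dataclass


@dataclass
class ModeratedFit:
    """Empirical-Bayes variance model fitted across genes."""

    s2: np.ndarray          # per-gene pooled residual variance
    df_resid: float         # residual df d_g (common: n - 2)
    d0: float               # prior df (D0_CAP == infinity)
    s0_2: float             # prior variance
    s2_tilde: np.ndarray    # posterior (moderated) variance

    @property
    def df_total(self) -> float:
        return self.df_resid + self.d0


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log s_g^2 under the scaled-F model."""
    ok = s2 > 0
    z = np.log(s2[ok])
    if len(z) < 2:
        return D0_CAP, float(np.exp(z.mean())) if len(z) else 1.0
    zbar = float(z.mean())
    zvar = float(z.var(ddof=1))
    evar = zvar - float(special.polygamma(1, df_resid / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
    else:
        d0 = D0_CAP
    log_s0 = zbar - float(special.polygamma(0, df_resid / 2.0)) + np.log(df_resid / 2.0)
    if d0 < D0_CAP:
        log_s0 += float(special.polygamma(0, d0 / 2.0)) - np.log(d0 / 2.0)
    return float(d0), float(np.exp(log_s0))


def moderated_fit(
    study: ExpressionStudy,
    d0: float | None = None,
    s0_2: float | None = None,
) -> ModeratedFit:
    """Fit the empirical-Bayes variance model for an array study.

    ``d0``/``s0_2`` override the estimated prior (``d0=0`` recovers the
    ordinary pooled t; a huge ``d0`` is full shrinkage to ``s0_2``).
    """
    if study.n_case < 2 or study.n_control < 2:
        raise DesignError(f"{study.study_id}: need >=2 samples per group")
    vals = study.values.to_numpy(dtype=float)
    is_case = study.is_case
    case = vals[:, is_case]
    ctrl = vals[:, ~is_case]
    n1, n2 = case.shape[1], ctrl.shape[1]
    df_resid = float(n1 + n2 - 2)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    if d0 is None or s0_2 is None:
        d0_hat, s0_hat = _fit_variance_prior(s2, df_resid)
        d0 = d0_hat if d0 is None else d0
        s0_2 = s0_hat if s0_2 is None else s0_2
    d0 = min(float(d0), D0_CAP)
    if d0 <= 0:
        s2_tilde = s2.copy()
        d0 = 0.0
    else:
        s2_tilde = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
    return ModeratedFit(s2=s2, df_resid=df_resid, d0=d0, s0_2=float(s0_2), s2_tilde=s2_tilde)


def moderated_t_de(
    study: ExpressionStudy,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression for an array study.

    Returns one row per gene with columns ``study_id, gene, log2fc, p, stat,
    df, n_case, n_control, n_total, flag``.  Genes with zero variance in both
    groups get p = 1 and flag ``degenerate`` rather than an exception.
    """
    if study.platform != "array":
        raise DesignError(f"{study.study_id}: moderated_t_de expects an array study")
    fit = moderated_fit(study, d0=d0, s0_2=s0_2)
    vals = study.values.to_numpy(dtype=float)
    is_case = study.is_case
    n1 = int(is_case.sum())
    n2 = int((~is_case).sum())
    lfc = vals[:, is_case].mean(axis=1) - vals[:, ~is_case].mean(axis=1)

    se2 = fit.s2_tilde * (1.0 / n1 + 1.0 / n2)
    # zero variance in both groups: no evidence scale, reported p = 1
    degenerate = (fit.s2 <= 0) | (se2 <= 0)
    stat = np.zeros(len(lfc))
    p = np.ones(len(lfc))
    ok = ~degenerate
    stat[ok] = lfc[ok] / np.sqrt(se2[ok])
    if fit.df_total >= D0_CAP:
        p[ok] = 2.0 * stats.norm.sf(np.abs(stat[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df=fit.df_total)
    p = np.clip(p, P_FLOOR, 1.0)

    return pd.DataFrame(
        {
            "study_id": study.study_id,
            "gene": study.values.index,
            "log2fc": lfc,
            "p": p,
            "stat": stat,
            "df": fit.df_total,
            "n_case": n1,
            "n_control": n2,
            "n_total": n1 + n2,
            "flag": np.where(degenerate, "degenerate", ""),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# negative-binomial count engine
# ---------------------------------------------------------------------------


def _norm_factors(counts: np.ndarray) -> np.ndarray:
    """Per-sample size factors: column sums over their geometric mean."""
    lib = counts.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        raise DataError("nb_count_de: a sample has zero total counts")
    return lib / np.exp(np.mean(np.log(lib)))


def _moment_dispersion(counts: np.ndarray, sf: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion pooled across the two groups."""
    y = counts / sf[None, :]
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    df = 0.0
    for mask in (is_case, ~is_case):
        yk = y[:, mask]
        nk = mask.sum()
        m = yk.mean(axis=1)
        v = yk.var(axis=1, ddof=1)
        inv_sf = np.mean(1.0 / sf[mask])
        # Var(y/s) ~= mu * E[1/s] + phi * mu^2
        num += (nk - 1) * (v - m * inv_sf)
        den += (nk - 1) * m**2
        df += nk - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.clip(phi, 0.0, 10.0)


def _nb_fit_mean(
    counts: np.ndarray, sf: np.ndarray, phi: np.ndarray, n_iter: int = 40
) -> np.ndarray:
    """MLE of the per-gene mean (per unit size factor) with fixed dispersion.

    Newton iterations on eta = log(m); the Poisson-weighted start
    sum(y)/sum(s) is already exact for phi = 0 or equal size factors.
    """
    tot = counts.sum(axis=1)
    m = tot / sf.sum()
    pos = m > 0
    eta = np.where(pos, np.log(np.maximum(m, 1e-12)), -np.inf)
    phi = np.asarray(phi, dtype=float)
    for _ in range(n_iter):
        mu = np.exp(eta[:, None]) * sf[None, :]
        w = 1.0 + phi[:, None] * mu
        score = ((counts - mu) / w).sum(axis=1)
        info = (mu * (1.0 + phi[:, None] * counts) / w**2).sum(axis=1)
        step = np.where(pos & (info > 0), score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        if np.max(np.abs(step), initial=0.0) < 1e-12:
            break
    return np.where(pos, np.exp(eta), 0.0)


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson where phi == 0); 0*log(0) := 0."""
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(counts.shape[0])
    mu_safe = np.maximum(mu, 1e-300)
    pois = phi <= 1e-12
    if pois.any():
        y = counts[pois]
        m = mu[pois]
        term = np.where(y > 0, y * np.log(np.maximum(m, 1e-300)), 0.0)
        out[pois] = (term - m - special.gammaln(y + 1.0)).sum(axis=1)
    nb = ~pois
    if nb.any():
        y = counts[nb]
        r = (1.0 / phi[nb])[:, None]
        m = mu_safe[nb]
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + m))
            + y * np.log(m / (r + m))
        )
        out[nb] = ll.sum(axis=1)
    return out


def nb_count_de(
    study: ExpressionStudy,
    dispersion: float | None = None,
    prior_df: float = 20.0,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial LRT differential expression for a count study.

    ``dispersion`` fixes a common dispersion for all genes (0 = Poisson
    limit); by default a per-gene moment estimate is shrunk, with weight
    ``prior_df`` against the residual df, toward the across-gene mean of the
    per-gene estimates (the mean, unlike the median, is an unbiased pooled
    estimate of a common dispersion at these tiny group sizes, where the
    per-gene estimates are strongly right-skewed).  All-zero genes get
    log2fc = 0, p = 1 and flag ``all_zero``.
    """
    if study.platform != "rnaseq":
        raise DesignError(f"{study.study_id}: nb_count_de expects an rnaseq study")
    if study.n_case < 2 or study.n_control < 2:
        raise DesignError(f"{study.study_id}: need >=2 samples per group")
    counts = study.values.to_numpy(dtype=float)
    is_case = study.is_case
    sf = _norm_factors(counts)

    if dispersion is not None:
        phi = np.full(counts.shape[0], float(dispersion))
    else:
        phi_raw = _moment_dispersion(counts, sf, is_case)
        expressed = counts.sum(axis=1) > 0
        phi_pool = float(np.mean(phi_raw[expressed])) if expressed.any() else 0.0
        df_resid = study.n_total - 2
        w = prior_df / (prior_df + df_resid)
        phi = (1.0 - w) * phi_raw + w * phi_pool

    # null fit: one mean; alt fit: a mean per group (independent sub-fits)
    m_null = _nb_fit_mean(counts, sf, phi)
    m_case = _nb_fit_mean(counts[:, is_case], sf[is_case], phi)
    m_ctrl = _nb_fit_mean(counts[:, ~is_case], sf[~is_case], phi)

    ll_null = _nb_loglik(counts, m_null[:, None] * sf[None, :], phi)
    ll_alt = _nb_loglik(counts[:, is_case], m_case[:, None] * sf[None, is_case], phi) + _nb_loglik(
        counts[:, ~is_case], m_ctrl[:, None] * sf[None, ~is_case], phi
    )
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    lfc = np.log2(m_case + pseudo_count) - np.log2(m_ctrl + pseudo_count)
    all_zero = counts.sum(axis=1) == 0
    lfc[all_zero] = 0.0
    p[all_zero] = 1.0
    lrt[all_zero] = 0.0
    p = np.clip(p, P_FLOOR, 1.0)

    return pd.DataFrame(
        {
            "study_id": study.study_id,
            "gene": study.values.index,
            "log2fc": lfc,
            "p": p,
            "stat": lrt,
            "df": 1.0,
            "n_case": study.n_case,
            "n_control": study.n_control,
            "n_total": study.n_total,
            "flag": np.where(all_zero, "all_zero", ""),
        }
    ).reset_index(drop=True)


def run_de(study: ExpressionStudy) -> pd.DataFrame:
    """Dispatch to the platform's DE engine and append BH q-values."""
    table = moderated_t_de(study) if study.platform == "array" else nb_count_de(study)
    table["q"] = fdr_bh(table["p"].to_numpy())
    return table


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise DataError("fdr_bh: NaN p-value in input")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("fdr_bh: p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
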