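"""Carrier-cohort risk models: genotype tables, trend test, Cox regression.

Breast-cancer risk in germline mutation carriers is modelled with a Cox
proportional-hazards cohort model: per-allele (multiplicative) or
genotype (2-df) coding for single SNPs, and posterior-weighted haplotype
dosages for haplotype effects.  The partial likelihood (Breslow ties by
default, Efron optional, optional stratification by study and late entry)
is maximized by Newton-Raphson from beta = 0.

This is a standard cohort analysis: it does not adjust for the non-random
ascertainment of carriers with respect to phenotype or for familial
relationships, and estimates are labelled accordingly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import DataError, ModelError

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CarrierRecord:
    """One mutation carrier in the cohort.

    ``status`` is True for affected (event observed), False for unaffected
    (censored).  ``time`` is follow-up or age at diagnosis/censoring in
    years; ``entry_time`` supports left-truncated (age-interval) input.
    ``dosages`` optionally carries expected haplotype copy numbers from
    posterior phasing.
    """

    carrier_id: str
    study: str
    genotype: Optional[int]
    status: bool
    time: float
    entry_time: float = 0.0
    dosages: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise DataError(f"carrier {self.carrier_id}: time must be > 0")
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise DataError(
                f"carrier {self.carrier_id}: genotype must be 0/1/2 or missing"
            )
        if not 0 <= self.entry_time < self.time:
            raise DataError(
                f"carrier {self.carrier_id}: entry_time must lie in [0, time)"
            )


# ---------------------------------------------------------------------------
# Genotype-by-status bookkeeping


@dataclass(frozen=True)
class GenotypeStatusTable:
    counts: np.ndarray  # 3 genotypes x 2 status columns (unaffected, affected)
    percent: np.ndarray  # column percentages, 2 decimals
    n_unaffected: int
    n_affected: int

    @property
    def total(self) -> int:
        return self.n_unaffected + self.n_affected


def genotype_status_table(carriers: Sequence[CarrierRecord]) -> GenotypeStatusTable:
    """3x2 genotype-by-status counts with within-status column percentages."""
    counts = np.zeros((3, 2), dtype=int)
    for c in carriers:
        if c.genotype is None:
            continue
        counts[c.genotype, 1 if c.status else 0] += 1
    if counts.sum() == 0:
        raise DataError("all genotypes missing")
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.round(100.0 * counts / col_tot, 2)
    return GenotypeStatusTable(
        counts=counts,
        percent=percent,
        n_unaffected=int(col_tot[0]),
        n_affected=int(col_tot[1]),
    )


def trend_test(table: Union[GenotypeStatusTable, np.ndarray]) -> tuple[float, float]:
    """Cochran-Armitage trend test with scores (0, 1, 2).

    Z is signed positive when the affected column carries an excess of
    minor alleles; the p-value is two-sided normal.  Uses the permutation
    (hypergeometric) variance.
    """
    counts = table.counts if isinstance(table, GenotypeStatusTable) else np.asarray(table)
    if counts.shape != (3, 2):
        raise DataError(f"expected a 3x2 table, got {counts.shape}")
    n_g = counts.sum(axis=1).astype(float)
    affected = counts[:, 1].astype(float)
    N = counts.sum()
    R = affected.sum()
    if N == 0:
        raise ValueError("empty table")
    if R == 0 or R == N:
        raise ValueError("both status columns must be non-empty")
    t = np.array([0.0, 1.0, 2.0])
    u = float(t @ affected - (R / N) * (t @ n_g))
    s2 = float(t @ (t * n_g) - (t @ n_g) ** 2 / N)
    var = R * (N - R) / (N * (N - 1)) * s2
    if var <= 0:
        return 0.0, 1.0
    z = u / math.sqrt(var)
    return z, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _partial_likelihood_parts(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    entry: Optional[np.ndarray],
    strata: Optional[np.ndarray],
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score vector and information matrix."""
    n, p = X.shape
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    groups = (
        [np.arange(n)]
        if strata is None
        else [np.flatnonzero(strata == s) for s in np.unique(strata)]
    )
    eta = X @ beta
    w = np.exp(eta)
    for g in groups:
        tg, eg, Xg, wg, etag = time[g], event[g], X[g], w[g], eta[g]
        entg = entry[g] if entry is not None else None
        if entg is None and ties == "breslow":
            # fully vectorized: suffix sums on descending-time order give the
            # risk-set aggregates; every event (tied or not) uses the full
            # risk set at its time (Breslow)
            order = np.argsort(-tg, kind="stable")
            ts, Xs, ws = tg[order], Xg[order], wg[order]
            S0 = np.cumsum(ws)
            S1 = np.cumsum(ws[:, None] * Xs, axis=0)
            S2 = np.cumsum(ws[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
            te = tg[eg]
            k = np.searchsorted(-ts, -te, side="right") - 1
            s0 = S0[k]
            r1 = S1[k] / s0[:, None]
            ll += float(etag[eg].sum() - np.log(s0).sum())
            score += Xg[eg].sum(axis=0) - r1.sum(axis=0)
            info += (S2[k] / s0[:, None, None]).sum(axis=0) - np.einsum(
                "ep,eq->pq", r1, r1
            )
            continue
        event_times = np.unique(tg[eg])
        if entg is None:  # efron ties, moderate n: loop over tied groups
            order = np.argsort(-tg, kind="stable")
            ts, Xs, ws = tg[order], Xg[order], wg[order]
            S0 = np.cumsum(ws)
            S1 = np.cumsum(ws[:, None] * Xs, axis=0)
            S2 = np.cumsum(ws[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
            for t_ev in event_times:
                kk = int(np.searchsorted(-ts, -t_ev, side="right")) - 1
                d_idx = np.flatnonzero((tg == t_ev) & eg)
                d = len(d_idx)
                s0, s1, s2 = S0[kk], S1[kk], S2[kk]
                wd = wg[d_idx].sum()
                s1d = (wg[d_idx, None] * Xg[d_idx]).sum(axis=0)
                s2d = (
                    wg[d_idx, None, None]
                    * (Xg[d_idx, :, None] * Xg[d_idx, None, :])
                ).sum(axis=0)
                ll += float(etag[d_idx].sum())
                score += Xg[d_idx].sum(axis=0)
                for r in range(d):
                    f = r / d
                    s0r = s0 - f * wd
                    s1r = s1 - f * s1d
                    s2r = s2 - f * s2d
                    ll -= math.log(s0r)
                    score -= s1r / s0r
                    info += s2r / s0r - np.outer(s1r / s0r, s1r / s0r)
        else:
            for t_ev in event_times:
                at_risk = (entg < t_ev) & (tg >= t_ev)
                d_idx = np.flatnonzero((tg == t_ev) & eg)
                d = len(d_idx)
                wr = wg[at_risk]
                Xr = Xg[at_risk]
                s0 = wr.sum()
                s1 = (wr[:, None] * Xr).sum(axis=0)
                s2 = (wr[:, None, None] * (Xr[:, :, None] * Xr[:, None, :])).sum(axis=0)
                ll += float(etag[d_idx].sum()) - d * math.log(s0)
                score += Xg[d_idx].sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
    return ll, score, info


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    score_norm: float
    warnings: list[str] = field(default_factory=list)


def cox_fit(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    entry: Optional[np.ndarray] = None,
    strata: Optional[np.ndarray] = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson from beta = 0.

    Convergence when the score's max-norm drops below ``tol``.  A monotone
    likelihood (diverging beta) or non-convergence is flagged in
    ``warnings`` rather than raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    if not event.any():
        raise ModelError("no events in the data")
    if np.ptp(X, axis=0).min() == 0:
        raise ModelError("a covariate has no variation")

    p = X.shape[1]
    beta = np.zeros(p)
    ll_null, _, _ = _partial_likelihood_parts(
        beta, X, time, event, entry, strata, ties
    )
    ll = ll_null
    warnings: list[str] = []
    converged = False
    score_norm = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, info = _partial_likelihood_parts(
            beta, X, time, event, entry, strata, ties
        )
        score_norm = float(np.abs(score).max())
        if score_norm < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            warnings.append("singular information matrix")
            break
        # step halving against likelihood decrease
        for _ in range(20):
            cand = beta + step
            ll_new, _, _ = _partial_likelihood_parts(
                cand, X, time, event, entry, strata, ties
            )
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.abs(beta).max() > 50:
            warnings.append("monotone likelihood: estimate diverging")
            break
    if not converged and not warnings:
        warnings.append(f"Newton-Raphson did not converge in {max_iter} iterations")

    _, _, info = _partial_likelihood_parts(beta, X, time, event, entry, strata, ties)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    return CoxFit(beta, se, cov, float(ll), float(ll_null), it, converged,
                  score_norm, warnings)


def cox_score_test_at_zero(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    entry: Optional[np.ndarray] = None,
    strata: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Score (log-rank-type) chi-square test at beta = 0 and its p-value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    event = np.asarray(event, dtype=bool)
    _, score, info = _partial_likelihood_parts(
        np.zeros(X.shape[1]), X, np.asarray(time, float), event, entry, strata,
        "breslow",
    )
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(stats.chi2.sf(chi2, X.shape[1]))


# ---------------------------------------------------------------------------
# Model-level wrappers


@dataclass(frozen=True)
class HrTerm:
    name: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class RiskEstimate:
    model: str
    terms: list[HrTerm]
    loglik: float
    loglik_null: float
    lrt_p: Optional[float]
    n_by_cell: dict[str, int]
    converged: bool
    warnings: list[str]
    note: str = (
        "standard cohort analysis; not adjusted for ascertainment or kinship"
    )


def _carrier_arrays(carriers: Sequence[CarrierRecord]):
    recs = [c for c in carriers if c.genotype is not None]
    if not recs:
        raise DataError("no carriers with non-missing genotype")
    g = np.array([c.genotype for c in recs], dtype=float)
    time = np.array([c.time for c in recs])
    event = np.array([c.status for c in recs], dtype=bool)
    entry = np.array([c.entry_time for c in recs])
    if not entry.any():
        entry = None
    study = np.array([c.study for c in recs])
    return recs, g, time, event, entry, study


def _wald_terms(names: Sequence[str], beta: np.ndarray, se: np.ndarray) -> list[HrTerm]:
    terms = []
    for name, b, s in zip(names, beta, se):
        z = b / s if s > 0 else math.nan
        terms.append(
            HrTerm(
                name=name,
                hr=math.exp(b),
                ci_low=math.exp(b - Z_95 * s),
                ci_high=math.exp(b + Z_95 * s),
                p_value=float(2 * stats.norm.sf(abs(z))) if math.isfinite(z) else math.nan,
            )
        )
    return terms


def cox_per_allele(
    carriers: Sequence[CarrierRecord],
    coding: str = "additive",
    stratify_by_study: bool = False,
    ties: str = "breslow",
) -> RiskEstimate:
    """Per-allele (multiplicative) or genotype (2-df) Cox hazard ratios.

    ``additive`` fits one log-HR per minor-allele copy; ``2df`` fits
    separate heterozygote and rare-homozygote HRs against the common
    homozygote and adds a 2-df likelihood-ratio test.
    """
    recs, g, time, event, entry, study = _carrier_arrays(carriers)
    if not event.any() or event.all():
        raise ModelError("need at least one affected and one unaffected carrier")
    strata = study if stratify_by_study else None
    n_by_cell = {
        f"g{int(k)}_{'affected' if s else 'unaffected'}": int(
            ((g == k) & (event == s)).sum()
        )
        for k in (0, 1, 2)
        for s in (False, True)
    }
    if coding == "additive":
        fit = cox_fit(g[:, None], time, event, entry, strata, ties)
        terms = _wald_terms(["per_allele"], fit.beta, fit.se)
        lrt_p = None
    elif coding == "2df":
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        if np.ptp(X, axis=0).min() == 0:
            raise ModelError("a genotype class is absent; 2-df model not estimable")
        fit = cox_fit(X, time, event, entry, strata, ties)
        terms = _wald_terms(["het", "hom"], fit.beta, fit.se)
        lrt = 2 * (fit.loglik - fit.loglik_null)
        lrt_p = float(stats.chi2.sf(lrt, 2))
    else:
        raise ValueError(f"coding must be 'additive' or '2df', got {coding!r}")
    return RiskEstimate(
        model=f"per-allele ({coding})",
        terms=terms,
        loglik=fit.loglik,
        loglik_null=fit.loglik_null,
        lrt_p=lrt_p,
        n_by_cell=n_by_cell,
        converged=fit.converged,
        warnings=fit.warnings,
    )


def heterogeneity_test(
    carriers: Sequence[CarrierRecord], ties: str = "breslow"
) -> tuple[float, int, float]:
    """Likelihood-ratio test of study-specific versus shared log-HRs.

    Both models stratify the baseline hazard by study; the full model gives
    each eligible study its own per-allele log-HR.  Studies without genotype
    variation or without events contribute no degree of freedom (logged).
    Returns (LR statistic, df, p).
    """
    recs, g, time, event, entry, study = _carrier_arrays(carriers)
    eligible = []
    for s in np.unique(study):
        m = study == s
        if event[m].any() and np.ptp(g[m]) > 0:
            eligible.append(s)
        else:
            log.info("study %s contributes no df to heterogeneity test", s)
    if len(eligible) < 2:
        raise ModelError("heterogeneity test needs >= 2 informative studies")
    keep = np.isin(study, eligible)
    g, time, event, study = g[keep], time[keep], event[keep], study[keep]
    entry = entry[keep] if entry is not None else None
    shared = cox_fit(g[:, None], time, event, entry, study, ties)
    X_full = np.column_stack(
        [np.where(study == s, g, 0.0) for s in eligible]
    )
    full = cox_fit(X_full, time, event, entry, study, ties)
    lr = 2 * (full.loglik - shared.loglik)
    df = len(eligible) - 1
    return float(lr), df, float(stats.chi2.sf(lr, df))


def haplotype_cohort_assoc(
    carriers: Sequence[CarrierRecord],
    reference_hap: Union[str, Iterable[str]],
    stratify_by_study: bool = False,
    ties: str = "breslow",
) -> RiskEstimate:
    """Per-copy haplotype HRs versus a reference haplotype (or set).

    Each carrier's expected haplotype dosages (posterior-weighted copy
    numbers summing to 2) enter additively; reference dosages are excluded
    from the covariates, so each HR is per copy of that haplotype relative
    to carrying the reference.
    """
    reference = {reference_hap} if isinstance(reference_hap, str) else set(reference_hap)
    recs = [c for c in carriers if c.dosages is not None]
    if not recs:
        raise DataError("no carriers with haplotype dosages")
    haps = sorted({h for c in recs for h in c.dosages})
    if not reference & set(haps):
        raise ValueError(
            f"reference haplotype(s) {sorted(reference)} absent from cohort"
        )
    covariate_haps = [h for h in haps if h not in reference]
    X = np.array(
        [[c.dosages.get(h, 0.0) for h in covariate_haps] for c in recs]
    )
    keep_cols = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    if not keep_cols:
        raise ModelError("no estimable haplotype covariates (all reference)")
    dropped = [covariate_haps[j] for j in range(X.shape[1]) if j not in keep_cols]
    if dropped:
        log.info("haplotypes with no dosage variation dropped: %s", dropped)
    X = X[:, keep_cols]
    names = [covariate_haps[j] for j in keep_cols]
    time = np.array([c.time for c in recs])
    event = np.array([c.status for c in recs], dtype=bool)
    entry = np.array([c.entry_time for c in recs])
    entry = entry if entry.any() else None
    strata = np.array([c.study for c in recs]) if stratify_by_study else None
    if not event.any() or event.all():
        raise ModelError("need at least one affected and one unaffected carrier")
    fit = cox_fit(X, time, event, entry, strata, ties)
    return RiskEstimate(
        model=f"haplotype (reference {'+'.join(sorted(reference))})",
        terms=_wald_terms(names, fit.beta, fit.se),
        loglik=fit.loglik,
        loglik_null=fit.loglik_null,
        lrt_p=None,
        n_by_cell={"n": len(recs), "events": int(event.sum())},
        converged=fit.converged,
        warnings=fit.warnings,
    )
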