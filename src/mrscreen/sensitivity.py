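"""Heterogeneity and pleiotropy diagnostics for one instrument set.

Cochran's Q tests whether the per-SNP Wald ratios share one causal
effect; the Egger intercept tests for directional pleiotropy; MR-PRESSO
detects (and corrects for) individual pleiotropic outlier instruments
by a simulation-calibrated residual-sum-of-squares test; leave-one-out
checks that no single SNP drives the pooled estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import MREstimate, _ivw_core, _normal_estimate, ivw, mr_egger
from .harmonization import HarmonizedSet

logger = logging.getLogger("mrscreen")


@dataclass
class SensitivityReport:
    """All diagnostics for one exposure-outcome pair.

    Fields are ``None`` where the instrument count does not permit the
    test.  ``loo_table`` maps each left-out variant to its
    (beta, ci_low, ci_high) IVW estimate without it, plus an ``__all__``
    reference row.
    """

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    egger_pleiotropy_flag: bool | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] | None = None
    presso_distortion_pval: float | None = None
    presso_corrected: MREstimate | None = None
    loo_table: dict[str, tuple[float, float, float]] | None = None


def cochran_q(set_: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over the per-SNP Wald ratios.

    ``Q = sum w_j (theta_j - theta_ivw)^2`` with ``w_j = (bx_j/sy_j)^2``
    (inverse first-order ratio variances); p from chi-square, J - 1 df.
    """
    J = len(set_)
    if J < 2:
        raise ValueError(f"cochran_q needs >= 2 instruments, got {J}")
    bx, _, by, sy = set_.betas()
    _, _, q = _ivw_core(bx, by, sy)
    df = J - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, max(p, np.nextafter(0, 1))


def egger_intercept_test(set_: HarmonizedSet) -> tuple[float, float, float] | None:
    """The MR-Egger intercept triple (estimate, SE, p).

    An intercept p below 0.05 is the conventional flag for possible
    directional pleiotropy.  None when J < 3.
    """
    est = mr_egger(set_)
    if not est.available:
        return None
    ex = est.extras
    return ex["intercept"], ex["intercept_se"], ex["intercept_pval"]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    set_: HarmonizedSet, n_sim: int = 1000, seed: int = 0
) -> tuple[float, list[str], float | None, MREstimate | None]:
    """MR-PRESSO global, outlier and distortion tests.

    Global: the observed residual sum of squares uses leave-one-out
    predictions (SNP j's residual is taken against the slope fitted
    without j, weighted by 1/sy_j^2); the null distribution is built by
    simulating outcome betas from ``Normal(slope_-j * bx_j, sy_j^2)``
    and recomputing the RSS (including its leave-one-out slopes) n_sim
    times.  Empirical p-values use the (+1)/(+1) correction so they are
    never zero.  Outlier: per-SNP simulated squared-residual tails,
    Bonferroni-corrected across J.  Distortion: only run when outliers
    are flagged — the relative slope change after removing them is
    compared with the change from removing random same-size subsets.
    Returns (global_p, outlier ids, distortion_p or None, corrected IVW
    or None).
    """
    J = len(set_)
    if J < 4:
        raise ValueError(f"mr_presso needs >= 4 instruments, got {J}")
    if n_sim < 100:
        logger.warning("mr_presso: n_sim=%d is small; p-values will be coarse", n_sim)
    rng = np.random.default_rng(seed)
    # order-invariance: simulate in a canonical variant order
    order = np.argsort([h.variant_id for h in set_.instruments], kind="stable")
    bx, _, by, sy = set_.betas()
    bx, by, sy = bx[order], by[order], sy[order]
    ids = [set_.instruments[i].variant_id for i in order]
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    obs_res2 = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, J))
    sxy = np.sum(w * bx * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx**2)
    slopes_sim = (sxy - w * bx * by_sim) / (sxx - w * bx**2)
    res2_sim = w * (by_sim - slopes_sim * bx) ** 2
    rss_sim = res2_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_snp = (1 + np.sum(res2_sim >= obs_res2, axis=0)) / (1 + n_sim)
    p_snp_bonf = np.minimum(p_snp * J, 1.0)
    outliers = [ids[j] for j in range(J) if p_snp_bonf[j] < 0.05]

    distortion_p = None
    corrected = None
    if outliers and len(outliers) < J - 1:
        keep = np.array([v not in outliers for v in ids])
        theta_all, _, _ = _ivw_core(bx, by, sy)
        theta_corr, se_corr, q_corr = _ivw_core(bx[keep], by[keep], sy[keep])
        n_keep = int(keep.sum())
        scale = max(1.0, np.sqrt(q_corr / (n_keep - 1))) if n_keep > 1 else 1.0
        corrected = _normal_estimate("ivw", theta_corr, se_corr * scale, n_keep)
        d_obs = abs((theta_all - theta_corr) / theta_corr) if theta_corr != 0 else np.inf
        n_out = len(outliers)
        d_sim = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(J, size=n_out, replace=False)
            mask = np.ones(J, dtype=bool)
            mask[drop] = False
            t_s, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
            d_sim[s] = abs((theta_all - t_s) / t_s) if t_s != 0 else np.inf
        distortion_p = float((1 + np.sum(d_sim >= d_obs)) / (1 + n_sim))
    return global_p, outliers, distortion_p, corrected


def leave_one_out(set_: HarmonizedSet) -> dict[str, tuple[float, float, float]]:
    """IVW re-estimated with each instrument left out in turn.

    Keys are the left-out variant IDs plus an ``__all__`` reference row;
    values are (beta, ci_low, ci_high).  Requires J >= 3 so each reduced
    fit retains >= 2 instruments.
    """
    J = len(set_)
    if J < 3:
        raise ValueError(f"leave_one_out needs >= 3 instruments, got {J}")
    out: dict[str, tuple[float, float, float]] = {}
    full = ivw(set_)
    out["__all__"] = (full.beta, full.ci_low, full.ci_high)
    for i, inst in enumerate(set_.instruments):
        reduced = HarmonizedSet(
            exposure_id=set_.exposure_id,
            outcome_id=set_.outcome_id,
            instruments=set_.instruments[:i] + set_.instruments[i + 1 :],
        )
        est = ivw(reduced)
        out[inst.variant_id] = (est.beta, est.ci_low, est.ci_high)
    return out


def sensitivity_report(
    set_: HarmonizedSet, n_sim: int = 1000, seed: int = 0
) -> SensitivityReport:
    """Run every diagnostic the instrument count permits."""
    rep = SensitivityReport()
    J = len(set_)
    if J >= 2:
        rep.q_stat, rep.q_df, rep.q_pval = cochran_q(set_)
    if J >= 3:
        trip = egger_intercept_test(set_)
        if trip is not None:
            rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_pval = trip
            rep.egger_pleiotropy_flag = rep.egger_intercept_pval < 0.05
        rep.loo_table = leave_one_out(set_)
    if J >= 4:
        (
            rep.presso_global_pval,
            rep.presso_outliers,
            rep.presso_distortion_pval,
            rep.presso_corrected,
        ) = mr_presso(set_, n_sim=n_sim, seed=seed)
    return rep
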