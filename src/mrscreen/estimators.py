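"""Summary-statistics MR estimators.

Given J harmonized instruments with exposure effects ``bx_j`` (SE
``sx_j``) and outcome effects ``by_j`` (SE ``sy_j``), the causal effect
``theta`` of the exposure on the outcome is estimated by:

* Wald ratio (J = 1): ``by / bx``;
* inverse-variance weighted (IVW): the zero-intercept weighted
  regression of ``by`` on ``bx`` with weights ``1/sy^2``, with a
  multiplicative random-effects SE inflation floored at 1;
* MR-Egger: the same regression with a free intercept; the intercept
  absorbs directional pleiotropy (under the InSIDE assumption) and the
  slope remains a causal estimate;
* weighted median: consistent when instruments carrying up to half the
  total weight are invalid;
* cML-MA: constrained maximum likelihood profiling over the number K of
  invalid instruments, combined by BIC model averaging; robust to both
  correlated and uncorrelated pleiotropy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonization import HarmonizedInstrument, HarmonizedSet

Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate with 95% CI.

    ``extras`` carries method-specific fields: the Egger intercept
    triple, or cML-MA's selected invalid count and BIC weights.
    ``available`` is False when the method's instrument-count
    requirement is not met (never an exception in the pipeline).
    """

    method: str
    beta: float = float("nan")
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    pval: float = float("nan")
    n_snp: int = 0
    extras: dict = field(default_factory=dict)
    available: bool = True

    @classmethod
    def unavailable(cls, method: str, n_snp: int, reason: str) -> "MREstimate":
        return cls(method=method, n_snp=n_snp, available=False, extras={"reason": reason})


def _clip_p(p: float) -> float:
    return float(np.clip(p, np.nextafter(0, 1), 1.0))


def _normal_estimate(method: str, beta: float, se: float, n_snp: int, **extras) -> MREstimate:
    p = _clip_p(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=p,
        n_snp=n_snp,
        extras=dict(extras),
    )


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument estimate ``by / bx`` with first-order delta SE
    ``sy / |bx|``."""
    if inst.beta_exp == 0:
        raise ValueError(f"wald_ratio: exposure beta is zero for {inst.variant_id}")
    beta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    return _normal_estimate("wald", beta, se, 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, its SE, and Cochran's Q."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    ratios = by / bx
    wq = (bx / sy) ** 2
    q = float(np.sum(wq * (ratios - beta) ** 2))
    return float(beta), float(se_fixed), q


def ivw(set_: HarmonizedSet) -> MREstimate:
    """Random-effects IVW: fixed-effect slope, SE inflated by
    ``max(1, sqrt(Q / (J - 1)))`` (multiplicative random effects, never
    deflated)."""
    J = len(set_)
    if J < 2:
        raise ValueError(f"ivw needs >= 2 instruments, got {J}")
    bx, _, by, sy = set_.betas()
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    scale = max(1.0, np.sqrt(q / (J - 1)))
    est = _normal_estimate("ivw", beta, se_fixed * scale, J, cochran_q=q, re_scale=scale)
    return est


def egger_line_fit(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Closed-form weighted least squares line (slope, intercept).

    Exposed separately so the two-point algebra of the solver can be
    checked; the pipeline-facing :func:`mr_egger` requires J >= 3.
    """
    w = np.asarray(w, dtype=float)
    xbar = np.sum(w * bx) / np.sum(w)
    ybar = np.sum(w * by) / np.sum(w)
    slope = np.sum(w * (bx - xbar) * (by - ybar)) / np.sum(w * (bx - xbar) ** 2)
    return float(slope), float(ybar - slope * xbar)


def mr_egger(set_: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted regression of by on bx with a free
    intercept, instruments oriented so every bx >= 0.

    Slope and intercept inference use a t reference with J - 2 degrees
    of freedom; standard errors carry a multiplicative scale floored at
    1 (under-dispersion never shrinks them).  The intercept triple is
    stored in ``extras`` for the pleiotropy test.
    """
    import statsmodels.api as sm

    J = len(set_)
    if J < 3:
        return MREstimate.unavailable("egger", J, "needs >= 3 instruments")
    bx, _, by, sy = set_.betas()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    sigma = np.sqrt(fit.scale)
    # bse includes sigma; dividing by min(1, sigma) floors the scale at 1
    adj = min(1.0, sigma)
    inter, slope = fit.params
    se_inter, se_slope = fit.bse / adj
    df = J - 2
    p_slope = _clip_p(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_inter = _clip_p(2.0 * stats.t.sf(abs(inter) / se_inter, df))
    tcrit = stats.t.ppf(0.975, df)
    return MREstimate(
        method="egger",
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tcrit * se_slope),
        ci_high=float(slope + tcrit * se_slope),
        pval=p_slope,
        n_snp=J,
        extras={
            "intercept": float(inter),
            "intercept_se": float(se_inter),
            "intercept_pval": p_inter,
            "re_scale": max(1.0, float(sigma)),
        },
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[k] == 0.5:
        return float(r[k])
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def weighted_median(
    set_: HarmonizedSet, boot_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Ratios are weighted by the inverse of their first-order variance
    ``(sy / |bx|)^2``; the estimate interpolates the weighted empirical
    ratio distribution at probability one half.  The SE comes from a
    parametric bootstrap: resample bx and by from normals at their SEs,
    recompute the weighted median, take the standard deviation.
    """
    J = len(set_)
    if J < 3:
        return MREstimate.unavailable("weighted_median", J, "needs >= 3 instruments")
    bx, sx, by, sy = set_.betas()
    ratios = by / bx
    weights = (bx / sy) ** 2
    beta = _weighted_median_point(ratios, weights)

    if boot_reps > 0:
        rng = np.random.default_rng(seed)
        bx_b = rng.normal(bx, sx, size=(boot_reps, J))
        by_b = rng.normal(by, sy, size=(boot_reps, J))
        with np.errstate(divide="ignore", invalid="ignore"):
            est_b = np.array(
                [
                    _weighted_median_point(by_b[i] / bx_b[i], (bx_b[i] / sy) ** 2)
                    for i in range(boot_reps)
                ]
            )
        se = float(np.std(est_b, ddof=1))
    else:
        se = float("nan")
    if not np.isfinite(se) or se <= 0:
        return MREstimate(
            method="weighted_median", beta=beta, se=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), pval=float("nan"), n_snp=J,
        )
    return _normal_estimate("weighted_median", beta, se, J)


# ---------------------------------------------------------------------------
# cML-MA: constrained maximum likelihood with BIC model averaging

def _cml_profile_nll(theta: float, bx, sx, by, sy, valid: np.ndarray) -> float:
    """Profile negative log-likelihood (x2) over gamma at fixed theta.

    For valid instruments the per-SNP gamma profiles out to leave
    ``(by - theta bx)^2 / (sy^2 + theta^2 sx^2)``; invalid instruments
    contribute zero (their direct effect absorbs the residual).
    """
    v = valid
    return float(np.sum((by[v] - theta * bx[v]) ** 2 / (sy[v] ** 2 + theta**2 * sx[v] ** 2)))


def _cml_fit_K(
    bx, sx, by, sy, K: int, theta0: float, max_iter: int = 200, tol: float = 1e-10
) -> tuple[float, np.ndarray, bool]:
    """Block-coordinate fit at a fixed invalid count K.

    Alternates (i) selecting the K instruments whose profile-likelihood
    contribution at the current theta is largest (setting their direct
    effects to the residual removes exactly that contribution), and
    (ii) the closed-form theta and gamma updates on the valid set.
    Returns (theta, invalid mask, converged).
    """
    J = len(bx)
    theta = theta0
    invalid = np.zeros(J, dtype=bool)
    converged = False
    for _ in range(max_iter):
        contrib = (by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)
        new_invalid = np.zeros(J, dtype=bool)
        if K > 0:
            new_invalid[np.argsort(contrib, kind="stable")[-K:]] = True
        valid = ~new_invalid
        g = (bx[valid] / sx[valid] ** 2 + theta * by[valid] / sy[valid] ** 2) / (
            1.0 / sx[valid] ** 2 + theta**2 / sy[valid] ** 2
        )
        denom = np.sum(g**2 / sy[valid] ** 2)
        if denom == 0:
            break
        new_theta = float(np.sum(g * by[valid] / sy[valid] ** 2) / denom)
        if abs(new_theta - theta) < tol and np.array_equal(new_invalid, invalid):
            theta, invalid = new_theta, new_invalid
            converged = True
            break
        theta, invalid = new_theta, new_invalid
    return theta, invalid, converged


def _cml_se(theta: float, bx, sx, by, sy, valid: np.ndarray) -> float:
    """Asymptotic SE from the profile Fisher information over
    (theta, gamma_valid) at the constrained optimum."""
    v = valid
    g = (bx[v] / sx[v] ** 2 + theta * by[v] / sy[v] ** 2) / (
        1.0 / sx[v] ** 2 + theta**2 / sy[v] ** 2
    )
    h_tt = np.sum(g**2 / sy[v] ** 2)
    h_tg = (2.0 * theta * g - by[v]) / sy[v] ** 2
    h_gg = theta**2 / sy[v] ** 2 + 1.0 / sx[v] ** 2
    info = h_tt - np.sum(h_tg**2 / h_gg)
    if info <= 0:
        return float("inf")
    return float(1.0 / np.sqrt(info))


def cml_ma(
    set_: HarmonizedSet,
    max_invalid: int | None = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> MREstimate:
    """cML with BIC model averaging over the invalid-instrument count.

    For each K = 0..max_invalid (default J - 2) the constrained MLE is
    found by block-coordinate iteration with seeded multiple restarts;
    ``BIC(K) = nll(K) + K log J`` (nll on the 2x scale).  The reported
    estimate averages the per-K estimates with weights proportional to
    ``exp(-(BIC - min BIC) / 2)``; the SE combines per-K asymptotic
    variances with between-model dispersion (Buckland).  ``extras``
    records the BIC-minimizing invalid count, its flagged instruments,
    and the weight vector.
    """
    J = len(set_)
    if J < 3:
        return MREstimate.unavailable("cml_ma", J, "needs >= 3 instruments")
    bx, sx, by, sy = set_.betas()
    if max_invalid is None:
        max_invalid = J - 2
    max_invalid = min(max_invalid, J - 2)

    rng = np.random.default_rng(seed)
    theta_ivw, _, _ = _ivw_core(bx, by, sy)
    # restart spread on the scale of the data (keeps the optimizer
    # equivariant under rescaling of the outcome)
    spread = abs(theta_ivw) + float(np.std(by / bx))

    thetas, ses, bics, masks = [], [], [], []
    any_nonconv = False
    for K in range(max_invalid + 1):
        best = None
        starts = [theta_ivw] + list(theta_ivw + rng.normal(0, spread, n_restarts - 1))
        for theta0 in starts:
            theta_k, inv_k, conv = _cml_fit_K(bx, sx, by, sy, K, theta0)
            nll = _cml_profile_nll(theta_k, bx, sx, by, sy, ~inv_k)
            if best is None or nll < best[0]:
                best = (nll, theta_k, inv_k, conv)
        nll, theta_k, inv_k, conv = best
        if not conv:
            any_nonconv = True
        thetas.append(theta_k)
        ses.append(_cml_se(theta_k, bx, sx, by, sy, ~inv_k))
        bics.append(nll + K * np.log(J))
        masks.append(inv_k)

    thetas = np.array(thetas)
    ses = np.array(ses)
    bics = np.array(bics)
    w = np.exp(-(bics - bics.min()) / 2.0)
    w /= w.sum()
    beta = float(np.sum(w * thetas))
    se = float(np.sum(w * np.sqrt(ses**2 + (thetas - beta) ** 2)))
    k_hat = int(np.argmin(bics))
    est = _normal_estimate(
        "cml_ma", beta, se, J,
        k_hat=k_hat,
        bic_weights=w.tolist(),
        invalid_at_k_hat=[
            set_.instruments[j].variant_id for j in np.flatnonzero(masks[k_hat])
        ],
        converged=not any_nonconv,
    )
    return est


def cml_bruteforce_K(
    bx, sx, by, sy, K: int, grid: np.ndarray
) -> tuple[float, tuple[int, ...], float]:
    """Exhaustive oracle for the constrained optimum at fixed K.

    Enumerates every invalid subset of size K and profiles the
    likelihood over theta on a dense grid.  Only feasible for small J;
    used to validate :func:`cml_ma`, never by the pipeline.
    """
    J = len(bx)
    best = (np.inf, (), np.nan)
    for subset in itertools.combinations(range(J), K):
        valid = np.ones(J, dtype=bool)
        valid[list(subset)] = False
        nlls = [
            _cml_profile_nll(t, np.asarray(bx), np.asarray(sx), np.asarray(by), np.asarray(sy), valid)
            for t in grid
        ]
        i = int(np.argmin(nlls))
        if nlls[i] < best[0]:
            best = (nlls[i], subset, float(grid[i]))
    return best


def all_estimates(
    set_: HarmonizedSet, boot_reps: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """Every estimator applicable at this instrument count.

    J = 1: Wald ratio only.  J = 2: IVW only (Egger with two points is
    saturated).  J >= 3: IVW, Egger, weighted median and cML-MA.
    """
    J = len(set_)
    if J == 0:
        return []
    if J == 1:
        return [wald_ratio(set_.instruments[0])]
    out = [ivw(set_)]
    out.append(mr_egger(set_))
    out.append(weighted_median(set_, boot_reps=boot_reps, seed=seed))
    out.append(cml_ma(set_, seed=seed))
    return [e for e in out if e.available]
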