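"""The genome-wide screen: every exposure against every outcome.

Per pair: select instruments, harmonize, run every applicable
estimator and diagnostic, take the IVW (or Wald) p-value as primary,
then control the false discovery rate across exposures with Storey
q-values.  A pair is *significant* when q < 0.1, *nominal* when
p < 0.05 but q >= 0.1, *null* otherwise, and *untestable* when no
instrument survives selection and harmonization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import MREstimate, all_estimates
from .harmonization import HarmonizedSet, harmonize
from .instruments import select_instruments
from .sensitivity import SensitivityReport, sensitivity_report
from .sumstats_io import LDTable, ScreenConfig, SumstatsTable

logger = logging.getLogger("mrscreen")

SIGNIFICANT = "significant"
NOMINAL = "nominal"
NULL = "null"
UNTESTABLE = "untestable"


@dataclass
class ScreenResult:
    exposure_id: str
    outcome_id: str
    estimates: list[MREstimate] = field(default_factory=list)
    sensitivity: SensitivityReport | None = None
    instruments: HarmonizedSet | None = None
    primary_pval: float | None = None
    qval: float | None = None
    classification: str = UNTESTABLE

    @property
    def primary_estimate(self) -> MREstimate | None:
        for est in self.estimates:
            if est.method in ("ivw", "wald"):
                return est
        return None


@dataclass
class OverlapSummary:
    """Cross-outcome association counts per exposure, the exposures
    meeting the count threshold, and their IVW beta matrix."""

    counts: dict[str, int]
    selected: list[str]
    beta_matrix: pd.DataFrame


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the smoother estimate of pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on
    lambda = 0.05, 0.10, ..., 0.95, smoothed by a natural cubic
    smoothing spline, taken at the largest lambda, and clipped to
    (0, 1].  ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the
    ascending order statistics.  With ``pi0`` forced to 1 the result is
    exactly the Benjamini-Hochberg adjusted p-values.  Fewer than 20
    p-values falls back to pi0 = 1 with a warning (the spline is
    unstable on tiny families).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("storey_qvalues: empty p-value collection")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size

    if pi0 is None:
        if m < 20:
            logger.warning(
                "storey_qvalues: only %d p-values; falling back to pi0 = 1 (BH)", m
            )
            pi0 = 1.0
        else:
            lambdas = np.arange(0.05, 0.96, 0.05)
            pi0_l = np.array(
                [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
            )
            from scipy.interpolate import make_smoothing_spline

            spline = make_smoothing_spline(lambdas, pi0_l)
            pi0 = float(spline(lambdas[-1]))
            pi0 = float(np.clip(pi0, np.nextafter(0, 1), 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_ranked = pi0 * m * ranked / np.arange(1, m + 1)
    q_ranked = np.minimum.accumulate(q_ranked[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return q


def screen_pair(
    exposure: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDTable | None,
    exclusions: set[str] | None,
    cfg: ScreenConfig,
) -> ScreenResult:
    """Select, harmonize, estimate and diagnose one exposure-outcome pair."""
    res = ScreenResult(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)
    inst = select_instruments(exposure, outcome, ld, exclusions, cfg)
    if len(inst) == 0:
        return res
    hset = harmonize(
        inst,
        outcome,
        resolve_strand_flips=cfg.resolve_strand_flips,
        palindromic_maf_rescue=cfg.palindromic_maf_rescue,
    )
    res.instruments = hset
    if len(hset) == 0:
        return res
    res.estimates = all_estimates(hset, boot_reps=cfg.boot_reps, seed=cfg.seed)
    if len(hset) >= 2:
        res.sensitivity = sensitivity_report(hset, n_sim=cfg.presso_n_sim, seed=cfg.seed)
    primary = res.primary_estimate
    if primary is not None:
        res.primary_pval = primary.pval
        res.classification = NULL  # refined after q-values
    return res


def run_screen(
    exposures: list[SumstatsTable],
    outcomes: list[SumstatsTable],
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
    cfg: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Screen every exposure against every outcome and classify.

    Iteration order is deterministic (sorted trait IDs).  A failure in
    one pair is caught, logged, and recorded as untestable; it never
    aborts the screen.  q-values are computed per outcome across the
    testable exposures by default (``cfg.qvalue_family='pooled'``
    corrects across all pairs at once).
    """
    if not exposures:
        raise ValueError("run_screen: empty exposure collection")
    if not outcomes:
        raise ValueError("run_screen: empty outcome collection")
    cfg = cfg or ScreenConfig()

    results: list[ScreenResult] = []
    for outcome in sorted(outcomes, key=lambda t: t.trait_id):
        for exposure in sorted(exposures, key=lambda t: t.trait_id):
            try:
                res = screen_pair(exposure, outcome, ld, exclusions, cfg)
            except Exception:
                logger.exception(
                    "pair %s x %s failed; marked untestable",
                    exposure.trait_id, outcome.trait_id,
                )
                res = ScreenResult(
                    exposure_id=exposure.trait_id, outcome_id=outcome.trait_id
                )
            results.append(res)

    if cfg.qvalue_family == "pooled":
        families: dict[str, list[ScreenResult]] = {"__all__": results}
    else:
        families = {}
        for res in results:
            families.setdefault(res.outcome_id, []).append(res)
    for fam in families.values():
        testable = [r for r in fam if r.primary_pval is not None]
        if not testable:
            continue
        qvals = storey_qvalues([r.primary_pval for r in testable])
        for r, q in zip(testable, qvals):
            r.qval = float(q)
            if r.qval < cfg.q_significant:
                r.classification = SIGNIFICANT
            elif r.primary_pval < cfg.p_nominal:
                r.classification = NOMINAL
            else:
                r.classification = NULL
    return results


def summarize_overlaps(
    results: list[ScreenResult], min_outcomes: int = 4
) -> OverlapSummary:
    """Count nominal-or-better outcomes per exposure and select the
    exposures associated with at least ``min_outcomes`` of them.

    The returned beta matrix (selected exposures x outcomes, IVW betas)
    backs the cross-outcome effect-direction heatmap.
    """
    counts: dict[str, int] = {}
    outcome_ids: list[str] = []
    betas: dict[tuple[str, str], float] = {}
    for res in results:
        counts.setdefault(res.exposure_id, 0)
        if res.outcome_id not in outcome_ids:
            outcome_ids.append(res.outcome_id)
        if res.classification in (NOMINAL, SIGNIFICANT):
            counts[res.exposure_id] += 1
        primary = res.primary_estimate
        if primary is not None:
            betas[(res.exposure_id, res.outcome_id)] = primary.beta
    selected = sorted(e for e, c in counts.items() if c >= min_outcomes)
    mat = pd.DataFrame(index=selected, columns=sorted(outcome_ids), dtype=float)
    for e in selected:
        for o in outcome_ids:
            if (e, o) in betas:
                mat.loc[e, o] = betas[(e, o)]
    return OverlapSummary(counts=counts, selected=selected, beta_matrix=mat)
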