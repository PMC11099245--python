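"""Instrumental-variable selection for one exposure.

The filter cascade is fixed and logged: (1) p-value threshold with a
relaxed-tier fallback, (2) greedy LD clumping, (3) user-supplied
confounder exclusions, (4) removal of variants associated with the
outcome, (5) weak-instrument removal via the per-SNP F statistic
``F = R^2 (N - 1 - K) / ((1 - R^2) K)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sumstats_io import LDTable, ScreenConfig, SumstatsTable, VariantAssociation

logger = logging.getLogger("mrscreen")


@dataclass
class InstrumentSet:
    """The retained instruments for one exposure, with strength metrics
    and a per-stage removal log."""

    exposure_id: str
    variants: list[VariantAssociation]
    per_snp_r2: dict[str, float] = field(default_factory=dict)
    per_snp_F: dict[str, float] = field(default_factory=dict)
    selection_log: dict[str, int] = field(default_factory=dict)
    pval_tier: str = "primary"  # "primary" | "relaxed"

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def aggregate_F(self) -> float | None:
        """Set-level F using total R-squared and K = set size; reported
        for information alongside the per-SNP (K=1) values."""
        if not self.variants:
            return None
        r2_total = min(sum(self.per_snp_r2.values()), 1.0 - 1e-12)
        n = min(v.n for v in self.variants if v.n is not None)
        k = len(self.variants)
        if n is None or n <= k + 1:
            return None
        return f_statistic(r2_total, int(n), k)


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F statistic: ``R^2 (N - 1 - K) / ((1 - R^2) K)``.

    ``r2`` is the variance in the exposure explained by the K variants,
    ``n`` the exposure-GWAS sample size.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    return (r2 * (n - 1 - k)) / ((1.0 - r2) * k)


def estimate_r2(v: VariantAssociation) -> float:
    """Per-SNP variance explained from summary statistics.

    With an effect-allele frequency: ``R^2 = 2 eaf (1 - eaf) beta^2``
    (standardized-trait convention).  Without one: ``R^2 = t^2 / (t^2 +
    n - 2)`` with ``t = beta / se``.  Requires a sample size in the
    latter case.
    """
    if v.eaf is not None:
        return 2.0 * v.eaf * (1.0 - v.eaf) * v.beta**2
    if v.n is not None and v.n > 2:
        t2 = (v.beta / v.se) ** 2
        return t2 / (t2 + v.n - 2)
    raise ValueError(f"variant {v.variant_id}: need eaf or sample size to estimate R^2")


def clump_greedy(
    candidates: list[VariantAssociation],
    ld: LDTable | None,
    window_bp: int = 10_000_000,
    r2_max: float = 0.001,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the most significant variant, discard
    linked neighbours, repeat.

    Variants are ranked by ascending p (ties broken by variant ID); a
    discarded neighbour is one on the same chromosome within
    ``window_bp`` whose r-squared with the kept index variant is at
    least ``r2_max``.  Without an LD table all candidates are kept and a
    prominent warning is logged.  Output preserves the rank order.
    """
    if ld is None:
        logger.warning(
            "clump_greedy: no LD table supplied — clumping skipped, all %d candidates kept",
            len(candidates),
        )
        return list(candidates)

    def _chrom_pos(v: VariantAssociation) -> tuple[str | None, int | None]:
        if v.variant_id in ld.positions:
            return ld.positions[v.variant_id]
        return v.chrom, v.pos

    ranked = sorted(candidates, key=lambda v: (v.pval, v.variant_id))
    retained: list[VariantAssociation] = []
    removed: set[str] = set()
    for v in ranked:
        if v.variant_id in removed:
            continue
        retained.append(v)
        v_chrom, v_pos = _chrom_pos(v)
        for u in ranked:
            if u.variant_id in removed or u.variant_id == v.variant_id:
                continue
            u_chrom, u_pos = _chrom_pos(u)
            in_window = (
                v_chrom is not None
                and v_chrom == u_chrom
                and v_pos is not None
                and u_pos is not None
                and abs(v_pos - u_pos) <= window_bp
            )
            if in_window and ld.r2(v.variant_id, u.variant_id) >= r2_max:
                removed.add(u.variant_id)
    return retained


def select_instruments(
    exposure: SumstatsTable,
    outcome: SumstatsTable | None,
    ld: LDTable | None = None,
    exclusions: set[str] | None = None,
    cfg: ScreenConfig | None = None,
) -> InstrumentSet:
    """Run the full instrument-selection cascade for one exposure.

    Stage 1 keeps variants with p below the primary threshold; if fewer
    than ``cfg.min_snps`` survive (or ``fallback_mode='always_relaxed'``)
    the relaxed threshold is used instead and the tier is recorded.
    Stages 2-5: clump, drop excluded variants, drop variants associated
    with the outcome, drop weak instruments (per-SNP F <= f_min, K=1).
    An empty result is valid — the pair is reported untestable downstream.
    """
    if not exposure.records:
        raise ValueError(f"exposure table {exposure.trait_id!r} is empty")
    cfg = cfg or ScreenConfig()
    exclusions = exclusions or set()
    log: dict[str, int] = {"input": len(exposure.records)}

    primary = [v for v in exposure.records if v.pval < cfg.p_primary]
    if cfg.fallback_mode == "always_relaxed" or len(primary) < cfg.min_snps:
        tier = "relaxed"
        kept = [v for v in exposure.records if v.pval < cfg.p_relaxed]
    else:
        tier = "primary"
        kept = primary
    log["pval_threshold_removed"] = len(exposure.records) - len(kept)

    clumped = clump_greedy(kept, ld, cfg.clump_window_bp, cfg.clump_r2)
    log["clump_removed"] = len(kept) - len(clumped)

    after_excl = [v for v in clumped if v.variant_id not in exclusions]
    log["exclusion_removed"] = len(clumped) - len(after_excl)

    if outcome is not None:
        out_p = {r.variant_id: r.pval for r in outcome.records}
        after_out = [
            v
            for v in after_excl
            if not (v.variant_id in out_p and out_p[v.variant_id] < cfg.outcome_assoc_p)
        ]
    else:
        after_out = after_excl
    log["outcome_assoc_removed"] = len(after_excl) - len(after_out)

    per_r2: dict[str, float] = {}
    per_f: dict[str, float] = {}
    strong: list[VariantAssociation] = []
    for v in after_out:
        r2 = estimate_r2(v)
        n = int(v.n) if v.n is not None else None
        if n is None or n <= 2 or r2 >= 1.0:
            continue
        f = f_statistic(min(r2, 1.0 - 1e-12), n, 1)
        if f > cfg.f_min:
            strong.append(v)
            per_r2[v.variant_id] = r2
            per_f[v.variant_id] = f
    log["weak_F_removed"] = len(after_out) - len(strong)
    log["retained"] = len(strong)

    logger.info(
        "%s: %d -> %d instruments (tier=%s; removed: p=%d clump=%d excl=%d outcome=%d weakF=%d)",
        exposure.trait_id, log["input"], log["retained"], tier,
        log["pval_threshold_removed"], log["clump_removed"],
        log["exclusion_removed"], log["outcome_assoc_removed"], log["weak_F_removed"],
    )
    return InstrumentSet(
        exposure_id=exposure.trait_id,
        variants=strong,
        per_snp_r2=per_r2,
        per_snp_F=per_f,
        selection_log=log,
        pval_tier=tier,
    )
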