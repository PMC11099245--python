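"""Allele harmonization of exposure and outcome summary statistics.

Both sides of each instrument must report effects for the same effect
allele.  Per variant present in both tables:

* same allele pair, same orientation — kept as is;
* same pair, swapped orientation — outcome beta negated, outcome eaf
  mirrored (``sign_flipped``);
* pair matches only after A<->T / C<->G complementation — complemented,
  then resolved as above (``strand_flipped``), if enabled;
* palindromic pair (A/T or C/G) — dropped outright by default, because
  strand cannot be resolved from alleles alone;
* anything else (including indels) — ``dropped_mismatch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .instruments import InstrumentSet
from .sumstats_io import SumstatsTable

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT = "kept"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
DROPPED_ABSENT = "dropped_absent_from_outcome"


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One variant's paired exposure/outcome effects on a common effect
    allele — the atomic MR input."""

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    action_taken: str = KEPT


@dataclass
class HarmonizedSet:
    """The retained instruments for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    instruments: list[HarmonizedInstrument]
    drop_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    def betas(self):
        """(beta_exp, se_exp, beta_out, se_out) arrays for estimators."""
        import numpy as np

        return (
            np.array([h.beta_exp for h in self.instruments]),
            np.array([h.se_exp for h in self.instruments]),
            np.array([h.beta_out for h in self.instruments]),
            np.array([h.se_out for h in self.instruments]),
        )


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def harmonize(
    exposure_snps: InstrumentSet,
    outcome: SumstatsTable,
    resolve_strand_flips: bool = True,
    palindromic_maf_rescue: float | None = None,
) -> HarmonizedSet:
    """Harmonize selected exposure instruments against an outcome table.

    ``palindromic_maf_rescue`` optionally keeps a palindromic SNP when
    both frequencies are on the same side of 0.5 and at least that far
    from it (off — ``None`` — by default, i.e. palindromes are always
    dropped).  SEs and effect magnitudes are never altered; only signs
    and frequencies change.
    """
    out_idx = {r.variant_id: r for r in outcome.records}
    kept: list[HarmonizedInstrument] = []
    log: dict[str, int] = {}

    def _count(action: str) -> None:
        log[action] = log.get(action, 0) + 1

    for ev in exposure_snps.variants:
        ov = out_idx.get(ev.variant_id)
        if ov is None:
            _count(DROPPED_ABSENT)
            continue
        if not ev.is_snp() or not ov.is_snp():
            _count(DROPPED_MISMATCH)
            continue

        e_pair = (ev.effect_allele, ev.other_allele)
        if is_palindromic(*e_pair):
            rescued = False
            if palindromic_maf_rescue is not None and ev.eaf is not None and ov.eaf is not None:
                d = palindromic_maf_rescue
                same_side = (ev.eaf - 0.5) * (ov.eaf - 0.5) > 0
                informative = abs(ev.eaf - 0.5) >= d and abs(ov.eaf - 0.5) >= d
                rescued = same_side and informative
            if not rescued:
                _count(DROPPED_PALINDROMIC)
                continue

        o_ea, o_oa, o_beta, o_eaf = ov.effect_allele, ov.other_allele, ov.beta, ov.eaf
        action = KEPT
        if (o_ea, o_oa) != e_pair and (o_oa, o_ea) != e_pair:
            c_ea, c_oa = COMPLEMENT.get(o_ea), COMPLEMENT.get(o_oa)
            if resolve_strand_flips and (c_ea, c_oa) in (e_pair, e_pair[::-1]):
                o_ea, o_oa = c_ea, c_oa
                action = STRAND_FLIPPED
            else:
                _count(DROPPED_MISMATCH)
                continue
        if (o_ea, o_oa) == (e_pair[1], e_pair[0]):
            o_beta = -o_beta
            o_eaf = None if o_eaf is None else 1.0 - o_eaf
            action = SIGN_FLIPPED if action == KEPT else STRAND_FLIPPED

        kept.append(
            HarmonizedInstrument(
                variant_id=ev.variant_id,
                effect_allele=ev.effect_allele,
                beta_exp=ev.beta,
                se_exp=ev.se,
                beta_out=o_beta,
                se_out=ov.se,
                eaf_exp=ev.eaf,
                eaf_out=o_eaf,
                action_taken=action,
            )
        )
        _count(action)

    return HarmonizedSet(
        exposure_id=exposure_snps.exposure_id,
        outcome_id=outcome.trait_id,
        instruments=kept,
        drop_log=log,
    )
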