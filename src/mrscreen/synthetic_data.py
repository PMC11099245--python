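"""Synthetic paired exposure/outcome summary statistics with known truth.

The generator emulates the structure of a miRNA-eQTL-to-disease
two-sample MR screen: many exposures (miRNAs) each instrumented by a
handful of cis-eQTL SNPs, and outcome GWAS summary statistics in which
each SNP's effect is ``theta * gamma_j + alpha_j`` — a causal part
through the exposure plus an optional direct (pleiotropic) part.

Traits are simulated on the standardized scale, so the sampling
variance of an estimated per-allele effect is
``1 / (2 * eaf * (1 - eaf) * n)``; this gives the instrument-strength
statistics (R-squared, F) closed forms that tests can verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats_io import LDTable, SumstatsTable, VariantAssociation

PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "correlated")


@dataclass
class DistSpec:
    """Mean and SD of a normal effect-size distribution."""

    mean: float = 0.0
    sd: float = 0.0


@dataclass
class LDBlockSpec:
    """Blocks of adjacent SNPs sharing within-block LD of ``r2``."""

    block_size: int = 2
    r2: float = 0.5


@dataclass
class SimulationScenario:
    """Data-generating conditions for one simulated screen.

    Defaults reflect the emulated study: a modest eQTL discovery cohort
    (n=710), large outcome GWAS, a few strong cis instruments per
    exposure, and no pleiotropy unless requested.
    """

    n_exposures: int = 1
    snps_per_exposure: int = 10
    theta: float | list[float] = 0.0
    gamma_dist: DistSpec = field(default_factory=lambda: DistSpec(mean=0.35, sd=0.05))
    n_exp: int = 710
    n_out: int = 50_000
    pleiotropy_mode: str = "none"
    pleiotropy_frac: float = 0.0
    alpha_dist: DistSpec = field(default_factory=lambda: DistSpec(mean=0.0, sd=0.05))
    palindromic_frac: float = 0.0
    ld_blocks: LDBlockSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0,1]")
        if not (0.0 <= self.palindromic_frac <= 1.0):
            raise ValueError("palindromic_frac must be in [0,1]")
        if self.n_exp <= 1 or self.n_out <= 1:
            raise ValueError("sample sizes must exceed 1")
        if self.pleiotropy_frac > 0 and self.pleiotropy_mode == "none":
            raise ValueError("pleiotropy_frac > 0 contradicts pleiotropy_mode='none'")

    def theta_for(self, i: int) -> float:
        if isinstance(self.theta, (int, float)):
            return float(self.theta)
        return float(self.theta[i])


@dataclass
class SimulationTruth:
    """Ground truth per simulated SNP, keyed in table order per exposure."""

    gamma: dict[str, np.ndarray]  # exposure_id -> true SNP-exposure effects
    alpha: dict[str, np.ndarray]  # exposure_id -> true direct SNP-outcome effects
    theta: dict[str, float]  # exposure_id -> true causal effect
    invalid: dict[str, np.ndarray]  # exposure_id -> boolean invalid-instrument mask
    variant_ids: dict[str, list[str]]


def _se_standardized(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(beta) / se)
    # p-value invariant requires p in (0, 1]
    return np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_pair(
    scenario: SimulationScenario,
) -> tuple[list[SumstatsTable], SumstatsTable, SimulationTruth, LDTable | None]:
    """Simulate exposure tables, one shared outcome table, and the truth.

    Per SNP j of exposure i:
    ``beta_exp ~ N(gamma_j, se_exp^2)``, ``beta_out ~ N(theta_i * gamma_j
    + alpha_j, se_out^2)`` with standardized-trait SEs.  The outcome
    table's allele orientation is randomly swapped relative to the
    exposure (beta negated, eaf mirrored) so harmonization is always
    exercised.  A fraction ``palindromic_frac`` of SNPs get A/T or C/G
    allele pairs.  With ``ld_blocks`` set, sampling errors are correlated
    within blocks at the requested r-squared and an LD table is returned.

    Fully reproducible from ``scenario.seed``: each exposure draws from
    its own deterministic substream.
    """
    root = np.random.SeedSequence(scenario.seed)
    substreams = root.spawn(scenario.n_exposures)

    exposures: list[SumstatsTable] = []
    outcome_records: list[VariantAssociation] = []
    truth = SimulationTruth(gamma={}, alpha={}, theta={}, invalid={}, variant_ids={})
    ld = LDTable() if scenario.ld_blocks is not None else None

    snp_counter = 0
    for i in range(scenario.n_exposures):
        rng = np.random.default_rng(substreams[i])
        J = scenario.snps_per_exposure
        exp_id = f"exp{i:04d}"
        theta_i = scenario.theta_for(i)

        eaf = rng.uniform(0.05, 0.5, size=J)
        gamma = rng.normal(scenario.gamma_dist.mean, scenario.gamma_dist.sd, size=J)
        invalid = np.zeros(J, dtype=bool)
        alpha = np.zeros(J)
        if scenario.pleiotropy_mode != "none" and scenario.pleiotropy_frac > 0:
            n_invalid = int(round(scenario.pleiotropy_frac * J))
            invalid[rng.choice(J, size=n_invalid, replace=False)] = True
            a = scenario.alpha_dist
            if scenario.pleiotropy_mode == "balanced":
                alpha[invalid] = rng.normal(0.0, max(a.sd, abs(a.mean)), size=n_invalid)
            elif scenario.pleiotropy_mode == "directional":
                alpha[invalid] = rng.normal(a.mean, a.sd, size=n_invalid)
            else:  # correlated: direct effect tracks instrument strength
                gm = scenario.gamma_dist.mean
                slope = a.mean / gm if gm != 0 else 1.0
                alpha[invalid] = slope * gamma[invalid] + rng.normal(0.0, a.sd, size=n_invalid)

        se_exp = _se_standardized(eaf, scenario.n_exp)
        se_out = _se_standardized(eaf, scenario.n_out)

        z_exp = rng.standard_normal(J)
        z_out = rng.standard_normal(J)
        if scenario.ld_blocks is not None:
            # shared block factor induces the requested within-block
            # correlation of the sampling errors (test statistics)
            bs = scenario.ld_blocks.block_size
            r = np.sqrt(scenario.ld_blocks.r2)
            n_blocks = int(np.ceil(J / bs))
            for stream in (z_exp, z_out):
                f = np.repeat(rng.standard_normal(n_blocks), bs)[:J]
                stream[:] = r * f + np.sqrt(1.0 - r**2) * stream

        beta_exp = gamma + se_exp * z_exp
        beta_out = theta_i * gamma + alpha + se_out * z_out

        ids, chroms, positions = [], [], []
        for j in range(J):
            ids.append(f"rs{snp_counter + j:07d}")
            # each exposure's SNPs sit on one chromosome; blocks 20 Mb
            # apart so only within-block pairs fall inside a clump window
            if scenario.ld_blocks is not None:
                block, off = divmod(j, scenario.ld_blocks.block_size)
                pos = 1_000_000 + block * 20_000_000 + off * 10_000
            else:
                pos = 1_000_000 + j * 20_000_000
            chroms.append(str((i % 22) + 1))
            positions.append(pos)
        snp_counter += J

        n_pal = int(round(scenario.palindromic_frac * J))
        pal_mask = np.zeros(J, dtype=bool)
        if n_pal:
            pal_mask[rng.choice(J, size=n_pal, replace=False)] = True
        allele_pairs = [
            PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
            if pal_mask[j]
            else NON_PALINDROMIC_PAIRS[rng.integers(len(NON_PALINDROMIC_PAIRS))]
            for j in range(J)
        ]

        exp_records = []
        for j in range(J):
            ea, oa = allele_pairs[j]
            exp_records.append(
                VariantAssociation(
                    variant_id=ids[j],
                    effect_allele=ea,
                    other_allele=oa,
                    beta=float(beta_exp[j]),
                    se=float(se_exp[j]),
                    pval=float(_two_sided_p(beta_exp[j : j + 1], se_exp[j : j + 1])[0]),
                    eaf=float(eaf[j]),
                    n=scenario.n_exp,
                    chrom=chroms[j],
                    pos=positions[j],
                )
            )
        exposures.append(SumstatsTable(trait_id=exp_id, records=exp_records))

        swap = rng.random(J) < 0.5
        for j in range(J):
            ea, oa = allele_pairs[j]
            b, f_ = beta_out[j], eaf[j]
            if swap[j]:
                ea, oa, b, f_ = oa, ea, -b, 1.0 - f_
            outcome_records.append(
                VariantAssociation(
                    variant_id=ids[j],
                    effect_allele=ea,
                    other_allele=oa,
                    beta=float(b),
                    se=float(se_out[j]),
                    pval=float(_two_sided_p(beta_out[j : j + 1], se_out[j : j + 1])[0]),
                    eaf=float(f_),
                    n=scenario.n_out,
                    chrom=chroms[j],
                    pos=positions[j],
                )
            )

        if ld is not None:
            bs = scenario.ld_blocks.block_size
            for j in range(J):
                ld.positions[ids[j]] = (chroms[j], positions[j])
                for k in range(j + 1, J):
                    if j // bs == k // bs:
                        ld.set_r2(ids[j], ids[k], scenario.ld_blocks.r2)

        truth.gamma[exp_id] = gamma
        truth.alpha[exp_id] = alpha
        truth.theta[exp_id] = theta_i
        truth.invalid[exp_id] = invalid
        truth.variant_ids[exp_id] = ids

    outcome = SumstatsTable(trait_id="outcome", records=outcome_records, trait_role="outcome")
    return exposures, outcome, truth, ld


def corrupt_with_outlier(
    outcome: SumstatsTable, variant_id: str, shift: float
) -> SumstatsTable:
    """Return a copy of ``outcome`` with one variant's beta shifted.

    Fixture builder for outlier-detection tests; everything else in the
    table is untouched.  Unknown ``variant_id`` is a hard error.
    """
    if outcome.get(variant_id) is None:
        raise KeyError(f"variant {variant_id!r} not in outcome table")
    from dataclasses import replace

    records = [
        replace(r, beta=r.beta + shift) if r.variant_id == variant_id else r
        for r in outcome.records
    ]
    return SumstatsTable(
        trait_id=outcome.trait_id, records=records, trait_role=outcome.trait_role
    )
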