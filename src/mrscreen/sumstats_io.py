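"""Reading, writing and validation of summary-statistics tables.

All pipeline inputs are plain text: TSV/CSV GWAS or eQTL summary
statistics, a three-column LD table, GMT gene-set files, one-variant-
per-line exclusion lists, and a YAML run configuration.  Tables are
held as lists of :class:`VariantAssociation` records wrapped in a
:class:`SumstatsTable`; pandas does the parsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("mrscreen")

VALID_ALLELES = {"A", "C", "G", "T"}

#: default mapping of standard field -> column name in input files
DEFAULT_COLUMN_MAP = {
    "variant_id": "SNP",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "samplesize",
}

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record for a single trait.

    ``beta`` is the per-effect-allele estimate (trait units or log-odds),
    ``se`` its standard error, ``eaf`` the effect-allele frequency.
    ``chrom``/``pos`` (1-based) are only needed for distance-window
    clumping; ``eaf`` and ``n`` may be missing (``None``).
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def is_valid(self) -> bool:
        if self.se is None or not self.se > 0:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return False
        if not (0.0 < self.pval <= 1.0):
            return False
        return True

    def is_snp(self) -> bool:
        """Biallelic single-nucleotide record (indels are not harmonizable)."""
        return self.effect_allele in VALID_ALLELES and self.other_allele in VALID_ALLELES


@dataclass
class SumstatsTable:
    """An ordered collection of variant records for one trait."""

    trait_id: str
    records: list[VariantAssociation]
    trait_role: str = "exposure"  # "exposure" | "outcome"

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            if r.variant_id in seen:
                raise ValueError(f"duplicate variant_id {r.variant_id!r} in table {self.trait_id!r}")
            seen.add(r.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


@dataclass
class LDTable:
    """Pairwise r-squared lookups plus optional variant positions.

    Entries are stored symmetrically; ``r2(x, x)`` is implied 1.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self.entries[(a, b)] = r2
        self.entries[(b, a)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.entries.get((a, b), 0.0)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    After :meth:`restrict`, every set is a subset of the universe.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def restrict(self) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={k: v & self.universe for k, v in self.sets.items()},
            universe=set(self.universe),
        )


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_role: str = "exposure",
    trait_id: str | None = None,
    sep: str | None = None,
) -> SumstatsTable:
    """Read a summary-statistics table from a delimited text file.

    ``column_map`` maps standard field names (``variant_id``, ``beta``,
    ...) to the file's column headers; unmapped optional fields are
    simply absent.  Rows violating record invariants (non-positive SE,
    identical alleles, frequency outside [0,1], p outside (0,1]) are
    dropped with a logged count, as are duplicate variant IDs (first
    occurrence kept).  Missing required columns and empty files raise.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty summary-statistics file: {path}") from None
    if df.empty:
        raise ValueError(f"summary-statistics file has no data rows: {path}")

    for fld in REQUIRED_FIELDS:
        if cmap[fld] not in df.columns:
            raise ValueError(f"required column {cmap[fld]!r} (field {fld!r}) missing from {path}")

    records: list[VariantAssociation] = []
    seen: set[str] = set()
    n_invalid = n_dup = 0
    for row in df.itertuples(index=False):
        row = row._asdict()

        def _get(fld, cast=float):
            col = cmap.get(fld)
            if col is None or col not in row:
                return None
            val = row[col]
            if pd.isna(val):
                return None
            return cast(val)

        rec = VariantAssociation(
            variant_id=str(row[cmap["variant_id"]]),
            effect_allele=str(row[cmap["effect_allele"]]).upper(),
            other_allele=str(row[cmap["other_allele"]]).upper(),
            beta=_get("beta"),
            se=_get("se"),
            pval=_get("pval"),
            eaf=_get("eaf"),
            n=_get("n"),
            chrom=_get("chrom", str),
            pos=_get("pos", lambda v: int(float(v))),
        )
        if rec.beta is None or rec.se is None or rec.pval is None or not rec.is_valid():
            n_invalid += 1
            continue
        if rec.variant_id in seen:
            n_dup += 1
            continue
        seen.add(rec.variant_id)
        records.append(rec)

    if n_invalid:
        logger.info("%s: dropped %d rows failing record invariants", path.name, n_invalid)
    if n_dup:
        logger.warning("%s: dropped %d duplicate variant IDs (first kept)", path.name, n_dup)
    return SumstatsTable(
        trait_id=trait_id if trait_id is not None else path.stem,
        records=records,
        trait_role=trait_role,
    )


def write_sumstats(table: SumstatsTable, path: str | Path) -> None:
    """Write a table in the same TSV dialect :func:`read_sumstats` reads."""
    df = table.to_frame()
    df = df.rename(columns={k: v for k, v in DEFAULT_COLUMN_MAP.items() if k in df.columns})
    df.to_csv(path, sep="\t", index=False)


def read_ld_table(path: str | Path, positions_path: str | Path | None = None) -> LDTable:
    """Read a 3-column LD table (snp_a, snp_b, r2), optionally with a
    4-column position map (snp, chrom, pos)."""
    df = pd.read_csv(path, sep="\t")
    ld = LDTable()
    cols = list(df.columns[:3])
    for a, b, r2 in df[cols].itertuples(index=False):
        ld.set_r2(str(a), str(b), float(r2))
    if positions_path is not None:
        pos_df = pd.read_csv(positions_path, sep="\t")
        for snp, chrom, pos in pos_df[pos_df.columns[:3]].itertuples(index=False):
            ld.positions[str(snp)] = (str(chrom), int(pos))
    return ld


def read_exclusion_list(path: str | Path) -> set[str]:
    """One variant ID per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_gmt(path: str | Path, universe_path: str | Path | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, genes...).

    The universe defaults to the union of all member genes; a separate
    one-gene-per-line universe file may override it.  A line with fewer
    than three fields is a hard error naming the line number.
    """
    sets: dict[str, set[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: GMT line {i} has {len(fields)} fields, need >= 3")
        name = fields[0]
        genes = {g for g in fields[2:] if g}
        sets[name] = genes
    if universe_path is not None:
        universe = {
            g.strip() for g in Path(universe_path).read_text().splitlines() if g.strip()
        }
    else:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe).restrict()


def read_target_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV mapping a miRNA name to one target gene per row."""
    df = pd.read_csv(path, sep="\t")
    tmap: dict[str, set[str]] = {}
    for mirna, gene in df[df.columns[:2]].itertuples(index=False):
        tmap.setdefault(str(mirna), set()).add(str(gene))
    return tmap


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class ScreenConfig:
    """Every tunable threshold of the screen, overridable from YAML/CLI."""

    p_primary: float = 5e-8
    p_relaxed: float = 1e-5
    min_snps: int = 1
    fallback_mode: str = "per_exposure"  # "per_exposure" | "always_relaxed"
    clump_window_bp: int = 10_000_000
    clump_r2: float = 0.001
    f_min: float = 10.0
    outcome_assoc_p: float = 5e-8
    resolve_strand_flips: bool = True
    palindromic_maf_rescue: float | None = None  # None = always drop
    qvalue_family: str = "per_outcome"  # "per_outcome" | "pooled"
    q_significant: float = 0.1
    p_nominal: float = 0.05
    min_outcomes: int = 4
    boot_reps: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "ScreenConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


def write_results(results: Iterable, out_dir: str | Path) -> dict[str, Path]:
    """Write screen outputs: the long per-method table, per-pair SNP-level
    tables (scatter / leave-one-out data), and the wide IVW-beta matrix for
    exposures with at least one nominal-or-better association.

    Returns a mapping of logical name -> written path.  Implemented here,
    close to the other writers; the structures come from ``screening``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "pairs").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    main_rows = []
    written: dict[str, Path] = {"main": out_dir / "mr_results.tsv"}
    beta_cells: dict[tuple[str, str], float] = {}
    for res in results:
        for est in res.estimates:
            main_rows.append(
                {
                    "exposure": res.exposure_id,
                    "outcome": res.outcome_id,
                    "method": est.method,
                    "n_snp": est.n_snp,
                    "beta": est.beta,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "qval": res.qval if est.method in ("ivw", "wald") else None,
                    "classification": res.classification,
                }
            )
            if est.method in ("ivw", "wald") and res.classification in ("nominal", "significant"):
                beta_cells[(res.exposure_id, res.outcome_id)] = est.beta
        if res.instruments is not None and len(res.instruments) > 0:
            pair_path = out_dir / "pairs" / f"{res.exposure_id}__{res.outcome_id}.tsv"
            snp_rows = [
                {
                    "variant_id": h.variant_id,
                    "beta_exp": h.beta_exp,
                    "se_exp": h.se_exp,
                    "beta_out": h.beta_out,
                    "se_out": h.se_out,
                }
                for h in res.instruments
            ]
            snp_df = pd.DataFrame(snp_rows)
            if res.sensitivity is not None and res.sensitivity.loo_table is not None:
                loo = res.sensitivity.loo_table
                snp_df["loo_beta"] = [loo[v][0] if v in loo else None for v in snp_df["variant_id"]]
            snp_df.to_csv(pair_path, sep="\t", index=False)

    main_cols = [
        "exposure", "outcome", "method", "n_snp", "beta",
        "ci_low", "ci_high", "pval", "qval", "classification",
    ]
    pd.DataFrame(main_rows, columns=main_cols).to_csv(written["main"], sep="\t", index=False)

    written["beta_matrix"] = out_dir / "ivw_beta_matrix.tsv"
    if beta_cells:
        mat = pd.Series(beta_cells).unstack()
    else:
        mat = pd.DataFrame()
    mat.to_csv(written["beta_matrix"], sep="\t")
    return written
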