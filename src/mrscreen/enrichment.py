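"""Target-gene collection and hypergeometric over-representation.

Screen hits (miRNAs) map to experimentally validated target genes via a
user-supplied two-column table; the pooled target list is tested for
over-representation in user-supplied gene sets (GO/KEGG/Reactome-style
GMT files) with the hypergeometric upper tail and Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .sumstats_io import GeneSetCollection

logger = logging.getLogger("mrscreen")


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int  # k
    set_size: int  # K
    selected_size: int  # n
    universe_size: int  # M
    pval: float
    adjusted_pval: float = float("nan")


def collect_targets(mirnas, tmap: dict[str, set[str]]) -> set[str]:
    """Union of target-gene sets over the queried miRNAs.

    miRNAs absent from the map contribute nothing and are logged.
    """
    out: set[str] = set()
    for m in mirnas:
        if m in tmap:
            out |= tmap[m]
        else:
            logger.warning("collect_targets: %r not in target map", m)
    return out


def ora_test(selected: set[str], sets: GeneSetCollection) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``selected`` in each set.

    Genes outside the universe are dropped with a logged count.  With
    universe size M, set size K, selection size n and overlap k, the
    p-value is ``P(X >= k)`` for X hypergeometric(M, K, n).  BH-adjusted
    p-values are computed across the tested sets; output is sorted by
    (p, set name) so ties are deterministic.
    """
    coll = sets.restrict()
    M = len(coll.universe)
    if M == 0:
        raise ValueError("ora_test: empty gene universe")
    inside = set(selected) & coll.universe
    n_outside = len(set(selected)) - len(inside)
    if n_outside:
        logger.info("ora_test: %d selected genes outside the universe dropped", n_outside)
    n = len(inside)

    results = []
    for name in sorted(coll.sets):
        members = coll.sets[name]
        K = len(members)
        k = len(inside & members)
        p = float(hypergeom.sf(k - 1, M, K, n)) if k > 0 else float(
            hypergeom.sf(-1, M, K, n)
        )
        p = min(max(p, 5e-324), 1.0)
        results.append(
            EnrichmentResult(
                set_name=name, overlap_count=k, set_size=K,
                selected_size=n, universe_size=M, pval=p,
            )
        )
    if results:
        adj = multipletests([r.pval for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.adjusted_pval = float(a)
    results.sort(key=lambda r: (r.pval, r.set_name))
    return results
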