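"""Over-representation analysis of hit lists against gene-set collections.

A hit list from the screen is tested against each gene set with the
upper-tail hypergeometric test (one-tailed enrichment only), and p-values
across sets are adjusted with Benjamini-Hochberg step-up FDR. The sampling
universe is the set of genes actually tested in the screen (those with
enough essentiality coverage), not the whole genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger("giscreen")

__all__ = ["EnrichmentResult", "hypergeom_tail", "hypergeom_ora", "bh_adjust", "enrich_collection"]


@dataclass
class EnrichmentResult:
    set_name: str
    universe_size: int  # N
    set_size: int  # K (after intersection with the universe)
    hits_size: int  # n
    overlap: int  # k
    p_value: float
    fdr: float
    overlapping_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "universe_size": self.universe_size,
            "set_size": self.set_size,
            "hits_size": self.hits_size,
            "overlap": self.overlap,
            "p_value": self.p_value,
            "fdr": self.fdr,
            "overlapping_genes": ",".join(self.overlapping_genes),
        }


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when ``n`` genes are drawn without replacement
    from a universe of ``N`` genes of which ``K`` belong to the set.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_ora(
    hits: set[str],
    gene_set: set[str],
    universe: set[str],
    set_name: str = "",
) -> EnrichmentResult:
    """One-tailed hypergeometric over-representation test.

    The gene set is intersected with the universe before testing; a set
    disjoint from the universe yields K=0 and p=1 with a logged warning.
    """
    if not universe:
        raise ValidationError("universe must not be empty")
    if not hits:
        raise ValidationError("hit list must not be empty")
    stray = hits - universe
    if stray:
        raise ValidationError(
            f"hits outside the universe: {', '.join(sorted(stray)[:5])}"
        )
    in_universe = gene_set & universe
    if gene_set and not in_universe:
        logger.warning(
            "gene set %r shares no genes with the tested universe", set_name
        )
    overlap = sorted(hits & in_universe)
    N, K, n, k = len(universe), len(in_universe), len(hits), len(overlap)
    p = hypergeom_tail(k, N, K, n)
    return EnrichmentResult(
        set_name=set_name,
        universe_size=N,
        set_size=K,
        hits_size=n,
        overlap=k,
        p_value=p,
        fdr=float("nan"),
        overlapping_genes=overlap,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich_collection(
    hits: set[str], sets: GeneSetCollection, universe: set[str]
) -> list[EnrichmentResult]:
    """Test a hit list against every set in a collection, with BH FDR."""
    results = [
        hypergeom_ora(hits, set(genes), universe, set_name=name)
        for name, genes in sets.sets.items()
    ]
    fdrs = bh_adjust([r.p_value for r in results])
    for res, fdr in zip(results, fdrs):
        res.fdr = float(fdr)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
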