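"""Expression-stratified differential gene essentiality screening.

The screen asks, gene by gene, whether knockout/knockdown fitness effects
differ between cell lines with high versus low expression of a query gene.
Cell lines are stratified into the top and bottom expression quantile of
the query gene, every other gene's essentiality scores are compared between
the two groups with a two-sided Wilcoxon rank-sum test, and significant
genes are classified by the sign of the median difference:

* GOF interaction (synthetic dosage lethality): the gene is *more*
  essential (more negative scores) in high-expression lines, i.e.
  ``median_high - median_low < 0``.
* LOF interaction (synthetic lethality): more essential in low-expression
  lines, ``median_high - median_low > 0``.

Datasets from different screening technologies (RNAi, CRISPR) are screened
independently and only reconciled afterwards into a consensus call per
gene; scores are never mixed across technologies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .enrichment import bh_adjust
from .errors import ConfigurationError, CoverageError, InsufficientDataError
from .io import GeneMatrix, GeneSetCollection, ScreenConfig

logger = logging.getLogger("giscreen")

__all__ = [
    "Direction",
    "ConsensusCall",
    "Stratification",
    "GIRecord",
    "ConsensusGIRecord",
    "AnnotatedGIRecord",
    "CorrelationRecord",
    "stratify_by_expression",
    "rank_sum_test",
    "screen_dataset",
    "build_consensus",
    "annotate_hits",
    "summarize_annotations",
    "spearman_correlate",
]


class Direction(str, Enum):
    GOF = "GOF"
    LOF = "LOF"
    NS = "NS"


class ConsensusCall(str, Enum):
    GOF = "GOF"
    LOF = "LOF"
    INCONSISTENT = "inconsistent"
    NONE = "none"


@dataclass
class Stratification:
    """High/low expression cell-line groups for one query gene."""

    high_lines: set[str]
    low_lines: set[str]
    quantile_used: float
    k_per_group: int

    def __post_init__(self) -> None:
        if self.high_lines & self.low_lines:
            raise ConfigurationError("high and low groups overlap")
        if len(self.high_lines) != self.k_per_group or len(self.low_lines) != self.k_per_group:
            raise ConfigurationError("group sizes do not match k_per_group")


@dataclass
class GIRecord:
    """Differential-essentiality test result for one gene in one dataset."""

    gene: str
    dataset_id: str
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    delta_median: float
    p_value: float
    significant: bool
    direction: Direction
    q_value: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "dataset_id": self.dataset_id,
            "n_high": self.n_high,
            "n_low": self.n_low,
            "median_high": self.median_high,
            "median_low": self.median_low,
            "delta_median": self.delta_median,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "significant": self.significant,
            "direction": self.direction.value,
        }


@dataclass
class ConsensusGIRecord:
    """Cross-dataset reconciliation of one gene's interaction calls."""

    gene: str
    per_dataset: dict[str, GIRecord]
    consensus: ConsensusCall


@dataclass
class AnnotatedGIRecord:
    gene: str
    consensus: ConsensusCall
    set_names: list[str]


@dataclass
class CorrelationRecord:
    """Spearman coexpression between two genes across cell lines."""

    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    n: int
    r_threshold: float
    above_threshold: bool


def stratify_by_expression(expr: GeneMatrix, cfg: ScreenConfig) -> Stratification:
    """Pick the top and bottom expression quantile of the query gene.

    ``k = floor(q * N)`` lines go into each group, where ``N`` counts cell
    lines with a non-missing query-gene expression value. Ties at the
    boundary are broken by ascending cell-line id so the stratification is
    deterministic.
    """
    row = expr.row(cfg.query_gene)  # raises KeyError when absent
    observed = row.dropna()
    n = int(observed.size)
    k = math.floor(cfg.q * n)
    if k < cfg.min_group_size:
        raise ConfigurationError(
            f"quantile groups too small: N={n}, q={cfg.q} gives k={k} "
            f"< min_group_size={cfg.min_group_size}"
        )
    order = sorted(zip(observed.to_numpy(), observed.index))
    low = {cid for _, cid in order[:k]}
    high = {cid for _, cid in order[-k:]}
    return Stratification(
        high_lines=high, low_lines=low, quantile_used=cfg.q, k_per_group=k
    )


def rank_sum_test(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the pooled sample has at most 20
    observations and no ties; otherwise the normal approximation with
    midranks, tie correction and continuity correction. Missing values are
    dropped before testing.

    Returns
    -------
    (statistic, p_value)
        ``statistic`` is the Mann-Whitney U of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 observations per group, got {a.size} and {b.size}"
        )
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def screen_dataset(
    ess: GeneMatrix, strat: Stratification, cfg: ScreenConfig
) -> list[GIRecord]:
    """Test every gene of one essentiality dataset against the stratification.

    Genes need at least ``cfg.min_obs`` non-missing scores in each group to
    be tested; others are skipped (not reported with p=1). Medians and the
    median difference are computed on exactly the observations used by the
    test. The query gene itself is excluded. Output is sorted with
    significant genes first, by decreasing ``|delta_median|``, and carries
    Benjamini-Hochberg q-values as an informational column (significance is
    by raw p < alpha).
    """
    columns = ess.cell_line_ids
    col_index = {c: i for i, c in enumerate(columns)}
    hi_idx = np.array(
        sorted(col_index[c] for c in strat.high_lines if c in col_index), dtype=int
    )
    lo_idx = np.array(
        sorted(col_index[c] for c in strat.low_lines if c in col_index), dtype=int
    )
    if hi_idx.size == 0 or lo_idx.size == 0:
        raise CoverageError(
            f"stratified cell lines do not overlap dataset {ess.dataset_id!r}"
        )
    records: list[GIRecord] = []
    n_skipped = 0
    for gi, gene in enumerate(ess.gene_ids):
        if gene == cfg.query_gene:
            continue
        row = ess.values[gi]
        hvals = row[hi_idx]
        hvals = hvals[~np.isnan(hvals)]
        lvals = row[lo_idx]
        lvals = lvals[~np.isnan(lvals)]
        if hvals.size < cfg.min_obs or lvals.size < cfg.min_obs:
            n_skipped += 1
            logger.debug(
                "skipping %s in %s: %d/%d non-missing scores (min_obs=%d)",
                gene,
                ess.dataset_id,
                hvals.size,
                lvals.size,
                cfg.min_obs,
            )
            continue
        _, p = rank_sum_test(hvals, lvals)
        median_high = float(np.median(hvals))
        median_low = float(np.median(lvals))
        delta = median_high - median_low
        significant = bool(p < cfg.alpha)
        if significant and delta < 0:
            direction = Direction.GOF
        elif significant and delta > 0:
            direction = Direction.LOF
        else:
            direction = Direction.NS
        records.append(
            GIRecord(
                gene=gene,
                dataset_id=ess.dataset_id,
                n_high=int(hvals.size),
                n_low=int(lvals.size),
                median_high=median_high,
                median_low=median_low,
                delta_median=delta,
                p_value=float(p),
                significant=significant,
                direction=direction,
            )
        )
    if n_skipped:
        logger.info(
            "%s: skipped %d gene(s) with fewer than %d scores per group",
            ess.dataset_id,
            n_skipped,
            cfg.min_obs,
        )
    qvals = bh_adjust([r.p_value for r in records])
    for rec, q in zip(records, qvals):
        rec.q_value = float(q)
    records.sort(key=lambda r: (not r.significant, -abs(r.delta_median), r.gene))
    return records


_CONSENSUS_TABLE = {
    # (any GOF, any LOF) -> call
    (True, False): ConsensusCall.GOF,
    (False, True): ConsensusCall.LOF,
    (True, True): ConsensusCall.INCONSISTENT,
    (False, False): ConsensusCall.NONE,
}


def build_consensus(
    records_by_dataset: Sequence[Sequence[GIRecord]],
) -> list[ConsensusGIRecord]:
    """Reconcile per-dataset interaction calls into one call per gene.

    A gene is GOF (respectively LOF) when at least one dataset calls that
    direction and none calls the opposite; a gene called GOF in one dataset
    and LOF in another is ``inconsistent``; a gene never significant is
    ``none``. Absence from a dataset contributes no direction.
    """
    if not records_by_dataset:
        raise ConfigurationError("need at least one dataset to build a consensus")
    by_gene: dict[str, dict[str, GIRecord]] = {}
    for records in records_by_dataset:
        for rec in records:
            by_gene.setdefault(rec.gene, {})[rec.dataset_id] = rec
    out: list[ConsensusGIRecord] = []
    for gene in sorted(by_gene):
        per_dataset = by_gene[gene]
        directions = {rec.direction for rec in per_dataset.values()}
        call = _CONSENSUS_TABLE[
            (Direction.GOF in directions, Direction.LOF in directions)
        ]
        out.append(
            ConsensusGIRecord(gene=gene, per_dataset=per_dataset, consensus=call)
        )
    return out


def annotate_hits(
    consensus: Sequence[ConsensusGIRecord], sets: GeneSetCollection
) -> list[AnnotatedGIRecord]:
    """Attach to each gene the names of the gene sets that contain it."""
    return [
        AnnotatedGIRecord(
            gene=rec.gene,
            consensus=rec.consensus,
            set_names=sets.sets_containing(rec.gene),
        )
        for rec in consensus
    ]


def summarize_annotations(
    annotated: Sequence[AnnotatedGIRecord],
) -> dict[tuple[str, ConsensusCall], int]:
    """Count annotated genes per (set name, consensus class)."""
    counts: dict[tuple[str, ConsensusCall], int] = {}
    for rec in annotated:
        for name in rec.set_names:
            key = (name, rec.consensus)
            counts[key] = counts.get(key, 0) + 1
    return counts


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value for |rho| >= |rho_obs| at small n.

    Enumerates all n! pairings of the (mid)ranks. The denominator of the
    correlation is permutation-invariant, so only the cross products vary.
    """
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    if denom == 0.0:
        return 1.0
    target = abs(rho_obs) * denom - 1e-12
    total = math.factorial(n)
    extreme = 0
    chunk: list[tuple[float, ...]] = []
    chunk_size = 40000
    perms = itertools.permutations(cy.tolist())
    while True:
        chunk = list(itertools.islice(perms, chunk_size))
        if not chunk:
            break
        arr = np.asarray(chunk)
        cross = np.abs(arr @ cx)
        extreme += int((cross >= target).sum())
    return extreme / total


def spearman_correlate(
    expr: GeneMatrix,
    gene_a: str,
    gene_b: str,
    r_threshold: float = 0.2,
) -> CorrelationRecord:
    """Spearman rank correlation of two genes' expression across cell lines.

    Uses midranks for ties. The p-value comes from the t approximation for
    n > 10 and from exact permutation enumeration for n <= 10. The 0.2
    threshold flag mirrors the common (if arbitrary) correlation detection
    cut-off used when scanning coexpression of candidate partners.
    """
    xa = expr.row(gene_a).to_numpy(dtype=float)
    xb = expr.row(gene_b).to_numpy(dtype=float)
    mask = ~np.isnan(xa) & ~np.isnan(xb)
    x = xa[mask]
    y = xb[mask]
    n = int(mask.sum())
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 paired observations for {gene_a}/{gene_b}, got {n}"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n > 10:
        p = float(res.pvalue)
    else:
        p = _exact_spearman_p(rx, ry, rho)
    return CorrelationRecord(
        gene_a=gene_a,
        gene_b=gene_b,
        rho=rho,
        p_value=p,
        n=n,
        r_threshold=r_threshold,
        above_threshold=bool(abs(rho) >= r_threshold),
    )
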