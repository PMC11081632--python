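import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

from giscreen import io, screen
from giscreen.errors import ConfigurationError, CoverageError, InsufficientDataError
from giscreen.screen import (
    ConsensusCall,
    Direction,
    GIRecord,
    Stratification,
    build_consensus,
    rank_sum_test,
    screen_dataset,
    spearman_correlate,
    stratify_by_expression,
)


def expr_matrix(values_by_line, query="MEMO1"):
    lines = sorted(values_by_line)
    vals = np.array([[values_by_line[c] for c in lines]], dtype=float)
    return io.GeneMatrix(vals, [query], lines, "expression", "expr")


def exact_ranksum_p(a, b):
    """Oracle: exhaustive enumeration over all label assignments (tie-free)."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, len(a)
    ranks = rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    us = [
        sum(ranks[list(c)]) - n1 * (n1 + 1) / 2
        for c in itertools.combinations(range(n), n1)
    ]
    us = np.asarray(us)
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


class TestStratify:
    def test_quartile_cut_on_ordered_expression(self):
        expr = expr_matrix({f"L{i:02d}": float(i) for i in range(1, 21)})
        cfg = io.ScreenConfig(query_gene="MEMO1", q=0.25, min_group_size=2)
        strat = stratify_by_expression(expr, cfg)
        assert strat.k_per_group == 5
        assert strat.low_lines == {f"L{i:02d}" for i in range(1, 6)}
        assert strat.high_lines == {f"L{i:02d}" for i in range(16, 21)}

    @pytest.mark.parametrize(
        "n_lines,q,expected_k",
        [(1028, 0.05, 51), (92, 0.25, 23)],
        ids=["pan-cancer-5pct", "subset-25pct"],
    )
    def test_group_size_is_floor_of_quantile(self, n_lines, q, expected_k, rng):
        values = rng.normal(size=n_lines)
        expr = expr_matrix({f"L{i:04d}": v for i, v in enumerate(values)})
        cfg = io.ScreenConfig(query_gene="MEMO1", q=q, min_group_size=2)
        assert stratify_by_expression(expr, cfg).k_per_group == expected_k

    def test_boundary_ties_broken_by_cell_line_id(self):
        # all-equal expression: membership decided purely by id order
        expr = expr_matrix({f"L{i}": 1.0 for i in range(8)})
        cfg = io.ScreenConfig(query_gene="MEMO1", q=0.25, min_group_size=1)
        strat = stratify_by_expression(expr, cfg)
        assert strat.low_lines == {"L0", "L1"}
        assert strat.high_lines == {"L6", "L7"}

    def test_query_gene_absent(self):
        expr = expr_matrix({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        cfg = io.ScreenConfig(query_gene="NOPE", q=0.25, min_group_size=1)
        with pytest.raises(KeyError, match="NOPE"):
            stratify_by_expression(expr, cfg)

    def test_too_small_groups_report_sizes(self):
        expr = expr_matrix({f"L{i}": float(i) for i in range(20)})
        cfg = io.ScreenConfig(query_gene="MEMO1", q=0.05, min_group_size=10)
        with pytest.raises(ConfigurationError, match="N=20"):
            stratify_by_expression(expr, cfg)


class TestRankSum:
    def test_complete_separation_three_vs_three(self):
        # one-sided 1/20 under exact enumeration -> two-sided 0.10
        _, p = rank_sum_test([-2.0, -1.8, -1.5], [0.0, 0.1, 0.2])
        assert p == pytest.approx(0.10)

    def test_complete_separation_four_vs_four(self):
        _, p = rank_sum_test([-2.0, -1.8, -1.5, -1.2], [0.0, 0.1, 0.2, 0.3])
        assert p == pytest.approx(2 / 70)

    def test_identical_groups_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = rank_sum_test(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_observations(self):
        with pytest.raises(InsufficientDataError):
            rank_sum_test([1.0], [2.0, 3.0])

    def test_missing_values_dropped(self):
        _, p_full = rank_sum_test([-2.0, -1.8, -1.5], [0.0, 0.1, 0.2])
        _, p_nan = rank_sum_test(
            [-2.0, -1.8, -1.5, np.nan], [0.0, 0.1, np.nan, 0.2]
        )
        assert p_nan == pytest.approx(p_full)

    @given(
        st.lists(
            st.floats(-50, 50).map(lambda v: round(v, 3)),
            min_size=4,
            max_size=12,
            unique=True,
        ),
        st.integers(2, 10),
    )
    def test_matches_enumeration_oracle(self, values, split):
        """Exact-path p equals brute-force enumeration over assignments."""
        n1 = min(max(2, split), len(values) - 2)
        a, b = values[:n1], values[n1:]
        _, p = rank_sum_test(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b))


def make_screen_inputs(k=25, sigma=0.1, n_null=5, seed=0):
    rng = np.random.default_rng(seed)
    lines_high = [f"H{i:03d}" for i in range(k)]
    lines_low = [f"L{i:03d}" for i in range(k)]
    lines = lines_high + lines_low
    genes = ["PLANTED"] + [f"N{i}" for i in range(n_null)]
    vals = rng.normal(0.0, sigma, (len(genes), len(lines)))
    vals[0, :k] -= 2.0  # planted gene: strongly essential in high lines
    ess = io.GeneMatrix(vals, genes, lines, "essentiality", "d1")
    strat = Stratification(set(lines_high), set(lines_low), 0.05, k)
    cfg = io.ScreenConfig(query_gene="MEMO1", min_group_size=2)
    return ess, strat, cfg


class TestScreenDataset:
    def test_planted_gof_gene_detected(self):
        ess, strat, cfg = make_screen_inputs()
        records = screen_dataset(ess, strat, cfg)
        rec = next(r for r in records if r.gene == "PLANTED")
        assert rec.significant and rec.direction is Direction.GOF
        assert rec.delta_median == pytest.approx(rec.median_high - rec.median_low)
        assert rec.delta_median < 0
        # sorted with significant hits first
        assert records[0].gene == "PLANTED"

    def test_gene_below_min_obs_skipped(self, caplog):
        ess, strat, cfg = make_screen_inputs()
        # leave only 2 non-missing scores in the high group for one gene
        gi = ess.gene_ids.index("N0")
        hi_cols = [i for i, c in enumerate(ess.cell_line_ids) if c.startswith("H")]
        ess.values[gi, hi_cols[2:]] = np.nan
        records = screen_dataset(ess, strat, cfg)
        assert all(r.gene != "N0" for r in records)

    def test_query_gene_excluded_and_output_is_permutation(self):
        ess, strat, cfg = make_screen_inputs()
        ess.gene_ids[1] = cfg.query_gene  # rename one null gene to the query
        records = screen_dataset(ess, strat, cfg)
        genes = [r.gene for r in records]
        assert cfg.query_gene not in genes
        assert sorted(genes) == sorted(set(genes))
        assert set(genes) == set(ess.gene_ids) - {cfg.query_gene}

    def test_antisymmetry_under_group_swap(self):
        """Swapping high/low flips delta signs and GOF<->LOF, keeps p."""
        ess, strat, cfg = make_screen_inputs()
        swapped = Stratification(
            strat.low_lines, strat.high_lines, strat.quantile_used, strat.k_per_group
        )
        fwd = {r.gene: r for r in screen_dataset(ess, strat, cfg)}
        rev = {r.gene: r for r in screen_dataset(ess, swapped, cfg)}
        flip = {Direction.GOF: Direction.LOF, Direction.LOF: Direction.GOF,
                Direction.NS: Direction.NS}
        for gene, r in fwd.items():
            s = rev[gene]
            assert s.delta_median == pytest.approx(-r.delta_median)
            assert s.p_value == pytest.approx(r.p_value)
            assert s.direction is flip[r.direction]

    def test_no_coverage_raises(self):
        ess, _, cfg = make_screen_inputs()
        strat = Stratification({"X1", "X2"}, {"X3", "X4"}, 0.05, 2)
        with pytest.raises(CoverageError):
            screen_dataset(ess, strat, cfg)


def make_record(gene, dataset, direction):
    sig = direction is not Direction.NS
    delta = -1.0 if direction is Direction.GOF else (1.0 if direction is Direction.LOF else 0.1)
    return GIRecord(
        gene=gene,
        dataset_id=dataset,
        n_high=25,
        n_low=25,
        median_high=delta,
        median_low=0.0,
        delta_median=delta,
        p_value=0.01 if sig else 0.5,
        significant=sig,
        direction=direction,
    )


class TestConsensus:
    def test_agreeing_and_conflicting_datasets(self):
        d1 = [make_record("TFR2", "d1", Direction.GOF),
              make_record("FTH1", "d1", Direction.GOF),
              make_record("SLC11A2", "d1", Direction.NS)]
        d2 = [make_record("TFR2", "d2", Direction.GOF),
              make_record("FTH1", "d2", Direction.LOF),
              make_record("SLC11A2", "d2", Direction.NS)]
        out = {r.gene: r.consensus for r in build_consensus([d1, d2])}
        assert out == {
            "TFR2": ConsensusCall.GOF,
            "FTH1": ConsensusCall.INCONSISTENT,
            "SLC11A2": ConsensusCall.NONE,
        }

    def test_gene_absent_from_one_dataset_contributes_nothing(self):
        d1 = [make_record("ACO1", "d1", Direction.LOF)]
        d2 = [make_record("OTHER", "d2", Direction.NS)]
        out = {r.gene: r.consensus for r in build_consensus([d1, d2])}
        assert out["ACO1"] is ConsensusCall.LOF
        assert out["OTHER"] is ConsensusCall.NONE


class TestAnnotate:
    def make_consensus(self, gene, call):
        return screen.ConsensusGIRecord(gene=gene, per_dataset={}, consensus=call)

    def test_membership_annotation(self):
        sets = io.GeneSetCollection({"IRON": ["TFR2", "ACO1"]})
        recs = [self.make_consensus("TFR2", ConsensusCall.GOF),
                self.make_consensus("GAPDH", ConsensusCall.NONE)]
        annotated = screen.annotate_hits(recs, sets)
        assert annotated[0].set_names == ["IRON"]
        assert annotated[1].set_names == []

    def test_summary_counts_per_class(self):
        """An 11 GOF / 6 LOF / 1 inconsistent hit list summarizes exactly."""
        genes = [f"IRON{i}" for i in range(18)]
        sets = io.GeneSetCollection({"IRON": genes})
        calls = ([ConsensusCall.GOF] * 11 + [ConsensusCall.LOF] * 6
                 + [ConsensusCall.INCONSISTENT])
        recs = [self.make_consensus(g, c) for g, c in zip(genes, calls)]
        summary = screen.summarize_annotations(screen.annotate_hits(recs, sets))
        assert summary == {
            ("IRON", ConsensusCall.GOF): 11,
            ("IRON", ConsensusCall.LOF): 6,
            ("IRON", ConsensusCall.INCONSISTENT): 1,
        }


def two_gene_expr(x, y):
    lines = [f"L{i}" for i in range(len(x))]
    vals = np.array([x, y], dtype=float)
    return io.GeneMatrix(vals, ["A", "B"], lines, "expression", "e")


class TestSpearman:
    def test_textbook_rho(self):
        rec = spearman_correlate(two_gene_expr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]), "A", "B")
        assert rec.rho == pytest.approx(0.8)
        assert rec.above_threshold

    @pytest.mark.parametrize("y,expected", [([1, 2, 3, 4, 5], 1.0),
                                            ([5, 4, 3, 2, 1], -1.0)])
    def test_monotone_extremes(self, y, expected):
        rec = spearman_correlate(two_gene_expr([1, 2, 3, 4, 5], y), "A", "B")
        assert rec.rho == pytest.approx(expected)

    def test_exact_permutation_p_small_n(self):
        # perfect monotone order at n=5: only 2 of 120 pairings reach |rho|=1
        rec = spearman_correlate(two_gene_expr([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]), "A", "B")
        assert rec.p_value == pytest.approx(2 / 120)

    def test_exact_p_matches_independent_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 6.0, 3.0, 5.0]
        rec = spearman_correlate(two_gene_expr(x, y), "A", "B")
        rx, ry = rankdata(x), rankdata(y)
        rhos = [np.corrcoef(rx, perm)[0, 1]
                for perm in itertools.permutations(ry)]
        expected = np.mean(np.abs(rhos) >= abs(rec.rho) - 1e-12)
        assert rec.p_value == pytest.approx(expected)

    def test_threshold_flag_uses_absolute_rho(self):
        rec = spearman_correlate(
            two_gene_expr([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]), "A", "B", r_threshold=0.2
        )
        assert rec.rho < 0 and rec.above_threshold

    def test_insufficient_pairs(self):
        m = two_gene_expr([1, 2, 3, np.nan, 5], [np.nan, 1, 2, 3, 4])
        with pytest.raises(InsufficientDataError):
            spearman_correlate(m, "A", "B")
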