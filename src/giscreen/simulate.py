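"""Synthetic data with the statistical structure each pipeline stage assumes.

Every generator is a pure function of its configuration and seed, so a
fixed seed reproduces byte-identical outputs. The screen generator plants
genes whose essentiality is linearly coupled to the standardized
expression of the query gene — a GOF (synthetic dosage lethal) gene gets
*more negative* scores in lines where the query gene is high — on top of
a null background of independent Gaussian scores. Linear coupling (rather
than a hard threshold at the screen's own quantile cut) keeps the planted
truth independent of the analysis choices, so recovery is a fair test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingFit, ITCGeometry, ITCTitration, itc_expected_heats
from .dose import DoseResponse, fourpl_value
from .errors import ConfigurationError
from .growth import GrowthCurve, logistic_value
from .io import GeneMatrix, MatrixKind, Technology

logger = logging.getLogger("giscreen")

__all__ = [
    "ScreenSimConfig",
    "GrowthDesign",
    "DoseDesign",
    "simulate_screen_data",
    "simulate_growth_curves",
    "simulate_dose_response",
    "simulate_itc",
    "default_itc_geometry",
]


@dataclass
class ScreenSimConfig:
    """Configuration of the synthetic essentiality/expression corpus.

    Defaults emulate a pan-cancer screening corpus: 1028 cell lines
    profiled by four screens (two RNAi-like, two CRISPR-like), log2-scale
    expression of the query gene roughly Normal(5, 1), unit-SD
    essentiality scores, 5% missing essentiality entries, and planted
    interactions at effect size 1.5 score-SD per expression-SD.
    """

    n_cell_lines: int = 1028
    n_genes: int = 3000
    n_datasets: int = 4
    n_planted_gof: int = 50
    n_planted_lof: int = 50
    effect_size: float = 1.5  # delta, in units of score SD
    score_sd: float = 1.0
    expression_mean: float = 5.0  # log2 scale
    expression_sd: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0
    query_gene: str = "QUERY"

    def __post_init__(self) -> None:
        if self.n_planted_gof + self.n_planted_lof > self.n_genes:
            raise ConfigurationError("planted gene counts exceed n_genes")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ConfigurationError("missing_rate must lie in [0, 0.5]")
        if self.n_cell_lines < 4 or self.n_genes < 1 or self.n_datasets < 1:
            raise ConfigurationError("corpus dimensions out of range")


def simulate_screen_data(
    cfg: ScreenSimConfig,
) -> tuple[GeneMatrix, list[GeneMatrix], pd.DataFrame]:
    """Generate expression, essentiality matrices and the planted truth.

    Returns
    -------
    expression : GeneMatrix
        log2-scale expression for all genes (query gene included); only
        the query gene's row drives the planted coupling.
    essentiality : list of GeneMatrix
        One matrix per dataset, independent noise per dataset, shared
        planted identities and directions.
    truth : DataFrame
        Columns ``gene`` and ``direction`` (GOF or LOF) for planted genes.
    """
    rng = np.random.default_rng(cfg.seed)
    lines = [f"CL{i:04d}" for i in range(cfg.n_cell_lines)]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    if cfg.query_gene in genes:
        raise ConfigurationError("query gene name collides with background genes")

    expr_query = rng.normal(cfg.expression_mean, cfg.expression_sd, cfg.n_cell_lines)
    z = (expr_query - expr_query.mean()) / expr_query.std()
    expr_background = rng.normal(
        cfg.expression_mean, cfg.expression_sd, (cfg.n_genes, cfg.n_cell_lines)
    )
    expression = GeneMatrix(
        values=np.vstack([expr_query[None, :], expr_background]),
        gene_ids=[cfg.query_gene] + genes,
        cell_line_ids=lines,
        kind=MatrixKind.EXPRESSION,
        dataset_id="sim_expression",
        technology=Technology.NA,
        log2_scale=True,
    )

    n_planted = cfg.n_planted_gof + cfg.n_planted_lof
    planted_idx = rng.choice(cfg.n_genes, size=n_planted, replace=False)
    gof_idx = planted_idx[: cfg.n_planted_gof]
    lof_idx = planted_idx[cfg.n_planted_gof :]
    truth = pd.DataFrame(
        {
            "gene": [genes[i] for i in gof_idx] + [genes[i] for i in lof_idx],
            "direction": ["GOF"] * cfg.n_planted_gof + ["LOF"] * cfg.n_planted_lof,
        }
    ).sort_values("gene", ignore_index=True)

    shift = np.zeros((cfg.n_genes, cfg.n_cell_lines))
    # GOF: more essential (more negative score) where the query gene is high
    shift[gof_idx] = -cfg.effect_size * cfg.score_sd * z
    shift[lof_idx] = +cfg.effect_size * cfg.score_sd * z

    datasets: list[GeneMatrix] = []
    for d in range(cfg.n_datasets):
        tech = Technology.RNAI if d % 2 == 0 else Technology.CRISPR
        scores = shift + rng.normal(
            0.0, cfg.score_sd, (cfg.n_genes, cfg.n_cell_lines)
        )
        if cfg.missing_rate > 0:
            mask = rng.random((cfg.n_genes, cfg.n_cell_lines)) < cfg.missing_rate
            scores = np.where(mask, np.nan, scores)
        datasets.append(
            GeneMatrix(
                values=scores,
                gene_ids=list(genes),
                cell_line_ids=lines,
                kind=MatrixKind.ESSENTIALITY,
                dataset_id=f"sim_{tech.value.lower()}_{d + 1}",
                technology=tech,
            )
        )
    return expression, datasets, truth


@dataclass
class GrowthDesign:
    """Sampling design for confluency series: every 8 h out to 120 h."""

    n_points: int = 16
    t_max: float = 120.0  # hours
    noise_sd: float = 2.0  # percent confluency
    n_replicates: int = 3
    seed: int = 0


def simulate_growth_curves(
    params: tuple[float, float, float],
    design: GrowthDesign,
    cell_line: str = "sim",
    condition: str = "sim",
) -> list[GrowthCurve]:
    """Logistic curves plus i.i.d. Gaussian noise, clipped to [0, 100]%."""
    r, K, N0 = params
    rng = np.random.default_rng(design.seed)
    times = np.linspace(0.0, design.t_max, design.n_points)
    clean = logistic_value(times, r, K, N0)
    curves = []
    for rep in range(design.n_replicates):
        noisy = clean + rng.normal(0.0, design.noise_sd, design.n_points)
        curves.append(
            GrowthCurve(
                times=times.copy(),
                confluency=np.clip(noisy, 0.0, 100.0),
                cell_line=cell_line,
                condition=condition,
                replicate=rep,
            )
        )
    return curves


@dataclass
class DoseDesign:
    """Eight doses per decade-spanning titration, duplicate wells."""

    doses: np.ndarray = field(
        default_factory=lambda: np.logspace(0.0, 3.0, 8)
    )  # µM
    noise_sd: float = 0.05  # viability fraction
    n_replicates: int = 2
    seed: int = 0


def simulate_dose_response(
    params: tuple[float, float, float, float],
    design: DoseDesign,
    condition: str = "sim",
) -> list[DoseResponse]:
    """4PL responses plus Gaussian noise, floored at zero viability."""
    ic50, hill, top, bottom = params
    rng = np.random.default_rng(design.seed)
    doses = np.asarray(design.doses, dtype=float)
    clean = fourpl_value(doses, ic50, hill, top, bottom)
    out = []
    for rep in range(design.n_replicates):
        noisy = clean + rng.normal(0.0, design.noise_sd, doses.size)
        out.append(
            DoseResponse(
                concentrations=doses.copy(),
                responses=np.maximum(noisy, 0.0),
                condition=condition,
                replicate=rep,
            )
        )
    return out


def default_itc_geometry(n_injections: int = 20) -> ITCGeometry:
    """A realistic titration: 0.5 mM ligand into 0.17 ml of 25 µM protein,
    2 µl per injection."""
    return ITCGeometry(
        cell_volume=0.17e-3,
        protein_conc=25e-6,
        syringe_conc=0.5e-3,
        injection_volumes=np.full(n_injections, 2e-6),
    )


def simulate_itc(
    geometry: ITCGeometry,
    params: BindingFit,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ITCTitration:
    """Forward-model heats plus Gaussian noise of the given SD (joules)."""
    rng = np.random.default_rng(seed)
    q = itc_expected_heats(geometry, params)
    if noise_sd > 0:
        q = q + rng.normal(0.0, noise_sd, q.size)
    return ITCTitration(geometry=geometry, heats=q)
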