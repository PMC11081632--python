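"""Readers, writers and domain containers shared by all pipeline stages.

The on-disk formats are deliberately plain: gene-by-cell-line matrices are
TSV/CSV with a header row of cell-line ids and a first column of gene
symbols; gene sets use the standard GMT format; tabular results are TSV.
Joins are always by string id and case-sensitive, because DepMap/CCLE-style
exports use HUGO symbols and silent case-folding hides real mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger("giscreen")

__all__ = [
    "MatrixKind",
    "Technology",
    "GeneMatrix",
    "GeneSetCollection",
    "ScreenConfig",
    "load_matrix",
    "write_matrix",
    "load_gmt",
    "write_table",
    "read_table",
]


class MatrixKind(str, Enum):
    ESSENTIALITY = "essentiality"
    EXPRESSION = "expression"


class Technology(str, Enum):
    RNAI = "RNAi"
    CRISPR = "CRISPR"
    NA = "NA"


@dataclass
class GeneMatrix:
    """A genes-by-cell-lines score matrix.

    Parameters
    ----------
    values
        2-D float array, ``NaN`` marks missing entries. Rows are genes,
        columns are cell lines.
    gene_ids, cell_line_ids
        Unique string identifiers for rows and columns.
    kind
        Whether the scores are essentiality (fitness effect of
        knockout/knockdown, more negative = more essential) or expression.
    dataset_id
        Free-form label of the source screen or expression compendium.
    technology
        Screening technology for essentiality matrices (RNAi or CRISPR);
        ``NA`` for expression.
    log2_scale
        For expression matrices: whether values are on log2 scale. The
        scale is recorded, never inferred, because log2 expression may
        legitimately be negative.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_line_ids: list[str]
    kind: MatrixKind
    dataset_id: str
    technology: Technology = Technology.NA
    log2_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.kind = MatrixKind(self.kind)
        self.technology = Technology(self.technology)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_line_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_line_ids)} cell lines"
            )
        for name, ids in (("gene", self.gene_ids), ("cell line", self.cell_line_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} id(s): {', '.join(dupes)}")
        if (
            self.kind is MatrixKind.EXPRESSION
            and not self.log2_scale
            and self.values.size
            and np.nanmin(self.values) < 0
        ):
            raise ValidationError(
                "linear-scale expression matrix contains negative entries"
            )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def row(self, gene: str) -> pd.Series:
        """Scores of one gene across cell lines, indexed by cell-line id."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in dataset {self.dataset_id!r}")
        return pd.Series(self.values[i], index=self.cell_line_ids, name=gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.cell_line_ids
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a curated iron-metabolism annotation)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            dupes = _duplicates(genes)
            if dupes:
                raise ValidationError(
                    f"gene set {name!r} contains duplicate gene(s): {', '.join(dupes)}"
                )

    def sets_containing(self, gene: str) -> list[str]:
        return [name for name, genes in self.sets.items() if gene in genes]


@dataclass
class ScreenConfig:
    """Settings for one expression-stratified essentiality screen.

    ``q`` is the expression quantile used to pick the high- and low-
    expression cell-line groups: 0.05 for a pan-cancer screen, 0.25 when
    restricting to a smaller tissue subset where 5% tails would be too few
    lines. ``alpha`` is the raw rank-sum significance cut. ``min_obs`` is
    the minimum number of non-missing essentiality scores per group a gene
    needs in order to be tested at all.
    """

    query_gene: str
    q: float = 0.05
    alpha: float = 0.05
    min_group_size: int = 10
    min_obs: int = 3
    test_sidedness: str = "two_sided"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.query_gene:
            raise ConfigurationError("query_gene must be a non-empty string")
        if not 0.0 < self.q <= 0.5:
            raise ConfigurationError(f"quantile q must be in (0, 0.5], got {self.q}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_group_size < 1:
            raise ConfigurationError("min_group_size must be a positive integer")
        if self.min_obs < 2:
            raise ConfigurationError("min_obs must be at least 2")
        if self.test_sidedness != "two_sided":
            raise ConfigurationError("only the two-sided rank-sum test is supported")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "ScreenConfig":
        """Load from YAML or JSON (identical schema); kwargs override."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


def _detect_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_matrix(
    path: str | Path,
    kind: MatrixKind | str,
    dataset_id: str,
    technology: Technology | str = Technology.NA,
    log2_scale: bool = True,
) -> GeneMatrix:
    """Load a gene-by-cell-line matrix from TSV or CSV.

    The first column holds gene ids, the header row holds cell-line ids.
    Empty cells or ``NA`` denote missing values, which are preserved as
    ``NaN`` (never imputed). Both LF and CRLF line endings are accepted.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\r\n")
    cols = header.split(sep)
    if len(cols) < 2 or any(c == "" for c in cols[1:]):
        raise FormatError(
            f"{path}: malformed header; expected a gene column followed by "
            "cell-line ids"
        )
    dupes = _duplicates(cols[1:])
    if dupes:
        raise ValidationError(
            f"{path}: duplicate cell-line id(s): {', '.join(dupes)}"
        )
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=["NA", ""],
        keep_default_na=False,
        dtype=str,
    )
    dupes = _duplicates(df.index.astype(str))
    if dupes:
        raise ValidationError(f"{path}: duplicate gene id(s): {', '.join(dupes)}")
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell value ({exc})") from exc
    matrix = GeneMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        cell_line_ids=[str(c) for c in df.columns],
        kind=kind,
        dataset_id=dataset_id,
        technology=technology,
        log2_scale=log2_scale,
    )
    logger.info(
        "loaded %s matrix %s: %d genes x %d cell lines, %d missing",
        matrix.kind.value,
        dataset_id,
        len(matrix.gene_ids),
        len(matrix.cell_line_ids),
        matrix.n_missing,
    )
    return matrix


def write_matrix(matrix: GeneMatrix, path: str | Path) -> None:
    """Write a GeneMatrix as TSV (gene column first, NA for missing)."""
    df = matrix.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Load gene sets from standard GMT (name, description, genes...).

    Duplicate genes within a set are dropped with a logged warning. A line
    with fewer than three tab-separated fields is a format error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected at least 3 (name, description, genes...)"
                )
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s:%d: duplicate gene %r in set %r dropped",
                        path,
                        lineno,
                        g,
                        name,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def _render(value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    if isinstance(value, (np.floating,)):
        return _render(float(value))
    if isinstance(value, (np.integer,)):
        return str(int(value))
    return str(value)


def write_table(
    records: Sequence[Mapping[str, Any]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write homogeneous records as TSV.

    Column order follows the first record (or the explicit ``columns``
    argument), reals are rendered with 6 significant digits, booleans as
    ``True``/``False`` so that thresholded statuses survive rounding.
    """
    if columns is None:
        columns = list(records[0].keys()) if records else []
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(_render(rec[c]) for c in columns) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` back into a DataFrame."""
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False
    )
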