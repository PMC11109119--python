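"""Core data model and file I/O.

The pipeline works on three plain-text artifacts:

* expression matrices — TSV, genes in rows, samples in columns, values on
  log2 scale (log2(TPM+1) for sequencing, RMA scale for arrays);
* sample sheets — long-format TSV, one row per sample, linking samples to
  tumors and patients and carrying subtype/MSI/mutation/survival metadata;
* gene sets — standard GMT, with an optional ``_UP``/``_DN`` suffix
  convention marking directed sets.

All downstream math assumes complete, finite matrices; NA values are
rejected at read time rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_VALUES = {"primary", "metastasis"}

#: Columns a sample sheet must always carry.
SHEET_REQUIRED = ["sample_id", "tumor_id", "patient_id"]

#: Optional sample-sheet columns understood downstream.
SHEET_OPTIONAL = [
    "site",
    "region_label",
    "subtype",
    "msi_status",
    "stage",
    "time_months",
    "event",
    "endpoint",
]


class FormatError(ValueError):
    """Malformed input file (duplicates, bad header, wrong field count)."""


class ParseError(ValueError):
    """A cell could not be interpreted as a number."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2-scale gene x sample expression matrix.

    Invariants: unique gene and sample identifiers, all values finite,
    dimensions consistent. Use :meth:`from_frame` / :func:`read_expression`
    to construct with validation.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        genes = [str(g) for g in df.index]
        samples = [str(s) for s in df.columns]
        _check_unique(genes, "gene")
        _check_unique(samples, "sample")
        values = df.to_numpy(dtype=float)
        if values.ndim != 2 or values.shape != (len(genes), len(samples)):
            raise FormatError("matrix dimensions do not match identifier lists")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ParseError(
                f"non-finite expression value at gene {genes[bad[0]]!r}, "
                f"sample {samples[bad[1]]!r}"
            )
        return cls(tuple(genes), tuple(samples), values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in set(self.gene_ids)]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids, self.values[rows, :])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, cols])


@dataclass(frozen=True)
class GeneSet:
    """Named gene set, optionally directed (up / down / undirected)."""

    name: str
    genes: frozenset
    direction: str = "undirected"

    def __post_init__(self):
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        if self.direction not in {"up", "down", "undirected"}:
            raise FormatError(f"bad direction {self.direction!r} for {self.name!r}")


@dataclass
class Cohort:
    """An expression matrix joined with its sample sheet.

    Sample order follows the matrix; the sheet is re-indexed to match.
    """

    expr: ExpressionMatrix
    sheet: pd.DataFrame
    dropped_samples: list = field(default_factory=list)

    @property
    def sample_ids(self):
        return self.expr.sample_ids


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    _check_unique(genes, "gene")
    _check_unique([str(c) for c in df.columns], "sample")
    try:
        num = df.astype(float)
    except ValueError:
        # locate the offending cell for a usable error message
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric value {v!r} at row {df.index[i]!r} "
                        f"(line {i + 2}), column {col!r} (field {j + 2})"
                    ) from None
        raise
    if num.isna().to_numpy().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"missing value at row {num.index[i]!r}, column {num.columns[j]!r}"
        )
    return ExpressionMatrix.from_frame(num)


def write_expression(expr: ExpressionMatrix, path, float_format: str = "%.17g") -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a long-format TSV sample sheet and validate its invariants."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in SHEET_REQUIRED})
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing required columns: {missing}")
    _check_unique(list(df["sample_id"].astype(str)), "sample")
    # each tumor maps to exactly one patient
    t2p = df.groupby("tumor_id")["patient_id"].nunique()
    multi = t2p[t2p > 1]
    if len(multi):
        raise FormatError(
            f"tumor(s) mapped to multiple patients: {list(multi.index)}"
        )
    if "site" in df.columns:
        bad = set(df["site"].dropna().unique()) - SITE_VALUES
        if bad:
            raise FormatError(f"unknown site value(s): {sorted(bad)}")
    if "time_months" in df.columns:
        times = pd.to_numeric(df["time_months"], errors="coerce")
        if (times.dropna() <= 0).any():
            raise FormatError("survival time_months must be strictly positive")
    return df.reset_index(drop=True)


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list:
    """Read a GMT file into a list of :class:`GeneSet`.

    Line format: name, description, then tab-separated gene ids. Names
    ending in ``_UP`` / ``_DN`` get direction up / down.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name.endswith("_UP"):
                direction = "up"
            elif name.endswith("_DN"):
                direction = "down"
            else:
                direction = "undirected"
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(name=name, genes=genes, direction=direction))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def join_cohort(expr: ExpressionMatrix, sheet: pd.DataFrame) -> Cohort:
    """Restrict matrix and sheet to their common samples (matrix order).

    Dropped samples from either side are logged and recorded on the
    returned :class:`Cohort`.
    """
    sheet = validate_sample_sheet(sheet)
    sheet_ids = set(sheet["sample_id"].astype(str))
    expr_ids = set(expr.sample_ids)
    common = [s for s in expr.sample_ids if s in sheet_ids]  # matrix order
    if not common:
        raise FormatError("expression matrix and sample sheet share no samples")
    dropped = sorted((sheet_ids | expr_ids) - set(common))
    if dropped:
        logger.info("join_cohort dropped %d sample(s): %s", len(dropped), dropped)
    sub_sheet = (
        sheet.set_index(sheet["sample_id"].astype(str)).loc[common].reset_index(drop=True)
    )
    return Cohort(expr=expr.subset_samples(common), sheet=sub_sheet, dropped_samples=dropped)
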