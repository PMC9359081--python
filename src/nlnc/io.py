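"""Core data containers and readers for the screening pipeline.

The pipeline consumes four kinds of input:

* a genes x samples expression matrix on a log-like continuous scale, with a
  biotype label (``lncRNA`` or ``mRNA``) for every gene (TSV or GCT);
* gene sets in GMT format (one set per line);
* per-sample tumour purity in ``[0, 1]`` (two-column TSV);
* a clinical table with survival time, an event indicator and optional
  covariates (TSV).

Expression data are held in :class:`ExpressionMatrix`, a thin validated
wrapper around a :class:`pandas.DataFrame`.  Purity is a validated
:class:`pandas.Series` and the clinical table a validated
:class:`pandas.DataFrame` indexed by sample id — the idiomatic containers for
this stack rather than bespoke classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("nlnc")

LNCRNA = "lncRNA"
MRNA = "mRNA"
VALID_BIOTYPES = frozenset({LNCRNA, MRNA})


class DataValidationError(ValueError):
    """Raised when an input violates a structural contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression with per-gene biotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  Missing
        entries are NaN.
    biotype
        Series mapping every gene id to ``"lncRNA"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    biotype: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise DataValidationError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise DataValidationError(f"duplicate sample id: {dup!r}")
        self.biotype = pd.Series(self.biotype)
        missing = idx.difference(self.biotype.index)
        if len(missing):
            raise DataValidationError(
                f"{len(missing)} gene(s) lack a biotype label, e.g. {missing[0]!r}"
            )
        self.biotype = self.biotype.reindex(idx)
        bad = set(self.biotype.unique()) - VALID_BIOTYPES
        if bad:
            raise DataValidationError(f"unknown biotype label(s): {sorted(bad)}")
        self.values = self.values.astype(float)

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def lncrna_ids(self) -> pd.Index:
        return self.gene_ids[self.biotype.to_numpy() == LNCRNA]

    @property
    def mrna_ids(self) -> pd.Index:
        return self.gene_ids[self.biotype.to_numpy() == MRNA]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        return ExpressionMatrix(self.values.loc[genes], self.biotype.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.biotype)

    # -- i/o ----------------------------------------------------------------
    def to_tsv(self, path: str | Path, biotype_path: str | Path | None = None) -> None:
        """Write values as TSV (gene ids in the first column); optionally the
        biotype sidecar as a two-column TSV."""
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if biotype_path is not None:
            self.biotype.rename("biotype").to_csv(
                biotype_path, sep="\t", index_label="gene_id"
            )


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    biotype: str | Path | Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or GCT.

    TSV layout: first column gene ids, header row sample ids.  GCT layout:
    the standard ``#1.2`` two-line preamble followed by ``NAME`` and
    ``Description`` columns.  Non-numeric cells become missing entries.

    ``biotype`` is either a path to a two-column ``gene_id<TAB>biotype``
    table or an in-memory mapping; it is required because every downstream
    step distinguishes lncRNA from mRNA rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1."):
                raise DataValidationError(f"not a GCT file (header {version!r})")
            fh.readline()  # dimensions line
            df = pd.read_csv(fh, sep="\t")
        df = df.set_index(df.columns[0])
        # drop the Description column, keep data columns
        df = df.drop(columns=df.columns[0])
    else:
        raise ValueError(f"unknown format {format!r}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"duplicate gene id: {dup!r}")

    if biotype is None:
        raise DataValidationError("a biotype table (gene_id -> lncRNA/mRNA) is required")
    if isinstance(biotype, (str, Path)):
        bt = pd.read_csv(biotype, sep="\t", index_col=0).iloc[:, 0]
    else:
        bt = pd.Series(dict(biotype) if isinstance(biotype, Mapping) else biotype)
    return ExpressionMatrix(df, bt)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered, named gene sets with free-text descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise DataValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate members within a line are deduplicated (order preserved) with a
    logged warning; a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "gene set %r (line %d): %d duplicate member(s) removed",
                    name, lineno, len(members) - len(deduped),
                )
            if name in sets:
                raise DataValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Purity and clinical tables
# ---------------------------------------------------------------------------

def validate_purity(purity: pd.Series) -> pd.Series:
    """Validate a per-sample tumour-purity vector (values in [0, 1])."""
    purity = pd.Series(purity, dtype=float)
    if purity.index.duplicated().any():
        raise DataValidationError("duplicate sample ids in purity table")
    if purity.isna().any():
        raise DataValidationError("missing purity values")
    if ((purity < 0) | (purity > 1)).any():
        bad = purity[(purity < 0) | (purity > 1)].index[0]
        raise DataValidationError(f"purity outside [0, 1] for sample {bad!r}")
    return purity


def read_purity(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>purity`` table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_purity(df.iloc[:, 0])


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table: positive time, event in {0, 1}, unique ids.

    Rows with missing time or event are dropped with a logged count.
    """
    if clinical.index.duplicated().any():
        raise DataValidationError("duplicate sample ids in clinical table")
    for col in ("time", "event"):
        if col not in clinical.columns:
            raise DataValidationError(f"clinical table lacks a {col!r} column")
    n0 = len(clinical)
    clinical = clinical.dropna(subset=["time", "event"])
    if len(clinical) < n0:
        logger.warning("dropped %d clinical row(s) with missing time/event", n0 - len(clinical))
    clinical = clinical.copy()
    clinical["time"] = clinical["time"].astype(float)
    clinical["event"] = clinical["event"].astype(float)
    if (clinical["time"] <= 0).any():
        raise DataValidationError("survival times must be > 0")
    if not clinical["event"].isin([0.0, 1.0]).all():
        raise DataValidationError("event indicator must be 0 or 1")
    clinical["event"] = clinical["event"].astype(int)
    return clinical


def read_clinical(
    path: str | Path,
    sample_col: str = "sample_id",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Read a clinical TSV; extra columns are kept as covariates."""
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise DataValidationError(f"clinical table lacks column {col!r}")
    df = df.set_index(sample_col)
    df = df.rename(columns={time_col: "time", event_col: "event"})
    return validate_clinical(df)


# ---------------------------------------------------------------------------
# Sample alignment and the coverage filter
# ---------------------------------------------------------------------------

def align_samples(
    matrix: ExpressionMatrix,
    *tables: pd.Series | pd.DataFrame,
    intersect: bool = False,
) -> tuple:
    """Canonicalise all tables to the expression matrix's sample order.

    By default the sample-id sets must match exactly; with
    ``intersect=True`` the common subset is taken and its size logged.
    """
    samples = matrix.sample_ids
    common = samples
    for t in tables:
        common = common.intersection(t.index)
    if len(common) < len(samples) or any(len(t.index) != len(samples) for t in tables):
        if not intersect:
            raise DataValidationError(
                "sample ids differ between inputs; pass intersect=True to use "
                f"the {len(common)}-sample intersection"
            )
        logger.warning("intersecting samples across inputs: %d in common", len(common))
    if len(common) == 0:
        raise DataValidationError("no samples in common between inputs")
    common = samples[samples.isin(common)]  # keep matrix order
    matrix = matrix.subset_samples(common)
    aligned = tuple(t.loc[common] for t in tables)
    return (matrix, *aligned)


def filter_low_coverage_lncrnas(
    matrix: ExpressionMatrix,
    max_missing_fraction: float = 0.5,
    empty_means: str = "either",
) -> tuple[ExpressionMatrix, pd.Index]:
    """Drop lncRNAs with empty expression in more than half the samples.

    A lncRNA row is removed when its count of "empty" entries strictly
    exceeds ``max_missing_fraction * n_samples``; mRNA rows are never
    touched.  "Empty" is platform-dependent, so it is configurable:
    ``missing`` (NaN only), ``zero`` (exact zeros only) or ``either``
    (default).  Returns the filtered matrix and the removed gene ids.
    """
    if not (0 < max_missing_fraction <= 1):
        raise ValueError("max_missing_fraction must be in (0, 1]")
    if empty_means not in ("missing", "zero", "either"):
        raise ValueError(f"unknown empty_means {empty_means!r}")
    vals = matrix.values
    empty = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    if empty_means in ("missing", "either"):
        empty |= vals.isna()
    if empty_means in ("zero", "either"):
        empty |= vals == 0
    n = matrix.n_samples
    frac_empty = empty.sum(axis=1) / n
    is_lnc = matrix.biotype == LNCRNA
    drop = is_lnc & (frac_empty > max_missing_fraction)
    removed = vals.index[drop]
    if len(removed):
        logger.info("coverage filter removed %d lncRNA(s)", len(removed))
    keep = vals.index[~drop]
    out = matrix.subset_genes(keep)
    if len(out.lncrna_ids) == 0:
        warnings.warn("coverage filter removed every lncRNA", stacklevel=2)
    return out, removed
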