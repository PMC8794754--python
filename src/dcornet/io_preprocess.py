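"""Input/output and quality control for expression matrices.

File conventions
----------------
Expression TSV
    First column holds gene ids, header row holds sample ids,
    tab-separated, ``NA`` marks a missing value.
Phenotype TSV
    Columns ``sample_id`` and ``condition`` (``A``/``normal`` or
    ``B``/``tumor``), plus optional ``time`` and ``event`` columns carrying
    survival information.

Correlations computed downstream use pairwise-complete observations when
missing values survive QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_A = "A"
CONDITION_B = "B"

_CONDITION_ALIASES = {
    "a": CONDITION_A,
    "normal": CONDITION_A,
    "control": CONDITION_A,
    "b": CONDITION_B,
    "tumor": CONDITION_B,
    "tumour": CONDITION_B,
    "case": CONDITION_B,
}

REASON_MISSINGNESS = "excess missingness"
REASON_ZERO_VARIANCE = "zero variance"
REASON_OUTLIER = "outlier"
REASON_MANUAL = "manual"


class ExpressionError(ValueError):
    """Raised for malformed expression data or invalid operations on it."""


def _normalize_condition(label: object) -> str:
    key = str(label).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise ExpressionError(
            f"unknown condition label {label!r}; expected one of "
            f"{sorted(set(_CONDITION_ALIASES))}"
        )
    return _CONDITION_ALIASES[key]


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with per-sample condition labels.

    Parameters
    ----------
    values:
        Numeric matrix, rows indexed by gene id and columns by sample id.
        May contain NaN for missing entries.
    condition:
        Series mapping every sample id to ``"A"`` (normal) or ``"B"``
        (tumor).
    phenotype:
        Optional full phenotype table (indexed by sample id) carrying e.g.
        survival ``time``/``event`` columns.
    """

    values: pd.DataFrame
    condition: pd.Series
    phenotype: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.values
        if not isinstance(values, pd.DataFrame):
            raise ExpressionError("values must be a pandas DataFrame")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample ids: {dups}")
        bad = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
        if bad:
            raise ExpressionError(f"non-numeric expression column(s): {bad}")
        self.values = values.astype(float)

        condition = pd.Series(self.condition)
        missing = [s for s in values.columns if s not in condition.index]
        if missing:
            raise ExpressionError(f"samples without a condition label: {missing}")
        condition = condition.reindex(values.columns)
        condition = condition.map(_normalize_condition)
        self.condition = condition

        if self.phenotype is not None:
            self.phenotype = self.phenotype.reindex(values.columns)

    # -- views ------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def trait(self) -> pd.Series:
        """0/1 indicator per sample: 1 for condition B (tumor)."""
        return (self.condition == CONDITION_B).astype(int)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def condition_counts(self) -> dict[str, int]:
        return self.condition.value_counts().to_dict()

    # -- subsetting -------------------------------------------------------
    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = list(genes)
        unknown = [g for g in genes if g not in self.values.index]
        if unknown:
            raise ExpressionError(f"unknown gene id(s): {unknown}")
        return ExpressionDataset(
            self.values.loc[genes], self.condition.copy(), self.phenotype
        )

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.values.columns]
        if unknown:
            raise ExpressionError(f"unknown sample id(s): {unknown}")
        pheno = self.phenotype.loc[samples] if self.phenotype is not None else None
        return ExpressionDataset(
            self.values[samples], self.condition.loc[samples], pheno
        )


@dataclass
class QCReport:
    """Record of what quality control removed and why."""

    removed_genes: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("gene", g, r) for g, r in self.removed_genes]
        rows += [("sample", s, r) for s, r in self.removed_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_phenotype(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in pheno.columns or "condition" not in pheno.columns:
        raise ExpressionError(
            f"phenotype table {path} must have 'sample_id' and 'condition' columns; "
            f"found {list(pheno.columns)}"
        )
    if pheno["sample_id"].duplicated().any():
        dups = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"].tolist()
        raise ExpressionError(f"duplicate sample ids in phenotype table: {dups}")
    return pheno.set_index("sample_id")


def read_expression(path, phenotype_path) -> ExpressionDataset:
    """Read an expression TSV plus its phenotype table into a dataset.

    Rows are genes, columns are samples; parsing is strict — any
    non-numeric token other than ``NA`` is an error.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    bad = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if bad:
        raise ExpressionError(
            f"expression file {path}: non-numeric values in sample column(s) {bad}"
        )
    pheno = read_phenotype(phenotype_path)
    missing = [s for s in values.columns if s not in pheno.index]
    if missing:
        raise ExpressionError(
            f"phenotype table {phenotype_path} is missing sample(s): {missing}"
        )
    return ExpressionDataset(values, pheno["condition"], phenotype=pheno)


def write_expression(ds: ExpressionDataset, path, phenotype_path=None) -> None:
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    if phenotype_path is not None:
        write_phenotype(ds, phenotype_path)


def write_phenotype(ds: ExpressionDataset, path) -> None:
    if ds.phenotype is not None:
        pheno = ds.phenotype.copy()
        pheno["condition"] = ds.condition
    else:
        pheno = ds.condition.to_frame("condition")
    pheno.index.name = "sample_id"
    pheno.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def good_samples_genes(
    ds: ExpressionDataset, max_missing_frac: float = 0.5
) -> tuple[ExpressionDataset, QCReport]:
    """Drop genes/samples with excess missingness and zero-variance genes.

    Gene and sample passes alternate until the dataset is stable, so the
    operation is idempotent even when removing samples creates newly
    constant genes. Surviving genes and samples keep their order.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ExpressionError(
            f"max_missing_frac must be in [0, 1], got {max_missing_frac}"
        )
    report = QCReport(thresholds={"max_missing_frac": max_missing_frac})
    values = ds.values

    for _ in range(ds.n_genes + ds.n_samples + 1):
        changed = False
        if values.shape[1] > 0:
            miss_frac = values.isna().mean(axis=1)
            n_obs = values.notna().sum(axis=1)
            var = values.var(axis=1, ddof=0)
            too_missing = miss_frac > max_missing_frac
            zero_var = (~too_missing) & ((n_obs < 2) | (var.fillna(0.0) == 0.0))
            for g in values.index[too_missing]:
                report.removed_genes.append((g, REASON_MISSINGNESS))
            for g in values.index[zero_var]:
                report.removed_genes.append((g, REASON_ZERO_VARIANCE))
            keep = ~(too_missing | zero_var)
            if not keep.all():
                values = values.loc[keep]
                changed = True
        if values.shape[0] > 0:
            smiss = values.isna().mean(axis=0)
            bad_samples = smiss > max_missing_frac
            for s in values.columns[bad_samples]:
                report.removed_samples.append((s, REASON_MISSINGNESS))
            if bad_samples.any():
                values = values.loc[:, ~bad_samples]
                changed = True
        if not changed:
            break

    if values.shape[0] == 0:
        raise ExpressionError("QC removed every gene; dataset is degenerate")
    if values.shape[1] == 0:
        raise ExpressionError("QC removed every sample; dataset is degenerate")

    pheno = ds.phenotype.loc[values.columns] if ds.phenotype is not None else None
    clean = ExpressionDataset(values, ds.condition.loc[values.columns], pheno)
    if report.removed_genes or report.removed_samples:
        logger.info(
            "good_samples_genes removed %d gene(s), %d sample(s)",
            len(report.removed_genes),
            len(report.removed_samples),
        )
    return clean, report


def detect_outlier_samples(ds: ExpressionDataset, z_cut: float = -2.5) -> list[str]:
    """Flag samples with abnormally low whole-network connectivity.

    Connectivity of a sample is the sum of its correlations with every
    other sample; samples whose standardized connectivity falls below
    ``z_cut`` are returned. Exclusion is left to an explicit
    :func:`exclude_samples` call.
    """
    if ds.n_samples < 3:
        raise ExpressionError(
            f"need at least 3 samples to detect outliers, got {ds.n_samples}"
        )
    values = ds.values
    if values.isna().any().any():
        cor = values.corr(min_periods=3)
    else:
        cor = pd.DataFrame(
            np.corrcoef(values.to_numpy().T),
            index=values.columns,
            columns=values.columns,
        )
    k = cor.sum(axis=1) - 1.0  # drop self-correlation
    sd = k.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        return []
    z = (k - k.mean()) / sd
    return list(z.index[z < z_cut])


def exclude_samples(ds: ExpressionDataset, ids) -> ExpressionDataset:
    """Remove the given samples (manual or outlier-based exclusion)."""
    ids = list(ids)
    unknown = [s for s in ids if s not in ds.values.columns]
    if unknown:
        raise ExpressionError(f"cannot exclude unknown sample(s): {unknown}")
    keep = [s for s in ds.sample_ids if s not in set(ids)]
    return ds.subset_samples(keep)
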