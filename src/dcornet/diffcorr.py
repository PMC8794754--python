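"""Fisher z-based differential correlation between two conditions.

For every gene pair the Pearson correlations in condition A (normal) and
condition B (tumor) are Fisher-transformed and their difference is tested
with

    Z = (z_A - z_B) / sqrt(1/(n_A - 3) + 1/(n_B - 3)),

two-sided against the standard normal. Multiplicity is controlled with an
Efron-style empirical-null local false discovery rate, falling back to
Benjamini-Hochberg when too few records are available for density
estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde, norm
from statsmodels.stats.multitest import multipletests

from .coexpression import correlation_matrix, first_principal_component
from .io_preprocess import CONDITION_A, CONDITION_B, ExpressionDataset, ExpressionError

logger = logging.getLogger(__name__)

_R_CLAMP = 1.0 - 1e-12

#: Output column order mirrors the published table schema, with the test
#: internals appended.
TABLE_COLUMNS = ["molecule_X", "molecule_Y", "r1", "r2", "Lfdr", "Z", "p", "module"]


def fisher_z(r):
    """Fisher transform ``0.5 * log((1 + r) / (1 - r))`` (= arctanh).

    Correlations at exactly +/-1 are clamped just inside the open interval
    with a warning so degenerate noiseless fixtures still run.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-9):
        raise ValueError(f"correlation outside [-1, 1]: {arr[np.abs(arr) > 1 + 1e-9]}")
    if np.any(np.abs(arr) >= 1.0):
        warnings.warn("correlation at +/-1 clamped for the Fisher transform")
    clamped = np.clip(arr, -_R_CLAMP, _R_CLAMP)
    out = np.arctanh(clamped)
    return out if out.ndim else float(out)


def diff_corr_statistic(rA, rB, nA: int, nB: int):
    """Difference-of-correlations statistic and two-sided normal p-value."""
    if nA <= 3 or nB <= 3:
        raise ValueError(f"sample sizes must exceed 3, got nA={nA}, nB={nB}")
    zA = fisher_z(rA)
    zB = fisher_z(rB)
    se = np.sqrt(1.0 / (nA - 3) + 1.0 / (nB - 3))
    z = (np.asarray(zA) - np.asarray(zB)) / se
    p = 2.0 * norm.sf(np.abs(z))
    if z.ndim:
        return z, p
    return float(z), float(p)


def pairwise_differential_correlations(
    ds: ExpressionDataset,
    genes=None,
    module: str | int = "",
    method: str = "pearson",
) -> pd.DataFrame:
    """One record per unordered gene pair with r1/r2/Z/p (lfdr unfilled).

    ``r1`` is the correlation among condition-A (normal) samples and
    ``r2`` among condition-B (tumor) samples. Genes without variance in
    either condition are skipped with a warning.
    """
    if genes is not None:
        ds = ds.subset_genes(genes)
    samples_a = ds.samples_in(CONDITION_A)
    samples_b = ds.samples_in(CONDITION_B)
    nA, nB = len(samples_a), len(samples_b)
    if nA < 4 or nB < 4:
        raise ExpressionError(
            f"each condition needs >= 4 samples, got A={nA}, B={nB}"
        )
    va = ds.values[samples_a]
    vb = ds.values[samples_b]
    degenerate = ds.values.index[
        (va.var(axis=1, ddof=0) == 0) | (vb.var(axis=1, ddof=0) == 0)
    ]
    if len(degenerate):
        warnings.warn(
            f"skipping {len(degenerate)} gene(s) with zero variance in a condition: "
            f"{list(degenerate[:5])}"
        )
        keep = [g for g in ds.gene_ids if g not in set(degenerate)]
        ds = ds.subset_genes(keep)
        va, vb = ds.values[samples_a], ds.values[samples_b]
    m = ds.n_genes
    if m < 2:
        raise ExpressionError("need at least 2 usable genes")
    ra = correlation_matrix(va, method=method).to_numpy()
    rb = correlation_matrix(vb, method=method).to_numpy()
    iu, ju = np.triu_indices(m, k=1)
    r1 = np.clip(ra[iu, ju], -_R_CLAMP, _R_CLAMP)
    r2 = np.clip(rb[iu, ju], -_R_CLAMP, _R_CLAMP)
    z, p = diff_corr_statistic(r1, r2, nA, nB)
    ids = np.asarray(ds.gene_ids)
    return pd.DataFrame(
        {
            "molecule_X": ids[iu],
            "molecule_Y": ids[ju],
            "r1": r1,
            "r2": r2,
            "zA": np.arctanh(r1),
            "zB": np.arctanh(r2),
            "Z": z,
            "p": p,
            "lfdr": np.nan,
            "module": module,
        }
    )


# ---------------------------------------------------------------------------
# local fdr
# ---------------------------------------------------------------------------

@dataclass
class LfdrFit:
    """Metadata for a local-fdr estimation run."""

    method: str  # "empirical-null" or "BH"
    pi0: float | None = None
    delta0: float | None = None
    sigma0: float | None = None
    n_records: int = 0
    warnings: list[str] = field(default_factory=list)


def _empirical_null_lfdr(z: np.ndarray) -> tuple[np.ndarray, LfdrFit]:
    kde = gaussian_kde(z)
    lo, hi = np.quantile(z, [0.25, 0.75])
    if hi <= lo:
        raise RuntimeError("degenerate interquartile range")
    grid = np.linspace(lo, hi, 41)
    dens = kde(grid)
    if (dens <= 0).any():
        raise RuntimeError("non-positive density on the central grid")
    b2, b1, b0 = np.polyfit(grid, np.log(dens), 2)
    if b2 >= -1e-12:
        raise RuntimeError("central log-density is not concave")
    sigma0 = float(np.sqrt(-1.0 / (2.0 * b2)))
    delta0 = float(b1 * sigma0**2)
    log_pi0 = b0 + np.log(sigma0 * np.sqrt(2.0 * np.pi)) + delta0**2 / (2.0 * sigma0**2)
    pi0 = float(min(1.0, np.exp(log_pi0)))
    f_z = np.maximum(kde(z), 1e-300)
    lfdr = np.clip(pi0 * norm.pdf(z, loc=delta0, scale=sigma0) / f_z, 0.0, 1.0)
    return lfdr, LfdrFit(
        method="empirical-null", pi0=pi0, delta0=delta0, sigma0=sigma0, n_records=len(z)
    )


def local_fdr(
    records: pd.DataFrame,
    method: str = "empirical-null",
    fallback: str = "BH",
    min_records: int = 100,
) -> tuple[pd.DataFrame, LfdrFit]:
    """Fill the ``lfdr`` column of a record table.

    The default estimator fits the marginal density of the Z statistics
    with a Gaussian kernel, recovers an empirical null
    ``N(delta0, sigma0^2)`` and its proportion ``pi0`` by central matching
    (a quadratic fit to the log density over the interquartile range), and
    sets ``lfdr(z) = pi0 * phi0(z) / f(z)`` clipped to [0, 1]. With fewer
    than ``min_records`` records, or if the fit degenerates, the
    Benjamini-Hochberg adjusted p-value is stored instead and the fit
    metadata flags the fallback.
    """
    if method not in {"empirical-null", "BH"}:
        raise ValueError(f"unknown lfdr method {method!r}")
    records = records.copy()
    z = records["Z"].to_numpy(dtype=float)
    if len(z) == 0:
        raise ValueError("no records")
    if np.ptp(z) == 0:
        raise ValueError("all Z statistics identical; lfdr undefined")
    fit: LfdrFit
    if method == "empirical-null" and len(z) >= min_records:
        try:
            lfdr, fit = _empirical_null_lfdr(z)
            records["lfdr"] = lfdr
            return records, fit
        except RuntimeError as exc:
            msg = f"empirical-null fit failed ({exc}); falling back to {fallback}"
            warnings.warn(msg)
            fit = LfdrFit(method="BH", n_records=len(z), warnings=[msg])
    else:
        fit = LfdrFit(method="BH", n_records=len(z))
        if method == "empirical-null":
            msg = (
                f"only {len(z)} records (< {min_records}); falling back to BH"
            )
            warnings.warn(msg)
            fit.warnings.append(msg)
    records["lfdr"] = multipletests(records["p"].to_numpy(), method="fdr_bh")[1]
    return records, fit


def top_differential_pairs(
    records: pd.DataFrame, k: int = 10, lfdr_max: float = 0.05
) -> pd.DataFrame:
    """Top-k pairs with lfdr below ``lfdr_max``.

    Sorted by lfdr ascending, then |Z| descending, then gene ids; ties in
    the published tables are broken the same way.
    """
    if records["lfdr"].isna().any():
        raise ValueError("lfdr not computed; run local_fdr first")
    surviving = records[records["lfdr"] < lfdr_max].copy()
    surviving["_absZ"] = surviving["Z"].abs()
    surviving = surviving.sort_values(
        by=["lfdr", "_absZ", "molecule_X", "molecule_Y"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_absZ")
    return surviving.head(k).reset_index(drop=True)


# ---------------------------------------------------------------------------
# eigen-molecule clustering
# ---------------------------------------------------------------------------

@dataclass
class EigenMoleculeClusters:
    """Gene clusters under 1 - r distance with first-PC summary profiles."""

    labels: pd.Series  # gene -> cluster id (1-based)
    profiles: pd.DataFrame  # samples x clusters, columns "C<id>"
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0


def eigen_molecule_clusters(
    ds: ExpressionDataset, genes=None, cutoff: float = 0.6
) -> EigenMoleculeClusters:
    """Average-linkage clustering of genes at 1 - r distance ``cutoff``.

    Correlation pools both conditions; each resulting cluster is
    summarized by its sign-aligned first principal component.
    """
    if genes is not None:
        ds = ds.subset_genes(genes)
    if ds.n_genes < 2:
        raise ExpressionError("need at least 2 genes to cluster")
    cor = correlation_matrix(ds).to_numpy()
    d = np.clip(1.0 - cor, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    raw = fcluster(z, t=cutoff, criterion="distance")
    # relabel by decreasing size, ties by first member
    sizes = pd.Series(raw).value_counts()
    first_pos = {c: int(np.argmax(raw == c)) for c in sizes.index}
    ordered = sorted(sizes.index, key=lambda c: (-sizes[c], first_pos[c]))
    remap = {c: i + 1 for i, c in enumerate(ordered)}
    labels = pd.Series([remap[c] for c in raw], index=ds.gene_ids)
    profiles = {}
    for cid in sorted(set(labels)):
        members = labels.index[labels == cid]
        if len(members) == 1:
            x = ds.values.loc[members[0]]
            prof = (x - x.mean()) / (x.std(ddof=1) or 1.0)
        else:
            prof, _ = first_principal_component(ds.values.loc[members])
        profiles[f"C{cid}"] = prof
    return EigenMoleculeClusters(
        labels=labels, profiles=pd.DataFrame(profiles), cutoff=cutoff
    )


def write_records(records: pd.DataFrame, path) -> None:
    """Write records with the published column order (Lfdr spelled as such)."""
    out = records.rename(columns={"lfdr": "Lfdr"})
    out[TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    out = raw.rename(columns={"Lfdr": "lfdr"})
    out["zA"] = np.arctanh(out["r1"])
    out["zB"] = np.arctanh(out["r2"])
    return out
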