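"""Weighted co-expression network construction and module detection.

Implements the classic chain: pairwise correlation -> soft-threshold
power picked by the scale-free topology criterion -> power adjacency ->
topological overlap -> average-linkage clustering -> fixed-height branch
cut -> module eigengenes -> module merging -> module/trait and
membership/significance statistics.

The branch cut is a documented simplification of the hybrid dynamic tree
cut: the dendrogram is cut at a fixed fraction of its maximum merge
height (one fraction per ``deep_split`` level) and branches with at least
``min_module_size`` leaves become modules; everything else is left
unassigned (label 0, "grey").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from scipy.stats import t as t_dist

from .io_preprocess import ExpressionDataset, ExpressionError

logger = logging.getLogger(__name__)

GREY = 0  # label reserved for unassigned genes

_DEEP_SPLIT_CUT = {0: 0.95, 1: 0.97, 2: 0.99, 3: 0.995}


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _check_no_zero_variance(values: pd.DataFrame) -> None:
    var = values.var(axis=1, ddof=0)
    bad = var.index[(var == 0) | var.isna()]
    if len(bad):
        raise ExpressionError(f"zero-variance gene(s): {list(bad[:5])}")


def _pearson(values: pd.DataFrame) -> np.ndarray:
    if values.isna().any().any():
        return values.T.corr(min_periods=3).to_numpy()
    return np.corrcoef(values.to_numpy())


def _bicor(values: pd.DataFrame) -> np.ndarray:
    """Biweight midcorrelation; genes with MAD = 0 fall back to Pearson."""
    x = values.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ExpressionError(
            "bicor requires a complete matrix; run QC / imputation first"
        )
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    ok = mad[:, 0] > 0
    u = np.zeros_like(x)
    u[ok] = (x[ok] - med[ok]) / (9.0 * mad[ok])
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xw = (x - med) * w
    # Pearson fallback for MAD-degenerate genes
    if (~ok).any():
        xm = x[~ok] - x[~ok].mean(axis=1, keepdims=True)
        xw[~ok] = xm
    norm = np.sqrt((xw**2).sum(axis=1, keepdims=True))
    xw = xw / norm
    return xw @ xw.T


def correlation_matrix(
    ds: ExpressionDataset | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Gene-gene correlation matrix (``pearson`` or ``bicor``).

    Uses all samples of the dataset; pass a pre-subset dataset for
    per-condition correlations.
    """
    values = ds.values if isinstance(ds, ExpressionDataset) else ds
    if values.shape[1] < 3:
        raise ExpressionError(
            f"need at least 3 samples for a correlation matrix, got {values.shape[1]}"
        )
    _check_no_zero_variance(values)
    if method == "pearson":
        r = _pearson(values)
    elif method == "bicor":
        r = _bicor(values)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


# ---------------------------------------------------------------------------
# soft threshold / scale-free fit
# ---------------------------------------------------------------------------

def scale_free_fit_index(connectivity, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution regression.

    Connectivities are discretized into ``n_bins`` equal-count (quantile)
    bins; log10 of the per-bin frequency density (bin fraction divided by
    bin width) is regressed on log10 of the per-bin mean connectivity.
    The R^2 is multiplied by ``-sign(slope)`` so it is positive only when
    the connectivity distribution decreases with connectivity. If fewer
    than ``n_bins`` distinct positive values exist the bin count is
    reduced; fully degenerate input returns 0 with a warning.
    """
    k = np.asarray(connectivity, dtype=float)
    if (k < 0).any():
        raise ValueError("connectivity must be non-negative")
    distinct_pos = np.unique(k[k > 0])
    if distinct_pos.size < 2 or k.max() == k.min():
        warnings.warn("degenerate connectivity distribution; returning 0")
        return 0.0
    n_bins = max(3, min(n_bins, distinct_pos.size))
    edges = np.unique(np.quantile(k, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) < 4:
        warnings.warn("fewer than 3 usable connectivity bins; returning 0")
        return 0.0
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, len(edges) - 2)
    mean_k, density = [], []
    n = len(k)
    for b in range(len(edges) - 1):
        sel = idx == b
        width = edges[b + 1] - edges[b]
        if not sel.any() or width <= 0:
            continue
        mk = k[sel].mean()
        if mk <= 0:
            continue
        mean_k.append(mk)
        density.append(sel.sum() / n / width)
    if len(mean_k) < 3:
        warnings.warn("fewer than 3 usable connectivity bins; returning 0")
        return 0.0
    fit = linregress(np.log10(mean_k), np.log10(density))
    if fit.slope == 0:
        return 0.0
    return float(fit.rvalue**2 * -np.sign(fit.slope))


def adjacency(
    cm: pd.DataFrame, beta: float, signed: bool = False, diag: float = 0.0
) -> pd.DataFrame:
    """Power adjacency: ``|r|^beta`` (unsigned) or ``((1+r)/2)^beta`` (signed).

    The diagonal is set to ``diag``; connectivity and the topological
    overlap formula both assume a zero diagonal.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    r = cm.to_numpy(dtype=float)
    a = ((1.0 + r) / 2.0) ** beta if signed else np.abs(r) ** beta
    np.fill_diagonal(a, diag)
    return pd.DataFrame(a, index=cm.index, columns=cm.columns)


@dataclass
class SoftThresholdResult:
    """Per-power scale-free fit, chosen power and whether the target was met."""

    table: pd.DataFrame  # columns: power, r_squared, mean_connectivity
    power: int
    target_r2: float
    reached_target: bool

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def pick_soft_threshold(
    cm: pd.DataFrame,
    powers=tuple(range(1, 21)),
    target_r2: float = 0.9,
    signed: bool = False,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit reaches ``target_r2``.

    If no candidate reaches the target the best-fitting power is returned
    with ``reached_target=False`` and a warning.
    """
    rows = []
    for beta in powers:
        a = adjacency(cm, beta, signed=signed).to_numpy()
        k = a.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = scale_free_fit_index(k, n_bins=n_bins)
        rows.append((int(beta), r2, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "r_squared", "mean_connectivity"])
    hits = table[table["r_squared"] >= target_r2]
    if len(hits):
        power = int(hits["power"].iloc[0])
        reached = True
    else:
        power = int(table.loc[table["r_squared"].idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no candidate power reached scale-free R^2 >= {target_r2}; "
            f"using argmax power {power}"
        )
    return SoftThresholdResult(table=table, power=power, target_r2=target_r2, reached_target=reached)


# ---------------------------------------------------------------------------
# topological overlap and clustering
# ---------------------------------------------------------------------------

def tom_similarity(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``l_ij`` counts shared-neighbor adjacency products and ``k`` is the
    connectivity; the diagonal is 1 by convention. Expects a symmetric
    adjacency with zero diagonal and entries in [0, 1].
    """
    m = a.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(m)).max(initial=0.0) > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if m.min(initial=0.0) < 0 or m.max(initial=0.0) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    ell = m @ m
    k = m.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - m
    tom = (ell + m) / np.maximum(denom, 1e-12)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes (scipy linkage encoding)."""

    linkage: np.ndarray
    ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def max_height(self) -> float:
        return float(self.linkage[:, 2].max()) if len(self.linkage) else 0.0


def cluster_genes(tom: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative tree on dissimilarity 1 - TOM."""
    ids = tuple(tom.index)
    if len(ids) == 0:
        raise ValueError("cannot cluster an empty TOM matrix")
    if len(ids) == 1:
        return Dendrogram(linkage=np.empty((0, 4)), ids=ids)
    d = 1.0 - tom.to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(linkage=z, ids=ids)


def cut_modules(
    dend: Dendrogram, min_module_size: int = 30, deep_split: int = 2
) -> pd.Series:
    """Fixed-height branch cut of the dendrogram into modules.

    Cuts at ``h(deep_split) * max merge height`` with
    ``h in {0.95, 0.97, 0.99, 0.995}`` for ``deep_split`` 0..3. Branches
    below the cut with at least ``min_module_size`` leaves become modules,
    labelled 1, 2, ... by decreasing size; all other genes get label 0.
    """
    if deep_split not in _DEEP_SPLIT_CUT:
        raise ValueError(f"deep_split must be one of {sorted(_DEEP_SPLIT_CUT)}")
    if dend.n_leaves == 0:
        raise ValueError("empty dendrogram")
    labels = pd.Series(GREY, index=list(dend.ids), dtype=int)
    if dend.n_leaves == 1 or len(dend.linkage) == 0:
        return labels
    cut_height = _DEEP_SPLIT_CUT[deep_split] * dend.max_height
    raw = fcluster(dend.linkage, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    # order by size descending, ties by first member position
    first_pos = {c: int(np.argmax(raw == c)) for c in big.index}
    ordered = sorted(big.index, key=lambda c: (-big[c], first_pos[c]))
    for new_label, c in enumerate(ordered, start=1):
        labels.iloc[np.flatnonzero(raw == c)] = new_label
    return labels


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

def first_principal_component(values: pd.DataFrame) -> tuple[pd.Series, float]:
    """First PC score across samples of a genes x samples block.

    Genes are z-scored across samples first; the score is scaled to unit
    variance and sign-aligned so it correlates non-negatively with the
    block's mean expression profile. Returns ``(score, variance explained)``.
    """
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(xz, full_matrices=False)
    pc = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    pc_sd = pc.std(ddof=1)
    if pc_sd > 0:
        pc = pc / pc_sd
    # sign alignment: first against mean z-scored profile, then raw mean
    for ref in (xz.mean(axis=0), x.mean(axis=0)):
        if ref.std() > 0:
            c = np.corrcoef(pc, ref)[0, 1]
            if abs(c) > 1e-12:
                if c < 0:
                    pc = -pc
                break
    else:
        if pc[np.argmax(np.abs(pc))] < 0:
            pc = -pc
    return pd.Series(pc, index=values.columns), var_explained


@dataclass
class ModuleEigengenes:
    """Per-module eigengene profiles and their variance explained."""

    eigengenes: pd.DataFrame  # samples x modules, columns "ME<label>"
    variance_explained: pd.Series

    @property
    def module_labels(self) -> list[int]:
        return [int(c[2:]) for c in self.eigengenes.columns]

    def write(self, path) -> None:
        out = self.eigengenes.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def module_eigengenes(ds: ExpressionDataset, modules: pd.Series) -> ModuleEigengenes:
    """First-PC summary profile for every non-grey module."""
    modules = modules.reindex(ds.gene_ids)
    cols = {}
    var = {}
    for label in sorted(set(modules) - {GREY}):
        genes = modules.index[modules == label]
        if len(genes) < 2:
            raise ExpressionError(
                f"module {label} has fewer than 2 genes; cannot form an eigengene"
            )
        pc, ve = first_principal_component(ds.values.loc[genes])
        cols[f"ME{label}"] = pc
        var[label] = ve
    if not cols:
        raise ExpressionError("no non-grey modules; nothing to summarize")
    return ModuleEigengenes(
        eigengenes=pd.DataFrame(cols),
        variance_explained=pd.Series(var, name="variance_explained"),
    )


def merge_close_modules(
    ds: ExpressionDataset,
    modules: pd.Series,
    mes: ModuleEigengenes | None = None,
    cut_height: float = 0.25,
    max_iterations: int = 20,
) -> tuple[pd.Series, ModuleEigengenes]:
    """Merge modules whose eigengenes correlate above ``1 - cut_height``.

    Eigengenes are clustered by average linkage on ``1 - cor``; clusters
    joined below ``cut_height`` are merged and eigengenes recomputed,
    iterating until stable.
    """
    modules = modules.copy()
    if mes is None:
        mes = module_eigengenes(ds, modules)
    for _ in range(max_iterations):
        labels = mes.module_labels
        if len(labels) <= 1:
            break
        cor = np.corrcoef(mes.eigengenes.to_numpy().T)
        d = np.clip(1.0 - cor, 0.0, None)
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
        groups = fcluster(z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(labels):
            break
        sizes = modules.value_counts()
        for gid in set(groups):
            members = [labels[i] for i in np.flatnonzero(groups == gid)]
            if len(members) == 1:
                continue
            target = max(members, key=lambda m: (sizes.get(m, 0), -m))
            modules[modules.isin(members)] = target
            logger.info("merged modules %s into %s", members, target)
        mes = module_eigengenes(ds, modules)
    return modules, mes


# ---------------------------------------------------------------------------
# module/trait statistics
# ---------------------------------------------------------------------------

def correlation_pvalue(r, n: int):
    """Two-sided p-value for a Pearson correlation via the exact t transform."""
    r = np.asarray(r, dtype=float)
    if n < 3:
        raise ValueError(f"need n >= 3 for a correlation p-value, got {n}")
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = np.where(np.abs(rr) >= 1.0, 0.0, 2.0 * t_dist.sf(np.abs(t), df=n - 2))
    return p if p.ndim else float(p)


def module_trait_correlation(mes: ModuleEigengenes, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of every module eigengene with a binary trait."""
    trait = trait.reindex(mes.eigengenes.index).astype(float)
    if trait.isna().any():
        raise ExpressionError("trait is missing for some samples")
    if trait.nunique() < 2:
        raise ExpressionError("trait is constant; correlation undefined")
    n = len(trait)
    rows = []
    for col in mes.eigengenes.columns:
        r = float(np.corrcoef(mes.eigengenes[col], trait)[0, 1])
        rows.append((int(col[2:]), r, correlation_pvalue(r, n)))
    return pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")


def gene_module_stats(
    ds: ExpressionDataset,
    modules: pd.Series,
    mes: ModuleEigengenes,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene module membership (MM) and gene significance (GS).

    MM is the correlation of a gene's profile with its own module's
    eigengene (NaN for grey genes); GS is the correlation with the trait.
    """
    modules = modules.reindex(ds.gene_ids)
    trait = trait.reindex(ds.sample_ids).astype(float)
    n = ds.n_samples
    x = ds.values.to_numpy(dtype=float)
    xz = x - x.mean(axis=1, keepdims=True)
    xsd = xz.std(axis=1)
    tz = trait.to_numpy() - trait.mean()
    gs = (xz @ tz) / (n * np.where(xsd == 0, np.nan, xsd) * trait.std(ddof=0))
    mm = np.full(ds.n_genes, np.nan)
    for label in mes.module_labels:
        me = mes.eigengenes[f"ME{label}"].to_numpy()
        mez = me - me.mean()
        mask = (modules == label).to_numpy()
        mm[mask] = (xz[mask] @ mez) / (
            n * np.where(xsd[mask] == 0, np.nan, xsd[mask]) * me.std()
        )
    out = pd.DataFrame(
        {
            "module": modules.to_numpy(),
            "MM": np.clip(mm, -1, 1),
            "GS": np.clip(gs, -1, 1),
        },
        index=ds.gene_ids,
    )
    out["MM_p"] = np.where(
        np.isnan(out["MM"]), np.nan, correlation_pvalue(out["MM"].fillna(0), n)
    )
    out["GS_p"] = np.where(
        np.isnan(out["GS"]), np.nan, correlation_pvalue(out["GS"].fillna(0), n)
    )
    return out


def mm_gs_correlation(stats: pd.DataFrame, module: int) -> tuple[float, float]:
    """Correlation between MM and |GS| over one module's genes."""
    sub = stats[(stats["module"] == module) & stats["MM"].notna() & stats["GS"].notna()]
    if len(sub) < 3:
        raise ExpressionError(f"module {module} has too few genes for an MM-GS correlation")
    r = float(np.corrcoef(sub["MM"], sub["GS"].abs())[0, 1])
    return r, correlation_pvalue(r, len(sub))


def select_significant_modules(
    trait_cors: pd.DataFrame,
    mm_gs_cors: pd.Series,
    trait_cut: float = 0.5,
    mmgs_cut: float = 0.5,
) -> list[int]:
    """Modules with |trait r| > trait_cut AND MM-|GS| r > mmgs_cut (strict)."""
    selected = []
    for module in trait_cors.index:
        if module not in mm_gs_cors.index:
            continue
        if abs(trait_cors.loc[module, "r"]) > trait_cut and mm_gs_cors[module] > mmgs_cut:
            selected.append(int(module))
    return selected
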