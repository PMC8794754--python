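"""End-to-end orchestration: QC -> coexpression -> module selection ->
per-module differential correlation -> switch network -> survival scan.

Every stage consumes and produces plain files under the output directory,
so individual stages can be re-run in isolation with identical results. A
JSON run manifest records the config hash, per-stage output checksums,
timings and collected warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clinical_stats, coexpression, diffcorr, io_preprocess, switch_network

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the published values as defaults."""

    expression_path: str = "expression.tsv"
    phenotype_path: str = "phenotype.tsv"
    outdir: str = "dcornet_out"
    # QC
    max_missing_frac: float = 0.5
    outlier_z: float = -2.5
    auto_exclude_outliers: bool = True
    manual_exclude: tuple[str, ...] = ()
    # network construction
    correlation_method: str = "pearson"
    signed: bool = False
    powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.9
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    deep_split: int = 2
    # module selection
    trait_cut: float = 0.5
    mmgs_cut: float = 0.5
    # differential correlation / network
    lfdr_threshold: float = 0.05
    switch_threshold: float = 0.5
    de_alpha: float = 0.05
    eigen_cluster_cutoff: float = 0.6
    network_formats: tuple[str, ...] = ("SIF", "GraphML", "TSV")
    # survival
    survival_scan: bool = False
    survival_gene: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_method not in {"pearson", "bicor"}:
            raise ValueError(f"correlation_method must be pearson|bicor")
        for name, lo, hi in [
            ("max_missing_frac", 0, 1),
            ("target_r2", 0, 1),
            ("merge_cut_height", 0, 2),
            ("trait_cut", 0, 1),
            ("mmgs_cut", 0, 1),
            ("lfdr_threshold", 0, 1),
            ("switch_threshold", 0, 1),
            ("de_alpha", 0, 1),
            ("eigen_cluster_cutoff", 0, 2),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if self.deep_split not in (0, 1, 2, 3):
            raise ValueError(f"deep_split must be 0..3, got {self.deep_split}")
        if self.min_module_size < 2:
            raise ValueError(f"min_module_size must be >= 2, got {self.min_module_size}")
        self.powers = tuple(int(p) for p in self.powers)
        self.manual_exclude = tuple(self.manual_exclude)
        self.network_formats = tuple(self.network_formats)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path) -> None:
        lines = []
        for k, v in self.to_dict().items():
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{k} = {v}")
            elif isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            elif isinstance(v, list):
                items = ", ".join(
                    f'"{x}"' if isinstance(x, str) else str(x) for x in v
                )
                lines.append(f"{k} = [{items}]")
            else:  # pragma: no cover - config fields are scalars/lists
                raise TypeError(f"cannot serialize config field {k}={v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    versions: dict = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, outputs: dict[str, str]) -> None:
        self.stages.append({"name": name, "seconds": round(seconds, 3), "outputs": outputs})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksums(paths) -> dict[str, str]:
    return {Path(p).name: _sha256(Path(p)) for p in paths}


# ---------------------------------------------------------------------------
# stages (files in, files out)
# ---------------------------------------------------------------------------

def stage_qc(config: PipelineConfig, outdir: Path) -> list[Path]:
    ds = io_preprocess.read_expression(config.expression_path, config.phenotype_path)
    ds, report = io_preprocess.good_samples_genes(ds, config.max_missing_frac)
    if config.manual_exclude:
        ds = io_preprocess.exclude_samples(ds, config.manual_exclude)
        report.removed_samples += [
            (s, io_preprocess.REASON_MANUAL) for s in config.manual_exclude
        ]
    if config.auto_exclude_outliers:
        outliers = io_preprocess.detect_outlier_samples(ds, config.outlier_z)
        if outliers:
            ds = io_preprocess.exclude_samples(ds, outliers)
            report.removed_samples += [
                (s, io_preprocess.REASON_OUTLIER) for s in outliers
            ]
    expr = outdir / "expression_qc.tsv"
    pheno = outdir / "phenotype_qc.tsv"
    qc = outdir / "qc_report.tsv"
    io_preprocess.write_expression(ds, expr, phenotype_path=pheno)
    report.write(qc)
    return [expr, pheno, qc]


def stage_coexpress(config: PipelineConfig, outdir: Path) -> list[Path]:
    ds = io_preprocess.read_expression(
        outdir / "expression_qc.tsv", outdir / "phenotype_qc.tsv"
    )
    cm = coexpression.correlation_matrix(ds, method=config.correlation_method)
    sft = coexpression.pick_soft_threshold(
        cm, powers=config.powers, target_r2=config.target_r2, signed=config.signed
    )
    if not sft.reached_target:
        warnings.warn(
            f"scale-free target R^2 {config.target_r2} not reached; "
            f"using power {sft.power}"
        )
    adj = coexpression.adjacency(cm, sft.power, signed=config.signed)
    tom = coexpression.tom_similarity(adj)
    dend = coexpression.cluster_genes(tom)
    modules = coexpression.cut_modules(
        dend, min_module_size=config.min_module_size, deep_split=config.deep_split
    )
    outputs = [outdir / "soft_threshold.tsv"]
    sft.write(outputs[0])
    if (modules != coexpression.GREY).sum() == 0:
        warnings.warn("no module passed the size threshold; downstream stages will be empty")
        selected: list[int] = []
        mod_path = outdir / "modules.tsv"
        modules.rename("module").to_frame().rename_axis("gene_id").to_csv(mod_path, sep="\t")
        sel_path = outdir / "selected_modules.tsv"
        pd.DataFrame(columns=["module", "trait_r", "trait_p", "mm_gs_r", "mm_gs_p", "selected"]).to_csv(
            sel_path, sep="\t", index=False
        )
        return outputs + [mod_path, sel_path]
    mes = coexpression.module_eigengenes(ds, modules)
    modules, mes = coexpression.merge_close_modules(
        ds, modules, mes, cut_height=config.merge_cut_height
    )
    trait = ds.trait
    trait_cors = coexpression.module_trait_correlation(mes, trait)
    stats = coexpression.gene_module_stats(ds, modules, mes, trait)
    mmgs = {}
    for label in trait_cors.index:
        try:
            mmgs[label] = coexpression.mm_gs_correlation(stats, label)
        except io_preprocess.ExpressionError:
            mmgs[label] = (np.nan, np.nan)
    mmgs_r = pd.Series({m: v[0] for m, v in mmgs.items()})
    selected = coexpression.select_significant_modules(
        trait_cors, mmgs_r.dropna(), trait_cut=config.trait_cut, mmgs_cut=config.mmgs_cut
    )
    if not selected:
        warnings.warn("no module passed the trait/MM-GS selection thresholds")

    mod_path = outdir / "modules.tsv"
    modules.rename("module").to_frame().rename_axis("gene_id").to_csv(mod_path, sep="\t")
    me_path = outdir / "module_eigengenes.tsv"
    mes.write(me_path)
    stats_path = outdir / "gene_module_stats.tsv"
    stats.rename_axis("gene_id").to_csv(stats_path, sep="\t")
    sel_path = outdir / "selected_modules.tsv"
    sel_table = pd.DataFrame(
        {
            "module": trait_cors.index,
            "trait_r": trait_cors["r"].to_numpy(),
            "trait_p": trait_cors["p"].to_numpy(),
            "mm_gs_r": [mmgs[m][0] for m in trait_cors.index],
            "mm_gs_p": [mmgs[m][1] for m in trait_cors.index],
            "selected": [m in selected for m in trait_cors.index],
        }
    )
    sel_table.to_csv(sel_path, sep="\t", index=False)
    return outputs + [mod_path, me_path, stats_path, sel_path]


def _read_selected_modules(outdir: Path) -> list[int]:
    sel = pd.read_csv(outdir / "selected_modules.tsv", sep="\t")
    if sel.empty:
        return []
    return [int(m) for m in sel.loc[sel["selected"], "module"]]


def stage_diffcorr(config: PipelineConfig, outdir: Path) -> list[Path]:
    ds = io_preprocess.read_expression(
        outdir / "expression_qc.tsv", outdir / "phenotype_qc.tsv"
    )
    modules = pd.read_csv(outdir / "modules.tsv", sep="\t", index_col=0)["module"]
    outputs: list[Path] = []
    for label in _read_selected_modules(outdir):
        genes = list(modules.index[modules == label])
        records = diffcorr.pairwise_differential_correlations(
            ds, genes=genes, module=label, method=config.correlation_method
        )
        records, fit = diffcorr.local_fdr(records)
        rec_path = outdir / f"diffcorr_module{label}.tsv"
        diffcorr.write_records(records, rec_path)
        top = diffcorr.top_differential_pairs(records, k=10, lfdr_max=config.lfdr_threshold)
        top_path = outdir / f"top_pairs_module{label}.tsv"
        diffcorr.write_records(top, top_path)
        clusters = diffcorr.eigen_molecule_clusters(
            ds, genes=genes, cutoff=config.eigen_cluster_cutoff
        )
        cl_path = outdir / f"eigen_clusters_module{label}.tsv"
        clusters.labels.rename("cluster").to_frame().rename_axis("gene_id").to_csv(
            cl_path, sep="\t"
        )
        meta_path = outdir / f"lfdr_fit_module{label}.json"
        meta_path.write_text(json.dumps(dataclasses.asdict(fit), indent=1))
        outputs += [rec_path, top_path, cl_path, meta_path]
    return outputs


def stage_network(config: PipelineConfig, outdir: Path) -> list[Path]:
    ds = io_preprocess.read_expression(
        outdir / "expression_qc.tsv", outdir / "phenotype_qc.tsv"
    )
    record_paths = sorted(outdir.glob("diffcorr_module*.tsv"))
    if record_paths:
        records = pd.concat(
            [diffcorr.read_records(p) for p in record_paths], ignore_index=True
        )
        edges = switch_network.detect_switched_pairs(
            records, threshold=config.switch_threshold, lfdr_max=config.lfdr_threshold
        )
    else:
        warnings.warn("no differential-correlation records; network will be empty")
        edges = switch_network.detect_switched_pairs(
            pd.DataFrame(columns=["molecule_X", "molecule_Y", "r1", "r2", "lfdr"])
        )
    directions = switch_network.de_direction(ds, alpha=config.de_alpha)
    tables = switch_network.build_network(edges, directions)
    outputs: list[Path] = []
    for fmt in config.network_formats:
        fmt_up = fmt.upper()
        if fmt_up == "SIF":
            outputs += switch_network.export_network(tables, outdir / "network.sif", "SIF")
        elif fmt_up == "GRAPHML":
            outputs += switch_network.export_network(
                tables, outdir / "network.graphml", "GraphML"
            )
        else:
            outputs += switch_network.export_network(tables, outdir / "network", "TSV")
    de_path = outdir / "de_direction.tsv"
    directions.rename_axis("gene_id").to_csv(de_path, sep="\t")
    hub_path = outdir / "hub_genes.tsv"
    switch_network.hub_genes(tables).to_csv(hub_path, sep="\t", index=False)
    return outputs + [de_path, hub_path]


def stage_survival(config: PipelineConfig, outdir: Path) -> list[Path]:
    ds = io_preprocess.read_expression(
        outdir / "expression_qc.tsv", outdir / "phenotype_qc.tsv"
    )
    pheno = ds.phenotype
    if pheno is None or "time" not in pheno.columns or "event" not in pheno.columns:
        warnings.warn("phenotype table has no time/event columns; skipping survival scan")
        return []
    gene = config.survival_gene
    if gene is None:
        hubs = pd.read_csv(outdir / "hub_genes.tsv", sep="\t")
        if hubs.empty:
            warnings.warn("no network hubs available; skipping survival scan")
            return []
        gene = str(hubs["gene"].iloc[0])
    if gene not in ds.values.index:
        raise io_preprocess.ExpressionError(f"survival gene {gene!r} not in dataset")
    keep = pheno["time"].notna() & pheno["event"].notna()
    table = pd.DataFrame(
        {
            "time": pheno.loc[keep, "time"].astype(float),
            "event": pheno.loc[keep, "event"].astype(int),
            "expression": ds.values.loc[gene, keep.index[keep]],
        }
    )
    scan = clinical_stats.cutoff_scan(table)
    scan_path = outdir / f"survival_scan_{gene}.tsv"
    scan.write(scan_path)
    groups = np.where(table["expression"] <= scan.best_cutoff, "low", "high")
    curves = clinical_stats.km_by_group(table, groups)
    km_paths = []
    for label, curve in curves.items():
        p = outdir / f"km_{gene}_{label}.tsv"
        curve.to_csv(p, sep="\t", index=False)
        km_paths.append(p)
    summary = outdir / f"survival_best_{gene}.json"
    summary.write_text(
        json.dumps(
            {
                "gene": gene,
                "best_percentile": scan.best_percentile,
                "best_cutoff": scan.best_cutoff,
                "best_p": scan.best_p,
                "n_low": scan.n_low,
                "n_high": scan.n_high,
                "caveat": scan.caveat,
            },
            indent=1,
        )
    )
    return [scan_path, summary] + km_paths


_STAGES = [
    ("qc", stage_qc),
    ("coexpress", stage_coexpress),
    ("diffcorr", stage_diffcorr),
    ("network", stage_network),
    ("survival", stage_survival),
]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in order, writing outputs and a manifest to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(outdir)
    manifest = RunManifest(
        config_hash=config.hash(),
        versions={"dcornet": __version__, "numpy": np.__version__, "pandas": pd.__version__},
    )
    config.to_toml(outdir / "config.toml")
    for name, fn in _STAGES:
        if name == "survival" and not config.survival_scan:
            continue
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                outputs = fn(config, outdir)
            for w in caught:
                msg = f"{name}: {w.message}"
                logger.warning(msg)
                manifest.warnings.append(msg)
        except Exception as exc:
            manifest.write(outdir / "manifest.partial.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.add_stage(name, time.perf_counter() - t0, _checksums(outputs))
        logger.info("stage %s finished (%d outputs)", name, len(outputs))
    manifest.write(outdir / "manifest.json")
    return manifest


def _setup_run_logging(outdir: Path) -> None:
    root = logging.getLogger("dcornet")
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (outdir / "run.log").resolve()
        for h in root.handlers
    ):
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
        root.addHandler(handler)
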