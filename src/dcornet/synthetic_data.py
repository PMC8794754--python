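"""Synthetic two-condition expression data with planted structure.

The generator plants three kinds of signal so downstream stages have
ground truth to recover:

* latent-factor co-expression modules whose factors correlate with the
  binary condition (the trait) at a configurable level,
* gene pairs sharing a private factor whose correlation flips sign
  between conditions ("switched" pairs),
* background genes of i.i.d. noise.

Module factors are built from the z-scored condition indicator plus
residual noise that is empirically orthogonalized against the indicator
and against earlier factors, so each factor hits its target trait
correlation exactly while distinct modules stay uncorrelated in the
pooled sample. All randomness derives from one seed through fixed
per-component substreams, so adding genes or modules never perturbs
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import (
    CONDITION_A,
    CONDITION_B,
    ExpressionDataset,
    write_expression,
)

# substream domains for the counter-based seed split
_DOM_MODULE_FACTOR = 1
_DOM_GENE = 2
_DOM_PAIR = 3
_DOM_NULL = 4
_DOM_SURVIVAL = 5


class SimulationError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure generator.

    ``n_genes`` covers module genes, switched-pair genes and background;
    whatever is not assigned to a module or a pair is background noise.
    """

    n_genes: int = 200
    n_samples_A: int = 100
    n_samples_B: int = 300
    module_sizes: tuple[int, ...] = (50, 50)
    module_trait_cor: tuple[float, ...] = (0.7, -0.7)
    n_switched_pairs: int = 10
    switch_strength: float = 0.7
    n_hub_partners: int = 0
    noise_sd: float = 0.3
    background_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(int(m) for m in self.module_sizes))
        object.__setattr__(
            self, "module_trait_cor", tuple(float(c) for c in self.module_trait_cor)
        )
        if self.n_genes <= 0:
            raise SimulationError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_samples_A < 4:
            raise SimulationError(
                f"n_samples_A must be >= 4 (Fisher z needs n > 3), got {self.n_samples_A}"
            )
        if self.n_samples_B < 4:
            raise SimulationError(
                f"n_samples_B must be >= 4 (Fisher z needs n > 3), got {self.n_samples_B}"
            )
        if any(m < 2 for m in self.module_sizes):
            raise SimulationError(f"module_sizes entries must be >= 2, got {self.module_sizes}")
        if len(self.module_trait_cor) != len(self.module_sizes):
            raise SimulationError(
                "module_trait_cor must have one entry per module "
                f"({len(self.module_sizes)} modules, {len(self.module_trait_cor)} correlations)"
            )
        if any(not -1.0 <= c <= 1.0 for c in self.module_trait_cor):
            raise SimulationError(
                f"module_trait_cor entries must lie in [-1, 1], got {self.module_trait_cor}"
            )
        if self.n_switched_pairs < 0:
            raise SimulationError(
                f"n_switched_pairs must be non-negative, got {self.n_switched_pairs}"
            )
        if not 0.0 < self.switch_strength < 1.0:
            raise SimulationError(
                f"switch_strength must lie in (0, 1), got {self.switch_strength}"
            )
        if self.noise_sd < 0:
            raise SimulationError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.n_hub_partners < 0:
            raise SimulationError(
                f"n_hub_partners must be non-negative, got {self.n_hub_partners}"
            )
        planted = sum(self.module_sizes) + 2 * self.n_switched_pairs + self._n_hub_genes
        if planted > self.n_genes:
            raise SimulationError(
                f"module_sizes plus switched-pair genes need {planted} genes "
                f"but n_genes is only {self.n_genes}"
            )
        if self.background_fraction is not None:
            actual = (self.n_genes - planted) / self.n_genes
            if abs(actual - self.background_fraction) > 0.5 / self.n_genes + 1e-9:
                raise SimulationError(
                    f"background_fraction={self.background_fraction} inconsistent with "
                    f"n_genes={self.n_genes} and planted genes={planted} "
                    f"(actual fraction {actual:.4f})"
                )
        n = self.n_samples_A + self.n_samples_B
        if n < len(self.module_sizes) + 2:
            raise SimulationError(
                "too few samples to orthogonalize module factors against the trait"
            )

    @property
    def n_samples(self) -> int:
        return self.n_samples_A + self.n_samples_B

    @property
    def _n_hub_genes(self) -> int:
        return 1 + self.n_hub_partners if self.n_hub_partners > 0 else 0

    @property
    def n_background(self) -> int:
        return (
            self.n_genes
            - sum(self.module_sizes)
            - 2 * self.n_switched_pairs
            - self._n_hub_genes
        )


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset.

    ``module_of_gene`` maps gene id to module label (0 = background or
    switched-pair gene). ``switched_pairs`` holds
    ``(geneX, geneY, sign_A, sign_B)`` with ``sign_A == -sign_B``.
    ``module_factors`` keeps the latent per-sample factors for tests.
    """

    module_of_gene: pd.Series
    switched_pairs: list[tuple[str, str, int, int]]
    hub_gene: str | None = None
    survival_driver_gene: str | None = None
    module_factors: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "module_of_gene": {g: int(m) for g, m in self.module_of_gene.items()},
            "switched_pairs": [
                [gx, gy, int(sa), int(sb)] for gx, gy, sa, sb in self.switched_pairs
            ],
            "hub_gene": self.hub_gene,
            "survival_driver_gene": self.survival_driver_gene,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            module_of_gene=pd.Series(payload["module_of_gene"], dtype=int),
            switched_pairs=[
                (gx, gy, int(sa), int(sb))
                for gx, gy, sa, sb in payload["switched_pairs"]
            ],
            hub_gene=payload.get("hub_gene"),
            survival_driver_gene=payload.get("survival_driver_gene"),
        )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise SimulationError("degenerate vector in factor construction")
    return (v - v.mean()) / sd


def _orthogonal_unit_residual(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Center ``v``, project out the (centered, unit) basis vectors, rescale."""
    r = v - v.mean()
    for b in basis:
        r = r - (r @ b) / (b @ b) * b
    return _standardize(r)


def generate_two_condition_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a two-condition dataset with planted modules and switches.

    Gene layout: module genes first (module 1, module 2, ...), then the
    switched pairs, then background genes. Sample layout: condition A
    (normal) samples first, then condition B (tumor).
    """
    cfg = config
    n = cfg.n_samples
    sample_ids = [f"S{j:04d}" for j in range(n)]
    condition = pd.Series(
        [CONDITION_A] * cfg.n_samples_A + [CONDITION_B] * cfg.n_samples_B,
        index=sample_ids,
    )
    trait = (condition == CONDITION_B).to_numpy(dtype=float)
    t_std = _standardize(trait)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    values = np.empty((cfg.n_genes, n))
    module_of_gene = np.zeros(cfg.n_genes, dtype=int)

    # module factors: exact trait correlation, pooled-orthogonal across modules
    basis = [t_std]
    factors = []
    for m, c in enumerate(cfg.module_trait_cor):
        u = _rng(cfg.seed, _DOM_MODULE_FACTOR, m).standard_normal(n)
        u_perp = _orthogonal_unit_residual(u, basis)
        basis.append(u_perp)
        factors.append(c * t_std + np.sqrt(1.0 - c * c) * u_perp)

    g = 0
    for m, size in enumerate(cfg.module_sizes):
        f = factors[m]
        for _ in range(size):
            grng = _rng(cfg.seed, _DOM_GENE, g)
            loading = grng.uniform(0.5, 1.0)
            eps = grng.standard_normal(n)
            values[g] = loading * f + cfg.noise_sd * eps
            module_of_gene[g] = m + 1
            g += 1

    # switched pairs: shared private factor, partner loading flips sign in B
    s = cfg.switch_strength
    delta = np.sqrt(1.0 / s - 1.0)
    switched_pairs: list[tuple[str, str, int, int]] = []
    for k in range(cfg.n_switched_pairs):
        prng = _rng(cfg.seed, _DOM_PAIR, k)
        shared = prng.standard_normal(n)
        sign_a = 1 if prng.integers(0, 2) == 1 else -1
        flip = np.where(condition.to_numpy() == CONDITION_A, sign_a, -sign_a)
        gx, gy = g, g + 1
        ex = _rng(cfg.seed, _DOM_GENE, gx).standard_normal(n)
        ey = _rng(cfg.seed, _DOM_GENE, gy).standard_normal(n)
        values[gx] = np.sqrt(s) * (shared + delta * ex)
        values[gy] = np.sqrt(s) * (flip * shared + delta * ey)
        switched_pairs.append((gene_ids[gx], gene_ids[gy], sign_a, -sign_a))
        g += 2

    # optional hub: one gene in a switched pair with each of its partners
    hub_gene = None
    if cfg.n_hub_partners > 0:
        hub_idx = g
        hub_gene = gene_ids[hub_idx]
        hrng = _rng(cfg.seed, _DOM_PAIR, cfg.n_switched_pairs)
        shared = hrng.standard_normal(n)
        e_hub = _rng(cfg.seed, _DOM_GENE, hub_idx).standard_normal(n)
        values[hub_idx] = np.sqrt(s) * (shared + delta * e_hub)
        g += 1
        flip = np.where(condition.to_numpy() == CONDITION_A, 1.0, -1.0)
        for _ in range(cfg.n_hub_partners):
            ep = _rng(cfg.seed, _DOM_GENE, g).standard_normal(n)
            values[g] = np.sqrt(s) * (flip * shared + delta * ep)
            switched_pairs.append((hub_gene, gene_ids[g], 1, -1))
            g += 1

    for _ in range(cfg.n_background):
        values[g] = _rng(cfg.seed, _DOM_GENE, g).standard_normal(n)
        g += 1

    ds = ExpressionDataset(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), condition
    )
    truth = GroundTruth(
        module_of_gene=pd.Series(module_of_gene, index=gene_ids),
        switched_pairs=switched_pairs,
        hub_gene=hub_gene,
        module_factors=pd.DataFrame(
            np.column_stack(factors) if factors else np.empty((n, 0)),
            index=sample_ids,
            columns=[f"M{m + 1}" for m in range(len(cfg.module_sizes))],
        ),
    )
    return ds, truth


def generate_null_dataset(
    n_genes: int, n_A: int, n_B: int, seed: int = 0
) -> ExpressionDataset:
    """Every gene i.i.d. standard normal in both conditions.

    No gene pair carries differential correlation by construction, which
    makes this the type-I-error benchmark for the differential-correlation
    test.
    """
    if n_genes <= 0:
        raise SimulationError(f"n_genes must be positive, got {n_genes}")
    if n_A < 4 or n_B < 4:
        raise SimulationError(
            f"n_A and n_B must be >= 4 (Fisher z needs n > 3), got {n_A}, {n_B}"
        )
    n = n_A + n_B
    values = _rng(seed, _DOM_NULL).standard_normal((n_genes, n))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n)]
    condition = pd.Series([CONDITION_A] * n_A + [CONDITION_B] * n_B, index=sample_ids)
    return ExpressionDataset(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), condition
    )


def generate_survival_data(
    expression,
    beta: float,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times whose hazard scales with expression.

    Event times are exponential with rate
    ``baseline_rate * exp(beta * z)`` where ``z`` is the z-scored
    expression; censoring times are independent exponentials with rate
    ``censor_rate``. Returns a table with ``time``, ``event`` (1 = death
    observed) and ``expression`` columns.
    """
    expr = pd.Series(expression).astype(float)
    if not np.isfinite(expr.to_numpy()).all():
        raise SimulationError("expression must be finite")
    if baseline_rate <= 0 or censor_rate <= 0:
        raise SimulationError(
            f"rates must be positive, got baseline_rate={baseline_rate}, "
            f"censor_rate={censor_rate}"
        )
    sd = expr.std(ddof=0)
    z = (expr - expr.mean()) / sd if sd > 0 else expr * 0.0
    rate = baseline_rate * np.exp(beta * z.to_numpy())
    rng = _rng(seed, _DOM_SURVIVAL)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_rate, size=len(expr))
    return pd.DataFrame(
        {
            "time": np.minimum(event_time, censor_time),
            "event": (event_time <= censor_time).astype(int),
            "expression": expr.to_numpy(),
        },
        index=expr.index,
    )


def simulate_to_files(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write expression/phenotype TSVs plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth = generate_two_condition_expression(config)
    paths = {
        "expression": outdir / "expression.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_expression(ds, paths["expression"], phenotype_path=paths["phenotype"])
    truth.to_json(paths["ground_truth"])
    return paths
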