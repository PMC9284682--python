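"""Synthetic RNA-seq count data with group effects, batch effects and quality coupling.

Counts for gene g in sample s are negative binomial with mean

    mu_gs = baseline_g
            * 2^(group_log2fc * [g is a group gene and s in the affected group])
            * 2^(batch_log2fc * w_s * [g is a batch gene and s in the affected batch])

and variance mu + dispersion * mu^2.  The per-sample weight
``w_s = (1 - quality_coupling) + quality_coupling * p_low_s / max(p_low)``
couples the batch-effect magnitude to sample quality: at coupling 0 the
batch effect is a flat multiplier, at coupling 1 it scales with p_low.

Per-sample quality is ``p_low_s = clip(plow_base + plow_batch_shift * [s in
shifted batch] + Normal(0, plow_noise_sd), 0, 1)``.  The lexicographically
last batch label is both the "shifted" batch (higher p_low) and the
"affected" batch (carries the expression batch effect); the lexicographically
last group is the affected group.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plowbatch.io_core import CountMatrix, SampleTable, ValidationError
import pandas as pd


class ConfigError(ValueError):
    """The simulation design is impossible (one group, too few samples...)."""


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    samples_per_cell: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("g1", "b1"): 10,
            ("g1", "b2"): 10,
            ("g2", "b1"): 10,
            ("g2", "b2"): 10,
        }
    )
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    frac_group_genes: float = 0.1
    group_log2fc: float = 1.5
    frac_batch_genes: float = 0.1
    batch_log2fc: float = 2.0
    plow_base: float = 0.2
    plow_batch_shift: float = 0.4
    plow_noise_sd: float = 0.05
    quality_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        for frac in (self.frac_group_genes, self.frac_batch_genes, self.quality_coupling):
            if not 0 <= frac <= 1:
                raise ConfigError("fractions and quality_coupling must be in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if self.group_log2fc < 0 or self.batch_log2fc < 0:
            raise ConfigError("log2 fold changes must be >= 0")
        if self.plow_noise_sd < 0:
            raise ConfigError("plow_noise_sd must be >= 0")
        total = sum(self.samples_per_cell.values())
        if total < 4:
            raise ConfigError("total samples must be >= 4")
        groups = {g for g, _ in self.samples_per_cell}
        if len(groups) < 2:
            raise ConfigError("design needs at least 2 groups")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_cell.values())


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for recovery tests."""

    group_gene_ids: list[str]
    batch_gene_ids: list[str]
    batch_multiplier: dict[str, float]  # per-sample true batch-effect multiplier on batch genes
    p_low_raw: dict[str, float]  # per-sample p_low before clipping
    affected_group: str
    affected_batch: str


def simulate_dataset(config: SimulationConfig) -> tuple[CountMatrix, SampleTable, SimulationTruth]:
    """Draw one dataset; fully reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)

    cells = sorted(config.samples_per_cell.items())
    sample_groups: list[str] = []
    sample_batches: list[str] = []
    for (group, batch), n in cells:
        sample_groups += [group] * n
        sample_batches += [batch] * n
    n_samples = len(sample_groups)
    sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]

    batches = sorted(set(sample_batches))
    groups = sorted(set(sample_groups))
    affected_batch = batches[-1]
    affected_group = groups[-1]

    in_affected_group = np.array([g == affected_group for g in sample_groups])
    in_affected_batch = np.array([b == affected_batch for b in sample_batches])

    # quality scores
    shift = np.where(in_affected_batch, config.plow_batch_shift, 0.0)
    raw_plow = config.plow_base + shift + rng.normal(0.0, config.plow_noise_sd, size=n_samples)
    p_low = np.clip(raw_plow, 0.0, 1.0)

    max_plow = p_low.max()
    scaled = p_low / max_plow if max_plow > 0 else np.zeros_like(p_low)
    w = (1.0 - config.quality_coupling) + config.quality_coupling * scaled

    # gene roles: disjoint group-gene and batch-gene sets
    n_group_genes = int(round(config.frac_group_genes * config.n_genes))
    n_batch_genes = int(round(config.frac_batch_genes * config.n_genes))
    perm = rng.permutation(config.n_genes)
    group_idx = perm[:n_group_genes]
    batch_idx = perm[n_group_genes : n_group_genes + n_batch_genes]

    # per-gene baselines lognormal around baseline_mean for realistic size-factor spread
    baseline = rng.lognormal(mean=np.log(config.baseline_mean), sigma=1.0, size=config.n_genes)

    log2mu = np.log2(baseline)[:, None] * np.ones((1, n_samples))
    is_group_gene = np.zeros(config.n_genes, dtype=bool)
    is_group_gene[group_idx] = True
    is_batch_gene = np.zeros(config.n_genes, dtype=bool)
    is_batch_gene[batch_idx] = True
    log2mu += config.group_log2fc * np.outer(is_group_gene, in_affected_group)
    log2mu += config.batch_log2fc * np.outer(is_batch_gene, in_affected_batch * w)
    mu = 2.0**log2mu

    # NB with var = mu + dispersion * mu^2  ->  shape r = 1/dispersion, p = r/(r+mu)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(gene_ids, sample_ids, counts)
    table = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": sample_groups,
                "batch": sample_batches,
                "p_low": p_low,
            }
        )
    )
    truth = SimulationTruth(
        group_gene_ids=[gene_ids[i] for i in sorted(group_idx)],
        batch_gene_ids=[gene_ids[i] for i in sorted(batch_idx)],
        batch_multiplier={
            s: float(2.0 ** (config.batch_log2fc * w_s) if aff else 1.0)
            for s, w_s, aff in zip(sample_ids, w, in_affected_batch)
        },
        p_low_raw=dict(zip(sample_ids, raw_plow.astype(float))),
        affected_group=affected_group,
        affected_batch=affected_batch,
    )
    return cm, table, truth


def inject_outliers(
    counts: CountMatrix,
    table: SampleTable,
    k: int,
    severity: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, SampleTable, list[str]]:
    """Turn ``k`` random samples into quality outliers.

    Chosen samples get ``p_low`` raised by 0.5 (capped at 1) and their counts
    multiplied gene-wise by iid lognormal(0, severity) noise, emulating the
    skewing samples that manual inspection would remove.  Returns modified
    copies and the chosen sample ids; inputs are not mutated.
    """
    n = counts.n_samples
    if not 0 <= k < n:
        raise ValidationError(f"k must satisfy 0 <= k < n_samples, got k={k}, n={n}")
    if severity <= 0:
        raise ValidationError("severity must be > 0")
    if k == 0:
        return counts, table, []
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(n, size=k, replace=False).tolist())
    new_counts = counts.counts.astype(float).copy()
    for j in chosen:
        noise = rng.lognormal(mean=0.0, sigma=severity, size=counts.n_genes)
        new_counts[:, j] = np.round(new_counts[:, j] * noise)
    new_df = table.data.copy()
    ids = [counts.sample_ids[j] for j in chosen]
    mask = new_df["sample_id"].isin(ids)
    new_df.loc[mask, "p_low"] = np.minimum(1.0, new_df.loc[mask, "p_low"] + 0.5)
    cm = CountMatrix(list(counts.gene_ids), list(counts.sample_ids), new_counts.astype(np.int64))
    ann = table.annotations.copy() if table.annotations is not None else None
    return cm, SampleTable(new_df, ann), ids
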