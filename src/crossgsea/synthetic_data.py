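"""Synthetic multi-dataset expression compendia with planted pathway effects.

The generator emulates the kind of compendium the pipeline is built for:
several independent case/control microarray studies of one disease, each
measuring an overlapping but not identical slice of a common gene universe,
each with multiple probes per gene, on a log2 intensity scale.  A chosen
subset of pathways is "planted" as dysregulated — member genes receive a
mean shift of +delta (up) or -delta (down) in the case group — so every
downstream stage (filtering, per-dataset GSEA, cross-study consensus, the
gene-level meta-analysis, over-representation) has an exact ground truth.

Generative model (all on the log2 scale):

* gene baseline means are drawn once per compendium from Normal(8, 2^2),
  mimicking RMA-normalized intensity ranges;
* each measured gene carries 1..probes_per_gene_max probes whose
  probe-specific offsets are Normal(0, 0.25^2);
* a sample value is baseline + probe offset + group effect + Normal(0, sigma^2);
* the group effect is +delta for an affected gene of a planted-up set in a
  case sample, -delta for planted-down, 0 otherwise; a gene affected in
  both directions (possible because sets may overlap) nets to 0;
* "affected" genes are a fixed per-set random subset of size
  ceil(affected_fraction * |set|), shared across all datasets, so
  cross-dataset consensus is learnable by design;
* each dataset measures a random gene_coverage fraction of the universe but
  always includes every affected gene of each planted set.

Randomness is organised as fixed-offset substreams of the config seed: the
collection, the compendium-level quantities (baselines, affected subsets)
and each dataset draw from independent streams, so adding datasets never
perturbs earlier ones and every output is bit-reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    Manifest,
    ManifestRow,
    write_expression_matrix,
    write_gmt,
    write_manifest,
)

__all__ = [
    "SimulationConfig",
    "generate_collection",
    "simulate_dataset",
    "simulate_compendium",
    "truth_table",
    "write_compendium",
]

# substream tags appended to the config seed
_STREAM_COLLECTION = 1
_STREAM_COMPENDIUM = 2
_STREAM_DATASET_BASE = 1000

_BASELINE_MEAN = 8.0
_BASELINE_SD = 2.0
_PROBE_OFFSET_SD = 0.25


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic compendium.

    Defaults describe a six-study compendium of 10 vs 10 samples with a
    1.5 log2-unit shift planted in two up- and two down-regulated pathways
    at sigma = 0.5 within-group noise — a regime where a single study can
    call a pathway but cross-study consensus is the interesting question.
    """

    n_genes: int = 800
    n_sets: int = 40
    set_size_range: tuple[int, int] = (10, 40)
    n_datasets: int = 6
    cases_per_dataset: tuple[int, ...] = (10,) * 6
    controls_per_dataset: tuple[int, ...] = (10,) * 6
    gene_coverage: float = 0.8
    probes_per_gene_max: int = 3
    effect_size: float = 1.5
    affected_fraction: float = 1.0
    noise_sd: float = 0.5
    planted_up: tuple[str, ...] = ("SET001", "SET002")
    planted_down: tuple[str, ...] = ("SET003", "SET004")
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases_per_dataset", tuple(self.cases_per_dataset))
        object.__setattr__(
            self, "controls_per_dataset", tuple(self.controls_per_dataset)
        )
        object.__setattr__(self, "planted_up", tuple(self.planted_up))
        object.__setattr__(self, "planted_down", tuple(self.planted_down))
        object.__setattr__(self, "set_size_range", tuple(self.set_size_range))
        if self.n_genes < 1 or self.n_sets < 1 or self.n_datasets < 1:
            raise ValueError("n_genes, n_sets and n_datasets must all be >= 1")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid set_size_range {self.set_size_range}")
        if hi > self.n_genes:
            raise ValueError(
                f"set_size_range max {hi} exceeds gene universe size {self.n_genes}"
            )
        if len(self.cases_per_dataset) != self.n_datasets:
            raise ValueError("cases_per_dataset must have length n_datasets")
        if len(self.controls_per_dataset) != self.n_datasets:
            raise ValueError("controls_per_dataset must have length n_datasets")
        if min(self.cases_per_dataset) < 2 or min(self.controls_per_dataset) < 2:
            raise ValueError("every dataset needs >=2 cases and >=2 controls")
        if not (0.0 < self.gene_coverage <= 1.0):
            raise ValueError("gene_coverage must be in (0, 1]")
        if self.probes_per_gene_max < 1:
            raise ValueError("probes_per_gene_max must be >= 1")
        if not (0.0 < self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ValueError(
                f"planted_up and planted_down must be disjoint; both contain "
                f"{sorted(overlap)}"
            )
        for name in (*self.planted_up, *self.planted_down):
            if name not in self._set_names():
                raise ValueError(
                    f"planted set {name!r} is not among the generated set names "
                    f"(SET001..SET{self.n_sets:03d})"
                )

    def _set_names(self) -> tuple[str, ...]:
        return tuple(f"SET{i + 1:03d}" for i in range(self.n_sets))

    def _gene_names(self) -> np.ndarray:
        return np.array([f"G{i + 1:05d}" for i in range(self.n_genes)])


def generate_collection(config: SimulationConfig) -> GeneSetCollection:
    """Draw the pathway collection: n_sets sets, sizes uniform in
    set_size_range, members sampled without replacement within each set
    (different sets may overlap).  Deterministic given config.seed.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COLLECTION])
    genes = config._gene_names()
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    sets = []
    for name, size in zip(config._set_names(), sizes):
        members = rng.choice(genes, size=int(size), replace=False)
        sets.append(GeneSet(name, "synthetic pathway", tuple(members)))
    return GeneSetCollection(sets)


def _affected_genes(
    config: SimulationConfig, collection: GeneSetCollection
) -> tuple[dict[str, tuple[str, ...]], dict[str, float]]:
    """Per-set affected subsets (shared across datasets) and the net
    per-gene effect on the log2 scale."""
    rng = np.random.default_rng([config.seed, _STREAM_COMPENDIUM])
    # baseline draw comes first in this stream; skip it to keep alignment
    # with _compendium_baselines below
    rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_genes)
    affected: dict[str, tuple[str, ...]] = {}
    effect: dict[str, float] = {}
    for name in (*config.planted_up, *config.planted_down):
        members = np.array(collection.members(name))
        k = math.ceil(config.affected_fraction * len(members))
        chosen = rng.choice(members, size=k, replace=False)
        affected[name] = tuple(chosen)
        sign = 1.0 if name in config.planted_up else -1.0
        for g in chosen:
            effect[g] = effect.get(g, 0.0) + sign * config.effect_size
    return affected, effect


def _compendium_baselines(config: SimulationConfig) -> pd.Series:
    rng = np.random.default_rng([config.seed, _STREAM_COMPENDIUM])
    baselines = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=config.n_genes)
    return pd.Series(baselines, index=config._gene_names())


def truth_table(config: SimulationConfig) -> dict[str, str]:
    """Ground truth per set name: 'up', 'down' or 'null'."""
    truth = {name: "null" for name in config._set_names()}
    for name in config.planted_up:
        truth[name] = "up"
    for name in config.planted_down:
        truth[name] = "down"
    return truth


def simulate_dataset(
    config: SimulationConfig,
    collection: GeneSetCollection,
    dataset_index: int,
) -> ExpressionDataset:
    """Simulate one study of the compendium (see module docstring)."""
    if not (0 <= dataset_index < config.n_datasets):
        raise ValueError(
            f"dataset_index {dataset_index} out of range for "
            f"{config.n_datasets} datasets"
        )
    baselines = _compendium_baselines(config)
    _, effect_of_gene = _affected_genes(config, collection)

    rng = np.random.default_rng(
        [config.seed, _STREAM_DATASET_BASE + dataset_index]
    )
    genes = config._gene_names()
    n_measured = max(1, round(config.gene_coverage * config.n_genes))
    forced = [g for g in genes if g in effect_of_gene]
    pool = np.array([g for g in genes if g not in effect_of_gene])
    n_extra = max(0, n_measured - len(forced))
    extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
    measured_set = set(forced) | set(extra)
    measured = [g for g in genes if g in measured_set]  # universe order

    n_probes_per_gene = rng.integers(
        1, config.probes_per_gene_max + 1, size=len(measured)
    )
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    for g, k in zip(measured, n_probes_per_gene):
        for j in range(int(k)):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_gene.append(g)
    n_probes = len(probe_ids)

    n_case = config.cases_per_dataset[dataset_index]
    n_control = config.controls_per_dataset[dataset_index]
    dataset_id = f"D{dataset_index + 1}"
    sample_ids = [f"{dataset_id}_case{j + 1}" for j in range(n_case)] + [
        f"{dataset_id}_ctrl{j + 1}" for j in range(n_control)
    ]
    groups = [CASE] * n_case + [CONTROL] * n_control

    base = baselines.loc[probe_gene].to_numpy()
    probe_offset = rng.normal(0.0, _PROBE_OFFSET_SD, size=n_probes)
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, len(sample_ids)))
    values = base[:, None] + probe_offset[:, None] + noise
    gene_effect = np.array([effect_of_gene.get(g, 0.0) for g in probe_gene])
    values[:, :n_case] += gene_effect[:, None]

    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sample_ids),
        gene_of_probe=pd.Series(probe_gene, index=pd.Index(probe_ids, name="probe_id"),
                                name="gene"),
        group_of_sample=pd.Series(groups, index=pd.Index(sample_ids), name="group"),
    )


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[GeneSetCollection, list[ExpressionDataset], dict[str, str]]:
    """Collection, all datasets and the truth table in one call."""
    collection = generate_collection(config)
    datasets = [
        simulate_dataset(config, collection, i) for i in range(config.n_datasets)
    ]
    return collection, datasets, truth_table(config)


def write_compendium(config: SimulationConfig, outdir: str | Path) -> Manifest:
    """Materialise a compendium on disk: GMT collection, per-dataset matrix
    and label TSVs, a manifest TSV, and the truth table as two-column TSV.
    Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, datasets, truth = simulate_compendium(config)
    write_gmt(collection, outdir / "collection.gmt")
    rows = []
    for ds in datasets:
        mpath = outdir / f"{ds.dataset_id}.expr.tsv"
        lpath = outdir / f"{ds.dataset_id}.expr.labels.tsv"
        write_expression_matrix(ds, mpath, lpath)
        rows.append(
            ManifestRow(
                dataset_id=ds.dataset_id,
                matrix_path=mpath.name,
                labels_path=lpath.name,
                n_case=ds.n_case,
                n_control=ds.n_control,
            )
        )
    manifest = Manifest(tuple(rows))
    write_manifest(manifest, outdir / "manifest.tsv")
    pd.DataFrame(
        {"set_name": list(truth), "direction": list(truth.values())}
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    return manifest
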