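"""Synthetic matched tumour/normal cohorts with planted structure.

The generator emulates, on the natural-log scale, the statistical structure
the analysis pipeline assumes:

* per-gene baselines drawn uniformly over a log-expression range, plus a
  per-(gene, site) offset — different tissues express different baselines;
* normal samples: baseline + Gaussian noise;
* tumour samples: baseline + a cluster-specific activation shift applied to
  the member genes of each planted module + a per-(module, sample) latent
  factor whose loading is scaled so that two member genes correlate at the
  configured level (within a cluster) + the same Gaussian noise;
* latent tumour clusters: sites designated *stratified* have their tumours
  split evenly across two clusters; the remaining sites each fall wholly
  into one of the remaining clusters — the dichotomy the stratification
  statistic is meant to detect.

Log values are exponentiated and floored at 1 so the output is a valid
TPM+1-scale matrix for either declared input scale. Everything is a pure
function of the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CONDITION_NORMAL,
    CONDITION_TUMOUR,
    SCALE_TPM,
    ExpressionMatrix,
    Pathway,
    PathwayCollection,
    SampleSheet,
)
from .network import UNASSIGNED


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module.

    ``shifts`` holds the mean activation (ln units) added to member genes in
    each latent cluster; its length must equal the number of clusters.
    ``correlation`` is the target Pearson correlation between member genes
    within a cluster, achieved through a shared latent factor; each gene's
    factor-variance share is drawn within ``correlation_spread`` of the
    target, giving modules the hub/periphery connectivity spread real
    co-expression modules show.
    """

    size: int = 40
    correlation: float = 0.6
    shifts: tuple[float, ...] = (2.0, 0.0, 0.0)
    correlation_spread: float = 0.25


def _default_modules() -> tuple[ModuleSpec, ...]:
    # one module activated per cluster: ~7.4-fold induction against silence
    return (
        ModuleSpec(size=60, correlation=0.6, shifts=(2.0, 0.0, 0.0)),
        ModuleSpec(size=45, correlation=0.6, shifts=(0.0, 2.0, 0.0)),
        ModuleSpec(size=35, correlation=0.6, shifts=(0.0, 0.0, 2.0)),
    )


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort. The seed is mandatory."""

    seed: int
    n_sites: int = 4
    tumours_per_site: int = 30
    normals_per_site: int = 25
    n_background_genes: int = 1000
    n_clusters: int = 3
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    stratified_sites: tuple[str, ...] = ("site-1", "site-2")
    stratified_clusters: tuple[int, ...] = (1, 2)
    noise_sd: float = 0.5
    site_sd: float = 0.3
    baseline_log_range: tuple[float, float] = (1.0, 6.0)
    # weak transcriptome-wide programs giving the network a soft correlation
    # floor and a heavy-tailed connectivity distribution, as real data has
    n_background_factors: int = 3
    background_rho_max: float = 0.3

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.tumours_per_site < 1 or self.normals_per_site < 1:
            raise ValueError("need at least one site and one sample per side per site")
        if self.n_clusters < 1:
            raise ValueError("need at least one latent cluster")
        for m in self.modules:
            if m.size < 2:
                raise ValueError("module size must be >= 2")
            if not (0.0 <= m.correlation < 1.0):
                raise ValueError(
                    f"member correlation must be in [0, 1), got {m.correlation}"
                )
            if len(m.shifts) != self.n_clusters:
                raise ValueError("each module needs one activation shift per cluster")
        if self.noise_sd < 0 or self.site_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_background_factors < 0 or not (0.0 <= self.background_rho_max < 1.0):
            raise ValueError("background factor settings out of range")
        if self.stratified_sites:
            valid = all(1 <= c <= self.n_clusters for c in self.stratified_clusters)
            if not valid or len(set(self.stratified_clusters)) < 2:
                raise ValueError(
                    "stratified_clusters must name >= 2 distinct clusters in range"
                )
            unknown = set(self.stratified_sites) - set(self.site_names())
            if unknown:
                raise ValueError(f"unknown stratified sites: {sorted(unknown)}")

    def site_names(self) -> list[str]:
        return [f"site-{i + 1}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """Planted structure: gene modules, latent tumour clusters, stratified sites."""

    module_of: pd.Series  # gene -> planted module label (or 'unassigned')
    cluster_of: pd.Series  # tumour sample -> latent cluster 1..k
    stratified: pd.Series  # site -> bool
    activation: pd.DataFrame  # modules x clusters, ln-unit shifts


def _latent_clusters(cfg: GeneratorConfig) -> pd.Series:
    """Deterministic site -> cluster layout implementing the stratified dichotomy."""
    remaining = [c for c in range(1, cfg.n_clusters + 1) if c not in cfg.stratified_clusters]
    if not remaining:
        remaining = list(range(1, cfg.n_clusters + 1))
    rotation = itertools.cycle(remaining)
    labels = []
    index = []
    for site in cfg.site_names():
        sample_ids = [f"T-{site}-{i + 1:03d}" for i in range(cfg.tumours_per_site)]
        if site in cfg.stratified_sites:
            split = cfg.stratified_clusters
            for i, sid in enumerate(sample_ids):
                labels.append(split[i % len(split)])
                index.append(sid)
        else:
            cluster = next(rotation)
            for sid in sample_ids:
                labels.append(cluster)
                index.append(sid)
    return pd.Series(labels, index=pd.Index(index, name="sample"), dtype=int)


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleSheet, GroundTruth]:
    """Draw one cohort: (tumour matrix, normal matrix, sample sheet, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    sites = cfg.site_names()

    module_labels = [f"module-{m + 1}" for m in range(len(cfg.modules))]
    gene_ids: list[str] = []
    gene_module: list[str] = []
    for label, spec in zip(module_labels, cfg.modules):
        for i in range(spec.size):
            gene_ids.append(f"G{len(gene_ids) + 1:05d}")
            gene_module.append(label)
    for _ in range(cfg.n_background_genes):
        gene_ids.append(f"G{len(gene_ids) + 1:05d}")
        gene_module.append(UNASSIGNED)
    n_genes = len(gene_ids)

    low, high = cfg.baseline_log_range
    baseline = rng.uniform(low, high, size=n_genes)
    site_offset = rng.normal(0.0, cfg.site_sd, size=(n_genes, cfg.n_sites))

    cluster_of = _latent_clusters(cfg)
    tumour_ids = list(cluster_of.index)
    normal_ids = [
        f"N-{site}-{i + 1:03d}" for site in sites for i in range(cfg.normals_per_site)
    ]
    t_site_idx = np.array([sites.index(s.split("-", 1)[1].rsplit("-", 1)[0]) for s in tumour_ids])
    n_site_idx = np.repeat(np.arange(cfg.n_sites), cfg.normals_per_site)

    # normals: baseline + site offset + noise
    normal_log = (
        baseline[:, None]
        + site_offset[:, n_site_idx]
        + rng.normal(0.0, cfg.noise_sd, size=(n_genes, len(normal_ids)))
    )

    # tumours: baseline + site offset + cluster activation + latent factor + noise
    tumour_log = (
        baseline[:, None]
        + site_offset[:, t_site_idx]
        + rng.normal(0.0, cfg.noise_sd, size=(n_genes, len(tumour_ids)))
    )
    cluster_idx = cluster_of.to_numpy() - 1
    activation = pd.DataFrame(
        [list(spec.shifts) for spec in cfg.modules],
        index=pd.Index(module_labels, name="module"),
        columns=pd.Index(range(1, cfg.n_clusters + 1), name="cluster"),
        dtype=float,
    )
    row = 0
    for label, spec in zip(module_labels, cfg.modules):
        members = slice(row, row + spec.size)
        shifts = np.asarray(spec.shifts)[cluster_idx]
        # per-gene factor-variance share around the target correlation;
        # loadings scale with the noise sd so cov/(cov + noise^2) = rho_g
        if spec.correlation > 0:
            rho_g = np.clip(
                rng.uniform(
                    spec.correlation - spec.correlation_spread,
                    spec.correlation + spec.correlation_spread,
                    size=spec.size,
                ),
                0.05,
                0.95,
            )
            loading = cfg.noise_sd * np.sqrt(rho_g / (1.0 - rho_g))
        else:
            loading = np.zeros(spec.size)
        factor = rng.normal(0.0, 1.0, size=len(tumour_ids))
        tumour_log[members, :] += shifts[None, :] + loading[:, None] * factor[None, :]
        row += spec.size

    # weak transcriptome-wide programs shared by all genes (tumour and normal)
    if cfg.n_background_factors > 0 and cfg.background_rho_max > 0:
        share = (
            rng.uniform(0.0, cfg.background_rho_max, size=(n_genes, cfg.n_background_factors))
            / cfg.n_background_factors
        )
        bg_loading = cfg.noise_sd * np.sqrt(share / (1.0 - share))
        tumour_log += bg_loading @ rng.normal(size=(cfg.n_background_factors, len(tumour_ids)))
        normal_log += bg_loading @ rng.normal(size=(cfg.n_background_factors, len(normal_ids)))

    tumour = ExpressionMatrix(
        pd.DataFrame(
            np.maximum(np.exp(tumour_log), 1.0), index=gene_ids, columns=tumour_ids
        ),
        SCALE_TPM,
    )
    normal = ExpressionMatrix(
        pd.DataFrame(
            np.maximum(np.exp(normal_log), 1.0), index=gene_ids, columns=normal_ids
        ),
        SCALE_TPM,
    )

    def site_of(sample_id: str) -> str:
        return sample_id.split("-", 1)[1].rsplit("-", 1)[0]

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "condition": [CONDITION_TUMOUR] * len(tumour_ids)
                + [CONDITION_NORMAL] * len(normal_ids),
                "primary_site": [site_of(s) for s in tumour_ids + normal_ids],
                "study": "synthetic",
            },
            index=pd.Index(tumour_ids + normal_ids, name="sample"),
        )
    )
    truth = GroundTruth(
        module_of=pd.Series(
            gene_module, index=pd.Index(gene_ids, name="gene"), name="module"
        ),
        cluster_of=cluster_of.rename("cluster"),
        stratified=pd.Series(
            [s in cfg.stratified_sites for s in sites],
            index=pd.Index(sites, name="site"),
            name="stratified",
        ),
        activation=activation,
    )
    return tumour, normal, sheet, truth


def make_pathways(
    truth: GroundTruth,
    seed: int,
    n_random: int = 10,
    random_size: tuple[int, int] = (20, 60),
) -> PathwayCollection:
    """Synthetic GMT-style collection: planted-module pathways plus random sets.

    The module-matched pathways give ORA power cases; the random draws from
    the same universe give size (null) cases.
    """
    rng = np.random.default_rng(seed)
    universe = list(truth.module_of.index)
    pathways: dict[str, Pathway] = {}
    for module in [m for m in dict.fromkeys(truth.module_of) if m != UNASSIGNED]:
        members = frozenset(truth.module_of.index[truth.module_of == module])
        pid = f"PW-{module}"
        pathways[pid] = Pathway(pid, f"planted {module} gene set", members)
    lo, hi = random_size
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        pid = f"PW-random-{i + 1}"
        pathways[pid] = Pathway(pid, "random gene set", members)
    return PathwayCollection(pathways)


TRUTH_FILES = {
    "modules": "true_modules.tsv",
    "clusters": "true_clusters.tsv",
    "sites": "true_sites.tsv",
    "activation": "true_activation.tsv",
}


def write_truth(truth: GroundTruth, out_dir) -> None:
    """Write the ground truth as four documented TSVs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.module_of.rename("module").to_csv(out / TRUTH_FILES["modules"], sep="\t")
    truth.cluster_of.rename("cluster").to_csv(out / TRUTH_FILES["clusters"], sep="\t")
    truth.stratified.rename("stratified").to_csv(out / TRUTH_FILES["sites"], sep="\t")
    truth.activation.to_csv(out / TRUTH_FILES["activation"], sep="\t")


def read_truth(out_dir) -> GroundTruth:
    out = Path(out_dir)
    module_of = pd.read_csv(out / TRUTH_FILES["modules"], sep="\t").set_index("gene")["module"]
    cluster_of = pd.read_csv(out / TRUTH_FILES["clusters"], sep="\t").set_index("sample")["cluster"]
    stratified = pd.read_csv(out / TRUTH_FILES["sites"], sep="\t").set_index("site")["stratified"]
    if stratified.dtype == object:
        stratified = stratified.map({"True": True, "False": False})
    activation = pd.read_csv(out / TRUTH_FILES["activation"], sep="\t", index_col="module")
    activation.columns = pd.Index([int(c) for c in activation.columns], name="cluster")
    return GroundTruth(
        module_of=module_of,
        cluster_of=cluster_of.astype(int),
        stratified=stratified.astype(bool),
        activation=activation,
    )
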