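"""End-to-end orchestration: parallel analyses of the three correction modes.

One run takes a single expression matrix (tumour and normal samples mixed, as
public compendia ship them), a phenotype sheet, an optional gene annotation
and optional pathway sets, and executes per correction mode (uncorrected /
tissue / grand): normalization, co-expression module detection, module
summarization, ORA, cosine/Ward clustering with silhouette-chosen k, the
cross-cluster and cross-site statistics, and the per-site stratification
count. A manifest records versions, the config hash, the seed and per-stage
row counts so reruns can be compared.

On the uncorrected mode module expression stays on the TPM+1 scale; on the
corrected modes it is the ln(tumour/normal) ratio.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterAssignment, Dendrogram, cosine_distance, cut_clusters, find_k, to_newick, ward_tree
from .data_io import (
    CohortPair,
    ExpressionMatrix,
    PathwayCollection,
    SampleSheet,
    filter_protein_coding,
    read_annotation,
    read_expression,
    read_gmt,
    read_phenotype,
    restrict_matched_cohort,
    SCALE_LOG2_TPM,
)
from .enrichment import run_ora
from .exceptions import PipelineStageError
from .network import ModuleAssignment, NetworkConfig, SoftPowerResult, compute_tom, detect_modules, pick_soft_power, summarize_modules
from .normalization import (
    MODE_GRAND,
    MODE_TISSUE,
    MODE_UNCORRECTED,
    MODES,
    grand_correct,
    grand_mean_normal,
    site_mean_normal,
    tissue_correct,
    write_corrected,
)
from .stats import (
    GroupTestResult,
    StratificationReport,
    dunn_posthoc,
    kruskal_wallis,
    site_cluster_enrichment,
    tukey_hsd,
)

log = logging.getLogger("pancanstrat")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from a YAML key-value file."""

    expression: str
    phenotype: str
    out_dir: str
    annotation: str | None = None
    pathways: str | None = None
    declared_scale: str = SCALE_LOG2_TPM
    modes: tuple[str, ...] = MODES
    min_samples: int = 20
    exclude_sites: tuple[str, ...] = ("Blood",)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    k_max: int = 20
    alpha_ora: float = 0.05
    alpha_strat: float = 0.05
    alpha_posthoc: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one correction mode is required")
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown modes: {sorted(unknown)}")
        for name in ("alpha_ora", "alpha_strat", "alpha_posthoc"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        net = NetworkConfig(**{k: tuple(v) if k == "powers" else v
                               for k, v in (raw.pop("network", {}) or {}).items()})
        for key in ("modes", "exclude_sites"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(network=net, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModeResult:
    """All per-mode outputs of one pipeline pass."""

    mode: str
    analysis: pd.DataFrame  # genes x tumour samples on the mode's analysis scale
    power: SoftPowerResult
    assignment: ModuleAssignment
    profile: pd.DataFrame
    tree: Dendrogram
    k: int
    silhouettes: pd.Series
    clusters: ClusterAssignment
    ora: pd.DataFrame | None
    kruskal: pd.DataFrame
    dunn: dict[str, pd.DataFrame]
    tukey: dict[str, pd.DataFrame]
    stratification: StratificationReport


def correct_for_mode(cohort: CohortPair, mode: str) -> pd.DataFrame:
    """Tumour matrix on the mode's analysis scale (TPM+1 or ln tumour/normal)."""
    if mode == MODE_UNCORRECTED:
        return cohort.tumour.data.copy()
    if mode == MODE_TISSUE:
        sm = site_mean_normal(cohort.normal, cohort.sheet)
        return tissue_correct(cohort.tumour, cohort.sheet, sm).data
    if mode == MODE_GRAND:
        gm = grand_mean_normal(cohort.normal, cohort.sheet)
        return grand_correct(cohort.tumour, gm).data
    raise ValueError(f"unknown mode {mode!r}")


def _group_values(profile_row: pd.Series, labels: pd.Series):
    groups, names = [], []
    for name in dict.fromkeys(labels):
        groups.append(profile_row[labels.index[labels == name]].to_numpy())
        names.append(str(name))
    return groups, names


def run_mode(
    cohort: CohortPair,
    mode: str,
    net_cfg: NetworkConfig | None = None,
    pathways: PathwayCollection | None = None,
    k_max: int = 20,
    alpha_ora: float = 0.05,
    alpha_strat: float = 0.05,
    alpha_posthoc: float = 0.05,
) -> ModeResult:
    """Run one correction mode's full analysis on an in-memory cohort."""
    net_cfg = net_cfg or NetworkConfig()
    analysis = correct_for_mode(cohort, mode)

    expr = analysis
    if net_cfg.top_n_variance is not None and net_cfg.top_n_variance < expr.shape[0]:
        keep = (
            expr.var(axis=1).sort_values(ascending=False).index[: net_cfg.top_n_variance]
        )
        expr = expr.loc[[g for g in expr.index if g in set(keep)]]

    power = pick_soft_power(expr, net_cfg)
    tom = compute_tom(expr, power.power, net_cfg.sign)
    assignment = detect_modules(tom, net_cfg)
    module_genes = assignment.assigned_genes()
    if not module_genes:
        raise ValueError(f"mode {mode!r}: no co-expression module survived detection")
    profile = summarize_modules(analysis, assignment)

    ora = None
    if pathways is not None:
        ora = run_ora(assignment, pathways, universe=analysis.index, alpha=alpha_ora)

    features = analysis.loc[module_genes].T  # samples x module-member genes
    distances = cosine_distance(features)
    tree = ward_tree(distances)
    k, silhouettes = find_k(distances, tree, k_max=min(k_max, tree.n - 1))
    clusters = cut_clusters(tree, k)

    cluster_labels = clusters.labels.astype(str)
    site_labels = cohort.sheet.site_of(list(clusters.labels.index))
    kw_rows = []
    dunn_tables: dict[str, pd.DataFrame] = {}
    tukey_tables: dict[str, pd.DataFrame] = {}
    for module in profile.index:
        row = profile.loc[module]
        groups, names = _group_values(row, cluster_labels)
        kw: GroupTestResult = kruskal_wallis(groups, label=module, grouping="cluster")
        kw_rows.append({
            "module": module, "grouping": "cluster",
            "statistic": kw.statistic, "df": kw.df, "p": kw.pvalue,
        })
        if len(groups) >= 2:
            dunn_tables[module] = dunn_posthoc(groups, names, alpha=alpha_posthoc)
        site_groups, site_names = _group_values(row, site_labels)
        if all(len(g) >= 2 for g in site_groups):
            try:
                tukey_tables[module] = tukey_hsd(site_groups, site_names, alpha=alpha_posthoc)
            except ValueError:
                pass  # zero within-site variance: degenerate module, skip post hoc
    kw_table = pd.DataFrame.from_records(kw_rows)
    strat = site_cluster_enrichment(clusters, cohort.sheet, alpha=alpha_strat)

    return ModeResult(
        mode=mode, analysis=analysis, power=power, assignment=assignment,
        profile=profile, tree=tree, k=k, silhouettes=silhouettes,
        clusters=clusters, ora=ora, kruskal=kw_table,
        dunn=dunn_tables, tukey=tukey_tables, stratification=strat,
    )


def load_cohort(cfg: RunConfig) -> CohortPair:
    """Read all inputs, apply the biotype filter and the matched-site restriction."""
    matrix = read_expression(cfg.expression, cfg.declared_scale)
    sheet = read_phenotype(cfg.phenotype)
    if cfg.annotation:
        matrix, report = filter_protein_coding(matrix, read_annotation(cfg.annotation))
        log.info(
            "biotype filter: %d of %d genes retained (%.1f%% removed)",
            report.retained, report.total, report.percent_removed,
        )
    known = [s for s in matrix.sample_ids if s in set(sheet.sample_ids)]
    matrix = matrix.subset_samples(known)
    tumour = matrix.subset_samples(
        [s for s in known if sheet.table.loc[s, "condition"] == "tumour"]
    )
    normal = matrix.subset_samples(
        [s for s in known if sheet.table.loc[s, "condition"] == "normal"]
    )
    return restrict_matched_cohort(
        tumour, normal, sheet, min_samples=cfg.min_samples, exclude_sites=cfg.exclude_sites
    )


def _write_mode_outputs(result: ModeResult, cohort: CohortPair, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    if result.mode != MODE_UNCORRECTED:
        sm = site_mean_normal(cohort.normal, cohort.sheet)
        from .normalization import CorrectedMatrix

        write_corrected(CorrectedMatrix(result.analysis, result.mode),
                        out / "corrected_matrix.tsv", sm)
    else:
        result.analysis.rename_axis("gene").to_csv(out / "corrected_matrix.tsv", sep="\t")
    result.power.fits.to_csv(out / "soft_power_fits.tsv", sep="\t")
    result.assignment.write(out / "module_assignment.tsv")
    result.profile.to_csv(out / "module_profile.tsv", sep="\t")
    result.silhouettes.to_csv(out / "silhouette_sweep.tsv", sep="\t")
    result.clusters.write(out / "cluster_assignment.tsv")
    (out / "dendrogram.nwk").write_text(to_newick(result.tree) + "\n")
    if result.ora is not None:
        result.ora.to_csv(out / "ora_results.tsv", sep="\t", index=False)
    result.kruskal.to_csv(out / "kruskal_wallis.tsv", sep="\t", index=False)
    for name, tables in (("dunn", result.dunn), ("tukey", result.tukey)):
        if tables:
            combined = pd.concat(tables, names=["module", "row"]).reset_index("module")
            combined.to_csv(out / f"{name}_pairwise.tsv", sep="\t", index=False)
    result.stratification.table().to_csv(out / "stratification.tsv", sep="\t")
    return {
        "genes": int(result.analysis.shape[0]),
        "tumour_samples": int(result.analysis.shape[1]),
        "modules": len(result.profile.index),
        "module_genes": len(result.assignment.assigned_genes()),
        "soft_power": int(result.power.power),
        "k": int(result.k),
        "stratified_sites": int(result.stratification.stratified.sum()),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured mode and write all outputs plus a manifest.

    Returns the manifest dict. A stage failure raises
    :class:`PipelineStageError` after writing a ``PARTIAL`` marker naming the
    failed stage.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - report stage then re-raise
            (out_root / "PARTIAL").write_text(f"failed stage: {name}\n{exc}\n")
            raise PipelineStageError(name, exc) from exc

    cohort = _stage("load_cohort", load_cohort, cfg)
    pathways = _stage("read_gmt", read_gmt, cfg.pathways) if cfg.pathways else None

    stage_counts: dict[str, dict] = {}
    for mode in cfg.modes:
        log.info("running mode %s", mode)
        result = _stage(
            f"mode:{mode}", run_mode, cohort, mode,
            net_cfg=cfg.network, pathways=pathways, k_max=cfg.k_max,
            alpha_ora=cfg.alpha_ora, alpha_strat=cfg.alpha_strat,
            alpha_posthoc=cfg.alpha_posthoc,
        )
        stage_counts[mode] = _stage(
            f"write:{mode}", _write_mode_outputs, result, cohort, out_root / mode
        )

    import numpy
    import scipy
    import sklearn

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "sites": cohort.sites,
        "stage_counts": stage_counts,
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    marker = out_root / "PARTIAL"
    if marker.exists():
        marker.unlink()
    return manifest


def stratification_matrix(run_dir) -> pd.DataFrame:
    """Assemble the per-mode x per-site enriched-cluster-count matrix of a run."""
    run_dir = Path(run_dir)
    rows = {}
    for mode in MODES:
        path = run_dir / mode / "stratification.tsv"
        if not path.exists():
            continue
        table = pd.read_csv(path, sep="\t", index_col="site")
        rows[mode] = table["enriched_clusters"]
    if not rows:
        raise FileNotFoundError(f"no stratification tables under {run_dir}")
    return pd.DataFrame(rows).T.rename_axis("mode")
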