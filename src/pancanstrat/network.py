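"""Weighted co-expression network module detection.

Pipeline: Pearson correlation between gene expression profiles is raised to a
soft-thresholding power to form an adjacency matrix (unsigned by default,
``a_ij = |cor(x_i, x_j)|**beta``). The power is chosen as the smallest
candidate whose network approximates scale-free topology (signed R^2 of the
log-log regression of connectivity frequency on connectivity). Adjacency is
then converted to the topological overlap matrix

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with ``k_i = sum_{u != i} a_iu``, which rewards genes that share network
neighbours, and genes are clustered by average linkage on the dissimilarity
``1 - TOM``. Branches below a fixed cut height form modules; branches smaller
than the minimum module size are left unassigned. Module expression per sample
is the arithmetic mean over member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .exceptions import ConstantGeneError

UNASSIGNED = "unassigned"

SIGN_UNSIGNED = "unsigned"
SIGN_SIGNED = "signed"


@dataclass
class NetworkConfig:
    """Tunables for module detection.

    Candidate powers are swept in order; the scale-free fit target is the
    signed R^2 a power must reach. A power is only accepted while the mean
    network connectivity stays at or above ``min_mean_connectivity`` —
    otherwise an essentially empty network can score an excellent apparent
    power-law fit. ``cut_height`` is the static dendrogram cut on the 1-TOM
    scale; ``min_module_size`` is the smallest branch kept as a module.
    ``top_n_variance`` optionally pre-filters genes to the most variable
    across samples before network construction (None = no filter).
    """

    powers: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.85
    fallback_power: int = 6
    sign: str = SIGN_UNSIGNED
    min_module_size: int = 30
    cut_height: float = 0.99
    top_n_variance: int | None = None
    min_mean_connectivity: float = 1.0

    def __post_init__(self) -> None:
        if not self.powers or any(p < 1 for p in self.powers):
            raise ValueError("candidate powers must be positive integers")
        if self.fallback_power < min(self.powers) or self.fallback_power > max(self.powers):
            raise ValueError("fallback power must lie within the candidate range")
        if not (0.0 <= self.rsq_target <= 1.0):
            raise ValueError("rsq_target must be in [0, 1]")
        if not (0.0 < self.cut_height <= 1.0):
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.sign not in (SIGN_UNSIGNED, SIGN_SIGNED):
            raise ValueError(f"sign must be '{SIGN_UNSIGNED}' or '{SIGN_SIGNED}'")


@dataclass
class SoftPowerResult:
    power: int
    target_met: bool
    fits: pd.DataFrame  # per candidate power: rsq (signed), slope, mean_k


@dataclass
class ModuleAssignment:
    """gene -> module label; ``unassigned`` is reserved for genes in no module.

    Modules are labelled ``module-1``, ``module-2``, ... by decreasing size
    (ties broken by the position of the module's first gene), so labels are
    deterministic given the input.
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate gene ids in module assignment")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.labels.index)

    def module_names(self) -> list[str]:
        """Module labels (excluding unassigned), numeric suffixes sorted naturally."""
        names = [m for m in dict.fromkeys(self.labels) if m != UNASSIGNED]

        def key(name: str):
            _, _, suffix = name.rpartition("-")
            return (0, int(suffix), name) if suffix.isdigit() else (1, 0, name)

        return sorted(names, key=key)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def assigned_genes(self) -> list[str]:
        return list(self.labels.index[self.labels != UNASSIGNED])

    def write(self, path) -> None:
        self.labels.rename("module").rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "ModuleAssignment":
        table = pd.read_csv(path, sep="\t", dtype=str).set_index("gene")
        return cls(table["module"])


def _corr_matrix(expr: pd.DataFrame) -> np.ndarray:
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        names = [str(expr.index[i]) for i in constant[:5]]
        raise ConstantGeneError(f"constant expression for gene(s) {names}")
    return np.corrcoef(values)


def adjacency_from_corr(corr: np.ndarray, power: int, sign: str = SIGN_UNSIGNED) -> np.ndarray:
    """Soft-thresholded adjacency with a zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    if sign == SIGN_UNSIGNED:
        a = np.abs(corr) ** power
    elif sign == SIGN_SIGNED:
        a = ((1.0 + corr) / 2.0) ** power
    else:
        raise ValueError(f"unknown sign mode {sign!r}")
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log regression of connectivity frequency on connectivity.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins and
    bins with non-positive mean connectivity are dropped. The R^2 is
    sign-adjusted (negated when the slope is positive) so that only
    power-law-*decaying* degree distributions score well. Returns
    ``(signed_rsq, slope)``.
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_freq, log_k = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        log_freq.append(np.log10(mask.mean()))
        log_k.append(np.log10(mean_k))
    if len(log_k) < 3:
        return 0.0, 0.0
    fit = linregress(log_k, log_freq)
    rsq = float(fit.rvalue**2)
    slope = float(fit.slope)
    return (-np.sign(slope) * rsq if slope != 0 else 0.0), slope


def pick_soft_power(expr: pd.DataFrame, cfg: NetworkConfig) -> SoftPowerResult:
    """Smallest candidate power meeting the scale-free target, else the fallback.

    ``expr`` is a genes x samples table with at least 10 genes and 4 samples.
    A candidate must reach the signed-R^2 target while keeping mean
    connectivity >= ``cfg.min_mean_connectivity``; when no candidate
    qualifies the fallback power is returned with ``target_met=False``.
    """
    if expr.shape[0] < 10:
        raise ValueError("need at least 10 genes to assess scale-free topology")
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to assess scale-free topology")
    corr = _corr_matrix(expr)
    records = []
    chosen: int | None = None
    for power in cfg.powers:
        a = adjacency_from_corr(corr, power, cfg.sign)
        k = a.sum(axis=1)
        rsq, slope = scale_free_fit(k)
        mean_k = float(k.mean())
        records.append({"power": power, "rsq": rsq, "slope": slope, "mean_k": mean_k})
        if chosen is None and rsq >= cfg.rsq_target and mean_k >= cfg.min_mean_connectivity:
            chosen = power
    fits = pd.DataFrame.from_records(records).set_index("power")
    if chosen is None:
        return SoftPowerResult(power=cfg.fallback_power, target_met=False, fits=fits)
    return SoftPowerResult(power=chosen, target_met=True, fits=fits)


def compute_tom(expr: pd.DataFrame, power: int, sign: str = SIGN_UNSIGNED) -> pd.DataFrame:
    """Topological overlap similarity between genes (symmetric, in [0, 1], diag 1)."""
    corr = _corr_matrix(expr)
    a = adjacency_from_corr(corr, power, sign)
    k = a.sum(axis=1)
    numerator = a @ a + a  # diag(a)=0, so the matmul sums over u != i, j
    denominator = np.minimum.outer(k, k) + 1.0 - a
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # shave numeric asymmetry/spill
    return pd.DataFrame(tom, index=expr.index, columns=expr.index)


def detect_modules(tom: pd.DataFrame, cfg: NetworkConfig) -> ModuleAssignment:
    """Average-linkage clustering of 1-TOM, static cut, small branches unassigned."""
    genes = list(tom.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to detect modules")
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    branch = fcluster(tree, t=cfg.cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene"), dtype=object)
    sizes: dict[int, int] = pd.Series(branch).value_counts().to_dict()
    first_pos = {}
    for pos, b in enumerate(branch):
        first_pos.setdefault(b, pos)
    kept = [b for b, size in sizes.items() if size >= cfg.min_module_size]
    kept.sort(key=lambda b: (-sizes[b], first_pos[b]))
    for rank, b in enumerate(kept, start=1):
        labels.iloc[np.flatnonzero(branch == b)] = f"module-{rank}"
    return ModuleAssignment(labels)


def summarize_modules(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """Module x sample table of mean member-gene expression on the analysis scale."""
    rows = {}
    for module in assignment.module_names():
        members = [g for g in assignment.members(module) if g in expr.index]
        if not members:
            raise ValueError(f"module {module!r} has no genes present in the expression table")
        rows[module] = expr.loc[members].mean(axis=0)
    profile = pd.DataFrame(rows).T
    profile.index.name = "module"
    return profile
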