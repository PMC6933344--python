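"""Over-representation analysis (ORA) of module gene lists against pathway sets.

For a module of n genes drawn from a universe of N genes (all protein-coding
genes of the analysis) and a pathway covering K universe genes, the overlap k
is scored with the upper-tail hypergeometric probability P(X >= k). Raw p
values are corrected per module across pathways with the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import PathwayCollection
from .network import ModuleAssignment

ORA_COLUMNS = [
    "module", "pathway_id", "description",
    "N", "K", "n", "k", "p", "p_adjusted", "significant",
]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: pathway size; n: list size; k: overlap.
    Computed through the survival function, which works in log space and is
    stable for large N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} impossible with K={K}, n={n}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0.0) | (p > 1.0)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    modules: ModuleAssignment,
    pathways: PathwayCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One hypergeometric test per (module, pathway), BH-corrected per module.

    Pathway member sets and module gene lists are intersected with the
    universe before counting, so N, K, n and k are all on the same footing.
    Returns a table with columns ``module, pathway_id, description, N, K, n,
    k, p, p_adjusted, significant``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("reference universe is empty")
    N = len(universe)
    pathway_members = {
        pw.pathway_id: (pw.description, pw.members & universe) for pw in pathways
    }
    records = []
    for module in modules.module_names():
        gene_list = set(modules.members(module)) & universe
        n = len(gene_list)
        block = []
        for pid, (desc, members) in pathway_members.items():
            K = len(members)
            k = len(gene_list & members)
            p = hypergeom_tail(N, K, n, k)
            block.append({
                "module": module, "pathway_id": pid, "description": desc,
                "N": N, "K": K, "n": n, "k": k, "p": p,
            })
        if block:
            adjusted = bh_adjust([row["p"] for row in block])
            for row, adj in zip(block, adjusted):
                row["p_adjusted"] = float(adj)
                row["significant"] = bool(adj <= alpha)
            records.extend(block)
    return pd.DataFrame.from_records(records, columns=ORA_COLUMNS)
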