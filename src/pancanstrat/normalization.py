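"""Tumour-vs-normal log-ratio corrections.

Two schemes remove non-cancer expression from tumour profiles, both operating
on the TPM+1 scale so every ratio is finite and positive:

* **tissue correction** — each tumour value is divided by the mean normal
  TPM+1 of the *same* gene at the *same* primary site, then natural-logged:
  ``L_tissue[i, j] = ln(X[i, j] / Ghat_tissue[i, site(j)])``.

* **grand-mean correction** — the denominator is instead the *unweighted*
  mean across sites of the per-site mean normal values (a mean of means, not
  a pooled mean over all normal samples), giving a single site-independent
  reference profile: ``L_grand[i, j] = ln(C[i, j] / Ghat_grand[i])``.

With a single primary site the two schemes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SCALE_TPM, ExpressionMatrix, SampleSheet

MODE_TISSUE = "tissue"
MODE_GRAND = "grand"
MODE_UNCORRECTED = "uncorrected"
MODES = (MODE_UNCORRECTED, MODE_TISSUE, MODE_GRAND)


@dataclass
class SiteMeans:
    """Per-gene, per-site mean normal expression (TPM+1) with per-site counts m_l."""

    means: pd.DataFrame  # genes x sites
    counts: pd.Series  # site -> number of normal samples m_l

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 1.0 - 1e-9).any():
            raise ValueError("site means must be on the TPM+1 scale (>= 1)")
        if (self.counts <= 0).any():
            raise ValueError("every site must have at least one normal sample")

    @property
    def sites(self) -> list[str]:
        return list(self.means.columns)


@dataclass
class GrandMeans:
    """Per-gene unweighted mean of per-site mean normal expression."""

    means: pd.Series  # gene -> grand mean (TPM+1)
    t: int  # number of primary sites averaged

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("grand mean needs at least one site")
        if (self.means.to_numpy() < 1.0 - 1e-9).any():
            raise ValueError("grand means must be on the TPM+1 scale (>= 1)")


@dataclass
class CorrectedMatrix:
    """Natural-log tumour/normal ratio matrix (genes x tumour samples)."""

    data: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in (MODE_TISSUE, MODE_GRAND):
            raise ValueError(f"mode must be '{MODE_TISSUE}' or '{MODE_GRAND}'")
        if self.data.size and not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("corrected values must be finite")


def _require_tpm(m: ExpressionMatrix, what: str) -> None:
    if m.scale != SCALE_TPM:
        raise ValueError(f"{what} matrix must be on the tpm_plus1 scale, got {m.scale!r}")


def site_mean_normal(normal: ExpressionMatrix, sheet: SampleSheet) -> SiteMeans:
    """Mean normal TPM+1 per gene and primary site, over exactly that site's samples."""
    _require_tpm(normal, "normal")
    sites = sheet.site_of(normal.sample_ids)
    means = normal.data.T.groupby(sites).mean().T
    counts = sites.value_counts()
    # keep site order of first appearance among the normal samples
    order = list(dict.fromkeys(sites))
    return SiteMeans(means[order], counts.loc[order])


def tissue_correct(
    tumour: ExpressionMatrix, sheet: SampleSheet, sm: SiteMeans
) -> CorrectedMatrix:
    """ln(tumour TPM+1 / same-site mean normal TPM+1), per gene and tumour sample."""
    _require_tpm(tumour, "tumour")
    tumour_sites = sheet.site_of(tumour.sample_ids)
    missing = sorted(set(tumour_sites) - set(sm.sites))
    if missing:
        raise ValueError(f"tumour primary sites missing from site means: {missing}")
    denom = sm.means.reindex(index=tumour.gene_ids)
    if denom.isna().any().any():
        raise ValueError("site means do not cover all tumour genes")
    denom_per_sample = denom[tumour_sites.to_numpy()].to_numpy()
    values = np.log(tumour.data.to_numpy() / denom_per_sample)
    return CorrectedMatrix(
        pd.DataFrame(values, index=tumour.gene_ids, columns=tumour.sample_ids),
        MODE_TISSUE,
    )


def grand_mean_normal(normal: ExpressionMatrix, sheet: SampleSheet) -> GrandMeans:
    """Unweighted mean across sites of per-site mean normal expression.

    This is a mean of site means — sites with many normal samples do not get
    extra weight — which is what makes the reference profile site-balanced.
    """
    sm = site_mean_normal(normal, sheet)
    return GrandMeans(sm.means.mean(axis=1), t=len(sm.sites))


def grand_correct(tumour: ExpressionMatrix, gm: GrandMeans) -> CorrectedMatrix:
    """ln(tumour TPM+1 / grand-mean normal TPM+1); identical for same profiles at any site."""
    _require_tpm(tumour, "tumour")
    if set(tumour.gene_ids) != set(gm.means.index):
        raise ValueError("tumour matrix and grand means cover different gene sets")
    denom = gm.means.reindex(tumour.gene_ids).to_numpy()[:, None]
    values = np.log(tumour.data.to_numpy() / denom)
    return CorrectedMatrix(
        pd.DataFrame(values, index=tumour.gene_ids, columns=tumour.sample_ids),
        MODE_GRAND,
    )


def write_corrected(cm: CorrectedMatrix, path, sm: SiteMeans | None = None) -> None:
    """Write a corrected matrix as TSV with a header comment recording mode/t/m_l."""
    with open(path, "w") as fh:
        fh.write(f"# mode={cm.mode}\n")
        if sm is not None:
            fh.write(f"# t={len(sm.sites)}\n")
            for site in sm.sites:
                fh.write(f"# m[{site}]={int(sm.counts[site])}\n")
        fh.write("gene\t" + "\t".join(cm.data.columns) + "\n")
        for gid, row in zip(cm.data.index, cm.data.to_numpy()):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
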