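"""Readers, writers, containers and cohort filters for expression study inputs.

Expression files follow the Xena/Toil dialect: tab-separated, first column a
stable gene identifier, header row of sample identifiers. Public repositories
distribute these tables on the log2(TPM+1) scale; on ingest they are converted
to TPM+1 (``v -> 2**v``) so that every downstream tumour/normal ratio has both
numerator and denominator >= 1 and every log-ratio is finite.

The cohort filters reproduce the two study-design reductions of a matched
tumour/normal analysis: restriction to protein-coding genes, and restriction
to primary sites with enough samples on both the tumour and the normal side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyCohortError, FormatError, ParseError

SCALE_LOG2_TPM = "log2_tpm_plus1"
SCALE_TPM = "tpm_plus1"
SCALE_LOG_RATIO = "log_ratio"
SCALES = (SCALE_LOG2_TPM, SCALE_TPM, SCALE_LOG_RATIO)

CONDITION_TUMOUR = "tumour"
CONDITION_NORMAL = "normal"

PROTEIN_CODING = "protein_coding"


@dataclass
class ExpressionMatrix:
    """Dense gene-by-sample expression table with an explicit value scale.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
    scale
        One of ``log2_tpm_plus1``, ``tpm_plus1`` or ``log_ratio``. TPM+1
        values must be >= 1 and log2(TPM+1) values >= 0; log-ratio values
        are unconstrained but must be finite.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if values.size:
            if self.scale == SCALE_TPM and values.min() < 1.0 - 1e-9:
                raise ValueError("tpm_plus1 values must be >= 1")
            if self.scale == SCALE_LOG2_TPM and values.min() < -1e-9:
                raise ValueError("log2_tpm_plus1 values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)


@dataclass
class SampleSheet:
    """Per-sample condition (tumour/normal), anatomical primary site and study."""

    table: pd.DataFrame  # index: sample_id; columns: condition, primary_site, study

    def __post_init__(self) -> None:
        required = {"condition", "primary_site"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if "study" not in self.table.columns:
            self.table = self.table.assign(study="")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in sheet: {dupes[:5]}")
        bad_cond = set(self.table["condition"]) - {CONDITION_TUMOUR, CONDITION_NORMAL}
        if bad_cond:
            raise ValueError(
                f"condition must be '{CONDITION_TUMOUR}' or '{CONDITION_NORMAL}', got {sorted(bad_cond)}"
            )
        sites = self.table["primary_site"]
        if sites.isna().any() or (sites.astype(str).str.len() == 0).any():
            raise ValueError("every sample needs a non-empty primary_site")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def tumour_ids(self) -> list[str]:
        return list(self.table.index[self.table["condition"] == CONDITION_TUMOUR])

    def normal_ids(self) -> list[str]:
        return list(self.table.index[self.table["condition"] == CONDITION_NORMAL])

    def site_of(self, sample_ids=None) -> pd.Series:
        sites = self.table["primary_site"]
        if sample_ids is None:
            return sites
        missing = [s for s in sample_ids if s not in sites.index]
        if missing:
            raise KeyError(f"samples absent from sheet: {missing[:5]}")
        return sites.loc[list(sample_ids)]

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())

    def sites(self) -> list[str]:
        """Primary sites in order of first appearance."""
        return list(dict.fromkeys(self.table["primary_site"]))


@dataclass
class GeneAnnotation:
    """gene_id -> biotype mapping (one biotype per gene)."""

    biotypes: pd.Series

    def __post_init__(self) -> None:
        if self.biotypes.index.has_duplicates:
            dupes = self.biotypes.index[self.biotypes.index.duplicated()].unique().tolist()
            raise ValueError(f"gene annotated more than once: {dupes[:5]}")

    def coding_genes(self) -> set[str]:
        return set(self.biotypes.index[self.biotypes == PROTEIN_CODING])


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    description: str
    members: frozenset[str]


@dataclass
class PathwayCollection:
    """Named gene sets (e.g. a GMT file) used as the enrichment reference."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if not pw.members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def ids(self) -> list[str]:
        return list(self.pathways)


@dataclass(frozen=True)
class FilterReport:
    """Accounting for a gene filter: totals, removals and the removal percentage."""

    total: int
    retained: int
    removed: int
    percent_removed: float


@dataclass
class CohortPair:
    """Matched tumour/normal matrices restricted to shared, well-sampled primary sites."""

    tumour: ExpressionMatrix
    normal: ExpressionMatrix
    sheet: SampleSheet
    sites: list[str]

    def __post_init__(self) -> None:
        if self.tumour.gene_ids != self.normal.gene_ids:
            raise ValueError("tumour and normal matrices must share identical gene ids in order")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, declared_scale: str = SCALE_LOG2_TPM) -> ExpressionMatrix:
    """Read a Xena-dialect expression TSV.

    ``declared_scale`` states how the file's values are to be interpreted.
    log2(TPM+1) input is converted to TPM+1 (``v -> 2**v``); TPM+1 and
    log-ratio input are stored as-is. Gene order is preserved from the file.
    """
    if declared_scale not in SCALES:
        raise ValueError(f"unknown scale {declared_scale!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        n_fields = len(sample_ids) + 1
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_fields:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
                )
            genes.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError:
                for col, x in enumerate(parts[1:], start=1):
                    try:
                        float(x)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric value {x!r} at line {lineno} "
                            f"(gene {parts[0]!r}, column {col}, sample {sample_ids[col - 1]!r})"
                        ) from None
    data = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)
    if declared_scale == SCALE_LOG2_TPM:
        return ExpressionMatrix(np.exp2(data), SCALE_TPM)
    return ExpressionMatrix(data, declared_scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write in the same dialect as :func:`read_expression` consumes.

    Floats are written with Python's shortest round-trip repr, so
    write -> read -> write is byte-stable.
    """
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        values = m.data.to_numpy()
        for gid, row in zip(m.gene_ids, values):
            fh.write(str(gid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotype(path) -> SampleSheet:
    """Read a phenotype TSV with required columns sample, condition, primary_site."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample", "condition", "primary_site"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {sorted(missing)}")
    table = table.set_index("sample")
    # tolerate the American spelling on input
    table["condition"] = table["condition"].str.lower().replace({"tumor": CONDITION_TUMOUR})
    keep = ["condition", "primary_site"] + (["study"] if "study" in table.columns else [])
    return SampleSheet(table[keep].copy())


def read_annotation(path) -> GeneAnnotation:
    """Read a two-column gene_id / biotype TSV."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "biotype"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {sorted(missing)}")
    return GeneAnnotation(table.set_index("gene_id")["biotype"])


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file: name <TAB> description <TAB> member gene ids.

    Duplicate member ids within a line are de-duplicated; a line with fewer
    than three fields is a format error naming the line number.
    """
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno} has {len(parts)} fields; GMT needs >= 3")
            pid, desc = parts[0], parts[1]
            if pid in pathways:
                raise FormatError(f"{path}: duplicate pathway id {pid!r} at line {lineno}")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise FormatError(f"{path}: pathway {pid!r} at line {lineno} has no members")
            pathways[pid] = Pathway(pid, desc, members)
    return PathwayCollection(pathways)


def write_gmt(pc: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pw in pc:
            fh.write("\t".join([pw.pathway_id, pw.description, *sorted(pw.members)]) + "\n")


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def filter_protein_coding(
    m: ExpressionMatrix, ann: GeneAnnotation
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep only genes positively annotated ``protein_coding``.

    Genes absent from the annotation are treated as non-coding and removed.
    """
    coding = ann.coding_genes()
    keep = [g for g in m.gene_ids if g in coding]
    total = m.n_genes
    retained = len(keep)
    if retained == 0:
        raise EmptyCohortError("no protein-coding genes left after biotype filtering")
    removed = total - retained
    report = FilterReport(
        total=total,
        retained=retained,
        removed=removed,
        percent_removed=100.0 * removed / total if total else 0.0,
    )
    return m.subset_genes(keep), report


def restrict_matched_cohort(
    tumour: ExpressionMatrix,
    normal: ExpressionMatrix,
    sheet: SampleSheet,
    min_samples: int = 20,
    exclude_sites=(),
) -> CohortPair:
    """Restrict to primary sites with >= ``min_samples`` tumour AND normal samples.

    Sites in ``exclude_sites`` (e.g. ones whose tumour and normal histology is
    not comparable, such as blood) are dropped regardless of counts. Samples of
    dropped sites are removed from both matrices. Raises
    :class:`EmptyCohortError` when no site survives.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if set(tumour.gene_ids) != set(normal.gene_ids):
        raise ValueError("tumour and normal matrices must cover the same genes")
    normal = normal.subset_genes(tumour.gene_ids)

    t_sites = sheet.site_of(tumour.sample_ids)
    n_sites = sheet.site_of(normal.sample_ids)
    bad = set(sheet.table.loc[tumour.sample_ids, "condition"]) - {CONDITION_TUMOUR}
    if bad:
        raise ValueError("tumour matrix contains samples not labelled tumour in the sheet")
    bad = set(sheet.table.loc[normal.sample_ids, "condition"]) - {CONDITION_NORMAL}
    if bad:
        raise ValueError("normal matrix contains samples not labelled normal in the sheet")

    t_counts = t_sites.value_counts()
    n_counts = n_sites.value_counts()
    excluded = set(exclude_sites)
    retained = [
        site
        for site in dict.fromkeys(sheet.table["primary_site"])  # order of first appearance
        if site not in excluded
        and t_counts.get(site, 0) >= min_samples
        and n_counts.get(site, 0) >= min_samples
    ]
    if not retained:
        raise EmptyCohortError(
            f"no primary site has >= {min_samples} tumour and normal samples"
        )
    keep_t = [s for s in tumour.sample_ids if t_sites[s] in retained]
    keep_n = [s for s in normal.sample_ids if n_sites[s] in retained]
    pair_sheet = sheet.subset(keep_t + keep_n)
    return CohortPair(
        tumour=tumour.subset_samples(keep_t),
        normal=normal.subset_samples(keep_n),
        sheet=pair_sheet,
        sites=retained,
    )
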