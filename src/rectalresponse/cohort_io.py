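"""Read and validate MAF-style mutation files and clinical tables.

Applies the study's variant filters (depth >= 30, allele fraction >= 0.1,
coding/nonsynonymous classes only), builds the binary samples x genes
mutation matrix, and computes per-sample tumor mutation burden
(mutations per megabase of interrogated coding territory).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "VariantRecord",
    "FilterConfig",
    "MutationMatrix",
    "MafSchemaError",
    "read_maf",
    "write_maf",
    "read_clinical",
    "filter_variants",
    "build_mutation_matrix",
    "compute_tmb",
]

logger = logging.getLogger(__name__)

#: conventional MAF nonsynonymous classification set
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
})

REQUIRED_MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)


class MafSchemaError(ValueError):
    """A required MAF column is missing or a row cannot be parsed."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call."""

    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    depth: int | None = None
    allele_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        af = self.allele_fraction
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"allele fraction outside [0,1]: {af}")


@dataclass(frozen=True)
class FilterConfig:
    """Variant retention rules; defaults follow the study protocol."""

    min_depth: int = 30
    min_af: float = 0.1
    coding_only: bool = True
    nonsynonymous_classes: frozenset = NONSYNONYMOUS_CLASSES
    strict_missing: bool = False  # drop records with missing depth/AF

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not (0.0 <= self.min_af <= 1.0):
            raise ValueError("min_af must lie in [0,1]")


@dataclass
class MutationMatrix:
    """Binary samples x genes incidence matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        inc = np.asarray(self.incidence, dtype=np.int8)
        if inc.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("incidence shape does not match id lists")
        if not np.all(np.isin(inc, (0, 1))):
            raise ValueError("incidence entries must be 0/1")
        self.incidence = inc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.sample_ids,
                            columns=self.gene_ids)

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.incidence[:, j]

    def subset_samples(self, mask) -> "MutationMatrix":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return MutationMatrix(ids, list(self.gene_ids), self.incidence[mask])


def _maybe_float(x):
    if pd.isna(x):
        return None
    return float(x)


def read_maf(path) -> list[VariantRecord]:
    """Parse a tab-separated MAF file into validated variant records.

    Allele fraction is taken from an ``AF``/``Allele_Fraction``/
    ``tumor_f`` column when present, computed from
    ``t_alt_count / t_depth`` otherwise, and left missing if neither is
    available.  Depth comes from ``t_depth`` or the sum of the tumor
    allele counts.  Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise MafSchemaError(f"MAF file {path} is missing required columns: {missing}")

    def numeric(col: str) -> pd.Series:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if bad.any():
            # +2: header line plus 1-based numbering (comment lines not tracked)
            line = int(bad.idxmax()) + 2
            raise MafSchemaError(
                f"unparseable numeric value {raw[bad.idxmax()]!r} in column "
                f"{col!r} near line {line} of {path}"
            )
        return out

    pos = numeric("Start_Position")
    depth = numeric("t_depth") if "t_depth" in df.columns else None
    alt = numeric("t_alt_count") if "t_alt_count" in df.columns else None
    ref = numeric("t_ref_count") if "t_ref_count" in df.columns else None
    if depth is None and alt is not None and ref is not None:
        depth = alt + ref
    af = None
    for cand in ("AF", "Allele_Fraction", "tumor_f"):
        if cand in df.columns:
            af = numeric(cand)
            break
    if af is None and alt is not None and depth is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            af = alt / depth.replace(0, np.nan)

    records = []
    for i in range(len(df)):
        row = df.iloc[i]
        d = _maybe_float(depth.iloc[i]) if depth is not None else None
        records.append(VariantRecord(
            sample_id=str(row["Tumor_Sample_Barcode"]),
            gene=str(row["Hugo_Symbol"]),
            chromosome=str(row["Chromosome"]),
            position=int(pos.iloc[i]),
            ref_allele=str(row["Reference_Allele"]),
            alt_allele=str(row["Tumor_Seq_Allele2"]),
            variant_classification=str(row["Variant_Classification"]),
            depth=int(d) if d is not None else None,
            allele_fraction=_maybe_float(af.iloc[i]) if af is not None else None,
        ))
    return records


def write_maf(records: list[VariantRecord], path) -> None:
    """Write records back to a MAF-style TSV (round-trip of the fields read)."""
    rows = [{
        "Hugo_Symbol": r.gene,
        "Chromosome": r.chromosome,
        "Start_Position": r.position,
        "Reference_Allele": r.ref_allele,
        "Tumor_Seq_Allele2": r.alt_allele,
        "Variant_Classification": r.variant_classification,
        "Tumor_Sample_Barcode": r.sample_id,
        "t_depth": "" if r.depth is None else r.depth,
        "AF": "" if r.allele_fraction is None else r.allele_fraction,
    } for r in records]
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Chromosome", "Start_Position",
                                "Reference_Allele", "Tumor_Seq_Allele2",
                                "Variant_Classification", "Tumor_Sample_Barcode",
                                "t_depth", "AF"]).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = ["sample_id", "response", "age", "gender", "bmi", "tumor_size",
                    "t_stage", "n_stage", "ajcc_stage", "recurrence", "msi_status"]


def read_clinical(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical table (TSV or CSV by extension) into canonical columns.

    ``column_map`` maps canonical names (``sample_id``, ``response``,
    ``age``, ...) to the file's column headers when they differ.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        df = df.rename(columns=rename)
    if "sample_id" not in df.columns or "response" not in df.columns:
        raise ValueError("clinical table needs at least sample_id and response columns")
    resp = set(df["response"].dropna().unique())
    if not resp <= {"CR", "ICR"}:
        raise ValueError(f"response labels must be CR/ICR, got {sorted(resp)}")
    for col in ("age", "bmi", "tumor_size"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def filter_variants(records: list[VariantRecord],
                    config: FilterConfig = FilterConfig()) -> list[VariantRecord]:
    """Apply the depth / allele-fraction / coding-class retention rules.

    Exclusion is strict: a variant is dropped when ``depth < min_depth``
    or ``allele_fraction < min_af``, so boundary values are retained.
    Records with missing depth or AF are kept (tallied in the log)
    unless ``strict_missing`` is set.
    """
    kept = []
    n_missing = 0
    for r in records:
        missing = r.depth is None or r.allele_fraction is None
        if missing:
            n_missing += 1
            if config.strict_missing:
                continue
        else:
            if r.depth < config.min_depth or r.allele_fraction < config.min_af:
                continue
        if config.coding_only and r.variant_classification not in config.nonsynonymous_classes:
            continue
        kept.append(r)
    if n_missing:
        action = "dropped" if config.strict_missing else "retained"
        logger.warning("%d variant(s) with missing depth/AF were %s", n_missing, action)
    return kept


def build_mutation_matrix(records: list[VariantRecord],
                          samples: list[str]) -> MutationMatrix:
    """Binarize filtered variants into a samples x genes incidence matrix.

    Genes are ordered by descending mutation frequency, ties broken
    alphabetically.  Every record's sample must appear in ``samples``.
    """
    sample_index = {s: i for i, s in enumerate(samples)}
    genes = sorted({r.gene for r in records})
    gene_index = {g: j for j, g in enumerate(genes)}
    inc = np.zeros((len(samples), len(genes)), dtype=np.int8)
    for r in records:
        if r.sample_id not in sample_index:
            raise ValueError(
                f"variant sample {r.sample_id!r} is not in the cohort sample list"
            )
        inc[sample_index[r.sample_id], gene_index[r.gene]] = 1
    freq = inc.sum(axis=0)
    order = sorted(range(len(genes)), key=lambda j: (-freq[j], genes[j]))
    return MutationMatrix(list(samples), [genes[j] for j in order], inc[:, order])


def compute_tmb(records: list[VariantRecord], coding_length_mb: float,
                samples: list[str]) -> pd.Series:
    """Per-sample mutation rate: retained variant count / coding megabases.

    The default denominator used elsewhere in this package is 38 Mb
    (typical exome capture); targeted panels must supply their own
    footprint.
    """
    if coding_length_mb <= 0:
        raise ValueError("coding_length_mb must be positive")
    counts = pd.Series(0.0, index=pd.Index(samples, name="sample_id"))
    for r in records:
        if r.sample_id in counts.index:
            counts[r.sample_id] += 1
    return counts / coding_length_mb


#: default exome coding footprint in megabases
DEFAULT_CODING_MB = 38.0
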