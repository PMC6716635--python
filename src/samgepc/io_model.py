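"""Data model and I/O for expression matrices, clinical tables and annotations.

The package analyses paired (baseline vs. follow-up) mRNA abundance measured on
up to three platforms — RT-qPCR (raw Ct values), microarray (log2-scale
normalized intensities) and RNA-Seq (FPKM) — in a longitudinal heart-failure
reverse-remodeling design.  Sample columns are keyed ``patientID_timepoint``
with timepoint one of ``baseline``, ``m3`` (3 months) or ``m12`` (12 months).

All matrices are genes × samples.  Missing values are explicit (empty TSV
cells → NaN) and are never imputed; downstream code excludes the affected
gene/patient pairs instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TIMEPOINTS = ("baseline", "m3", "m12")

#: The controlled vocabulary of biologic categories used by default for
#: gene annotation (manually curated, myocardium-relevant groupings).
DEFAULT_CATEGORIES = (
    "Contractile and associated proteins",
    "Metabolism",
    "Growth/hypertrophy Regulation",
    "Channels, Solute Exchangers, Transporters",
    "Ca2+ Handling or signaling",
    "Cell Homeostasis",
    "Fibroblast growth, Extracellular Matrix or TGF signaling",
    "Extracellular to intracellular signaling",
    "Apoptosis",
    "Microtubules",
    "Immune function other than cytokines",
    "Vascular/thrombosis",
    "Cytoskeleton",
    "Gene regulation",
    "Unclassified/Unknown Function",
)


class Platform(str, enum.Enum):
    """Measurement platform; fixes the unit semantics of the matrix values."""

    QPCR = "qpcr"
    MICROARRAY = "microarray"
    RNASEQ = "rnaseq"

    @property
    def unit(self) -> str:
        return {"qpcr": "Ct", "microarray": "log2_intensity", "rnaseq": "FPKM"}[
            self.value
        ]


def parse_sample_key(key: str) -> tuple[str, str]:
    """Split ``patientID_timepoint`` into its parts.

    Patient IDs may not contain underscores; the timepoint suffix must be one
    of ``baseline``/``m3``/``m12``.
    """
    patient, sep, timepoint = str(key).rpartition("_")
    if not sep or timepoint not in TIMEPOINTS or not patient or "_" in patient:
        raise ValueError(
            f"malformed sample key {key!r}: expected 'patientID_timepoint' "
            f"with timepoint in {TIMEPOINTS}"
        )
    return patient, timepoint


@dataclass
class ExpressionMatrix:
    """Genes × samples values for one platform.

    ``values`` is a DataFrame indexed by gene ID with sample-key columns.
    Units follow the platform: Ct for qPCR, log2 intensity for microarray,
    FPKM for RNA-Seq.
    """

    platform: Platform
    values: pd.DataFrame
    sample_keys: list[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)!r}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample keys: {list(dups)!r}")
        self.sample_keys = [parse_sample_key(c) for c in self.values.columns]
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if self.platform is Platform.RNASEQ and (finite < 0).any():
            raise ValueError("FPKM values must be >= 0")
        if self.platform is Platform.QPCR and (finite <= 0).any():
            raise ValueError("Ct values must be > 0")

    @property
    def unit(self) -> str:
        return self.platform.unit

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def column_for(self, patient: str, timepoint: str) -> str | None:
        key = f"{patient}_{timepoint}"
        return key if key in self.values.columns else None

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for patient, _ in self.sample_keys:
            seen.setdefault(patient, None)
        return list(seen)


@dataclass
class ClinicalTable:
    """Per-patient clinical record: LVEF at baseline/3mo/12mo, optional RVEF,
    cohort membership tags (e.g. ``A-S``, ``S-R``)."""

    data: pd.DataFrame  # indexed by patient_id

    COLUMNS = (
        "lvef_baseline",
        "lvef_m3",
        "lvef_m12",
        "rvef_baseline",
        "rvef_locf",
        "cohort_tags",
    )

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate patient ids: {list(dups)!r}")
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col != "cohort_tags" else [set() for _ in df.index]
        for col in ("lvef_baseline", "lvef_m3", "lvef_m12"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.dropna()[(vals.dropna() < 0) | (vals.dropna() > 100)]
            if len(bad):
                raise ValueError(
                    f"LVEF outside [0, 100] in column {col}: "
                    f"{dict(bad.round(1))}"
                )
            df[col] = vals

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)


@dataclass
class GeneAnnotation:
    """gene_id → biologic category (controlled vocabulary) and candidate flag."""

    data: pd.DataFrame  # indexed by gene_id; columns: category, is_candidate
    vocabulary: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in annotation")
        cats = self.data["category"].dropna()
        unknown = sorted(set(cats) - set(self.vocabulary))
        if unknown:
            raise ValueError(f"categories outside controlled vocabulary: {unknown}")
        self.data["is_candidate"] = self.data["is_candidate"].astype(bool)

    def category_of(self, gene: str) -> str | None:
        if gene in self.data.index:
            cat = self.data.at[gene, "category"]
            if isinstance(cat, str) and cat:
                return cat
        return None

    @property
    def candidates(self) -> list[str]:
        return list(self.data.index[self.data["is_candidate"]])


@dataclass
class PairedView:
    """Baseline/LOCF column pairing per patient for one expression matrix."""

    baseline_col: dict[str, str]
    locf_col: dict[str, str]
    excluded: dict[str, str]  # patient -> reason

    @property
    def patients(self) -> list[str]:
        return list(self.baseline_col)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, platform: Platform | str) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column ``gene_id``) for one platform.

    Empty cells become missing values (NaN), never zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    for col in df.columns:  # fail early with the offending column named
        parse_sample_key(col)
    return ExpressionMatrix(Platform(platform), df.astype(float))


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV/TSV (delimiter sniffed from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError("clinical table must have a 'patient_id' column")
    df = df.set_index("patient_id")
    if "cohort_tags" in df.columns:
        df["cohort_tags"] = [
            set(str(t).split(";")) - {"", "nan"} if pd.notna(t) else set()
            for t in df["cohort_tags"]
        ]
    return ClinicalTable(df)


def write_clinical_table(ct: ClinicalTable, path: str | Path) -> None:
    df = ct.data.copy()
    df["cohort_tags"] = [";".join(sorted(t)) if t else "" for t in df["cohort_tags"]]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index_label="patient_id")


def read_annotation(path: str | Path, vocabulary: Iterable[str] = DEFAULT_CATEGORIES) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df = df.set_index("gene_id")
    if "category" not in df.columns:
        df["category"] = np.nan
    if "is_candidate" not in df.columns:
        df["is_candidate"] = False
    df["is_candidate"] = df["is_candidate"].map(
        lambda v: str(v).strip().lower() in {"true", "1", "yes"} if not isinstance(v, (bool, np.bool_)) else bool(v)
    )
    return GeneAnnotation(df[["category", "is_candidate"]], tuple(vocabulary))


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# pairing and gene-universe logic


def pair_samples(expr: ExpressionMatrix, locf: Mapping[str, str | None]) -> PairedView:
    """Pair each patient's baseline column with their designated LOCF column.

    Only patients with *both* columns present in the matrix are paired;
    everyone else is listed under ``excluded`` with a reason.
    """
    baseline_col: dict[str, str] = {}
    locf_col: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for patient in expr.patients:
        tp = locf.get(patient)
        if tp is None:
            excluded[patient] = "no LOCF timepoint (patient unclassifiable or absent from clinical table)"
            continue
        b = expr.column_for(patient, "baseline")
        l = expr.column_for(patient, tp)
        if b is None:
            excluded[patient] = "no baseline sample"
        elif l is None:
            excluded[patient] = f"no {tp} sample"
        else:
            baseline_col[patient] = b
            locf_col[patient] = l
    if not baseline_col:
        raise ValueError("no analyzable patients: every patient lacks a baseline/LOCF pair")
    return PairedView(baseline_col, locf_col, excluded)


def shared_gene_universe(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix) -> list[str]:
    """Intersection of the two platforms' gene lists, lexicographically ordered.

    All downstream concordance counting is restricted to this shared universe.
    """
    universe = sorted(set(expr_a.gene_ids) & set(expr_b.gene_ids))
    if not universe:
        raise ValueError("empty gene universe: the two matrices share no gene ids")
    return universe


def universe_overlap_percent(n_universe: int, n_platform: int) -> float:
    """Shared-universe size as a percentage of one platform's gene count."""
    if n_platform <= 0:
        raise ValueError("platform gene count must be positive")
    return 100.0 * n_universe / n_platform
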