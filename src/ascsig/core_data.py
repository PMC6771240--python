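"""Domain containers, tabular I/O and preprocessing rules.

The analysis operates on relative-abundance matrices (samples x proteins,
SOMAscan-unit-like arbitrary units) with per-sample class labels
(``ascites``, ``oc_plasma``, ``n_plasma``), and on a clinical table with
relapse-free survival (RFS, months) and a relapse event indicator.

Preprocessing follows three rules:

* plasma samples diluted 1:2 during preparation are corrected by
  multiplying their measured units by 2;
* probes are retained only if they exceed the dataset-wide median signal
  (strictly) in at least one sample ("low-signal" filter);
* patients are classified as short-term survivors (relapse observed before
  the 24-month cutoff), long-term survivors (RFS >= cutoff, censored or
  not), or indeterminate (censored before the cutoff — no class
  information).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_CLASSES",
    "AbundanceMatrix",
    "ClinicalTable",
    "CohortDataset",
    "load_abundance",
    "write_abundance",
    "load_clinical",
    "write_clinical",
    "apply_dilution_correction",
    "filter_low_signal",
    "classify_survivor",
    "write_provenance",
]

SAMPLE_CLASSES = frozenset({"ascites", "oc_plasma", "n_plasma"})

SHORT = "short"
LONG = "long"
INDETERMINATE = "indeterminate"


@dataclass
class AbundanceMatrix:
    """Samples x proteins relative-abundance table with class labels.

    ``values`` is a DataFrame indexed by sample id with protein-id columns;
    entries must be finite and non-negative (missing values are rejected —
    the assay reports complete probe panels).
    """

    values: pd.DataFrame
    sample_class: pd.Series
    platform: str = "somascan-like"

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate protein ids")
        arr = v.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if arr.size and not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite/missing abundance at sample {v.index[bad[0]]!r}, "
                f"protein {v.columns[bad[1]]!r}"
            )
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at sample {v.index[bad[0]]!r}, "
                f"protein {v.columns[bad[1]]!r}"
            )
        sc = self.sample_class.reindex(v.index)
        if sc.isna().any():
            missing = list(sc.index[sc.isna()])[:3]
            raise ValueError(f"samples without class label: {missing}")
        unknown = set(sc.unique()) - SAMPLE_CLASSES
        if unknown:
            raise ValueError(f"unknown sample classes: {sorted(unknown)}")
        object.__setattr__(self, "sample_class", sc)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self):
        return self.values.shape

    def subset_classes(self, classes: Iterable[str]) -> "AbundanceMatrix":
        classes = set(classes)
        keep = self.sample_class.isin(classes)
        return AbundanceMatrix(
            self.values.loc[keep], self.sample_class.loc[keep], self.platform
        )


@dataclass
class ClinicalTable:
    """Per-patient RFS (months), event indicator, derived survivor class."""

    table: pd.DataFrame  # index patient_id; columns rfs_months, event, survivor_class
    cutoff_months: float = 24.0

    def __post_init__(self):
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        for col in ("rfs_months", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        rfs = t["rfs_months"].to_numpy(dtype=float)
        if np.any(rfs < 0) or not np.all(np.isfinite(rfs)):
            raise ValueError("rfs_months must be finite and >= 0")
        t = t.assign(
            event=t["event"].astype(bool),
            survivor_class=[
                classify_survivor(r, e, self.cutoff_months)
                for r, e in zip(rfs, t["event"].astype(bool))
            ],
        )
        object.__setattr__(self, "table", t)

    @property
    def patient_ids(self) -> list:
        return list(self.table.index)

    @property
    def rfs_months(self) -> np.ndarray:
        return self.table["rfs_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=bool)

    @property
    def survivor_class(self) -> pd.Series:
        return self.table["survivor_class"]

    def classifiable(self) -> pd.DataFrame:
        """Rows with a definite short/long class (indeterminate excluded)."""
        return self.table[self.table["survivor_class"] != INDETERMINATE]


@dataclass
class CohortDataset:
    """An abundance matrix joined to clinical follow-up.

    Every ascites sample must map to exactly one patient present in the
    clinical table; plasma samples may lack clinical linkage.
    """

    abundance: AbundanceMatrix
    clinical: ClinicalTable
    sample_to_patient: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        patients = set(self.clinical.patient_ids)
        asc = self.abundance.sample_class == "ascites"
        for sid in self.abundance.values.index[asc]:
            pid = self.sample_to_patient.get(sid)
            if pid is None:
                raise ValueError(f"ascites sample {sid!r} has no patient mapping")
            if pid not in patients:
                raise ValueError(
                    f"ascites sample {sid!r} maps to unknown patient {pid!r}"
                )
        mapped = [self.sample_to_patient[s] for s in self.abundance.values.index[asc]]
        if len(set(mapped)) != len(mapped):
            raise ValueError("two ascites samples map to the same patient")

    def patient_values(self) -> pd.DataFrame:
        """Ascites abundance matrix re-indexed by patient id, restricted to
        patients present in the clinical table."""
        asc = self.abundance.sample_class == "ascites"
        v = self.abundance.values.loc[asc].copy()
        v.index = [self.sample_to_patient[s] for s in v.index]
        return v

    def survival_arrays(self, patient_index=None):
        """(times, events) aligned to ``patient_index`` (default: the
        patients of :meth:`patient_values`)."""
        if patient_index is None:
            patient_index = self.patient_values().index
        sub = self.clinical.table.loc[patient_index]
        return (
            sub["rfs_months"].to_numpy(dtype=float),
            sub["event"].to_numpy(dtype=bool),
        )


# ---------------------------------------------------------------------------
# I/O


def _read_table(path, sep="\t"):
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse {path}: {exc}") from exc


def load_abundance(path, class_map, platform="somascan-like", sep="\t") -> AbundanceMatrix:
    """Load a samples x proteins TSV (header row of protein ids, one row
    per sample).  ``class_map`` maps sample id -> class label.

    Raises a parse error naming the offending row/column for non-numeric
    cells, and validation errors for duplicate ids or negative values.
    """
    # pandas mangles duplicate header names; check the raw header first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicated protein column(s) in {path}: {dups}")
    df = _read_table(path, sep=sep)
    df.index.name = None
    df.columns.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample row(s) in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if isinstance(class_map, pd.Series):
        sc = class_map.reindex(numeric.index)
    else:
        sc = pd.Series({s: class_map[s] for s in numeric.index if s in class_map})
        sc = sc.reindex(numeric.index)
    return AbundanceMatrix(numeric, sc, platform=platform)


def write_abundance(m: AbundanceMatrix, path, sep="\t"):
    m.values.to_csv(path, sep=sep, index_label="sample_id")


def load_clinical(path, cutoff_months=24.0, sep="\t") -> ClinicalTable:
    """Load a clinical TSV with columns patient_id, rfs_months, event (0/1)."""
    df = pd.read_csv(path, sep=sep)
    required = {"patient_id", "rfs_months", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    df = df.set_index("patient_id")
    return ClinicalTable(df[["rfs_months", "event"]], cutoff_months=cutoff_months)


def write_clinical(c: ClinicalTable, path, sep="\t"):
    out = c.table[["rfs_months", "event"]].copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep=sep, index_label="patient_id")


def write_provenance(path, **record):
    """Write a JSON provenance record (inputs, parameters, seed, versions)."""
    import ascsig

    record = dict(record)
    record.setdefault("ascsig_version", ascsig.__version__)
    record.setdefault("numpy_version", np.__version__)
    record.setdefault("pandas_version", pd.__version__)
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing rules


def apply_dilution_correction(
    m: AbundanceMatrix,
    classes: Iterable[str] = ("oc_plasma", "n_plasma"),
    factor: float = 2.0,
) -> AbundanceMatrix:
    """Multiply the values of samples in ``classes`` by ``factor``.

    The default undoes the 1:2 dilution of plasma samples during
    preparation; ascites samples are left unchanged.
    """
    classes = set(classes)
    unknown = classes - SAMPLE_CLASSES
    if unknown:
        raise ValueError(f"unknown sample classes: {sorted(unknown)}")
    if not factor > 0:
        raise ValueError("dilution factor must be positive")
    v = m.values.copy()
    sel = m.sample_class.isin(classes).to_numpy()
    v.iloc[sel] = v.iloc[sel] * factor
    return AbundanceMatrix(v, m.sample_class, m.platform)


def filter_low_signal(m: AbundanceMatrix, threshold="auto"):
    """Drop probes never exceeding ``threshold`` (strict ``>``) in any sample.

    ``threshold="auto"`` uses the median over all sample x protein values of
    the matrix — the dataset-wide median signal.  Returns
    ``(filtered_matrix, removed_protein_ids)``.
    """
    if m.values.size == 0:
        raise ValueError("empty abundance matrix")
    if threshold == "auto":
        threshold = float(np.median(m.values.to_numpy()))
    threshold = float(threshold)
    keep = (m.values.to_numpy() > threshold).any(axis=0)
    removed = [p for p, k in zip(m.values.columns, keep) if not k]
    if not keep.any():
        warnings.warn(
            f"low-signal filter at threshold {threshold} removed every probe"
        )
    filtered = AbundanceMatrix(
        m.values.loc[:, keep], m.sample_class, m.platform
    )
    return filtered, removed


def write_cohort_dir(cohort: CohortDataset, outdir):
    """Write a cohort as a directory of TSVs (abundance, sample classes,
    clinical table, sample-to-patient mapping)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance(cohort.abundance, outdir / "abundance.tsv")
    cohort.abundance.sample_class.rename("class").to_csv(
        outdir / "sample_classes.tsv", sep="\t", index_label="sample_id"
    )
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    pd.Series(dict(cohort.sample_to_patient), name="patient_id").to_csv(
        outdir / "sample_to_patient.tsv", sep="\t", index_label="sample_id"
    )


def load_cohort_dir(indir, cutoff_months=24.0, platform="somascan-like") -> CohortDataset:
    """Load a cohort written by :func:`write_cohort_dir`."""
    indir = Path(indir)
    classes = pd.read_csv(indir / "sample_classes.tsv", sep="\t", index_col=0)["class"]
    abundance = load_abundance(indir / "abundance.tsv", classes, platform=platform)
    clinical = load_clinical(indir / "clinical.tsv", cutoff_months=cutoff_months)
    mapping_path = indir / "sample_to_patient.tsv"
    mapping = {}
    if mapping_path.exists():
        mapping = (
            pd.read_csv(mapping_path, sep="\t", index_col=0)["patient_id"].to_dict()
        )
    return CohortDataset(abundance, clinical, mapping)


def classify_survivor(rfs_months: float, event: bool, cutoff: float = 24.0) -> str:
    """Short/long/indeterminate survivor class from (RFS, event).

    * ``short``: relapse observed before the cutoff;
    * ``long``: RFS at or beyond the cutoff, censored or not;
    * ``indeterminate``: censored before the cutoff (carries no class
      information; excluded from signature accounting).
    """
    if rfs_months < 0:
        raise ValueError("rfs_months must be >= 0")
    if rfs_months >= cutoff:
        return LONG
    return SHORT if event else INDETERMINATE
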