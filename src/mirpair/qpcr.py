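"""Ct-level quantification for TaqMan-style miRNA qPCR array cards.

The quantities here follow the standard relative-quantification conventions:

* **Ct** — the qPCR cycle at which the fluorescence signal crosses the
  detection threshold. Lower Ct means higher abundance; one cycle is one
  doubling, so the Ct scale is log2.
* **deltaCt** — ``Ct(assay) - Ct(reference)`` within a sample, with U6 snRNA
  as the default endogenous reference. ``2**(-deltaCt)`` is the expression of
  the assay relative to the reference.
* **paired fold change** — for a patient with one primary-tumor and one
  metastatic sample, ``log2FC = deltaCt(primary) - deltaCt(metastatic)``;
  positive values mean higher expression in the metastasis.

Wells that never amplify within the instrument's cycle range are *undetected*.
They are carried as an explicit status flag, never as a sentinel Ct value.
An optional censoring step assigns undetected wells the maximum cycle tested
(40 by default), which bounds fold-change estimates for assays absent in one
condition; every censored cell keeps a provenance flag that propagates through
deltaCt and fold-change computation.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ComputationError,
    FormatError,
    PairingError,
    ValidationError,
)

PRIMARY = "primary"
METASTATIC = "metastatic"
SITES = (PRIMARY, METASTATIC)

DEFAULT_REFERENCE = "U6 snRNA"
DEFAULT_MAX_CYCLE = 40.0
DEFAULT_DETECTION_CT = 35.0

#: cell spellings mapped to undetected status on read (case-insensitive)
UNDETECTED_TOKENS = frozenset({"undetermined", "undet", "na", "nan", ""})


def _false_like(values: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(False, index=values.index, columns=values.columns)


@dataclasses.dataclass
class CtMatrix:
    """Raw cycle-threshold values per (assay, sample).

    ``ct`` holds floats with NaN at undetected wells; ``undetected`` and
    ``censored`` are aligned boolean frames. Replicate reference wells are
    named ``<reference>`` plus ``<reference>.2``, ``<reference>.3``, ...
    """

    ct: pd.DataFrame
    undetected: pd.DataFrame
    max_cycle: float = DEFAULT_MAX_CYCLE
    reference_assay: str = DEFAULT_REFERENCE
    censored: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = _false_like(self.ct)

    @property
    def assays(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def reference_rows(self) -> list[str]:
        ref = self.reference_assay
        return [a for a in self.ct.index if a == ref or str(a).startswith(ref + ".")]

    def validate(self) -> None:
        if not self.reference_rows:
            raise FormatError(
                f"reference assay {self.reference_assay!r} absent from Ct table"
            )
        ref = self.ct.loc[self.reference_rows]
        missing = ref.columns[ref.isna().any(axis=0)]
        if len(missing):
            raise ComputationError(
                "reference assay undetected in sample(s): " + ", ".join(missing)
            )
        detected = self.ct.to_numpy(float)
        bad = np.nan_to_num(detected, nan=1.0)
        if (bad <= 0).any() or (np.nan_to_num(detected, nan=0.0) > self.max_cycle).any():
            raise FormatError(
                f"detected Ct values must lie in (0, {self.max_cycle}]"
            )

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            ct=self.ct.copy(),
            undetected=self.undetected.copy(),
            max_cycle=self.max_cycle,
            reference_assay=self.reference_assay,
            censored=self.censored.copy(),
        )


@dataclasses.dataclass
class PairedCohort:
    """Sample annotations: sample_id -> (patient_id, site)."""

    annotations: pd.DataFrame  # index sample_id; columns patient_id, site

    def __post_init__(self) -> None:
        required = {"patient_id", "site"}
        if not required.issubset(self.annotations.columns):
            raise FormatError("annotations need columns patient_id and site")
        bad = set(self.annotations["site"]) - set(SITES)
        if bad:
            raise FormatError(f"unknown site value(s): {sorted(bad)}")
        if self.annotations.index.duplicated().any():
            raise FormatError("duplicate sample ids in annotations")

    @property
    def samples(self) -> list[str]:
        return list(self.annotations.index)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.annotations["patient_id"]:
            seen.setdefault(p, None)
        return list(seen)

    def validate_paired(self) -> None:
        """Each patient must contribute exactly one sample per site."""
        counts = self.annotations.groupby(["patient_id", "site"]).size()
        for patient in self.patients:
            for site in SITES:
                n = counts.get((patient, site), 0)
                if n != 1:
                    raise PairingError(
                        f"patient {patient!r} has {n} {site} samples (expected 1)"
                    )

    def sample_for(self, patient: str, site: str) -> str:
        sel = self.annotations[
            (self.annotations["patient_id"] == patient)
            & (self.annotations["site"] == site)
        ]
        if len(sel) != 1:
            raise PairingError(f"patient {patient!r} lacks a unique {site} sample")
        return str(sel.index[0])

    def pairs(self) -> list[tuple[str, str, str]]:
        """(patient, primary_sample, metastatic_sample) triples."""
        self.validate_paired()
        return [
            (p, self.sample_for(p, PRIMARY), self.sample_for(p, METASTATIC))
            for p in self.patients
        ]


@dataclasses.dataclass
class DeltaCtMatrix:
    """deltaCt values (cycles relative to the reference assay).

    The reference row is retained with deltaCt == 0 in every sample.
    ``censored`` marks cells whose Ct (assay or reference) was censored.
    """

    dct: pd.DataFrame
    censored: pd.DataFrame
    reference_assay: str = DEFAULT_REFERENCE

    @property
    def relative_expression(self) -> pd.DataFrame:
        """2**(-deltaCt); strictly positive wherever deltaCt is defined."""
        return 2.0 ** (-self.dct)


@dataclasses.dataclass
class FoldChangeTable:
    """Per-patient metastasis-vs-primary fold changes (miRNA x patient).

    ``log2fc = deltaCt(primary) - deltaCt(metastatic)``; the linear fold
    change is ``2**log2fc`` so the two scales can never drift apart.
    """

    log2fc: pd.DataFrame
    censored: pd.DataFrame

    @property
    def fold_change(self) -> pd.DataFrame:
        return 2.0**self.log2fc


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotations(path) -> PairedCohort:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    return PairedCohort(df.set_index("sample_id"))


def read_ct_table(
    path,
    annotations_path,
    *,
    max_cycle: float = DEFAULT_MAX_CYCLE,
    reference_assay: str = DEFAULT_REFERENCE,
    treat_max_as_undetected: bool = True,
) -> tuple[CtMatrix, PairedCohort]:
    """Read a Ct table TSV (assay x sample) plus sample annotations.

    Cells reading "Undetermined" (or blank), and optionally cells at or above
    ``max_cycle``, become undetected. Duplicate (assay, sample) rows and a
    missing reference assay are format errors; a sample absent from the
    annotations is an alignment error.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    raw = raw.set_index(raw.columns[0])
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate assay row(s): {sorted(set(dup))}")
    if raw.columns.duplicated().any():
        raise FormatError("duplicate sample columns in Ct table")

    ct = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    undetected = _false_like(ct)
    for col in raw.columns:
        for row in raw.index:
            cell = raw.at[row, col].strip()
            if cell.lower() in UNDETECTED_TOKENS:
                undetected.at[row, col] = True
                continue
            try:
                value = float(cell)
            except ValueError as exc:
                raise FormatError(f"bad Ct cell ({row}, {col}): {cell!r}") from exc
            if treat_max_as_undetected and value >= max_cycle:
                undetected.at[row, col] = True
            else:
                ct.at[row, col] = value

    matrix = CtMatrix(
        ct=ct, undetected=undetected, max_cycle=max_cycle, reference_assay=reference_assay
    )
    matrix.validate()

    cohort = read_annotations(annotations_path)
    unknown = set(matrix.samples) - set(cohort.samples)
    if unknown:
        raise AlignmentError(
            "sample(s) in Ct table absent from annotations: " + ", ".join(sorted(unknown))
        )
    return matrix, cohort


def write_ct_table(ct: CtMatrix, path) -> None:
    out = ct.ct.astype(object).copy()
    out[ct.undetected & ct.ct.isna()] = "Undetermined"
    out.index.name = "assay"
    out.to_csv(path, sep="\t")


def write_annotations(cohort: PairedCohort, path) -> None:
    out = cohort.annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_delta_ct(dct: DeltaCtMatrix, path) -> None:
    out = dct.dct.copy()
    out.index.name = "assay"
    out.to_csv(path, sep="\t")


def read_delta_ct(path, *, reference_assay: str = DEFAULT_REFERENCE) -> DeltaCtMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DeltaCtMatrix(
        dct=df, censored=_false_like(df), reference_assay=reference_assay
    )


def write_fold_changes(fc: FoldChangeTable, path) -> None:
    out = fc.log2fc.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t")


def read_fold_changes(path) -> FoldChangeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FoldChangeTable(log2fc=df, censored=_false_like(df))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def call_detection(
    ct: CtMatrix, detection_ct_threshold: float = DEFAULT_DETECTION_CT
) -> pd.DataFrame:
    """Boolean detection mask: a well is detected iff it has a Ct value and
    Ct < threshold. Censored wells carry a value but sit at max_cycle, so with
    any threshold <= max_cycle they remain undetected, as intended."""
    if not (0 < detection_ct_threshold <= ct.max_cycle):
        raise ValidationError(
            f"detection threshold must be in (0, {ct.max_cycle}], got {detection_ct_threshold}"
        )
    return ct.ct.notna() & (ct.ct < detection_ct_threshold) & ~ct.undetected


def censor_undetected(ct: CtMatrix) -> CtMatrix:
    """Assign every undetected well Ct = max_cycle and flag it censored.

    This is the bounding rule used to estimate a fold change for an assay that
    never amplifies in one condition; detected wells pass through unchanged.
    """
    out = ct.copy()
    mask = out.undetected.to_numpy(bool)
    values = out.ct.to_numpy(float)
    values[mask] = ct.max_cycle
    out.ct = pd.DataFrame(values, index=ct.ct.index, columns=ct.ct.columns)
    out.censored = out.censored | out.undetected
    return out


def delta_ct(ct: CtMatrix) -> DeltaCtMatrix:
    """deltaCt(assay, sample) = Ct(assay, sample) - Ct(reference, sample).

    Replicate reference wells are combined by arithmetic mean per sample. The
    reference must carry a value (detected or censored) in every sample.
    """
    refs = ct.reference_rows
    if not refs:
        raise FormatError(f"reference assay {ct.reference_assay!r} absent")
    ref_block = ct.ct.loc[refs]
    missing = ref_block.columns[ref_block.isna().any(axis=0)]
    if len(missing):
        raise ComputationError(
            "reference assay undetected in sample(s): " + ", ".join(missing)
        )
    ref_mean = ref_block.mean(axis=0)
    ref_censored = ct.censored.loc[refs].any(axis=0)

    others = [a for a in ct.assays if a not in refs]
    dct = ct.ct.loc[others].sub(ref_mean, axis=1)
    censored = ct.censored.loc[others].add(ref_censored, axis=1).astype(bool)

    ref_row = pd.DataFrame(0.0, index=[ct.reference_assay], columns=ct.ct.columns)
    ref_cen = pd.DataFrame(
        ref_censored.to_numpy(bool)[None, :],
        index=[ct.reference_assay],
        columns=ct.ct.columns,
    )
    return DeltaCtMatrix(
        dct=pd.concat([ref_row, dct]),
        censored=pd.concat([ref_cen, censored]),
        reference_assay=ct.reference_assay,
    )


def paired_fold_changes(dct: DeltaCtMatrix, cohort: PairedCohort) -> FoldChangeTable:
    """Per-patient log2 fold change = deltaCt(primary) - deltaCt(metastatic).

    Positive values mean higher expression in the metastasis. Cells where
    either side is missing are NaN; cells where either side was censored carry
    the censored flag. The reference row (identically zero) is dropped.
    """
    pairs = cohort.pairs()
    missing = [s for _, p, m in pairs for s in (p, m) if s not in dct.dct.columns]
    if missing:
        raise AlignmentError(
            "cohort sample(s) absent from deltaCt matrix: " + ", ".join(missing)
        )
    assays = [a for a in dct.dct.index if a != dct.reference_assay]
    log2fc = {}
    censored = {}
    for patient, pri, met in pairs:
        log2fc[patient] = dct.dct.loc[assays, pri] - dct.dct.loc[assays, met]
        censored[patient] = dct.censored.loc[assays, pri] | dct.censored.loc[assays, met]
    return FoldChangeTable(
        log2fc=pd.DataFrame(log2fc), censored=pd.DataFrame(censored)
    )
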