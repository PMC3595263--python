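"""Synthetic paired tumor cohorts with known planted structure.

The generator emulates the design of a paired primary/omental-metastasis
miRNA screen: 9 patients, two sites per patient, a 377-assay qPCR array card
with a U6 snRNA reference well, roughly half the assays falling below the
detection range, a handful of miRNAs planted with real metastasis-vs-primary
fold changes (a few of them down-regulated), and a matched mRNA matrix in
which the planted miRNAs' predicted target genes are anti-correlated with
miRNA expression. Every dataset ships with a truth table so downstream
estimates can be checked against the planted parameters.

Generative model (all noise additive Gaussian on the Ct scale, which is log2,
so qPCR measurement noise is log-normal on the linear scale):

    Ct(m, s) = Ct_ref(s) + baseline_dct(m) - log2FC(m) * [site(s) == metastatic]
               + N(0, pair_noise_sd)

Wells whose latent Ct exceeds ``dropout_ct_cutoff`` are undetected. Reference
wells are noise-free by default so deltaCt noise is attributable to the miRNA
well; reference noise is configurable.

mRNA model: each gene g has a baseline N(baseline_expr_mean, baseline_expr_sd);
targets of a planted miRNA m additionally receive
``repression_slope * (-deltaCt(m, s))`` (negative slope = repression), plus
N(0, mrna_noise_sd) noise everywhere.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, ValidationError
from .qpcr import (
    DEFAULT_MAX_CYCLE,
    DEFAULT_REFERENCE,
    METASTATIC,
    PRIMARY,
    CtMatrix,
    PairedCohort,
)
from .targets import TargetSetCollection

#: default planted effects: 17 miRNAs with |log2FC| >= 1.5, three of them
#: down-regulated in the metastasis, echoing a screen in which most recurrent
#: changes are up-regulations with a small down-regulated cluster.
DEFAULT_PLANTED: tuple[tuple[str, float], ...] = (
    ("miR-sim-001", 3.2),
    ("miR-sim-002", 2.9),
    ("miR-sim-003", 2.7),
    ("miR-sim-004", 2.5),
    ("miR-sim-005", 2.3),
    ("miR-sim-006", 2.2),
    ("miR-sim-007", 2.0),
    ("miR-sim-008", 1.9),
    ("miR-sim-009", 1.8),
    ("miR-sim-010", 1.7),
    ("miR-sim-011", 1.6),
    ("miR-sim-012", 1.6),
    ("miR-sim-013", 1.5),
    ("miR-sim-014", 1.5),
    ("miR-sim-015", -1.5),
    ("miR-sim-016", -1.8),
    ("miR-sim-017", -2.2),
)

TARGETSCAN_LIKE = "targetscan_sim"
PITA_LIKE = "pita_sim"


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Parameters of the paired-cohort simulator.

    Ct-scale quantities are in cycles; expression quantities are on the
    log2-like scale of normalized array signal.
    """

    n_patients: int = 9
    n_mirnas: int = 377
    n_reference_wells: int = 1
    planted_mirnas: tuple[tuple[str, float], ...] = DEFAULT_PLANTED
    baseline_dct_mean: float = 16.0
    baseline_dct_sd: float = 4.0
    pair_noise_sd: float = 0.5
    dropout_ct_cutoff: float = 35.0
    max_cycle: float = DEFAULT_MAX_CYCLE
    reference_ct_mean: float = 20.0
    reference_noise_sd: float = 0.0
    planted_baseline_range: tuple[float, float] = (5.0, 10.0)
    n_genes: int = 2000
    targets_per_mirna: int = 50
    source_overlap: float = 0.6
    repression_slope: float = -0.5
    baseline_expr_mean: float = 7.0
    baseline_expr_sd: float = 2.0
    mrna_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_mirnas": self.n_mirnas,
            "n_reference_wells": self.n_reference_wells,
            "n_genes": self.n_genes,
            "targets_per_mirna": self.targets_per_mirna,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be a count >= 1, got {value}")
        for name in ("pair_noise_sd", "mrna_noise_sd", "reference_noise_sd",
                     "baseline_dct_sd", "baseline_expr_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.dropout_ct_cutoff > self.max_cycle:
            raise ValidationError("dropout_ct_cutoff must be <= max_cycle")
        if not (0 <= self.source_overlap <= 1):
            raise ValidationError("source_overlap must be in [0, 1]")
        ids = set(self.mirna_ids())
        planted = [m for m, _ in self.planted_mirnas]
        if len(planted) != len(set(planted)):
            raise ValidationError("duplicate planted miRNA ids")
        unknown = [m for m in planted if m not in ids]
        if unknown:
            raise ValidationError(
                "planted miRNA id(s) not among generated assays: " + ", ".join(unknown)
            )
        if self.targets_per_mirna > self.n_genes:
            raise ValidationError("targets_per_mirna exceeds n_genes")

    def mirna_ids(self) -> list[str]:
        return [f"miR-sim-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def reference_well_ids(self) -> list[str]:
        ref = DEFAULT_REFERENCE
        if self.n_reference_wells == 1:
            return [ref]
        return [ref] + [f"{ref}.{i}" for i in range(2, self.n_reference_wells + 1)]

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:05d}" for i in range(1, self.n_genes + 1)]

    def patient_ids(self) -> list[str]:
        return [f"P{i:02d}" for i in range(1, self.n_patients + 1)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_mirnas"] = [[m, float(f)] for m, f in self.planted_mirnas]
        d["planted_baseline_range"] = list(self.planted_baseline_range)
        return d


def generate_paired_cohort(
    params: SimParams,
) -> tuple[CtMatrix, PairedCohort, pd.DataFrame]:
    """Simulate a paired cohort's Ct matrix.

    Returns the Ct matrix (reference wells first), the sample annotations
    (one primary and one metastatic sample per patient), and the truth table
    of planted log2 fold changes with the baseline deltaCt assigned to each
    planted miRNA. Identical parameters (including the seed) give identical
    output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    mirnas = params.mirna_ids()
    patients = params.patient_ids()
    samples, patient_of, site_of = [], [], []
    for p in patients:
        for site, tag in ((PRIMARY, "pri"), (METASTATIC, "met")):
            samples.append(f"{p}-{tag}")
            patient_of.append(p)
            site_of.append(site)
    is_met = np.array([s == METASTATIC for s in site_of], dtype=float)

    baseline = rng.normal(params.baseline_dct_mean, params.baseline_dct_sd, params.n_mirnas)
    planted_ids = [m for m, _ in params.planted_mirnas]
    lo, hi = params.planted_baseline_range
    planted_baseline = rng.uniform(lo, hi, len(planted_ids))
    index_of = {m: i for i, m in enumerate(mirnas)}
    lfc = np.zeros(params.n_mirnas)
    for (mirna, fc), b in zip(params.planted_mirnas, planted_baseline):
        baseline[index_of[mirna]] = b
        lfc[index_of[mirna]] = fc

    n_samples = len(samples)
    ref_wells = params.reference_well_ids()
    ref_ct = params.reference_ct_mean + rng.normal(
        0.0, params.reference_noise_sd, (len(ref_wells), n_samples)
    )
    ref_mean = ref_ct.mean(axis=0)

    noise = rng.normal(0.0, params.pair_noise_sd, (params.n_mirnas, n_samples))
    latent = (
        ref_mean[None, :]
        + baseline[:, None]
        - lfc[:, None] * is_met[None, :]
        + noise
    )
    latent = np.maximum(latent, 1e-3)

    undetected = latent > params.dropout_ct_cutoff
    ct_values = latent.copy()
    ct_values[undetected] = np.nan

    ct = pd.DataFrame(
        np.vstack([ref_ct, ct_values]),
        index=ref_wells + mirnas,
        columns=samples,
    )
    undet = pd.DataFrame(
        np.vstack([np.zeros((len(ref_wells), n_samples), dtype=bool), undetected]),
        index=ct.index,
        columns=samples,
    )
    matrix = CtMatrix(
        ct=ct, undetected=undet, max_cycle=params.max_cycle, reference_assay=DEFAULT_REFERENCE
    )
    cohort = PairedCohort(
        pd.DataFrame(
            {"patient_id": patient_of, "site": site_of},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = pd.DataFrame(
        {
            "log2_fold_change": [f for _, f in params.planted_mirnas],
            "baseline_dct": planted_baseline,
        },
        index=pd.Index(planted_ids, name="mirna"),
    )
    return matrix, cohort, truth


def generate_target_sets(params: SimParams) -> TargetSetCollection:
    """Emit two overlapping prediction sources for each planted miRNA.

    For each planted miRNA a contiguous pool of distinct genes is reserved
    (disjoint across miRNAs); each of the two sources takes exactly
    ``targets_per_mirna`` genes from it, sharing a ``source_overlap`` fraction,
    so the union operation is exercised. With overlap 1 the sources coincide.
    """
    params.validate()
    planted_ids = [m for m, _ in params.planted_mirnas]
    tp = params.targets_per_mirna
    extra = int(round(tp * (1.0 - params.source_overlap)))
    per_mirna = tp + extra
    if per_mirna * len(planted_ids) > params.n_genes:
        raise ValidationError(
            f"need {per_mirna * len(planted_ids)} distinct target genes "
            f"but only {params.n_genes} genes are generated"
        )
    rng = np.random.default_rng((params.seed, 1))
    genes = np.array(params.gene_ids())
    order = rng.permutation(params.n_genes)
    sources: dict[str, dict[str, set[str]]] = {TARGETSCAN_LIKE: {}, PITA_LIKE: {}}
    for i, mirna in enumerate(planted_ids):
        block = genes[order[i * per_mirna : (i + 1) * per_mirna]]
        sources[TARGETSCAN_LIKE][mirna] = set(block[:tp])
        sources[PITA_LIKE][mirna] = set(block[extra : extra + tp])
    return TargetSetCollection(sources)


def generate_matched_mrna(
    params: SimParams,
    ct: CtMatrix,
    targets: TargetSetCollection,
    cohort: PairedCohort | None = None,
) -> pd.DataFrame:
    """Simulate the matched mRNA matrix (genes x samples, log-scale signal).

    Targets of each planted miRNA receive ``repression_slope`` times the
    miRNA's log2 relative expression (-deltaCt, with undetected miRNA wells
    censored at max_cycle); all genes get independent Gaussian noise around
    gene-specific baselines.
    """
    params.validate()
    if cohort is not None and list(ct.samples) != list(cohort.samples):
        raise AlignmentError("Ct matrix samples do not match the cohort samples")
    rng = np.random.default_rng((params.seed, 2))
    genes = params.gene_ids()
    samples = ct.samples

    baseline = rng.normal(params.baseline_expr_mean, params.baseline_expr_sd, params.n_genes)
    noise = rng.normal(0.0, params.mrna_noise_sd, (params.n_genes, len(samples)))
    expr = baseline[:, None] + noise

    ref_rows = ct.reference_rows
    ref_mean = ct.ct.loc[ref_rows].mean(axis=0).to_numpy(float)
    gene_index = {g: i for i, g in enumerate(genes)}
    for mirna, _ in params.planted_mirnas:
        if mirna not in ct.ct.index:
            raise AlignmentError(f"planted miRNA {mirna!r} absent from Ct matrix")
        well = ct.ct.loc[mirna].to_numpy(float)
        well = np.where(np.isnan(well), params.max_cycle, well)
        v = -(well - ref_mean)  # log2 relative expression
        rows = [gene_index[g] for g in sorted(targets.union(mirna)) if g in gene_index]
        expr[rows, :] += params.repression_slope * v[None, :]

    return pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_manifest(params: SimParams, path, extra: dict | None = None) -> None:
    """Echo all simulation parameters (and the seed) to a YAML run manifest."""
    payload = {"sim_params": params.to_dict()}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
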