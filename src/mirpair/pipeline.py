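"""End-to-end orchestration: simulate -> quantify -> differential -> cluster
-> target anti-correlation, driven by a single YAML configuration.

Every run writes its artifacts (TSV tables, GMT target sets, Newick trees,
a YAML manifest) plus a machine-readable JSON report carrying the seed, a
hash of the resolved configuration, and the stage-by-stage counts, so that
identical configuration + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Any

import pandas as pd
import yaml

from . import cluster as _cluster
from . import differential as _differential
from . import qpcr as _qpcr
from . import simulate as _simulate
from . import targets as _targets
from .errors import OrchestrationError, ValidationError

STAGES = ("simulate", "quantify", "differential", "cluster", "targets")

_SECTION_KEYS = {
    "stages": set(STAGES),
    "simulate": {f.name for f in dataclasses.fields(_simulate.SimParams)},
    "inputs": {"ct_table", "annotations", "expression", "target_sets"},
    "quantify": {"reference_assay", "detection_ct", "max_cycle", "censor_undetected"},
    "differential": {"alpha", "min_detected", "test_scale"},
    "cluster": {"k", "orientation"},
    "targets": {"n_perm", "threshold", "mirnas"},
}
_TOP_KEYS = {"seed", "outdir"} | set(_SECTION_KEYS)


@dataclasses.dataclass
class RunConfig:
    """Resolved pipeline configuration with defaults filled in."""

    seed: int = 0
    outdir: str = "mirpair_run"
    stages: dict[str, bool] = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate: dict[str, Any] = dataclasses.field(default_factory=dict)
    inputs: dict[str, Any] = dataclasses.field(
        default_factory=lambda: {
            "ct_table": None, "annotations": None, "expression": None, "target_sets": []
        }
    )
    reference_assay: str = _qpcr.DEFAULT_REFERENCE
    detection_ct: float = _qpcr.DEFAULT_DETECTION_CT
    max_cycle: float = _qpcr.DEFAULT_MAX_CYCLE
    censor_undetected: bool = False
    alpha: float = 0.05
    min_detected: int = 2
    test_scale: str = "log2"
    cluster_k: int = 3
    cluster_orientation: tuple[str, ...] = ("patients", "mirnas")
    n_perm: int = 1000
    anticorr_threshold: float = _targets.DEFAULT_ANTICORR_THRESHOLD
    target_mirnas: tuple[str, ...] | None = None

    def validate(self) -> None:
        problems = []
        if not (0 < self.alpha < 1):
            problems.append(f"alpha out of (0, 1): {self.alpha}")
        if not (0 < self.detection_ct <= self.max_cycle):
            problems.append(
                f"detection_ct out of (0, max_cycle]: {self.detection_ct}"
            )
        if self.min_detected < 1:
            problems.append(f"min_detected < 1: {self.min_detected}")
        if self.n_perm < 1:
            problems.append(f"n_perm < 1: {self.n_perm}")
        if not (-1 < self.anticorr_threshold <= 0):
            problems.append(
                f"anticorrelation threshold out of (-1, 0]: {self.anticorr_threshold}"
            )
        if self.cluster_k < 1:
            problems.append(f"cluster k < 1: {self.cluster_k}")
        if self.test_scale not in ("log2", "linear"):
            problems.append(f"unknown test_scale: {self.test_scale!r}")
        bad_orient = set(self.cluster_orientation) - {"patients", "mirnas"}
        if bad_orient:
            problems.append(f"unknown cluster orientation(s): {sorted(bad_orient)}")
        unknown_stage = set(self.stages) - set(STAGES)
        if unknown_stage:
            problems.append(f"unknown stage(s): {sorted(unknown_stage)}")
        if problems:
            raise ValidationError("; ".join(problems))

    def sim_params(self) -> _simulate.SimParams:
        overrides = dict(self.simulate)
        if "seed" not in overrides:
            overrides["seed"] = self.seed
        if "planted_mirnas" in overrides:
            overrides["planted_mirnas"] = tuple(
                (str(m), float(f)) for m, f in overrides["planted_mirnas"]
            )
        if "planted_baseline_range" in overrides:
            overrides["planted_baseline_range"] = tuple(
                overrides["planted_baseline_range"]
            )
        return _simulate.SimParams(**overrides)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": dict(self.stages),
            "simulate": self.sim_params().to_dict()
            if self.stages.get("simulate")
            else dict(self.simulate),
            "inputs": dict(self.inputs),
            "quantify": {
                "reference_assay": self.reference_assay,
                "detection_ct": self.detection_ct,
                "max_cycle": self.max_cycle,
                "censor_undetected": self.censor_undetected,
            },
            "differential": {
                "alpha": self.alpha,
                "min_detected": self.min_detected,
                "test_scale": self.test_scale,
            },
            "cluster": {"k": self.cluster_k, "orientation": list(self.cluster_orientation)},
            "targets": {
                "n_perm": self.n_perm,
                "threshold": self.anticorr_threshold,
                "mirnas": list(self.target_mirnas) if self.target_mirnas else None,
            },
        }

    @property
    def config_hash(self) -> str:
        # the hash covers the analysis parameters, not where outputs land
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _check_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) in {section!r}: {sorted(unknown)}"
        )


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError("configuration must be a mapping")
    _check_unknown("config", raw, _TOP_KEYS)
    for section, allowed in _SECTION_KEYS.items():
        if section in raw and raw[section] is not None:
            if not isinstance(raw[section], dict):
                raise ValidationError(f"section {section!r} must be a mapping")
            _check_unknown(section, raw[section], allowed)

    cfg = RunConfig()
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.outdir = str(raw.get("outdir", cfg.outdir))
    cfg.stages.update(raw.get("stages") or {})
    cfg.simulate = dict(raw.get("simulate") or {})
    cfg.inputs.update(raw.get("inputs") or {})
    q = raw.get("quantify") or {}
    cfg.reference_assay = q.get("reference_assay", cfg.reference_assay)
    cfg.detection_ct = float(q.get("detection_ct", cfg.detection_ct))
    cfg.max_cycle = float(q.get("max_cycle", cfg.max_cycle))
    cfg.censor_undetected = bool(q.get("censor_undetected", cfg.censor_undetected))
    d = raw.get("differential") or {}
    cfg.alpha = float(d.get("alpha", cfg.alpha))
    cfg.min_detected = int(d.get("min_detected", cfg.min_detected))
    cfg.test_scale = str(d.get("test_scale", cfg.test_scale))
    c = raw.get("cluster") or {}
    cfg.cluster_k = int(c.get("k", cfg.cluster_k))
    cfg.cluster_orientation = tuple(c.get("orientation", cfg.cluster_orientation))
    t = raw.get("targets") or {}
    cfg.n_perm = int(t.get("n_perm", cfg.n_perm))
    cfg.anticorr_threshold = float(t.get("threshold", cfg.anticorr_threshold))
    if t.get("mirnas"):
        cfg.target_mirnas = tuple(str(m) for m in t["mirnas"])
    cfg.validate()
    if cfg.stages.get("simulate"):
        cfg.sim_params()  # surface simulation parameter errors at validation time
    return cfg


def validate_config(path) -> RunConfig:
    """Parse + validate a YAML config file; empty file means all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def write_resolved_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    Artifacts are written under ``config.outdir``. Stage dependencies are
    resolved in memory first, then from configured input paths; a stage whose
    dependency is unavailable raises an orchestration error naming it.
    """
    config.validate()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "counts": {},
        "log": [],
    }

    def log(stage: str, **kv) -> None:
        parts = " ".join(f"{k}={v}" for k, v in kv.items())
        report["log"].append(f"stage={stage} {parts}")

    ct = cohort = truth = None
    expr = None
    collection = None

    if config.stages.get("simulate"):
        params = config.sim_params()
        ct, cohort, truth = _simulate.generate_paired_cohort(params)
        collection = _simulate.generate_target_sets(params)
        expr = _simulate.generate_matched_mrna(params, ct, collection, cohort)
        _qpcr.write_ct_table(ct, outdir / "ct_table.tsv")
        _qpcr.write_annotations(cohort, outdir / "annotations.tsv")
        _simulate.write_truth(truth, outdir / "truth.tsv")
        _targets.write_gmt(collection, outdir / "target_sets.gmt")
        _targets.write_expression(expr, outdir / "mrna_expression.tsv")
        _simulate.write_manifest(
            params, outdir / "manifest.yaml", extra={"config_hash": config.config_hash}
        )
        log("simulate", assays=len(ct.assays), samples=len(ct.samples),
            planted=len(truth))
        report["counts"]["assays_simulated"] = len(ct.assays)
        report["counts"]["samples"] = len(ct.samples)
        report["counts"]["planted_mirnas"] = len(truth)

    if ct is None and config.inputs.get("ct_table"):
        if not config.inputs.get("annotations"):
            raise OrchestrationError("ct_table input given without annotations")
        ct, cohort = _qpcr.read_ct_table(
            config.inputs["ct_table"],
            config.inputs["annotations"],
            max_cycle=config.max_cycle,
            reference_assay=config.reference_assay,
        )
    if expr is None and config.inputs.get("expression"):
        expr = _targets.read_expression(config.inputs["expression"])
    if collection is None and config.inputs.get("target_sets"):
        collection = _targets.merge_collections(
            *[_targets.read_gmt(p) for p in config.inputs["target_sets"]]
        )

    dct = None
    fc = None
    detection = None
    if config.stages.get("quantify"):
        if ct is None or cohort is None:
            raise OrchestrationError(
                "stage 'quantify' needs a Ct table (enable 'simulate' or set inputs)"
            )
        detection = _qpcr.call_detection(ct, config.detection_ct)
        work = _qpcr.censor_undetected(ct) if config.censor_undetected else ct
        dct = _qpcr.delta_ct(work)
        fc = _qpcr.paired_fold_changes(dct, cohort)
        _qpcr.write_delta_ct(dct, outdir / "delta_ct.tsv")
        _qpcr.write_fold_changes(fc, outdir / "fold_changes.tsv")
        n_censored = int(work.censored.to_numpy().sum())
        log("quantify", assays=len(ct.assays), censored_wells=n_censored,
            detected_wells=int(detection.to_numpy().sum()))
        report["counts"]["detected_wells"] = int(detection.to_numpy().sum())
        report["counts"]["censored_wells"] = n_censored

    table = selected = None
    if config.stages.get("differential"):
        if fc is None or detection is None:
            raise OrchestrationError(
                "stage 'differential' needs quantified fold changes "
                "(enable 'quantify')"
            )
        expressed = _differential.filter_expressed(detection, config.min_detected)
        expressed = [m for m in expressed if m in fc.log2fc.index]
        table = _differential.differential_screen(
            fc, expressed=expressed, test_scale=config.test_scale
        )
        selected = _differential.select_significant(table, config.alpha)
        _differential.write_differential(table, outdir / "differential.tsv")
        _differential.write_differential(selected, outdir / "selected.tsv")
        log("differential", expressed=len(expressed), tested=len(table),
            selected=len(selected))
        report["counts"]["mirnas_expressed"] = len(expressed)
        report["counts"]["mirnas_tested"] = len(table)
        report["counts"]["mirnas_selected"] = len(selected)
        report["selected_mirnas"] = list(selected.index)

    if config.stages.get("cluster"):
        if fc is None or selected is None:
            raise OrchestrationError(
                "stage 'cluster' needs the differential selection "
                "(enable 'differential')"
            )
        # complete-case on miRNAs so every patient keeps a full profile
        block = fc.log2fc.loc[selected.index].dropna(axis=0, how="any")
        report["clusters"] = {}
        if block.shape[0] >= 2 and block.shape[1] >= 2:
            for orientation in config.cluster_orientation:
                data = block.T if orientation == "patients" else block
                if data.shape[0] < 2 or data.shape[1] < 2:
                    continue
                tree = _cluster.upgma(_cluster.pearson_distance(data))
                k = min(config.cluster_k, tree.n_leaves)
                assignments = tree.cut(k)
                _cluster.write_newick(tree, outdir / f"tree_{orientation}.newick")
                _cluster.write_clusters(
                    assignments, outdir / f"clusters_{orientation}.tsv"
                )
                report["clusters"][orientation] = {
                    label: sorted(assignments.index[assignments == label])
                    for label in sorted(assignments.unique())
                }
                log("cluster", orientation=orientation, k=k,
                    items=tree.n_leaves)
        else:
            log("cluster", skipped="too few selected miRNAs or patients")

    if config.stages.get("targets"):
        if dct is None:
            raise OrchestrationError("stage 'targets' needs deltaCt (enable 'quantify')")
        if expr is None or collection is None:
            raise OrchestrationError(
                "stage 'targets' needs an expression matrix and target sets "
                "(enable 'simulate' or set inputs)"
            )
        prepared = _targets.lowest_quartile_filter(_targets.quantile_normalize(expr))
        to_test = list(config.target_mirnas or collection.mirnas)
        report["targets"] = {}
        null_rows = []
        for i, mirna in enumerate(to_test):
            if mirna not in dct.dct.index:
                log("targets", mirna=mirna, skipped="absent from deltaCt matrix")
                continue
            v = _targets.mirna_expression_vector(dct, mirna)
            if v.constant or v.values.isna().any():
                log("targets", mirna=mirna, skipped="unusable miRNA vector")
                continue
            result = _targets.permutation_target_test(
                prepared,
                v,
                collection.union(mirna),
                n_perm=config.n_perm,
                seed=config.seed + 1000 + i,
                mirna=mirna,
            )
            anticorr = _targets.anticorrelated_gene_list(
                result.target_r, config.anticorr_threshold
            )
            entry = result.to_dict()
            entry["n_anticorrelated"] = len(anticorr)
            report["targets"][mirna] = entry
            null_rows.append(
                pd.Series(result.null_means, name=mirna)
            )
            log("targets", mirna=mirna, observed=f"{result.observed_mean:.4f}",
                p_low=result.p_low)
        if null_rows:
            pd.DataFrame(null_rows).T.to_csv(outdir / "null_means.tsv", sep="\t",
                                             index_label="perm")
        with open(outdir / "target_results.json", "w") as fh:
            json.dump(report["targets"], fh, sort_keys=True, indent=2)
        report["counts"]["mirnas_target_tested"] = len(report["targets"])

    write_resolved_config(config, outdir / "resolved_config.yaml")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2)
    return report
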