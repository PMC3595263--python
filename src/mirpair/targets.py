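"""miRNA target anti-correlation analysis.

A miRNA that actively represses its mRNA targets should leave a footprint in
matched expression data: across samples, predicted target genes correlate
*negatively* with the miRNA's expression. This module implements that test.

Workflow:

1. Prepare the mRNA matrix — quantile-normalize samples, then drop genes whose
   signal sits below the lowest quartile in every sample (consistently
   unexpressed probes contribute only noise to correlations).
2. Express the miRNA as its log2 relative expression, ``-deltaCt``, per sample.
3. Compute the Pearson correlation of each gene with the miRNA vector across
   the pooled samples.
4. Compare the mean correlation of the predicted target set (the union over
   prediction sources, e.g. TargetScan- and PITA-style sets) against a null of
   equally sized gene sets drawn at random from the non-target genes. Two
   one-sided permutation p-values are reported with the add-one correction
   ``p = (1 + #{null <= observed}) / (N_perm + 1)`` so p is never zero.

Target sets travel in GMT format: one set per line, tab-separated
``name  description  member ...``, with the set name the miRNA id and the
description the prediction source.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ComputationError, TargetLookupError, ValidationError

DEFAULT_N_PERM = 1000
DEFAULT_ANTICORR_THRESHOLD = -0.3


class TargetSetCollection:
    """Mapping of prediction source -> (miRNA id -> set of gene ids)."""

    def __init__(self, sources: Mapping[str, Mapping[str, Iterable[str]]]):
        self._sources: dict[str, dict[str, set[str]]] = {
            src: {m: set(genes) for m, genes in sets.items()}
            for src, sets in sources.items()
        }

    @property
    def sources(self) -> list[str]:
        return list(self._sources)

    @property
    def mirnas(self) -> list[str]:
        seen: dict[str, None] = {}
        for sets in self._sources.values():
            for m in sets:
                seen.setdefault(m, None)
        return list(seen)

    def get(self, source: str, mirna: str) -> set[str]:
        return set(self._sources[source][mirna])

    def union(self, mirna: str) -> set[str]:
        """Union of the miRNA's predicted targets across all sources."""
        found = False
        out: set[str] = set()
        for sets in self._sources.values():
            if mirna in sets:
                found = True
                out |= sets[mirna]
        if not found:
            raise TargetLookupError(f"miRNA {mirna!r} absent from every source")
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetSetCollection) and self._sources == other._sources


def union_target_sets(collection: TargetSetCollection, mirna: str) -> set[str]:
    return collection.union(mirna)


def read_gmt(path, *, source: str | None = None) -> TargetSetCollection:
    """Read one GMT file; the description field names the source unless
    ``source`` overrides it."""
    sources: dict[str, dict[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line needs >=3 fields: {line[:60]!r}")
            name, description, *members = fields
            src = source or description or "unknown"
            sources.setdefault(src, {})[name] = set(members)
    return TargetSetCollection(sources)


def merge_collections(*collections: TargetSetCollection) -> TargetSetCollection:
    merged: dict[str, dict[str, set[str]]] = {}
    for coll in collections:
        for src in coll.sources:
            merged.setdefault(src, {})
            for m in coll._sources[src]:
                merged[src][m] = coll.get(src, m)
    return TargetSetCollection(merged)


def write_gmt(collection: TargetSetCollection, path) -> None:
    with open(path, "w") as fh:
        for src in sorted(collection.sources):
            for mirna in sorted(collection._sources[src]):
                members = sorted(collection.get(src, mirna))
                fh.write("\t".join([mirna, src, *members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix preparation
# ---------------------------------------------------------------------------

def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution formed by the
    across-sample mean of sorted values; ties receive the average of the
    quantile values they span."""
    if expr.shape[1] < 2:
        raise ValidationError("quantile normalization needs >=2 samples")
    values = expr.to_numpy(float)
    if not np.isfinite(values).all():
        raise ValidationError("expression matrix contains non-finite values")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    ranks = expr.rank(axis=0, method="average").to_numpy(float)
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def lowest_quartile_filter(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose signal is below the per-sample 25th percentile in
    *every* sample (consistently unexpressed)."""
    if expr.shape[0] < 4:
        raise ValidationError("quartile filter needs >=4 genes")
    q1 = expr.quantile(0.25, axis=0)
    below_everywhere = expr.lt(q1, axis=1).all(axis=1)
    return expr.loc[~below_everywhere]


# ---------------------------------------------------------------------------
# Correlation and permutation test
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MirnaVector:
    """A miRNA's log2 relative expression (-deltaCt) per sample."""

    mirna: str
    values: pd.Series
    censored: pd.Series

    @property
    def constant(self) -> bool:
        v = self.values.to_numpy(float)
        return bool(np.all(v == v[0]))

    @property
    def any_censored(self) -> bool:
        return bool(self.censored.any())


def mirna_expression_vector(dct, mirna: str) -> MirnaVector:
    """-deltaCt per sample for one miRNA (log2 scale, higher = more miRNA)."""
    if mirna not in dct.dct.index:
        raise TargetLookupError(f"miRNA {mirna!r} absent from deltaCt matrix")
    return MirnaVector(
        mirna=mirna,
        values=-dct.dct.loc[mirna],
        censored=dct.censored.loc[mirna].astype(bool),
    )


def gene_mirna_correlations(
    expr: pd.DataFrame, v: pd.Series | MirnaVector, genes: Iterable[str] | None = None
) -> pd.Series:
    """Pearson r of each gene with the miRNA vector over shared samples."""
    if isinstance(v, MirnaVector):
        v = v.values
    shared = [s for s in expr.columns if s in v.index]
    if len(shared) < 3:
        raise ValidationError("need >=3 shared samples for correlation")
    sub = expr[shared]
    if genes is not None:
        genes = [g for g in genes if g in sub.index]
        sub = sub.loc[genes]
    x = sub.to_numpy(float)
    y = v.loc[shared].to_numpy(float)
    y_c = y - y.mean()
    y_norm = np.sqrt((y_c**2).sum())
    if y_norm == 0:
        raise ValidationError("miRNA vector is constant; correlation undefined")
    x_c = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x_c @ y_c) / (x_norm * y_norm)
    return pd.Series(r, index=sub.index, name="r")


@dataclasses.dataclass
class TargetCorrelationResult:
    """Observed target-set mean correlation and its permutation null."""

    mirna: str
    n_targets: int
    n_missing: int
    target_r: pd.Series
    observed_mean: float
    null_means: np.ndarray
    p_low: float
    p_high: float
    n_perm: int
    seed: int
    mirna_vector_censored: bool = False

    def to_dict(self) -> dict:
        return {
            "mirna": self.mirna,
            "n_targets": self.n_targets,
            "n_missing": self.n_missing,
            "observed_mean_r": self.observed_mean,
            "p_low": self.p_low,
            "p_high": self.p_high,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "mirna_vector_censored": self.mirna_vector_censored,
        }


def permutation_target_test(
    expr: pd.DataFrame,
    v: pd.Series | MirnaVector,
    targets: Iterable[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    mirna: str | None = None,
) -> TargetCorrelationResult:
    """Test whether predicted targets are anti-correlated with the miRNA.

    The observed statistic is the mean per-gene Pearson r over the target
    genes present in the matrix. The null draws ``n_perm`` gene sets of the
    same size, without replacement, from the non-target genes; ``p_low`` is
    the add-one fraction of null means at or below the observed mean (the
    repression direction, the primary p-value) and ``p_high`` the analogue
    for the other tail.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    name = mirna or (v.mirna if isinstance(v, MirnaVector) else "miRNA")
    censored_flag = v.any_censored if isinstance(v, MirnaVector) else False
    r = gene_mirna_correlations(expr, v)

    requested = set(targets)
    present = sorted(requested & set(r.index))
    if not present:
        raise ValidationError("target set empty after intersection with the matrix")
    # sorted pool: the null depends only on ids, not input row order
    pool = sorted(set(r.index) - requested)
    if len(pool) < len(present):
        raise ValidationError(
            f"non-target pool ({len(pool)}) smaller than target set ({len(present)})"
        )

    target_r = r.loc[present]
    observed = float(target_r.mean())

    pool_r = r.loc[pool].to_numpy(float)
    rng = np.random.default_rng(seed)
    k = len(present)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(len(pool_r), size=k, replace=False)
        null_means[i] = pool_r[idx].mean()

    p_low = (1 + int((null_means <= observed).sum())) / (n_perm + 1)
    p_high = (1 + int((null_means >= observed).sum())) / (n_perm + 1)
    return TargetCorrelationResult(
        mirna=name,
        n_targets=len(present),
        n_missing=len(requested) - len(present),
        target_r=target_r,
        observed_mean=observed,
        null_means=null_means,
        p_low=p_low,
        p_high=p_high,
        n_perm=n_perm,
        seed=seed,
        mirna_vector_censored=censored_flag,
    )


def anticorrelated_gene_list(
    r: pd.Series, threshold: float = DEFAULT_ANTICORR_THRESHOLD
) -> list[str]:
    """Genes with Pearson r strictly below the threshold, most negative first."""
    if not (-1 < threshold <= 0):
        raise ValidationError(f"threshold must be in (-1, 0], got {threshold}")
    selected = r[r < threshold].sort_values()
    return list(selected.index)


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
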