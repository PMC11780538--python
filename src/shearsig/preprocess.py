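"""Gene filtering and library-size normalization.

Filtering runs three sequential stages over all measured samples:

1. drop genes absent from a supplied annotation (skipped when none given);
2. drop the bottom ``abundance_frac`` quantile of low-abundance genes
   (default 4%, mean raw count metric);
3. drop the bottom ``variance_frac`` quantile of low-variance genes
   (default 15%, variance of log2CPM metric).

Quantile boundaries use the nearest-rank rule (``ceil(frac * n)`` genes
removed), with ties broken by gene-ID lexical order so the result is
deterministic.  Both metrics are configurable because "low abundance" and
"low variance" admit several conventional readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .datatypes import CountMatrix, ExpressionMatrix, ValidationError

ABUNDANCE_METRICS = ("mean_count", "median_count", "max_count")
VARIANCE_METRICS = ("log2cpm_variance", "count_variance")


@dataclass
class FilterReport:
    n_input: int
    n_after_annotation: int
    n_after_abundance: int
    n_after_variance: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.n_input
            >= self.n_after_annotation
            >= self.n_after_abundance
            >= self.n_after_variance
        ):
            raise ValidationError("filter stage counts must be non-increasing")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_annotation": self.n_after_annotation,
            "n_after_abundance": self.n_after_abundance,
            "n_after_variance": self.n_after_variance,
            "removed_ids": {k: list(v) for k, v in self.removed_ids.items()},
        }


def _bottom_quantile(gene_ids: list[str], metric: np.ndarray, frac: float) -> list[str]:
    """Gene IDs in the bottom ``frac`` nearest-rank quantile of ``metric``."""
    n = len(gene_ids)
    k = math.ceil(frac * n)
    if k <= 0:
        return []
    order = sorted(range(n), key=lambda i: (metric[i], gene_ids[i]))
    return [gene_ids[i] for i in order[:k]]


def cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million: each sample's counts scaled to sum to 1e6."""
    lib = cm.library_sizes().astype(float)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValidationError(
            f"zero library size for sample(s): {[cm.sample_ids[i] for i in zero]}"
        )
    values = cm.counts / lib[None, :] * 1e6
    return ExpressionMatrix(list(cm.gene_ids), list(cm.sample_ids), values, "cpm")


def log2cpm(cm: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); the pseudocount keeps zero counts finite."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    e = cpm(cm)
    return ExpressionMatrix(
        e.gene_ids, e.sample_ids, np.log2(e.values + pseudocount), "log2cpm"
    )


def filter_genes(
    cm: CountMatrix,
    annotation: Iterable[str] | None = None,
    abundance_frac: float = 0.04,
    variance_frac: float = 0.15,
    abundance_metric: str = "mean_count",
    variance_metric: str = "log2cpm_variance",
    pseudocount: float = 1.0,
) -> tuple[CountMatrix, FilterReport]:
    """Sequentially remove unannotated, low-abundance and low-variance genes.

    Percentile filters are computed on the gene set surviving the previous
    stage; the log2CPM used by the variance metric is recomputed on the
    current submatrix so the stage is self-contained.
    """
    if not (0 <= abundance_frac < 1 and 0 <= variance_frac < 1):
        raise ValidationError("filter fractions must lie in [0, 1)")
    if abundance_metric not in ABUNDANCE_METRICS:
        raise ValidationError(f"abundance_metric must be one of {ABUNDANCE_METRICS}")
    if variance_metric not in VARIANCE_METRICS:
        raise ValidationError(f"variance_metric must be one of {VARIANCE_METRICS}")

    removed: dict[str, list[str]] = {}
    current = cm
    n_input = cm.n_genes

    # stage 1: annotation
    if annotation is not None:
        ann = set(map(str, annotation))
        keep = [g for g in current.gene_ids if g in ann]
        removed["annotation"] = [g for g in current.gene_ids if g not in ann]
        if not keep:
            raise ValidationError("no genes left after annotation filter")
        current = current.subset_genes(keep)
    else:
        removed["annotation"] = []
    n_after_annotation = current.n_genes

    # stage 2: abundance
    counts = current.counts.astype(float)
    if abundance_metric == "mean_count":
        ab = counts.mean(axis=1)
    elif abundance_metric == "median_count":
        ab = np.median(counts, axis=1)
    else:
        ab = counts.max(axis=1)
    drop = set(_bottom_quantile(current.gene_ids, ab, abundance_frac))
    removed["abundance"] = sorted(drop)
    keep = [g for g in current.gene_ids if g not in drop]
    if not keep:
        raise ValidationError("no genes left after abundance filter")
    current = current.subset_genes(keep)
    n_after_abundance = current.n_genes

    # stage 3: variance
    if variance_metric == "log2cpm_variance":
        var = log2cpm(current, pseudocount).values.var(axis=1, ddof=1)
    else:
        var = current.counts.astype(float).var(axis=1, ddof=1)
    drop = set(_bottom_quantile(current.gene_ids, var, variance_frac))
    removed["variance"] = sorted(drop)
    keep = [g for g in current.gene_ids if g not in drop]
    if not keep:
        raise ValidationError("no genes left after variance filter")
    current = current.subset_genes(keep)

    report = FilterReport(
        n_input=n_input,
        n_after_annotation=n_after_annotation,
        n_after_abundance=n_after_abundance,
        n_after_variance=current.n_genes,
        removed_ids=removed,
    )
    return current, report
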