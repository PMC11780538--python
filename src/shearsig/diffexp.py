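"""Grouped differential expression under a negative-binomial Wald contract.

Each contrast compares two disjoint sample sets of the filtered count
matrix as a simple two-group design (no donor pairing): size factors by
median-of-ratios over the union of the two sets, per-gene NB dispersion
estimation, a Wald test on the two-level group coefficient, and BH
correction.  The fitting engine is pydeseq2, which implements the DESeq2
procedure; the contract above is what this module guarantees regardless of
engine.  DEGs are genes with padj <= alpha (0.05), with no fold-change
cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)


def _resolve_samples(
    ann: SampleAnnotation, selector: Mapping[str, str] | Sequence[str]
) -> list[str]:
    """A selector is either an explicit sample list or a field filter dict
    like ``{"group": "PAH", "condition": "HSS"}``."""
    if isinstance(selector, Mapping):
        return ann.samples_where(
            group=selector.get("group"),
            condition=selector.get("condition"),
            donor=selector.get("donor"),
        )
    return list(selector)


@dataclass
class DEResult:
    """Wald-test results for one two-group contrast (log2fc of B over A)."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # index gene; basemean, log2fc, pvalue, padj
    alpha: float = 0.05
    excluded_genes: list[str] | None = None  # all-zero rows never tested

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def degs(self, alpha: float | None = None) -> frozenset[str]:
        a = self.alpha if alpha is None else alpha
        padj = self.table["padj"]
        return frozenset(self.table.index[padj.notna() & (padj <= a)])

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.table.index) | frozenset(self.excluded_genes or [])


def run_de(
    cm: CountMatrix,
    ann: SampleAnnotation,
    setA: Mapping[str, str] | Sequence[str],
    setB: Mapping[str, str] | Sequence[str],
    alpha: float = 0.05,
    independent_filter: bool = True,
    cooks_filter: bool = True,
    refit_cooks: bool = True,
    labels: tuple[str, str] | None = None,
) -> DEResult:
    """Negative-binomial Wald differential expression of setB vs setA.

    Sets with fewer than two samples are refused (no dispersion estimate is
    possible); all-zero gene rows are excluded from testing and recorded in
    the result.
    """
    samplesA = _resolve_samples(ann, setA)
    samplesB = _resolve_samples(ann, setB)
    if not samplesA or not samplesB:
        raise ValidationError("both sample sets must be non-empty")
    overlap = set(samplesA) & set(samplesB)
    if overlap:
        raise ValidationError(f"sample sets overlap: {sorted(overlap)}")
    for name, ss in (("A", samplesA), ("B", samplesB)):
        if len(ss) < 2:
            warnings.warn(
                f"set {name} has {len(ss)} sample(s); dispersion cannot be "
                "estimated", stacklevel=2
            )
            raise ValidationError(f"set {name} needs >= 2 samples")

    sub = cm.subset_samples(samplesA + samplesB)
    zero_rows = sub.counts.sum(axis=1) == 0
    excluded = [g for g, z in zip(sub.gene_ids, zero_rows) if z]
    if excluded:
        logger.info("excluding %d all-zero gene rows from DE", len(excluded))
        sub = sub.subset_genes([g for g in sub.gene_ids if g not in set(excluded)])

    counts_df = sub.to_frame().T  # samples x genes, as the engine expects
    meta = pd.DataFrame(
        {"grp": ["A"] * len(samplesA) + ["B"] * len(samplesB)},
        index=counts_df.index,
    )

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.default_inference import DefaultInference
    from pydeseq2.ds import DeseqStats

    inference = DefaultInference(n_cpus=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=counts_df,
            metadata=meta,
            design="~grp",
            refit_cooks=refit_cooks,
            quiet=True,
            inference=inference,
        )
        dds.deseq2()
        ds = DeseqStats(
            dds,
            contrast=["grp", "B", "A"],
            alpha=alpha,
            cooks_filter=cooks_filter,
            independent_filter=independent_filter,
            quiet=True,
            inference=inference,
        )
        ds.summary()
    res = ds.results_df
    table = pd.DataFrame(
        {
            "basemean": res["baseMean"],
            "log2fc": res["log2FoldChange"],
            "pvalue": res["pvalue"],
            "padj": res["padj"],
        },
        index=pd.Index(res.index, name="gene"),
    )
    if labels is None:
        labels = (_describe(setA), _describe(setB))
    return DEResult(labels, table, alpha=alpha, excluded_genes=excluded)


def _describe(selector) -> str:
    if isinstance(selector, Mapping):
        return ",".join(f"{k}={v}" for k, v in sorted(selector.items()))
    return "+".join(selector)


@dataclass
class DegOverlap:
    """Set algebra on the DEG lists of two contrasts over one gene universe."""

    contrast_pair: tuple[str, str]
    a_only: list[str]
    b_only: list[str]
    shared: list[str]

    @property
    def n_a_only(self) -> int:
        return len(self.a_only)

    @property
    def n_b_only(self) -> int:
        return len(self.b_only)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_non_overlapping(self) -> int:
        return self.n_a_only + self.n_b_only

    def to_dict(self) -> dict:
        return {
            "contrast_pair": list(self.contrast_pair),
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "n_shared": self.n_shared,
            "n_non_overlapping": self.n_non_overlapping,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "shared": self.shared,
        }


def deg_overlap(resA: DEResult, resB: DEResult, alpha: float = 0.05) -> DegOverlap:
    """Overlap bookkeeping between two DEG sets on the same gene universe."""
    if resA.gene_universe != resB.gene_universe:
        raise ValidationError("DE results cover different gene universes")
    degsA, degsB = resA.degs(alpha), resB.degs(alpha)
    return DegOverlap(
        contrast_pair=("/".join(resA.contrast), "/".join(resB.contrast)),
        a_only=sorted(degsA - degsB),
        b_only=sorted(degsB - degsA),
        shared=sorted(degsA & degsB),
    )
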