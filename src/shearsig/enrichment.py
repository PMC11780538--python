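"""Over-representation analysis (ORA) against a filtered background.

For a query gene list drawn from a background of N genes, and a pathway
with K background members, the enrichment p-value is the upper tail of the
hypergeometric distribution, P(X >= k) for an overlap of k among n draws —
equivalently a one-tailed Fisher's exact test on the 2x2 overlap table.
Benjamini-Hochberg correction is applied per gene-set collection, and a
pathway only counts as significant when, in addition to padj <= alpha, at
least ``min_overlap`` query genes fall in it (3 by default): a pathway "hit"
carried by one or two genes is not interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, ValidationError


@dataclass
class OraResult:
    """Per-pathway enrichment statistics for one query against one collection."""

    source: str
    n_background: int
    n_query: int
    table: pd.DataFrame  # index pathway; n_set_in_bg, n_overlap, pvalue, padj,
    # significant, overlap_genes

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["overlap_genes"] = out["overlap_genes"].map(lambda gs: ";".join(gs))
        return out

    def significant_pathways(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def overlap_genes(self, pathway: str) -> list[str]:
        return list(self.table.loc[pathway, "overlap_genes"])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: Iterable[str],
    background: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 3,
) -> OraResult:
    """Hypergeometric over-representation of ``query`` in each pathway.

    ``query`` must be a subset of ``background``; callers intersect
    explicitly so the universe of the test is never ambiguous.  Pathway
    members outside the background are ignored, and pathways with no
    background member are dropped before testing (and before BH).
    """
    bg = frozenset(map(str, background))
    q = frozenset(map(str, query))
    stray = q - bg
    if stray:
        raise ValidationError(
            f"query contains genes outside the background: {sorted(stray)[:10]}"
        )
    N, n = len(bg), len(q)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & bg
        if not members:
            continue
        K = len(members)
        overlap = sorted(members & q)
        k = len(overlap)
        # P(X >= k) with population N, K successes, n draws
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, p, overlap))
    if not rows:
        table = pd.DataFrame(
            columns=["n_set_in_bg", "n_overlap", "pvalue", "padj",
                     "significant", "overlap_genes"]
        )
        table.index.name = "pathway"
        return OraResult(collection.source, N, n, table)
    names, Ks, ks, ps, overlaps = zip(*rows)
    padj = bh_adjust(ps)
    table = pd.DataFrame(
        {
            "n_set_in_bg": Ks,
            "n_overlap": ks,
            "pvalue": ps,
            "padj": padj,
            "significant": (padj <= alpha) & (np.array(ks) >= min_overlap),
            "overlap_genes": list(overlaps),
        },
        index=pd.Index(names, name="pathway"),
    )
    return OraResult(collection.source, N, n, table)


@dataclass
class ConcordanceResult:
    """Per-pathway DEG-count pairs for two contrasts, with Pearson r and MAE."""

    pairs: pd.DataFrame  # index pathway; columns x (contrast A), y (contrast B)
    pearson_r: float
    pearson_p: float
    mae: float

    def to_frame(self) -> pd.DataFrame:
        return self.pairs


def pathway_deg_concordance(
    oraA: OraResult,
    oraB: OraResult,
    degsA: Iterable[str],
    degsB: Iterable[str],
    collection: GeneSetCollection,
) -> ConcordanceResult:
    """How similarly two DEG sets populate the pathways either one enriches.

    For every pathway significant in A or B, x counts A's DEGs in the
    pathway and y counts B's.  Pearson r is undefined (NaN) below three
    pathways; MAE is the mean absolute x-y gap.
    """
    pathways = sorted(set(oraA.significant_pathways()) | set(oraB.significant_pathways()))
    if not pathways:
        raise ValidationError("no pathway is significant in either result")
    dA = frozenset(map(str, degsA))
    dB = frozenset(map(str, degsB))
    xs = [len(collection.sets[p] & dA) for p in pathways]
    ys = [len(collection.sets[p] & dB) for p in pathways]
    pairs = pd.DataFrame({"x": xs, "y": ys}, index=pd.Index(pathways, name="pathway"))
    if len(pathways) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(xs, ys)
    mae = float(np.mean(np.abs(np.array(xs) - np.array(ys))))
    return ConcordanceResult(pairs, float(r), float(p), mae)


def pathway_deg_log2fc(
    ora: OraResult, de_log2fc: Mapping[str, float]
) -> dict[str, dict]:
    """Per significant pathway: the DEG log2FC vector and its mean.

    This is the data behind per-pathway fold-change density displays; no
    rendering is done here.
    """
    out: dict[str, dict] = {}
    for p in ora.significant_pathways():
        genes = [g for g in ora.overlap_genes(p) if g in de_log2fc]
        vals = [float(de_log2fc[g]) for g in genes]
        out[p] = {
            "genes": genes,
            "log2fc": vals,
            "mean_log2fc": float(np.mean(vals)) if vals else float("nan"),
        }
    return out
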