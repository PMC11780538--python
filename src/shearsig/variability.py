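"""Differential gene-expression variability: bias-corrected CV, dCV, ddCV.

The coefficient of variation of a gene's CPM values within one
(group, condition) cell is computed with the small-sample bias correction

    CV(%) = (1 + 1/(4n)) * (s / x_bar) * 100,

where ``s`` is the sample standard deviation (n-1 denominator).  dCV is the
within-group change of CV from a reference flow condition to a target one
(Static -> HSS by default), and

    ddCV = dCV_case - dCV_reference   (PAH minus control)

scores how much more variable a gene's shear response is in the case group.
Genes with a ddCV above a cutoff (50 CV percentage points by default) form
the "top variable" list that seeds patient stratification.

Only genes with nonzero raw counts in every sample of the considered
conditions are eligible: a zero anywhere makes the CV estimate untrustworthy
at n = 4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ExpressionMatrix, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)


def corrected_cv(values, n: int | None = None) -> float:
    """Bias-corrected coefficient of variation, in percent.

    Returns NaN (with a log entry) when the mean is not positive, where the
    CV is undefined.
    """
    values = np.asarray(values, dtype=float)
    if n is None:
        n = values.size
    if n != values.size or n < 2:
        raise ValidationError(f"corrected_cv needs n = len(values) >= 2, got {n}")
    mean = values.mean()
    if mean <= 0:
        logger.info("corrected_cv undefined for non-positive mean %g", mean)
        return float("nan")
    sd = values.std(ddof=1)
    return float((1.0 + 1.0 / (4.0 * n)) * sd / mean * 100.0)


def _cell_cv(values: np.ndarray) -> np.ndarray:
    """Vectorized corrected CV over rows of a genes x samples block."""
    n = values.shape[1]
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, (1.0 + 1.0 / (4.0 * n)) * sd / mean * 100.0, np.nan)
    return cv


@dataclass
class VariabilityTable:
    """Per-gene CV per (group, condition), dCV per group, and ddCV."""

    table: pd.DataFrame  # index gene; cv_*, dcv_*, ddcv, eligible
    group_case: str
    group_ref: str
    cond_from: str
    cond_to: str

    def to_frame(self) -> pd.DataFrame:
        return self.table


def variability_table(
    E: ExpressionMatrix,
    ann: SampleAnnotation,
    cond_from: str = "Static",
    cond_to: str = "HSS",
    group_case: str = "PAH",
    group_ref: str = "control",
    counts: CountMatrix | None = None,
    per_group_eligibility: bool = False,
) -> VariabilityTable:
    """Compute CV, dCV and ddCV for every gene.

    ``E`` must be on the CPM scale.  Eligibility requires a nonzero raw
    count in every sample of ``cond_from`` and ``cond_to`` in both groups
    (or within each group separately with ``per_group_eligibility``); raw
    counts are taken from ``counts`` when given, otherwise CPM > 0 is used,
    which is equivalent whenever library sizes are positive.
    """
    if E.scale != "cpm":
        raise ValidationError(f"variability_table expects CPM input, got {E.scale!r}")
    groups = (group_ref, group_case)
    conds = (cond_from, cond_to)
    cells: dict[tuple[str, str], np.ndarray] = {}
    raw = counts.to_frame().loc[E.gene_ids] if counts is not None else None
    nonzero: dict[str, np.ndarray] = {}
    for g in groups:
        group_ok = np.ones(E.n_genes, dtype=bool)
        for c in conds:
            samples = ann.samples_where(group=g, condition=c)
            if len(samples) < 2:
                raise ValidationError(
                    f"group {g!r} condition {c!r} has {len(samples)} sample(s); "
                    "need >= 2 for a CV"
                )
            block = E.subset_samples(samples).values
            cells[(g, c)] = block
            if raw is not None:
                ok = (raw[samples].to_numpy() > 0).all(axis=1)
            else:
                ok = (block > 0).all(axis=1)
            group_ok &= ok
        nonzero[g] = group_ok

    if per_group_eligibility:
        eligible = {g: nonzero[g] for g in groups}
    else:
        both = nonzero[group_ref] & nonzero[group_case]
        eligible = {g: both for g in groups}

    data: dict[str, np.ndarray] = {}
    for g in groups:
        for c in conds:
            data[f"cv_{g}_{c}"] = _cell_cv(cells[(g, c)])
    for g in groups:
        dcv = data[f"cv_{g}_{cond_to}"] - data[f"cv_{g}_{cond_from}"]
        data[f"dcv_{g}"] = np.where(eligible[g], dcv, np.nan)
    ddcv = data[f"dcv_{group_case}"] - data[f"dcv_{group_ref}"]
    data["ddcv"] = ddcv
    data["eligible"] = eligible[group_ref] & eligible[group_case]

    df = pd.DataFrame(data, index=pd.Index(E.gene_ids, name="gene"))
    return VariabilityTable(df, group_case, group_ref, cond_from, cond_to)


def select_top_variable(vt: VariabilityTable, cutoff: float = 50.0) -> list[str]:
    """Eligible genes with ddCV strictly above ``cutoff``, most variable first.

    Ties in ddCV are broken by gene ID so the ordering is deterministic.
    """
    t = vt.table
    mask = t["eligible"].to_numpy(dtype=bool) & (t["ddcv"].to_numpy() > cutoff)
    sub = t.loc[mask, "ddcv"]
    order = sorted(sub.index, key=lambda g: (-sub[g], g))
    return list(order)
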