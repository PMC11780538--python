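"""Core in-memory containers for the shear-stress transcriptomics pipeline.

The pipeline's root object is an integer gene x sample count matrix with a
companion sample sheet recording, for every sequencing channel, the donor it
came from, the disease group (``control`` vs ``PAH``) and the flow condition
it was exposed to (``Static`` 0 dyn/cm2, ``LSS`` 2.5 dyn/cm2, ``HSS``
15 dyn/cm2).  Downstream stages exchange :class:`ExpressionMatrix` objects
whose ``scale`` records which normalization produced them, GMT-style gene-set
collections, and (for signature transfer) a probe-level log2 microarray
matrix from an external case/control cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "PAH")
CONDITIONS = ("Static", "LSS", "HSS")
EXPRESSION_SCALES = ("counts", "cpm", "log2cpm", "log2microarray")


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class ParseError(ValueError):
    """An external file could not be interpreted."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class CountMatrix:
    """Integer read counts, genes in rows, samples in columns."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.counts.size:
            if np.any(self.counts < 0):
                g, s = np.argwhere(self.counts < 0)[0]
                raise ValidationError(
                    f"negative count for gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            if not np.issubdtype(self.counts.dtype, np.integer):
                rounded = np.rint(self.counts)
                if np.any(np.abs(self.counts - rounded) > 1e-9):
                    g, s = np.argwhere(np.abs(self.counts - rounded) > 1e-9)[0]
                    raise ValidationError(
                        f"non-integer count for gene {self.gene_ids[g]!r}, "
                        f"sample {self.sample_ids[s]!r}"
                    )
                self.counts = rounded.astype(np.int64)
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"unknown genes: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return CountMatrix(list(genes), list(self.sample_ids), self.counts[rows])

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:10]}")
        cols = [idx[s] for s in samples]
        return CountMatrix(list(self.gene_ids), list(samples), self.counts[:, cols])


@dataclass
class SampleAnnotation:
    """Per-sample design: donor, disease group, flow condition.

    One channel per donor per condition, so ``(donor_id, condition)`` pairs
    are unique.
    """

    table: pd.DataFrame  # columns: sample_id, donor_id, group, condition

    REQUIRED = ("sample_id", "donor_id", "group", "condition")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        self.table = self.table.loc[:, list(self.REQUIRED)].astype(str)
        self.table = self.table.reset_index(drop=True)
        _check_unique(list(self.table["sample_id"]), "sample IDs")
        bad_grp = sorted(set(self.table["group"]) - set(GROUPS))
        if bad_grp:
            raise ValidationError(f"unknown group labels {bad_grp}; expected {GROUPS}")
        bad_cond = sorted(set(self.table["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ValidationError(
                f"unknown condition labels {bad_cond}; expected {CONDITIONS}"
            )
        pairs = list(zip(self.table["donor_id"], self.table["condition"]))
        _check_unique([f"{d}/{c}" for d, c in pairs], "(donor, condition) pairs")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def check_matches(self, cm: CountMatrix) -> None:
        """Every count-matrix sample must appear exactly once in the sheet."""
        sheet = set(self.table["sample_id"])
        missing = [s for s in cm.sample_ids if s not in sheet]
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {missing}")

    def samples_where(
        self, group: str | None = None, condition: str | None = None,
        donor: str | None = None,
    ) -> list[str]:
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if group is not None:
            mask &= (t["group"] == group).to_numpy()
        if condition is not None:
            mask &= (t["condition"] == condition).to_numpy()
        if donor is not None:
            mask &= (t["donor_id"] == donor).to_numpy()
        return list(t.loc[mask, "sample_id"])

    def donor_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return str(row["donor_id"].iloc[0])

    def group_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return str(row["group"].iloc[0])


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x samples, with a declared scale."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if self.scale not in EXPRESSION_SCALES:
            raise ValidationError(
                f"unknown scale {self.scale!r}; expected one of {EXPRESSION_SCALES}"
            )
        if self.scale in ("log2cpm", "log2microarray") and self.values.size:
            if not np.all(np.isfinite(self.values)):
                raise ValidationError(f"{self.scale} values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene"),
            columns=self.sample_ids,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:10]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols], self.scale
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows], self.scale
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) from one database export."""

    source: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            fs = frozenset(str(m) for m in members)
            if not fs:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[str(name)] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, background: Iterable[str]) -> "GeneSetCollection":
        bg = frozenset(background)
        kept = {
            name: members & bg
            for name, members in self.sets.items()
            if members & bg
        }
        return GeneSetCollection(self.source, kept)


@dataclass
class ExternalCohortMatrix:
    """Probe-level log2 expression for an external case/control cohort.

    Several probes may map to the same gene; unannotated probes carry an
    empty-string gene ID and are dropped before probe collapse.
    """

    probe_ids: list[str]
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: list[str]  # per sample, "control" or "case"

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.gene_ids = ["" if g in ("", "NA", "nan", "None") else str(g)
                         for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe IDs")
        _check_unique(self.sample_ids, "sample IDs")
        if len(self.gene_ids) != len(self.probe_ids):
            raise ValidationError("one gene ID required per probe")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.probe_ids)} probes, {len(self.sample_ids)} samples)"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("one label required per sample")
        bad = sorted(set(self.labels) - {"control", "case"})
        if bad:
            raise ValidationError(f"unknown cohort labels {bad}")
        self.labels = [str(x) for x in self.labels]

    def control_samples(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == "control"]

    def case_samples(self) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == "case"]
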