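"""Patient stratification from high-variability genes.

The top-variable genes' log2CPM values under HSS are z-scored per gene over
the PAH patients, turning each gene into a relative patient-to-patient
pattern.  Partitioning Around Medoids (PAM, classic BUILD + SWAP) groups
genes with similar patterns; each cluster is mapped to the patient in which
its members are, on average, most upregulated.  Cluster gene sets are then
tested for pathway over-representation, and each significantly enriched
pathway is scored per patient as the mean log2 fold change of its
contributing genes against the pooled control group — the per-patient
pathway "fingerprint".  The same pathway gene lists can finally be scored
in an external log2 expression cohort (probe-level microarray data) to
transfer the signature to clinically accessible material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ExternalCohortMatrix, ValidationError
from .enrichment import OraResult


@dataclass
class ZScoreMatrix:
    """Per-gene z-scores over patients; constant genes are zeroed and flagged."""

    gene_ids: list[str]
    patient_ids: list[str]
    z: np.ndarray
    constant_genes: frozenset[str] = frozenset()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.z, index=pd.Index(self.gene_ids, name="gene"),
            columns=self.patient_ids,
        )


def zscore_over_patients(
    E: ExpressionMatrix,
    genes: list[str],
    patient_samples: dict[str, str],
) -> ZScoreMatrix:
    """Z-score each gene's log2 expression across patients.

    ``patient_samples`` maps patient labels to the sample (one per patient,
    e.g. that patient's HSS channel) whose values are used.  Standard
    deviations use the n-1 denominator; a constant gene gets all-zero
    z-scores and is flagged rather than dropped.
    """
    if len(patient_samples) < 2:
        raise ValidationError("need >= 2 patients to z-score")
    missing = [g for g in genes if g not in set(E.gene_ids)]
    if missing:
        raise ValidationError(f"genes absent from expression matrix: {missing[:10]}")
    patients = list(patient_samples)
    sub = E.subset_genes(genes).subset_samples([patient_samples[p] for p in patients])
    X = sub.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    sd[const] = 1.0
    z = (X - mean) / sd
    z[const] = 0.0
    return ZScoreMatrix(
        list(genes), patients, z,
        frozenset(g for g, c in zip(genes, const) if c),
    )


@dataclass
class ClusterModel:
    """A PAM clustering of genes with its cluster -> patient correspondence."""

    k: int
    medoid_gene_ids: list[str]
    assignment: dict[str, int]  # gene -> cluster label (1-based)
    cost: float
    cluster_patient_map: dict[int, str]

    def cluster_genes(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.assignment.items() if c == cluster)

    def clusters(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "medoid_gene_ids": self.medoid_gene_ids,
            "assignment": self.assignment,
            "cost": self.cost,
            "cluster_patient_map": {str(k): v for k, v in
                                    self.cluster_patient_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            k=d["k"],
            medoid_gene_ids=list(d["medoid_gene_ids"]),
            assignment={g: int(c) for g, c in d["assignment"].items()},
            cost=float(d["cost"]),
            cluster_patient_map={int(k): v for k, v in
                                 d["cluster_patient_map"].items()},
        )


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: start from the 1-medoid optimum, then add the
    point that most reduces total cost; ties go to the lowest index."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(nearest - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)
        nearest = np.minimum(nearest, D[:, best_j])
    return medoids


def _pam_swap(
    D: np.ndarray, medoids: list[int], trace: list | None = None
) -> tuple[list[int], float]:
    """First-improvement SWAP scans in deterministic index order."""
    n = D.shape[0]
    medoids = sorted(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    if trace is not None:
        trace.append(float(cost))
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + medoids[mi + 1:] + [h]
                trial_cost = D[:, trial].min(axis=1).sum()
                if trial_cost < cost - 1e-12:
                    medoids = sorted(trial)
                    cost = trial_cost
                    if trace is not None:
                        trace.append(float(cost))
                    improved = True
                    break
            if improved:
                break
    return medoids, float(cost)


def pam(
    z: ZScoreMatrix,
    k: int = 4,
    distance: str = "euclidean",
    trace: list | None = None,
) -> ClusterModel:
    """Classic Partitioning Around Medoids on z-score gene profiles.

    BUILD seeds the medoids greedily; SWAP accepts the first
    medoid/non-medoid exchange that lowers total cost, scanning in
    deterministic gene order, until no exchange improves.  Genes are
    assigned to their nearest medoid (ties to the lowest medoid index),
    clusters are re-labeled 1..k by descending size, and each cluster is
    mapped to the patient with the highest mean z over its members.
    """
    X = np.asarray(z.z, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds the number of genes ({n})")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not np.all(np.isfinite(X)):
        raise ValidationError("z-scores must be finite")
    if distance == "euclidean":
        sq = np.sum(X**2, axis=1)
        D2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
        D = np.sqrt(np.maximum(D2, 0.0))
    elif distance == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(Xc, axis=1)
        norm[norm == 0] = 1.0
        D = 1.0 - (Xc @ Xc.T) / np.outer(norm, norm)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValidationError(f"unknown distance {distance!r}")

    medoids = _pam_build(D, k)
    medoids, cost = _pam_swap(D, medoids, trace=trace)
    labels_raw = np.argmin(D[:, medoids], axis=1)  # argmin takes lowest index on ties

    # relabel clusters 1..k by descending size, ties by medoid gene ID
    sizes = [(int(np.sum(labels_raw == i)), z.gene_ids[m], i)
             for i, m in enumerate(medoids)]
    order = sorted(sizes, key=lambda t: (-t[0], t[1]))
    relabel = {old: new + 1 for new, (_, _, old) in enumerate(order)}
    assignment = {g: relabel[int(l)] for g, l in zip(z.gene_ids, labels_raw)}
    medoid_genes = [z.gene_ids[medoids[old]] for (_, _, old) in order]

    cluster_patient_map: dict[int, str] = {}
    for cl in range(1, len(medoids) + 1):
        members = [i for i, g in enumerate(z.gene_ids) if assignment[g] == cl]
        mean_z = X[members].mean(axis=0)
        cluster_patient_map[cl] = z.patient_ids[int(np.argmax(mean_z))]

    return ClusterModel(
        k=k,
        medoid_gene_ids=medoid_genes,
        assignment=assignment,
        cost=cost,
        cluster_patient_map=cluster_patient_map,
    )


def brute_force_kmedoids(X: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exhaustive k-medoids optimum (test oracle for small instances)."""
    n = X.shape[0]
    sq = np.sum(X**2, axis=1)
    D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0))
    best, best_cost = None, np.inf
    for med in combinations(range(n), k):
        c = D[:, med].min(axis=1).sum()
        if c < best_cost - 1e-12:
            best, best_cost = list(med), c
    return best, float(best_cost)


@dataclass
class PathwayScoreTable:
    """Per (patient, pathway, cluster) mean log2FC vs the pooled controls."""

    table: pd.DataFrame  # columns patient, pathway, cluster, mean_log2fc,
    # n_genes, genes

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["genes"] = out["genes"].map(lambda gs: ";".join(gs))
        return out

    def score(self, patient: str, pathway: str) -> float:
        t = self.table
        row = t[(t["patient"] == patient) & (t["pathway"] == pathway)]
        if row.empty:
            raise KeyError((patient, pathway))
        return float(row["mean_log2fc"].iloc[0])

    def pathway_genes(self) -> dict[tuple[int, str], list[str]]:
        out: dict[tuple[int, str], list[str]] = {}
        for _, row in self.table.iterrows():
            out[(int(row["cluster"]), row["pathway"])] = list(row["genes"])
        return out


def score_patient_pathways(
    E: ExpressionMatrix,
    clusters: ClusterModel,
    ora_per_cluster: dict[int, list[OraResult]],
    control_samples: list[str],
    patient_samples: dict[str, str],
) -> PathwayScoreTable:
    """Mean log2FC of each enriched pathway's genes, patient vs pooled controls.

    For every pathway significant in a cluster's ORA, the contributing genes
    are the ORA overlap genes (pathway members inside the cluster); a
    patient's score is the mean over those genes of (patient log2 value -
    mean control log2 value).  Pathways with fewer than three contributing
    genes are excluded, consistent with the ORA significance rule.
    """
    if not control_samples:
        raise ValidationError("need control samples to score against")
    ctrl = E.subset_samples(control_samples)
    ctrl_mean = pd.Series(ctrl.values.mean(axis=1), index=ctrl.gene_ids)
    rows = []
    for cl in sorted(ora_per_cluster):
        for ora in ora_per_cluster[cl]:
            for pathway in ora.significant_pathways():
                genes = [g for g in ora.overlap_genes(pathway) if g in ctrl_mean.index]
                if len(genes) < 3:
                    continue
                for patient, sample in patient_samples.items():
                    pat = E.subset_genes(genes).subset_samples([sample]).values[:, 0]
                    diffs = pat - ctrl_mean[genes].to_numpy()
                    rows.append(
                        {
                            "patient": patient,
                            "pathway": pathway,
                            "cluster": cl,
                            "source": ora.source,
                            "mean_log2fc": float(np.mean(diffs)),
                            "n_genes": len(genes),
                            "genes": sorted(genes),
                        }
                    )
    table = pd.DataFrame(
        rows, columns=["patient", "pathway", "cluster", "source",
                       "mean_log2fc", "n_genes", "genes"],
    )
    return PathwayScoreTable(table)


def collapse_probes(
    X: ExternalCohortMatrix, criterion: str = "mean"
) -> pd.DataFrame:
    """Collapse probes to genes, keeping the highest-expressed probe.

    Unannotated probes (empty gene ID) are dropped.  ``criterion`` picks
    the probe with the highest mean expression across all samples
    ("mean", default) or the highest single value ("max").
    """
    if criterion not in ("mean", "max"):
        raise ValidationError("criterion must be 'mean' or 'max'")
    df = pd.DataFrame(
        X.values, index=pd.Index(X.probe_ids, name="probe"), columns=X.sample_ids
    )
    genes = pd.Series(X.gene_ids, index=df.index)
    annotated = genes != ""
    df, genes = df[annotated], genes[annotated]
    stat = df.mean(axis=1) if criterion == "mean" else df.max(axis=1)
    # stable, deterministic winner: highest stat, ties by probe ID
    order = pd.DataFrame({"gene": genes, "stat": stat}).sort_values(
        ["gene", "stat", "probe"], ascending=[True, False, True],
        kind="mergesort",
    )
    winners = order.groupby("gene", sort=True).head(1).index
    out = df.loc[winners]
    out.index = pd.Index(genes[winners], name="gene")
    return out


@dataclass
class TransferResult:
    scores: PathwayScoreTable
    coverage: dict[str, dict]  # pathway -> {n_source, n_found, missing}
    excluded_pathways: list[str]


def transfer_to_cohort(
    X: ExternalCohortMatrix,
    pathway_genes: dict[tuple[int, str], list[str]],
    collapse_criterion: str = "mean",
) -> TransferResult:
    """Score the cluster pathway signatures in an external log2 cohort.

    Probes are collapsed per gene; genes absent from the cohort are dropped
    with a coverage report; each case sample is scored per pathway as the
    mean over available genes of (case log2 value - mean control log2
    value).  Pathways losing all genes after mapping are excluded.
    """
    expr = collapse_probes(X, criterion=collapse_criterion)
    controls = X.control_samples()
    cases = X.case_samples()
    if not controls or not cases:
        raise ValidationError("cohort needs both control and case samples")
    ctrl_mean = expr[controls].mean(axis=1)
    rows = []
    coverage: dict[str, dict] = {}
    excluded: list[str] = []
    for (cl, pathway), genes in sorted(pathway_genes.items()):
        found = [g for g in genes if g in expr.index]
        coverage[pathway] = {
            "n_source": len(genes),
            "n_found": len(found),
            "missing": sorted(set(genes) - set(found)),
        }
        if not found:
            excluded.append(pathway)
            continue
        diffs = expr.loc[found, cases].to_numpy() - ctrl_mean[found].to_numpy()[:, None]
        means = diffs.mean(axis=0)
        for sample, val in zip(cases, means):
            rows.append(
                {
                    "patient": sample,
                    "pathway": pathway,
                    "cluster": cl,
                    "source": "external",
                    "mean_log2fc": float(val),
                    "n_genes": len(found),
                    "genes": sorted(found),
                }
            )
    table = pd.DataFrame(
        rows, columns=["patient", "pathway", "cluster", "source",
                       "mean_log2fc", "n_genes", "genes"],
    )
    return TransferResult(PathwayScoreTable(table), coverage, excluded)
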