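"""Synthetic count data with the structure the analysis assumes.

The generator emulates the study design — two disease groups (control, PAH)
of four donors each, one channel per donor per flow condition (Static, LSS,
HSS) — as negative-binomial counts (Var = mu + dispersion * mu^2) around
log-normal gene baselines, with three planted layers of structure:

* a shared shear response: a fraction of genes shift expression under flow,
  with a condition-dependent log2 effect and a random sign, identically in
  both groups (flow responses are conserved across groups);
* PAH-specific variance inflation: a set of genes receives an independent
  per-PAH-donor random effect only under HSS, creating high ddCV without a
  consistent direction;
* patient-specific blocks: each block of genes is upregulated by a fixed
  log2 effect in exactly one PAH donor under HSS, creating the clusterable
  patient signatures.

Donor baseline offsets are drawn once per donor and shared across that
donor's three channels, emulating the repeated-measures structure that the
grouped differential-expression contrasts deliberately ignore.

A companion generator produces an external probe-level log2 cohort whose
case samples carry attenuated versions of the same planted blocks, for
exercising signature transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    ExternalCohortMatrix,
    GeneSetCollection,
    SampleAnnotation,
    ValidationError,
)

CONDITION_ORDER = ("Static", "LSS", "HSS")


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults reflect the study layout (2 groups x 4 donors x 3 conditions)
    at a reduced gene count, with sequencing depth chosen to keep per-gene
    counts in the range typical of bulk RNA-seq (~1000 reads per gene on
    average).  Planted gene sets are mutually disjoint.
    """

    n_genes: int = 2000
    donors_per_group: int = 4
    conditions: tuple[str, ...] = CONDITION_ORDER
    baseline_log2_mean: tuple[float, float] = (4.0, 1.0)  # (mu, sigma), log2
    nb_dispersion: float = 0.01
    donor_sd: float = 0.1  # log2, shared across a donor's channels
    shear_response: tuple[float, dict] = field(
        default_factory=lambda: (0.10, {"LSS": 1.0, "HSS": 2.0})
    )
    planted_variable: tuple[int, float] = (200, 2.5)  # (n genes, log2 SD)
    planted_blocks: tuple[tuple[int, int, float], ...] = (
        (0, 40, 2.0), (1, 40, 2.0), (2, 40, 2.0), (3, 40, 2.0),
    )  # (PAH patient index, n genes, log2 effect)
    library_size_range: tuple[float, float] = (1.8e6, 2.2e6)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.donors_per_group < 1:
            raise ValidationError("n_genes and donors_per_group must be >= 1")
        frac, effects = self.shear_response
        if not 0 <= frac <= 1:
            raise ValidationError("shear fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        unknown = set(effects) - set(self.conditions)
        if unknown:
            raise ValidationError(f"shear effects for unknown conditions {unknown}")
        n_pv, pv_sd = self.planted_variable
        if n_pv < 0 or pv_sd < 0:
            raise ValidationError("planted_variable must be non-negative")
        n_block = sum(b[1] for b in self.planted_blocks)
        for idx, nb, eff in self.planted_blocks:
            if not 0 <= idx < self.donors_per_group:
                raise ValidationError(f"block patient index {idx} out of range")
            if nb < 0:
                raise ValidationError("block sizes must be non-negative")
        n_shear = int(round(frac * self.n_genes))
        if n_block + n_pv + n_shear > self.n_genes:
            raise ValidationError(
                "planted gene sets (blocks + variable + shear) exceed n_genes"
            )
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValidationError("library_size_range must satisfy 0 < lo <= hi")


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate(cfg: SimConfig) -> tuple[CountMatrix, SampleAnnotation, dict]:
    """Draw one synthetic dataset; deterministic under ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes = _gene_names(n)

    donors = [f"CTR{i + 1:02d}" for i in range(cfg.donors_per_group)] + [
        f"PAH{i + 1:02d}" for i in range(cfg.donors_per_group)
    ]
    groups = ["control"] * cfg.donors_per_group + ["PAH"] * cfg.donors_per_group
    rows = []
    for donor, group in zip(donors, groups):
        for cond in cfg.conditions:
            rows.append(
                {"sample_id": f"{donor}_{cond}", "donor_id": donor,
                 "group": group, "condition": cond}
            )
    ann = SampleAnnotation(pd.DataFrame(rows))
    samples = ann.sample_ids

    # disjoint planted gene allocations: blocks, then variable, then shear
    cursor = 0
    block_truth = []
    for idx, nb, eff in cfg.planted_blocks:
        block_truth.append(
            {"patient": f"PAH{idx + 1:02d}",
             "genes": genes[cursor:cursor + nb], "log2_effect": float(eff)}
        )
        cursor += nb
    n_pv, pv_sd = cfg.planted_variable
    pv_genes = genes[cursor:cursor + n_pv]
    cursor += n_pv
    frac, shear_effects = cfg.shear_response
    n_shear = int(round(frac * n))
    shear_genes = genes[cursor:cursor + n_shear]
    shear_slice = slice(cursor, cursor + n_shear)

    base = rng.normal(cfg.baseline_log2_mean[0], cfg.baseline_log2_mean[1], n)
    shear_sign = rng.choice([-1.0, 1.0], size=n_shear)
    donor_eff = {d: rng.normal(0.0, cfg.donor_sd) for d in donors}
    pv_eff = {
        d: rng.normal(0.0, pv_sd, n_pv)
        for d, g in zip(donors, groups) if g == "PAH"
    }

    # draw library-size targets from the interior of the admissible range so
    # realized totals (NB noise ~1-2% relative SD) stay inside it
    lo, hi = cfg.library_size_range
    margin = 0.15 * (hi - lo)
    lib_targets = rng.uniform(lo + margin, hi - margin, len(samples))

    counts = np.empty((n, len(samples)), dtype=np.int64)
    pv_index = {g: i for i, g in enumerate(pv_genes)}
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, sid in enumerate(samples):
        donor = ann.donor_of(sid)
        group = ann.group_of(sid)
        cond = sid.rsplit("_", 1)[1]
        log2q = base.copy()
        log2q += donor_eff[donor]
        eff = float(shear_effects.get(cond, 0.0))
        if n_shear and eff:
            log2q[shear_slice] += shear_sign * eff
        if group == "PAH" and cond == "HSS":
            if n_pv:
                for g, i in pv_index.items():
                    log2q[gene_index[g]] += pv_eff[donor][i]
            for block in block_truth:
                if block["patient"] == donor:
                    for g in block["genes"]:
                        log2q[gene_index[g]] += block["log2_effect"]
        q = np.exp2(log2q)
        mu = lib_targets[j] * q / q.sum()
        lam = rng.gamma(1.0 / cfg.nb_dispersion, mu * cfg.nb_dispersion)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(genes, samples, counts)
    truth = {
        "shear_genes": shear_genes,
        "shear_signs": {g: float(s) for g, s in zip(shear_genes, shear_sign)},
        "planted_variable_genes": pv_genes,
        "planted_variable_sd": float(pv_sd),
        "blocks": block_truth,
        "seed": cfg.seed,
    }
    return cm, ann, truth


def block_gene_sets(
    truth: dict,
    all_genes: Sequence[str],
    n_decoys: int = 10,
    decoy_size: int = 30,
    seed: int = 0,
) -> GeneSetCollection:
    """A toy gene-set collection whose pathways align with planted blocks,
    plus random decoy pathways drawn from the full gene list."""
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset[str]] = {}
    for block in truth["blocks"]:
        if block["genes"]:
            sets[f"BLOCK_{block['patient']}_SIGNATURE"] = frozenset(block["genes"])
    pool = list(all_genes)
    for i in range(n_decoys):
        members = rng.choice(pool, size=min(decoy_size, len(pool)), replace=False)
        sets[f"DECOY_{i + 1:02d}"] = frozenset(members.tolist())
    return GeneSetCollection("synthetic", sets)


def simulate_external_cohort(
    truth: dict,
    n_control: int = 41,
    n_cases: int = 30,
    attenuation: float = 0.5,
    noise_sd: float = 0.5,
    baseline_log2: tuple[float, float] = (8.0, 1.0),
    duplicate_frac: float = 0.2,
    n_unannotated: int = 10,
    seed: int = 0,
) -> tuple[ExternalCohortMatrix, dict[str, str]]:
    """A synthetic probe-level log2 cohort carrying attenuated block effects.

    Each case sample mimics one planted source patient (cycled), with that
    patient's block genes shifted by ``attenuation`` times the source log2
    effect.  A fraction of genes get a duplicate, dimmer probe, and a few
    probes are left unannotated, exercising the probe-collapse rules.
    Returns the cohort and the case-sample -> source-patient map.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(
        {g for b in truth["blocks"] for g in b["genes"]}
        | set(truth.get("planted_variable_genes", []))
    )
    if not genes:
        raise ValidationError("truth record contains no planted genes")
    block_of = {}
    for b in truth["blocks"]:
        for g in b["genes"]:
            block_of[g] = (b["patient"], b["log2_effect"])
    patients = [b["patient"] for b in truth["blocks"] if b["genes"]]

    base = rng.normal(baseline_log2[0], baseline_log2[1], len(genes))
    control_ids = [f"EXT_CTRL{i + 1:03d}" for i in range(n_control)]
    case_ids = [f"EXT_CASE{i + 1:03d}" for i in range(n_cases)]
    case_patient = {
        cid: patients[i % len(patients)] for i, cid in enumerate(case_ids)
    }
    samples = control_ids + case_ids
    values = np.empty((len(genes), len(samples)))
    for j, sid in enumerate(samples):
        v = base + rng.normal(0.0, noise_sd, len(genes))
        if sid in case_patient:
            mimic = case_patient[sid]
            for i, g in enumerate(genes):
                if g in block_of and block_of[g][0] == mimic:
                    v[i] += attenuation * block_of[g][1]
        values[:, j] = v

    probes = [f"P_{g}" for g in genes]
    gene_ids = list(genes)
    # duplicate, dimmer probes for a subset of genes
    n_dup = int(round(duplicate_frac * len(genes)))
    dup_idx = rng.choice(len(genes), size=n_dup, replace=False)
    for i in sorted(dup_idx):
        probes.append(f"P_{genes[i]}_alt")
        gene_ids.append(genes[i])
        values = np.vstack([values, values[i] - abs(rng.normal(1.0, 0.2))])
    for u in range(n_unannotated):
        probes.append(f"P_UNKNOWN_{u + 1:02d}")
        gene_ids.append("")
        values = np.vstack(
            [values, rng.normal(baseline_log2[0], baseline_log2[1], len(samples))[None]]
        )
    labels = ["control"] * n_control + ["case"] * n_cases
    cohort = ExternalCohortMatrix(probes, gene_ids, samples, values, labels)
    return cohort, case_patient


def write_synthetic_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Write counts TSV, sample sheet, truth JSON and a matching toy GMT."""
    from .io import write_counts, write_gmt, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, ann, truth = simulate(cfg)
    paths = {
        "counts": str(outdir / "counts.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "truth": str(outdir / "truth.json"),
        "gmt": str(outdir / "synthetic_blocks.gmt"),
    }
    write_counts(cm, paths["counts"])
    write_sample_sheet(ann, paths["samples"])
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    write_gmt(
        block_gene_sets(truth, cm.gene_ids, seed=cfg.seed), paths["gmt"]
    )
    return paths
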