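"""Z-scoring, PAM clustering, patient pathway scores, cohort transfer."""

import numpy as np
import pandas as pd
import pytest

from shearsig.datatypes import (
    ExpressionMatrix,
    ExternalCohortMatrix,
    GeneSetCollection,
    ValidationError,
)
from shearsig.enrichment import run_ora
from shearsig.stratify import (
    ClusterModel,
    ZScoreMatrix,
    brute_force_kmedoids,
    collapse_probes,
    pam,
    score_patient_pathways,
    transfer_to_cohort,
    zscore_over_patients,
)


def _expr(values, genes=None, samples=None, scale="log2cpm"):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, scale)


class TestZScore:
    def test_rows_have_zero_mean_unit_sd(self):
        E = _expr([[1, 2, 3, 4], [5, 1, 9, 2]])
        z = zscore_over_patients(E, ["g0", "g1"],
                                 {f"p{j}": f"s{j}" for j in range(4)})
        np.testing.assert_allclose(z.z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_two_patient_hand_case(self):
        E = _expr([[10.0, 20.0]])
        z = zscore_over_patients(E, ["g0"], {"p1": "s0", "p2": "s1"})
        np.testing.assert_allclose(z.z[0], [-0.70710678, 0.70710678], atol=1e-6)

    def test_constant_row_zeroed_and_flagged(self):
        E = _expr([[3, 3, 3], [1, 2, 4]])
        z = zscore_over_patients(E, ["g0", "g1"],
                                 {"a": "s0", "b": "s1", "c": "s2"})
        np.testing.assert_array_equal(z.z[0], 0.0)
        assert z.constant_genes == frozenset({"g0"})

    def test_missing_gene_listed(self):
        E = _expr([[1, 2]])
        with pytest.raises(ValidationError, match="gX"):
            zscore_over_patients(E, ["gX"], {"a": "s0", "b": "s1"})


class TestPam:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(0)
        z = ZScoreMatrix([f"g{i}" for i in range(5)], ["a", "b"],
                         rng.normal(size=(5, 2)))
        model = pam(z, k=5)
        assert model.cost == 0.0
        assert sorted(model.medoid_gene_ids) == sorted(z.gene_ids)

    def test_two_separated_blobs_found_optimally(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.3, (4, 2)),
                         rng.normal(8, 0.3, (4, 2))])
        z = ZScoreMatrix([f"g{i}" for i in range(8)], ["a", "b"], pts)
        model = pam(z, k=2)
        labels = [model.assignment[f"g{i}"] for i in range(8)]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        _, best_cost = brute_force_kmedoids(pts, 2)
        assert model.cost == pytest.approx(best_cost, rel=1e-12)

    def test_swap_cost_non_increasing(self):
        rng = np.random.default_rng(2)
        z = ZScoreMatrix([f"g{i}" for i in range(40)], ["a", "b", "c"],
                         rng.normal(size=(40, 3)))
        trace: list = []
        pam(z, k=4, trace=trace)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_one_hot_blocks_give_bijective_patient_map(self):
        patients = ["PAH01", "PAH02", "PAH03", "PAH04"]
        rows, genes = [], []
        rng = np.random.default_rng(3)
        for b in range(4):
            for i in range(6):
                v = np.full(4, -0.5) + rng.normal(0, 0.05, 4)
                v[b] = 1.5 + rng.normal(0, 0.05)
                rows.append(v)
                genes.append(f"b{b}_g{i}")
        z = ZScoreMatrix(genes, patients, np.array(rows))
        model = pam(z, k=4)
        assert sorted(model.cluster_patient_map.values()) == patients

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        z = ZScoreMatrix([f"g{i}" for i in range(30)], list("abcd"), X)
        m1, m2 = pam(z, k=3), pam(z, k=3)
        assert m1.assignment == m2.assignment and m1.cost == m2.cost

    def test_k_larger_than_n_rejected(self):
        z = ZScoreMatrix(["g0"], ["a", "b"], np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            pam(z, k=2)

    def test_medoids_belong_to_their_clusters(self):
        rng = np.random.default_rng(5)
        z = ZScoreMatrix([f"g{i}" for i in range(25)], list("abcd"),
                         rng.normal(size=(25, 4)))
        model = pam(z, k=3)
        for cl, medoid in zip(sorted(model.clusters()), model.medoid_gene_ids):
            assert model.assignment[medoid] == cl

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        z = ZScoreMatrix([f"g{i}" for i in range(12)], list("abcd"),
                         rng.normal(size=(12, 4)))
        model = pam(z, k=2)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ClusterModel.from_json(p)
        assert back.assignment == model.assignment
        assert back.cluster_patient_map == model.cluster_patient_map
        assert back.cost == pytest.approx(model.cost)


def _score_setup():
    """Four patients, four controls; one pathway of 3 genes shifted by
    +[1,2,3] in patient p1 only."""
    genes = [f"g{i}" for i in range(6)]
    samples = [f"ctl{j}" for j in range(4)] + [f"pat{j}" for j in range(4)]
    base = np.full((6, 8), 5.0)
    base[0, 4] += 1.0
    base[1, 4] += 2.0
    base[2, 4] += 3.0
    E = ExpressionMatrix(genes, samples, base, "log2cpm")
    model = ClusterModel(
        k=1, medoid_gene_ids=["g0"],
        assignment={g: 1 for g in genes[:3]},
        cost=0.0, cluster_patient_map={1: "p1"},
    )
    coll = GeneSetCollection("toy", {"PW": frozenset(genes[:3])})
    ora = run_ora(genes[:3], genes, coll, alpha=1.0, min_overlap=3)
    patient_samples = {f"p{j + 1}": f"pat{j}" for j in range(4)}
    return E, model, {1: [ora]}, samples[:4], patient_samples


class TestScorePatientPathways:
    def test_mean_of_diffs(self):
        E, model, ora, controls, patients = _score_setup()
        scores = score_patient_pathways(E, model, ora, controls, patients)
        assert scores.score("p1", "PW") == pytest.approx(2.0)

    def test_patient_equal_to_control_mean_scores_zero(self):
        E, model, ora, controls, patients = _score_setup()
        scores = score_patient_pathways(E, model, ora, controls, patients)
        for p in ("p2", "p3", "p4"):
            assert scores.score(p, "PW") == pytest.approx(0.0)

    def test_small_pathways_excluded(self):
        E, model, _, controls, patients = _score_setup()
        coll = GeneSetCollection("toy", {"TINY": frozenset(["g0", "g1"])})
        ora = run_ora(["g0", "g1"], E.gene_ids, coll, alpha=1.0, min_overlap=1)
        scores = score_patient_pathways(E, model, {1: [ora]}, controls, patients)
        assert scores.table.empty


def _cohort(values, probes, genes, n_control=2):
    samples = [f"s{j}" for j in range(values.shape[1])]
    labels = ["control"] * n_control + ["case"] * (len(samples) - n_control)
    return ExternalCohortMatrix(probes, genes, samples, values, labels)


class TestTransfer:
    def test_single_probe_collapse_is_identity(self):
        x = _cohort(np.array([[8.0, 9.0, 7.0]]), ["p1"], ["GENE"], n_control=2)
        out = collapse_probes(x)
        assert list(out.index) == ["GENE"]
        np.testing.assert_allclose(out.iloc[0], [8.0, 9.0, 7.0])

    def test_highest_mean_probe_kept(self):
        vals = np.array([[8.0, 8.0], [10.0, 10.0]])
        x = _cohort(vals, ["pA", "pB"], ["G", "G"], n_control=1)
        out = collapse_probes(x, criterion="mean")
        np.testing.assert_allclose(out.loc["G"], [10.0, 10.0])

    def test_max_criterion_differs_when_single_spike(self):
        # probe A has the higher single value, probe B the higher mean
        vals = np.array([[12.0, 1.0], [8.0, 8.0]])
        x = _cohort(vals, ["pA", "pB"], ["G", "G"], n_control=1)
        assert collapse_probes(x, "max").loc["G"].tolist() == [12.0, 1.0]
        assert collapse_probes(x, "mean").loc["G"].tolist() == [8.0, 8.0]

    def test_unannotated_probes_dropped(self):
        vals = np.array([[5.0, 5.0], [6.0, 6.0]])
        x = _cohort(vals, ["pA", "pB"], ["G", ""], n_control=1)
        assert list(collapse_probes(x).index) == ["G"]

    def test_control_scores_centered_at_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(5)]
        vals = rng.normal(8, 1, (5, 6))
        x = _cohort(vals, [f"p{i}" for i in range(5)], genes, n_control=6 - 2)
        res = transfer_to_cohort(x, {(1, "PW"): genes})
        # pooled mean of per-control scores vs control mean is exactly zero
        ctrl_scores = vals[:, :4].mean(axis=1, keepdims=True) - \
            vals[:, :4].mean(axis=1, keepdims=True)
        assert np.allclose(ctrl_scores, 0.0)
        case_scores = res.scores.table["mean_log2fc"]
        assert len(case_scores) == 2

    def test_relative_patterns_preserved_under_transfer(self):
        """Attenuated planted blocks in an external cohort reproduce the
        source patients' pathway-score rankings (Spearman rho > 0.8).

        Pathways span several patient blocks with different weights, the
        way real gene sets straddle clusters, so each (patient, pathway)
        score carries a graded signal whose ranking the transfer must
        preserve — a one-hot pattern would leave most cells as pure noise
        and no ranking to test.
        """
        from scipy.stats import spearmanr

        from shearsig.datatypes import GeneSetCollection
        from shearsig.enrichment import run_ora
        from shearsig.preprocess import cpm, filter_genes, log2cpm
        from shearsig.simulate import SimConfig, simulate, simulate_external_cohort
        from shearsig.variability import select_top_variable, variability_table

        cm, ann, truth = simulate(SimConfig(planted_variable=(0, 0.0), seed=11))
        filtered, _ = filter_genes(cm)
        vt = variability_table(cpm(filtered), ann, counts=filtered)
        top = select_top_variable(vt, 50.0)
        E = log2cpm(filtered)
        donors = ["PAH01", "PAH02", "PAH03", "PAH04"]
        patient_samples = {d: f"{d}_HSS" for d in donors}
        blocks = truth["blocks"]
        coll = GeneSetCollection("composite", {
            f"PW{i + 1}": frozenset(
                blocks[i]["genes"][:20]
                + blocks[(i + 1) % 4]["genes"][:12]
                + blocks[(i + 2) % 4]["genes"][:8]
            )
            for i in range(4)
        })
        background = list(filtered.gene_ids)
        block_genes = sorted(
            {g for b in blocks for g in b["genes"]} & set(background)
        )
        model = ClusterModel(
            k=1, medoid_gene_ids=[block_genes[0]],
            assignment={g: 1 for g in block_genes}, cost=0.0,
            cluster_patient_map={1: donors[0]},
        )
        ora = run_ora(block_genes, background, coll)
        controls = [f"CTR{i:02d}_HSS" for i in range(1, 5)]
        source = score_patient_pathways(E, model, {1: [ora]}, controls,
                                        patient_samples)
        assert set(source.table["pathway"]) == {"PW1", "PW2", "PW3", "PW4"}
        cohort, case_map = simulate_external_cohort(
            truth, n_control=20, n_cases=16, attenuation=0.5, noise_sd=0.3,
            seed=12,
        )
        transferred = transfer_to_cohort(cohort, source.pathway_genes())
        src_vec, ext_vec = [], []
        t = transferred.scores.table
        for pw in ("PW1", "PW2", "PW3", "PW4"):
            for d in donors:
                src_vec.append(source.score(d, pw))
                cases = [c for c, p in case_map.items() if p == d]
                vals = t.loc[(t["pathway"] == pw)
                             & (t["patient"].isin(cases)), "mean_log2fc"]
                ext_vec.append(float(vals.mean()))
        rho = spearmanr(src_vec, ext_vec).statistic
        assert rho > 0.8, rho
        # the attenuated external effect sizes track the source's
        diag_src = [src_vec[i * 4 + i] for i in range(4)]
        diag_ext = [ext_vec[i * 4 + i] for i in range(4)]
        assert np.all(np.array(diag_ext) > 0.3)
        assert np.all(np.array(diag_ext) < np.array(diag_src))

    def test_pathway_losing_all_genes_excluded(self):
        vals = np.array([[8.0, 9.0, 7.0]])
        x = _cohort(vals, ["p1"], ["G"], n_control=2)
        res = transfer_to_cohort(x, {(1, "GONE"): ["ZZZ"], (1, "OK"): ["G"]})
        assert res.excluded_pathways == ["GONE"]
        assert res.coverage["GONE"]["n_found"] == 0
        assert set(res.scores.table["pathway"]) == {"OK"}
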