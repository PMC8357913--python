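import math

import numpy as np
import pandas as pd
import pytest

from proxiquant import (ProteinMatrix, SimParams, annotation_enrichment,
                        design_two_group, filter_psms, merge_transcript_degs,
                        partition_quantifiable, proteogenomic_correlation,
                        qc_cv, qc_mds, qc_replicate_correlation,
                        reference_normalize, simulate_experiment, stratified_de,
                        summarize_proteins)
from proxiquant.downstream import read_gmt
from proxiquant.errors import ParameterError, ValidationError

from conftest import make_design
from oracles import oracle_hypergeom_upper, oracle_pearson


def pm_from(values, samples):
    df = pd.DataFrame(values, columns=samples,
                      index=[f"P{i}" for i in range(len(values))])
    return ProteinMatrix(values=df, psm_support=pd.DataFrame(
        1, index=df.index, columns=["run1"]))


class TestStratifiedDe:
    def _null_run(self, seed, alpha_rule, refnorm=True, batch_sd=0.5,
                  n_runs=2, channel_sd=0.1):
        design = design_two_group(n_per_group=4, n_runs=n_runs)
        params = SimParams(n_proteins=300, seed=seed, enrichment_scale_log2=0.0,
                           frac_background_binders=0.0,
                           frac_endogenous_biotin=0.0, batch_sd_log2=batch_sd,
                           channel_sd_log2=channel_sd)
        frame, truth = simulate_experiment(params, design)
        filt = filter_psms(frame)
        part = partition_quantifiable(filt)
        pm = summarize_proteins(filt, design, proteins=part.quantifiable)
        if refnorm:
            pm = reference_normalize(pm, design)
        strata = pd.DataFrame({"accession": pm.proteins,
                               "compartment": ["nucleus"] * len(pm.proteins)})
        tabs = stratified_de(pm, design, strata, ("A", "B"),
                             alpha_rule=alpha_rule)
        return tabs["nucleus"]

    def test_q_rule_flags_nothing_in_most_null_simulations(self):
        zero_flag = sum(
            int(self._null_run(800 + s, "q")["significant"].sum() == 0)
            for s in range(30))
        # global-null BH: >= 95% of runs flag nothing (3-sigma binomial slack)
        assert zero_flag >= 26

    def test_p_rule_type_one_error_close_to_alpha(self):
        """On a single-run null (no between-plex structure) the pooled
        moderated t is calibrated, so the p-rule flags ~ alpha."""
        fracs = [self._null_run(900 + s, "p", refnorm=False, batch_sd=0.0,
                                n_runs=1, channel_sd=0.0)["significant"].mean()
                 for s in range(15)]
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)

    def test_p_rule_conservative_on_multi_run_data(self):
        """With two plexes, run-shared error components (reference-channel
        noise, run-specific retained-peptide sets) inflate within-group
        variance but cancel out of run-balanced contrasts, so the realised
        type-I rate sits at or below alpha — never above."""
        fracs = [self._null_run(950 + s, "p")["significant"].mean()
                 for s in range(10)]
        assert np.mean(fracs) <= 0.05 + 0.01

    def test_invalid_rule_rejected(self):
        with pytest.raises(ParameterError, match="alpha_rule"):
            stratified_de(pm_from([[1.0]], ["s1"]),
                          make_design([("run1", "126", "s1", "A", 1, False)]),
                          pd.DataFrame({"accession": ["P0"],
                                        "compartment": ["nucleus"]}),
                          ("A", "B"), alpha_rule="z")

    def test_empty_stratum_yields_empty_table(self):
        design = design_two_group(n_per_group=4)
        params = SimParams(n_proteins=30, seed=44)
        frame, _ = simulate_experiment(params, design)
        filt = filter_psms(frame)
        pm = summarize_proteins(filt, design)
        strata = pd.DataFrame({"accession": ["NOT_PRESENT"],
                               "compartment": ["membrane"]})
        with pytest.warns(UserWarning, match="no quantified"):
            tabs = stratified_de(pm, design, strata, ("A", "B"))
        assert tabs["membrane"].empty


class TestMergeTranscriptDegs:
    def _src(self, rows, source):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "adj_p"]).assign(
            source=source)

    def test_threshold_rule(self):
        out = merge_transcript_degs([self._src(
            [("Drd1", 1.5, 0.01), ("Pde10a", 0.5, 0.01), ("Adora2a", -1.8, 0.001),
             ("Gapdh", 2.0, 0.2)], "trapseq")])
        assert set(out["gene"]) == {"Drd1", "Adora2a"}

    def test_cluster_label_source_included_without_test(self):
        clus = pd.DataFrame({"gene": ["Tac1"], "log2fc": [1.2],
                             "adj_p": [np.nan], "source": "scrnaseq_cluster"})
        out = merge_transcript_degs([clus])
        assert list(out["gene"]) == ["Tac1"]

    def test_deduplication_keeps_both_source_tags(self):
        out = merge_transcript_degs([
            self._src([("Drd1", 1.5, 0.01)], "trapseq"),
            self._src([("Drd1", 2.5, 0.001)], "scrnaseq")])
        assert len(out) == 1
        assert out.loc[0, "sources"] == "scrnaseq,trapseq"
        assert not out.loc[0, "direction_conflict"]

    def test_conflicting_directions_flagged(self):
        out = merge_transcript_degs([
            self._src([("Gng7", 1.5, 0.01)], "a"),
            self._src([("Gng7", -1.5, 0.01)], "b")])
        assert bool(out.loc[0, "direction_conflict"])

    def test_accession_mapping_reports_unmapped(self):
        mapping = pd.DataFrame({"gene": ["Drd1"], "accession": ["P11111"]})
        out = merge_transcript_degs([self._src(
            [("Drd1", 1.5, 0.01), ("Adora2a", -1.8, 0.001)], "x")],
            mapping=mapping).set_index("gene")
        assert out.loc["Drd1", "accession"] == "P11111"
        assert pd.isna(out.loc["Adora2a", "accession"])


class TestProteogenomicCorrelation:
    def test_identical_vectors(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, p, n = proteogenomic_correlation(s, s)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_exact_negation(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        r, _, _ = proteogenomic_correlation(s, -s)
        assert r == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_oracle(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([1.1, 1.9, 3.2, 3.8], index=list("abcd"))
        r, _, _ = proteogenomic_correlation(x, y)
        assert abs(r - oracle_pearson(list(x), list(y))) < 1e-12

    def test_intersection_and_minimum_n(self):
        x = pd.Series([1.0, 2, 3], index=list("abc"))
        y = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValidationError, match=">= 3"):
            proteogenomic_correlation(x, y)


class TestAnnotationEnrichment:
    def test_foreground_equal_background_is_null(self):
        bg = {f"P{i}" for i in range(50)}
        sets = {"T1": {"description": "", "members": {f"P{i}" for i in range(20)}}}
        out = annotation_enrichment(bg, bg, sets)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_term(self):
        bg = {f"P{i}" for i in range(50)}
        fg = {f"P{i}" for i in range(10)}
        sets = {"T1": {"description": "", "members": {f"P{i}" for i in range(30, 40)}}}
        out = annotation_enrichment(fg, bg, sets)
        assert out.loc[0, "fold_enrichment"] == 0.0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_sum(self):
        bg = {f"P{i}" for i in range(100)}
        term = {f"P{i}" for i in range(20)}
        fg = {f"P{i}" for i in range(8)} | {f"P{i}" for i in range(60, 62)}
        out = annotation_enrichment(fg, bg, {"T": {"description": "",
                                                   "members": term}})
        assert out.loc[0, "overlap"] == 8
        assert out.loc[0, "fold_enrichment"] == pytest.approx(4.0)
        assert out.loc[0, "p"] == pytest.approx(
            oracle_hypergeom_upper(8, 100, 20, 10), rel=1e-10)

    def test_p_values_exactly_valid_under_random_foreground(self):
        """P(p <= p_k) equals p_k at every achievable cutoff (the discrete
        analogue of uniformity; sub-uniform in between)."""
        rng = np.random.default_rng(55)
        bg = [f"P{i}" for i in range(200)]
        term = {"T": {"description": "", "members": set(bg[:50])}}
        ps = []
        for _ in range(1000):
            fg = rng.choice(bg, size=30, replace=False)
            ps.append(annotation_enrichment(fg, bg, term).loc[0, "p"])
        ps = np.array(ps)
        from scipy import stats
        for k in (6, 9, 12):
            cut = float(stats.hypergeom.sf(k - 1, 200, 50, 30))
            freq = (ps <= cut + 1e-12).mean()
            se = math.sqrt(cut * (1 - cut) / len(ps))
            assert abs(freq - cut) < 4 * se + 1e-9

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValidationError, match="subset"):
            annotation_enrichment({"X"}, {"P1"}, {})
        with pytest.raises(ValidationError, match="empty"):
            annotation_enrichment(set(), {"P1"}, {})

    def test_read_gmt(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:1\tnucleus\tP1\tP2\nGO:2\tmembrane\tP3\n")
        sets = read_gmt(path)
        assert sets["GO:1"]["members"] == {"P1", "P2"}
        assert sets["GO:2"]["description"] == "membrane"


class TestQcMds:
    def _matrix(self, n=600, s=6, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(10, 2, (n, 1))
        vals = base + rng.normal(0, 0.3, (n, s))
        return pm_from(vals, [f"s{i}" for i in range(s)])

    def test_duplicated_samples_have_zero_distance(self):
        pm = self._matrix()
        pm.values["s1"] = pm.values["s0"]
        coords = qc_mds(pm, top_n=100)
        assert np.allclose(coords.loc["s0"], coords.loc["s1"], atol=1e-9)

    def test_three_samples_embed_exactly(self):
        pm = self._matrix(s=3, seed=1)
        coords = qc_mds(pm, top_n=200)
        V = pm.values.to_numpy()
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            diff = np.sort((V[:, i] - V[:, j]) ** 2)[-200:]
            d = math.sqrt(diff.mean())
            got = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
            assert got == pytest.approx(d, rel=1e-8)

    def test_permutation_equivariant(self):
        pm = self._matrix(seed=2)
        coords = qc_mds(pm, top_n=150)
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        pm2 = ProteinMatrix(pm.values[perm], pm.psm_support, pm.stage_tag)
        coords2 = qc_mds(pm2, top_n=150)
        for s in perm:
            np.testing.assert_allclose(coords2.loc[s], coords.loc[s], atol=1e-8)

    def test_fewer_complete_proteins_than_top_n_warns(self):
        pm = self._matrix(n=50)
        with pytest.warns(UserWarning, match="complete"):
            qc_mds(pm, top_n=500)

    def test_too_few_samples_or_proteins_rejected(self):
        with pytest.raises(ValidationError):
            qc_mds(self._matrix(s=2))
        pm = self._matrix(n=10)
        pm.values.iloc[2:, 0] = np.nan
        with pytest.raises(ValidationError, match="complete"):
            qc_mds(pm)


class TestQcCv:
    def _design(self):
        return make_design(
            [("run1", f"ch{i}", f"a{i}", "A", i + 1, False) for i in range(3)]
            + [("run1", "ch9", "b0", "B", 1, False)])

    def test_constant_replicates_have_zero_cv(self):
        pm = pm_from([[10.0, 10.0, 10.0, 5.0]], ["a0", "a1", "a2", "b0"])
        with pytest.warns(UserWarning, match="< 2 replicates"):
            out = qc_cv(pm, self._design())
        assert out["A"]["mean"] == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        # values (9, 10, 11): sd = 1, mean = 10 -> %CV = 10.0
        pm = pm_from([[9.0, 10.0, 11.0, 5.0]], ["a0", "a1", "a2", "b0"])
        with pytest.warns(UserWarning):
            out = qc_cv(pm, self._design())
        assert out["A"]["values"][0] == pytest.approx(10.0)

    def test_nonpositive_mean_excluded_and_counted(self):
        pm = pm_from([[-1.0, 0.5, 0.5, 5.0]], ["a0", "a1", "a2", "b0"])
        with pytest.warns(UserWarning):
            out = qc_cv(pm, self._design())
        assert out["A"]["n_excluded_nonpositive_mean"] == 1
        assert len(out["A"]["values"]) == 0


class TestReplicateCorrelation:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(6)
        pm = pm_from(rng.normal(10, 2, (100, 3)), ["s1", "s2", "s3"])
        corr = qc_replicate_correlation(pm)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_variance_ratio_oracle(self):
        """Two replicates sharing baseline sd 2 with noise sd 0.25:
        r = 2^2 / (2^2 + 0.25^2)."""
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(100):
            base = rng.normal(10, 2, 2000)
            a = base + rng.normal(0, 0.25, 2000)
            b = base + rng.normal(0, 0.25, 2000)
            pm = pm_from(np.column_stack([a, b]), ["r1", "r2"])
            rs.append(qc_replicate_correlation(pm).loc["r1", "r2"])
        expected = 4.0 / (4.0 + 0.0625)
        mc_se = np.std(rs, ddof=1) / math.sqrt(len(rs))
        assert abs(np.mean(rs) - expected) < 3 * mc_se

    def test_independent_samples_uncorrelated(self):
        rng = np.random.default_rng(8)
        pm = pm_from(rng.normal(0, 1, (5000, 2)), ["x", "y"])
        assert abs(qc_replicate_correlation(pm).loc["x", "y"]) < 0.05

    def test_sparse_pair_is_missing(self):
        vals = np.full((5, 2), np.nan)
        vals[:, 0] = 1.0
        vals[0:2, 1] = [1.0, 2.0]  # only 2 shared observations
        pm = pm_from(vals, ["x", "y"])
        corr = qc_replicate_correlation(pm, min_shared=3)
        assert np.isnan(corr.loc["x", "y"])
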