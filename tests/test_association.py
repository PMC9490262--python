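import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromascope.association import (
    cox_fit,
    median_split,
    ora_enrichment,
    read_gmt,
    select_correlated_genes,
    spearman_gene_scan,
    write_gmt,
)
from stromascope.synthetic_data import generate_cohort


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = median_split([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            median_split([5, 5, 5, 5])

    def test_matches_sorting_oracle_and_partition(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=101)
        labels = median_split(v)
        med = np.sort(v)[50]  # odd length: exact middle
        assert (labels == np.where(v <= med, "low", "high")).all()
        n_low, n_high = (labels == "low").sum(), (labels == "high").sum()
        assert n_low + n_high == 101
        assert abs(n_low - n_high) <= 1  # no ties in continuous draws


class TestCox:
    def test_null_effect_estimated_near_zero(self):
        est = []
        for rep in range(10):
            c = generate_cohort(n_cases=400, n_genes=2, planted_log_hr=0.0,
                                planted_gene_frac=0.0, seed=100 + rep)
            fit = cox_fit(c.clinical, group=c.clinical["fibrosis_group"].to_numpy())
            est.append(fit.loc[fit["covariate"] == "group_high", "log_hr"].iloc[0])
        assert abs(np.mean(est)) < 0.2

    def test_ci_covers_planted_hazard(self):
        cover = 0
        for rep in range(20):
            c = generate_cohort(n_cases=400, n_genes=2, planted_log_hr=0.69,
                                planted_gene_frac=0.0, seed=300 + rep)
            fit = cox_fit(c.clinical, group=c.clinical["fibrosis_group"].to_numpy())
            row = fit[fit["covariate"] == "group_high"].iloc[0]
            cover += row["ci_lower"] <= 2.0 <= row["ci_upper"]
        assert cover >= 16  # ~95% nominal coverage over 20 replicates

    def test_multivariable_mode_reports_all_covariates(self):
        c = generate_cohort(n_cases=200, n_genes=2, seed=4)
        fit = cox_fit(c.clinical, group=c.clinical["fibrosis_group"].to_numpy(),
                      covariates=("age", "stage", "debulking"))
        assert set(fit["covariate"]) == {
            "group_high", "age", "stage_iv", "debulking_suboptimal"
        }
        assert ((fit["ci_lower"] <= fit["hr"]) & (fit["hr"] <= fit["ci_upper"])).all()

    def test_group_without_events_rejected(self):
        c = generate_cohort(n_cases=50, n_genes=2, seed=5)
        clin = c.clinical.copy()
        grp = clin["fibrosis_group"].to_numpy()
        clin.loc[grp == "high", "event"] = 0
        with pytest.raises(ValueError, match="events"):
            cox_fit(clin, group=grp)


class TestSpearmanScan:
    def _cohort(self):
        return generate_cohort(n_cases=60, n_genes=50, planted_gene_frac=0.2, seed=6)

    def test_perfectly_correlated_gene(self):
        c = self._cohort()
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        expr = c.expression.copy()
        expr.loc["g0000"] = scores.loc[expr.columns].to_numpy()
        expr.loc["g0001"] = -scores.loc[expr.columns].to_numpy()
        rows = spearman_gene_scan(expr, scores).set_index("gene")
        assert rows.loc["g0000", "rho"] == pytest.approx(1.0)
        assert rows.loc["g0001", "rho"] == pytest.approx(-1.0)

    def test_matches_scipy_per_gene(self):
        """Vectorized scan must agree with scipy's spearmanr gene by gene."""
        c = self._cohort()
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        rows = spearman_gene_scan(c.expression, scores).set_index("gene")
        y = scores.loc[c.expression.columns].to_numpy()
        for gene in list(c.expression.index[:10]):
            rho, p = stats.spearmanr(c.expression.loc[gene].to_numpy(), y)
            assert rows.loc[gene, "rho"] == pytest.approx(rho)
            assert rows.loc[gene, "p"] == pytest.approx(p, rel=1e-6)

    def test_misaligned_ids_rejected(self):
        c = self._cohort()
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        bad = scores.rename(index=lambda s: s + "_x")
        with pytest.raises(ValueError):
            spearman_gene_scan(c.expression, bad)

    def test_planted_genes_separate_from_null(self):
        c = generate_cohort(n_cases=200, n_genes=1000, planted_gene_frac=0.10, seed=7)
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        rows = spearman_gene_scan(c.expression, scores)
        planted = rows["gene"].isin(set(c.planted_genes))
        planted_median = rows.loc[planted, "rho"].abs().median()
        null_95 = rows.loc[~planted, "rho"].abs().quantile(0.95)
        assert planted_median > null_95


class TestSelection:
    def test_empty_and_monotone(self):
        rows = pd.DataFrame({"gene": ["a", "b"], "rho": [0.5, -0.5], "p": [0.5, 0.9]})
        pos, neg = select_correlated_genes(rows)
        assert pos == [] and neg == []
        rows2 = pd.DataFrame(
            {"gene": list("abcd"), "rho": [0.9, 0.5, -0.5, -0.9],
             "p": [0.001, 0.03, 0.03, 0.001]}
        )
        p01 = select_correlated_genes(rows2, alpha=0.01)
        p05 = select_correlated_genes(rows2, alpha=0.05)
        assert set(p01[0]) <= set(p05[0]) and set(p01[1]) <= set(p05[1])

    def test_null_cohort_false_positive_rate_near_alpha(self):
        c = generate_cohort(n_cases=200, n_genes=1000, planted_log_hr=0.0,
                            planted_gene_frac=0.0, seed=8)
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        rows = spearman_gene_scan(c.expression, scores)
        pos, neg = select_correlated_genes(rows, alpha=0.05)
        n_selected = len(pos) + len(neg)
        # Binomial(1000, 0.05): mean 50, sd ~6.9; 3.5 sd band
        assert 26 <= n_selected <= 74


class TestORA:
    def test_whole_set_selected_matches_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        selected = universe[:10]
        sets = {"hit": universe[:10], "other": universe[50:70]}
        out = ora_enrichment(selected, sets, universe).set_index("gene_set")
        from math import comb

        assert out.loc["hit", "p"] == pytest.approx(1 / comb(100, 10))
        # direct hypergeometric summation for the 'other' set
        k_other = 0
        p_other = sum(
            comb(20, k) * comb(80, 10 - k) / comb(100, 10) for k in range(k_other, 11)
        )
        assert out.loc["other", "p"] == pytest.approx(min(p_other, 1.0))

    def test_zero_overlap_never_flagged(self):
        universe = [f"g{i}" for i in range(100)]
        out = ora_enrichment(universe[:10], {"disjoint": universe[90:]}, universe)
        assert out["p"].iloc[0] >= 0.5
        assert out["fdr"].iloc[0] >= 0.5

    def test_fdr_monotone_and_not_below_p(self):
        universe = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(13)
        sets = {f"s{j}": list(rng.choice(universe, 20, replace=False)) for j in range(30)}
        out = ora_enrichment(universe[:30], sets, universe)
        assert (out["fdr"] >= out["p"] - 1e-12).all()
        assert (np.diff(out["p"]) >= -1e-12).all()  # sorted by p
        assert out["fdr"].is_monotonic_increasing or len(out) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["a"], {}, [])
        with pytest.raises(ValueError):
            ora_enrichment([], {"s": ["a"]}, ["a"])

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["zz"], {"s": ["a"]}, ["a"])

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"pathway_a": ["g1", "g2"], "pathway_b": ["g3"]}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_planted_set_ranks_first(self):
        c = generate_cohort(n_cases=200, n_genes=1000, planted_gene_frac=0.10, seed=9)
        scores = c.clinical.set_index("case_id")["fibrosis_score"]
        rows = spearman_gene_scan(c.expression, scores)
        pos, _ = select_correlated_genes(rows)
        universe = list(c.expression.index)
        rng = np.random.default_rng(9)
        sets = {"planted": c.planted_genes}
        for j in range(20):
            sets[f"rand{j}"] = list(rng.choice(universe, 100, replace=False))
        out = ora_enrichment(pos, sets, universe)
        assert out.iloc[0]["gene_set"] == "planted"
        assert out.iloc[0]["fdr"] < 0.05
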