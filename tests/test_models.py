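import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from invbehave import ValidationError, build_ladder, compare_ladder, fit_mixed
from invbehave.models import posthoc_pairwise, run_analysis
from invbehave.simulate import TraitEffects, TraitTableConfig, simulate_phenotype_table


def _table(seed=0, n=20, **effect_kwargs):
    effects = {
        "sleep_min_per_hour": TraitEffects(
            intercept=30.0, beta_het=2.0, beta_inv=4.0, beta_cov=1.5,
            sigma_block=3.0, sigma_resid=2.0, **effect_kwargs,
        )
    }
    df, _ = simulate_phenotype_table(
        TraitTableConfig(seed=seed, n_per_cell=n, traits=effects)
    )
    return df.rename(columns={"sleep_min_per_hour": "y"})


class TestBuildLadder:
    def test_structural_npar_sequences(self):
        for covariate in ("sex", "temperature"):
            specs = build_ladder("sleep_min_per_hour", covariate)
            assert [s.npar for s in specs] == [3, 5, 6, 8]
            assert [s.name for s in specs] == [
                "null", "inversion", "covariate", "interaction",
            ]
        assert build_ladder("sleep_min_per_hour", "temperature")[2].label == "Temp Model"

    def test_null_model_has_no_genotype_term(self):
        spec = build_ladder("base_speed_mm_s", "sex")[0]
        assert "genotype" not in spec.formula

    def test_proportion_traits_flagged_for_transform(self):
        assert build_ladder("prop_near_food", "sex")[0].transform
        assert not build_ladder("base_speed_mm_s", "sex")[0].transform

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValidationError):
            build_ladder("wingbeat_hz", "sex")


class TestFitMixed:
    def test_row_duplication_leaves_fixed_effects_unchanged(self):
        df = _table(seed=3, n=10)
        spec = build_ladder("sleep_min_per_hour", "sex")[1]
        single = fit_mixed(spec, df)
        double = fit_mixed(spec, pd.concat([df, df], ignore_index=True))
        np.testing.assert_allclose(
            single.params.to_numpy(), double.params.to_numpy(), atol=1e-6
        )

    def test_constant_trait_zero_variance_boundary(self):
        df = _table(seed=1, n=5)
        df["y"] = 12.0
        spec = build_ladder("sleep_min_per_hour", "sex")[0]
        fit = fit_mixed(spec, df)  # must not crash
        assert fit.resid_var == 0.0

    def test_single_block_rejected(self):
        df = _table(seed=1, n=5)
        df = df[df["experiment_block"] == "1"]
        spec = build_ladder("sleep_min_per_hour", "sex")[0]
        with pytest.raises(ValidationError, match="block"):
            fit_mixed(spec, df)

    def test_aic_identity(self):
        df = _table(seed=4, n=12)
        for spec in build_ladder("sleep_min_per_hour", "sex"):
            fit = fit_mixed(spec, df)
            assert fit.aic == 2.0 * fit.npar - 2.0 * fit.loglik

    def test_matches_lme4_maximum_likelihood(self, tmp_path):
        """Cross-check the ML log-likelihoods of the whole ladder against
        R lme4 on the same table."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the lme4 cross-check")
        df = _table(seed=9, n=15)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            fml <- c("y ~ 1 + (1|experiment_block)",
                     "y ~ genotype + (1|experiment_block)",
                     "y ~ genotype + sex + (1|experiment_block)",
                     "y ~ genotype*sex + (1|experiment_block)")
            for (f in fml) {{
              m <- lmer(as.formula(f), data=d, REML=FALSE)
              cat(sprintf("%.8f\\n", as.numeric(logLik(m))))
            }}
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_llf = [float(x) for x in out.stdout.strip().splitlines()]
        fits = [fit_mixed(s, df) for s in build_ladder("sleep_min_per_hour", "sex")]
        for fit, ref in zip(fits, r_llf):
            assert fit.loglik == pytest.approx(ref, abs=1e-3)


class TestCompareLadder:
    def test_inversion_lrt_df_is_two(self):
        df = _table(seed=2, n=10)
        fits = [fit_mixed(s, df) for s in build_ladder("sleep_min_per_hour", "sex")]
        table = compare_ladder(fits).table
        assert table["Df"].tolist()[1:] == [2.0, 1.0, 2.0]
        assert table["npar"].tolist() == [3, 5, 6, 8]

    def test_single_level_covariate_gives_zero_chisq(self):
        df = _table(seed=2, n=10)
        df = df[df["sex"] == "F"]
        fits = [fit_mixed(s, df) for s in build_ladder("sleep_min_per_hour", "sex")]
        table = compare_ladder(fits).table
        # the sex term carries no information in an all-female table
        assert table.loc[table["model"] == "covariate", "Chisq"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert table.loc[table["model"] == "covariate", "p"].iloc[0] == pytest.approx(1.0)

    def test_loglik_monotone_along_ladder(self):
        df = _table(seed=6, n=15)
        fits = [fit_mixed(s, df) for s in build_ladder("sleep_min_per_hour", "sex")]
        lls = [f.loglik for f in fits]
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_misordered_fits_rejected(self):
        df = _table(seed=2, n=8)
        fits = [fit_mixed(s, df) for s in build_ladder("sleep_min_per_hour", "sex")]
        with pytest.raises(ValidationError):
            compare_ladder(fits[::-1])


class TestPosthoc:
    @staticmethod
    def _frame(values_by_geno, stratum="F"):
        rows = []
        for g, vals in values_by_geno.items():
            for v in vals:
                rows.append({"genotype": g, "sex": stratum, "y": float(v)})
        return pd.DataFrame(rows)

    def test_identical_groups_t_zero_p_one(self):
        df = self._frame({"INV": [1, 2, 3], "STD": [1, 2, 3]})
        res = posthoc_pairwise(df, "sleep_min_per_hour", "sex", gate_passed=True)
        assert len(res) == 1
        assert res[0].t == pytest.approx(0.0)
        assert res[0].p == pytest.approx(1.0)

    def test_three_genotypes_three_pairs_per_stratum(self):
        df = pd.concat(
            [
                self._frame({"INV": [1, 2], "HET": [2, 3], "STD": [3, 4]}, "F"),
                self._frame({"INV": [1, 2], "HET": [2, 3], "STD": [3, 4]}, "M"),
            ]
        )
        res = posthoc_pairwise(df, "sleep_min_per_hour", "sex", gate_passed=True)
        assert len(res) == 6

    def test_welch_textbook_values(self):
        df = self._frame({"INV": [1, 2, 3], "STD": [4, 5, 6]})
        res = posthoc_pairwise(df, "sleep_min_per_hour", "sex", gate_passed=True)[0]
        assert res.t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0, abs=1e-9)

    def test_pooled_variance_option(self):
        df = self._frame({"INV": [1.0, 2, 3, 9], "STD": [4.0, 5, 6]})
        welch = posthoc_pairwise(df, "sleep_min_per_hour", "sex", True, welch=True)[0]
        pooled = posthoc_pairwise(df, "sleep_min_per_hour", "sex", True, welch=False)[0]
        assert pooled.df == pytest.approx(5.0)
        assert welch.df != pytest.approx(5.0)

    def test_failed_gate_yields_no_tests(self):
        df = self._frame({"INV": [1, 2, 3], "STD": [4, 5, 6]})
        assert posthoc_pairwise(df, "sleep_min_per_hour", "sex", gate_passed=False) == []

    def test_tiny_genotype_group_skipped(self):
        df = self._frame({"INV": [1.0], "STD": [4, 5, 6], "HET": [2.0, 3.0]})
        res = posthoc_pairwise(df, "sleep_min_per_hour", "sex", gate_passed=True)
        pairs = {r.pair for r in res}
        assert pairs == {("HET", "STD")}


class TestRunAnalysis:
    def test_sex_analysis_filters_to_25C(self):
        df, _ = simulate_phenotype_table(TraitTableConfig(seed=5, n_per_cell=6))
        extra = df.iloc[:10].copy()
        extra["temperature_c"] = 20.0
        extra["sex"] = "M"
        extra["fly_id"] = [f"x{i}" for i in range(10)]
        full = pd.concat([df, extra], ignore_index=True)
        rep = run_analysis(full, "sex", traits=("sleep_min_per_hour",))
        assert rep.n_flies == len(df)

    def test_temperature_analysis_excludes_males(self):
        from invbehave.simulate import default_trait_effects

        cfg = TraitTableConfig(
            seed=5, n_per_cell=6, covariate="temperature",
            traits=default_trait_effects("temperature"),
        )
        df, _ = simulate_phenotype_table(cfg)
        males = df.iloc[:10].copy()
        males["sex"] = "M"
        males["fly_id"] = [f"m{i}" for i in range(10)]
        full = pd.concat([df, males], ignore_index=True)
        rep = run_analysis(full, "temperature", traits=("sleep_min_per_hour",))
        assert rep.n_flies == len(df)

    def test_missing_stratum_rejected(self):
        df, _ = simulate_phenotype_table(TraitTableConfig(seed=5, n_per_cell=4))
        with pytest.raises(ValidationError, match="sex"):
            run_analysis(df[df["sex"] == "F"], "sex")

    def test_selective_gating_with_single_trait_effect(self):
        """A genotype effect planted only on sleep opens the sleep gate and
        leaves a null trait's gate closed (and post-hoc list empty)."""
        effects = {
            "sleep_min_per_hour": TraitEffects(
                intercept=30.0, beta_het=3.0, beta_inv=6.0,
                sigma_block=1.0, sigma_resid=2.0,
            ),
            "base_speed_mm_s": TraitEffects(
                intercept=1.2, sigma_block=0.05, sigma_resid=0.3,
            ),
        }
        hits = 0
        n_rep = 10
        for k in range(n_rep):
            df, _ = simulate_phenotype_table(
                TraitTableConfig(seed=200 + k, n_per_cell=15, traits=effects)
            )
            rep = run_analysis(
                df, "sex", traits=("sleep_min_per_hour", "base_speed_mm_s")
            )
            sleep_gate = rep.tables["sleep_min_per_hour"].gate_passed()
            speed_gate = rep.tables["base_speed_mm_s"].gate_passed()
            speed_posthoc = [r for r in rep.posthoc if r.trait == "base_speed_mm_s"]
            assert sleep_gate  # planted effect is far above the noise
            if not speed_gate and not speed_posthoc:
                hits += 1
        # the null trait's gate is two alpha=0.05 LRTs, so ~90% stay closed
        assert hits >= 8
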