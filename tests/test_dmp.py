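"""Per-CpG regression, variance moderation, empirical-null correction, FDR.

The moderated-t machinery is cross-checked against the Bioconductor limma
implementation (via Rscript) on a small simulated dataset, and the OLS path
against a brute-force normal-equations oracle.
"""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fhmeth.datasets import MethylationDataset, make_annotation
from fhmeth.deconv import estimate_proportions
from fhmeth.dmp import (
    DesignError,
    bh_fdr,
    correct_inflation,
    dmp_pipeline,
    fit_dmp,
    fit_variance_prior,
    moderate_variances,
)
from fhmeth.synthdata import CohortConfig, SpikeSpec, generate_cohort

from conftest import make_dataset


def _two_group_dataset(y, groups):
    betas = pd.DataFrame(
        {"cg00000001": y}, index=[f"S{i}" for i in range(len(y))]
    )
    return make_dataset(betas, groups=groups, ages=[40.0] * len(y))


class TestOls:
    def test_hand_computed_two_group_fit(self):
        """y=[.1,.2,.3,.4], pos/pos/neg/neg: effect 0.2, t = 0.2/sqrt(0.005)."""
        ds = _two_group_dataset([0.1, 0.2, 0.3, 0.4], ["pos", "pos", "neg", "neg"])
        res = fit_dmp(ds, include_age=False)
        row = res.table.iloc[0]
        assert row["beta_hat"] == pytest.approx(0.2, abs=1e-12)
        assert row["se"] == pytest.approx(np.sqrt(0.005), abs=1e-12)
        assert row["t"] == pytest.approx(0.2 / np.sqrt(0.005), abs=1e-9)
        assert row["df"] == 2

    def test_matches_normal_equations_oracle(self, reference):
        """Full-design fits agree with brute-force (X'X)^-1 X'y to 1e-10."""
        rng = np.random.default_rng(33)
        for trial in range(20):
            cfg = CohortConfig(
                n_group_neg=12, n_group_pos=8, n_probes=70,
                seed=int(rng.integers(2**31)),
            )
            ds, _ = generate_cohort(cfg, reference)
            props = estimate_proportions(ds, reference)
            res = fit_dmp(ds, props)
            # independent oracle: rebuild the design and solve per probe
            P = props.renormalized
            X = np.column_stack(
                [
                    np.ones(20),
                    ds.group_mask_neg.astype(float),
                    ds.samples["age"].to_numpy(float),
                ]
                + [P[c].to_numpy() for c in P.columns if c != "Gran"]
            )
            XtX_inv = np.linalg.inv(X.T @ X)
            for probe in rng.choice(ds.betas.columns, 5, replace=False):
                y = ds.betas[probe].to_numpy()
                b = XtX_inv @ X.T @ y
                resid = y - X @ b
                s2 = resid @ resid / (20 - X.shape[1])
                se = np.sqrt(s2 * XtX_inv[1, 1])
                row = res.table.loc[probe]
                assert row["beta_hat"] == pytest.approx(b[1], abs=1e-10)
                assert row["se"] == pytest.approx(se, abs=1e-10)
                assert row["t"] == pytest.approx(b[1] / se, abs=1e-8)

    def test_zero_variance_probe_flagged(self):
        betas = pd.DataFrame(
            {
                "cg00000001": [0.3] * 8,
                "cg00000002": np.linspace(0.2, 0.6, 8),
            },
            index=[f"S{i}" for i in range(8)],
        )
        res = fit_dmp(make_dataset(betas))
        assert bool(res.table.loc["cg00000001", "degenerate"])
        assert np.isnan(res.table.loc["cg00000001", "t"])
        assert not bool(res.table.loc["cg00000002", "degenerate"])

    def test_collinear_design_rejected(self):
        betas = pd.DataFrame(
            np.random.default_rng(0).uniform(0.2, 0.8, (8, 3)),
            index=[f"S{i}" for i in range(8)],
            columns=["cg1", "cg2", "cg3"],
        )
        ds = make_dataset(betas, ages=[50.0] * 8)  # constant age == intercept
        with pytest.raises(DesignError, match="age"):
            fit_dmp(ds)

    def test_effect_sign_matches_t_sign(self, small_cohort, reference):
        ds, _ = small_cohort
        props = estimate_proportions(ds, reference)
        res = fit_dmp(ds, props)
        ok = ~res.table["degenerate"]
        assert (
            np.sign(res.table.loc[ok, "beta_hat"]) == np.sign(res.table.loc[ok, "t"])
        ).all()


class TestModeration:
    @pytest.fixture()
    def fitted(self, small_cohort):
        ds, _ = small_cohort
        return fit_dmp(ds)

    def test_no_shrinkage_limit(self, fitted):
        mod = moderate_variances(fitted, prior=(0.0, 1.0))
        np.testing.assert_allclose(
            mod.table["t_moderated"].to_numpy(),
            mod.table["t"].to_numpy(),
            rtol=1e-12,
        )

    def test_complete_shrinkage_limit(self, fitted):
        s0sq = 0.004
        mod = moderate_variances(fitted, prior=(np.inf, s0sq))
        expect = mod.table["beta_hat"] / (fitted.stdev_unscaled * np.sqrt(s0sq))
        np.testing.assert_allclose(
            mod.table["t_moderated"].to_numpy(), expect.to_numpy(), rtol=1e-12
        )

    def test_prior_recovery_from_simulated_variances(self):
        """d0 within factor 2, s0^2 within 20% on scaled-inv-chi2 draws."""
        rng = np.random.default_rng(8)
        d0_true, s0sq_true, df = 4.0, 0.01, 20
        sigma2 = s0sq_true * d0_true / rng.chisquare(d0_true, size=1000)
        s2 = sigma2 * rng.chisquare(df, size=1000) / df
        d0, s0sq = fit_variance_prior(s2, df)
        assert d0_true / 2 <= d0 <= d0_true * 2
        assert abs(s0sq - s0sq_true) / s0sq_true <= 0.2

    def test_matches_bioconductor_limma(self, tmp_path):
        """Moderated t, prior df and prior variance agree with limma eBayes."""
        rng = np.random.default_rng(12)
        n, m = 24, 80
        groups = ["neg"] * 12 + ["pos"] * 12
        betas = pd.DataFrame(
            np.clip(rng.normal(0.5, 0.08, (n, m)), 0.01, 0.99),
            index=[f"S{i}" for i in range(n)],
            columns=[f"cg{i:08d}" for i in range(m)],
        )
        ds = make_dataset(betas, groups=groups, ages=[40.0] * n)
        mine = moderate_variances(fit_dmp(ds, include_age=False))

        y_path, design_path, out_path = (
            tmp_path / "y.tsv", tmp_path / "design.tsv", tmp_path / "out.tsv"
        )
        betas.T.to_csv(y_path, sep="\t")
        X = pd.DataFrame(
            {"intercept": 1.0, "group_neg": ds.group_mask_neg.astype(float)}
        )
        X.to_csv(design_path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{y_path}", row.names=1, check.names=FALSE))
            design <- as.matrix(read.delim("{design_path}", check.names=FALSE))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(probe=rownames(y), t=fit$t[,"group_neg"],
                              df_prior=fit$df.prior, s2_prior=fit$s2.prior)
            write.table(out, "{out_path}", sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(out_path, sep="\t").set_index("probe")
        np.testing.assert_allclose(
            mine.table["t_moderated"].to_numpy(),
            theirs["t"].to_numpy(),
            rtol=1e-5,
        )
        assert mine.prior_df == pytest.approx(theirs["df_prior"].iloc[0], rel=1e-4)
        assert mine.prior_var == pytest.approx(theirs["s2_prior"].iloc[0], rel=1e-4)


class TestInflation:
    def test_exact_null_calibration(self):
        z = np.random.default_rng(1).normal(0, 1, 10000)
        fit, p = correct_inflation(z)
        assert fit.sigma0 == pytest.approx(1.0, abs=0.05)
        assert fit.lambda_gc == pytest.approx(1.0, abs=0.05)
        # corrected p approximately uniform
        assert abs((p < 0.05).mean() - 0.05) < 0.01

    def test_inflated_null_recovery(self):
        z = np.random.default_rng(2).normal(0, 1.5, 10000)
        fit, _ = correct_inflation(z)
        assert fit.sigma0 == pytest.approx(1.5, abs=0.1)

    def test_contaminated_null(self):
        """5% true signals at mean 4 are absorbed by the tail component."""
        rng = np.random.default_rng(3)
        z = np.concatenate([rng.normal(0, 1, 9500), rng.normal(4, 1, 500)])
        fit, _ = correct_inflation(z)
        assert fit.sigma0 == pytest.approx(1.0, abs=0.05)
        assert fit.pi0 < 1.0

    def test_small_input_identity(self, caplog):
        z = np.random.default_rng(4).normal(0, 2, 100)
        fit, p = correct_inflation(z)
        assert fit.method == "identity"
        assert fit.sigma0 == 1.0
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(z)))


class TestBhFdr:
    def test_hand_computation(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_monotone_with_p_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all()


class TestPipeline:
    def test_spiked_probe_detected(self, reference):
        cfg = CohortConfig(n_probes=300, noise_sd_logit=0.05, seed=40)
        ds, _ = generate_cohort(
            cfg, reference, spikes=[SpikeSpec("cg00574958", -0.013)]
        )
        props = estimate_proportions(ds, reference)
        res, fit = dmp_pipeline(ds, props)
        assert res.table.loc["cg00574958", "q"] < 0.05
        assert res.table.loc["cg00574958", "beta_hat"] < 0

    def test_m_scale_agrees_in_direction(self, reference):
        cfg = CohortConfig(n_probes=300, noise_sd_logit=0.05, seed=41)
        ds, _ = generate_cohort(
            cfg, reference, spikes=[SpikeSpec("cg00574958", -0.013)]
        )
        props = estimate_proportions(ds, reference)
        res_m, _ = dmp_pipeline(ds, props, scale="m")
        # effect on the M scale: negative and significant at the spike
        assert res_m.table.loc["cg00574958", "beta_hat"] < 0
        assert res_m.table.loc["cg00574958", "q"] < 0.05
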