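"""REML variance decomposition, IS index, individual WIC, and the WIC GLM."""

import numpy as np
import pandas as pd
import pytest

from codniche.specialization import (
    fit_random_intercept_reml,
    individual_wic,
    is_index,
    log10_wic,
    paired_wide,
    reml_profile,
    simplify_by_aic,
    wic_glm,
)


def mixed_data(n_fish, s2b, s2w, rng, beta_fl=0.002, beta_tissue=0.5,
               n_obs_per_fish=2):
    rows = []
    for i in range(n_fish):
        fl = rng.uniform(250, 580)
        u = rng.normal(0, np.sqrt(s2b))
        for j in range(n_obs_per_fish):
            tissue = "RBC" if j % 2 == 0 else "plasma"
            y = 1.0 + beta_fl * fl + beta_tissue * (tissue == "plasma") + u \
                + rng.normal(0, np.sqrt(s2w))
            rows.append({"fish_id": f"f{i:04d}", "tissue": tissue,
                         "fork_length_mm": fl, "y": y})
    return pd.DataFrame(rows)


def dense_reml_grid_oracle(y, X, groups):
    """Dense-matrix REML criterion evaluated on a two-stage lambda grid."""
    labels = pd.unique(groups)
    Z = np.column_stack([(groups == g).astype(float) for g in labels])
    n, p = X.shape

    def crit(lam):
        V0 = np.eye(n) + lam * (Z @ Z.T)
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        q = r @ Vi @ r
        return ((n - p) * np.log(q) + np.linalg.slogdet(V0)[1]
                + np.linalg.slogdet(XtViX)[1]), q / (n - p)

    coarse = np.concatenate([[0.0], np.logspace(-6, 4, 101)])
    vals = [crit(l)[0] for l in coarse]
    j = int(np.argmin(vals))
    lo = coarse[max(j - 1, 0)]
    hi = coarse[min(j + 1, len(coarse) - 1)]
    fine = np.linspace(lo, hi if hi > lo else lo + 1e-6, 4001)
    vals = [crit(l)[0] for l in fine]
    lam = fine[int(np.argmin(vals))]
    _, s2w = crit(lam)
    return lam, s2w, lam * s2w


class TestISIndex:
    @pytest.mark.parametrize(
        "wic, bic, expected",
        [(0.69, 0.00, 1.00), (0.27, 0.36, 0.43), (0.24, 0.36, 0.40)],
    )
    def test_published_decomposition_triples(self, wic, bic, expected):
        assert round(is_index(wic, bic), 2) == expected

    def test_pure_generalist_boundary(self):
        assert is_index(0.5, 0.0) == 1.0

    def test_undefined_at_zero_total(self):
        with pytest.raises(ZeroDivisionError):
            is_index(0.0, 0.0)

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            is_index(-0.1, 0.2)


class TestREML:
    def test_no_fish_heterogeneity_gives_boundary_is_one(self, rng):
        # every fish has exactly the population mean: all variation is
        # within-fish, so the between-fish component sits at the 0 boundary
        rows = []
        for i in range(40):
            d = rng.normal(0, 0.5)
            for t, e in (("RBC", d), ("plasma", -d)):
                rows.append({"fish_id": f"f{i}", "tissue": t, "y": 2.0 + e})
        df = pd.DataFrame(rows)
        dec = fit_random_intercept_reml(
            df, "y", numeric_effects=(), categorical_effects=()
        )
        assert dec.boundary
        assert dec.bic == 0.0
        assert dec.is_index == 1.0

    def test_exact_duplicates_give_is_zero(self, rng):
        rows = []
        for i in range(25):
            y = rng.normal(0, 1)
            fl = rng.uniform(300, 500)
            for t in ("RBC", "plasma"):
                rows.append({"fish_id": f"f{i}", "tissue": t, "y": y,
                             "fork_length_mm": fl})
        df = pd.DataFrame(rows)
        dec = fit_random_intercept_reml(df, "y", categorical_effects=())
        assert dec.wic < 1e-6
        assert dec.is_index < 1e-4

    def test_components_match_dense_grid_oracle(self, rng):
        df = mixed_data(20, s2b=0.36, s2w=0.24, rng=rng)
        dec = fit_random_intercept_reml(df, "y")
        X = np.column_stack([
            np.ones(len(df)),
            df["fork_length_mm"],
            (df["tissue"] == "plasma").astype(float),
        ])
        lam, s2w, s2b = dense_reml_grid_oracle(
            df["y"].to_numpy(), X, df["fish_id"].to_numpy()
        )
        assert dec.wic == pytest.approx(s2w, abs=1e-4)
        assert dec.bic == pytest.approx(s2b, abs=1e-4)

    def test_balanced_intercept_only_equals_anova_mom(self, rng):
        """Balanced two-observations-per-fish data, no covariates: REML
        equals the one-way random-effects method-of-moments estimators."""
        df = mixed_data(30, s2b=0.4, s2w=0.2, rng=rng,
                        beta_fl=0.0, beta_tissue=0.0)
        dec = fit_random_intercept_reml(
            df, "y", numeric_effects=(), categorical_effects=()
        )
        y = df["y"].to_numpy()
        g = df["fish_id"].to_numpy()
        means = df.groupby("fish_id")["y"].mean()
        G, m = len(means), 2
        msb = m * ((means - y.mean()) ** 2).sum() / (G - 1)
        msw = sum((y[g == f] - means[f]) ** 2 for f in means.index).sum() / (len(y) - G)
        s2b_mom = max((msb - msw) / m, 0.0)
        assert dec.wic == pytest.approx(msw, abs=1e-8)
        assert dec.bic == pytest.approx(s2b_mom, abs=1e-8)

    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf
        df = mixed_data(40, s2b=0.36, s2w=0.24, rng=rng)
        dec = fit_random_intercept_reml(df, "y")
        md = smf.mixedlm("y ~ fork_length_mm + C(tissue)", df,
                         groups=df["fish_id"]).fit(reml=True)
        assert dec.wic == pytest.approx(md.scale, rel=1e-4)
        assert dec.bic == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-5)

    def test_interior_optimum_is_stationary(self, rng):
        df = mixed_data(50, s2b=0.36, s2w=0.24, rng=rng)
        X = np.column_stack([np.ones(len(df)), df["fork_length_mm"],
                             (df["tissue"] == "plasma").astype(float)])
        y = df["y"].to_numpy()
        groups = df["fish_id"].to_numpy()
        lam, s2w, s2b, _, crit = reml_profile(y, X, groups)
        assert lam > 0
        from codniche.specialization import _GroupStats
        stats_ = _GroupStats(y, X, groups)
        for bump in (1 - 1e-4, 1 + 1e-4):
            assert stats_.criterion(lam * bump)[0] >= crit - 1e-9

    def test_invariant_to_relabeling_and_row_order(self, rng):
        df = mixed_data(25, s2b=0.3, s2w=0.2, rng=rng)
        dec1 = fit_random_intercept_reml(df, "y")
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabel = {f: f"zz{i}" for i, f in enumerate(df["fish_id"].unique())}
        shuffled["fish_id"] = shuffled["fish_id"].map(relabel)
        dec2 = fit_random_intercept_reml(shuffled, "y")
        assert dec1.wic == pytest.approx(dec2.wic, abs=1e-8)
        assert dec1.bic == pytest.approx(dec2.bic, abs=1e-8)

    def test_errors(self, rng):
        df = mixed_data(1, s2b=0.1, s2w=0.1, rng=rng)
        with pytest.raises(ValueError, match=">= 2"):
            fit_random_intercept_reml(df, "y")
        df2 = mixed_data(10, s2b=0.1, s2w=0.1, rng=rng)
        df2["dup"] = df2["fork_length_mm"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_random_intercept_reml(
                df2, "y", numeric_effects=("fork_length_mm", "dup")
            )


def wide_frame(n, rng, noise=0.4, slope=0.8, intercept=-3.0):
    rbc = rng.normal(-21, 1.0, size=n)
    plasma = intercept + slope * rbc + rng.normal(0, noise, size=n)
    return pd.DataFrame({
        "fish_id": [f"f{i:03d}" for i in range(n)],
        "d13C_corr_RBC": rbc,
        "d13C_corr_plasma": plasma,
        "cluster": rng.integers(1, 3, size=n),
        "fork_length_mm": rng.uniform(250, 580, size=n),
        "year": rng.choice([2018, 2019], size=n),
    })


class TestIndividualWIC:
    def test_fish_on_fitted_line_have_zero_wic(self):
        df = pd.DataFrame({
            "fish_id": list("abcd"),
            "d13C_corr_RBC": [-22.0, -21.0, -20.0, -19.0],
            "d13C_corr_plasma": [-23.0, -22.0, -21.0, -20.0],
        })
        out = individual_wic(df, "d13C")
        np.testing.assert_allclose(out["wic_value"], 0, atol=1e-12)

    def test_residuals_match_normal_equations_oracle(self, rng):
        df = wide_frame(5, rng)
        out = individual_wic(df, "d13C")
        A = np.column_stack([np.ones(5), df["d13C_corr_RBC"]])
        y = df["d13C_corr_plasma"].to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(out["wic_value"], np.abs(y - A @ beta), atol=1e-12)

    def test_direction_switch_changes_regression(self, rng):
        df = wide_frame(20, rng)
        a = individual_wic(df, "d13C", direction="plasma_on_rbc")
        b = individual_wic(df, "d13C", direction="rbc_on_plasma")
        assert not np.allclose(a["wic_value"], b["wic_value"])

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({
            "fish_id": list("abc"),
            "d13C_corr_RBC": [-21.0] * 3,
            "d13C_corr_plasma": [-22.0, -21.5, -21.0],
        })
        with pytest.raises(ValueError, match="zero variance"):
            individual_wic(df, "d13C")


class TestPairedWide:
    def test_unpaired_fish_dropped(self, rng):
        rows = []
        for i in range(6):
            for t in ("RBC", "plasma"):
                if i == 0 and t == "plasma":
                    continue
                rows.append({"fish_id": f"f{i}", "tissue": t,
                             "d13C_corr": rng.normal(), "d15N_corr": rng.normal()})
        wide = paired_wide(pd.DataFrame(rows))
        assert len(wide) == 5
        assert "f0" not in set(wide["fish_id"])


class TestLog10WIC:
    def test_zero_floored_at_half_min_positive(self):
        vals, n = log10_wic(np.array([0.0, 0.4, 1.0]))
        assert n == 1
        assert vals[0] == pytest.approx(np.log10(0.2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            log10_wic(np.zeros(3))


def glm_frame(n, rng, cluster_effect=0.0, fl_effect=0.0, year_effect=0.0,
              interaction=0.0, sd=0.3):
    cluster = rng.integers(1, 3, size=n)
    fl = rng.uniform(250, 580, size=n)
    year = rng.choice([2018, 2019], size=n)
    z = (fl - fl.mean()) / fl.std()
    mu = (0.1 + cluster_effect * (cluster == 2) + fl_effect * z
          + year_effect * (year == 2019) + interaction * (cluster == 2) * z)
    return pd.DataFrame({
        "fish_id": [f"f{i}" for i in range(n)],
        "wic_value": 10.0 ** (mu + rng.normal(0, sd, size=n)),
        "cluster": cluster,
        "fork_length_mm": fl,
        "year": year,
    })


class TestWicGLM:
    def test_binary_predictor_closed_form(self, rng):
        # orthogonal design: identical lengths/years in both clusters, so
        # the cluster coefficient is exactly the group-mean difference
        fl = np.tile(np.linspace(300, 500, 6), 2)
        year = np.tile([2018, 2019] * 3, 2)
        cluster = np.repeat([1, 2], 6)
        wic = 10.0 ** rng.normal(0, 0.5, size=12)
        df = pd.DataFrame({"wic_value": wic, "cluster": cluster,
                           "fork_length_mm": fl, "year": year})
        res, table = wic_glm(df)
        lw = np.log10(wic)
        expected = lw[cluster == 2].mean() - lw[cluster == 1].mean()
        got = table.set_index("term").loc["C(cluster)[T.2]", "estimate_log10"]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_backtransform_is_power_of_ten(self, rng):
        df = glm_frame(40, rng, cluster_effect=0.3)
        _, table = wic_glm(df)
        np.testing.assert_allclose(
            table["estimate_backtransformed"], 10.0 ** table["estimate_log10"]
        )

    def test_cluster_effect_coverage(self):
        """True cluster effect recovered within 2 SE in ~95% of fits."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            df = glm_frame(40, rng, cluster_effect=0.4)
            res, table = wic_glm(df)
            row = table.set_index("term").loc["C(cluster)[T.2]"]
            hits += abs(row["estimate_log10"] - 0.4) <= 2 * row["se_log10"]
        assert hits / n_sim >= 0.93

    def test_min_observations(self, rng):
        with pytest.raises(ValueError, match=">= 10"):
            wic_glm(glm_frame(8, rng))


class TestSimplifyByAIC:
    def test_no_interactions_returned_unchanged(self, rng):
        df = glm_frame(40, rng, cluster_effect=0.3)
        res, table, log = simplify_by_aic(df, ())
        assert log == []
        assert set(table["term"]) == {
            "Intercept", "C(cluster)[T.2]", "C(year)[T.2019]", "fork_length_mm"
        }

    def test_term_kept_when_removal_raises_aic_beyond_threshold(self):
        # a borderline interaction: non-significant at alpha yet informative
        # enough that dropping it degrades AIC past the configured threshold
        rng = np.random.default_rng(5)
        df = glm_frame(60, rng, cluster_effect=0.4, interaction=0.12, sd=0.35)
        res_full, _ = wic_glm(df, ("C(cluster):fork_length_mm",))
        res, table, log = simplify_by_aic(
            df, ("C(cluster):fork_length_mm",), delta_aic=0.0
        )
        (entry,) = log
        if entry["action"] == "retained":
            assert entry["delta_aic"] > 0.0
            assert any("fork_length_mm" in t and ":" in t.replace("C(cluster)", "x")
                       or ":" in t for t in table["term"])
        else:
            assert entry["delta_aic"] <= 0.0

    def test_true_interaction_survives_spurious_dropped(self):
        rng = np.random.default_rng(123)
        n_sim = 500
        good = 0
        for _ in range(n_sim):
            df = glm_frame(60, rng, cluster_effect=0.3, interaction=0.45, sd=0.25)
            _, table, _ = simplify_by_aic(
                df, ("C(cluster):fork_length_mm", "C(cluster):C(year)")
            )
            terms = set(table["term"])
            has_true = any("cluster" in t and "fork_length_mm" in t for t in terms)
            has_spur = any("cluster" in t and "year" in t and ":" in t for t in terms)
            good += has_true and not has_spur
        assert good / n_sim >= 0.90
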