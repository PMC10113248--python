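import numpy as np
import pandas as pd
import pytest

from abitraj import contributions, encode, fit_famd, project, variance_explained
from abitraj.cohort import Variable, VariableDictionary


def continuous_dict(names):
    return VariableDictionary([Variable(n, "continuous") for n in names])


@pytest.fixture()
def continuous_table():
    rng = np.random.default_rng(42)
    latent = rng.standard_normal(80)
    df = pd.DataFrame(
        {
            "x1": 2.0 * latent + rng.standard_normal(80),
            "x2": -1.5 * latent + rng.standard_normal(80),
            "x3": rng.standard_normal(80),
        }
    )
    return df


@pytest.fixture()
def mixed_rank1_table():
    """Mixed table driven by a single latent factor (near rank-1)."""
    rng = np.random.default_rng(7)
    latent = rng.standard_normal(200)
    df = pd.DataFrame(
        {
            "u": 1.0 * latent,
            "v": -2.0 * latent,
            "c": np.where(latent > 0, "high", "low"),
        }
    )
    dictionary = VariableDictionary(
        [
            Variable("u", "continuous"),
            Variable("v", "continuous"),
            Variable("c", "categorical", ("low", "high")),
        ]
    )
    return df, dictionary, latent


class TestEncode:
    def test_continuous_only_is_zscore(self, continuous_table):
        enc = encode(continuous_table, continuous_dict(continuous_table.columns))
        expected = (continuous_table - continuous_table.mean()) / continuous_table.std(ddof=0)
        np.testing.assert_allclose(enc.values, expected.to_numpy(), atol=1e-12)

    def test_balanced_binary_indicator_weighting(self):
        # 4-row hand computation: levels at proportions (0.5, 0.5) give
        # indicator/sqrt(0.5) centered at sqrt(0.5)
        df = pd.DataFrame({"b": ["yes", "yes", "no", "no"]})
        d = VariableDictionary([Variable("b", "categorical", ("yes", "no"))])
        enc = encode(df, d)
        r = 1 / np.sqrt(0.5) - np.sqrt(0.5)  # = sqrt(0.5)
        expected = np.array([[r, -np.sqrt(0.5)], [r, -np.sqrt(0.5)],
                             [-np.sqrt(0.5), r], [-np.sqrt(0.5), r]])
        np.testing.assert_allclose(enc.values, expected, atol=1e-12)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance"):
            encode(df, continuous_dict(["x"]))

    def test_incomplete_rows_dropped_and_counted(self, continuous_table):
        continuous_table.loc[3, "x1"] = np.nan
        enc = encode(continuous_table, continuous_dict(continuous_table.columns))
        assert enc.n_dropped == 1
        assert 3 not in enc.row_index


class TestFitFAMD:
    def test_continuous_only_matches_classical_pca(self, continuous_table):
        """Oracle: eigendecomposition of the correlation matrix."""
        d = continuous_dict(continuous_table.columns)
        model = fit_famd(encode(continuous_table, d))
        Z = (continuous_table - continuous_table.mean()) / continuous_table.std(ddof=0)
        Z = Z.to_numpy()
        evals, evecs = np.linalg.eigh(Z.T @ Z / len(Z))
        evals = evals[::-1]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-10)
        scores_ref = np.abs(Z @ evecs[:, ::-1])
        np.testing.assert_allclose(
            np.abs(model.scores_.to_numpy()), scores_ref, atol=1e-8
        )

    def test_rank1_table_concentrates_variance(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        model = fit_famd(encode(df, d))
        assert variance_explained(model)[0] > 0.9

    def test_row_permutation_invariance(self, continuous_table):
        d = continuous_dict(continuous_table.columns)
        model = fit_famd(encode(continuous_table, d))
        perm = np.random.default_rng(0).permutation(len(continuous_table))
        shuffled = continuous_table.iloc[perm].reset_index(drop=True)
        model_p = fit_famd(encode(shuffled, d))
        np.testing.assert_allclose(model_p.eigenvalues, model.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(
            model_p.scores_.to_numpy(), model.scores_.to_numpy()[perm], atol=1e-8
        )

    def test_score_columns_uncorrelated(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        model = fit_famd(encode(df, d))
        S = model.scores_.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestProject:
    def test_training_rows_reproduce_stored_scores(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        model = fit_famd(encode(df, d))
        proj = project(model, df, d)
        np.testing.assert_allclose(
            proj.to_numpy(), model.scores_.to_numpy(), atol=1e-10
        )

    def test_mean_profile_projects_to_zero(self, continuous_table):
        d = continuous_dict(continuous_table.columns)
        model = fit_famd(encode(continuous_table, d))
        mean_row = continuous_table.mean().to_frame().T
        np.testing.assert_allclose(
            project(model, mean_row, d).to_numpy(), 0.0, atol=1e-10
        )

    def test_held_out_rows_collinear_with_latent(self, mixed_rank1_table):
        # exact collinearity on the continuous rank-1 part; the binarized
        # categorical coarsens the latent, so the mixed bound is looser
        df, d, latent = mixed_rank1_table
        cont = df[["u", "v"]]
        d_cont = continuous_dict(["u", "v"])
        model_c = fit_famd(encode(cont.iloc[:150], d_cont))
        proj_c = project(model_c, cont.iloc[150:], d_cont)
        assert abs(np.corrcoef(proj_c["dim1"], latent[150:])[0, 1]) > 0.9999
        model = fit_famd(encode(df.iloc[:150], d))
        proj = project(model, df.iloc[150:], d)
        assert abs(np.corrcoef(proj["dim1"], latent[150:])[0, 1]) > 0.95

    def test_unseen_level_rejected(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        d2 = VariableDictionary(
            [
                Variable("u", "continuous"),
                Variable("v", "continuous"),
                Variable("c", "categorical", ("low", "high", "medium")),
            ]
        )
        model = fit_famd(encode(df, d2))
        new = df.iloc[:2].copy()
        new.loc[new.index[0], "c"] = "medium"
        with pytest.raises(ValueError, match="unseen"):
            project(model, new, d2)

    def test_missing_value_rejected(self, continuous_table):
        d = continuous_dict(continuous_table.columns)
        model = fit_famd(encode(continuous_table, d))
        new = continuous_table.iloc[:2].copy()
        new.loc[new.index[0], "x1"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            project(model, new, d)


class TestVarianceAndContributions:
    def test_fractions_sum_to_one(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        model = fit_famd(encode(df, d))
        fr = variance_explained(model)
        assert fr.sum() == pytest.approx(1.0)
        assert (fr >= 0).all() and (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_contributions_sum_to_100(self, mixed_rank1_table):
        df, d, _ = mixed_rank1_table
        model = fit_famd(encode(df, d))
        for comp in range(model.n_components()):
            assert contributions(model, comp).sum() == pytest.approx(100.0)

    def test_equally_loaded_variables_share_contribution(self):
        rng = np.random.default_rng(5)
        latent = rng.standard_normal(500)
        df = pd.DataFrame({"p": latent, "q": latent + 0.0})
        model = fit_famd(encode(df, continuous_dict(["p", "q"])))
        ctr = contributions(model, 0)
        assert ctr["p"] == pytest.approx(ctr["q"], abs=1e-8)
        assert ctr["p"] == pytest.approx(50.0, abs=1e-6)

    def test_component_index_out_of_range(self, continuous_table):
        model = fit_famd(
            encode(continuous_table, continuous_dict(continuous_table.columns))
        )
        with pytest.raises(IndexError):
            contributions(model, 99)


def test_json_round_trip(tmp_path, mixed_rank1_table):
    from abitraj.famd import FAMDModel

    df, d, _ = mixed_rank1_table
    model = fit_famd(encode(df, d))
    model.to_json(tmp_path / "m.json")
    back = FAMDModel.from_json(tmp_path / "m.json")
    np.testing.assert_allclose(back.loadings, model.loadings)
    proj = project(back, df, d)
    np.testing.assert_allclose(proj.to_numpy(), model.scores_.to_numpy(), atol=1e-10)
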