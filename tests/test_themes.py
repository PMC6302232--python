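"""NMF theme clustering, message theme loads, p(theme|disease), and PMI."""

import math

import numpy as np
import pandas as pd
import pytest

from infodem.experiments import nmf_block_recovery
from infodem.themes import (
    ThemeModel,
    fit_themes,
    message_theme_distribution,
    pmi_disease_theme,
    theme_given_disease,
)
from infodem.topics import TopicModel, Vocabulary


def _model_from_phi(phi, seed=0):
    K, V = phi.shape
    tokens = [f"v{i}" for i in range(V)]
    vocab = Vocabulary(tokens, {t: 1.0 for t in tokens}, 1)
    return TopicModel(K, phi, np.full(K, 1.0 / K), 50.0 / K, 0.01, vocab, seed, np.empty(0))


@pytest.fixture(scope="module")
def block_themes():
    rng = np.random.default_rng(1)
    phi = np.zeros((4, 40))
    phi[0, :20] = rng.dirichlet(np.ones(20))
    phi[1, :20] = rng.dirichlet(np.ones(20))
    phi[2, 20:] = rng.dirichlet(np.ones(20))
    phi[3, 20:] = rng.dirichlet(np.ones(20))
    model = _model_from_phi(phi, seed=1)
    return fit_themes(model, T=2, seed=1)


class TestNmf:
    def test_perfect_two_cluster_recovery(self):
        for seed in range(1, 6):
            assert nmf_block_recovery(seed) == 1.0

    def test_reconstruction_error_nonincreasing(self, block_themes):
        diffs = np.diff(block_themes.residuals)
        assert np.all(diffs <= 1e-10)

    def test_factor_normalizations(self, block_themes):
        assert np.all(block_themes.W >= 0)
        assert np.allclose(block_themes.word_given_theme.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(block_themes.theme_given_word.sum(axis=1), 1.0, atol=1e-9)
        assert block_themes.theme_prior.sum() == pytest.approx(1.0)

    def test_matches_reference_nmf_objective(self):
        """Independent oracle: sklearn's NMF reaches a comparable Frobenius
        reconstruction error on the same matrix and rank."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(7)
        phi = rng.dirichlet(np.ones(30), size=8)
        themes = fit_themes(_model_from_phi(phi), T=3, seed=7, n_iter=800)
        ours = float(np.linalg.norm(phi - themes.W @ themes.H))
        ref = NMF(n_components=3, init="nndsvda", solver="mu", max_iter=2000, random_state=7, tol=1e-10)
        Wr = ref.fit_transform(phi)
        theirs = float(np.linalg.norm(phi - Wr @ ref.components_))
        assert ours <= theirs * 1.10 + 1e-9

    def test_invalid_rank_rejected(self):
        model = _model_from_phi(np.full((4, 10), 0.1))
        with pytest.raises(ValueError):
            fit_themes(model, T=5)
        with pytest.raises(ValueError):
            fit_themes(model, T=1)


class TestMessageThemeLoad:
    def test_single_token_identity(self, block_themes):
        idx = {f"v{i}": i for i in range(40)}
        load = message_theme_distribution(["v3"], block_themes, idx)
        assert np.allclose(load.p_theme, block_themes.theme_given_word[3], atol=1e-12)

    def test_uniform_posterior_gives_uniform_load_and_tiebreak_zero(self):
        tm = ThemeModel(
            T=3, W=np.ones((2, 3)), H=np.ones((3, 4)),
            word_given_theme=np.full((3, 4), 0.25), theme_prior=np.full(3, 1 / 3),
            theme_given_word=np.full((4, 3), 1 / 3), names=["a", "b", "c"],
            seed=0, residuals=np.empty(0),
        )
        load = message_theme_distribution(["v0", "v2"], tm, {f"v{i}": i for i in range(4)})
        assert np.allclose(load.p_theme, 1 / 3, atol=1e-12)
        assert load.assigned_theme == 0

    def test_matches_bruteforce_sum(self, block_themes):
        idx = {f"v{i}": i for i in range(40)}
        msg = ["v1", "v21", "v21", "v5", "v30"]
        load = message_theme_distribution(msg, block_themes, idx)
        expected = np.zeros(2)
        for tok in msg:
            expected += block_themes.theme_given_word[idx[tok]] / len(msg)
        assert np.allclose(load.p_theme, expected, atol=1e-12)

    def test_out_of_vocabulary_is_none(self, block_themes):
        assert message_theme_distribution(["zzz"], block_themes, {}) is None


def _loads_frame(assignments):
    return pd.DataFrame(
        {"assigned_theme": assignments}, index=[f"m{i}" for i in range(len(assignments))]
    )


class TestThemeGivenDisease:
    def test_counts_and_percentages(self):
        loads = _loads_frame([0, 0, 1, 1, 1, 0])
        labels = pd.DataFrame({"d": [1, 1, 1, 1, 0, 0]}, index=loads.index)
        stats = theme_given_disease(loads, labels)
        d = stats.set_index("theme")
        assert d.loc[0, "n"] == 2 and d.loc[0, "p_pct"] == 50.0
        assert d.loc[1, "n"] == 2 and d.loc[1, "p_pct"] == 50.0

    def test_degenerate_single_theme(self):
        loads = _loads_frame([1, 1, 1])
        labels = pd.DataFrame({"d": [1, 1, 1]}, index=loads.index)
        stats = theme_given_disease(loads, labels).set_index("theme")
        assert stats.loc[1, "p_pct"] == 100.0
        assert stats.loc[0, "p_pct"] == 0.0

    def test_zero_message_disease_omitted(self):
        loads = _loads_frame([0, 1])
        labels = pd.DataFrame({"d": [1, 1], "empty": [0, 0]}, index=loads.index)
        stats = theme_given_disease(loads, labels)
        assert set(stats["disease"]) == {"d"}


def _pmi_from_counts(counts):
    """counts: {(disease, theme): n} -> stats frame through the package ops."""
    rows = [(d, t, n, 0) for (d, t), n in counts.items()]
    df = pd.DataFrame(rows, columns=["disease", "theme", "n", "n_disease"])
    df["n_disease"] = df.groupby("disease")["n"].transform("sum")
    df["p_pct"] = 100.0 * df["n"] / df["n_disease"]
    return pmi_disease_theme(df)


class TestPmi:
    def test_independent_table_gives_zero(self):
        # joint counts exactly proportional to the product of marginals
        counts = {}
        for i, nd in enumerate([100, 300]):
            for j, pt in enumerate([0.25, 0.75]):
                counts[(f"d{i}", j)] = nd * pt
        stats = _pmi_from_counts(counts)
        assert np.allclose(stats["pmi"], 0.0, atol=1e-12)

    def test_doubled_conditional_gives_ln2(self):
        # p(t|d0) = 0.5 while p(t) overall = 0.25  =>  PMI = ln 2
        counts = {("d0", 0): 50, ("d0", 1): 50, ("d1", 0): 25, ("d1", 1): 175}
        stats = _pmi_from_counts(counts).set_index(["disease", "theme"])
        assert stats.loc[("d0", 0), "pmi"] == pytest.approx(math.log(2), abs=1e-12)

    def test_two_by_two_hand_evaluation(self):
        counts = {("d", 0): 30, ("d", 1): 70, ("other", 0): 100, ("other", 1): 800}
        stats = _pmi_from_counts(counts).set_index(["disease", "theme"])
        expected = math.log((30 / 1000) / ((100 / 1000) * (130 / 1000)))
        assert stats.loc[("d", 0), "pmi"] == pytest.approx(expected, abs=1e-12)

    def test_configurable_base(self):
        counts = {("d0", 0): 50, ("d0", 1): 50, ("d1", 0): 25, ("d1", 1): 175}
        stats = pmi_disease_theme(_pmi_from_counts(counts).drop(columns="pmi"), base=2).set_index(
            ["disease", "theme"]
        )
        assert stats.loc[("d0", 0), "pmi"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_joint_count_is_na(self):
        counts = {("d", 0): 0, ("d", 1): 10, ("e", 0): 5, ("e", 1): 5}
        stats = _pmi_from_counts(counts).set_index(["disease", "theme"])
        assert math.isnan(stats.loc[("d", 0), "pmi"])

    def test_sign_iff_overrepresentation(self):
        rng = np.random.default_rng(11)
        counts = {
            (f"d{i}", t): int(rng.integers(1, 50)) for i in range(4) for t in range(3)
        }
        stats = _pmi_from_counts(counts)
        N = stats["n"].sum()
        for _, row in stats.iterrows():
            p_t = stats.loc[stats["theme"] == row["theme"], "n"].sum() / N
            over = row["n"] / row["n_disease"] > p_t
            assert (row["pmi"] > 0) == over

    def test_joint_marginal_consistency(self):
        rng = np.random.default_rng(13)
        counts = {(f"d{i}", t): int(rng.integers(1, 50)) for i in range(3) for t in range(4)}
        stats = _pmi_from_counts(counts)
        N = stats["n"].sum()
        for d, g in stats.groupby("disease"):
            assert g["n"].sum() / N == pytest.approx(g["n_disease"].iloc[0] / N)
        assert stats["n"].sum() / N == pytest.approx(1.0)
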