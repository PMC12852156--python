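import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import punishstrat as ps
from punishstrat.classify import DECISION_COLUMNS
from punishstrat.model import ConvergenceWarning, _softmax


def _frame(vectors, country="UK"):
    frame = pd.DataFrame(vectors, columns=DECISION_COLUMNS, dtype=float)
    frame.insert(0, "country", country)
    frame.insert(0, "id", [f"p{i}" for i in range(len(frame))])
    return frame


# -- conditional probabilities ---------------------------------------------

def test_conditional_probs_contamination(matrix):
    table = ps.conditional_probs(matrix, 0.05)
    np.testing.assert_array_equal(table.row("never_punish"), np.full(12, 0.05))
    eg = table.row("egalitarian")
    punish_idx = [DECISION_COLUMNS.index(c) for c in ("E_steal", "F_steal")]
    assert all(eg[j] == 0.95 for j in punish_idx)
    assert sum(eg == 0.05) == 10
    np.testing.assert_array_equal(table.row("random_choice"), np.full(12, 0.5))
    zero = ps.conditional_probs(matrix, 0.0)
    assert set(np.unique(zero.probs)) == {0.0, 0.5, 1.0}
    with pytest.raises(ValueError):
        ps.conditional_probs(matrix, 0.5)


def test_mixture_theta(matrix, table):
    S = table.n_strategies
    point = np.zeros(S)
    point[table.labels.index("never_punish")] = 1.0
    np.testing.assert_allclose(ps.mixture_theta(point, table), np.full(12, 0.05))
    rand = np.zeros(S)
    rand[table.labels.index("random_choice")] = 1.0
    np.testing.assert_allclose(ps.mixture_theta(rand, table), np.full(12, 0.5))
    # uniform mix at delta=0: brute-force column sum
    zero = ps.conditional_probs(matrix, 0.0)
    uniform = np.full(S, 1 / S)
    j = DECISION_COLUMNS.index("E_steal")
    punishers = sum(matrix.values[:, j])
    assert ps.mixture_theta(uniform, zero, j) == pytest.approx((punishers + 0.5) / S)
    theta = ps.mixture_theta(uniform, table)
    assert np.all(theta >= table.probs.min(axis=0)) \
        and np.all(theta <= table.probs.max(axis=0))
    with pytest.raises(ValueError):
        ps.mixture_theta(np.full(S, 0.5), table)


# -- likelihood -------------------------------------------------------------

def _naive_decision_loglik(data, p_by_country, table):
    """Independent oracle: explicit double loop over participants and
    decisions."""
    total = 0.0
    for _, row in data.iterrows():
        p = np.asarray(p_by_country[row["country"]])
        for j, col in enumerate(DECISION_COLUMNS):
            y = row[col]
            if pd.isna(y):
                continue
            theta = float(sum(p[s] * table.probs[s, j]
                              for s in range(table.n_strategies)))
            total += math.log(theta if y == 1 else 1 - theta)
    return total


def test_decision_loglik_matches_naive_double_loop(matrix, table):
    rng = np.random.default_rng(0)
    vectors = rng.integers(0, 2, size=(10, 12)).astype(float)
    data = _frame(vectors)
    data.loc[3, "B_steal"] = np.nan
    p = rng.dirichlet(np.ones(table.n_strategies))
    value = ps.log_likelihood(data, {"UK": p}, table, mode="decision")
    oracle = _naive_decision_loglik(data, {"UK": p}, table)
    assert value == pytest.approx(oracle, abs=1e-10)


def test_point_mass_closed_form(table):
    data = _frame([np.zeros(12)])
    point = np.zeros(table.n_strategies)
    point[table.labels.index("never_punish")] = 1.0
    expected = 12 * math.log(0.95)
    for mode in ("decision", "participant"):
        assert ps.log_likelihood(data, point, table, mode=mode) \
            == pytest.approx(expected, abs=1e-12)


def test_missing_decision_contributes_nothing(table):
    rng = np.random.default_rng(1)
    data = _frame(rng.integers(0, 2, size=(4, 12)).astype(float))
    p = rng.dirichlet(np.ones(table.n_strategies))
    with_all = {m: ps.log_likelihood(data, p, table, mode=m)
                for m in ("decision", "participant")}
    incomplete = data.copy()
    incomplete.loc[2, "D_nosteal"] = np.nan
    dropped = data.copy()
    dropped.loc[2, "D_nosteal"] = 1 - dropped.loc[2, "D_nosteal"]
    for mode in ("decision", "participant"):
        val = ps.log_likelihood(incomplete, p, table, mode=mode)
        assert val != with_all[mode]
        # the missing cell's contribution is gone, not imputed
        y = data.loc[2, "D_nosteal"]
        j = DECISION_COLUMNS.index("D_nosteal")
        if mode == "decision":
            theta = float(p @ table.probs[:, j])
            contrib = math.log(theta if y == 1 else 1 - theta)
            assert val == pytest.approx(with_all[mode] - contrib, abs=1e-10)


def test_covariate_with_zero_slope_reduces_to_base(table):
    """Per-participant membership from softmax(alpha + 0*x) gives exactly
    the country-level likelihood."""
    rng = np.random.default_rng(2)
    data = _frame(rng.integers(0, 2, size=(8, 12)).astype(float))
    alpha = rng.normal(size=table.n_strategies)
    p = _softmax(alpha[None, :])[0]
    per_participant = np.tile(p, (8, 1))
    for mode in ("decision", "participant"):
        a = ps.log_likelihood(data, {"UK": p}, table, mode=mode)
        b = ps.log_likelihood(data, per_participant, table, mode=mode)
        assert a == b


# -- softmax properties -----------------------------------------------------

@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(-20, 20), min_size=10, max_size=10),
       st.floats(-50, 50))
def test_softmax_simplex_and_shift_invariance(alpha, shift):
    alpha = np.asarray(alpha)
    p = _softmax(alpha[None, :])[0]
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p >= 0)
    shifted = _softmax((alpha + shift)[None, :])[0]
    np.testing.assert_allclose(p, shifted, atol=1e-12)


# -- fitting ----------------------------------------------------------------

@pytest.fixture(scope="module")
def never_punish_fit(matrix):
    spec = ps.GeneratorSpec(sample_sizes={"UK": 300},
                            frequencies={"UK": {"never_punish": 1.0}},
                            delta=0.05, seed=21)
    data, _ = ps.sample_dataset(spec, matrix)
    config = ps.ModelConfig(samples=1500, warmup=700, seed=21)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        draws = ps.fit_base(data, config, matrix)
    return draws


def test_fit_base_contract(never_punish_fit):
    draws = never_punish_fit
    chains, ndraws, G, S = draws.p.shape
    assert chains == 4 and G == 1 and S == 10
    np.testing.assert_allclose(draws.p.sum(axis=-1), 1.0, atol=1e-9)
    assert set(draws.diagnostics) >= {"rhat_max", "ess_min", "converged"}


def test_pure_cohort_concentrates_on_true_strategy(never_punish_fit):
    draws = never_punish_fit
    med = np.median(draws.p_flat()[:, 0, :], axis=0)
    best = draws.strategy_labels[int(np.argmax(med))]
    assert best == "never_punish"
    assert med[draws.strategy_labels.index("never_punish")] > 0.8


def test_membership_probabilities(never_punish_fit, matrix, table):
    draws = never_punish_fit
    member = ps.membership_probabilities(np.zeros(12), draws)
    assert member.sum() == pytest.approx(1.0, abs=1e-9)
    assert member.idxmax() == "never_punish"

    # brute-force oracle at uniform p: membership equals likelihood share
    vec = matrix.row("egalitarian").astype(float)
    S = table.n_strategies
    lik = np.array([
        np.prod([table.probs[s, j] if vec[j] == 1 else 1 - table.probs[s, j]
                 for j in range(12)])
        for s in range(S)
    ])
    uniform_draws = ps.PosteriorDraws(
        strategy_labels=list(table.labels), groups=["UK"],
        alpha=np.zeros((1, 5, 1, S)), p=np.full((1, 5, 1, S), 1 / S),
        diagnostics={}, config=ps.ModelConfig(), matrix=matrix,
    )
    member = ps.membership_probabilities(vec, uniform_draws)
    np.testing.assert_allclose(member.to_numpy(), lik / lik.sum(), atol=1e-12)


def test_summarize_shapes_and_degenerate_intervals(never_punish_fit):
    summary = ps.summarize(never_punish_fit)
    p_rows = summary[summary["param"] == "p"]
    assert len(p_rows) == 10
    degenerate = ps.PosteriorDraws(
        strategy_labels=["a", "b"], groups=["UK"],
        alpha=np.zeros((1, 4, 1, 2)), p=np.full((1, 4, 1, 2), 0.5),
        diagnostics={}, config=ps.ModelConfig(),
        matrix=ps.base_matrix(),
    )
    d = ps.summarize(degenerate)
    assert (d["q2.5"] == d["q97.5"]).all()


def test_fit_rejects_empty_and_bad_config():
    with pytest.raises(ValueError):
        ps.fit_base(pd.DataFrame())
    with pytest.raises(ValueError):
        ps.ModelConfig(samples=100, warmup=100)
    with pytest.raises(ValueError):
        ps.ModelConfig(delta=0.7)


def test_categorical_predictor_gets_level_intercepts(matrix):
    spec = ps.GeneratorSpec(sample_sizes={"UK": 160},
                            frequencies={"UK": {"never_punish": 0.7,
                                                "egalitarian": 0.3}},
                            delta=0.05, seed=31)
    data, _ = ps.sample_dataset(spec, matrix)
    data["religious"] = np.where(np.arange(len(data)) % 2 == 0, "yes", "no")
    config = ps.ModelConfig(samples=900, warmup=400, seed=31,
                            ess_min=100.0, rhat_max=1.05)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        draws = ps.fit_predictor(data, "religious", config, matrix)
    assert sorted(draws.groups) == ["UK:no", "UK:yes"]
    assert draws.beta is None


def test_continuous_predictor_standardized_slopes(matrix):
    spec = ps.GeneratorSpec(sample_sizes={"UK": 150},
                            frequencies={"UK": {"never_punish": 1.0}},
                            delta=0.05, seed=33)
    data, _ = ps.sample_dataset(spec, matrix)
    rng = np.random.default_rng(33)
    data["svo"] = rng.normal(10, 4, size=len(data))
    data.loc[0, "svo"] = np.nan
    config = ps.ModelConfig(samples=700, warmup=300, seed=33,
                            ess_min=50.0, rhat_max=1.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        draws = ps.fit_predictor(data, "svo", config, matrix)
    assert draws.beta is not None and draws.beta.shape[-2:] == (1, 10)
    mean, sd = draws.covariate_scaling
    assert mean == pytest.approx(np.nanmean(data["svo"].iloc[1:]), rel=1e-6)
    assert draws.diagnostics["n_dropped_missing_covariate"] == 1
    with pytest.raises(ValueError):
        data2 = data.dropna(subset=["svo"]).copy()
        data2["flat"] = 1.0
        ps.fit_predictor(data2, "flat", config, matrix)


def test_draws_round_trip_to_frame(never_punish_fit, tmp_path):
    frame = never_punish_fit.to_frame()
    assert {"chain", "draw", "group", "strategy", "p", "alpha"} <= set(frame.columns)
    path = tmp_path / "draws.csv"
    never_punish_fit.save(path)
    assert len(pd.read_csv(path)) == len(frame)
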