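import numpy as np
import pandas as pd
import pytest

import punishstrat as ps
from punishstrat.classify import DECISION_COLUMNS
from punishstrat.simulate import DEFAULT_VALIDATION_MIX


def test_noiseless_point_mass_is_exact(matrix):
    spec = ps.GeneratorSpec(sample_sizes={"UK": 50},
                            frequencies={"UK": {"egalitarian": 1.0}},
                            delta=0.0, seed=1)
    data, truth = ps.sample_dataset(spec, matrix)
    expected = matrix.row("egalitarian")
    assert (data[DECISION_COLUMNS].to_numpy() == expected).all()
    assert (truth["strategy"] == "egalitarian").all()


def test_error_rate_matches_delta(matrix):
    spec = ps.GeneratorSpec(sample_sizes={"UK": 10_000},
                            frequencies={"UK": {"never_punish": 1.0}},
                            delta=0.05, seed=2)
    data, _ = ps.sample_dataset(spec, matrix)
    rate = data[DECISION_COLUMNS].to_numpy().mean()
    se = np.sqrt(0.05 * 0.95 / (10_000 * 12))
    assert abs(rate - 0.05) < 3 * se


def test_conditional_rates_match_table(matrix, table):
    """Conditional on a deterministic true strategy, each decision's punish
    rate converges to the contaminated table entry."""
    spec = ps.GeneratorSpec(sample_sizes={"UK": 4000},
                            frequencies={"UK": {"revenge": 0.5, "antisocial": 0.5}},
                            delta=0.05, seed=7)
    data, truth = ps.sample_dataset(spec, matrix)
    for label in ("revenge", "antisocial"):
        block = data[truth["strategy"] == label][DECISION_COLUMNS].to_numpy()
        empirical = block.mean(axis=0)
        np.testing.assert_allclose(empirical, table.row(label), atol=0.03)


def test_seed_reproducibility(matrix):
    spec = ps.paper_validation_spec(seed=5)
    d1, t1 = ps.sample_dataset(spec, matrix)
    d2, t2 = ps.sample_dataset(spec, matrix)
    pd.testing.assert_frame_equal(d1, d2)
    pd.testing.assert_frame_equal(t1, t2)


def test_validation_template():
    spec = ps.paper_validation_spec()
    assert sum(spec.sample_sizes.values()) == 100
    assert spec.delta == 0.05
    assert sum(next(iter(spec.frequencies.values())).values()) == pytest.approx(1)


def test_exact_classification_rate_echo(matrix):
    """Under delta=0.05, a deterministic-strategy participant matches their
    own row exactly with probability 0.95^12 ~ 0.54; the realized exact-
    classification rate should sit in a loose band around that."""
    mix = {k: v for k, v in DEFAULT_VALIDATION_MIX.items() if k != "random_choice"}
    total = sum(mix.values())
    mix = {k: v / total for k, v in mix.items()}
    spec = ps.GeneratorSpec(sample_sizes={"UK": 4000}, frequencies={"UK": mix},
                            delta=0.05, seed=11)
    data, _ = ps.sample_dataset(spec, matrix)
    labels = ps.classify.classify_dataset(data, matrix)
    rate = (labels != "NA").mean()
    # above 0.95**12 because a corrupted vector can still match another row
    assert 0.50 < rate < 0.65


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        ps.GeneratorSpec(sample_sizes={"UK": 0},
                         frequencies={"UK": {"never_punish": 1.0}})
    with pytest.raises(ValueError):
        ps.GeneratorSpec(sample_sizes={"UK": 10},
                         frequencies={"UK": {"never_punish": 0.5}})
    with pytest.raises(ValueError):
        ps.GeneratorSpec(sample_sizes={"UK": 10},
                         frequencies={"UK": {"never_punish": 1.0}}, delta=0.5)


def test_spec_yaml_round_trip():
    spec = ps.paper_validation_spec(seed=3)
    again = ps.GeneratorSpec.from_yaml(spec.to_yaml())
    assert again == spec


def test_covariate_shifts_membership(matrix):
    """A strong positive never-punish slope makes punishment decrease in x."""
    S = matrix.n_strategies + 1
    alpha = [0.0] * S
    beta = [0.0] * S
    beta[matrix.labels.index("never_punish")] = 3.0
    cov = ps.CovariateSpec(name="svo", alpha={"UK": alpha}, beta={"UK": beta})
    spec = ps.GeneratorSpec(sample_sizes={"UK": 1500}, delta=0.05, seed=13,
                            covariate=cov)
    data, truth = ps.sample_with_covariate(spec, matrix)
    assert "svo" in data.columns
    total_punish = data[DECISION_COLUMNS].sum(axis=1)
    rho = pd.Series(total_punish).corr(data["svo"], method="spearman")
    assert rho < -0.3


def test_covariate_null_reduces_to_marginal(matrix):
    S = matrix.n_strategies + 1
    alpha = [0.0] * S
    cov = ps.CovariateSpec(name="x", alpha={"UK": alpha}, beta={"UK": [0.0] * S})
    spec = ps.GeneratorSpec(sample_sizes={"UK": 3000}, delta=0.05, seed=17,
                            covariate=cov)
    _, truth = ps.sample_with_covariate(spec, matrix)
    freqs = truth["strategy"].value_counts(normalize=True)
    np.testing.assert_allclose(freqs, 1 / S, atol=0.03)
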