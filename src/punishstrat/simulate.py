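"""Synthetic decision cohorts with the exact structure the model assumes.

Each simulated participant is assigned a latent strategy from a per-country
frequency simplex over the deterministic strategies plus random choice.
Deterministic-strategy participants emit each prescribed decision flipped
independently with implementation-error probability delta; random-choice
participants flip a fair coin on every decision. Ground-truth strategy
labels are returned (and written) separately from the decision table so
that fitting code cannot see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .strategies import PredictionMatrix, RANDOM_CHOICE, base_matrix
from .classify import DECISION_COLUMNS

__all__ = [
    "CovariateSpec",
    "GeneratorSpec",
    "sample_dataset",
    "sample_with_covariate",
    "paper_validation_spec",
    "DEFAULT_VALIDATION_MIX",
]

#: Package-default strategy mix for validation cohorts. This is not taken
#: from any empirical estimate; it is a documented, realistic mix in which
#: never-punish dominates, the inequality-averse strategies come next, and
#: every strategy (including random choice) has non-zero support.
DEFAULT_VALIDATION_MIX: dict[str, float] = {
    "deterrent": 0.03,
    "norm_enforcing": 0.05,
    "revenge": 0.03,
    "avoid_DI": 0.08,
    "egalitarian": 0.12,
    "seek_AI": 0.04,
    "competitive": 0.03,
    "antisocial": 0.02,
    "never_punish": 0.45,
    RANDOM_CHOICE: 0.15,
}


@dataclass
class CovariateSpec:
    """A continuous covariate linked to membership through softmax regression.

    ``alpha`` and ``beta`` map country -> per-strategy vectors (aligned to
    the generator's strategy order); membership probabilities for
    participant i are softmax(alpha[c] + beta[c] * x_i) with x_i drawn from
    a standard normal unless another (loc, scale) is given.
    """

    name: str
    alpha: dict[str, list[float]]
    beta: dict[str, list[float]]
    loc: float = 0.0
    scale: float = 1.0


@dataclass
class GeneratorSpec:
    """Configuration of a synthetic cohort.

    ``frequencies`` maps country -> {strategy: probability} over the full
    strategy set (deterministic strategies plus ``random_choice``); each
    simplex must sum to 1. When a covariate is present the frequencies are
    ignored in favour of the covariate's softmax coefficients.
    """

    sample_sizes: dict[str, int]
    frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    delta: float = 0.05
    seed: int = 0
    covariate: CovariateSpec | None = None

    def __post_init__(self) -> None:
        for country, n in self.sample_sizes.items():
            if n < 1:
                raise ValueError(f"sample size for {country!r} must be >= 1")
        if self.covariate is None:
            for country in self.sample_sizes:
                if country not in self.frequencies:
                    raise ValueError(f"no frequencies for country {country!r}")
                total = sum(self.frequencies[country].values())
                if not np.isclose(total, 1.0, atol=1e-8):
                    raise ValueError(
                        f"frequencies for {country!r} sum to {total}, not 1"
                    )
                if any(v < 0 for v in self.frequencies[country].values()):
                    raise ValueError("frequencies must be non-negative")
        if not 0 <= self.delta < 0.5:
            raise ValueError("delta must lie in [0, 0.5)")

    # YAML round-trip -------------------------------------------------------

    def to_yaml(self) -> str:
        payload = {
            "sample_sizes": dict(self.sample_sizes),
            "frequencies": {c: dict(f) for c, f in self.frequencies.items()},
            "delta": float(self.delta),
            "seed": int(self.seed),
        }
        if self.covariate is not None:
            payload["covariate"] = {
                "name": self.covariate.name,
                "alpha": {c: list(map(float, v)) for c, v in self.covariate.alpha.items()},
                "beta": {c: list(map(float, v)) for c, v in self.covariate.beta.items()},
                "loc": float(self.covariate.loc),
                "scale": float(self.covariate.scale),
            }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorSpec":
        raw = yaml.safe_load(text)
        cov = raw.pop("covariate", None)
        spec = cls(**raw, covariate=CovariateSpec(**cov) if cov else None)
        return spec


def _strategy_labels(matrix: PredictionMatrix) -> list[str]:
    return matrix.labels + [RANDOM_CHOICE]


def _emit_decisions(rng: np.random.Generator, strategy_idx: np.ndarray,
                    matrix: PredictionMatrix, delta: float) -> np.ndarray:
    """Decisions for participants with strategy indices into labels+random."""
    n = strategy_idx.size
    n_det = matrix.n_strategies
    # float so decision columns round-trip through the CSV dialect, which
    # uses NaN for missing
    decisions = np.empty((n, matrix.n_decisions), dtype=float)
    is_random = strategy_idx == n_det
    # deterministic rows: prescribed bit flipped w.p. delta
    det = ~is_random
    prescribed = matrix.values[strategy_idx[det]]
    flips = rng.random(prescribed.shape) < delta
    decisions[det] = np.where(flips, 1 - prescribed, prescribed)
    decisions[is_random] = (
        rng.random((int(is_random.sum()), matrix.n_decisions)) < 0.5
    ).astype(float)
    return decisions


def sample_dataset(spec: GeneratorSpec,
                   matrix: PredictionMatrix | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort from per-country strategy frequencies.

    Returns ``(data, truth)``: the wide decision table (id, country, twelve
    decision columns) and a sidecar frame with each participant's true
    strategy. Fixed seeds reproduce both exactly.
    """
    if matrix is None:
        matrix = base_matrix()
    labels = _strategy_labels(matrix)
    rng = np.random.default_rng(spec.seed)
    frames, truths = [], []
    for country in sorted(spec.sample_sizes):
        n = spec.sample_sizes[country]
        freq_map = spec.frequencies[country]
        unknown = set(freq_map) - set(labels)
        if unknown:
            raise ValueError(f"frequencies name unknown strategies: {sorted(unknown)}")
        freqs = np.array([freq_map.get(lab, 0.0) for lab in labels])
        strategy_idx = rng.choice(len(labels), size=n, p=freqs)
        decisions = _emit_decisions(rng, strategy_idx, matrix, spec.delta)
        ids = [f"{country}_{i:05d}" for i in range(n)]
        frame = pd.DataFrame(decisions, columns=DECISION_COLUMNS)
        frame.insert(0, "country", country)
        frame.insert(0, "id", ids)
        frames.append(frame)
        truths.append(pd.DataFrame(
            {"id": ids, "country": country,
             "strategy": [labels[s] for s in strategy_idx]}
        ))
    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    return data, truth


def sample_with_covariate(spec: GeneratorSpec,
                          matrix: PredictionMatrix | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort whose membership depends on a continuous covariate.

    Participant i in country c gets membership simplex
    softmax(alpha[c] + beta[c] * x_i); the covariate value is included in
    the returned data under the covariate's name, and the truth sidecar
    also records x.
    """
    if spec.covariate is None:
        raise ValueError("spec has no covariate")
    if matrix is None:
        matrix = base_matrix()
    labels = _strategy_labels(matrix)
    cov = spec.covariate
    rng = np.random.default_rng(spec.seed)
    frames, truths = [], []
    for country in sorted(spec.sample_sizes):
        n = spec.sample_sizes[country]
        alpha = np.asarray(cov.alpha[country], dtype=float)
        beta = np.asarray(cov.beta[country], dtype=float)
        if alpha.shape != (len(labels),) or beta.shape != (len(labels),):
            raise ValueError(
                f"alpha/beta for {country!r} must have length {len(labels)}"
            )
        x = rng.normal(cov.loc, cov.scale, size=n)
        eta = alpha[None, :] + beta[None, :] * x[:, None]
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        strategy_idx = np.array(
            [rng.choice(len(labels), p=p[i]) for i in range(n)]
        )
        decisions = _emit_decisions(rng, strategy_idx, matrix, spec.delta)
        ids = [f"{country}_{i:05d}" for i in range(n)]
        frame = pd.DataFrame(decisions, columns=DECISION_COLUMNS)
        frame.insert(0, "country", country)
        frame.insert(0, "id", ids)
        frame[cov.name] = x
        frames.append(frame)
        truths.append(pd.DataFrame(
            {"id": ids, "country": country,
             "strategy": [labels[s] for s in strategy_idx],
             cov.name: x}
        ))
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True)


def paper_validation_spec(seed: int = 0) -> GeneratorSpec:
    """The n = 100, delta = 0.05, single-country validation template.

    The frequency mix is the package's documented default
    (:data:`DEFAULT_VALIDATION_MIX`); the validation design fixes only the
    sample size and error rate, not a particular mix.
    """
    return GeneratorSpec(
        sample_sizes={"simulated": 100},
        frequencies={"simulated": dict(DEFAULT_VALIDATION_MIX)},
        delta=0.05,
        seed=seed,
    )
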