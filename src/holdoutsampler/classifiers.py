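"""The two base learners sampled inside each holdout.

Extreme Learning Machine (ELM)
    A single-hidden-layer network whose hidden weights are random and never
    trained.  With hidden outputs h_i(x) = g(w_i . x + b_i), the model is
    f(x) = sum_i beta_i h_i(x); only the output weights beta are fit, as the
    minimum-norm least-squares solution beta = pinv(H) y of H beta = y via the
    Moore-Penrose pseudoinverse.  Targets are coded -1/+1 and the decision
    threshold is 0.  Inputs are standardized with the training-bag mean and
    standard deviation so the sigmoid/sinusoid activations stay responsive;
    the constants are stored in the model.

Random Forest (RF)
    Breiman bagging of decision trees: each tree is grown to purity on a
    bootstrap resample of the training bag with sqrt(d) random features per
    split; the ensemble score is the fraction of trees voting *deleterious*.
    The fitting itself is delegated to scikit-learn's RandomForestClassifier.

Both learners are deterministic given the seed carried by their
:class:`ClassifierSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier

from .errors import ContractError

#: rcond passed to the pseudoinverse: singular values below rcond * sigma_max
#: are treated as zero, giving the minimum-norm least-squares solution.
PINV_RCOND = 1e-10

ACTIVATIONS = {
    "sigmoid": expit,
    "sinusoid": np.sin,
    "linear": lambda z: z,
}


@dataclass(frozen=True)
class HyperRanges:
    """Hyperparameter ranges the spec sampler draws from."""

    elm_hidden: tuple[int, int] = (10, 200)
    elm_activations: tuple[str, ...] = ("sigmoid", "sinusoid", "linear")
    rf_trees: tuple[int, int] = (100, 100)
    kinds: tuple[str, ...] = ("elm", "rf")

    def validate(self) -> None:
        if self.elm_hidden[0] > self.elm_hidden[1] or self.elm_hidden[0] < 1:
            raise ContractError(f"invalid ELM hidden range {self.elm_hidden}")
        if self.rf_trees[0] > self.rf_trees[1] or self.rf_trees[0] < 1:
            raise ContractError(f"invalid RF tree range {self.rf_trees}")
        if not self.kinds or not set(self.kinds) <= {"elm", "rf"}:
            raise ContractError(f"invalid classifier kinds {self.kinds}")
        if not self.elm_activations or not set(self.elm_activations) <= set(ACTIVATIONS):
            raise ContractError(f"invalid activations {self.elm_activations}")


@dataclass(frozen=True)
class ClassifierSpec:
    """One randomly sampled classifier architecture."""

    kind: str  # "elm" | "rf"
    elm_hidden: int
    elm_activation: str
    rf_trees: int
    seed: int


def sample_spec(rng: np.random.Generator, ranges: HyperRanges = HyperRanges()) -> ClassifierSpec:
    """Draw a random architecture: kind uniform over the allowed kinds, then
    ELM hidden-node count and activation (or RF tree count) uniform over their
    ranges.  Reproducible given *rng*."""
    ranges.validate()
    kind = str(rng.choice(list(ranges.kinds)))
    lo, hi = ranges.elm_hidden
    hidden = int(rng.integers(lo, hi + 1))
    activation = str(rng.choice(list(ranges.elm_activations)))
    tlo, thi = ranges.rf_trees
    trees = int(rng.integers(tlo, thi + 1))
    seed = int(rng.integers(0, 2**31 - 1))
    return ClassifierSpec(
        kind=kind, elm_hidden=hidden, elm_activation=activation, rf_trees=trees, seed=seed
    )


@dataclass
class ELMModel:
    """A fitted extreme learning machine."""

    W: np.ndarray  # (L, d) random hidden weights
    b: np.ndarray  # (L,) random biases
    beta: np.ndarray  # (L,) output weights, min-norm least squares
    activation: str
    mean: np.ndarray  # (d,) training-bag standardization
    sd: np.ndarray  # (d,)
    class_threshold: float = 0.0

    def hidden(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.W.shape[1]:
            raise ContractError(
                f"expected {self.W.shape[1]} attribute columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        Z = (X - self.mean) / self.sd
        return ACTIVATIONS[self.activation](Z @ self.W.T + self.b)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (real-valued scores, 0/1 classes); class 1 iff score > threshold."""
        scores = self.hidden(X) @ self.beta
        return scores, (scores > self.class_threshold).astype(int)


def elm_train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator | None = None,
) -> ELMModel:
    """Fit an ELM on targets y in {-1, +1}.

    Hidden weights and biases are i.i.d. uniform on [-1, 1]; the output
    weights solve H beta = y in the least-squares sense via the Moore-Penrose
    pseudoinverse (minimum-norm solution).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ContractError(f"need a non-empty 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ContractError("non-finite entries in X")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ContractError("ELM targets must be coded -1/+1")
    if spec.elm_hidden < 1:
        raise ContractError("need at least one hidden node")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n, d = X.shape
    L = spec.elm_hidden
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns pass through unscaled
    W = rng.uniform(-1.0, 1.0, size=(L, d))
    b = rng.uniform(-1.0, 1.0, size=L)
    H = ACTIVATIONS[spec.elm_activation](((X - mean) / sd) @ W.T + b)
    beta = np.linalg.pinv(H, rcond=PINV_RCOND) @ y
    return ELMModel(W=W, b=b, beta=beta, activation=spec.elm_activation, mean=mean, sd=sd)


def elm_predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X)


@dataclass
class RFModel:
    """A fitted random forest; scores are per-tree vote fractions."""

    forest: RandomForestClassifier
    B: int
    class_threshold: float = 0.5
    tie_class: int = field(default=1)  # score == threshold -> deleterious

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.forest.n_features_in_:
            raise ContractError(
                f"expected {self.forest.n_features_in_} attribute columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        votes = np.zeros(X.shape[0])
        for tree in self.forest.estimators_:
            votes += (tree.predict(X) == 1.0)
        scores = votes / self.B
        classes = np.where(
            scores > self.class_threshold,
            1,
            np.where(scores == self.class_threshold, self.tie_class, 0),
        )
        return scores, classes.astype(int)


def rf_train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    rng: np.random.Generator | None = None,
) -> RFModel:
    """Fit a random forest of ``spec.rf_trees`` bootstrap trees on y in {0, 1}.

    Breiman defaults: Gini impurity, sqrt(d) features per split, trees grown
    to purity (no depth cap, minimum leaf 1).  Deterministic given spec.seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ContractError(f"need a non-empty 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ContractError("non-finite entries in X")
    if set(np.unique(y)) - {0, 1}:
        raise ContractError("RF targets must be coded 0/1")
    seed = spec.seed if rng is None else int(rng.integers(0, 2**31 - 1))
    forest = RandomForestClassifier(
        n_estimators=spec.rf_trees,
        criterion="gini",
        max_features="sqrt",
        min_samples_leaf=1,
        max_depth=None,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return RFModel(forest=forest, B=spec.rf_trees)


def rf_predict(model: RFModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X)


def fit_classifier(X: np.ndarray, y01: np.ndarray, spec: ClassifierSpec, rng=None):
    """Fit the learner named by *spec* on 0/1 labels; returns a model exposing
    ``predict(X) -> (scores, classes01)``."""
    y01 = np.asarray(y01, dtype=int)
    if spec.kind == "elm":
        return elm_train(X, 2.0 * y01 - 1.0, spec, rng)
    if spec.kind == "rf":
        return rf_train(X, y01, spec, rng)
    raise ContractError(f"unknown classifier kind {spec.kind!r}")
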