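"""The consensus holdout sampler.

The learning data are divided into many random *holdouts* (data bags): each
bag takes an independent 75/25 train/test split, a random subset of the
attribute groups, and a randomly sampled classifier architecture (ELM or RF).
After every bag is trained and tested, the bags whose test accuracy satisfies

    Acc_i > tau * Acc_max        (tau = 0.90 by default)

are selected; their (accuracy-weighted) vote is the consensus predictor used
for blind validation.  Sampling both the data and the architecture explores
the set of near-equivalent models instead of committing to a single fit, and
the posterior frequency of attribute groups among the selected bags measures
which groups carry the discriminative signal.

Randomness discipline: one master seed spawns per-holdout child streams by
counter (``numpy.random.SeedSequence(seed).spawn``), so enlarging
``n_holdouts`` never perturbs earlier holdouts, and refitting a holdout is
bit-reproducible from the seeds stored on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec, HyperRanges, fit_classifier, sample_spec
from .dataio import FeatureMatrix, GROUPS
from .discriminatory import MetricsReport, confusion_and_metrics
from .errors import ContractError

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SamplerConfig:
    """All tunables of the sampler, in one reproducible record."""

    n_holdouts: int = 100
    train_frac: float = 0.75
    selection_tau: float = 0.90
    k_folds: int = 5
    seed: int = 0
    ranges: HyperRanges = field(default_factory=HyperRanges)
    vote_rule: str = "accuracy_weighted"  # or "majority"
    class_threshold: float = 0.5
    group_include_prob: float = 0.5
    per_column_sampling: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ContractError(f"train_frac {self.train_frac} outside (0, 1)")
        if not 0 < self.selection_tau <= 1:
            raise ContractError(f"selection_tau {self.selection_tau} outside (0, 1]")
        if self.k_folds < 2:
            raise ContractError("k_folds must be >= 2")
        if self.n_holdouts < 1:
            raise ContractError("n_holdouts must be >= 1")
        if self.vote_rule not in ("accuracy_weighted", "majority"):
            raise ContractError(f"unknown vote rule {self.vote_rule!r}")
        self.ranges.validate()

    @classmethod
    def from_yaml(cls, path) -> "SamplerConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ranges_raw = raw.pop("ranges", None)
        ranges = HyperRanges(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in ranges_raw.items()}) if ranges_raw else HyperRanges()
        return cls(ranges=ranges, **raw)


@dataclass
class Holdout:
    """One data bag: split + attribute-group subset + sampled architecture."""

    index: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    groups: tuple[str, ...]
    spec: ClassifierSpec
    fit_seed: int  # stream for column draws, ELM weights, degenerate resampling
    per_column_prob: float = 0.0  # 0 disables per-column subsampling
    columns: tuple[str, ...] | None = None  # resolved at fit time
    model: object | None = None
    acc_train: float | None = None
    acc_test: float | None = None
    flagged: bool = False

    @property
    def fitted(self) -> bool:
        return self.model is not None and not self.flagged


def make_holdouts(
    n_samples: int,
    config: SamplerConfig,
    attribute_groups: tuple[str, ...] = GROUPS,
    rng: np.random.Generator | None = None,
) -> list[Holdout]:
    """Generate ``config.n_holdouts`` unfitted holdouts over *n_samples* rows.

    Each holdout draws an independent uniform train/test split at
    ``train_frac``, includes each attribute group independently with
    probability ``group_include_prob`` (redrawn if the subset comes out
    empty), and samples a classifier architecture.
    """
    if n_samples < 4:
        raise ContractError("need at least 4 samples to form a holdout")
    attribute_groups = tuple(attribute_groups)
    if not attribute_groups:
        raise ContractError("no attribute groups available")
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_holdouts)
    n_train = int(round(config.train_frac * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    holdouts = []
    for i, child in enumerate(children):
        h_rng = np.random.default_rng(child)
        perm = h_rng.permutation(n_samples)
        groups = _draw_groups(h_rng, attribute_groups, config.group_include_prob)
        spec = sample_spec(h_rng, config.ranges)
        fit_seed = int(h_rng.integers(0, 2**31 - 1))
        holdouts.append(
            Holdout(
                index=i,
                train_idx=np.sort(perm[:n_train]),
                test_idx=np.sort(perm[n_train:]),
                groups=groups,
                spec=spec,
                fit_seed=fit_seed,
                per_column_prob=0.5 if config.per_column_sampling else 0.0,
            )
        )
    return holdouts


def _draw_groups(rng, available, p):
    while True:
        mask = rng.random(len(available)) < p
        if mask.any():
            return tuple(g for g, m in zip(available, mask) if m)


def fit_holdout(holdout: Holdout, data: FeatureMatrix) -> Holdout:
    """Train the holdout's classifier on its bag and record both accuracies.

    A training bag containing a single class is resplit once from the
    holdout's own random stream; if still degenerate the holdout is flagged
    (excluded from selection) instead of raising.
    """
    cols = data.columns_for_groups(holdout.groups)
    if cols.size == 0:
        raise ContractError(
            f"holdout {holdout.index}: groups {holdout.groups} resolve to no columns"
        )
    if holdout.train_idx.max(initial=-1) >= data.n_samples:
        raise ContractError("holdout indices out of range for this matrix")

    rng = np.random.default_rng(holdout.fit_seed)
    if holdout.per_column_prob > 0:
        while True:
            mask = rng.random(cols.size) < holdout.per_column_prob
            if mask.any():
                break
        cols = cols[mask]
    train_idx, test_idx = holdout.train_idx, holdout.test_idx
    y = data.labels
    if len(np.unique(y[train_idx])) < 2:
        # one resample of the split, then give up
        n = data.n_samples
        perm = rng.permutation(n)
        n_train = len(train_idx)
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if len(np.unique(y[train_idx])) < 2:
            holdout.flagged = True
            return holdout
        holdout.train_idx, holdout.test_idx = train_idx, test_idx

    holdout.columns = tuple(data.attribute_names[j] for j in cols)
    Xtr = data.X[np.ix_(train_idx, cols)]
    Xte = data.X[np.ix_(test_idx, cols)]
    model = fit_classifier(Xtr, y[train_idx], holdout.spec, rng=rng)
    _, pred_tr = model.predict(Xtr)
    _, pred_te = model.predict(Xte)
    holdout.model = model
    holdout.acc_train = float(np.mean(pred_tr == y[train_idx]))
    holdout.acc_test = float(np.mean(pred_te == y[test_idx]))
    return holdout


@dataclass
class ConsensusModel:
    """The selected high-accuracy holdouts plus the voting rule."""

    selected: list[Holdout]
    selection_tau: float
    vote_rule: str = "accuracy_weighted"
    class_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.selected:
            raise ContractError("consensus requires at least one selected holdout")

    def predict(self, data: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Consensus scores in [0, 1] and 0/1 classes for every row of *data*.

        Each selected holdout votes with its own attribute subset; the score
        is the (accuracy-weighted) mean vote and the class is deleterious when
        the score reaches the threshold (ties go to deleterious).
        """
        votes = np.zeros(data.n_samples)
        total_w = 0.0
        name_to_j = {n: j for j, n in enumerate(data.attribute_names)}
        for h in self.selected:
            needed = h.columns
            if needed is None:
                raise ContractError(f"holdout {h.index} was never fitted")
            missing = sorted(set(needed) - set(name_to_j))
            if missing:
                raise ContractError(
                    f"holdout {h.index} needs missing column(s) {missing}"
                )
            cols = np.array([name_to_j[c] for c in needed], dtype=int)
            _, classes = h.model.predict(data.X[:, cols])
            w = h.acc_test if self.vote_rule == "accuracy_weighted" else 1.0
            votes += w * classes
            total_w += w
        scores = votes / total_w
        return scores, (scores >= self.class_threshold).astype(int)


def select_holdouts(
    holdouts: list[Holdout],
    tau: float = 0.90,
    *,
    vote_rule: str = "accuracy_weighted",
    class_threshold: float = 0.5,
) -> ConsensusModel:
    """Apply the selection rule Acc_i > tau * Acc_max over fitted holdouts.

    The strict inequality is applied exactly as stated; the maximum-accuracy
    holdout is always included (for tau < 1 and Acc_max > 0 it qualifies by
    itself; the degenerate Acc_max = 0 or tau = 1 cases fall back to the
    argmax by convention).
    """
    valid = [h for h in holdouts if h.fitted and h.acc_test is not None]
    if not valid:
        raise ContractError("no valid holdouts: all flagged or unfitted")
    acc_max = max(h.acc_test for h in valid)
    selected = [h for h in valid if h.acc_test > tau * acc_max]
    if not selected:
        selected = [max(valid, key=lambda h: h.acc_test)]
    return ConsensusModel(
        selected=selected,
        selection_tau=tau,
        vote_rule=vote_rule,
        class_threshold=class_threshold,
    )


def consensus_predict(cm: ConsensusModel, data: FeatureMatrix):
    return cm.predict(data)


def accuracy_summary(accs) -> dict[str, float]:
    """Mean / median / sd / interquartile range / min / max of accuracies.

    The interquartile range uses linear-interpolation quartiles; sd uses the
    n-1 denominator (0 for a single value).
    """
    a = np.asarray(list(accs), dtype=float)
    if a.size == 0:
        raise ContractError("no accuracies to summarize")
    q25, q75 = np.percentile(a, [25, 75])
    return {
        "mean": float(a.mean()),
        "median": float(np.median(a)),
        "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "iqr": float(q75 - q25),
        "min": float(a.min()),
        "max": float(a.max()),
        "n": int(a.size),
    }


def accuracy_cdf(holdouts: list[Holdout], stage: str = "test") -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Right-continuous empirical CDFs of holdout accuracy, overall and by kind.

    Returns ``{"all": (values, cumfrac), "elm": ..., "rf": ...}`` (kinds with
    no holdouts omitted); suitable for step plotting of the two performance
    populations the ELM/RF mixture produces.
    """
    valid = [h for h in holdouts if h.fitted]
    if not valid:
        raise ContractError("no fitted holdouts")
    attr = "acc_test" if stage == "test" else "acc_train"
    out = {}
    for key, subset in (
        ("all", valid),
        ("elm", [h for h in valid if h.spec.kind == "elm"]),
        ("rf", [h for h in valid if h.spec.kind == "rf"]),
    ):
        if not subset:
            continue
        vals = np.sort([getattr(h, attr) for h in subset])
        out[key] = (vals, np.arange(1, len(vals) + 1) / len(vals))
    return out


@dataclass
class FoldResult:
    """Blind validation of one fold: consensus metrics plus accuracy spreads."""

    fold: int
    blind_idx: np.ndarray
    consensus_metrics: MetricsReport
    holdout_test_stats: dict[str, float]  # acc_test over all valid holdouts
    selected_blind_stats: dict[str, float]  # individual blind acc of selected
    n_selected: int
    n_holdouts: int
    holdout_test_accs: np.ndarray
    holdout_train_idx: list[np.ndarray] = field(repr=False, default_factory=list)
    holdout_test_idx: list[np.ndarray] = field(repr=False, default_factory=list)


@dataclass
class KFoldReport:
    """Per-fold and pooled blind-validation results."""

    folds: list[FoldResult]
    pooled_metrics: MetricsReport
    fold_accuracies: np.ndarray  # consensus blind accuracy per fold
    config: SamplerConfig

    def to_dict(self) -> dict:
        return {
            "k_folds": len(self.folds),
            "fold_accuracy": [float(a) for a in self.fold_accuracies],
            "pooled": self.pooled_metrics.to_dict(),
            "per_fold": [
                {
                    "fold": f.fold,
                    "consensus": f.consensus_metrics.to_dict(),
                    "holdout_test_stats": f.holdout_test_stats,
                    "selected_blind_stats": f.selected_blind_stats,
                    "n_selected": f.n_selected,
                    "n_holdouts": f.n_holdouts,
                }
                for f in self.folds
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(1000 + fold,)).generate_state(1)[0] % (2**31))


def kfold_validate(
    data: FeatureMatrix,
    config: SamplerConfig,
    *,
    keep_models: bool = False,
) -> KFoldReport:
    """Stratified k-fold blind validation of the full sampler pipeline.

    For each fold, holdouts are built and fitted on the remaining k-1 folds
    only, the consensus is selected there, and metrics are computed on the
    untouched blind fold.  The pooled report concatenates the per-fold blind
    predictions.
    """
    y = data.labels
    if data.n_samples < config.k_folds:
        raise ContractError("fewer samples than folds")
    counts = np.bincount(y[y >= 0], minlength=2)
    if counts.min() < config.k_folds:
        raise ContractError(
            f"a class has fewer members ({counts.min()}) than k_folds ({config.k_folds})"
        )
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.seed % (2**31)
    )
    folds: list[FoldResult] = []
    pooled_true, pooled_pred, pooled_scores = [], [], []
    fold_accs = []
    for f, (learn_idx, blind_idx) in enumerate(skf.split(data.X, y)):
        sub = data.subset(learn_idx)
        fold_config = replace(config, seed=_fold_seed(config.seed, f))
        holdouts = make_holdouts(sub.n_samples, fold_config, sub.groups_present)
        for h in holdouts:
            fit_holdout(h, sub)
        cm = select_holdouts(
            holdouts,
            config.selection_tau,
            vote_rule=config.vote_rule,
            class_threshold=config.class_threshold,
        )
        blind = data.subset(blind_idx)
        scores, classes = cm.predict(blind)
        metrics = confusion_and_metrics(blind.labels, classes, scores)
        name_to_j = {n: j for j, n in enumerate(blind.attribute_names)}
        selected_blind = []
        for h in cm.selected:
            cols = np.array([name_to_j[c] for c in h.columns], dtype=int)
            _, cls = h.model.predict(blind.X[:, cols])
            selected_blind.append(float(np.mean(cls == blind.labels)))
        valid = [h for h in holdouts if h.fitted]
        folds.append(
            FoldResult(
                fold=f,
                blind_idx=np.asarray(blind_idx),
                consensus_metrics=metrics,
                holdout_test_stats=accuracy_summary(h.acc_test for h in valid),
                selected_blind_stats=accuracy_summary(selected_blind),
                n_selected=len(cm.selected),
                n_holdouts=len(holdouts),
                holdout_test_accs=np.array([h.acc_test for h in valid]),
                holdout_train_idx=[learn_idx[h.train_idx] for h in valid],
                holdout_test_idx=[learn_idx[h.test_idx] for h in valid],
            )
        )
        fold_accs.append(metrics.accuracy)
        pooled_true.append(blind.labels)
        pooled_pred.append(classes)
        pooled_scores.append(scores)
        if not keep_models:
            for h in holdouts:
                h.model = None
    pooled = confusion_and_metrics(
        np.concatenate(pooled_true), np.concatenate(pooled_pred), np.concatenate(pooled_scores)
    )
    return KFoldReport(
        folds=folds,
        pooled_metrics=pooled,
        fold_accuracies=np.asarray(fold_accs),
        config=config,
    )


def save_consensus(cm: ConsensusModel, path) -> None:
    """Serialize a consensus model as a versioned joblib archive."""
    payload = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "selection_tau": cm.selection_tau,
        "vote_rule": cm.vote_rule,
        "class_threshold": cm.class_threshold,
        "selected": cm.selected,
    }
    joblib.dump(payload, path)


def load_consensus(path) -> ConsensusModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ContractError(f"unsupported archive version {version!r}")
    return ConsensusModel(
        selected=payload["selected"],
        selection_tau=payload["selection_tau"],
        vote_rule=payload["vote_rule"],
        class_threshold=payload["class_threshold"],
    )
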