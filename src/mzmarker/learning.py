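"""Patient-grouped partitioning, Random-Forest feature ranking and evaluation.

The workflow mirrors a replicate-aware biomarker screen:

* split patients (never individual replicate spectra) into a held-out
  test partition and a fit partition, stratified per class;
* reshuffle the fit partition into a fixed number of train/validation
  experiments;
* choose the forest size by a grid search over (vector length, tree
  count) maximizing mean validation f1 then accuracy;
* iteratively rank channels by mean Random-Forest importance, trimming
  the vector to ``floor(0.9 * length)`` per iteration down to length 1;
* train a final diagnosis classifier on the whole fit partition and
  score held-out patients, aggregating replicate predictions per
  patient by majority vote.

"Accuracy" throughout is the balanced form (sensitivity+specificity)/2.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigError
from .io import NEGATIVE_CLASS, POSITIVE_CLASS, IntensityMatrix

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "accuracy")


def derive_seed(master: int, *names) -> int:
    """Deterministic 31-bit substream seed from a master seed and names."""
    h = zlib.crc32(str(int(master)).encode())
    for name in names:
        h = zlib.crc32(str(name).encode(), h)
    return h & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Proportions in [0, 1]; undefined metrics carry the NaN sentinel."""

    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Report-time percentages, rounded once at ``ndigits`` decimals."""
        return {
            name: round(100 * getattr(self, name), ndigits)
            for name in METRIC_NAMES
        }


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, precision, f1 and balanced accuracy.

    f1 is the harmonic mean of precision and sensitivity; accuracy is
    (sensitivity + specificity)/2, *not* (Tp+Tn)/total. A zero
    denominator yields NaN, never a silent zero.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    stv = tp / (tp + fn) if tp + fn > 0 else math.nan
    spc = tn / (tn + fp) if tn + fp > 0 else math.nan
    prc = tp / (tp + fp) if tp + fp > 0 else math.nan
    if math.isnan(prc) or math.isnan(stv) or prc + stv == 0:
        f1 = math.nan
    else:
        f1 = 2 * prc * stv / (prc + stv)
    acc = (stv + spc) / 2  # NaN-propagating by construction
    return Metrics(stv, spc, prc, f1, acc)


def mean_and_rsd(metrics_list: Sequence[Metrics]) -> tuple[dict[str, float], dict[str, float]]:
    """Per-metric mean and relative standard deviation (%) across runs."""
    means, rsds = {}, {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metrics_list], dtype=float)
        mean = float(np.nanmean(vals))
        means[name] = mean
        sd = float(np.nanstd(vals, ddof=1)) if np.sum(~np.isnan(vals)) > 1 else 0.0
        rsds[name] = 100.0 * sd / mean if mean else math.nan
    return means, rsds


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Experiment:
    train: dict[str, tuple[str, ...]]  # class -> patients
    val: dict[str, tuple[str, ...]]

    def train_patients(self) -> set[str]:
        return {p for ps in self.train.values() for p in ps}

    def val_patients(self) -> set[str]:
        return {p for ps in self.val.values() for p in ps}


@dataclass(frozen=True)
class PartitionPlan:
    """Patient-level test/fit split plus train/validation experiments."""

    test_patients: dict[str, tuple[str, ...]]
    fit_patients: dict[str, tuple[str, ...]]
    experiments: tuple[Experiment, ...] = ()

    def all_test(self) -> set[str]:
        return {p for ps in self.test_patients.values() for p in ps}

    def all_fit(self) -> set[str]:
        return {p for ps in self.fit_patients.values() for p in ps}

    def assert_no_leakage(self) -> None:
        """Patient sets of test/fit and train/val must be disjoint."""
        if self.all_test() & self.all_fit():
            raise ConfigError("test and fit partitions share patients")
        for i, exp in enumerate(self.experiments):
            train, val = exp.train_patients(), exp.val_patients()
            if train & val:
                raise ConfigError(f"experiment {i}: train and validation share patients")
            if (train | val) - self.all_fit():
                raise ConfigError(f"experiment {i}: uses patients outside the fit partition")


def split_fit_test(
    patient_class: Mapping[str, str], test_fraction: float = 0.2, seed: int = 0
) -> PartitionPlan:
    """Stratified patient-level split into held-out test and fit sets.

    Per class, ``floor(test_fraction * n)`` patients go to the test
    partition (at least one, and at least one must remain for fitting).
    Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    classes = sorted(set(patient_class.values()))
    if len(classes) != 2:
        raise ConfigError(f"need exactly two classes, got {classes}")
    rng = np.random.default_rng(derive_seed(seed, "split"))
    test: dict[str, tuple[str, ...]] = {}
    fit: dict[str, tuple[str, ...]] = {}
    for cls in classes:
        members = sorted(p for p, c in patient_class.items() if c == cls)
        n_test = int(test_fraction * len(members))
        if n_test < 1 or n_test >= len(members):
            raise ConfigError(
                f"class {cls!r}: {len(members)} patients cannot support "
                f"test_fraction={test_fraction}"
            )
        order = rng.permutation(len(members))
        test[cls] = tuple(sorted(members[i] for i in order[:n_test]))
        fit[cls] = tuple(sorted(members[i] for i in order[n_test:]))
    return PartitionPlan(test_patients=test, fit_patients=fit)


def make_experiments(
    plan: PartitionPlan,
    n_experiments: int = 10,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> PartitionPlan:
    """Shuffle the fit partition into train/validation experiments.

    Per class and experiment, ``floor((1 - val_fraction) * n)`` patients
    train and the remainder validate, so an 82-patient class at 20%
    validation yields 65 train + 17 validation. Independent shuffles per
    experiment; train and validation unite to the fit set.
    """
    if not 0 < val_fraction < 1:
        raise ConfigError(f"val_fraction must lie in (0, 1), got {val_fraction}")
    if n_experiments < 1:
        raise ConfigError("n_experiments must be >= 1")
    experiments = []
    for e in range(n_experiments):
        rng = np.random.default_rng(derive_seed(seed, "experiments", e))
        train: dict[str, tuple[str, ...]] = {}
        val: dict[str, tuple[str, ...]] = {}
        for cls, members in sorted(plan.fit_patients.items()):
            n_train = int((1 - val_fraction) * len(members))
            if n_train < 1 or n_train >= len(members):
                raise ConfigError(
                    f"class {cls!r}: {len(members)} fit patients cannot support "
                    f"val_fraction={val_fraction}"
                )
            order = rng.permutation(len(members))
            train[cls] = tuple(sorted(members[i] for i in order[:n_train]))
            val[cls] = tuple(sorted(members[i] for i in order[n_train:]))
        experiments.append(Experiment(train=train, val=val))
    out = replace(plan, experiments=tuple(experiments))
    out.assert_no_leakage()
    return out


# ---------------------------------------------------------------------------
# prediction -> confusion helpers
# ---------------------------------------------------------------------------


def majority_vote(labels: Sequence[str]) -> str:
    """Patient-level vote over replicate predictions; ties -> positive.

    The positive tie-break is a deliberate screening bias: with an even
    replicate count and a split vote, the patient is flagged.
    """
    pos = sum(1 for lab in labels if lab == POSITIVE_CLASS)
    return POSITIVE_CLASS if pos * 2 >= len(labels) else NEGATIVE_CLASS


def _confusion(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == POSITIVE_CLASS and p == POSITIVE_CLASS)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == NEGATIVE_CLASS and p == NEGATIVE_CLASS)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == NEGATIVE_CLASS and p == POSITIVE_CLASS)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == POSITIVE_CLASS and p == NEGATIVE_CLASS)
    return ConfusionCounts(tp, tn, fp, fn)


def _evaluate_rows(
    model,
    matrix: IntensityMatrix,
    patients: Iterable[str],
    aggregation: str = "patient",
) -> tuple[Metrics, ConfusionCounts]:
    """Score the rows of ``patients`` and fold them into Metrics."""
    sub = matrix.subset_patients(patients)
    for p in set(patients):  # pre: every evaluated patient must have vectors
        if p not in set(sub.patient_id):
            raise ConfigError(f"patient {p!r} has zero vectors")
    pred = model.predict(sub.values)
    if aggregation == "vector":
        counts = _confusion(list(sub.row_class), list(pred))
    elif aggregation == "patient":
        truth, voted = [], []
        for patient in sorted(set(sub.patient_id)):
            mask = sub.patient_id == patient
            truth.append(sub.patient_class[patient])
            voted.append(majority_vote(list(pred[mask])))
        counts = _confusion(truth, voted)
    else:
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    return compute_metrics(counts), counts


def _fit_forest(matrix: IntensityMatrix, patients: Iterable[str], n_trees: int, seed: int):
    sub = matrix.subset_patients(patients)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(sub.values, sub.row_class.astype(str))
    return model


# ---------------------------------------------------------------------------
# tree-count grid search
# ---------------------------------------------------------------------------


@dataclass
class TreesFunction:
    """Grid-search results plus the selected length -> tree-count mapping.

    Lengths the loop visits but the grid did not are served by the
    nearest visited length (ties toward the smaller length) — no
    functional form is fitted to the grid.
    """

    records: pd.DataFrame  # length, n_trees, mean_f1, mean_accuracy
    mapping: dict[int, int]

    def trees_for(self, length: int) -> int:
        if not self.mapping:
            raise ConfigError("empty tree-count mapping")
        nearest = min(self.mapping, key=lambda k: (abs(k - length), k))
        return self.mapping[nearest]


def grid_search_trees(
    matrix: IntensityMatrix,
    plan: PartitionPlan,
    lengths: Sequence[int],
    trees: Sequence[int],
    seed: int = 0,
    aggregation: str = "patient",
) -> TreesFunction:
    """Mean validation f1/accuracy per (vector length, tree count) cell.

    Features for a cell are the top-``length`` channels of a baseline
    importance ranking (mean normalized importance of one forest per
    experiment at full length). Per length, the tree count maximizing
    mean f1 wins, ties broken by accuracy and then by fewer trees.
    """
    if len(lengths) == 0 or len(trees) == 0:
        raise ConfigError("lengths and trees grids must be non-empty")
    if min(trees) < 1:
        raise ConfigError("tree counts must be >= 1")
    plan.assert_no_leakage()

    baseline = rank_channels_once(matrix, plan, n_trees=max(trees), seed=seed)
    rows = []
    for length in sorted({min(int(l), matrix.n_channels) for l in lengths}):
        if length < 1:
            raise ConfigError("grid lengths must be >= 1")
        channels = baseline[:length]
        sub = matrix.select_channels(channels)
        for n_trees in sorted(set(int(t) for t in trees)):
            per_exp = []
            for e, exp in enumerate(plan.experiments):
                model = _fit_forest(
                    sub, exp.train_patients(), n_trees,
                    derive_seed(seed, "grid", length, n_trees, e),
                )
                metrics, _ = _evaluate_rows(model, sub, exp.val_patients(), aggregation)
                per_exp.append(metrics)
            means, _ = mean_and_rsd(per_exp)
            rows.append(
                {"length": length, "n_trees": n_trees,
                 "mean_f1": means["f1"], "mean_accuracy": means["accuracy"]}
            )
    records = pd.DataFrame(rows)
    mapping = {}
    for length, cell in records.groupby("length"):
        best = cell.sort_values(
            by=["mean_f1", "mean_accuracy", "n_trees"],
            ascending=[False, False, True],
            kind="mergesort",
        ).iloc[0]
        mapping[int(length)] = int(best["n_trees"])
    return TreesFunction(records=records, mapping=mapping)


def rank_channels_once(
    matrix: IntensityMatrix, plan: PartitionPlan, n_trees: int, seed: int
) -> list[int]:
    """Channels ordered by mean normalized forest importance (desc).

    Ties broken toward lower m/z. One forest per experiment, trained on
    that experiment's training patients over all channels.
    """
    importance = np.zeros(matrix.n_channels)
    for e, exp in enumerate(plan.experiments):
        model = _fit_forest(
            matrix, exp.train_patients(), n_trees, derive_seed(seed, "baseline", e)
        )
        imp = model.feature_importances_
        total = imp.sum()
        importance += (imp / total) if total > 0 else np.full_like(imp, 1 / imp.size)
    importance /= max(len(plan.experiments), 1)
    order = sorted(range(matrix.n_channels), key=lambda c: (-importance[c], matrix.mz[c]))
    return [int(matrix.mz[c]) for c in order]


# ---------------------------------------------------------------------------
# iterative importance ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IterationRecord:
    length: int
    n_trees: int
    channels: tuple[int, ...]  # surviving channels evaluated this iteration
    importance: dict[int, float]  # channel -> mean normalized importance
    metric_means: dict[str, float]
    metric_rsds: dict[str, float]


@dataclass
class RankingTrace:
    """Everything the ranking loop measured, one record per iteration."""

    iterations: tuple[IterationRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            row = {"length": it.length, "n_trees": it.n_trees}
            row.update({f"mean_{k}": v for k, v in it.metric_means.items()})
            row.update({f"rsd_{k}": v for k, v in it.metric_rsds.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def iterate_ranking(
    matrix: IntensityMatrix,
    plan: PartitionPlan,
    trees_fn: TreesFunction,
    reduction_factor: float = 0.9,
    seed: int = 0,
    aggregation: str = "patient",
) -> RankingTrace:
    """Iteratively discard the least important channels down to length 1.

    At each iteration one forest per experiment is trained on the
    surviving channels; validation metrics are recorded; channels are
    ranked by the mean of per-forest importances (each normalized to sum
    one; ties toward lower m/z); the top ``max(1, floor(factor *
    length))`` survive. Lengths strictly decrease, so the loop always
    terminates at 1.
    """
    if not 0 < reduction_factor < 1:
        raise ConfigError(f"reduction_factor must lie in (0,1), got {reduction_factor}")
    plan.assert_no_leakage()
    surviving = [int(m) for m in matrix.mz]
    records: list[IterationRecord] = []
    iteration = 0
    while True:
        length = len(surviving)
        n_trees = trees_fn.trees_for(length)
        sub = matrix.select_channels(surviving)
        importance = np.zeros(length)
        per_exp: list[Metrics] = []
        for e, exp in enumerate(plan.experiments):
            model = _fit_forest(
                sub, exp.train_patients(), n_trees,
                derive_seed(seed, "ranking", iteration, e),
            )
            metrics, _ = _evaluate_rows(model, sub, exp.val_patients(), aggregation)
            per_exp.append(metrics)
            imp = model.feature_importances_
            total = imp.sum()
            importance += (imp / total) if total > 0 else np.full_like(imp, 1 / imp.size)
        importance /= len(plan.experiments)
        means, rsds = mean_and_rsd(per_exp)
        by_mz = {int(m): importance[i] for i, m in enumerate(sub.mz)}
        ranked = sorted(surviving, key=lambda m: (-by_mz[m], m))
        records.append(
            IterationRecord(
                length=length,
                n_trees=n_trees,
                channels=tuple(surviving),
                importance=by_mz,
                metric_means=means,
                metric_rsds=rsds,
            )
        )
        if length == 1:
            break
        surviving = ranked[: max(1, int(reduction_factor * length))]
        iteration += 1
    return RankingTrace(iterations=tuple(records))


def select_optimal(trace: RankingTrace) -> tuple[int, ...]:
    """Surviving channel set at the iteration with maximum mean f1.

    Ties go to the smaller vector length (the leaner classifier).
    """
    if not trace.iterations:
        raise ConfigError("empty ranking trace")
    best = max(
        trace.iterations,
        key=lambda it: (
            -math.inf if math.isnan(it.metric_means["f1"]) else it.metric_means["f1"],
            -it.length,
        ),
    )
    return best.channels


# ---------------------------------------------------------------------------
# final classifier
# ---------------------------------------------------------------------------


@dataclass
class DiagnosisClassifier:
    """A trained forest restricted to the selected channels."""

    model: RandomForestClassifier
    channels: tuple[int, ...]

    def predict(self, matrix: IntensityMatrix) -> np.ndarray:
        sub = matrix.select_channels(self.channels)
        return self.model.predict(sub.values)

    def predict_scores(self, matrix: IntensityMatrix) -> np.ndarray:
        """Per-vector probability of the positive class."""
        sub = matrix.select_channels(self.channels)
        idx = list(self.model.classes_).index(POSITIVE_CLASS)
        return self.model.predict_proba(sub.values)[:, idx]


def train_diagnosis_classifier(
    matrix: IntensityMatrix,
    plan: PartitionPlan,
    selected_channels: Sequence[int],
    trees_fn: TreesFunction,
    seed: int = 0,
) -> DiagnosisClassifier:
    """Train the final forest on every fit-partition vector."""
    missing = set(int(c) for c in selected_channels) - set(int(m) for m in matrix.mz)
    if missing:
        raise ConfigError(f"unknown channels: {sorted(missing)[:5]}")
    channels = tuple(sorted(int(c) for c in selected_channels))
    sub = matrix.select_channels(channels)
    n_trees = trees_fn.trees_for(len(channels))
    model = _fit_forest(sub, plan.all_fit(), n_trees, derive_seed(seed, "final"))
    return DiagnosisClassifier(model=model, channels=channels)


def evaluate_on_test(
    classifier: DiagnosisClassifier,
    matrix: IntensityMatrix,
    plan: PartitionPlan,
    aggregation: str = "patient",
) -> tuple[Metrics, ConfusionCounts]:
    """Score held-out test patients (majority vote per patient by default)."""
    test = plan.all_test()
    if test & plan.all_fit():
        raise ConfigError("test patients overlap the fit partition")
    sub = matrix.select_channels(classifier.channels)
    return _evaluate_rows(classifier.model, sub, test, aggregation)


# ---------------------------------------------------------------------------
# classifier comparison harness
# ---------------------------------------------------------------------------


def _make_learner(learner: str, n_trees: int, seed: int):
    if learner == "random_forest":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if learner == "svm_smo":
        # SMO-family quadratic-programming solver
        return SVC(kernel="linear", random_state=seed)
    if learner == "svm_isda":
        # the second, coordinate/subgradient-style solver family
        return LinearSVC(random_state=seed, max_iter=5000)
    if learner == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    raise ConfigError(f"unknown learner {learner!r}")


def compare_classifiers(
    matrix: IntensityMatrix,
    plan: PartitionPlan,
    selected_channels: Sequence[int],
    learners: Sequence[str] = ("random_forest", "svm_smo", "svm_isda", "decision_tree"),
    n_trees: int = 58,
    seed: int = 0,
    aggregation: str = "patient",
) -> pd.DataFrame:
    """Identical partitions and channels fed to every learner.

    Returns one row per requested learner (duplicates yield identical
    rows) with mean and relative standard deviation of each metric over
    the experiments.
    """
    plan.assert_no_leakage()
    sub = matrix.select_channels(sorted(int(c) for c in selected_channels))
    rows = []
    for learner in learners:
        per_exp = []
        for e, exp in enumerate(plan.experiments):
            model = _make_learner(learner, n_trees, derive_seed(seed, "compare", learner, e))
            train = sub.subset_patients(exp.train_patients())
            model.fit(train.values, train.row_class.astype(str))
            metrics, _ = _evaluate_rows(model, sub, exp.val_patients(), aggregation)
            per_exp.append(metrics)
        means, rsds = mean_and_rsd(per_exp)
        row = {"learner": learner}
        row.update({f"mean_{k}": v for k, v in means.items()})
        row.update({f"rsd_{k}": v for k, v in rsds.items()})
        rows.append(row)
    return pd.DataFrame(rows)
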