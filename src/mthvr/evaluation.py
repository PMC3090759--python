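"""Cross-validation, independent-test evaluation, accuracy metrics and region scans.

Micro-accuracy is the pooled fraction correct, 100 · Σ C_i / Σ N_i; macro-
accuracy is the unweighted mean of per-class accuracies, 100 · (1/K) Σ C_i/N_i.
The confusion table may carry predicted-class columns absent from the truth
(a training class missing from the test set still attracts predictions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import pca as pca_mod
from ._folds import stratified_fold_ids
from .classifiers import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    GaussianClassifier,
    HammingNeighborClassifier,
    MajorityClassifier,
    SVMClassifier,
    tune_svm,
)
from .feature_encoding import (
    CommonRegionError,
    FeatureSpace,
    build_feature_space,
    encode_binary,
    encode_probability,
    encode_rcrs,
    position_rates,
    restrict_to_common_region,
)
from .profile_io import (
    HVR_LENGTH,
    ProfileDataset,
    SampleProfile,
    ValidationError,
    hvr_position_at,
)

logger = logging.getLogger(__name__)

STRATEGIES = ("plain", "rcrs", "probability", "common_region")


# ---------------------------------------------------------------------------
# Confusion tables and accuracy metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """Counts of (true class × predicted class) outcomes.

    ``pred_classes`` may be a superset of ``true_classes``: predictions into
    a class with no true samples form a column with zero diagonal.
    """

    true_classes: tuple
    pred_classes: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.true_classes), len(self.pred_classes)):
            raise ValueError("counts shape must match class lists")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def class_sizes(self) -> np.ndarray:
        """N_i: per-true-class totals (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def correct_counts(self) -> np.ndarray:
        """C_i: correctly labeled count per true class."""
        pred_index = {c: j for j, c in enumerate(self.pred_classes)}
        out = np.zeros(len(self.true_classes), dtype=np.int64)
        for i, cls in enumerate(self.true_classes):
            j = pred_index.get(cls)
            if j is not None:
                out[i] = self.counts[i, j]
        return out

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_accuracy(self) -> Dict[str, float]:
        sizes = self.class_sizes
        correct = self.correct_counts
        return {
            cls: 100.0 * correct[i] / sizes[i]
            for i, cls in enumerate(self.true_classes)
        }

    def row_percentages(self) -> np.ndarray:
        sizes = self.class_sizes.astype(np.float64)
        return 100.0 * self.counts / sizes[:, None]


def confusion_table(
    true_labels: Sequence,
    predicted_labels: Sequence,
    class_order: Sequence,
    true_class_order: Optional[Sequence] = None,
) -> ConfusionTable:
    """Tally a confusion table.

    ``class_order`` fixes the predicted-class columns; rows default to the
    classes of ``class_order`` actually present in the truth (override with
    ``true_class_order``).
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists must have equal length")
    class_order = list(class_order)
    present = set(true_labels)
    if true_class_order is None:
        true_class_order = [c for c in class_order if c in present]
        extra_truth = present - set(class_order)
        if extra_truth:
            raise ValueError(f"true labels {sorted(extra_truth)} outside class_order")
    true_class_order = list(true_class_order)
    row_index = {c: i for i, c in enumerate(true_class_order)}
    col_index = {c: j for j, c in enumerate(class_order)}
    counts = np.zeros((len(true_class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in row_index:
            raise ValueError(f"true label {t!r} outside the true class order")
        if p not in col_index:
            raise ValueError(f"predicted label {p!r} outside class_order")
        counts[row_index[t], col_index[p]] += 1
    return ConfusionTable(tuple(true_class_order), tuple(class_order), counts)


def micro_accuracy(confusion: ConfusionTable) -> float:
    """Pooled percentage correct: 100 · Σ C_i / Σ N_i."""
    total = confusion.total
    if total == 0:
        raise ValueError("empty confusion table")
    return 100.0 * confusion.correct_counts.sum() / total


def macro_accuracy(confusion: ConfusionTable) -> float:
    """Unweighted mean of per-class accuracies: 100 · (1/K) Σ C_i / N_i."""
    sizes = confusion.class_sizes
    if len(sizes) == 0 or (sizes == 0).any():
        raise ValueError("macro accuracy undefined with an empty true class")
    return float(np.mean(100.0 * confusion.correct_counts / sizes))


@dataclass(frozen=True)
class ExperimentResult:
    """A confusion table with its derived accuracies and run metadata."""

    confusion: ConfusionTable
    metadata: dict = field(default_factory=dict)

    @property
    def micro(self) -> float:
        return micro_accuracy(self.confusion)

    @property
    def macro(self) -> float:
        return macro_accuracy(self.confusion)

    def per_class(self) -> Dict[str, float]:
        return self.confusion.per_class_accuracy()

    def predicted_share(self, label) -> float:
        """Fraction of all predictions assigned to *label*."""
        j = self.confusion.pred_classes.index(label)
        return float(self.confusion.counts[:, j].sum() / self.confusion.total)


# ---------------------------------------------------------------------------
# Pipeline specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineSpec:
    """What to run per training partition.

    ``classifier`` is one of ``svm``, ``lda``, ``qda``, ``1nn``, ``majority``.
    PCA applies to svm/lda/qda only (1NN operates on the raw binary encoding).
    ``k`` fixed skips dimension selection; ``C``/``gamma`` fixed skip SVM
    tuning; otherwise nested CV on the training partition chooses them.
    """

    classifier: str = "svm"
    k: Optional[int] = None
    k_candidates: Optional[tuple] = None
    C: Optional[float] = None
    gamma: Optional[float] = None
    C_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    regularization: Optional[float] = None
    priors: str = "empirical"

    def __post_init__(self) -> None:
        if self.classifier not in ("svm", "lda", "qda", "1nn", "majority"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def uses_pca(self) -> bool:
        return self.classifier in ("svm", "lda", "qda")

    def make_classifier(self, C: Optional[float] = None, gamma: Optional[float] = None):
        if self.classifier == "svm":
            return SVMClassifier(C=C if C is not None else (self.C or 1.0),
                                 gamma=gamma if gamma is not None else self.gamma)
        if self.classifier == "lda":
            return GaussianClassifier(True, self.regularization, self.priors)
        if self.classifier == "qda":
            return GaussianClassifier(False, self.regularization, self.priors)
        if self.classifier == "1nn":
            return HammingNeighborClassifier()
        return MajorityClassifier()


def _fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    spec: PipelineSpec,
    seed: int,
) -> Tuple[np.ndarray, dict]:
    """Fit the spec's pipeline on (train_X, train_y) and predict test_X.

    Hyperparameters not fixed in the spec are chosen by nested CV on the
    training partition only (leakage-safe). Returns predictions plus the
    chosen settings.
    """
    chosen: dict = {}
    if train_X.shape[1] == 0:
        # degenerate partition with no observed polymorphism: majority fallback
        clf = MajorityClassifier().fit(train_X, train_y)
        return clf.predict(np.zeros((test_X.shape[0], 0))), {"degenerate": "no_features"}
    if spec.uses_pca:
        if spec.k is not None:
            k = min(spec.k, train_X.shape[1])
        else:
            candidates = spec.k_candidates
            if candidates is not None:
                candidates = [k for k in candidates if k <= train_X.shape[1]]
                candidates = candidates or [train_X.shape[1]]
            k = pca_mod.select_k(
                train_X,
                train_y,
                classifier_factory=lambda: spec.make_classifier(),
                folds=spec.inner_folds,
                candidates=candidates,
                seed=seed,
            )
        model = pca_mod.fit_pca(train_X, k=k)
        train_X = pca_mod.transform(model, train_X, k=k)
        test_X = pca_mod.transform(model, test_X, k=k)
        chosen["k"] = k
    if spec.classifier == "svm":
        if spec.C is not None and spec.gamma is not None:
            C, gamma = spec.C, spec.gamma
        else:
            C, gamma = tune_svm(
                train_X, train_y,
                C_grid=(spec.C,) if spec.C is not None else spec.C_grid,
                gamma_grid=(spec.gamma,) if spec.gamma is not None else spec.gamma_grid,
                folds=spec.inner_folds, seed=seed,
            )
        chosen["C"], chosen["gamma"] = C, gamma
        clf = spec.make_classifier(C=C, gamma=gamma)
    else:
        clf = spec.make_classifier()
    clf.fit(train_X, train_y)
    return clf.predict(test_X), chosen


def _encode_pair(train: ProfileDataset, test: ProfileDataset, strategy: str):
    """Encode a train/test pair under a (non-common-region) strategy."""
    space = build_feature_space(train)
    if strategy in ("plain", "rcrs"):
        enc = encode_binary if strategy == "plain" else encode_rcrs
        return enc(train, space), enc(test, space)
    if strategy == "probability":
        rates = position_rates(train)
        return (
            encode_probability(train, space, rates),
            encode_probability(test, space, rates),
        )
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    dataset: ProfileDataset,
    spec: PipelineSpec,
    folds: int = 5,
    seed: int = 0,
    strategy: str = "plain",
    stratified: bool = True,
) -> ExperimentResult:
    """K-fold cross-validation of the full pipeline.

    Folds are class-stratified by default (switchable off) with sizes
    differing by at most one. The feature space, PCA dimension and
    hyperparameters are all re-derived inside each training partition;
    pooled predictions over the test folds form one confusion table.
    """
    labels = dataset.labels()
    if any(lb is None for lb in labels):
        raise ValidationError("cross-validation requires every sample to be labeled")
    class_order = dataset.label_universe
    for cls in class_order:
        if labels.count(cls) < folds:
            raise ValidationError(
                f"class {cls!r} has fewer than {folds} samples; cannot stratify folds"
            )
    fold_ids = stratified_fold_ids(labels, folds, seed, stratified=stratified)
    all_true: List[str] = []
    all_pred: List[str] = []
    fold_settings = []
    for fold in range(folds):
        test_idx = [i for i in range(len(dataset)) if fold_ids[i] == fold]
        train_idx = [i for i in range(len(dataset)) if fold_ids[i] != fold]
        train_ds = dataset.subset(train_idx)
        test_ds = dataset.subset(test_idx)
        train_mat, test_mat = _encode_pair(train_ds, test_ds, strategy)
        pred, chosen = _fit_predict(
            train_mat.values,
            np.asarray(train_mat.labels),
            test_mat.values,
            spec,
            seed=seed + fold,
        )
        all_true.extend(test_mat.labels)
        all_pred.extend(pred.tolist())
        fold_settings.append(chosen)
    confusion = confusion_table(all_true, all_pred, class_order)
    return ExperimentResult(
        confusion=confusion,
        metadata={
            "mode": "cross_validation",
            "folds": folds,
            "seed": seed,
            "strategy": strategy,
            "classifier": spec.classifier,
            "fold_settings": fold_settings,
        },
    )


# ---------------------------------------------------------------------------
# Independent-test evaluation with missing-data strategies
# ---------------------------------------------------------------------------

def _region_signature(sample: SampleProfile) -> tuple:
    return sample.typed.regions


def holdout_evaluate(
    train: ProfileDataset,
    test: ProfileDataset,
    strategy: str,
    spec: PipelineSpec,
    seed: int = 0,
    min_overlap_fraction: float = 0.0,
) -> ExperimentResult:
    """Fit on *train*, evaluate on *test* under a missing-data strategy.

    For ``common_region`` one model is fit per distinct test typed-region
    signature (cached — many test samples share identical sequencing ranges);
    test samples whose typed region overlaps no training polymorphism are
    reported unclassifiable and excluded from the counts. The confusion table
    uses the training label universe as predicted classes and the test label
    universe as true classes.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    if len(train.label_universe) < 2:
        raise ValidationError("holdout evaluation requires >= 2 training classes")
    unclassifiable: List[str] = []
    if strategy == "common_region":
        groups: Dict[tuple, List[int]] = {}
        for i, s in enumerate(test):
            groups.setdefault(_region_signature(s), []).append(i)
        pred_by_index: Dict[int, str] = {}
        for signature, indices in groups.items():
            representative = test.samples[indices[0]]
            try:
                space, train_mat, _ = restrict_to_common_region(
                    representative, train, min_overlap_fraction
                )
            except CommonRegionError:
                unclassifiable.extend(test.samples[i].sample_id for i in indices)
                continue
            rows = np.zeros((len(indices), space.n))
            index = space.index()
            for r, i in enumerate(indices):
                for poly in test.samples[i].polymorphisms:
                    j = index.get(poly)
                    if j is not None:
                        rows[r, j] = 1.0
            pred, _ = _fit_predict(
                train_mat.values, np.asarray(train_mat.labels), rows, spec, seed=seed
            )
            for r, i in enumerate(indices):
                pred_by_index[i] = pred[r]
        kept = sorted(pred_by_index)
        all_true = [test.samples[i].label for i in kept]
        all_pred = [pred_by_index[i] for i in kept]
        if unclassifiable:
            logger.warning(
                "%d test samples unclassifiable under common_region: %s",
                len(unclassifiable), unclassifiable,
            )
    else:
        train_mat, test_mat = _encode_pair(train, test, strategy)
        pred, _ = _fit_predict(
            train_mat.values, np.asarray(train_mat.labels), test_mat.values,
            spec, seed=seed,
        )
        all_true = list(test_mat.labels)
        all_pred = pred.tolist()
    confusion = confusion_table(
        all_true, all_pred,
        class_order=train.label_universe,
        true_class_order=test.label_universe,
    )
    return ExperimentResult(
        confusion=confusion,
        metadata={
            "mode": "holdout",
            "strategy": strategy,
            "seed": seed,
            "classifier": spec.classifier,
            "unclassifiable": unclassifiable,
        },
    )


# ---------------------------------------------------------------------------
# Region-informativeness scans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanEntry:
    index: int
    n_features: int
    descriptor: str
    result: Optional[ExperimentResult]


@dataclass(frozen=True)
class ScanResult:
    mode: str
    entries: tuple

    def accuracies(self) -> List[Optional[float]]:
        return [e.result.micro if e.result is not None else None for e in self.entries]


def _filter_features(dataset: ProfileDataset, keep: frozenset) -> ProfileDataset:
    samples = tuple(
        SampleProfile(
            s.sample_id, s.typed,
            frozenset(p for p in s.polymorphisms if p in keep),
            label=s.label, country=s.country,
        )
        for s in dataset
    )
    return ProfileDataset(samples)


def _axis_ordered_features(dataset: ProfileDataset) -> list:
    space = build_feature_space(dataset)
    return sorted(space.features, key=lambda p: p.axis_sort_key)


def deletion_scan(
    dataset: ProfileDataset,
    spec: PipelineSpec,
    from_end: str = "hvr1_end",
    fraction: float = 0.10,
    folds: int = 5,
    seed: int = 0,
) -> ScanResult:
    """Iteratively delete blocks of features from one end of the HVR axis.

    Features are ordered along the concatenated HVR1(16024→16569) then
    HVR2(1→576) axis. ``hvr1_end`` deletes from the axis start (the HVR1 end
    non-adjacent to HVR2), ``hvr2_end`` from the axis end. Each round removes
    ⌈fraction · n⌉ features and re-runs cross-validation; entry 0 is the
    undeleted baseline.
    """
    if from_end not in ("hvr1_end", "hvr2_end"):
        raise ValueError("from_end must be 'hvr1_end' or 'hvr2_end'")
    features = _axis_ordered_features(dataset)
    n = len(features)
    if n == 0:
        raise ValidationError("deletion_scan requires a non-empty feature set")
    step = math.ceil(fraction * n)
    planned_rounds = math.ceil(1.0 / fraction)
    entries = []
    remaining = list(features)
    round_no = 0
    while remaining:
        reduced = _filter_features(dataset, frozenset(remaining))
        result = cross_validate(reduced, spec, folds=folds, seed=seed)
        descriptor = f"round={round_no} deleted_from={from_end}"
        entries.append(ScanEntry(round_no, len(remaining), descriptor, result))
        remaining = remaining[step:] if from_end == "hvr1_end" else remaining[:-step]
        round_no += 1
    if round_no < planned_rounds:
        logger.warning(
            "deletion_scan exhausted the feature set after %d of %d rounds",
            round_no, planned_rounds,
        )
    return ScanResult(mode=f"delete-{from_end}", entries=tuple(entries))


def window_scan(
    dataset: ProfileDataset,
    spec: PipelineSpec,
    nucleotide_fraction: float = 0.10,
    n_windows: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> ScanResult:
    """Sliding-window scan over the concatenated HVR axis.

    Each window spans ``round(nucleotide_fraction · 1122)`` nucleotides;
    ``n_windows`` evenly spaced start offsets cover the axis. Only features
    inside a window are kept for its cross-validation run; a window with no
    features records an absent accuracy.
    """
    w = round(nucleotide_fraction * HVR_LENGTH)
    if n_windows < 1 or w < 1:
        raise ValueError("need at least one window of positive width")
    features = _axis_ordered_features(dataset)
    entries = []
    span = HVR_LENGTH - w
    for i in range(n_windows):
        start = round(i * span / (n_windows - 1)) if n_windows > 1 else 0
        lo, hi = start, start + w - 1
        keep = frozenset(
            f for f in features if lo <= f.axis_sort_key[0] <= hi
        )
        descriptor = (
            f"window={i} axis={lo}-{hi} start_pos={hvr_position_at(lo)}"
        )
        if not keep:
            entries.append(ScanEntry(i, 0, descriptor, None))
            continue
        reduced = _filter_features(dataset, keep)
        result = cross_validate(reduced, spec, folds=folds, seed=seed)
        entries.append(ScanEntry(i, len(keep), descriptor, result))
    return ScanResult(mode="window", entries=tuple(entries))


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_result_tsv(result: ExperimentResult) -> str:
    """Render confusion counts plus per-class/micro/macro accuracies as TSV."""
    ct = result.confusion
    lines = ["\t".join(["true\\pred"] + [str(c) for c in ct.pred_classes] + ["N"])]
    for i, cls in enumerate(ct.true_classes):
        row = [str(cls)] + [str(int(v)) for v in ct.counts[i]] + [str(int(ct.class_sizes[i]))]
        lines.append("\t".join(row))
    per_class = result.per_class()
    for cls in ct.true_classes:
        lines.append(f"accuracy_{cls}\t{per_class[cls]:.2f}")
    lines.append(f"micro_accuracy\t{result.micro:.2f}")
    lines.append(f"macro_accuracy\t{result.macro:.2f}")
    for key, value in result.metadata.items():
        lines.append(f"meta_{key}\t{value}")
    return "\n".join(lines) + "\n"


def render_scan_tsv(scan: ScanResult) -> str:
    lines = ["index\tn_features\tdescriptor\tmicro_accuracy\tmacro_accuracy"]
    for e in scan.entries:
        micro = f"{e.result.micro:.2f}" if e.result is not None else "NA"
        macro = f"{e.result.macro:.2f}" if e.result is not None else "NA"
        lines.append(f"{e.index}\t{e.n_features}\t{e.descriptor}\t{micro}\t{macro}")
    return "\n".join(lines) + "\n"
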