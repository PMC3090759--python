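"""Numeric encodings of HVR profiles.

The plain scheme represents a sample as an n-element binary vector over the
distinct polymorphisms observed in the training data. Three strategies handle
samples with untyped (missing) regions:

* **rcrs** — untyped positions are assumed reference-identical, i.e. the
  binary encoding is used unchanged (this biases predictions toward
  reference-like classes);
* **probability** — the binary block is augmented with one variable per HVR
  position holding the observed polymorphism state for typed positions and
  the training polymorphism rate for untyped ones;
* **common_region** — the feature universe is restricted to the test
  sample's typed region and the model refit on that restriction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .profile_io import (
    HVR_LENGTH,
    Polymorphism,
    ProfileDataset,
    RegionSet,
    SampleProfile,
    ValidationError,
    hvr_axis_index,
)

logger = logging.getLogger(__name__)


class CommonRegionError(ValueError):
    """Raised when a test sample's typed region covers no training feature."""


@dataclass(frozen=True)
class FeatureSpace:
    """The ordered universe of distinct polymorphisms seen in training data."""

    features: tuple
    source_region: RegionSet

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.features), key=lambda p: p.sort_key))
        if ordered != tuple(self.features):
            raise ValidationError("features must be unique and canonically ordered")
        for feat in self.features:
            if not self.source_region.contains(feat.position):
                raise ValidationError(
                    f"feature {feat.render()} outside source region"
                )

    @property
    def n(self) -> int:
        return len(self.features)

    def index(self) -> dict:
        return {feat: j for j, feat in enumerate(self.features)}

    def tokens(self) -> list:
        return [feat.render() for feat in self.features]


@dataclass(frozen=True)
class FeatureMatrix:
    """An m × width encoded matrix with row ids, labels, and its feature space.

    ``width`` is ``space.n`` for binary encodings and ``space.n + 1122`` for
    the probability encoding (``extra_width`` distinguishes the two).
    """

    values: np.ndarray
    row_ids: tuple
    labels: tuple
    space: FeatureSpace
    extra_width: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        m, width = values.shape
        if m != len(self.row_ids) or m != len(self.labels):
            raise ValidationError("row_ids/labels length must match matrix rows")
        if width != self.space.n + self.extra_width:
            raise ValidationError(
                f"matrix width {width} != n ({self.space.n}) + extra ({self.extra_width})"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValidationError("feature values must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.space.n

    def to_tsv(self, sink) -> None:
        """Audit export: row ids, labels, and feature columns by token."""
        header = ["sample_id", "label"] + self.space.tokens()
        header += [f"pos_{i}" for i in range(self.extra_width)]
        sink.write("\t".join(header) + "\n")
        for rid, label, row in zip(self.row_ids, self.labels, self.values):
            cells = [rid, label or ""] + [format(v, "g") for v in row]
            sink.write("\t".join(cells) + "\n")


@dataclass(frozen=True)
class PositionRateTable:
    """Per-position polymorphism rates over the 1122 HVR positions."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=np.float64)
        object.__setattr__(self, "rates", rates)
        if rates.shape != (HVR_LENGTH,):
            raise ValidationError(f"rate table must have length {HVR_LENGTH}")
        if rates.size and (rates.min() < 0.0 or rates.max() > 1.0):
            raise ValidationError("rates must lie in [0, 1]")

    def rate(self, position: int) -> float:
        return float(self.rates[hvr_axis_index(position)])


def build_feature_space(training: ProfileDataset) -> FeatureSpace:
    """Ordered union of all polymorphisms observed in the training samples."""
    if len(training) == 0:
        raise ValidationError("cannot build a feature space from an empty dataset")
    seen = set()
    for s in training:
        seen.update(s.polymorphisms)
    features = tuple(sorted(seen, key=lambda p: p.sort_key))
    if not features:
        logger.warning("training data is entirely rCRS-identical: empty feature space")
    region = RegionSet()
    for s in training:
        region = region.union(s.typed)
    return FeatureSpace(features=features, source_region=region)


def encode_binary(samples: ProfileDataset, space: FeatureSpace) -> FeatureMatrix:
    """Binary encoding: entry (i, j) = 1 iff sample i harbors feature j.

    Polymorphisms absent from *space* (e.g. test-only variants) carry no
    signal for a model trained on *space* and are dropped with a logged count.
    """
    index = space.index()
    values = np.zeros((len(samples), space.n), dtype=np.float64)
    dropped = 0
    for i, s in enumerate(samples):
        for poly in s.polymorphisms:
            j = index.get(poly)
            if j is None:
                dropped += 1
            else:
                values[i, j] = 1.0
    if dropped:
        logger.info("encode_binary: dropped %d out-of-space polymorphisms", dropped)
    return FeatureMatrix(
        values=values,
        row_ids=tuple(s.sample_id for s in samples),
        labels=tuple(s.label for s in samples),
        space=space,
    )


def encode_rcrs(samples: ProfileDataset, space: FeatureSpace) -> FeatureMatrix:
    """Reference-imputation strategy: untyped positions are treated as rCRS.

    Numerically identical to :func:`encode_binary` — an absent feature scores
    0 whether the position is typed-reference or untyped — but kept as a
    named strategy so the missing-data comparison is explicit.
    """
    return encode_binary(samples, space)


def position_rates(training: ProfileDataset) -> PositionRateTable:
    """Polymorphism rate at each HVR position among samples typed there.

    rate(p) = (# typed-at-p samples with any polymorphism anchored at p)
    ÷ (# samples typed at p); 0 where no sample is typed. Substitutions,
    insertions (keyed to their anchor) and deletions all count.
    """
    if len(training) == 0:
        raise ValidationError("position_rates requires a non-empty dataset")
    typed_counts = np.zeros(HVR_LENGTH, dtype=np.int64)
    poly_counts = np.zeros(HVR_LENGTH, dtype=np.int64)
    for s in training:
        for start, end in s.typed.regions:
            i, j = hvr_axis_index(start), hvr_axis_index(end)
            typed_counts[i : j + 1] += 1
        for p in {hvr_axis_index(poly.position) for poly in s.polymorphisms}:
            poly_counts[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(typed_counts > 0, poly_counts / np.maximum(typed_counts, 1), 0.0)
    return PositionRateTable(rates)


def _typed_mask(sample: SampleProfile) -> np.ndarray:
    mask = np.zeros(HVR_LENGTH, dtype=bool)
    for start, end in sample.typed.regions:
        mask[hvr_axis_index(start) : hvr_axis_index(end) + 1] = True
    return mask


def encode_probability(
    samples: ProfileDataset, space: FeatureSpace, rates: PositionRateTable
) -> FeatureMatrix:
    """Probability strategy: binary block plus 1122 per-position variables.

    The positional variable is 1 where the sample is typed and polymorphic,
    0 where typed and reference, and the training rate where untyped; the
    result is an m × (n + 1122) matrix.
    """
    binary = encode_binary(samples, space)
    block = np.empty((len(samples), HVR_LENGTH), dtype=np.float64)
    for i, s in enumerate(samples):
        typed = _typed_mask(s)
        row = np.where(typed, 0.0, rates.rates)
        for poly in s.polymorphisms:
            row[hvr_axis_index(poly.position)] = 1.0
        block[i] = row
    return FeatureMatrix(
        values=np.hstack([binary.values, block]),
        row_ids=binary.row_ids,
        labels=binary.labels,
        space=space,
        extra_width=HVR_LENGTH,
    )


def restrict_to_common_region(
    test: SampleProfile,
    training: ProfileDataset,
    min_overlap_fraction: float = 0.0,
) -> Tuple[FeatureSpace, FeatureMatrix, np.ndarray]:
    """Common-region strategy: keep only training features the test sample covers.

    Returns the restricted feature space, the training matrix encoded over it,
    and the binary feature row for the test sample. Training samples are kept
    even under partial overlap (their uncovered features are 0) unless their
    overlap with the test region falls below ``min_overlap_fraction``.
    """
    if test.typed.is_empty:
        raise CommonRegionError(
            f"test sample {test.sample_id!r} has no typed region; "
            "use the rcrs or probability strategy instead"
        )
    full_space = build_feature_space(training)
    restricted = tuple(
        feat for feat in full_space.features if test.typed.contains(feat.position)
    )
    if not restricted:
        raise CommonRegionError(
            f"typed region of test sample {test.sample_id!r} overlaps no training "
            "polymorphism; fall back to the rcrs or probability strategy"
        )
    kept = []
    test_len = test.typed.total_length
    for i, s in enumerate(training):
        overlap = s.typed.intersect(test.typed).total_length
        if overlap / test_len >= min_overlap_fraction:
            kept.append(i)
    sub_training = training.subset(kept)
    space = FeatureSpace(
        features=restricted, source_region=full_space.source_region
    )
    matrix = encode_binary(sub_training, space)
    test_row = np.zeros(space.n, dtype=np.float64)
    index = space.index()
    for poly in test.polymorphisms:
        j = index.get(poly)
        if j is not None:
            test_row[j] = 1.0
    return space, matrix, test_row
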