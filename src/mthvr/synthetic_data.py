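"""Synthetic HVR profile datasets with controllable population structure.

The generator emulates the statistical structure the classifiers exploit in
real forensic/published mtDNA databases: a small number of haplogroup founder
motifs (shared polymorphism sets), a stochastic class → haplogroup mixing
matrix, per-sample private mutations, and laboratory-style coverage dropout
(all-samples-cover-a-core "forensic-like" vs. mostly-HVR1-only
"published-like"). No coalescent realism is attempted — only the association
structure.

All randomness flows from a single integer seed through one generator, in a
fixed consumption order, so datasets are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .profile_io import (
    HVR1,
    HVR2,
    HVR_LENGTH,
    Polymorphism,
    ProfileDataset,
    RegionSet,
    SampleProfile,
    hvr_position_at,
)

#: Core ranges every "forensic-like" sample is guaranteed to cover.
FORENSIC_CORE_HVR1 = (16024, 16365)
FORENSIC_CORE_HVR2 = (73, 340)

COVERAGE_MODELS = ("full", "forensic_like", "published_like")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic profile dataset."""

    n_samples: int = 400
    class_labels: tuple = ("Caucasian", "African", "Asian", "Hispanic")
    class_proportions: Optional[tuple] = None  # default: uniform
    n_haplogroups: int = 8
    mixing: Optional[tuple] = None  # class × haplogroup rows; default: block-diagonal-ish
    motif_size: int = 6
    motif_overlap: float = 0.0
    private_rate: float = 0.5
    coverage_model: str = "full"
    published_hvr2_missing_fraction: float = 0.6
    published_hvr1_missing_fraction: float = 0.05
    reference_like_class: Optional[str] = None
    motif_region: Optional[tuple] = None  # (start, end) pairs restricting motif positions
    motif_hvr2_fraction: Optional[float] = None  # fraction of motif positions in HVR2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_model not in COVERAGE_MODELS:
            raise ValueError(f"coverage_model must be one of {COVERAGE_MODELS}")
        props = self.proportions
        if len(props) != len(self.class_labels):
            raise ValueError("one proportion per class required")
        if abs(sum(props) - 1.0) > 1e-12:
            raise ValueError("class proportions must sum to 1")
        mix = self.mixing_matrix
        if mix.shape != (len(self.class_labels), self.n_haplogroups):
            raise ValueError("mixing matrix must be class × haplogroup")
        if np.abs(mix.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("mixing rows must sum to 1")
        if self.reference_like_class is not None and (
            self.reference_like_class not in self.class_labels
        ):
            raise ValueError("reference_like_class must be one of class_labels")

    @property
    def proportions(self) -> tuple:
        if self.class_proportions is not None:
            return tuple(self.class_proportions)
        k = len(self.class_labels)
        return tuple([1.0 / k] * k)

    @property
    def mixing_matrix(self) -> np.ndarray:
        if self.mixing is not None:
            return np.asarray(self.mixing, dtype=np.float64)
        # default: each class dominated by its own haplogroup block, 10% leakage
        K = len(self.class_labels)
        H = self.n_haplogroups
        mix = np.full((K, H), 0.1 / H)
        for g in range(K):
            own = [h for h in range(H) if h % K == g]
            for h in own:
                mix[g, h] += 0.9 / len(own)
        return mix / mix.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample generating state: class, haplogroup, motif and private variants."""

    records: tuple  # of dicts: sample_id, label, haplogroup, motif, private

    def haplogroups(self) -> List[str]:
        return [r["haplogroup"] for r in self.records]

    def labels(self) -> List[str]:
        return [r["label"] for r in self.records]


def _motif_position_universe(config: SyntheticConfig) -> List[int]:
    if config.motif_region is None:
        return [hvr_position_at(i) for i in range(HVR_LENGTH)]
    region = RegionSet.from_pairs(config.motif_region)
    return list(region.positions())


def generate_motifs(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Dict[str, frozenset]:
    """Draw one founder polymorphism motif per haplogroup.

    With ``motif_overlap == 0`` motifs are pairwise disjoint. Otherwise
    motifs are sampled from a candidate universe sized so the expected
    pairwise overlap of two random size-s subsets, s²/|universe|, equals the
    configured value.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s, H = config.motif_size, config.n_haplogroups
    positions = _motif_position_universe(config)
    if config.motif_hvr2_fraction is not None:
        if config.motif_overlap > 0:
            raise ValueError(
                "motif_hvr2_fraction is only supported with motif_overlap == 0"
            )
        s2 = round(config.motif_hvr2_fraction * s)
        s1 = s - s2
        hvr1_pool = [p for p in positions if p >= HVR1[0]]
        hvr2_pool = [p for p in positions if p <= HVR2[1]]
        if s1 * H > len(hvr1_pool) or s2 * H > len(hvr2_pool):
            raise ValueError("not enough candidate positions for the requested split")
        pick1 = rng.choice(len(hvr1_pool), size=s1 * H, replace=False)
        pick2 = rng.choice(len(hvr2_pool), size=s2 * H, replace=False)
        motifs = {}
        for h in range(H):
            block = [hvr1_pool[i] for i in pick1[h * s1 : (h + 1) * s1]]
            block += [hvr2_pool[i] for i in pick2[h * s2 : (h + 1) * s2]]
            motifs[f"HG{h:02d}"] = frozenset(
                _random_substitution(p, rng) for p in block
            )
        return motifs
    if config.motif_overlap <= 0:
        needed = s * H
        if needed > len(positions):
            raise ValueError(
                f"cannot place {H} disjoint motifs of size {s} in "
                f"{len(positions)} candidate positions"
            )
        chosen = rng.choice(len(positions), size=needed, replace=False)
        motifs = {}
        for h in range(H):
            block = chosen[h * s : (h + 1) * s]
            motifs[f"HG{h:02d}"] = frozenset(
                _random_substitution(positions[i], rng) for i in block
            )
        return motifs
    universe_size = max(s, round(s * s / config.motif_overlap))
    if universe_size > len(positions):
        raise ValueError(
            f"motif universe of {universe_size} positions exceeds the "
            f"{len(positions)} candidate positions"
        )
    universe_idx = rng.choice(len(positions), size=universe_size, replace=False)
    universe = [_random_substitution(positions[i], rng) for i in universe_idx]
    motifs = {}
    for h in range(H):
        pick = rng.choice(universe_size, size=s, replace=False)
        motifs[f"HG{h:02d}"] = frozenset(universe[i] for i in pick)
    return motifs


def _random_substitution(position: int, rng: np.random.Generator) -> Polymorphism:
    base = "ACGT"[rng.integers(4)]
    return Polymorphism(position, "substitution", base)


def _draw_typed_regions(
    model: str, config: SyntheticConfig, rng: np.random.Generator
) -> RegionSet:
    if model == "full":
        return RegionSet.from_pairs([HVR2, HVR1])
    if model == "forensic_like":
        # guaranteed cores, endpoints extended uniformly toward the HVR bounds
        hvr1_end = int(rng.integers(FORENSIC_CORE_HVR1[1], HVR1[1] + 1))
        hvr2_start = int(rng.integers(HVR2[0], FORENSIC_CORE_HVR2[0] + 1))
        hvr2_end = int(rng.integers(FORENSIC_CORE_HVR2[1], HVR2[1] + 1))
        return RegionSet.from_pairs(
            [(hvr2_start, hvr2_end), (FORENSIC_CORE_HVR1[0], hvr1_end)]
        )
    # published_like: a large fraction entirely missing HVR2, a few missing HVR1
    drop_hvr2 = rng.random() < config.published_hvr2_missing_fraction
    drop_hvr1 = rng.random() < config.published_hvr1_missing_fraction
    if drop_hvr1 and drop_hvr2:
        drop_hvr1 = False  # keep at least one region typed
    pairs = []
    if not drop_hvr2:
        hvr2_start = int(rng.integers(HVR2[0], FORENSIC_CORE_HVR2[0] + 1))
        hvr2_end = int(rng.integers(FORENSIC_CORE_HVR2[1], HVR2[1] + 1))
        pairs.append((hvr2_start, hvr2_end))
    if not drop_hvr1:
        hvr1_end = int(rng.integers(FORENSIC_CORE_HVR1[1], HVR1[1] + 1))
        pairs.append((FORENSIC_CORE_HVR1[0], hvr1_end))
    return RegionSet.from_pairs(pairs)


def _draw_private(
    count: int, rng: np.random.Generator
) -> List[Polymorphism]:
    out = []
    for _ in range(count):
        pos = hvr_position_at(int(rng.integers(HVR_LENGTH)))
        out.append(_random_substitution(pos, rng))
    return out


def generate_dataset(
    config: SyntheticConfig,
) -> Tuple[ProfileDataset, GroundTruth]:
    """Generate a labeled profile dataset and its generating ground truth.

    Per sample: class ~ proportions, haplogroup ~ the class's mixing row,
    polymorphisms = founder motif ∪ Poisson(private_rate) private
    substitutions, typed regions from the coverage model; polymorphisms
    falling outside the typed regions are removed. Samples of the
    ``reference_like_class`` carry no founder motif (rCRS-like profiles).
    """
    rng = np.random.default_rng(config.seed)
    motifs = generate_motifs(config, rng)
    hap_names = sorted(motifs)
    mixing = config.mixing_matrix
    proportions = np.asarray(config.proportions)
    samples = []
    records = []
    for i in range(config.n_samples):
        g = int(rng.choice(len(config.class_labels), p=proportions))
        label = config.class_labels[g]
        h = int(rng.choice(config.n_haplogroups, p=mixing[g]))
        haplogroup = hap_names[h]
        motif = (
            frozenset()
            if label == config.reference_like_class
            else motifs[haplogroup]
        )
        private = _draw_private(int(rng.poisson(config.private_rate)), rng)
        typed = _draw_typed_regions(config.coverage_model, config, rng)
        visible = frozenset(
            p for p in (set(motif) | set(private)) if typed.contains(p.position)
        )
        sample_id = f"SYN{i:05d}"
        samples.append(
            SampleProfile(sample_id, typed, visible, label=label)
        )
        records.append(
            {
                "sample_id": sample_id,
                "label": label,
                "haplogroup": haplogroup,
                "motif": motif,
                "private": frozenset(private),
            }
        )
    return ProfileDataset(tuple(samples)), GroundTruth(tuple(records))


def make_biased_split(
    config: SyntheticConfig,
    test_fraction: float,
    drop_class_in_test: Optional[str] = None,
    test_coverage_model: str = "published_like",
) -> Tuple[ProfileDataset, ProfileDataset, GroundTruth]:
    """Train/test split emulating independently assembled databases.

    The named class (if any) is removed from the test portion and the test
    coverage model re-applied to test samples, so the split reproduces the
    structure of a reference database paired with a literature-derived test
    set (one training class absent, much poorer HVR2 coverage).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if drop_class_in_test is not None and drop_class_in_test not in config.class_labels:
        raise ValueError("drop_class_in_test must be one of the class labels")
    base_config = replace(config, coverage_model="full")
    dataset, truth = generate_dataset(base_config)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(len(dataset))
    n_test = int(round(test_fraction * len(dataset)))
    test_idx = set(order[:n_test].tolist())
    train_samples: List[SampleProfile] = []
    test_samples: List[SampleProfile] = []
    for i, sample in enumerate(dataset):
        if i in test_idx:
            if drop_class_in_test is not None and sample.label == drop_class_in_test:
                continue
            typed = _draw_typed_regions(test_coverage_model, config, rng)
            visible = frozenset(
                p for p in sample.polymorphisms if typed.contains(p.position)
            )
            test_samples.append(
                SampleProfile(sample.sample_id, typed, visible, label=sample.label)
            )
        else:
            if config.coverage_model != "full":
                typed = _draw_typed_regions(config.coverage_model, config, rng)
                visible = frozenset(
                    p for p in sample.polymorphisms if typed.contains(p.position)
                )
                sample = SampleProfile(
                    sample.sample_id, typed, visible, label=sample.label
                )
            train_samples.append(sample)
    test = ProfileDataset(tuple(test_samples))
    if len(test) == 0:
        raise ValueError("test split is empty after class drop")
    return ProfileDataset(tuple(train_samples)), test, truth


def write_truth_table(truth: GroundTruth, sink) -> None:
    """TSV with columns sample_id, class, haplogroup."""
    from pathlib import Path

    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as handle:
            write_truth_table(truth, handle)
        return
    sink.write("sample_id\tclass\thaplogroup\n")
    for r in truth.records:
        sink.write(f"{r['sample_id']}\t{r['label']}\t{r['haplogroup']}\n")
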