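"""Parsing, validation and manipulation of mtDNA hypervariable-region profile tables.

Profiles are reported relative to the revised Cambridge Reference Sequence
(rCRS): each sample carries the sub-ranges of HVR1/HVR2 that were actually
sequenced ("typed" ranges) plus a list of polymorphism tokens such as
``16298C`` (substitution), ``16124.1C`` (insertion) or ``16189-`` (deletion).

The on-disk format is a TSV with header
``sample_id  label  country  ranges  polymorphisms`` where ``ranges`` is a
``;``-joined list of ``start-end`` pairs and ``polymorphisms`` is a
space-joined list of canonical tokens. Empty fields mean absent label/country
or a reference-identical (rCRS) sample over its typed range.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

#: Length of the rCRS mitochondrial reference.
RCRS_LENGTH = 16569
#: Hypervariable region 1, 1-based inclusive.
HVR1 = (16024, 16569)
#: Hypervariable region 2, 1-based inclusive.
HVR2 = (1, 576)
HVR1_LENGTH = HVR1[1] - HVR1[0] + 1  # 546
HVR2_LENGTH = HVR2[1] - HVR2[0] + 1  # 576
#: Total number of HVR positions (the feature-position universe).
HVR_LENGTH = HVR1_LENGTH + HVR2_LENGTH  # 1122

VALID_BASES = frozenset("ACGT")

PROFILE_COLUMNS = ("sample_id", "label", "country", "ranges", "polymorphisms")


class ProfileError(ValueError):
    """Base class for profile parsing/validation failures."""


class ParseError(ProfileError):
    """A malformed token, range string, or table row."""


class ValidationError(ProfileError):
    """Structurally valid input violating a dataset invariant."""


def hvr_axis_index(position: int) -> int:
    """Map an rCRS position to its index on the concatenated HVR1→HVR2 axis.

    HVR1 (16024..16569) occupies axis indices 0..545 and HVR2 (1..576)
    occupies 546..1121; the two regions are circularly adjacent on the
    mitochondrial genome, which motivates this axis order.
    """
    if HVR1[0] <= position <= HVR1[1]:
        return position - HVR1[0]
    if HVR2[0] <= position <= HVR2[1]:
        return HVR1_LENGTH + (position - HVR2[0])
    raise ValueError(f"position {position} lies outside HVR1/HVR2")


def hvr_position_at(index: int) -> int:
    """Inverse of :func:`hvr_axis_index`."""
    if not 0 <= index < HVR_LENGTH:
        raise ValueError(f"axis index {index} out of range")
    if index < HVR1_LENGTH:
        return HVR1[0] + index
    return HVR2[0] + (index - HVR1_LENGTH)


def in_hvr(position: int) -> bool:
    return HVR1[0] <= position <= HVR1[1] or HVR2[0] <= position <= HVR2[1]


_KIND_ORDER = {"substitution": 0, "insertion": 1, "deletion": 2}

_SUB_RE = re.compile(r"^(\d+)([A-Za-z])$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([A-Za-z])$")
_DEL_RE = re.compile(r"^(\d+)(-|DEL|del)$")


@dataclass(frozen=True)
class Polymorphism:
    """A single rCRS-relative variant.

    ``16298C`` is a substitution at 16298, ``16124.1C`` the first inserted
    base after 16124, ``16189-`` a deletion of position 16189. Deletions are
    canonicalized to the ``<pos>-`` form; ``<pos>DEL`` is accepted on input.
    """

    position: int
    kind: str
    base: Optional[str] = None
    insert_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ValueError(f"unknown polymorphism kind {self.kind!r}")
        if not 1 <= self.position <= RCRS_LENGTH:
            raise ValueError(
                f"position {self.position} outside rCRS coordinates [1, {RCRS_LENGTH}]"
            )
        if self.kind == "deletion":
            if self.base is not None:
                raise ValueError("deletions carry no base")
        else:
            if self.base not in VALID_BASES:
                raise ValueError(f"base {self.base!r} not one of A, C, G, T")
        if self.kind == "insertion":
            if self.insert_index is None or self.insert_index < 1:
                raise ValueError("insertions require a positive insert_index")
        elif self.insert_index is not None:
            raise ValueError("insert_index is only valid for insertions")

    @property
    def sort_key(self) -> tuple:
        return (
            self.position,
            _KIND_ORDER[self.kind],
            self.insert_index or 0,
            self.base or "",
        )

    @property
    def axis_sort_key(self) -> tuple:
        """Sort key along the concatenated HVR1→HVR2 axis (used by scans)."""
        return (
            hvr_axis_index(self.position),
            _KIND_ORDER[self.kind],
            self.insert_index or 0,
            self.base or "",
        )

    def render(self) -> str:
        if self.kind == "substitution":
            return f"{self.position}{self.base}"
        if self.kind == "insertion":
            return f"{self.position}.{self.insert_index}{self.base}"
        return f"{self.position}-"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_polymorphism(token: str) -> Polymorphism:
    """Parse a polymorphism token into its structured form.

    Accepted grammar: ``<pos><BASE>`` (substitution), ``<pos>.<idx><BASE>``
    (insertion), ``<pos>-`` or ``<pos>DEL`` (deletion). IUPAC ambiguity codes
    are rejected: silently coercing heteroplasmies would corrupt the feature
    space.
    """
    if not token:
        raise ParseError("empty polymorphism token")
    m = _INS_RE.match(token)
    if m:
        pos, idx, base = int(m.group(1)), int(m.group(2)), m.group(3).upper()
        _check_pos_base(token, pos, base)
        if idx < 1:
            raise ParseError(f"insertion index must be >= 1 in token {token!r}")
        return Polymorphism(pos, "insertion", base, idx)
    m = _DEL_RE.match(token)
    if m:
        pos = int(m.group(1))
        _check_pos_base(token, pos, None)
        return Polymorphism(pos, "deletion")
    m = _SUB_RE.match(token)
    if m:
        pos, base = int(m.group(1)), m.group(2).upper()
        _check_pos_base(token, pos, base)
        return Polymorphism(pos, "substitution", base)
    raise ParseError(f"malformed polymorphism token {token!r}")


def _check_pos_base(token: str, pos: int, base: Optional[str]) -> None:
    if not 1 <= pos <= RCRS_LENGTH:
        raise ParseError(
            f"position {pos} in token {token!r} outside rCRS range [1, {RCRS_LENGTH}]"
        )
    if base is not None and base not in VALID_BASES:
        raise ParseError(f"base {base!r} in token {token!r} not one of A, C, G, T")


@dataclass(frozen=True)
class RegionSet:
    """An ordered set of disjoint 1-based inclusive intervals inside HVR1 ∪ HVR2."""

    regions: tuple = ()

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.regions:
            if start > end:
                raise ValidationError(f"region {start}-{end} has start > end")
            within_hvr1 = HVR1[0] <= start and end <= HVR1[1]
            within_hvr2 = HVR2[0] <= start and end <= HVR2[1]
            if not (within_hvr1 or within_hvr2):
                raise ValidationError(
                    f"region {start}-{end} not contained in HVR1 ({HVR1[0]}-{HVR1[1]}) "
                    f"or HVR2 ({HVR2[0]}-{HVR2[1]})"
                )
            if prev_end is not None and start <= prev_end:
                raise ValidationError("regions must be disjoint and sorted")
            prev_end = end

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[int]]) -> "RegionSet":
        ordered = tuple(sorted((int(s), int(e)) for s, e in pairs))
        return cls(ordered)

    @classmethod
    def from_string(cls, text: str) -> "RegionSet":
        text = text.strip()
        if not text:
            return cls(())
        pairs = []
        for chunk in text.split(";"):
            m = re.match(r"^(\d+)-(\d+)$", chunk.strip())
            if not m:
                raise ParseError(f"malformed range {chunk!r}")
            pairs.append((int(m.group(1)), int(m.group(2))))
        return cls.from_pairs(pairs)

    def to_string(self) -> str:
        return ";".join(f"{s}-{e}" for s, e in self.regions)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.regions)

    def contains_region(self, other: "RegionSet") -> bool:
        """True if every position of *other* is covered by this set."""
        return all(
            any(s <= os and oe <= e for s, e in self.regions)
            for os, oe in other.regions
        )

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out = []
        for s1, e1 in self.regions:
            for s2, e2 in other.regions:
                s, e = max(s1, s2), min(e1, e2)
                if s <= e:
                    out.append((s, e))
        return RegionSet.from_pairs(out)

    def union(self, other: "RegionSet") -> "RegionSet":
        covered = sorted(
            set(self.positions()) | set(other.positions()), key=hvr_axis_index
        )
        return RegionSet.from_pairs(_runs(covered))

    def positions(self) -> Iterator[int]:
        for s, e in self.regions:
            yield from range(s, e + 1)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.regions)

    @property
    def is_empty(self) -> bool:
        return not self.regions


def _runs(sorted_positions: Sequence[int]) -> Iterator[tuple]:
    """Collapse positions (sorted along the HVR axis) into maximal runs."""
    run_start = None
    prev = None
    for p in sorted_positions:
        if run_start is None:
            run_start = prev = p
            continue
        if p == prev + 1 and hvr_axis_index(p) == hvr_axis_index(prev) + 1:
            prev = p
        else:
            yield (run_start, prev)
            run_start = prev = p
    if run_start is not None:
        yield (run_start, prev)


@dataclass(frozen=True)
class SampleProfile:
    """One sample: typed ranges plus rCRS-relative polymorphisms.

    Typed ranges are carried explicitly rather than inferred from the
    polymorphism list — a reference-identical typed region is informative
    (absence of polymorphism is data), whereas an untyped region is missing
    data.
    """

    sample_id: str
    typed: RegionSet
    polymorphisms: frozenset = frozenset()
    label: Optional[str] = None
    country: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "polymorphisms", frozenset(self.polymorphisms))
        for poly in self.polymorphisms:
            if not self.typed.contains(poly.position):
                raise ValidationError(
                    f"sample {self.sample_id!r}: polymorphism {poly.render()} "
                    f"outside typed ranges {self.typed.to_string()!r}"
                )

    def sorted_polymorphisms(self) -> list:
        return sorted(self.polymorphisms, key=lambda p: p.sort_key)


@dataclass(frozen=True)
class ProfileDataset:
    """An ordered collection of :class:`SampleProfile` with unique ids."""

    samples: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        seen = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleProfile]:
        return iter(self.samples)

    @property
    def label_universe(self) -> tuple:
        """Sorted distinct non-absent labels."""
        return tuple(sorted({s.label for s in self.samples if s.label is not None}))

    def labels(self) -> list:
        return [s.label for s in self.samples]

    def subset(self, indices: Iterable[int]) -> "ProfileDataset":
        return ProfileDataset(tuple(self.samples[i] for i in indices))


def read_profile_table(source: Union[str, Path, TextIO]) -> ProfileDataset:
    """Read a profile TSV (see module docstring for the dialect)."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as handle:
            return read_profile_table(handle)
    reader = csv.reader(source, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty profile table (missing header)") from None
    if tuple(header) != PROFILE_COLUMNS:
        raise ParseError(
            f"unexpected header {header!r}; expected {list(PROFILE_COLUMNS)}"
        )
    samples = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not cell for cell in row):
            continue
        if len(row) != len(PROFILE_COLUMNS):
            raise ParseError(f"line {lineno}: expected {len(PROFILE_COLUMNS)} fields")
        sample_id, label, country, ranges, tokens = row
        typed = RegionSet.from_string(ranges)
        polys = []
        for token in tokens.split():
            try:
                polys.append(parse_polymorphism(token))
            except ParseError as exc:
                raise ParseError(f"sample {sample_id!r}: {exc}") from None
        samples.append(
            SampleProfile(
                sample_id=sample_id,
                typed=typed,
                polymorphisms=frozenset(polys),
                label=label or None,
                country=country or None,
            )
        )
    return ProfileDataset(tuple(samples))


def write_profile_table(dataset: ProfileDataset, sink: Union[str, Path, TextIO]) -> None:
    """Write a dataset in the profile TSV dialect; round-trips with the reader."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as handle:
            write_profile_table(dataset, handle)
        return
    writer = csv.writer(sink, delimiter="\t", lineterminator="\n")
    writer.writerow(PROFILE_COLUMNS)
    for s in dataset:
        writer.writerow(
            [
                s.sample_id,
                s.label or "",
                s.country or "",
                s.typed.to_string(),
                " ".join(p.render() for p in s.sorted_polymorphisms()),
            ]
        )


def profile_table_text(dataset: ProfileDataset) -> str:
    buf = io.StringIO()
    write_profile_table(dataset, buf)
    return buf.getvalue()


def trim_dataset(
    dataset: ProfileDataset,
    region: RegionSet,
    require_full_coverage: bool = False,
) -> ProfileDataset:
    """Intersect every sample's typed ranges and polymorphisms with *region*.

    With ``require_full_coverage``, samples whose typed ranges do not fully
    contain *region* are dropped (how the trimmed subsets of the source
    databases were built). Idempotent.
    """
    kept = []
    for s in dataset:
        if require_full_coverage and not s.typed.contains_region(region):
            continue
        typed = s.typed.intersect(region)
        polys = frozenset(p for p in s.polymorphisms if typed.contains(p.position))
        kept.append(
            SampleProfile(s.sample_id, typed, polys, label=s.label, country=s.country)
        )
    if not kept:
        logger.warning("trim_dataset produced an empty dataset")
    return ProfileDataset(tuple(kept))


def coverage_profile(dataset: ProfileDataset):
    """Fraction of samples typed at each HVR position.

    Returns a length-1122 numpy array indexed along the concatenated
    HVR1→HVR2 axis (see :func:`hvr_axis_index`); values lie in [0, 1].
    """
    import numpy as np

    if len(dataset) == 0:
        raise ValidationError("coverage_profile requires a non-empty dataset")
    counts = np.zeros(HVR_LENGTH, dtype=np.int64)
    for s in dataset:
        for start, end in s.typed.regions:
            i, j = hvr_axis_index(start), hvr_axis_index(end)
            counts[i : j + 1] += 1
    return counts / len(dataset)


def composition_summary(dataset: ProfileDataset) -> list:
    """Per-class counts and percentage shares, share rounded to one decimal.

    Returns ``[{"label", "count", "percent"}, ...]`` ordered by the dataset's
    label universe. Unlabeled samples still count toward the total.
    """
    total = len(dataset)
    if total == 0:
        raise ValidationError("composition_summary requires a non-empty dataset")
    out = []
    for label in dataset.label_universe:
        count = sum(1 for s in dataset if s.label == label)
        out.append(
            {"label": label, "count": count, "percent": round(100.0 * count / total, 1)}
        )
    return out
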