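"""Dataset curation and I/O for short-axis cine slice stacks.

A dataset on disk is::

    <root>/<subject_id>/<phase_id>/<slice_index>.png   # 8-bit grayscale
    <root>/labels.json                                 # subject -> phase -> index -> token
    <root>/manifest.json                               # written by the phantom generator

Subjects are screened by three exclusion rules before anything downstream
sees them: duplicated slice identifiers, inconsistent slice counts between
the two cardiac phases, and non-contiguous slice indices within a phase.
A subject is retained only if it violates none of them.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from PIL import Image

PHASES = ("diastole", "systole")

__all__ = [
    "PHASES",
    "SliceLabel",
    "SliceImage",
    "SliceStack",
    "LabelStore",
    "SplitAssignment",
    "Violation",
    "ViolationKind",
    "CuratedDataset",
    "LabelStoreError",
    "rescale_to_uint8",
    "validate_subject",
    "curate_dataset",
    "load_slice_stack",
    "split_subjects",
    "load_label_store",
    "save_label_store",
    "assemble_samples",
    "read_dicom_slice",
    "pick_systolic_frame",
]


class SliceLabel(enum.IntEnum):
    """Five ordered slice levels, apex to base.

    The ordinal encodes anatomical order: out-of-apical (no LV blood pool),
    apical (myocardial ring, no papillary muscle), mid (papillary muscle
    visible), basal (larger ring, no papillary muscle), out-of-basal
    (crescent of basal lateral myocardium, no discernible pool).
    """

    OAP = 0
    AP = 1
    MID = 2
    BS = 3
    OBS = 4

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "SliceLabel":
        try:
            return cls[token.upper()]
        except KeyError:
            raise ValueError(f"unknown class token: {token!r}") from None


N_CLASSES = 5
MAX_SLICES = 25


@dataclass(frozen=True)
class SliceImage:
    """One grayscale slice with its identifying metadata."""

    pixels: np.ndarray  # uint8, 2-D
    subject_id: str
    phase_id: str
    slice_index: int

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")


@dataclass
class SliceStack:
    """Ordered slices for one (subject, phase), apex to base."""

    subject_id: str
    phase_id: str
    slices: list[SliceImage]

    def __post_init__(self) -> None:
        idx = [s.slice_index for s in self.slices]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("slice indices must be strictly increasing")
        if sorted(idx) != list(range(min(idx), min(idx) + len(idx))):
            raise ValueError("slice indices must be contiguous")
        if not 1 <= len(self.slices) <= MAX_SLICES:
            raise ValueError(f"stack length must be in [1, {MAX_SLICES}]")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def indices(self) -> list[int]:
        return [s.slice_index for s in self.slices]


class ViolationKind(str, enum.Enum):
    DUPLICATE_IDENTIFIER = "duplicate-identifier"
    INCONSISTENT_PHASE_SLICE_COUNT = "inconsistent-phase-slice-count"
    NON_CONTIGUOUS_INDICES = "non-contiguous-indices"


@dataclass(frozen=True)
class Violation:
    kind: ViolationKind
    detail: str


def rescale_to_uint8(raw: np.ndarray) -> np.ndarray:
    """Linearly map an intensity image to integers in [0, 255].

    The map is per-image min-max: round(255 * (x - min) / (max - min)).
    A constant image has no dynamic range and maps to all zeros.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise ValueError("cannot rescale an empty array")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(raw.shape, dtype=np.uint8)
    scaled = np.rint(255.0 * (raw - lo) / (hi - lo))
    return scaled.astype(np.uint8)


def _parse_slice_files(phase_dir: Path) -> list[tuple[int, Path]]:
    """Map PNG files to slice indices; filename stem parses as the index."""
    out = []
    for f in sorted(phase_dir.glob("*.png")):
        try:
            out.append((int(f.stem), f))
        except ValueError:
            raise OSError(f"unparseable slice filename: {f}") from None
    return out


def validate_subject(subject_dir: Path) -> list[Violation]:
    """Screen one subject directory against the three exclusion rules.

    Returns an empty list for a clean subject.  I/O problems (missing or
    unreadable directories) raise ``OSError`` — they are not rule
    violations.
    """
    subject_dir = Path(subject_dir)
    if not subject_dir.is_dir():
        raise OSError(f"subject directory not readable: {subject_dir}")
    violations: list[Violation] = []
    counts: dict[str, int] = {}
    for phase in sorted(p.name for p in subject_dir.iterdir() if p.is_dir()):
        entries = _parse_slice_files(subject_dir / phase)
        indices = [i for i, _ in entries]
        unique = sorted(set(indices))
        if len(unique) != len(indices):
            dups = sorted({i for i in indices if indices.count(i) > 1})
            violations.append(
                Violation(
                    ViolationKind.DUPLICATE_IDENTIFIER,
                    f"phase {phase}: duplicated slice indices {dups}",
                )
            )
        counts[phase] = len(unique)
        if unique and unique != list(range(unique[0], unique[0] + len(unique))):
            missing = sorted(set(range(unique[0], unique[-1] + 1)) - set(unique))
            violations.append(
                Violation(
                    ViolationKind.NON_CONTIGUOUS_INDICES,
                    f"phase {phase}: missing slice indices {missing}",
                )
            )
    if len(set(counts.values())) > 1:
        violations.append(
            Violation(
                ViolationKind.INCONSISTENT_PHASE_SLICE_COUNT,
                f"slice counts per phase: {counts}",
            )
        )
    return violations


def load_slice_stack(subject_dir: Path, subject_id: str, phase_id: str) -> SliceStack:
    """Read one phase's PNG series into a SliceStack (ascending index)."""
    entries = _parse_slice_files(Path(subject_dir) / phase_id)
    slices = [
        SliceImage(
            pixels=np.asarray(Image.open(path).convert("L")),
            subject_id=subject_id,
            phase_id=phase_id,
            slice_index=idx,
        )
        for idx, path in sorted(entries)
    ]
    return SliceStack(subject_id=subject_id, phase_id=phase_id, slices=slices)


@dataclass
class CuratedDataset:
    """Retained subjects plus a record of why the others were excluded."""

    root: Path
    retained: list[str]
    excluded: dict[str, list[Violation]] = field(default_factory=dict)

    def stack(self, subject_id: str, phase_id: str) -> SliceStack:
        return load_slice_stack(self.root / subject_id, subject_id, phase_id)

    def phases(self, subject_id: str) -> list[str]:
        d = self.root / subject_id
        return sorted(p.name for p in d.iterdir() if p.is_dir())


def curate_dataset(root: Path) -> CuratedDataset:
    """Apply the exclusion rules to every subject directory under ``root``."""
    root = Path(root)
    retained, excluded = [], {}
    for sub in sorted(p.name for p in root.iterdir() if p.is_dir()):
        violations = validate_subject(root / sub)
        if violations:
            excluded[sub] = violations
        else:
            retained.append(sub)
    return CuratedDataset(root=root, retained=retained, excluded=excluded)


# ---------------------------------------------------------------------------
# Label store


class LabelStoreError(ValueError):
    """Raised when a label sidecar file fails to parse."""


@dataclass
class LabelStore:
    """Mapping (subject, phase, slice_index) -> SliceLabel, JSON-persisted.

    Partial stores are valid: labeling can be saved and resumed at any
    point, so lookups on unlabeled slices simply fail.
    """

    mapping: dict[tuple[str, str, int], SliceLabel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, subject: str, phase: str, index: int) -> SliceLabel:
        key = (subject, phase, index)
        if key not in self.mapping:
            raise KeyError(f"no label for subject={subject} phase={phase} slice={index}")
        return self.mapping[key]

    def set(self, subject: str, phase: str, index: int, label: SliceLabel) -> None:
        self.mapping[(subject, phase, index)] = label

    def sequence(self, subject: str, phase: str, indices: Sequence[int]) -> list[SliceLabel]:
        return [self.get(subject, phase, i) for i in indices]


def save_label_store(store: LabelStore, path: Path) -> None:
    nested: dict[str, dict[str, dict[str, str]]] = {}
    for (subject, phase, index), label in sorted(store.mapping.items()):
        nested.setdefault(subject, {}).setdefault(phase, {})[str(index)] = label.token
    Path(path).write_text(json.dumps(nested, indent=1, sort_keys=True))


def load_label_store(path: Path) -> LabelStore:
    try:
        nested = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise LabelStoreError(f"label file {path} is not valid JSON: {e}") from e
    store = LabelStore()
    for subject, phases in nested.items():
        for phase, entries in phases.items():
            for index, token in entries.items():
                try:
                    label = SliceLabel.from_token(token)
                except ValueError as e:
                    raise LabelStoreError(
                        f"record ({subject}, {phase}, {index}): {e}"
                    ) from None
                store.set(subject, phase, int(index), label)
    return store


# ---------------------------------------------------------------------------
# Subject-wise split

PARTITIONS = ("training", "validation", "testing")
DEFAULT_FRACTIONS = (0.591, 0.220, 0.189)


@dataclass(frozen=True)
class SplitAssignment:
    assignment: Mapping[str, str]  # subject_id -> partition name
    fractions: tuple[float, float, float]
    seed: int

    def members(self, partition: str) -> list[str]:
        return sorted(s for s, p in self.assignment.items() if p == partition)

    def sizes(self) -> tuple[int, int, int]:
        return tuple(len(self.members(p)) for p in PARTITIONS)  # type: ignore[return-value]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    rem = n - sum(sizes)
    # distribute leftovers by descending fractional part; ties by partition order
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return sizes


def split_subjects(
    subject_ids: Iterable[str],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition subjects into training/validation/testing.

    The partition is subject-wise: a subject's images all land in one
    partition.  Sizes follow largest-remainder rounding of the fractions,
    so e.g. 974 subjects at (0.591, 0.220, 0.189) give (576, 214, 184).
    """
    ids = sorted(set(subject_ids))
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(ids) < n_nonzero:
        raise ValueError(
            f"{len(ids)} subjects cannot populate {n_nonzero} nonzero partitions"
        )
    sizes = _largest_remainder(len(ids), fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment: dict[str, str] = {}
    start = 0
    for name, size in zip(PARTITIONS, sizes):
        for k in perm[start : start + size]:
            assignment[ids[k]] = name
        start += size
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# Sample assembly


def assemble_samples(
    dataset: CuratedDataset,
    labels: LabelStore,
    mode: Literal["per-image", "per-sequence"],
    subjects: Sequence[str] | None = None,
):
    """Pair curated images with labels.

    per-image: one ``(SliceImage, SliceLabel)`` per labeled slice — the
    unit the CNN-alone classifier trains on.  per-sequence: one
    ``(SliceStack, [SliceLabel, ...])`` per (subject, phase) — exactly two
    per subject — the unit the sequence models train on.
    """
    if mode not in ("per-image", "per-sequence"):
        raise ValueError(f"unknown mode {mode!r}")
    chosen = list(subjects) if subjects is not None else list(dataset.retained)
    samples = []
    for subject in chosen:
        for phase in dataset.phases(subject):
            stack = dataset.stack(subject, phase)
            try:
                seq = labels.sequence(subject, phase, stack.indices)
            except KeyError as e:
                raise ValueError(f"missing label: {e}") from None
            if mode == "per-image":
                samples.extend(zip(stack.slices, seq))
            else:
                samples.append((stack, seq))
    return samples


# ---------------------------------------------------------------------------
# Real-data helpers (optional)


def read_dicom_slice(path: Path, subject_id: str, phase_id: str, slice_index: int) -> SliceImage:
    """Minimal DICOM ingestion: pixel array rescaled to uint8 plus the three
    identifiers.  Requires pydicom; intended for real cine data only."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    return SliceImage(
        pixels=rescale_to_uint8(ds.pixel_array),
        subject_id=subject_id,
        phase_id=phase_id,
        slice_index=slice_index,
    )


def pick_systolic_frame(frames: Sequence[np.ndarray]) -> int:
    """Stand-in systolic frame selector for full cine series.

    Real pipelines select end-systole by ventricular volume; this helper
    simply proxies blood-pool area by the count of pixels above the frame's
    median and returns the frame index minimizing it (frame 0 is taken as
    diastole by convention).  It is a documented stand-in, not the method
    the source data's curation used.
    """
    if not frames:
        raise ValueError("empty frame list")
    areas = [int((np.asarray(f) > np.median(f)).sum()) for f in frames]
    return int(np.argmin(areas))
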