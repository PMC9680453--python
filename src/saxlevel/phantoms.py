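"""Synthetic short-axis cardiac phantoms with ground-truth slice levels.

Real short-axis cine stacks cannot be redistributed, so this module
generates stacks that encode only the *label-defining* morphology of the
five slice levels:

* **oap** — textured background, no LV blood pool, no myocardial ring;
* **ap**  — dark myocardial annulus enclosing a small bright blood pool,
  no papillary muscles;
* **mid** — annulus + pool with one or more dark papillary-muscle blobs
  inside the pool;
* **bs**  — larger annulus + pool, no blobs;
* **obs** — dark crescent (partial annulus) of basal lateral myocardium
  with no discernible pool.

Each subject has two phases (diastole, systole) rendered from the same
label sequence; systole shrinks the cavity.  The renderer also emits the
exact pool/blob/ring masks it drew, as a side channel, so tests can verify
the morphology without image analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .curation import PHASES, LabelStore, SliceLabel, save_label_store

__all__ = [
    "PhantomConfig",
    "SliceGeometry",
    "RenderedSlice",
    "PhantomSubject",
    "render_slice",
    "sample_geometry",
    "generate_label_sequence",
    "generate_subject",
    "generate_dataset",
    "VIOLATION_KINDS",
]

VIOLATION_KINDS = (
    "duplicate-identifier",
    "inconsistent-phase-slice-count",
    "non-contiguous-indices",
)

# rendered intensity levels (uint8 scale)
_BG_MEAN = 75.0
_MYO = 35.0
_POOL = 215.0
_BLOB = 50.0


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; defaults define the study conditions.

    Radii and thicknesses are in pixels at the given ``image_size``;
    ``noise_sd`` is the additive Gaussian noise level in 8-bit intensity
    units.  ``systolic_scale_range`` bounds the per-subject cavity
    contraction factor (systole < diastole).
    """

    n_subjects: int = 20
    image_size: int = 128
    slices_min: int = 8
    slices_max: int = 25
    noise_sd: float = 8.0
    cavity_radius_ap: tuple[float, float] = (6.0, 10.0)
    cavity_radius_mid: tuple[float, float] = (10.0, 14.0)
    cavity_radius_bs: tuple[float, float] = (13.0, 18.0)
    wall_thickness: tuple[float, float] = (4.0, 7.0)
    blob_radius: tuple[float, float] = (2.0, 4.0)
    systolic_scale_range: tuple[float, float] = (0.60, 0.85)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slices_min < 1:
            raise ValueError("slices_min must be >= 1")
        if self.slices_max > 25:
            raise ValueError("slices_max must be <= 25 (model time-step bound)")
        if self.slices_min > self.slices_max:
            raise ValueError("slices_min must not exceed slices_max")
        if not (0 < self.systolic_scale_range[0] <= self.systolic_scale_range[1] < 1.0):
            raise ValueError("systolic scale must lie in (0, 1)")
        for name in ("cavity_radius_ap", "cavity_radius_mid", "cavity_radius_bs",
                     "wall_thickness", "blob_radius"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} range must be positive and ordered")
        outer = self.cavity_radius_bs[1] + self.wall_thickness[1]
        if outer >= self.image_size / 2 - 4:
            raise ValueError(
                f"largest ring (radius {outer:.1f}px) does not fit inside a "
                f"{self.image_size}px image with margin"
            )


@dataclass(frozen=True)
class SliceGeometry:
    """One subject's sampled geometry, shared by all of its slices."""

    cavity_radius: Mapping[SliceLabel, float]  # for AP, MID, BS
    wall_thickness: float
    blob_radius: float
    n_blobs: int
    systolic_scale: float
    center: tuple[float, float]
    crescent_start: float  # radians
    crescent_span: float  # radians


@dataclass(frozen=True)
class RenderedSlice:
    """Rendered image plus the exact masks the renderer drew (side channel)."""

    image: np.ndarray  # uint8
    pool_mask: np.ndarray  # bool, blood pool pixels
    blob_mask: np.ndarray  # bool, papillary blob pixels
    ring_mask: np.ndarray  # bool, myocardial ring / crescent pixels


def sample_geometry(config: PhantomConfig, rng: np.random.Generator) -> SliceGeometry:
    u = lambda lo_hi: float(rng.uniform(*lo_hi))
    size = config.image_size
    jitter = rng.uniform(-0.04 * size, 0.04 * size, size=2)
    return SliceGeometry(
        cavity_radius={
            SliceLabel.AP: u(config.cavity_radius_ap),
            SliceLabel.MID: u(config.cavity_radius_mid),
            SliceLabel.BS: u(config.cavity_radius_bs),
        },
        wall_thickness=u(config.wall_thickness),
        blob_radius=u(config.blob_radius),
        n_blobs=int(rng.integers(1, 4)),
        systolic_scale=u(config.systolic_scale_range),
        center=(size / 2 + float(jitter[0]), size / 2 + float(jitter[1])),
        crescent_start=float(rng.uniform(0, 2 * np.pi)),
        crescent_span=float(rng.uniform(np.pi * 0.5, np.pi * 0.9)),
    )


def _check_fit(geometry: SliceGeometry, image_size: int) -> None:
    outer = max(geometry.cavity_radius.values()) + geometry.wall_thickness
    cy, cx = geometry.center
    for c in (cy, cx):
        if c - outer < 0 or c + outer > image_size:
            raise ValueError(
                f"ring of outer radius {outer:.1f}px centered at ({cy:.1f}, {cx:.1f}) "
                f"does not fit a {image_size}px image"
            )


def render_slice(
    level: SliceLabel,
    phase: str,
    geometry: SliceGeometry,
    noise_seed: int,
    image_size: int = 128,
    noise_sd: float = 8.0,
) -> RenderedSlice:
    """Render one slice at the given level and cardiac phase.

    Deterministic in all arguments: the same call returns a bit-identical
    ``RenderedSlice``.  Systole shrinks the cavity by the geometry's
    systolic scale and thickens the wall correspondingly.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    _check_fit(geometry, image_size)
    rng = np.random.default_rng(noise_seed)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    cy, cx = geometry.center
    r = np.hypot(yy - cy, xx - cx)

    # textured background: smoothed noise so no image is constant
    canvas = _BG_MEAN + gaussian_filter(rng.normal(0.0, 22.0, r.shape), sigma=5.0)

    pool_mask = np.zeros(r.shape, dtype=bool)
    blob_mask = np.zeros(r.shape, dtype=bool)
    ring_mask = np.zeros(r.shape, dtype=bool)

    scale = geometry.systolic_scale if phase == "systole" else 1.0
    if level in (SliceLabel.AP, SliceLabel.MID, SliceLabel.BS):
        cavity = geometry.cavity_radius[level] * scale
        # systolic wall thickening: myocardium conserves area as cavity shrinks
        wall = geometry.wall_thickness * (1.0 + 0.5 * (1.0 - scale))
        pool_mask = r < cavity
        ring_mask = (r >= cavity) & (r < cavity + wall)
        canvas[pool_mask] = _POOL
        canvas[ring_mask] = _MYO
        if level is SliceLabel.MID:
            for k in range(geometry.n_blobs):
                ang = geometry.crescent_start + 2 * np.pi * k / geometry.n_blobs
                br = min(geometry.blob_radius, 0.45 * cavity)
                dist = max(cavity - br - 1.0, 0.0) * 0.6
                by, bx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
                blob = (np.hypot(yy - by, xx - bx) < br) & pool_mask
                blob_mask |= blob
            canvas[blob_mask] = _BLOB
    elif level is SliceLabel.OBS:
        # crescent: partial annulus at basal radius, no enclosed pool
        cavity = geometry.cavity_radius[SliceLabel.BS] * scale
        wall = geometry.wall_thickness * (1.0 + 0.5 * (1.0 - scale))
        theta = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
        span = (theta - geometry.crescent_start) % (2 * np.pi) < geometry.crescent_span
        ring_mask = (r >= cavity) & (r < cavity + wall) & span
        canvas[ring_mask] = _MYO
    # OAP: background texture only — no pool, no ring

    canvas = canvas + rng.normal(0.0, noise_sd, r.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return RenderedSlice(image=image, pool_mask=pool_mask, blob_mask=blob_mask, ring_mask=ring_mask)


def generate_label_sequence(
    n_slices: int, rng: np.random.Generator
) -> list[SliceLabel]:
    """Draw a monotone apex-to-base label sequence oap* ap* mid* bs* obs*.

    ap, mid and bs each get at least one slice (so at least three classes
    always occur); the out-of-level runs at either end are present with
    high but not certain probability, so all five classes occur across a
    dataset of realistic size.
    """
    include = {
        SliceLabel.OAP: bool(rng.random() < 0.85),
        SliceLabel.AP: True,
        SliceLabel.MID: True,
        SliceLabel.BS: True,
        SliceLabel.OBS: bool(rng.random() < 0.85),
    }
    classes = [c for c in SliceLabel if include[c]]
    counts = {c: 1 for c in classes}
    extra = n_slices - len(classes)
    # interior levels are thicker than the out-of-level caps
    weights = np.array(
        [{SliceLabel.OAP: 1.0, SliceLabel.AP: 1.6, SliceLabel.MID: 1.7,
          SliceLabel.BS: 1.3, SliceLabel.OBS: 1.0}[c] for c in classes]
    )
    draw = rng.multinomial(extra, weights / weights.sum())
    for c, d in zip(classes, draw):
        counts[c] += int(d)
    seq: list[SliceLabel] = []
    for c in SliceLabel:  # ordinal order == apex-to-base order
        seq.extend([c] * counts.get(c, 0))
    return seq


@dataclass
class PhantomSubject:
    """One generated subject: per-phase rendered stacks + shared labels."""

    subject_id: str
    labels: list[SliceLabel]
    rendered: dict[str, list[RenderedSlice]] = field(default_factory=dict)
    geometry: SliceGeometry | None = None

    @property
    def n_slices(self) -> int:
        return len(self.labels)


def generate_subject(config: PhantomConfig, subject_seed: int, subject_id: str = "subject") -> PhantomSubject:
    """Generate one subject: labels, geometry and both phase stacks.

    Deterministic in (config, subject_seed).  The label sequence is shared
    across the two phases and its ordinals are non-decreasing apex→base by
    construction.
    """
    rng = np.random.default_rng(subject_seed)
    n_slices = int(rng.integers(config.slices_min, config.slices_max + 1))
    labels = generate_label_sequence(n_slices, rng)
    geometry = sample_geometry(config, rng)
    noise_seeds = rng.integers(0, 2**31, size=(len(PHASES), n_slices))
    rendered: dict[str, list[RenderedSlice]] = {}
    for p, phase in enumerate(PHASES):
        rendered[phase] = [
            render_slice(
                labels[i], phase, geometry, int(noise_seeds[p, i]),
                image_size=config.image_size, noise_sd=config.noise_sd,
            )
            for i in range(n_slices)
        ]
    return PhantomSubject(subject_id=subject_id, labels=labels, rendered=rendered, geometry=geometry)


def _subject_seed(config_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([config_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _corrupt(subject_dir: Path, kind: str, labels: LabelStore, subject_id: str, n_slices: int) -> None:
    if kind == "duplicate-identifier":
        # an extra file whose parsed slice index collides with an existing one
        mid = n_slices // 2
        src = subject_dir / PHASES[0] / f"{mid:03d}.png"
        (subject_dir / PHASES[0] / f"{mid}.png").write_bytes(src.read_bytes())
    elif kind == "inconsistent-phase-slice-count":
        last = n_slices - 1
        (subject_dir / PHASES[1] / f"{last:03d}.png").unlink()
        labels.mapping.pop((subject_id, PHASES[1], last), None)
    elif kind == "non-contiguous-indices":
        gap = min(3, n_slices - 2)  # interior index, echoing "index 3 missing"
        for phase in PHASES:
            (subject_dir / phase / f"{gap:03d}.png").unlink()
            labels.mapping.pop((subject_id, phase, gap), None)
    else:
        raise ValueError(f"unknown violation kind {kind!r}; expected one of {VIOLATION_KINDS}")


def generate_dataset(
    config: PhantomConfig,
    out_dir: Path,
    planted_violations: Mapping[str, str] | None = None,
) -> dict:
    """Write a phantom dataset in the curation on-disk layout.

    Layout: ``<out_dir>/<subject>/<phase>/<index>.png`` plus ``labels.json``
    and ``manifest.json``.  ``planted_violations`` maps subject ids to one
    of the three exclusion-rule kinds and corrupts those subjects on disk so
    curation can be exercised; the manifest records clean vs corrupted ids.
    Byte-identical output for identical (config, violations).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subject_ids = [f"subj{i:03d}" for i in range(config.n_subjects)]
    plan = dict(planted_violations or {})
    unknown = set(plan) - set(subject_ids)
    if unknown:
        raise ValueError(f"violation plan names unknown subjects: {sorted(unknown)}")
    for kind in plan.values():
        if kind not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind {kind!r}")

    labels = LabelStore()
    for i, subject_id in enumerate(subject_ids):
        subject = generate_subject(config, _subject_seed(config.seed, i), subject_id)
        sdir = out_dir / subject_id
        for phase in PHASES:
            pdir = sdir / phase
            pdir.mkdir(parents=True, exist_ok=True)
            for idx, rendered in enumerate(subject.rendered[phase]):
                Image.fromarray(rendered.image, mode="L").save(pdir / f"{idx:03d}.png")
                labels.set(subject_id, phase, idx, subject.labels[idx])
        if subject_id in plan:
            _corrupt(sdir, plan[subject_id], labels, subject_id, subject.n_slices)

    save_label_store(labels, out_dir / "labels.json")
    manifest = {
        "subjects": subject_ids,
        "clean": [s for s in subject_ids if s not in plan],
        "corrupted": plan,
        "phases": list(PHASES),
        "direction": "apex_to_base",
        "seed": config.seed,
        "config": asdict(config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
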