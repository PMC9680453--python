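"""Frozen-backbone feature extraction and padded sequence assembly.

Transfer learning here is the fixed-feature-extractor setting: a frozen
convolutional backbone maps each slice image to a global-average-pooled
feature vector, and only the classifier heads are ever trained.  Four
named ImageNet backbones are described with their published feature
dimensions; since their pretrained weights are not bundled, they are
usable with ``weights="random"`` (a seeded, frozen random convolutional
trunk projected to the declared dimension).  ``TinyTest`` is a small
random backbone intended as the default extractor for CPU experiments.

Sequences are post-padded to 25 time steps — the maximum slice count in
the target data — with an explicit validity mask.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .curation import SliceImage, SliceLabel, SliceStack

__all__ = [
    "T_MAX",
    "PAD_LABEL",
    "BackboneSpec",
    "FeatureVector",
    "FeatureSequence",
    "get_backbone_spec",
    "BACKBONES",
    "preprocess_image",
    "extract_features",
    "extract_stack_features",
    "build_sequence",
    "cached_stack_features",
]

T_MAX = 25  # time steps: the maximum number of short-axis slices
PAD_LABEL = -1  # label sentinel at padded positions


@dataclass(frozen=True)
class BackboneSpec:
    """Descriptor of a frozen convolutional feature extractor."""

    name: str
    feature_dim: int
    input_size: int
    preprocess_mode: str  # "unit" [0,1], "symmetric" [-1,1], "raw" passthrough
    weights: str = "pretrained"  # "pretrained" | "random"
    seed: int = 0  # weight seed for weights="random"


# Published feature dimensions after global average pooling.
_REGISTRY: dict[str, dict] = {
    "EfficientNetB0": dict(feature_dim=1280, input_size=224, preprocess_mode="raw"),
    "MobileNet": dict(feature_dim=1024, input_size=224, preprocess_mode="symmetric"),
    "NASNetMobile": dict(feature_dim=1056, input_size=224, preprocess_mode="symmetric"),
    "ResNet50V2": dict(feature_dim=2048, input_size=224, preprocess_mode="symmetric"),
    "TinyTest": dict(feature_dim=64, input_size=64, preprocess_mode="unit"),
}
BACKBONES = tuple(_REGISTRY)


def get_backbone_spec(name: str, weights: str | None = None, seed: int = 0) -> BackboneSpec:
    if name not in _REGISTRY:
        raise ValueError(f"unknown backbone {name!r}; known: {BACKBONES}")
    if weights is None:
        weights = "random" if name == "TinyTest" else "pretrained"
    return BackboneSpec(name=name, weights=weights, seed=seed, **_REGISTRY[name])


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray  # (feature_dim,)
    subject_id: str
    phase_id: str
    slice_index: int
    backbone: str


@dataclass
class FeatureSequence:
    """Post-padded T×D feature matrix with validity mask and aligned labels."""

    matrix: np.ndarray  # (T_MAX, feature_dim)
    mask: np.ndarray  # (T_MAX,) bool, True for valid steps
    label_sequence: np.ndarray  # (T_MAX,) int, PAD_LABEL at padding
    subject_id: str = ""
    phase_id: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def preprocess_image(image: SliceImage | np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Grayscale uint8 -> backbone-ready (input_size, input_size, 3) float array."""
    pixels = image.pixels if isinstance(image, SliceImage) else np.asarray(image)
    if pixels.dtype != np.uint8:
        raise ValueError("expected an 8-bit grayscale image")
    pil = Image.fromarray(pixels, mode="L")
    if pil.size != (spec.input_size, spec.input_size):
        pil = pil.resize((spec.input_size, spec.input_size), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float64)
    if spec.preprocess_mode == "unit":
        arr = arr / 255.0
    elif spec.preprocess_mode == "symmetric":
        arr = arr / 127.5 - 1.0
    elif spec.preprocess_mode == "raw":
        pass
    else:
        raise ValueError(f"unsupported preprocess_mode {spec.preprocess_mode!r}")
    return np.repeat(arr[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# Random convolutional trunk (frozen)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(B, H, W, C) -> (B, Ho*Wo, k*k*C) patch matrix, valid padding."""
    b, h, w, c = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, ho, wo, k, k, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(b, ho * wo, k * k * c), ho, wo


class _RandomConvTrunk:
    """Frozen He-initialized conv stack: 3x3 stride-2 convs + ReLU, then GAP.

    Channels 3 -> 16 -> 32 -> 64; an optional fixed random projection maps
    the 64-d pooled vector to the spec's declared feature dimension so the
    named backbones keep their published output sizes.
    """

    CHANNELS = (16, 32, 64)

    def __init__(self, spec: BackboneSpec):
        rng = np.random.default_rng(spec.seed + 7919)
        self.kernels: list[np.ndarray] = []
        c_in = 3
        for c_out in self.CHANNELS:
            fan_in = 9 * c_in
            self.kernels.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
            c_in = c_out
        if spec.feature_dim != self.CHANNELS[-1]:
            self.projection = rng.normal(
                0.0, 1.0 / np.sqrt(self.CHANNELS[-1]), size=(self.CHANNELS[-1], spec.feature_dim)
            )
        else:
            self.projection = None

    def forward(self, batch: np.ndarray) -> np.ndarray:
        x = batch
        for kernel in self.kernels:
            cols, ho, wo = _im2col(x, k=3, stride=2)
            x = np.maximum(cols @ kernel, 0.0).reshape(x.shape[0], ho, wo, -1)
        pooled = x.mean(axis=(1, 2))  # global average pooling
        if self.projection is not None:
            pooled = pooled @ self.projection
        return pooled


_trunk_cache: dict[tuple, _RandomConvTrunk] = {}


def _get_trunk(spec: BackboneSpec) -> _RandomConvTrunk:
    key = (spec.name, spec.feature_dim, spec.seed)
    if key not in _trunk_cache:
        _trunk_cache[key] = _RandomConvTrunk(spec)
    return _trunk_cache[key]


def extract_features(
    images: Sequence[SliceImage], spec: BackboneSpec, batch_size: int = 64
) -> list[FeatureVector]:
    """Map images to frozen global-average-pooled feature vectors.

    The extractor holds no trainable state: repeated calls on the same
    image return identical vectors, and nothing downstream can modify it.
    """
    if spec.weights == "pretrained":
        raise RuntimeError(
            f"pretrained weights for {spec.name} are not bundled with this package; "
            f'use get_backbone_spec("{spec.name}", weights="random") for a frozen '
            "random-weight extractor of the same output dimension"
        )
    if spec.weights != "random":
        raise ValueError(f"unknown weights mode {spec.weights!r}")
    trunk = _get_trunk(spec)
    out: list[FeatureVector] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        batch = np.stack([preprocess_image(img, spec) for img in chunk])
        feats = trunk.forward(batch)
        for img, vec in zip(chunk, feats):
            if not np.all(np.isfinite(vec)):
                raise FloatingPointError("non-finite feature vector")
            out.append(
                FeatureVector(
                    values=vec,
                    subject_id=img.subject_id,
                    phase_id=img.phase_id,
                    slice_index=img.slice_index,
                    backbone=spec.name,
                )
            )
    return out


def extract_stack_features(stack: SliceStack, spec: BackboneSpec) -> list[FeatureVector]:
    return extract_features(stack.slices, spec)


def build_sequence(
    features: Sequence[FeatureVector],
    labels: Sequence[SliceLabel | int],
    t_max: int = T_MAX,
    sort: bool = False,
) -> FeatureSequence:
    """Assemble one stack's features into a padded, masked sequence.

    Features must arrive ordered by slice index, apex to base (pass
    ``sort=True`` to sort internally).  Valid steps occupy rows
    ``0..N-1``; rows ``N..T-1`` are zero with mask False and a label
    sentinel.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    n = len(features)
    if n == 0:
        raise ValueError("empty stack")
    if n > t_max:
        raise ValueError(f"stack of {n} slices exceeds the {t_max}-step bound")
    order = [f.slice_index for f in features]
    if sort:
        perm = np.argsort(order, kind="stable")
        features = [features[i] for i in perm]
        labels = [labels[i] for i in perm]
    elif order != sorted(order):
        raise ValueError("features must be ordered by ascending slice index")
    dim = len(features[0].values)
    matrix = np.zeros((t_max, dim))
    mask = np.zeros(t_max, dtype=bool)
    label_seq = np.full(t_max, PAD_LABEL, dtype=np.int64)
    for i, (f, lab) in enumerate(zip(features, labels)):
        matrix[i] = f.values
        mask[i] = True
        label_seq[i] = int(lab)
    return FeatureSequence(
        matrix=matrix,
        mask=mask,
        label_sequence=label_seq,
        subject_id=features[0].subject_id,
        phase_id=features[0].phase_id,
    )


# ---------------------------------------------------------------------------
# On-disk feature cache (runtime artifact, keyed by content checksum)


def _stack_checksum(stack: SliceStack, spec: BackboneSpec) -> str:
    h = hashlib.sha256()
    h.update(f"{spec.name}|{spec.weights}|{spec.seed}|{spec.input_size}".encode())
    for s in stack.slices:
        h.update(s.pixels.tobytes())
    return h.hexdigest()


def cached_stack_features(
    stack: SliceStack, spec: BackboneSpec, cache_dir: Path | None
) -> list[FeatureVector]:
    """extract_stack_features with an npz cache; cache hit by checksum."""
    if cache_dir is None:
        return extract_stack_features(stack, spec)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    checksum = _stack_checksum(stack, spec)
    path = cache_dir / f"{stack.subject_id}_{stack.phase_id}_{spec.name}.npz"
    if path.exists():
        data = np.load(path, allow_pickle=False)
        if str(data["checksum"]) == checksum:
            return [
                FeatureVector(
                    values=data["features"][i],
                    subject_id=stack.subject_id,
                    phase_id=stack.phase_id,
                    slice_index=int(idx),
                    backbone=spec.name,
                )
                for i, idx in enumerate(data["indices"])
            ]
    feats = extract_stack_features(stack, spec)
    np.savez(
        path,
        features=np.stack([f.values for f in feats]),
        indices=np.array([f.slice_index for f in feats]),
        checksum=np.array(checksum),
        backbone=np.array(spec.name),
    )
    return feats
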