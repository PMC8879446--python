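"""Synthetic multi-domain, class-incremental image benchmarks.

The generator emulates the *structure* of the security-screening and
retinal-imaging corpora the continual objective was designed for —
grayscale vs. color domains, a composite "multiple" class for scans
holding several suspicious items, a "normal" class whose size is an
explicit multiple of the positive count (the SIXray10/100/1000 imbalance
design), and a small-train / large-test split (default 20/80) — without
any photometric realism.  Classes are simple geometric primitives (disc,
bar, cross, ring, wedge, blob) rendered at random position, scale and
rotation with additive Gaussian pixel noise, so class separability is a
single dial (``noise_sigma``) rather than an accident of real data.

Everything is bitwise deterministic given ``(spec, seed)``.  Images can
be kept in memory as uint8 arrays or written as 8-bit PNGs with a CSV
manifest; the trainer consumes either path through the same
``TaskSequence`` container.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ValidationError

__all__ = [
    "DomainSpec",
    "LabeledImageSet",
    "Increment",
    "TaskSequence",
    "generate_domain",
    "generate_benchmark",
    "default_benchmark",
    "write_benchmark",
    "load_benchmark",
]

SHAPES = ("disc", "bar", "cross", "ring", "wedge", "blob")

MIN_IMAGE_SIZE = 12

MULTIPLE_CLASS = "multiple"
NORMAL_CLASS = "normal"


@dataclass(frozen=True)
class DomainSpec:
    """Declarative description of one image domain.

    ``imbalance_ratio`` is the number of "normal" (negative) samples per
    positive sample; the composite "multiple" class counts as positive.
    """

    name: str
    channels: int = 1
    image_size: int = 24
    class_shapes: Mapping[str, str] = field(default_factory=dict)
    noise_sigma: float = 0.2
    include_multiple: bool = False
    include_normal: bool = False
    imbalance_ratio: float = 1.0
    items_per_class: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.channels not in (1, 3):
            raise ValidationError("channels must be 1 or 3")
        if self.image_size < MIN_IMAGE_SIZE:
            raise ValidationError(
                f"image_size {self.image_size} too small to render shapes "
                f"(minimum {MIN_IMAGE_SIZE})"
            )
        if not self.class_shapes:
            raise ValidationError("at least one class is required")
        shapes = list(self.class_shapes.values())
        if len(set(shapes)) != len(shapes):
            raise ValidationError("shape primitives must be distinct within a domain")
        for s in shapes:
            if s not in SHAPES:
                raise ValidationError(f"unknown shape primitive {s!r}")
        if self.imbalance_ratio < 0:
            raise ValidationError("imbalance_ratio must be >= 0")
        if self.items_per_class < 1:
            raise ValidationError("items_per_class must be >= 1")

    def class_list(self) -> list[str]:
        out = list(self.class_shapes)
        if self.include_multiple:
            out.append(MULTIPLE_CLASS)
        if self.include_normal:
            out.append(NORMAL_CLASS)
        return out


@dataclass
class LabeledImageSet:
    """Rendered samples of one domain: uint8 images plus labels and ids."""

    domain: str
    images: np.ndarray  # (n, H, W, C) uint8
    labels: list[str]
    ids: list[str]

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class Increment:
    """One step of the incremental schedule, with its train/test partition."""

    domain: str
    classes: list[str]  # registry-qualified "domain/class"
    train_x: np.ndarray  # (n, d) float features in [0, 1]
    train_y: list[str]
    train_ids: list[str]
    test_x: np.ndarray
    test_y: list[str]
    test_ids: list[str]


@dataclass
class TaskSequence:
    """Ordered increments plus the global label registry (first appearance order)."""

    increments: list[Increment]
    registry: list[str]
    image_size: int
    channels_by_domain: dict[str, int]
    split_fraction: float
    seed: int

    @property
    def feature_dim(self) -> int:
        return 3 * self.image_size * self.image_size

    def cumulative_test(self, upto: int) -> tuple[np.ndarray, list[str]]:
        """Union of the test sets of increments 0..upto (inclusive)."""
        xs = [inc.test_x for inc in self.increments[: upto + 1]]
        ys = [y for inc in self.increments[: upto + 1] for y in inc.test_y]
        return np.concatenate(xs, axis=0), ys


def qualified(domain: str, cls: str) -> str:
    return f"{domain}/{cls}"


# ---------------------------------------------------------------------------
# rendering

def _rotated_coords(size: int, cx: float, cy: float, theta: float):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dx, dy = xx - cx, yy - cy
    c, s = np.cos(theta), np.sin(theta)
    return c * dx + s * dy, -s * dx + c * dy


def _shape_mask(shape: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Soft [0,1] mask of one primitive at random position/scale/rotation."""
    # position jitter is deliberately small: pixel-space learners have no
    # built-in translation invariance and the train split is tiny
    jitter = size / 8.0
    cx = size / 2.0 + rng.uniform(-jitter, jitter)
    cy = size / 2.0 + rng.uniform(-jitter, jitter)
    r = rng.uniform(size / 5.0, size / 3.8)
    theta = rng.uniform(0.0, np.pi)
    u, v = _rotated_coords(size, cx, cy, theta)
    rad = np.hypot(u, v)
    if shape == "disc":
        mask = rad <= r
    elif shape == "bar":
        mask = (np.abs(u) <= 1.6 * r) & (np.abs(v) <= 0.45 * r)
    elif shape == "cross":
        mask = ((np.abs(u) <= 1.4 * r) & (np.abs(v) <= 0.4 * r)) | (
            (np.abs(v) <= 1.4 * r) & (np.abs(u) <= 0.4 * r)
        )
    elif shape == "ring":
        mask = (rad <= 1.3 * r) & (rad >= 0.75 * r)
    elif shape == "wedge":
        mask = (v >= -0.6 * r) & (v <= 1.2 * r) & (np.abs(u) <= 0.8 * (1.2 * r - v) / 1.8)
    elif shape == "blob":
        return np.exp(-(rad**2) / (2 * (1.1 * r) ** 2))
    else:  # pragma: no cover - guarded by DomainSpec.validate
        raise ValidationError(f"unknown shape {shape!r}")
    return mask.astype(float)


def _distractor_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency texture for 'normal' scans: no coherent shape."""
    fx, fy = rng.uniform(0.5, 2.0, 2)
    px, py = rng.uniform(0, 2 * np.pi, 2)
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    tex = 0.5 + 0.25 * np.sin(2 * np.pi * fx * xx + px) * np.cos(2 * np.pi * fy * yy + py)
    return 0.35 * tex


def _class_color(rng: np.random.Generator) -> np.ndarray:
    """A saturated RGB color, stable per class within a domain."""
    hue = rng.uniform(0, 3)
    base = np.clip(
        [abs(((hue - k) % 3) - 1.5) / 1.5 for k in (0.0, 1.0, 2.0)], 0.25, 1.0
    )
    return np.asarray(base)


def _render_sample(
    shapes: Sequence[str],
    spec: DomainSpec,
    colors: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    size = spec.image_size
    img = np.zeros((size, size, 3))
    img += _distractor_texture(size, rng)[..., None] * 0.4
    for shape in shapes:
        mask = _shape_mask(shape, size, rng)
        color = colors[shape] if spec.channels == 3 else np.ones(3)
        intensity = rng.uniform(0.85, 1.0)
        img = np.maximum(img, mask[..., None] * color * intensity)
    if spec.channels == 1:
        img = img.mean(axis=2, keepdims=True)
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    return np.round(img * 255).astype(np.uint8)


def generate_domain(spec: DomainSpec) -> LabeledImageSet:
    """Render one domain deterministically from its spec.

    Class counts are exact: each positive class (including "multiple")
    gets ``items_per_class`` samples and "normal" gets
    ``round(imbalance_ratio * n_positive)`` samples.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    colors = {shape: _class_color(rng) for shape in spec.class_shapes.values()}
    all_shapes = list(spec.class_shapes.values())

    plan: list[tuple[str, list[str] | None]] = []
    for cls, shape in spec.class_shapes.items():
        plan.extend((cls, [shape]) for _ in range(spec.items_per_class))
    if spec.include_multiple:
        if len(all_shapes) < 2:
            raise ValidationError("'multiple' requires >= 2 positive classes")
        for _ in range(spec.items_per_class):
            k = int(rng.integers(2, len(all_shapes) + 1))
            picks = list(rng.choice(all_shapes, size=k, replace=False))
            plan.append((MULTIPLE_CLASS, picks))
    n_pos = len(plan)
    if spec.include_normal:
        n_norm = int(round(spec.imbalance_ratio * n_pos))
        plan.extend((NORMAL_CLASS, None) for _ in range(n_norm))

    images = np.empty((len(plan), spec.image_size, spec.image_size, spec.channels), dtype=np.uint8)
    labels: list[str] = []
    ids: list[str] = []
    for i, (cls, shapes) in enumerate(plan):
        if shapes is None:
            img = np.zeros((spec.image_size, spec.image_size, 3))
            img += _distractor_texture(spec.image_size, rng)[..., None]
            img += _distractor_texture(spec.image_size, rng)[..., None]
            if spec.channels == 1:
                img = img.mean(axis=2, keepdims=True)
            img += rng.normal(0.0, spec.noise_sigma, img.shape)
            images[i] = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
        else:
            images[i] = _render_sample(shapes, spec, colors, rng)
        labels.append(cls)
        ids.append(f"{spec.name}-{i:05d}")
    return LabeledImageSet(domain=spec.name, images=images, labels=labels, ids=ids)


# ---------------------------------------------------------------------------
# benchmark assembly

def _to_features(images: np.ndarray) -> np.ndarray:
    """Canonical flat features: replicate grayscale to 3 channels, scale to [0,1]."""
    if images.shape[-1] == 1:
        images = np.repeat(images, 3, axis=-1)
    return images.reshape(images.shape[0], -1).astype(float) / 255.0


def generate_benchmark(
    domain_specs: Sequence[DomainSpec],
    increments: Sequence[tuple[str, Sequence[str]]],
    split_fraction: float = 0.2,
    seed: int = 0,
) -> TaskSequence:
    """Render all domains, split per class, and assemble the increment schedule.

    ``increments`` is an ordered list of ``(domain_name, class_names)``
    pairs (class names unqualified).  The split is stratified per class at
    ``split_fraction`` train (default 20% train / 80% test).  The global
    registry lists qualified class names in first-appearance order.
    """
    if not increments:
        raise ValidationError("at least one increment is required")
    if not 0 < split_fraction < 1:
        raise ValidationError("split_fraction must be in (0, 1)")
    specs = {s.name: s for s in domain_specs}
    sizes = {s.image_size for s in domain_specs}
    if len(sizes) != 1:
        raise ValidationError("all domains must share one image_size")
    image_size = sizes.pop()

    rendered: dict[str, LabeledImageSet] = {}
    splits: dict[str, np.ndarray] = {}
    for k, (name, spec) in enumerate(specs.items()):
        seeded = replace(spec, seed=int(np.random.default_rng([seed, k]).integers(2**31)))
        dom = generate_domain(seeded)
        rendered[name] = dom
        labels = np.asarray(dom.labels, dtype=object)
        is_train = np.zeros(len(dom), dtype=bool)
        split_rng = np.random.default_rng([seed, k, 1])
        for cls in dict.fromkeys(dom.labels):
            idx = np.flatnonzero(labels == cls)
            n_train = int(round(split_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) >= 2 else n_train
            chosen = split_rng.choice(idx, size=n_train, replace=False)
            is_train[chosen] = True
        splits[name] = is_train

    registry: list[str] = []
    incs: list[Increment] = []
    for name, classes in increments:
        if name not in rendered:
            raise ValidationError(f"unknown domain {name!r} in schedule")
        dom, is_train = rendered[name], splits[name]
        known = set(dom.labels)
        for cls in classes:
            if cls not in known:
                raise ValidationError(f"unknown class {cls!r} for domain {name!r}")
        qcls = [qualified(name, c) for c in classes]
        for qc in qcls:
            if qc not in registry:
                registry.append(qc)
        labels = np.asarray(dom.labels, dtype=object)
        keep = np.isin(labels, list(classes))
        feats = _to_features(dom.images)
        tr = keep & is_train
        te = keep & ~is_train
        incs.append(
            Increment(
                domain=name,
                classes=qcls,
                train_x=feats[tr],
                train_y=[qualified(name, c) for c in labels[tr]],
                train_ids=[dom.ids[i] for i in np.flatnonzero(tr)],
                test_x=feats[te],
                test_y=[qualified(name, c) for c in labels[te]],
                test_ids=[dom.ids[i] for i in np.flatnonzero(te)],
            )
        )
    return TaskSequence(
        increments=incs,
        registry=registry,
        image_size=image_size,
        channels_by_domain={s.name: s.channels for s in domain_specs},
        split_fraction=split_fraction,
        seed=seed,
    )


def default_benchmark(
    seed: int = 0,
    items_per_class: int = 60,
    noise_sigma: float = 0.2,
    image_size: int = 24,
    split_fraction: float = 0.2,
) -> TaskSequence:
    """The bundled 3-domain, 3-increment benchmark.

    Domain 1 emulates grayscale baggage screening (three contraband
    shapes plus "multiple" and "normal"), domain 2 the same application
    in color with different item classes, domain 3 a grayscale retinal
    set with three pathology classes.  13 registry classes in total,
    mirroring the combined-corpus setup the objective was evaluated on.
    """
    specs = [
        DomainSpec(
            name="baggage-gray",
            channels=1,
            image_size=image_size,
            class_shapes={"gun": "bar", "knife": "wedge", "shuriken": "cross"},
            include_multiple=True,
            include_normal=True,
            imbalance_ratio=1.0,
            items_per_class=items_per_class,
            noise_sigma=noise_sigma,
        ),
        DomainSpec(
            name="baggage-color",
            channels=3,
            image_size=image_size,
            class_shapes={"pliers": "cross", "scissors": "wedge", "hammer": "bar"},
            include_multiple=True,
            include_normal=True,
            imbalance_ratio=1.0,
            items_per_class=items_per_class,
            noise_sigma=noise_sigma,
        ),
        DomainSpec(
            name="retina-gray",
            channels=1,
            image_size=image_size,
            class_shapes={"amd": "blob", "dme": "disc", "healthy": "ring"},
            items_per_class=items_per_class,
            noise_sigma=noise_sigma,
        ),
    ]
    schedule = [(s.name, s.class_list()) for s in specs]
    return generate_benchmark(specs, schedule, split_fraction=split_fraction, seed=seed)


# ---------------------------------------------------------------------------
# disk round trip

def write_benchmark(tasks: TaskSequence, root: str) -> str:
    """Write <root>/<domain>/<split>/<class>/<id>.png plus manifest.csv."""
    rows = []
    for k, inc in enumerate(tasks.increments):
        for split, xs, ys, ids in (
            ("train", inc.train_x, inc.train_y, inc.train_ids),
            ("test", inc.test_x, inc.test_y, inc.test_ids),
        ):
            for x, y, sid in zip(xs, ys, ids):
                cls = y.split("/", 1)[1]
                path = os.path.join(inc.domain, split, cls, f"{sid}.png")
                full = os.path.join(root, path)
                os.makedirs(os.path.dirname(full), exist_ok=True)
                img = np.round(x.reshape(tasks.image_size, tasks.image_size, 3) * 255)
                if tasks.channels_by_domain[inc.domain] == 1:
                    Image.fromarray(img[..., 0].astype(np.uint8), mode="L").save(full)
                else:
                    Image.fromarray(img.astype(np.uint8), mode="RGB").save(full)
                rows.append(
                    {
                        "path": path,
                        "domain": inc.domain,
                        "split": split,
                        "class": cls,
                        "increment": k,
                        "id": sid,
                    }
                )
    manifest = os.path.join(root, "manifest.csv")
    meta = {
        "image_size": tasks.image_size,
        "split_fraction": tasks.split_fraction,
        "seed": tasks.seed,
        "registry": tasks.registry,
        "channels_by_domain": tasks.channels_by_domain,
    }
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(os.path.join(root, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return manifest


def load_benchmark(root: str) -> TaskSequence:
    """Rebuild a TaskSequence from a written benchmark directory."""
    manifest = pd.read_csv(os.path.join(root, "manifest.csv"))
    with open(os.path.join(root, "meta.json")) as fh:
        meta = json.load(fh)
    incs: list[Increment] = []
    for k in sorted(manifest["increment"].unique()):
        sub = manifest[manifest["increment"] == k]
        domain = sub["domain"].iloc[0]
        parts: dict[str, dict] = {}
        for split in ("train", "test"):
            ss = sub[sub["split"] == split]
            imgs = []
            for path in ss["path"]:
                arr = np.asarray(Image.open(os.path.join(root, path)))
                if arr.ndim == 2:
                    arr = arr[..., None]
                imgs.append(arr)
            parts[split] = {
                "x": _to_features(np.stack(imgs)),
                "y": [qualified(domain, c) for c in ss["class"]],
                "ids": list(ss["id"]),
            }
        classes = [
            q for q in meta["registry"]
            if q.startswith(domain + "/")
            and q.split("/", 1)[1] in set(sub["class"])
        ]
        incs.append(
            Increment(
                domain=domain,
                classes=classes,
                train_x=parts["train"]["x"],
                train_y=parts["train"]["y"],
                train_ids=parts["train"]["ids"],
                test_x=parts["test"]["x"],
                test_y=parts["test"]["y"],
                test_ids=parts["test"]["ids"],
            )
        )
    return TaskSequence(
        increments=incs,
        registry=list(meta["registry"]),
        image_size=int(meta["image_size"]),
        channels_by_domain={k: int(v) for k, v in meta["channels_by_domain"].items()},
        split_fraction=float(meta["split_fraction"]),
        seed=int(meta["seed"]),
    )
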