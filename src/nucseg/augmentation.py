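"""Deterministic offline augmentation recipes.

The offline pipeline enlarges a training set before training (never per
epoch): grid-crop every tile, horizontally flip the crops, vertically flip
crops+h-flips, then run fixed translate/crop/resize passes over that base
set.  Every geometric transform is applied identically to the image and its
mask (bilinear vs. nearest interpolation respectively), and each preset's
per-step output counts are content-independent, so 30 tiles of 1000x1000
always yield 2880 outputs and 43 tiles of 512x512 always yield 2064.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "Pair",
    "GridCrop",
    "Flip",
    "TranslateCropResize",
    "AugmentationRecipe",
    "AugmentedSet",
    "grid_crop",
    "translate_crop_resize",
    "run_recipe",
    "preset_tcga",
    "preset_tnbc",
    "preset_output_count",
]


@dataclass
class Pair:
    """An image with its aligned mask and a provenance chain."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) integer labels
    source: str = ""
    chain: tuple[str, ...] = ()

    def derived(self, step: str, image: np.ndarray, mask: np.ndarray) -> "Pair":
        return Pair(image=image, mask=mask, source=self.source,
                    chain=self.chain + (step,))


def _resize_image(image: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an RGB uint8 image via PIL."""
    pil = Image.fromarray(image)
    return np.asarray(pil.resize((out_hw[1], out_hw[0]), Image.BILINEAR))


def _resize_mask(mask: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Exact nearest-neighbour resize; never interpolates label values."""
    h, w = mask.shape
    oh, ow = out_hw
    rows = np.minimum((np.arange(oh) + 0.5) * h / oh, h - 1).astype(np.intp)
    cols = np.minimum((np.arange(ow) + 0.5) * w / ow, w - 1).astype(np.intp)
    return mask[np.ix_(rows, cols)]


def grid_crop(image: np.ndarray, mask: np.ndarray,
              size: int, stride: int) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """All fully-contained size x size crops at offsets {0, stride, 2*stride, ...}.

    1000 -> 500 @ stride 500 gives 4 crops; 512 -> 502 @ stride 10 gives 4
    (offsets 0 and 10 on each axis).  Returns (image crop, mask crop, tag).
    """
    h, w = mask.shape
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image size {h}x{w}")
    out = []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            out.append((image[r:r + size, c:c + size],
                        mask[r:r + size, c:c + size], f"crop{r}_{c}"))
    return out


def translate_crop_resize(image: np.ndarray, mask: np.ndarray,
                          dx: int, dy: int,
                          out_size: int | tuple[int, int] | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Translate by (dx, dy), keep the surviving window, resize back.

    Shifting content by (dx, dy) and discarding rows/columns that left the
    canvas is equivalent to cropping the (H-|dy|) x (W-|dx|) window that
    survives; that window is then resized to ``out_size`` (default: the
    original size) — bilinear for the image, nearest-neighbour for the mask.
    """
    h, w = mask.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError("shift magnitude must be smaller than the image")
    if out_size is None:
        out_hw = (h, w)
    elif isinstance(out_size, int):
        out_hw = (out_size, out_size)
    else:
        out_hw = tuple(out_size)
    r0, r1 = max(0, -dy), h - max(0, dy)
    c0, c1 = max(0, -dx), w - max(0, dx)
    return (_resize_image(image[r0:r1, c0:c1], out_hw),
            _resize_mask(mask[r0:r1, c0:c1], out_hw))


# ---- recipe steps -------------------------------------------------------

@dataclass(frozen=True)
class GridCrop:
    name: str
    source: tuple[str, ...]
    size: int
    stride: int
    resize_to: int | None = None  # resize crops back to a common size


@dataclass(frozen=True)
class Flip:
    name: str
    source: tuple[str, ...]
    axis: str  # "h" (left-right) or "v" (up-down)


@dataclass(frozen=True)
class TranslateCropResize:
    name: str
    source: tuple[str, ...]
    dx: int
    dy: int
    then_hflip: bool = False


@dataclass(frozen=True)
class AugmentationRecipe:
    """Ordered steps over named subsets; "input" is the original set.

    The recipe output is the union of every step's outputs (the originals
    themselves are not part of the output, matching the reference counts).
    """

    steps: tuple = ()

    def validate(self) -> None:
        known = {"input"}
        for step in self.steps:
            unknown = set(step.source) - known
            if unknown:
                raise ValueError(f"step {step.name} references unknown "
                                 f"subsets {sorted(unknown)}")
            known.add(step.name)

    def outputs_per_input(self) -> dict[str, int]:
        """Content-independent per-step count for one square original
        (assumes the grid produces a 2x2 crop layout, as both presets do)."""
        self.validate()
        counts = {"input": 1}
        for step in self.steps:
            base = sum(counts[s] for s in step.source)
            if isinstance(step, GridCrop):
                counts[step.name] = base * 4
            elif isinstance(step, Flip):
                counts[step.name] = base
            else:
                counts[step.name] = base * (2 if step.then_hflip else 1)
        return {k: v for k, v in counts.items() if k != "input"}


@dataclass
class AugmentedSet:
    """Realized outputs plus the per-step count ledger."""

    pairs: list[Pair] = field(default_factory=list)
    ledger: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.ledger.values())


def preset_tcga() -> AugmentationRecipe:
    """1000x1000 preset: 4 grid crops of 500 @ stride 500, h-flip, v-flip of
    both, then three fixed translate passes (+10/+10; -5/-5 with h-flips;
    +5/+5 with h-flips) over the 16-per-tile base set -> 96 per tile."""
    base = ("crop", "hflip", "vflip")
    return AugmentationRecipe(steps=(
        GridCrop("crop", ("input",), size=500, stride=500),
        Flip("hflip", ("crop",), axis="h"),
        Flip("vflip", ("crop", "hflip"), axis="v"),
        TranslateCropResize("t+10", base, dx=10, dy=10),
        TranslateCropResize("t-5", base, dx=-5, dy=-5, then_hflip=True),
        TranslateCropResize("t+5", base, dx=5, dy=5, then_hflip=True),
    ))


def preset_tnbc() -> AugmentationRecipe:
    """512x512 preset: 4 grid crops of 502 @ stride 10 (resized back to 512),
    h-flip, v-flip of both, then two fixed translate passes (+5/+5 and
    -5/-5) over the 16-per-tile base set -> 48 per tile."""
    base = ("crop", "hflip", "vflip")
    return AugmentationRecipe(steps=(
        GridCrop("crop", ("input",), size=502, stride=10, resize_to=512),
        Flip("hflip", ("crop",), axis="h"),
        Flip("vflip", ("crop", "hflip"), axis="v"),
        TranslateCropResize("t+5", base, dx=5, dy=5),
        TranslateCropResize("t-5", base, dx=-5, dy=-5),
    ))


def preset_output_count(recipe: AugmentationRecipe, n_inputs: int) -> int:
    """Closed-form output count (content independent)."""
    return n_inputs * sum(recipe.outputs_per_input().values())


def _apply_flip(pair: Pair, step: Flip) -> Pair:
    if step.axis == "h":
        return pair.derived(step.name, pair.image[:, ::-1].copy(),
                            pair.mask[:, ::-1].copy())
    return pair.derived(step.name, pair.image[::-1].copy(),
                        pair.mask[::-1].copy())


def run_recipe(pairs: Iterable[Pair], recipe: AugmentationRecipe,
               sink: Callable[[Pair], None] | None = None) -> AugmentedSet:
    """Execute a recipe over input pairs.

    Outputs of steps that later steps still reference are kept in memory;
    every output is also passed to ``sink`` (or collected into the returned
    :class:`AugmentedSet` when no sink is given — for large runs prefer a
    sink that writes to disk).  Deterministic: the offsets are fixed
    constants of the recipe.
    """
    recipe.validate()
    referenced: set[str] = set()
    for step in recipe.steps:
        referenced.update(step.source)
    subsets: dict[str, list[Pair]] = {"input": list(pairs)}
    result = AugmentedSet()

    def emit(step_name: str, pair: Pair) -> None:
        result.ledger[step_name] = result.ledger.get(step_name, 0) + 1
        if step_name in referenced:
            subsets.setdefault(step_name, []).append(pair)
        if sink is not None:
            sink(pair)
        else:
            result.pairs.append(pair)

    for step in recipe.steps:
        source = [p for s in step.source for p in subsets[s]]
        if isinstance(step, GridCrop):
            for pair in source:
                for img, msk, tag in grid_crop(pair.image, pair.mask,
                                               step.size, step.stride):
                    if step.resize_to is not None:
                        img = _resize_image(img, (step.resize_to,) * 2)
                        msk = _resize_mask(msk, (step.resize_to,) * 2)
                    emit(step.name, pair.derived(f"{step.name}:{tag}", img, msk))
        elif isinstance(step, Flip):
            for pair in source:
                emit(step.name, _apply_flip(pair, step))
        else:  # TranslateCropResize
            for pair in source:
                img, msk = translate_crop_resize(pair.image, pair.mask,
                                                 step.dx, step.dy)
                out = pair.derived(step.name, img, msk)
                emit(step.name, out)
                if step.then_hflip:
                    emit(step.name,
                         _apply_flip(out, Flip(step.name + ":hflip",
                                               (step.name,), "h")))
    return result


def write_augmented(pairs: Iterable[Pair], recipe: AugmentationRecipe,
                    out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Run a recipe, writing outputs and a provenance manifest to disk."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    counter = [0]

    def sink(pair: Pair) -> None:
        stem = f"aug_{counter[0]:06d}"
        counter[0] += 1
        iio.imwrite(out / "images" / f"{stem}.png", pair.image)
        if pair.mask.max() > 255:
            tifffile.imwrite(out / "masks" / f"{stem}.tif",
                             pair.mask.astype(np.uint16))
            mask_path = f"masks/{stem}.tif"
        else:
            iio.imwrite(out / "masks" / f"{stem}.png",
                        pair.mask.astype(np.uint8))
            mask_path = f"masks/{stem}.png"
        rows.append([f"images/{stem}.png", mask_path, pair.source,
                     "|".join(pair.chain)])

    run_recipe(pairs, recipe, sink=sink)
    manifest = out / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "source", "chain"])
        writer.writerows(rows)
    return manifest
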