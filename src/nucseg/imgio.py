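"""Image, mask, annotation, manifest, and config I/O.

Conventions, used everywhere in the package: arrays are (row, col) indexed
and 0-based; annotation files use x = column.  RGB images are 8-bit PNG or
TIFF; binary masks are 8-bit 0/255 PNG mapped to {0,1} on read; instance
masks are 16-bit single-channel PNG or TIFF and round-trip losslessly.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_instance_mask",
    "write_instance_mask",
    "read_binary_mask",
    "write_binary_mask",
    "PolygonAnnotation",
    "read_aperio_xml",
    "polygons_to_instance_mask",
    "DatasetManifest",
    "load_config",
    "resize_rgb",
]


def _read_array(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(path)
    import imageio.v3 as iio
    return iio.imread(path)


def read_image(path) -> np.ndarray:
    """Read an 8-bit RGB image; alpha is dropped, grayscale is replicated."""
    arr = _read_array(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit RGB, got dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: not an RGB image (shape {arr.shape})")
    return arr[..., :3]


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, image)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, image)


def read_instance_mask(path) -> np.ndarray:
    """Read an integer-labeled mask (8/16-bit single channel)."""
    arr = _read_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: instance mask must be single-channel, "
                         f"got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16, np.int32):
        raise ValueError(f"{path}: unsupported mask dtype {arr.dtype}")
    return arr.astype(np.int32)


def write_instance_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance labels out of 16-bit range")
    mask16 = mask.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, mask16)
    else:
        import imageio.v3 as iio
        iio.imwrite(path, mask16)


def read_binary_mask(path) -> np.ndarray:
    """Read an 8-bit mask; any nonzero value maps to 1."""
    arr = _read_array(path)
    if arr.ndim == 3:
        raise ValueError(f"{path}: binary mask must be single-channel")
    return (arr != 0).astype(np.uint8)


def write_binary_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(path, ((np.asarray(mask) != 0) * 255).astype(np.uint8))


def resize_rgb(image: np.ndarray, size: int | tuple[int, int]) -> np.ndarray:
    """Bilinear resize of an RGB uint8 image (test-time resizing option)."""
    from PIL import Image
    if isinstance(size, int):
        size = (size, size)
    pil = Image.fromarray(np.asarray(image, dtype=np.uint8))
    return np.asarray(pil.resize((size[1], size[0]), Image.BILINEAR))


# ---- polygon annotations -------------------------------------------------

@dataclass
class PolygonAnnotation:
    """Nucleus outlines as ordered (x, y) vertex lists, pixel units."""

    polygons: list[np.ndarray]


def read_aperio_xml(path) -> PolygonAnnotation:
    """Parse Aperio-style XML (Annotations/Annotation/Regions/Region/
    Vertices/Vertex with X/Y attributes) into polygon vertex lists."""
    root = ET.parse(path).getroot()
    polygons = []
    for region in root.iter("Region"):
        verts = [(float(v.get("X")), float(v.get("Y")))
                 for v in region.iter("Vertex")]
        polygons.append(np.asarray(verts, dtype=np.float64))
    return PolygonAnnotation(polygons=polygons)


def polygons_to_instance_mask(ann: PolygonAnnotation,
                              shape: tuple[int, int]) -> np.ndarray:
    """Fill polygons into an instance mask by the even-odd rule.

    A pixel (r, c) covers the unit square [r, r+1) x [c, c+1); it is inside a
    polygon iff its center (x = c + 0.5, y = r + 0.5) is, under the even-odd
    rule.  Later polygons overwrite earlier ones; polygons with fewer than 3
    vertices are skipped with a warning.
    """
    import warnings
    from matplotlib.path import Path as MplPath

    h, w = shape
    mask = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.reshape(-1) + 0.5, yy.reshape(-1) + 0.5])
    label = 0
    for poly in ann.polygons:
        if len(poly) < 3:
            warnings.warn(f"skipping degenerate polygon with {len(poly)} "
                          "vertices", stacklevel=2)
            continue
        label += 1
        xmin, ymin = poly.min(axis=0)
        xmax, ymax = poly.max(axis=0)
        sel = ((centers[:, 0] >= xmin) & (centers[:, 0] <= xmax)
               & (centers[:, 1] >= ymin) & (centers[:, 1] <= ymax))
        if not sel.any():
            continue
        inside = MplPath(poly).contains_points(centers[sel])
        idx = np.flatnonzero(sel)[inside]
        mask.reshape(-1)[idx] = label
    return mask


# ---- manifests and configs ----------------------------------------------

@dataclass
class DatasetManifest:
    """Rows of (image path, mask path, patient/slide id, split)."""

    rows: list[dict]
    root: Path

    @classmethod
    def load(cls, path, check_paths: bool = True) -> "DatasetManifest":
        path = Path(path)
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        root = path.parent
        if check_paths:
            for row in rows:
                for key in row:
                    if key.endswith(("image", "mask")) and row[key]:
                        p = root / row[key]
                        if not p.exists():
                            raise FileNotFoundError(f"manifest entry missing: {p}")
        return cls(rows=rows, root=root)

    def split(self, name: str) -> list[dict]:
        return [r for r in self.rows if r.get("split") == name]

    def patients(self) -> list[str]:
        ids = [r.get("slide_id") or r.get("patient_id") or "" for r in self.rows]
        if any(not i for i in ids):
            raise ValueError("manifest rows lack patient/slide ids")
        return sorted(set(ids))

    def leave_one_patient_out(self):
        """Yield (patient, train_rows, test_rows) folds; a patient's images
        never straddle the train/test boundary."""
        for patient in self.patients():
            test = [r for r in self.rows
                    if (r.get("slide_id") or r.get("patient_id")) == patient]
            train = [r for r in self.rows if r not in test]
            yield patient, train, test


def load_config(path) -> dict:
    """YAML config; CLI flags override config values (flags win)."""
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
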