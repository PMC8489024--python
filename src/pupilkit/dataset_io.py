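"""Reader and summarizer for annotated eye-image datasets.

Supports two on-disk layouts, auto-detected:

1. **Index table** — a CSV (``index.csv``, ``annotations.csv`` or
   ``labels.csv``) with a ``filename`` column plus either a ``mask``
   column of mask-image paths, ellipse columns (``cx, cy, a, b, angle``),
   or a ``polygon`` column of whitespace-separated ``x y`` vertex pairs.
   Optional columns: ``class`` (mouse / 2P-mouse / human), ``blink``,
   ``eye_present``.
2. **Image + mask pairs** — a ``masks/`` directory mirroring the image
   filenames, or ``*_mask`` siblings next to each image.

Ellipse annotations are rasterized with the same pixel-center rule the
synthetic generator uses, so both agree exactly on fixture annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon as sk_polygon

from .synth import CLASSES, ellipse_mask

logger = logging.getLogger(__name__)

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
_TABLE_NAMES = ("index.csv", "annotations.csv", "labels.csv")


@dataclass
class DatasetRecord:
    image_path: Path
    mask_path: Path | None = None
    ellipse: tuple[float, float, float, float, float] | None = None  # cx, cy, a, b, angle
    polygon: np.ndarray | None = None  # (n, 2) of (x, y)
    class_tag: str | None = None
    blink: bool = False
    eye_present: bool = True

    def __post_init__(self) -> None:
        if self.class_tag is not None and self.class_tag not in CLASSES:
            raise ValueError(f"class tag {self.class_tag!r} not in {CLASSES}")


@dataclass
class DatasetIndex:
    root: Path
    records: list[DatasetRecord]

    def __len__(self) -> int:
        return len(self.records)

    def load_image(self, record: DatasetRecord) -> np.ndarray:
        img = np.asarray(iio.imread(record.image_path), dtype=float)
        if img.ndim == 3:
            img = img[..., :3].mean(axis=-1)
        return img / 255.0 if img.max() > 1.0 else img

    def load_mask(self, record: DatasetRecord) -> np.ndarray:
        """Binary pupil mask, rasterizing ellipse/polygon annotations."""
        if record.mask_path is not None:
            return np.asarray(iio.imread(record.mask_path)) > 0
        shape = iio.improps(record.image_path).shape[:2]
        if record.ellipse is not None:
            cx, cy, a, b, angle = record.ellipse
            return ellipse_mask(shape, (cx, cy), (a, b), angle)
        if record.polygon is not None:
            rr, cc = sk_polygon(record.polygon[:, 1], record.polygon[:, 0], shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            return mask
        raise ValueError(f"record {record.image_path} has no annotation")


def _records_from_table(root: Path, table: Path) -> list[DatasetRecord]:
    df = pd.read_csv(table)
    if "filename" not in df.columns:
        raise ValueError(f"{table}: annotation table must have a 'filename' column")
    has_ellipse = {"cx", "cy", "a", "b"}.issubset(df.columns)
    records = []
    for i, row in df.iterrows():
        image_path = root / str(row["filename"])
        if not image_path.exists():
            logger.warning("skipping %s: image file missing", image_path)
            continue
        rec = dict(image_path=image_path)
        if "mask" in df.columns and isinstance(row.get("mask"), str) and row["mask"]:
            mask_path = root / row["mask"]
            if not mask_path.exists():
                logger.warning("skipping %s: mask file %s missing", image_path, mask_path)
                continue
            rec["mask_path"] = mask_path
        elif has_ellipse and np.isfinite(row["cx"]):
            rec["ellipse"] = (
                float(row["cx"]), float(row["cy"]), float(row["a"]), float(row["b"]),
                float(row.get("angle", 0.0)),
            )
        elif "polygon" in df.columns and isinstance(row.get("polygon"), str):
            pts = np.array([float(v) for v in row["polygon"].split()], dtype=float)
            rec["polygon"] = pts.reshape(-1, 2)
        else:
            blink = bool(int(row["blink"])) if "blink" in df.columns else False
            if not blink:
                logger.warning("skipping %s: no annotation", image_path)
                continue
            rec["mask_path"] = None  # a blink legitimately has no pupil annotation
        if "class" in df.columns and isinstance(row.get("class"), str) and row["class"]:
            rec["class_tag"] = row["class"]
        if "blink" in df.columns:
            rec["blink"] = bool(int(row["blink"]))
        if "eye_present" in df.columns:
            rec["eye_present"] = bool(int(row["eye_present"]))
        records.append(DatasetRecord(**rec))
    return records


def _records_from_pairs(root: Path) -> list[DatasetRecord]:
    mask_dir = root / "masks"
    image_dir = root / "images" if (root / "images").is_dir() else root
    records = []
    for img in sorted(image_dir.iterdir()):
        if img.suffix.lower() not in _IMAGE_EXTS or img.stem.endswith("_mask"):
            continue
        candidates = [img.with_name(img.stem + "_mask" + img.suffix)]
        if mask_dir.is_dir():
            candidates.insert(0, mask_dir / img.name)
        mask_path = next((c for c in candidates if c.exists()), None)
        if mask_path is None:
            logger.warning("skipping %s: no matching mask", img)
            continue
        mask = np.asarray(iio.imread(mask_path)) > 0
        # pair layouts carry no blink flag; an empty mask is the only cue
        records.append(DatasetRecord(
            image_path=img, mask_path=mask_path,
            blink=bool(not mask.any()), eye_present=True,
        ))
    return records


def load_deposit(root) -> DatasetIndex:
    """Load an extracted annotated-eye dataset from ``root``.

    Auto-detects the layout (annotation table vs. image+mask pairs) and
    fails loudly if neither is recognizable.  Images without a usable
    annotation are excluded with a logged warning.  An empty directory
    yields an empty index.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"dataset root {root} is not a directory")
    entries = list(root.iterdir())
    if not entries:
        return DatasetIndex(root=root, records=[])
    for name in _TABLE_NAMES:
        if (root / name).exists():
            return DatasetIndex(root=root, records=_records_from_table(root, root / name))
    has_images = any(
        p.suffix.lower() in _IMAGE_EXTS for p in root.rglob("*") if p.is_file()
    )
    if has_images:
        records = _records_from_pairs(root)
        if records:
            return DatasetIndex(root=root, records=records)
    raise ValueError(
        f"unrecognized dataset layout under {root}: expected an annotation table "
        f"({', '.join(_TABLE_NAMES)}) or image+mask pairs"
    )


def summarize_counts(index: DatasetIndex) -> pd.DataFrame:
    """Counts by class × blink with margins; margins sum to the total.

    Rows are class tags (``unknown`` for untagged records), columns are
    ``non_blink`` / ``blink`` / ``total``; the last row is the margin.
    """
    tags = [r.class_tag or "unknown" for r in index.records]
    blinks = [r.blink for r in index.records]
    df = pd.DataFrame({"class": tags, "blink": blinks})
    if df.empty:
        return pd.DataFrame(columns=["non_blink", "blink", "total"])
    tab = pd.crosstab(df["class"], df["blink"])
    tab = tab.reindex(columns=[False, True], fill_value=0)
    tab.columns = ["non_blink", "blink"]
    tab["total"] = tab.sum(axis=1)
    tab.loc["total"] = tab.sum(axis=0)
    return tab
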