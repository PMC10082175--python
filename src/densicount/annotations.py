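"""Point annotations: the only supervision the counting model needs.

Each animal is marked by a single 2-D point (its center). Coordinates are
0-based with ``x`` the pixel column and ``y`` the pixel row; pixel centers sit
at integer coordinates. Annotations are exchanged as a CSV with header
``image_id,x,y`` (one row per point) plus a manifest listing every image id,
so images with zero animals — which exist in real surveys and matter for
training — are represented too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["PointAnnotationSet", "read_annotations", "write_annotations"]


class AnnotationError(ValueError):
    """A point lies outside its image, or the annotation table is malformed."""


@dataclass
class PointAnnotationSet:
    """Per-image set of object-center points.

    Parameters
    ----------
    image_id:
        Identifier linking the points to an image file.
    points:
        List of ``(x, y)`` pixel coordinates, ``x`` = column, ``y`` = row.
        May be empty: background-only images are legitimate samples.
    image_size:
        ``(height, width)`` of the annotated image in pixels.
    """

    image_id: str
    points: list[tuple[float, float]] = field(default_factory=list)
    image_size: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        h, w = self.image_size
        for x, y in self.points:
            if not (0 <= x < w and 0 <= y < h):
                raise AnnotationError(
                    f"point ({x}, {y}) outside {h}x{w} image '{self.image_id}'"
                )

    @property
    def count(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)


def write_annotations(
    annotations: list[PointAnnotationSet], csv_path: str | Path, manifest_path: str | Path | None = None
) -> None:
    """Write point rows to ``csv_path`` and all image ids (+sizes) to a manifest.

    The manifest (JSON) is what records zero-count images; the CSV alone
    cannot distinguish "no animals" from "not annotated".
    """
    rows = [
        {"image_id": a.image_id, "x": x, "y": y}
        for a in annotations
        for x, y in a.points
    ]
    pd.DataFrame(rows, columns=["image_id", "x", "y"]).to_csv(csv_path, index=False)
    if manifest_path is not None:
        manifest = {
            a.image_id: {"height": int(a.image_size[0]), "width": int(a.image_size[1])}
            for a in annotations
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def read_annotations(
    csv_path: str | Path, manifest_path: str | Path | None = None,
    image_size: tuple[int, int] | None = None,
) -> list[PointAnnotationSet]:
    """Read annotation sets back from CSV (+ optional manifest).

    With a manifest, every listed image id yields a set (possibly empty) with
    its recorded size. Without one, only ids present in the CSV appear and
    ``image_size`` must be given (applied to all images).
    """
    df = pd.read_csv(csv_path)
    expected = ["image_id", "x", "y"]
    if list(df.columns[:3]) != expected:
        raise AnnotationError(f"annotation CSV must have columns {expected}, got {list(df.columns)}")
    by_id: dict[str, list[tuple[float, float]]] = {}
    for rec in df.itertuples(index=False):
        by_id.setdefault(str(rec.image_id), []).append((float(rec.x), float(rec.y)))

    if manifest_path is not None:
        manifest = json.loads(Path(manifest_path).read_text())
        return [
            PointAnnotationSet(
                image_id=iid,
                points=by_id.get(iid, []),
                image_size=(int(rec["height"]), int(rec["width"])),
            )
            for iid, rec in manifest.items()
        ]
    if image_size is None:
        raise AnnotationError("image_size required when no manifest is given")
    return [
        PointAnnotationSet(image_id=iid, points=pts, image_size=image_size)
        for iid, pts in by_id.items()
    ]
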