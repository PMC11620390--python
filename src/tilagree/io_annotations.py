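"""Readers and writers for multi-observer annotation data.

Conventions shared across the package:

* Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel centers
  sit at integer coordinates.  Distances are in pixels unless a μm quantity is
  explicit in the name.
* Binary stromal masks hold 1 for stroma and 0 for everything else.
* Point annotations are cell (lymphocyte) center coordinates in pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "CategoryMap",
    "MaskStack",
    "PointSets",
    "DatasetManifest",
    "AgreementReport",
    "read_mask_stack",
    "read_point_sets",
    "write_point_set",
    "write_mask",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class CategoryMap:
    """Mapping from label codes to the stroma / non-stroma dichotomy.

    Parameters
    ----------
    stroma_codes : frozenset of int
        Label values binarized to stroma (1).
    exclusion_codes : frozenset of int
        Label values (e.g. regions marked "other": necrosis, fat, debris)
        removed from the pixel universe entirely.  With
        ``exclude_other=False`` they are folded into non-stroma instead.
    exclude_other : bool
        Whether exclusion codes drop pixels from the universe (default) or
        count as non-stroma.
    """

    stroma_codes: frozenset = frozenset({1})
    exclusion_codes: frozenset = frozenset()
    exclude_other: bool = True
    known_codes: frozenset | None = None  # declared label universe, optional

    def __post_init__(self) -> None:
        if self.stroma_codes & self.exclusion_codes:
            raise ValueError("stroma codes and exclusion codes overlap")

    def binarize(self, label_image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Collapse a label image to (binary stroma mask, exclusion mask)."""
        arr = np.asarray(label_image)
        stroma = np.isin(arr, list(self.stroma_codes)).astype(np.uint8)
        if self.exclusion_codes and self.exclude_other:
            excluded = np.isin(arr, list(self.exclusion_codes))
        else:
            excluded = np.zeros(arr.shape, dtype=bool)
        return stroma, excluded


#: Default mapping for 8-bit grayscale masks: any positive value is stroma.
GRAYSCALE = "grayscale"


@dataclass
class MaskStack:
    """Aligned binary stromal masks for one image, one per observer.

    ``masks`` has shape ``(N, H, W)`` with values exactly 0 or 1;
    ``exclusion`` is an optional boolean ``(H, W)`` mask of pixels dropped
    from the agreement universe.
    """

    masks: np.ndarray
    observer_ids: list[str]
    image_id: str = ""
    exclusion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must have shape (N, H, W)")
        if self.masks.shape[0] < 1:
            raise ValueError("a MaskStack needs at least 1 observer")
        vals = np.unique(self.masks)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"mask values must be 0/1, found {vals}")
        if len(self.observer_ids) != self.masks.shape[0]:
            raise ValueError("observer_ids length must match number of masks")
        if self.exclusion is not None:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != self.masks.shape[1:]:
                raise ValueError("exclusion mask shape mismatch")

    @property
    def n_observers(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]


@dataclass
class PointSets:
    """Per-observer cell center coordinates for one image.

    ``points`` is a list of ``(m_i, 2)`` float arrays in ``(x, y)`` order.
    """

    points: list[np.ndarray]
    observer_ids: list[str]
    image_id: str = ""
    frame: tuple[int, int] | None = None  # (H, W) if attached

    def __post_init__(self) -> None:
        cleaned = []
        for obs_id, pts in zip(self.observer_ids, self.points, strict=True):
            arr = np.asarray(pts, dtype=float).reshape(-1, 2)
            if arr.size and not np.isfinite(arr).all():
                raise ValueError(f"non-finite coordinate in points of {obs_id!r}")
            if self.frame is not None and arr.size:
                h, w = self.frame
                if (arr[:, 0] < 0).any() or (arr[:, 0] >= w).any() or (
                    arr[:, 1] < 0
                ).any() or (arr[:, 1] >= h).any():
                    raise ValueError(
                        f"points of {obs_id!r} fall outside the {h}x{w} frame"
                    )
            if arr.shape[0] != np.unique(arr, axis=0).shape[0]:
                warnings.warn(
                    f"duplicate points in observer {obs_id!r}", stacklevel=2
                )
            cleaned.append(arr)
        self.points = cleaned

    @property
    def n_observers(self) -> int:
        return len(self.points)

    @property
    def counts(self) -> list[int]:
        return [len(p) for p in self.points]

    @property
    def total_points(self) -> int:
        return sum(self.counts)


@dataclass
class ManifestEntry:
    image_id: str
    mask_paths: dict[str, str]  # observer id -> mask path
    point_paths: dict[str, str]  # observer id -> point file path


@dataclass
class DatasetManifest:
    """Groups per-image, per-observer annotation files plus calibration."""

    entries: list[ManifestEntry]
    pixel_size_um: float
    observer_ids: list[str] = field(default_factory=list)
    root: Path | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.observer_ids and self.entries:
            self.observer_ids = sorted(self.entries[0].mask_paths)
        for e in self.entries:
            if sorted(e.mask_paths) != sorted(self.observer_ids) or sorted(
                e.point_paths
            ) != sorted(self.observer_ids):
                raise ValueError(
                    f"image {e.image_id!r} does not list the common observer set"
                )

    @property
    def image_ids(self) -> list[str]:
        return [e.image_id for e in self.entries]

    def _resolve(self, p: str) -> Path:
        path = Path(p)
        if not path.is_absolute() and self.root is not None:
            path = self.root / path
        return path

    def load_image(
        self, image_id: str, category_map: CategoryMap | str = GRAYSCALE
    ) -> tuple[MaskStack, PointSets]:
        entry = next(e for e in self.entries if e.image_id == image_id)
        obs = self.observer_ids
        stack = read_mask_stack(
            [self._resolve(entry.mask_paths[o]) for o in obs],
            category_map,
            observer_ids=obs,
            image_id=image_id,
        )
        pts = read_point_sets(
            [self._resolve(entry.point_paths[o]) for o in obs],
            observer_ids=obs,
            image_id=image_id,
        )
        pts.frame = stack.shape
        return stack, pts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = [
            ManifestEntry(
                image_id=str(e["image_id"]),
                mask_paths=dict(e["masks"]),
                point_paths=dict(e["points"]),
            )
            for e in raw["images"]
        ]
        return cls(
            entries=entries,
            pixel_size_um=float(raw["pixel_size_um"]),
            observer_ids=list(raw.get("observers", [])),
            root=path.parent,
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "pixel_size_um": self.pixel_size_um,
            "observers": list(self.observer_ids),
            "images": [
                {
                    "image_id": e.image_id,
                    "masks": dict(e.mask_paths),
                    "points": dict(e.point_paths),
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _load_image_array(path: str | Path) -> np.ndarray:
    suffix = Path(path).suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    with Image.open(path) as img:
        return np.asarray(img)


def read_mask_stack(
    paths: Sequence[str | Path],
    category_map: CategoryMap | str = GRAYSCALE,
    observer_ids: Sequence[str] | None = None,
    image_id: str = "",
) -> MaskStack:
    """Read per-observer mask images into a binarized :class:`MaskStack`.

    Grayscale masks (``category_map="grayscale"``) are thresholded at > 0;
    indexed-label images are collapsed via the supplied :class:`CategoryMap`.
    The exclusion mask is the union over observers of excluded label pixels.
    """
    if observer_ids is None:
        observer_ids = [Path(p).stem for p in paths]
    masks, exclusion = [], None
    for path in paths:
        arr = _load_image_array(path)
        if arr.ndim == 3:  # RGB(A): any nonzero channel is foreground
            arr = arr[..., :3].max(axis=-1)
        if category_map == GRAYSCALE:
            binary, excl = (arr > 0).astype(np.uint8), None
        elif isinstance(category_map, CategoryMap):
            if category_map.known_codes is not None:
                unknown = set(np.unique(arr).tolist()) - set(
                    category_map.known_codes
                )
                if unknown:
                    raise ValueError(
                        f"unknown label codes {sorted(unknown)} in {path}"
                    )
            binary, excl = category_map.binarize(arr)
        else:
            raise TypeError("category_map must be a CategoryMap or 'grayscale'")
        if masks and binary.shape != masks[0].shape:
            raise ValueError(
                f"mask dimension mismatch: {path} is {binary.shape}, "
                f"expected {masks[0].shape}"
            )
        masks.append(binary)
        if excl is not None and excl.any():
            exclusion = excl if exclusion is None else (exclusion | excl)
    return MaskStack(
        masks=np.stack(masks),
        observer_ids=list(observer_ids),
        image_id=image_id,
        exclusion=exclusion,
    )


def read_point_sets(
    paths: Sequence[str | Path],
    observer_ids: Sequence[str] | None = None,
    image_id: str = "",
) -> PointSets:
    """Read per-observer point files (CSV with ``x,y`` header, or JSON list).

    File order is preserved; an empty file yields an empty set with a warning.
    """
    if observer_ids is None:
        observer_ids = [Path(p).stem for p in paths]
    all_points = []
    for path in paths:
        path = Path(path)
        if path.suffix.lower() == ".json":
            with open(path) as fh:
                rows = json.load(fh)
            arr = np.asarray(rows, dtype=float).reshape(-1, 2)
        else:
            try:
                df = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame(columns=["x", "y"])
            if len(df) and not {"x", "y"} <= set(df.columns):
                raise ValueError(f"{path}: expected columns x,y")
            for col in ("x", "y"):
                if len(df):
                    coerced = pd.to_numeric(df[col], errors="coerce")
                    bad = coerced.isna() & df[col].notna()
                    if bad.any():
                        row = int(bad.idxmax()) + 2  # header + 1-based
                        raise ValueError(
                            f"{path}: non-numeric {col!r} at line {row}"
                        )
                    df[col] = coerced
            df = df.dropna(subset=["x", "y"]) if len(df) else df
            arr = df[["x", "y"]].to_numpy(dtype=float) if len(df) else np.empty((0, 2))
        if arr.size == 0:
            warnings.warn(f"empty point file: {path}", stacklevel=2)
        all_points.append(arr)
    return PointSets(
        points=all_points, observer_ids=list(observer_ids), image_id=image_id
    )


def write_point_set(points: np.ndarray, path: str | Path) -> None:
    """Write one observer's points as a CSV with an ``x,y`` header."""
    df = pd.DataFrame(np.asarray(points, dtype=float).reshape(-1, 2), columns=["x", "y"])
    df.to_csv(path, index=False)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit image (stroma=255)."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr).save(path)


@dataclass
class AgreementReport:
    """Per-image agreement measures plus dataset-level concordance statistics.

    ``per_image`` is a DataFrame indexed by image id with columns such as
    ``fk``, ``bwfk``, ``dbcaa`` and ``tils_<observer>``;  ``dataset`` holds
    scalar dataset-level results (ICC, LOAM limits, correlations, config).
    """

    per_image: pd.DataFrame
    dataset: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "config": self.config,
            "dataset": self.dataset,
            "per_image": {
                "index_name": self.per_image.index.name,
                "index": [str(i) for i in self.per_image.index],
                "columns": list(self.per_image.columns),
                "values": self.per_image.to_numpy().tolist(),
            },
        }
        return json.dumps(payload, indent=2)


def write_report(report: AgreementReport, path: str | Path) -> tuple[Path, Path]:
    """Write a report as JSON (machine) and CSV (per-image table).

    Returns the two paths written.  ``read_report(json_path)`` round-trips
    the JSON losslessly.
    """
    path = Path(path)
    json_path = path.with_suffix(".json")
    csv_path = path.with_suffix(".csv")
    json_path.write_text(report.to_json())
    report.per_image.to_csv(csv_path, index_label="image_id")
    return json_path, csv_path


def read_report(json_path: str | Path) -> AgreementReport:
    with open(json_path) as fh:
        payload = json.load(fh)
    tab = payload["per_image"]
    df = pd.DataFrame(
        np.asarray(tab["values"]).reshape(len(tab["index"]), len(tab["columns"])),
        index=pd.Index(tab["index"], name=tab.get("index_name")),
        columns=tab["columns"],
    )
    return AgreementReport(
        per_image=df, dataset=payload["dataset"], config=payload["config"]
    )
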