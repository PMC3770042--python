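"""Reading and writing images, seed files, masks and contours.

Every other module obeys the conventions defined here:

* an *intensity image* is a 2-D ``float64`` array indexed ``(row, col)``,
  0-based, row-major, origin at the top-left; 8-bit sources load to values
  in ``[0, 255]``;
* a *binary mask* is a 2-D array of the same shape with values in ``{0, 1}``
  (stored as ``uint8``);
* seeds are sparse ``(row, col, label)`` triples with nonzero integer
  labels; in the binary convention label ``1`` marks foreground and ``-1``
  background;
* contours store ``(x=col, y=row)`` sub-pixel coordinates at pixel centres;
* bounding boxes are half-open ``(r0, c0, r1, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SeedMap",
    "read_image",
    "read_seeds",
    "write_seeds",
    "read_mask",
    "write_mask",
    "write_image",
    "read_contour",
    "write_contour",
]

_GRAY_MODES = {"L", "I", "I;16", "1"}


@dataclass(frozen=True)
class SeedMap:
    """Sparse user-marked pixels with integer class labels.

    Entries are canonicalised to row-major order; exact duplicates are
    merged and a coordinate carrying two different labels is an error.
    """

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        rows = np.atleast_1d(np.asarray(self.rows, dtype=np.intp))
        cols = np.atleast_1d(np.asarray(self.cols, dtype=np.intp))
        labels = np.atleast_1d(np.asarray(self.labels, dtype=np.int64))
        if not (rows.shape == cols.shape == labels.shape) or rows.ndim != 1:
            raise ValueError("rows, cols and labels must be 1-D and equal length")
        if len(rows) == 0:
            raise ValueError("a SeedMap must contain at least one entry")
        if np.any(labels == 0):
            raise ValueError("seed label 0 is reserved for unlabeled cells")
        seen: dict[tuple[int, int], int] = {}
        for r, c, l in zip(rows.tolist(), cols.tolist(), labels.tolist()):
            if seen.setdefault((r, c), l) != l:
                raise ValueError(f"coordinate ({r}, {c}) has conflicting labels")
        triples = sorted((r, c, l) for (r, c), l in seen.items())
        arr = np.asarray(triples, dtype=np.int64)
        object.__setattr__(self, "rows", arr[:, 0].astype(np.intp))
        object.__setattr__(self, "cols", arr[:, 1].astype(np.intp))
        object.__setattr__(self, "labels", arr[:, 2])

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def distinct_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if np.any((self.rows < 0) | (self.rows >= h) | (self.cols < 0) | (self.cols >= w)):
            raise ValueError(f"seed coordinates fall outside a {h}x{w} image")

    def translate(self, dr: int, dc: int, shape: tuple[int, int]) -> "SeedMap":
        """Shift all seeds by ``(dr, dc)`` and keep those inside ``shape``."""
        r = self.rows + dr
        c = self.cols + dc
        h, w = shape
        keep = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        if not keep.any():
            raise ValueError("no seeds remain inside the target frame")
        return SeedMap(r[keep], c[keep], self.labels[keep])


def read_image(
    path: str | Path,
    window: tuple[float, float] | None = None,
    to_gray: bool = False,
) -> np.ndarray:
    """Load an 8-bit grayscale PNG/BMP (or a windowed DICOM) as float64.

    Parameters
    ----------
    path
        PNG/BMP file, or a single-frame monochrome DICOM when ``window``
        is given.
    window
        ``(center, width)`` linear window mapping DICOM stored values to
        ``[0, 255]``: ``v -> (v - (center - width/2)) / width * 255``,
        clipped.
    to_gray
        Allow colour inputs by converting to luminance; colour files are
        rejected otherwise, since the method is defined on gray images.
    """
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _read_dicom(path, window)
    with Image.open(path) as im:
        if im.mode not in _GRAY_MODES:
            if not to_gray:
                raise ValueError(
                    f"{path} is not grayscale (mode {im.mode}); "
                    "pass to_gray=True for a luminance conversion"
                )
            im = im.convert("L")
        elif im.mode != "L":
            im = im.convert("L")
        arr = np.asarray(im, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{path} did not decode to a 2-D image")
    return arr


def _read_dicom(path: Path, window: tuple[float, float] | None) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "DICOM support requires pydicom (install the 'dicom' extra)"
        ) from exc
    if window is None:
        raise ValueError("reading DICOM requires an explicit (center, width) window")
    center, width = float(window[0]), float(window[1])
    if width <= 0:
        raise ValueError("window width must be positive")
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("only single-frame monochrome DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    arr = (arr - (center - width / 2.0)) / width * 255.0
    return np.clip(arr, 0.0, 255.0)


def read_seeds(path: str | Path, image_shape: tuple[int, int]) -> SeedMap:
    """Parse a ``row,col,label`` CSV (``#`` comments allowed) into a SeedMap."""
    entries: list[tuple[int, int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'row,col,label', got {raw!r}")
        try:
            r, c, l = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field in {raw!r}") from exc
        entries.append((r, c, l))
    if not entries:
        raise ValueError(f"{path}: no seed entries")
    arr = np.asarray(entries, dtype=np.int64)
    seeds = SeedMap(arr[:, 0], arr[:, 1], arr[:, 2])
    seeds.check_bounds(image_shape)
    return seeds


def write_seeds(seeds: SeedMap, path: str | Path) -> None:
    lines = [f"{r},{c},{l}" for r, c, l in zip(seeds.rows, seeds.cols, seeds.labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("mask must be a non-empty 2-D array")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit PNG with 0 -> 0 and 1 -> 255."""
    arr = _validate_mask(mask)
    Image.fromarray(arr * np.uint8(255), mode="L").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG written by :func:`write_mask` back to {0,1}."""
    arr = read_image(path)
    if not np.isin(arr, (0.0, 255.0)).all():
        raise ValueError(f"{path} is not a binary 0/255 mask image")
    return (arr > 0).astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write an intensity image as 8-bit PNG/BMP (values clipped/rounded)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    data = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(Path(path))


def write_contour(points: np.ndarray, path: str | Path) -> None:
    """Write contour points as an ``x,y`` CSV (sub-pixel, pixel-centre)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour points must have shape (N, 2)")
    lines = ["x,y"] + [f"{x:.6f},{y:.6f}" for x, y in pts]
    Path(path).write_text("\n".join(lines) + "\n")


def read_contour(path: str | Path) -> np.ndarray:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.lower().startswith("x"):
            continue
        x, y = line.split(",")
        rows.append((float(x), float(y)))
    if not rows:
        raise ValueError(f"{path}: no contour points")
    return np.asarray(rows, dtype=np.float64)
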