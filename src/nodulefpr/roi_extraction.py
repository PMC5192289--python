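"""ROI patch extraction from LIDC-style CT annotations.

The pipeline mirrors how nodule candidates reach a false-positive-reduction
classifier: each annotated region (a freehand contour for nodules >= 3 mm, a
single centroid mark for small nodules and nonnodules) yields one labeled
patch.  The geometric center of the contour is computed, the region's bounding
box decides the cut: regions that fit within the target size are cropped
directly; larger regions are cropped at twice the size and mean-pooled down,
so a 40x40 nodule still lands in a 32x32 input.

Coordinates are 0-based ``(row, col)`` with pixel-center semantics; crops are
half-open ``[c - size//2, c + size//2)``.  Crops that extend past the slice
are padded with the intensity window floor (air-equivalent).  Patch values are
normalized to [0, 1] by a fixed linear intensity window — by default the full
stored dynamic range of the slice dtype, or [-1000, 400] HU for DICOM input —
so normalization never depends on the dataset being processed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationRecord",
    "ImagePatch",
    "Case",
    "PatchDataset",
    "DICOM_WINDOW",
    "parse_annotations",
    "geometric_center",
    "region_extent",
    "extract_patch",
    "downsample_2x",
    "normalize_patch",
    "build_dataset",
    "save_dataset",
    "load_dataset",
    "load_slice_pixels",
    "MANIFEST_COLUMNS",
]

logger = logging.getLogger(__name__)

#: fixed HU window used for DICOM slices (air .. soft tissue / nodule range)
DICOM_WINDOW = (-1000.0, 400.0)

MANIFEST_COLUMNS = ["case_id", "slice_id", "label", "center_row", "center_col",
                    "patch_path"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    """One annotated region: a nodule contour or a single-point mark."""

    case_id: str
    slice_id: str
    kind: str  # "nodule" | "nonnodule"
    contour: list[tuple[int, int]]  # 0-based (row, col) vertices
    diameter_mm: float | None = None

    def __post_init__(self):
        if self.kind not in {"nodule", "nonnodule"}:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if not self.contour:
            raise ValueError("annotation contour must be non-empty")

    @property
    def label(self) -> int:
        return 1 if self.kind == "nodule" else 0


@dataclass
class ImagePatch:
    """One normalized grayscale ROI with its label and exam identifier."""

    pixels: np.ndarray  # (S, S) float32 in [0, 1]
    label: int  # 1 nodule / 0 nonnodule
    case_id: str
    provenance: dict = field(default_factory=dict)  # slice_id, center, branch, ...

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"patch must be square 2-D, got shape {self.pixels.shape}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class Case:
    """One exam: its slices (by slice_id) and its annotation records."""

    case_id: str
    slices: dict[str, np.ndarray]
    annotations: list[AnnotationRecord]


@dataclass
class PatchDataset:
    """Stacked patches ready for training: X (N,1,S,S), labels, exam ids."""

    X: np.ndarray
    y: np.ndarray
    exam_ids: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.intp)
        self.exam_ids = np.asarray(self.exam_ids)
        if self.X.ndim != 4 or len(self.y) != len(self.X) or \
                len(self.exam_ids) != len(self.X):
            raise ValueError("inconsistent dataset arrays")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "PatchDataset":
        return PatchDataset(self.X[idx], self.y[idx], self.exam_ids[idx])

    @classmethod
    def from_patches(cls, patches: list[ImagePatch]) -> "PatchDataset":
        if not patches:
            raise ValueError("cannot build a dataset from zero patches")
        X = np.stack([p.pixels for p in patches])[:, None, :, :]
        y = np.array([p.label for p in patches], dtype=np.intp)
        exams = np.array([p.case_id for p in patches])
        return cls(X, y, exams)


# ---------------------------------------------------------------------------
# annotation parsing (LIDC-dialect XML)
# ---------------------------------------------------------------------------

def _tag(elem) -> str:
    """Local tag name, namespace stripped."""
    return elem.tag.rpartition("}")[2]


def _find(elem, name):
    for child in elem.iter():
        if _tag(child) == name:
            return child
    return None


def _children(elem, name):
    return [c for c in elem.iter() if _tag(c) == name]


def _read_point(elem, context: str) -> tuple[int, int]:
    x = _find(elem, "xCoord")
    y = _find(elem, "yCoord")
    if x is None or y is None or x.text is None or y.text is None:
        raise ValueError(f"malformed annotation: {context} lacks xCoord/yCoord")
    # LIDC stores xCoord = image column, yCoord = image row
    return int(round(float(y.text))), int(round(float(x.text)))


def parse_annotations(source) -> list[AnnotationRecord]:
    """Parse a LIDC-dialect annotation document into AnnotationRecords.

    ``source`` may be a path, an XML string/bytes, or a parsed Element.
    Nodule regions come from ``unblindedReadNodule`` elements (one record per
    ``roi``, contour from its ``edgeMap`` points); nonnodules from
    ``nonNodule`` elements (single ``locus`` mark).  An empty document yields
    an empty list; structurally broken elements raise ``ValueError`` naming
    the offender.
    """
    if isinstance(source, (str, Path)) and "<" not in str(source):
        root = ElementTree.parse(source).getroot()
    elif isinstance(source, (str, bytes)):
        root = ElementTree.fromstring(source)
    else:
        root = source

    header = _find(root, "SeriesInstanceUid")
    case_id = header.text.strip() if header is not None and header.text else "unknown"

    records: list[AnnotationRecord] = []
    for nodule in _children(root, "unblindedReadNodule"):
        nid_elem = _find(nodule, "noduleID")
        nid = nid_elem.text if nid_elem is not None else "?"
        rois = _children(nodule, "roi")
        if not rois:
            raise ValueError(f"malformed annotation: nodule {nid} has no roi element")
        for roi in rois:
            uid = _find(roi, "imageSOP_UID")
            if uid is None or uid.text is None:
                raise ValueError(f"malformed annotation: roi of nodule {nid} lacks imageSOP_UID")
            points = _children(roi, "edgeMap")
            if not points:
                raise ValueError(f"malformed annotation: roi of nodule {nid} has no edgeMap")
            contour = [_read_point(p, f"edgeMap of nodule {nid}") for p in points]
            records.append(AnnotationRecord(case_id=case_id, slice_id=uid.text.strip(),
                                            kind="nodule", contour=contour))
    for nn in _children(root, "nonNodule"):
        nnid_elem = _find(nn, "nonNoduleID")
        nnid = nnid_elem.text if nnid_elem is not None else "?"
        uid = _find(nn, "imageSOP_UID")
        if uid is None or uid.text is None:
            raise ValueError(f"malformed annotation: nonNodule {nnid} lacks imageSOP_UID")
        locus = _find(nn, "locus")
        if locus is None:
            raise ValueError(f"malformed annotation: nonNodule {nnid} lacks locus")
        point = _read_point(locus, f"locus of nonNodule {nnid}")
        records.append(AnnotationRecord(case_id=case_id, slice_id=uid.text.strip(),
                                        kind="nonnodule", contour=[point]))
    return records


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def geometric_center(contour) -> tuple[int, int]:
    """Arithmetic mean of the contour vertices, rounded half-up per axis."""
    pts = np.asarray(contour, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("contour must be non-empty")
    mean = pts.reshape(-1, 2).mean(axis=0)
    return _round_half_up(mean[0]), _round_half_up(mean[1])


def region_extent(contour) -> tuple[int, int]:
    """Bounding-box (height, width) of the contour, inclusive of endpoints."""
    pts = np.asarray(contour, dtype=np.int64).reshape(-1, 2)
    if pts.size == 0:
        raise ValueError("contour must be non-empty")
    return (int(pts[:, 0].max() - pts[:, 0].min() + 1),
            int(pts[:, 1].max() - pts[:, 1].min() + 1))


# ---------------------------------------------------------------------------
# cropping / normalization
# ---------------------------------------------------------------------------

def _resolve_window(slice_pixels: np.ndarray, window) -> tuple[float, float]:
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        if not hi > lo:
            raise ValueError("intensity window must have ceiling > floor")
        return lo, hi
    dt = slice_pixels.dtype
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        return float(info.min), float(info.max)
    return 0.0, 1.0  # float fixtures are stored already scaled


def _crop(slice_pixels: np.ndarray, center: tuple[int, int], size: int,
          pad_value: float) -> np.ndarray:
    h, w = slice_pixels.shape
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} lies outside the {h}x{w} slice")
    out = np.full((size, size), pad_value, dtype=np.float64)
    r0, c0 = r - size // 2, c - size // 2
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    out[rs - r0:re - r0, cs - c0:ce - c0] = slice_pixels[rs:re, cs:ce]
    return out


def downsample_2x(patch: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 mean pooling; preserves the image mean exactly."""
    a = np.asarray(patch, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] % 2:
        raise ValueError(f"downsample_2x expects a square even-sided image, got {a.shape}")
    s = a.shape[0] // 2
    return a.reshape(s, 2, s, 2).mean(axis=(1, 3))


def normalize_patch(raw_patch: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Fixed linear window map to [0, 1], clamped at both ends."""
    lo, hi = float(window[0]), float(window[1])
    a = np.asarray(raw_patch, dtype=np.float64)
    return np.clip((a - lo) / (hi - lo), 0.0, 1.0)


def extract_patch(slice_pixels: np.ndarray, center: tuple[int, int],
                  extent: tuple[int, int], patch_size: int = 32,
                  window=None) -> tuple[np.ndarray, str]:
    """Cut one normalized ``patch_size`` patch around ``center``.

    If the region's bounding box fits inside ``patch_size`` per axis, a direct
    crop of that size is taken; otherwise a crop of twice the size is taken
    and mean-pooled down — the branch depends only on the extent, never on
    pixel intensities.  Returns ``(pixels in [0,1], branch)`` with branch one
    of ``"direct"`` / ``"downsampled"``.
    """
    slice_pixels = np.asarray(slice_pixels)
    lo, hi = _resolve_window(slice_pixels, window)
    if max(extent) <= patch_size:
        raw = _crop(slice_pixels.astype(np.float64), center, patch_size, pad_value=lo)
        return normalize_patch(raw, (lo, hi)), "direct"
    raw = _crop(slice_pixels.astype(np.float64), center, 2 * patch_size, pad_value=lo)
    return normalize_patch(downsample_2x(raw), (lo, hi)), "downsampled"


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(cases, mode: int = 32, window=None
                  ) -> tuple[list[ImagePatch], pd.DataFrame, int]:
    """One ImagePatch per annotation record across all cases.

    Records are processed in deterministic order — sorted by (case_id,
    slice_id, center) — so reruns produce byte-identical manifests.
    Annotations whose slice is missing are logged and skipped; the count of
    skips is returned alongside the patches and the manifest frame.
    """
    if mode not in (32, 64):
        raise ValueError(f"mode must be 32 or 64, got {mode}")
    jobs = []
    by_case = {}
    for case in cases:
        by_case[case.case_id] = case
        for rec in case.annotations:
            jobs.append((case.case_id, rec.slice_id, geometric_center(rec.contour), rec))
    jobs.sort(key=lambda j: (j[0], j[1], j[2]))

    patches: list[ImagePatch] = []
    rows = []
    skipped = 0
    for case_id, slice_id, center, rec in jobs:
        slice_pixels = by_case[case_id].slices.get(slice_id)
        if slice_pixels is None:
            logger.warning("case %s: slice %s missing, annotation skipped", case_id, slice_id)
            skipped += 1
            continue
        pixels, branch = extract_patch(slice_pixels, center, region_extent(rec.contour),
                                       patch_size=mode, window=window)
        patches.append(ImagePatch(pixels=pixels, label=rec.label, case_id=case_id,
                                  provenance={"slice_id": slice_id, "center": center,
                                              "branch": branch}))
        rows.append({"case_id": case_id, "slice_id": slice_id, "label": rec.label,
                     "center_row": center[0], "center_col": center[1], "patch_path": ""})
    if skipped:
        logger.warning("build_dataset: skipped %d annotation(s) with missing slices", skipped)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return patches, manifest, skipped


def save_dataset(patches: list[ImagePatch], manifest: pd.DataFrame, out_dir) -> Path:
    """Write one ``.npy`` file per patch plus ``manifest.csv``; returns the csv path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for i, patch in enumerate(patches):
        rel = f"patch_{i:05d}.npy"
        np.save(out / rel, patch.pixels.astype(np.float32))
        paths.append(rel)
    manifest["patch_path"] = paths
    csv_path = out / "manifest.csv"
    manifest.to_csv(csv_path, index=False)
    return csv_path


def load_dataset(manifest_csv) -> PatchDataset:
    """Load a manifest.csv + patch files back into a PatchDataset."""
    csv_path = Path(manifest_csv)
    manifest = pd.read_csv(csv_path, dtype={"case_id": str, "slice_id": str})
    if manifest.empty:
        raise ValueError(f"manifest {csv_path} holds no patches")
    base = csv_path.parent
    X = np.stack([np.load(base / p) for p in manifest["patch_path"]])[:, None, :, :]
    return PatchDataset(X, manifest["label"].to_numpy(),
                        manifest["case_id"].to_numpy())


# ---------------------------------------------------------------------------
# slice input
# ---------------------------------------------------------------------------

def load_slice_pixels(path) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Read one CT slice; returns (pixels, suggested intensity window).

    ``.npy`` arrays are returned as stored (window inferred from dtype later);
    ``.dcm`` files are converted to Hounsfield units via RescaleSlope/Intercept
    and paired with the fixed [-1000, 400] HU window; ``.png`` grayscale is
    supported through Pillow when available.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".npy":
        return np.load(p), None
    if suffix == ".dcm":
        import pydicom  # optional dependency, DICOM input only

        ds = pydicom.dcmread(p)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return ds.pixel_array.astype(np.float64) * slope + intercept, DICOM_WINDOW
    if suffix == ".png":
        from PIL import Image  # optional dependency, PNG input only

        return np.asarray(Image.open(p).convert("L")), (0.0, 255.0)
    raise ValueError(f"unsupported slice format {suffix!r} for {p}")
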