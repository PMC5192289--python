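"""Synthetic labeled patch datasets and annotation fixtures.

The generator emulates the appearance classes a false-positive-reduction
classifier has to separate: the three nodule presentations — solid (bright
compact blob), semisolid (bright core inside a fainter halo) and ground-glass
opacity (wide, low-contrast blob) — against the two dominant negatives, a
vessel cut longitudinally (an elongated bright ridge at random orientation)
and plain background texture.  Intensities are not calibrated to Hounsfield
units; the targets are the topology/contrast classes, not radiological
realism.

``separation`` controls the contrast-to-noise ratio: ``high`` yields a
cleanly learnable problem, ``low`` pushes the signal under the noise floor so
accuracy collapses toward chance — useful for confirming a model is not
reading labels through some side channel.

The default class imbalance mirrors the published LIDC-scale extraction,
40,772 nodules to 21,720 nonnodules (ratio ~1.877); patches are assigned
round-robin to synthetic exam identifiers so grouped splits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi_extraction import (AnnotationRecord, Case, ImagePatch, MANIFEST_COLUMNS,
                             PatchDataset)

__all__ = [
    "PAPER_NODULE_COUNT",
    "PAPER_NONNODULE_COUNT",
    "GeneratorSpec",
    "generate_patch",
    "generate_dataset",
    "generate_annotation_fixture",
    "class_counts",
]

#: LIDC-scale class counts the default imbalance mirrors
PAPER_NODULE_COUNT = 40_772
PAPER_NONNODULE_COUNT = 21_720

NODULE_KINDS = ("solid", "semisolid", "ggo")
NONNODULE_KINDS = ("vessel", "background")

#: background gray level all patches share
BACKGROUND_LEVEL = 0.25

#: separation level -> (peak blob contrast over background, noise sd)
SEPARATION_LEVELS = {
    "high": (0.55, 0.04),
    "medium": (0.25, 0.08),
    "low": (0.03, 0.12),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic dataset."""

    n_nodules: int
    n_nonnodules: int
    nodule_mix: dict = field(default_factory=lambda: {"solid": 0.5, "semisolid": 0.25,
                                                      "ggo": 0.25})
    nonnodule_mix: dict = field(default_factory=lambda: {"vessel": 0.5, "background": 0.5})
    separation: str = "high"
    patch_size: int = 32
    exams: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_nodules < 0 or self.n_nonnodules < 0:
            raise ValueError("class counts must be nonnegative")
        if self.n_nodules + self.n_nonnodules == 0:
            raise ValueError("a dataset needs at least one patch")
        if self.separation not in SEPARATION_LEVELS:
            raise ValueError(f"unknown separation {self.separation!r}")
        if self.patch_size not in (32, 64):
            raise ValueError("patch_size must be 32 or 64")
        for mix, kinds in ((self.nodule_mix, NODULE_KINDS),
                          (self.nonnodule_mix, NONNODULE_KINDS)):
            if set(mix) - set(kinds):
                raise ValueError(f"unknown kinds in mix: {set(mix) - set(kinds)}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mix weights must sum to 1")

    @classmethod
    def mirror_ratio(cls, n_total: int, **kwargs) -> "GeneratorSpec":
        """Split ``n_total`` patches at the published 40,772 : 21,720 imbalance."""
        total = PAPER_NODULE_COUNT + PAPER_NONNODULE_COUNT
        n_nodules = int(round(n_total * PAPER_NODULE_COUNT / total))
        return cls(n_nodules=n_nodules, n_nonnodules=n_total - n_nodules, **kwargs)


# ---------------------------------------------------------------------------
# single patches
# ---------------------------------------------------------------------------

def _gaussian2d(size: int, center: tuple[float, float], sigma_long: float,
                sigma_short: float, theta: float) -> np.ndarray:
    """Anisotropic 2-D Gaussian bump, peak 1, axes rotated by theta."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    return np.exp(-0.5 * ((u / sigma_long) ** 2 + (v / sigma_short) ** 2))


def generate_patch(kind: str, rng: np.random.Generator, separation: str = "high",
                   patch_size: int = 32) -> ImagePatch:
    """One synthetic patch of the given appearance class.

    Nodule kinds (label 1): ``solid``, ``semisolid``, ``ggo``.  Nonnodule
    kinds (label 0): ``vessel``, ``background``.  Structures sit near the
    patch center (the candidate detector is assumed to have fired there) over
    Gaussian background noise; output pixels are clipped to [0, 1].
    """
    if kind not in NODULE_KINDS + NONNODULE_KINDS:
        raise ValueError(f"unknown patch kind {kind!r}")
    amp, noise_sd = SEPARATION_LEVELS[separation]
    s = patch_size
    scale = s / 32.0  # structure sizes defined at 32 px and scaled up for 64
    img = np.full((s, s), BACKGROUND_LEVEL, dtype=np.float64)

    center = (s / 2 - 0.5 + rng.uniform(-2, 2) * scale,
              s / 2 - 0.5 + rng.uniform(-2, 2) * scale)
    a = amp * rng.uniform(0.9, 1.1)

    if kind == "solid":
        sigma = rng.uniform(2.0, 3.5) * scale
        img += a * _gaussian2d(s, center, sigma, sigma, 0.0)
    elif kind == "semisolid":
        core = rng.uniform(1.5, 2.5) * scale
        halo = rng.uniform(4.0, 6.0) * scale
        img += a * _gaussian2d(s, center, core, core, 0.0)
        img += 0.45 * a * _gaussian2d(s, center, halo, halo, 0.0)
    elif kind == "ggo":
        sigma = rng.uniform(5.0, 8.0) * scale
        img += 0.5 * a * _gaussian2d(s, center, sigma, sigma, 0.0)
    elif kind == "vessel":
        long_ax = rng.uniform(9.0, 14.0) * scale
        short_ax = rng.uniform(1.0, 1.8) * scale
        theta = rng.uniform(0.0, np.pi)
        img += a * _gaussian2d(s, center, long_ax, short_ax, theta)
    else:  # background: a few faint off-center lumps, no compact bright core
        for _ in range(3):
            pos = (rng.uniform(0, s - 1), rng.uniform(0, s - 1))
            sigma = rng.uniform(3.0, 7.0) * scale
            img += 0.15 * a * _gaussian2d(s, pos, sigma, sigma, 0.0)

    img += rng.normal(0.0, noise_sd, size=(s, s))
    label = 1 if kind in NODULE_KINDS else 0
    return ImagePatch(pixels=np.clip(img, 0.0, 1.0), label=label, case_id="",
                      provenance={"kind": kind, "separation": separation})


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def _draw_kinds(rng, kinds, mix, n) -> list[str]:
    probs = np.array([mix.get(k, 0.0) for k in kinds])
    return list(rng.choice(kinds, size=n, p=probs / probs.sum()))


def generate_dataset(spec: GeneratorSpec) -> tuple[list[ImagePatch], pd.DataFrame]:
    """Deterministic patch collection + manifest for a GeneratorSpec.

    The manifest schema is identical to the ROI-extraction output, so the
    training and evaluation code consumes either interchangeably.  Patches are
    dealt round-robin to ``spec.exams`` synthetic exam ids.
    """
    rng = np.random.default_rng(spec.seed)
    kinds = (_draw_kinds(rng, NODULE_KINDS, spec.nodule_mix, spec.n_nodules)
             + _draw_kinds(rng, NONNODULE_KINDS, spec.nonnodule_mix, spec.n_nonnodules))
    patches: list[ImagePatch] = []
    rows = []
    mid = spec.patch_size // 2
    for i, kind in enumerate(kinds):
        patch = generate_patch(kind, rng, separation=spec.separation,
                               patch_size=spec.patch_size)
        patch.case_id = f"SYNEXAM{i % spec.exams:04d}"
        patch.provenance["slice_id"] = "synthetic"
        patches.append(patch)
        rows.append({"case_id": patch.case_id, "slice_id": "synthetic",
                     "label": patch.label, "center_row": mid, "center_col": mid,
                     "patch_path": ""})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return patches, manifest


def class_counts(manifest: pd.DataFrame) -> tuple[int, int, int]:
    """(nodules, nonnodules, total) accounted from a manifest frame."""
    labels = manifest["label"].to_numpy()
    n_nodule = int((labels == 1).sum())
    n_nonnodule = int((labels == 0).sum())
    return n_nodule, n_nonnodule, n_nodule + n_nonnodule


def dataset_from_spec(spec: GeneratorSpec) -> PatchDataset:
    """Convenience: generate and stack straight into a PatchDataset."""
    patches, _ = generate_dataset(spec)
    return PatchDataset.from_patches(patches)


# ---------------------------------------------------------------------------
# annotation fixtures (exercise parsing + extraction end to end)
# ---------------------------------------------------------------------------

def _circle_contour(center: tuple[int, int], radius: float, n_vertices: int = 16
                    ) -> list[tuple[int, int]]:
    angles = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    return [(int(round(center[0] + radius * np.sin(t))),
             int(round(center[1] + radius * np.cos(t)))) for t in angles]


def generate_annotation_fixture(n_cases: int, seed: int = 0, slice_size: int = 160
                                ) -> tuple[list[Case], list[str]]:
    """Synthetic slices with planted blobs plus matching LIDC-dialect XML.

    Each case carries one slice with two nodules — one small (contour fits
    inside 32x32, direct-crop branch) and one large (contour wider than 32,
    64->32 downsample branch) — and one nonnodule point mark, so parsing, both
    extraction branches and labeling are all exercised.  Returns the in-memory
    cases and the serialized XML documents (one per case).
    """
    if n_cases < 1:
        raise ValueError("need at least one case")
    rng = np.random.default_rng(seed)
    cases: list[Case] = []
    docs: list[str] = []
    for ci in range(n_cases):
        case_id = f"FIXCASE{ci:03d}"
        slice_id = f"slice{ci:03d}.0"
        img = np.full((slice_size, slice_size), BACKGROUND_LEVEL)
        img += rng.normal(0.0, 0.02, size=img.shape)

        # well-separated anchor points with jitter; small nodule takes the
        # direct-crop branch, the large one the 64->32 downsample branch
        q, m = slice_size // 4, slice_size // 2
        anchors = [(q + m // 4, q), (q, 3 * q), (3 * q, m)]
        spots = []
        for (kind, radius), anchor in zip((("nodule", rng.uniform(5, 9)),
                                           ("nodule", rng.uniform(18, 22)),
                                           ("nonnodule", 0.0)), anchors):
            center = (int(anchor[0] + rng.integers(-6, 7)),
                      int(anchor[1] + rng.integers(-6, 7)))
            spots.append((kind, radius, center))

        annotations: list[AnnotationRecord] = []
        nodule_xml = []
        nonnodule_xml = []
        for si, (kind, radius, center) in enumerate(spots):
            if kind == "nodule":
                img += 0.5 * _gaussian2d(slice_size, center, radius / 2, radius / 2, 0.0)
                contour = _circle_contour(center, radius)
                annotations.append(AnnotationRecord(case_id=case_id, slice_id=slice_id,
                                                    kind="nodule", contour=contour))
                edges = "".join(
                    f"<edgeMap><xCoord>{c}</xCoord><yCoord>{r}</yCoord></edgeMap>"
                    for r, c in contour)
                nodule_xml.append(
                    f"<unblindedReadNodule><noduleID>N{ci:03d}-{si}</noduleID>"
                    f"<roi><imageSOP_UID>{slice_id}</imageSOP_UID>{edges}</roi>"
                    f"</unblindedReadNodule>")
            else:
                img += 0.4 * _gaussian2d(slice_size, center, 9.0, 1.3,
                                         rng.uniform(0, np.pi))
                annotations.append(AnnotationRecord(case_id=case_id, slice_id=slice_id,
                                                    kind="nonnodule",
                                                    contour=[center]))
                nonnodule_xml.append(
                    f"<nonNodule><nonNoduleID>NN{ci:03d}-{si}</nonNoduleID>"
                    f"<imageSOP_UID>{slice_id}</imageSOP_UID>"
                    f"<locus><xCoord>{center[1]}</xCoord><yCoord>{center[0]}</yCoord>"
                    f"</locus></nonNodule>")

        doc = ("<LidcReadMessage><ResponseHeader>"
               f"<SeriesInstanceUid>{case_id}</SeriesInstanceUid></ResponseHeader>"
               "<readingSession>" + "".join(nodule_xml) + "".join(nonnodule_xml)
               + "</readingSession></LidcReadMessage>")
        cases.append(Case(case_id=case_id, slices={slice_id: np.clip(img, 0.0, 1.0)},
                          annotations=annotations))
        docs.append(doc)
    return cases, docs
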