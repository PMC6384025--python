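"""Punctum detection, size-band filtering and pixel-overlap colocalization.

This is the core quantification engine shared by the microisland-doublet,
culture-field and RNAscope analyses.  The operational definition of a
synaptic punctum is a connected component of the thresholded channel whose
calibrated area falls inside a size band (default 0.5-7.5 µm², the standard
particle-analysis reading of a "0.5-7.5 µm" band of continuous pixels); a
synapse is a presynaptic punctum overlapping a postsynaptic punctum by at
least ``min_overlap_px`` pixels.

Notes on conventions (all configurable):

* binarization is strict: a pixel is foreground iff intensity > threshold;
* components are 8-connected by default (4-connected available);
* the size band is a closed interval on both ends;
* the size band may alternatively be interpreted as an equivalent-diameter
  band in µm (``band_mode="diameter"``);
* colocalization requires >= ``min_overlap_px`` shared pixels (default 1;
  set 2 for a strict "> 1 pixel" reading).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image import CalibratedImage

__all__ = [
    "ThresholdResult",
    "Punctum",
    "PunctaSet",
    "ColocalizationResult",
    "LinearDensity",
    "threshold_and_binarize",
    "detect_puncta",
    "colocalize",
    "restrict_to_mask",
    "linear_density",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Binary mask plus the threshold that produced it (for provenance)."""

    mask: np.ndarray
    threshold: float
    method: str
    constant_input: bool = False


def threshold_and_binarize(
    img: CalibratedImage,
    method: str = "otsu",
    value: float | None = None,
) -> ThresholdResult:
    """Threshold a channel and convert it to a binary image.

    Parameters
    ----------
    img
        Calibrated intensity raster.
    method
        ``"otsu"`` (default) or ``"fixed"``; ``"fixed"`` requires ``value``.
    value
        Fixed threshold when ``method="fixed"``.

    Returns
    -------
    ThresholdResult
        Mask is True strictly above the threshold.  A constant image under
        Otsu yields an empty mask and a warning rather than an exception.
    """
    px = img.pixels
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a value")
        thr = float(value)
    elif method == "otsu":
        if np.ptp(px) == 0:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning empty mask",
                stacklevel=2,
            )
            return ThresholdResult(
                np.zeros(px.shape, dtype=bool), float(px.flat[0]), "otsu", True
            )
        thr = float(threshold_otsu(px))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdResult(px > thr, thr, method)


@dataclass(frozen=True)
class Punctum:
    """One labeled connected component of a binarized channel."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel indices
    pixel_size_um: float
    channel_name: str = ""

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the disk with the same calibrated area."""
        return 2.0 * math.sqrt(self.area_um2 / math.pi)

    @property
    def centroid_um(self) -> tuple[float, float]:
        r, c = self.coords.mean(axis=0)
        return (float(r) * self.pixel_size_um, float(c) * self.pixel_size_um)

    @property
    def pixel_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(map(tuple, self.coords.tolist()))


@dataclass
class PunctaSet:
    """Detected puncta of one channel plus the parameters that produced them."""

    puncta: list[Punctum]
    shape: tuple[int, int]
    pixel_size_um: float
    channel_name: str = ""
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    def __getitem__(self, i: int) -> Punctum:
        return self.puncta[i]

    @property
    def labels(self) -> list[int]:
        return [p.label for p in self.puncta]

    def mask(self) -> np.ndarray:
        """Binary union of all puncta pixels."""
        m = np.zeros(self.shape, dtype=bool)
        for p in self.puncta:
            m[p.coords[:, 0], p.coords[:, 1]] = True
        return m

    def label_image(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        for p in self.puncta:
            out[p.coords[:, 0], p.coords[:, 1]] = p.label
        return out

    def subset(self, labels) -> "PunctaSet":
        keep = set(labels)
        return PunctaSet(
            [p for p in self.puncta if p.label in keep],
            self.shape,
            self.pixel_size_um,
            self.channel_name,
            dict(self.params),
        )


def _validate_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (bool or {0,1})")
        arr = arr.astype(bool)
    return arr


def detect_puncta(
    mask: np.ndarray,
    pixel_size_um: float,
    band_um2: tuple[float, float] = (0.5, 7.5),
    connectivity: int = 8,
    channel_name: str = "",
    band_mode: str = "area",
) -> PunctaSet:
    """Label connected components and keep those inside the size band.

    Parameters
    ----------
    mask
        Binary image (bool or 0/1).
    pixel_size_um
        Calibration, µm per pixel.
    band_um2
        Closed size band.  In ``band_mode="area"`` (default) the bounds are
        areas in µm²; in ``band_mode="diameter"`` they are equivalent-disk
        diameters in µm.
    connectivity
        8 (default) or 4.
    """
    arr = _validate_binary(mask)
    lo, hi = band_um2
    if lo > hi:
        raise ValueError("band min must be <= band max")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if band_mode not in ("area", "diameter"):
        raise ValueError("band_mode must be 'area' or 'diameter'")

    lab = cc_label(arr, connectivity=1 if connectivity == 4 else 2)
    coords_all = np.argwhere(lab > 0)
    labels_all = lab[coords_all[:, 0], coords_all[:, 1]]
    order = np.argsort(labels_all, kind="stable")
    coords_all, labels_all = coords_all[order], labels_all[order]
    bounds = np.searchsorted(labels_all, np.arange(1, lab.max() + 2))
    puncta: list[Punctum] = []
    n_discarded = 0
    next_label = 1
    for lbl in range(1, lab.max() + 1):
        coords = coords_all[bounds[lbl - 1] : bounds[lbl]]
        p = Punctum(next_label, coords, pixel_size_um, channel_name)
        size = p.area_um2 if band_mode == "area" else p.equivalent_diameter_um
        if lo <= size <= hi:
            puncta.append(p)
            next_label += 1
        else:
            n_discarded += 1
    return PunctaSet(
        puncta,
        arr.shape,
        pixel_size_um,
        channel_name,
        params={
            "band": (lo, hi),
            "band_mode": band_mode,
            "connectivity": connectivity,
            "n_discarded": n_discarded,
        },
    )


@dataclass(frozen=True)
class ColocalizationResult:
    """Which query puncta overlap the reference set, and with whom.

    ``partners`` maps a colocalized query label to
    ``(reference partner label, overlap in pixels)`` where the partner is the
    reference punctum of maximal pixel intersection (ties broken by lowest
    reference label); overlap is with the union of all reference puncta.
    """

    query: PunctaSet
    partners: dict[int, tuple[int, int]]
    min_overlap_px: int

    @property
    def count(self) -> int:
        return len(self.partners)

    @property
    def colocalized(self) -> PunctaSet:
        return self.query.subset(self.partners.keys())


def colocalize(
    query: PunctaSet,
    reference: PunctaSet,
    min_overlap_px: int = 1,
) -> ColocalizationResult:
    """Flag query puncta overlapping the reference set by >= min_overlap_px.

    A query punctum is colocalized iff its pixel intersection with the union
    of reference puncta contains at least ``min_overlap_px`` pixels.
    """
    if query.shape != reference.shape:
        raise ValueError(
            f"raster shape mismatch: query {query.shape} vs reference {reference.shape}"
        )
    if min_overlap_px < 1:
        raise ValueError("min_overlap_px must be >= 1")
    ref_label = reference.label_image()
    partners: dict[int, tuple[int, int]] = {}
    for p in query:
        hit = ref_label[p.coords[:, 0], p.coords[:, 1]]
        hit = hit[hit > 0]
        if hit.size >= min_overlap_px:
            labels, counts = np.unique(hit, return_counts=True)
            best = labels[np.lexsort((labels, -counts))][0]
            partners[p.label] = (int(best), int(hit.size))
    return ColocalizationResult(query, partners, min_overlap_px)


def restrict_to_mask(
    puncta: PunctaSet,
    mask: np.ndarray,
    min_overlap_px: int = 1,
) -> PunctaSet:
    """Keep puncta overlapping a cell/dendrite mask by >= min_overlap_px pixels."""
    arr = _validate_binary(mask)
    if arr.shape != puncta.shape:
        raise ValueError("mask shape must match puncta raster shape")
    keep = [
        p.label
        for p in puncta
        if int(arr[p.coords[:, 0], p.coords[:, 1]].sum()) >= min_overlap_px
    ]
    return puncta.subset(keep)


@dataclass(frozen=True)
class LinearDensity:
    """Synapse count per 100 µm of dendrite, with the analysis-minimum flag."""

    count: float
    length_um: float
    density_per_100um: float
    excluded: bool  # dendrite shorter than the analysis minimum
    min_length_um: float = 50.0


def linear_density(
    count: float,
    dendrite_length_um: float,
    min_length_um: float = 50.0,
) -> LinearDensity:
    """Synapses per 100 µm of dendrite.

    Records shorter than ``min_length_um`` (default 50 µm, the per-cell
    analysis minimum) are computed but flagged ``excluded``.
    """
    if dendrite_length_um <= 0:
        raise ValueError("dendrite length must be positive")
    return LinearDensity(
        count=float(count),
        length_um=float(dendrite_length_um),
        density_per_100um=100.0 * count / dendrite_length_um,
        excluded=dendrite_length_um < min_length_um,
        min_length_um=min_length_um,
    )
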