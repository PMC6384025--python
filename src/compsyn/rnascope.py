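"""RNAscope quantification: per-nucleus dot counting and class scoring.

Probe channels are blurred, background-subtracted and binarized at one
shared threshold (the same value for every probe of a section, by design —
per-probe auto-thresholds would break comparability of dot counts between
probes).  Dots are connected components of 4–100 pixels.  Nuclei are
segmented from DAPI and become ROIs; an ROI is positive for CTIP2 and/or
SATB2 if it contains at least 10 dots of that probe, giving three classes
(CTIP2-only, double-positive, SATB2-only), and ephrin-B3 dots are counted
per ROI and compared across classes by one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .image import CalibratedImage
from .puncta import PunctaSet, _validate_binary, detect_puncta
from .stats import TestResult, one_way_anova

__all__ = [
    "NucleusROI",
    "preprocess_probe_channel",
    "detect_dots",
    "segment_nuclei",
    "score_cells",
]


@dataclass
class NucleusROI:
    """One segmented nucleus with its per-probe dot counts and class."""

    roi_id: int
    coords: np.ndarray  # (n, 2) pixel indices
    centroid_px: tuple[float, float]
    dot_counts: dict[str, int] = field(default_factory=dict)
    ctip2_positive: bool = False
    satb2_positive: bool = False
    roi_class: str = "unclassified"

    @property
    def area_px(self) -> int:
        return int(self.coords.shape[0])


def preprocess_probe_channel(
    img: CalibratedImage,
    shared_threshold: float,
    blur_sigma: float = 1.0,
    background_radius: float = 25.0,
) -> np.ndarray:
    """Blur, background-subtract and binarize one probe channel.

    ``shared_threshold`` must be the one value used for every probe channel
    of the section; it is deliberately a required argument with no
    auto-selection, so callers cannot accidentally threshold probes
    differently.  Background is estimated by the rolling-ball algorithm
    (radius in pixels) and subtracted before thresholding; the mask is
    intensity > threshold.
    """
    if shared_threshold is None:
        raise ValueError("shared_threshold must be set explicitly")
    px = img.pixels.astype(float)
    if blur_sigma > 0:
        px = gaussian(px, sigma=blur_sigma, preserve_range=True)
    if background_radius > 0:
        px = px - rolling_ball(px, radius=background_radius)
    return px > float(shared_threshold)


def detect_dots(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    band_px: tuple[int, int] = (4, 100),
    connectivity: int = 8,
    channel_name: str = "",
) -> PunctaSet:
    """Connected components of 4–100 pixels (closed band, in pixels).

    The size band is in raw pixels, not µm² — dot size is set by the assay's
    amplification chemistry, not by physical scale.
    """
    arr = _validate_binary(mask)
    lo, hi = band_px
    # reuse the core detector with the band expressed as area in um^2
    band_um2 = (lo * pixel_size_um**2, hi * pixel_size_um**2)
    ps = detect_puncta(arr, pixel_size_um, band_um2, connectivity, channel_name)
    ps.params["band_px"] = (lo, hi)
    return ps


def segment_nuclei(
    dapi: CalibratedImage,
    min_area_um2: float = 30.0,
    max_area_um2: float = 500.0,
    split_touching: bool = True,
    min_peak_distance_px: int = 10,
) -> list[NucleusROI]:
    """Segment nuclei from the DAPI channel into disjoint ROIs.

    Recipe: Otsu threshold, hole filling, optional watershed split of
    touching nuclei (distance-transform peaks as markers), then an area
    filter keeping [min_area_um2, max_area_um2].
    """
    px = dapi.pixels
    if np.ptp(px) == 0:
        return []
    mask = px > threshold_otsu(px)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return []
    if split_touching:
        dist = ndi.distance_transform_edt(mask)
        peaks = peak_local_max(
            dist, min_distance=min_peak_distance_px, labels=mask,
            exclude_border=False,
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        markers, _ = ndi.label(markers > 0)
        lab = watershed(-dist, markers, mask=mask) if len(peaks) else cc_label(mask)
    else:
        lab = cc_label(mask, connectivity=2)

    min_px = min_area_um2 / dapi.pixel_size_um**2
    max_px = max_area_um2 / dapi.pixel_size_um**2
    rois: list[NucleusROI] = []
    next_id = 1
    for lbl in range(1, lab.max() + 1):
        coords = np.argwhere(lab == lbl)
        if coords.shape[0] < min_px or coords.shape[0] > max_px:
            continue
        centroid = tuple(coords.mean(axis=0).tolist())
        rois.append(NucleusROI(next_id, coords, centroid))
        next_id += 1
    return rois


def score_cells(
    rois: list[NucleusROI],
    dots_per_probe: dict[str, PunctaSet],
    positivity_min: int = 10,
    efnb3_probe: str = "probe_efnb3",
    ctip2_probe: str = "probe_ctip2",
    satb2_probe: str = "probe_satb2",
) -> tuple[list[NucleusROI], pd.DataFrame, TestResult | None]:
    """Score ROIs for CTIP2/SATB2 positivity and count ephrin-B3 dots.

    A dot belongs to an ROI when its centroid pixel lies inside the ROI
    (each dot counts in at most one ROI).  An ROI is positive for a marker
    probe when it holds >= ``positivity_min`` of its dots; classes are
    CTIP2+, CTIP2+/SATB2+, SATB2+ or unclassified.  Returns the scored
    ROIs, a per-class summary of ephrin-B3 counts, and the one-way ANOVA
    (+ Tukey) across classes when at least two classes have >= 2 ROIs.
    """
    if not rois:
        return [], pd.DataFrame(
            columns=["roi_class", "n", "efnb3_mean", "efnb3_sem"]
        ), None
    shape_ref = next(iter(dots_per_probe.values())).shape if dots_per_probe else None
    roi_label = np.zeros(shape_ref or (1, 1), dtype=np.int32)
    for roi in rois:
        roi_label[roi.coords[:, 0], roi.coords[:, 1]] = roi.roi_id
    by_id = {roi.roi_id: roi for roi in rois}
    for roi in rois:
        roi.dot_counts = {probe: 0 for probe in dots_per_probe}
    for probe, dots in dots_per_probe.items():
        for d in dots:
            r, c = d.centroid_um
            rr = int(round(r / d.pixel_size_um))
            cc = int(round(c / d.pixel_size_um))
            rr = min(max(rr, 0), roi_label.shape[0] - 1)
            cc = min(max(cc, 0), roi_label.shape[1] - 1)
            owner = int(roi_label[rr, cc])
            if owner:
                by_id[owner].dot_counts[probe] += 1

    for roi in rois:
        roi.ctip2_positive = roi.dot_counts.get(ctip2_probe, 0) >= positivity_min
        roi.satb2_positive = roi.dot_counts.get(satb2_probe, 0) >= positivity_min
        if roi.ctip2_positive and roi.satb2_positive:
            roi.roi_class = "CTIP2+/SATB2+"
        elif roi.ctip2_positive:
            roi.roi_class = "CTIP2+"
        elif roi.satb2_positive:
            roi.roi_class = "SATB2+"
        else:
            roi.roi_class = "unclassified"

    rows = []
    groups = []
    for cls in ("CTIP2+", "CTIP2+/SATB2+", "SATB2+"):
        counts = [
            roi.dot_counts.get(efnb3_probe, 0)
            for roi in rois
            if roi.roi_class == cls
        ]
        if counts:
            arr = np.asarray(counts, dtype=float)
            rows.append(
                {
                    "roi_class": cls,
                    "n": len(counts),
                    "efnb3_mean": float(arr.mean()),
                    "efnb3_sem": float(arr.std(ddof=1) / np.sqrt(len(counts)))
                    if len(counts) > 1
                    else float("nan"),
                }
            )
            if len(counts) >= 2:
                groups.append(arr)
    table = pd.DataFrame(rows)
    anova = None
    if len(groups) >= 2:
        try:
            anova = one_way_anova(groups)
        except ValueError:
            # degenerate cohorts (e.g. zero within-class variance) carry no test
            anova = None
    return rois, table, anova
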