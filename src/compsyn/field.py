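"""Culture-field analysis: assigning vGlut1 puncta to red and green cells.

Each 150 × 150 µm field contains tdTomato+ (red) and EGFP+ (green) neurons.
After axon removal (small-particle deletion) each detected vGlut1 punctum is
assigned to the cell channel containing the largest pixel overlap with it;
equal non-zero overlaps are "unknown", no overlap is "none".  Per-field
synapse density is puncta per 1000 µm² of the corresponding channel's
cell-mask area, and the channel with the larger density is the field winner.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .image import CalibratedImage
from .puncta import PunctaSet, _validate_binary, detect_puncta, threshold_and_binarize
from .stats import TestResult, fisher_exact_two_sided, two_sample_t
from skimage.measure import label as cc_label

__all__ = [
    "FieldRecord",
    "remove_axons",
    "assign_puncta",
    "field_density",
    "analyze_field",
    "field_winner_contrast",
    "cell_count_balance",
]


@dataclass(frozen=True)
class FieldRecord:
    """Per-field assigned counts, densities and winner call."""

    field_id: str
    condition: str  # e.g. "control", "heterogenotypic", optionally "+ttx"
    area_red_um2: float
    area_green_um2: float
    count_red: int
    count_green: int
    count_unknown: int
    density_red: float  # puncta per 1000 um^2 of red cell-mask area
    density_green: float
    winner: str  # "red" | "green" | "tie"
    excluded: bool = False
    exclusion_reason: str = ""
    n_somata: int = 0


def remove_axons(
    mask: np.ndarray,
    min_component_area_um2: float,
    pixel_size_um: float,
    connectivity: int = 8,
) -> tuple[np.ndarray, float]:
    """Delete connected components smaller than the area threshold.

    Mirrors particle-analysis axon removal on cell-fill channels.  Returns
    the cleaned mask and the fraction of foreground area removed.
    """
    arr = _validate_binary(mask)
    if min_component_area_um2 <= 0:
        return arr.copy(), 0.0
    lab = cc_label(arr, connectivity=1 if connectivity == 4 else 2)
    if lab.max() == 0:
        return arr.copy(), 0.0
    areas_px = np.bincount(lab.ravel())[1:]
    min_px = min_component_area_um2 / pixel_size_um**2
    keep = np.flatnonzero(areas_px >= min_px) + 1
    cleaned = np.isin(lab, keep)
    total = arr.sum()
    removed_fraction = float((total - cleaned.sum()) / total) if total else 0.0
    return cleaned, removed_fraction


def assign_puncta(
    vglut1: PunctaSet,
    red_mask: np.ndarray,
    green_mask: np.ndarray,
) -> list[str]:
    """Assign each punctum to the channel with the larger pixel overlap.

    Returns one of ``"red"``, ``"green"``, ``"unknown"`` (equal non-zero
    overlaps) or ``"none"`` (no overlap with either channel) per punctum,
    in punctum order.
    """
    red = _validate_binary(red_mask)
    green = _validate_binary(green_mask)
    if red.shape != vglut1.shape or green.shape != vglut1.shape:
        raise ValueError("mask shapes must match the puncta raster shape")
    out: list[str] = []
    for p in vglut1:
        o_red = int(red[p.coords[:, 0], p.coords[:, 1]].sum())
        o_green = int(green[p.coords[:, 0], p.coords[:, 1]].sum())
        if o_red == 0 and o_green == 0:
            out.append("none")
        elif o_red > o_green:
            out.append("red")
        elif o_green > o_red:
            out.append("green")
        else:
            out.append("unknown")
    return out


def field_density(
    field_id: str,
    condition: str,
    assignments: list[str],
    red_mask: np.ndarray,
    green_mask: np.ndarray,
    pixel_size_um: float,
    max_somata: int = 8,
    max_coverage: float = 0.60,
) -> FieldRecord:
    """Build a :class:`FieldRecord` from assignments and cleaned cell masks.

    Density is 1000 · count / cell-mask area (µm²) per channel.  Fields are
    flagged excluded when a present channel has zero mask area, when the
    soma count exceeds ``max_somata``, or when cell-mask coverage exceeds
    ``max_coverage`` (the automated surrogate for the manual high-density
    exclusion); exclusion never alters the computed values.
    """
    red = _validate_binary(red_mask)
    green = _validate_binary(green_mask)
    area_red = float(red.sum()) * pixel_size_um**2
    area_green = float(green.sum()) * pixel_size_um**2
    n_red = assignments.count("red")
    n_green = assignments.count("green")
    n_unknown = assignments.count("unknown")
    density_red = 1000.0 * n_red / area_red if area_red > 0 else float("nan")
    density_green = 1000.0 * n_green / area_green if area_green > 0 else float("nan")
    if np.isnan(density_red) or np.isnan(density_green):
        winner = "tie"
    elif density_red > density_green:
        winner = "red"
    elif density_green > density_red:
        winner = "green"
    else:
        winner = "tie"

    n_somata = int(cc_label(red, connectivity=2).max() + cc_label(green, connectivity=2).max())
    coverage = float((red | green).mean())
    excluded, reason = False, ""
    if area_red == 0 or area_green == 0:
        excluded, reason = True, "missing channel (zero cell-mask area)"
    elif n_somata > max_somata:
        excluded, reason = True, f"{n_somata} somata > {max_somata}"
    elif coverage > max_coverage:
        excluded, reason = True, f"coverage {coverage:.2f} > {max_coverage}"
    return FieldRecord(
        field_id, condition, area_red, area_green, n_red, n_green, n_unknown,
        density_red, density_green, winner, excluded, reason, n_somata,
    )


def analyze_field(
    images: dict[str, CalibratedImage],
    field_id: str = "",
    condition: str = "",
    threshold_method: str = "otsu",
    axon_min_area_um2: float = 50.0,
    band_um2: tuple[float, float] = (0.5, 7.5),
    min_overlap_px: int = 1,
    max_somata: int = 8,
    max_coverage: float = 0.60,
) -> FieldRecord:
    """Full field pipeline: threshold, axon removal, detection, assignment.

    ``images`` must contain ``tdtomato``, ``egfp`` and ``vglut1`` channels of
    identical shape and calibration.
    """
    for name in ("tdtomato", "egfp", "vglut1"):
        if name not in images:
            raise KeyError(f"missing required channel {name!r}")
    px = images["vglut1"].pixel_size_um
    red_raw = threshold_and_binarize(images["tdtomato"], threshold_method).mask
    green_raw = threshold_and_binarize(images["egfp"], threshold_method).mask
    red, _ = remove_axons(red_raw, axon_min_area_um2, px)
    green, _ = remove_axons(green_raw, axon_min_area_um2, px)
    vmask = threshold_and_binarize(images["vglut1"], threshold_method).mask
    vglut = detect_puncta(vmask, px, band_um2, channel_name="vglut1")
    assignments = assign_puncta(vglut, red, green)
    return field_density(
        field_id, condition, assignments, red, green, px, max_somata, max_coverage
    )


def field_winner_contrast(
    heterogenotypic: list[FieldRecord],
    control: list[FieldRecord],
) -> TestResult:
    """Fisher's exact contrast of red-winner field proportions."""
    def row(records):
        kept = [r for r in records if not r.excluded and r.winner != "tie"]
        wins = sum(1 for r in kept if r.winner == "red")
        return [wins, len(kept) - wins]

    return fisher_exact_two_sided(np.asarray([row(heterogenotypic), row(control)]))


def cell_count_balance(red_counts, green_counts) -> TestResult:
    """Two-tailed Student's t-test on per-field red vs green soma counts."""
    return two_sample_t(red_counts, green_counts)
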