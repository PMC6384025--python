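"""Microisland doublet analysis: who wins the competition for synapses.

In a two-neuron microisland one cell is transfected (its postsynaptic sites
carry PSD-95-GFP) and the other is not.  Synapse density on the transfected
neuron is the density of colocalized PSD-95-GFP/vGlut1 puncta; density on the
untransfected neuron is obtained by subtraction: colocalized PSD-95/vGlut1
pairs minus colocalized PSD-95-GFP/vGlut1 pairs, per 100 µm of dendrite.
Each doublet then yields a fraction-of-total per cell and a winner call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image import CalibratedImage
from .puncta import (
    LinearDensity,
    PunctaSet,
    colocalize,
    detect_puncta,
    linear_density,
    threshold_and_binarize,
)
from .stats import TestResult, fisher_exact_two_sided, mean_sem

__all__ = [
    "DoubletRecord",
    "transfected_synapse_density",
    "untransfected_synapse_density",
    "make_record",
    "analyze_doublet_scene",
    "doublet_summary",
    "winner_contrast",
]


@dataclass(frozen=True)
class DoubletRecord:
    """Synapse densities and winner call for one microisland pair."""

    island_id: str
    condition: str  # "control" or "competitive"
    density_transfected: float  # synapses / 100 um
    density_untransfected: float
    fraction_transfected: float
    fraction_untransfected: float
    winner: str  # "transfected" | "untransfected" | "tie"
    difference: float  # untransfected - transfected
    flagged: bool = False  # negative subtraction count or short dendrite

    @property
    def total_density(self) -> float:
        return self.density_transfected + self.density_untransfected


def transfected_synapse_density(
    psd95gfp: PunctaSet,
    vglut1: PunctaSet,
    dendrite_length_um: float,
    min_overlap_px: int = 1,
    min_length_um: float = 50.0,
) -> LinearDensity:
    """Density of colocalized PSD-95-GFP/vGlut1 puncta per 100 µm."""
    n = colocalize(psd95gfp, vglut1, min_overlap_px).count
    return linear_density(n, dendrite_length_um, min_length_um)


def untransfected_synapse_density(
    psd95: PunctaSet,
    psd95gfp: PunctaSet,
    vglut1: PunctaSet,
    dendrite_length_um: float,
    min_overlap_px: int = 1,
    min_length_um: float = 50.0,
    clamp_negative: bool = False,
) -> LinearDensity:
    """Untransfected-cell density by the subtraction rule.

    count = |PSD-95 ∩ vGlut1| − |PSD-95-GFP ∩ vGlut1|.  A negative count
    (total colocalization below the GFP-tagged colocalization, possible with
    noisy detections) is reported as-is and flagged via a negative
    ``count``; set ``clamp_negative`` to clip it at zero instead.
    """
    n_all = colocalize(psd95, vglut1, min_overlap_px).count
    n_gfp = colocalize(psd95gfp, vglut1, min_overlap_px).count
    n = n_all - n_gfp
    if clamp_negative:
        n = max(n, 0)
    return linear_density(n, dendrite_length_um, min_length_um)


def make_record(
    island_id: str,
    condition: str,
    transfected: LinearDensity,
    untransfected: LinearDensity,
) -> DoubletRecord:
    """Assemble a doublet record: fractions, winner call, within-pair difference.

    Exact density ties are classified ``"tie"`` (excluded from winner
    proportions downstream).  Records with a negative subtraction count or a
    dendrite below the length minimum are flagged.
    """
    d_t = transfected.density_per_100um
    d_u = untransfected.density_per_100um
    total = d_t + d_u
    if total > 0:
        f_t, f_u = d_t / total, d_u / total
    else:
        f_t = f_u = float("nan")
    if d_t > d_u:
        winner = "transfected"
    elif d_u > d_t:
        winner = "untransfected"
    else:
        winner = "tie"
    flagged = (
        transfected.excluded
        or untransfected.excluded
        or untransfected.count < 0
        or transfected.count < 0
    )
    return DoubletRecord(
        island_id, condition, d_t, d_u, f_t, f_u, winner, d_u - d_t, flagged
    )


def analyze_doublet_scene(
    images: dict[str, CalibratedImage],
    length_transfected_um: float,
    length_untransfected_um: float,
    island_id: str = "",
    condition: str = "control",
    threshold_method: str = "otsu",
    band_um2: tuple[float, float] = (0.5, 7.5),
    min_overlap_px: int = 1,
    min_length_um: float = 50.0,
) -> DoubletRecord:
    """Full doublet pipeline on one scene's channels.

    ``images`` must contain ``psd95``, ``psd95gfp`` and ``vglut1`` channels.
    Channels are thresholded, puncta detected inside the size band, and the
    two per-cell densities computed by the GFP-subtraction rule.
    """
    for name in ("psd95", "psd95gfp", "vglut1"):
        if name not in images:
            raise KeyError(f"missing required channel {name!r}")
    sets = {}
    for name in ("psd95", "psd95gfp", "vglut1"):
        img = images[name]
        mask = threshold_and_binarize(img, threshold_method).mask
        sets[name] = detect_puncta(mask, img.pixel_size_um, band_um2, channel_name=name)
    d_t = transfected_synapse_density(
        sets["psd95gfp"], sets["vglut1"], length_transfected_um,
        min_overlap_px, min_length_um,
    )
    d_u = untransfected_synapse_density(
        sets["psd95"], sets["psd95gfp"], sets["vglut1"], length_untransfected_um,
        min_overlap_px, min_length_um,
    )
    return make_record(island_id, condition, d_t, d_u)


def doublet_summary(
    records: list[DoubletRecord],
    include_flagged: bool = False,
) -> pd.DataFrame:
    """Condition-level summary table.

    One row per condition with mean ± SEM of the per-cell fraction of total
    density, mean ± SEM of total density, winner proportions (ties excluded
    from the proportions, counted separately), and n.  Scatter coordinates
    (density_transfected, density_untransfected) per island are available
    from the records themselves.
    """
    kept = [r for r in records if include_flagged or not r.flagged]
    rows = []
    for cond in sorted({r.condition for r in kept}):
        sub = [r for r in kept if r.condition == cond]
        ft = mean_sem([r.fraction_transfected for r in sub if np.isfinite(r.fraction_transfected)])
        fu = mean_sem([r.fraction_untransfected for r in sub if np.isfinite(r.fraction_untransfected)])
        tot = mean_sem([r.total_density for r in sub])
        diff = mean_sem([r.difference for r in sub])
        decided = [r for r in sub if r.winner != "tie"]
        n_u = sum(1 for r in decided if r.winner == "untransfected")
        rows.append(
            {
                "condition": cond,
                "n_islands": len(sub),
                "fraction_transfected_mean": ft.mean,
                "fraction_transfected_sem": ft.sem,
                "fraction_untransfected_mean": fu.mean,
                "fraction_untransfected_sem": fu.sem,
                "total_density_mean": tot.mean,
                "total_density_sem": tot.sem,
                "difference_mean": diff.mean,
                "difference_sem": diff.sem,
                "n_ties": len(sub) - len(decided),
                "untransfected_winner_prop": n_u / len(decided) if decided else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def winner_contrast(
    competitive: list[DoubletRecord],
    control: list[DoubletRecord],
    competitive_class: str = "untransfected",
    control_class: str = "transfected",
) -> TestResult:
    """Fisher's exact contrast of winner proportions between conditions.

    Builds the 2×2 table [[competitive wins of ``competitive_class``,
    other decided competitive doublets], [control wins of ``control_class``,
    other decided control doublets]]; ties are excluded.  The default
    classes reproduce the published contrast of untransfected winners in
    competitive doublets against transfected winners in control doublets.
    """
    def row(records, cls):
        decided = [r for r in records if r.winner != "tie"]
        wins = sum(1 for r in decided if r.winner == cls)
        return [wins, len(decided) - wins]

    table = [row(competitive, competitive_class), row(control, control_class)]
    return fisher_exact_two_sided(np.asarray(table))
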