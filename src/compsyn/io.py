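"""Scene IO, run configuration and report writing.

Scenes travel as multi-page TIFF (one page per channel, channel name and
µm-per-pixel in each page's JSON description, calibration also in the TIFF
resolution tags), ground truth as JSON, tables as CSV.  Channel names are
fixed: ``vglut1, psd95, psd95gfp, tdtomato, egfp, dapi, probe_ctip2,
probe_satb2, probe_efnb3``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import CalibratedImage

__all__ = ["RunConfig", "read_scene", "write_scene", "write_reports"]

CHANNEL_NAMES = (
    "vglut1", "psd95", "psd95gfp", "tdtomato", "egfp", "dapi",
    "probe_ctip2", "probe_satb2", "probe_efnb3",
)


@dataclass
class RunConfig:
    """All tunable analysis parameters, with the published defaults.

    Defaults that are fixed by the assay definitions: puncta size band
    0.5–7.5 µm², RNAscope dot band 4–100 px, positivity minimum 10 dots,
    thick/thin boundary 1.6 µm, dendrite analysis minima 50 µm (density) and
    40 µm (spines), 150 × 150 µm fields.
    """

    threshold_method: str = "otsu"
    fixed_thresholds: dict = field(default_factory=dict)  # channel -> value
    connectivity: int = 8
    band_um2: tuple[float, float] = (0.5, 7.5)
    band_mode: str = "area"
    min_overlap_px: int = 1
    min_dendrite_um: float = 50.0
    # field analysis
    axon_min_area_um2: float = 50.0
    max_somata: int = 8
    max_coverage: float = 0.60
    # morphometry
    opening_radius_um: float = 0.4
    min_spine_segment_um: float = 40.0
    # rnascope
    rnascope_blur_sigma: float = 1.0
    rnascope_background_radius: float = 25.0
    rnascope_shared_threshold: float | None = None
    rnascope_band_px: tuple[int, int] = (4, 100)
    positivity_min: int = 10
    nucleus_area_um2: tuple[float, float] = (30.0, 500.0)
    # misc
    pixel_size_um: float | None = None  # overrides TIFF calibration when set
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band_um2", "rnascope_band_px", "nucleus_area_um2"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("band_um2", "rnascope_band_px", "nucleus_area_um2"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full parameter set, for provenance."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_scene(
    channels: dict[str, CalibratedImage],
    path,
    ground_truth=None,
) -> None:
    """Write one scene as a multi-page TIFF (+ optional ground-truth JSON).

    Each page stores the channel name and pixel size in its JSON
    description; XResolution/YResolution tags carry pixels-per-centimetre.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name, img in channels.items():
            px_per_cm = 1e4 / img.pixel_size_um
            tif.write(
                img.pixels.astype(np.float32),
                description=json.dumps(
                    {"channel": name, "pixel_size_um": img.pixel_size_um}
                ),
                resolution=(px_per_cm, px_per_cm),
                resolutionunit="CENTIMETER",
            )
    if ground_truth is not None:
        gt_path = path.with_suffix(".truth.json")
        with open(gt_path, "w") as fh:
            json.dump(ground_truth.to_dict(), fh, indent=1)


def read_scene(
    path,
    calibration_override: float | None = None,
    required: tuple[str, ...] = (),
) -> dict[str, CalibratedImage]:
    """Read a multi-page scene TIFF into named calibrated channels.

    Calibration comes from the page description (falling back to the
    resolution tags); ``calibration_override`` wins when given.  Raises
    ``KeyError`` naming any missing required channel; all channels must
    share one raster shape.
    """
    out: dict[str, CalibratedImage] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            desc = page.tags.get("ImageDescription")
            name, px_um = f"page{i}", None
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    name = meta.get("channel", name)
                    px_um = meta.get("pixel_size_um")
                except (json.JSONDecodeError, TypeError):
                    pass
            if px_um is None:
                xres = page.tags.get("XResolution")
                if xres is not None:
                    num, den = xres.value
                    if num:
                        px_um = 1e4 * den / num  # px/cm -> um/px
            if calibration_override is not None:
                px_um = calibration_override
            if px_um is None:
                raise ValueError(
                    f"page {i} of {path} has no calibration; "
                    "pass calibration_override"
                )
            out[name] = CalibratedImage(page.asarray(), float(px_um), name)
    shapes = {img.shape for img in out.values()}
    if len(shapes) > 1:
        raise ValueError(f"channel shape mismatch in {path}: {shapes}")
    missing = [ch for ch in required if ch not in out]
    if missing:
        raise KeyError(f"scene {path} is missing required channels {missing}")
    return out


def _result_to_dict(res) -> dict:
    d = {
        "test": res.name,
        "statistic": res.statistic,
        "df": list(res.df) if isinstance(res.df, tuple) else res.df,
        "pvalue": res.pvalue,
        "groups": [dataclasses.asdict(g) for g in res.groups],
    }
    if res.pairwise:
        d["tukey"] = [dataclasses.asdict(p) for p in res.pairwise]
    return d


def write_reports(records, results: dict, outdir, config: RunConfig | None = None) -> None:
    """Write per-record CSV tables, a JSON test summary and run provenance.

    ``records`` maps table name -> list of dataclass records, a DataFrame,
    or a ``(list, record_type)`` pair (the type supplies CSV headers when
    the list is empty); ``results`` maps result name ->
    :class:`~compsyn.stats.TestResult`.  Re-running with identical inputs
    and config produces byte-identical CSV bodies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, recs in records.items():
        rtype = None
        if isinstance(recs, tuple):
            recs, rtype = recs
        if isinstance(recs, pd.DataFrame):
            df = recs
        elif not recs and rtype is not None:
            df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(rtype)])
        else:
            df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
        df.to_csv(outdir / f"{name}.csv", index=False)
    summary = {name: _result_to_dict(res) for name, res in results.items()}
    with open(outdir / "test_results.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    if config is not None:
        prov = {"config_digest": config.digest(), "seed": config.seed}
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=1, sort_keys=True)
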