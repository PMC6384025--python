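"""Synthetic calibrated fluorescence scenes with known ground truth.

Three scene families mirror the experiments the pipeline quantifies:

* **doublet** — a one- or two-neuron microisland: a transfected neuron
  (tdTomato fill, PSD-95-GFP-tagged postsynaptic puncta) and an untransfected
  neighbour, with a fixed pool of synapses split between them;
* **field** — a 150 × 150 µm culture field of red (tdTomato) and green
  (EGFP) neurons at ~1:1, vGlut1 puncta allocated to cells, and optional
  thin axon-like fragments below the axon-removal size threshold;
* **rnascope** — a section of non-overlapping elliptical nuclei carrying
  per-probe fluorescent dots (CTIP2 / SATB2 / ephrin-B3 channels).

The competitive-allocation model distributes a fixed synapse pool S over
neurons in proportion to their ephrin-B3 expression weights: cell i receives
a multinomial share with p_i ∝ e_i**gamma (gamma = 1 by default, i.e. the
share is linear in expression).  The pool total is conserved by
construction — competition redistributes synapses, it does not create or
destroy them.

Rendering: puncta and somata are uniform-intensity disks, optionally
convolved with a Gaussian PSF; noise is Poisson shot noise on the signal
plus additive Gaussian read noise on a constant background.  With PSF and
noise switched off, rasters are pixel-exact renderings of the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_se

from .image import CalibratedImage

__all__ = [
    "CompetitionParams",
    "SceneSpec",
    "RnascopeClassParams",
    "PlantedPunctum",
    "GroundTruth",
    "PlacementError",
    "allocate_synapses",
    "generate_doublet_scene",
    "generate_field_scene",
    "generate_rnascope_scene",
]


class PlacementError(RuntimeError):
    """Requested scene contents cannot be placed without overlap."""


@dataclass(frozen=True)
class CompetitionParams:
    """Parameters of the competitive synapse-allocation model.

    ``eb3_levels`` are per-neuron non-negative expression weights (arbitrary
    units); ``pool_size`` is the total synapse count S of the scene;
    ``gamma`` is the allocation exponent (p_i ∝ e_i**gamma).
    """

    eb3_levels: tuple[float, ...]
    pool_size: int
    seed: int = 0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.eb3_levels, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("eb3_levels must be a non-empty 1-D sequence")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("eb3_levels must be finite and non-negative")
        if self.pool_size < 0:
            raise ValueError("pool_size must be >= 0")
        if self.pool_size > 0 and w.sum() == 0:
            raise ValueError("at least one eb3 level must be positive when pool_size > 0")

    @property
    def n_cells(self) -> int:
        return len(self.eb3_levels)

    def probabilities(self) -> np.ndarray:
        """Allocation probabilities p_i = e_i**gamma / Σ e_j**gamma."""
        w = np.asarray(self.eb3_levels, dtype=float) ** self.gamma
        s = w.sum()
        if s == 0:
            # only reachable with pool_size == 0; degenerate but harmless
            return np.full(w.size, 1.0 / w.size)
        return w / s


def allocate_synapses(
    params: CompetitionParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-neuron synapse counts for one scene.

    Counts are multinomial over ``params.probabilities()`` and always sum to
    ``params.pool_size``.  A fresh generator seeded from ``params.seed`` is
    used unless ``rng`` is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return rng.multinomial(params.pool_size, params.probabilities())


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and noise of one synthetic scene.

    Defaults reproduce the study conditions: 150 × 150 µm fields at
    0.2 µm/px, puncta whose calibrated area sits inside the 0.5–7.5 µm²
    detection band, and red/green cells at 1:1.
    """

    field_size_um: tuple[float, float] = (150.0, 150.0)
    pixel_size_um: float = 0.2
    n_cells: int = 2
    # dendrite geometry
    n_branches: int = 3
    branch_length_um: float = 60.0
    dendrite_width_um: float = 1.5
    soma_radius_um: float = 6.0
    # punctum model: disk radius; area = pi r^2 must sit in-band by default
    punctum_radius_um: float = 0.5
    coloc_fraction: float = 1.0
    # centre spacing leaves >= 1 px between 0.5-um-radius disks even after
    # the partner-punctum offset, so planted puncta never merge
    min_separation_um: float = 1.5
    # imaging model
    amplitude: float = 200.0
    background: float = 10.0
    read_noise_sigma: float = 0.0
    shot_noise: bool = False
    psf_sigma_um: float = 0.0
    # field-scene extras
    cell_colors: tuple[str, ...] | None = None  # default: alternate red/green
    n_axon_fragments: int = 0
    axon_length_um: float = 8.0
    axon_width_um: float = 0.4
    # rnascope extras
    nucleus_radii_um: tuple[float, float] = (3.3, 4.5)  # area stays above the 30 um^2 ROI filter
    dot_radius_px: float = 1.3
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        for dim in self.field_size_um:
            n = dim / self.pixel_size_um
            if abs(n - round(n)) > 1e-6:
                raise ValueError(
                    "field_size_um must be an integer multiple of pixel_size_um"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.field_size_um[0] / self.pixel_size_um)),
            int(round(self.field_size_um[1] / self.pixel_size_um)),
        )

    def px(self, um: float) -> float:
        return um / self.pixel_size_um


@dataclass(frozen=True)
class RnascopeClassParams:
    """Dot-count model for one transcriptomic class of nuclei.

    ``distribution="poisson"`` draws per-nucleus counts Poisson(mean);
    ``"fixed"`` plants exactly round(mean) dots in every nucleus.
    """

    name: str
    n_nuclei: int
    ctip2_mean: float
    satb2_mean: float
    efnb3_mean: float
    distribution: str = "poisson"


@dataclass(frozen=True)
class PlantedPunctum:
    """One ground-truth punctum: channel, pixels, owner, optional partner."""

    channel: str
    center_px: tuple[int, int]
    coords: np.ndarray  # (n, 2) pixel indices
    cell: int | None = None
    partner: int | None = None  # index into GroundTruth.puncta


@dataclass
class GroundTruth:
    """Planted contents of one scene, the oracle for every downstream stage."""

    cell_masks: dict[int, np.ndarray] = field(default_factory=dict)
    cell_channels: dict[int, str] = field(default_factory=dict)
    puncta: list[PlantedPunctum] = field(default_factory=list)
    per_cell_counts: dict[int, int] = field(default_factory=dict)
    dendrite_length_um: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def count(self, channel: str, cell: int | None = None) -> int:
        return sum(
            1
            for p in self.puncta
            if p.channel == channel and (cell is None or p.cell == cell)
        )

    def colocalized_pairs(self) -> list[tuple[int, int]]:
        """Indices (i, j) of planted (presynaptic, postsynaptic) pairs."""
        return [
            (i, p.partner)
            for i, p in enumerate(self.puncta)
            if p.channel == "vglut1" and p.partner is not None
        ]

    def to_dict(self) -> dict:
        """JSON-serializable summary (masks reduced to pixel counts)."""
        return {
            "cell_channels": self.cell_channels,
            "cell_mask_area_px": {k: int(m.sum()) for k, m in self.cell_masks.items()},
            "per_cell_counts": self.per_cell_counts,
            "dendrite_length_um": self.dendrite_length_um,
            "n_puncta": len(self.puncta),
            "n_colocalized_pairs": len(self.colocalized_pairs()),
            "warnings": list(self.warnings),
            "extra": {
                k: v for k, v in self.extra.items() if _json_safe(v)
            },
        }


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, list, dict, type(None)))


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _disk_coords(center: tuple[float, float], radius_px: float, shape) -> np.ndarray:
    rr, cc = draw_disk(center, radius_px, shape=shape)
    return np.stack([rr, cc], axis=1)

def _paint(mask: np.ndarray, coords: np.ndarray) -> None:
    mask[coords[:, 0], coords[:, 1]] = True


def _render_channel(
    mask: np.ndarray,
    spec: SceneSpec,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Intensity raster from a boolean structure mask under the noise model."""
    signal = spec.amplitude * mask.astype(float)
    if spec.psf_sigma_um > 0:
        signal = gaussian_filter(signal, spec.psf_sigma_um / spec.pixel_size_um)
    img = signal + spec.background
    if spec.shot_noise:
        if rng is None:
            raise ValueError("shot noise requires an rng")
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.read_noise_sigma > 0:
        if rng is None:
            raise ValueError("read noise requires an rng")
        img = img + rng.normal(0.0, spec.read_noise_sigma, img.shape)
    return np.clip(img, 0.0, None)


def _dendrite_arbor(
    spec: SceneSpec,
    soma_center: tuple[float, float],
    rng: np.random.Generator,
    angle_range: tuple[float, float] = (0.0, 2 * math.pi),
    branch_length_um: float | None = None,
) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Render a soma plus straight dendrite branches.

    Returns (cell mask, per-branch centre-line pixel paths, total dendrite
    length in µm).  Branch angles are drawn uniformly inside ``angle_range``
    with a minimum angular spacing so branches do not lie on top of each
    other.
    """
    shape = spec.shape
    length_um = branch_length_um if branch_length_um is not None else spec.branch_length_um
    mask = np.zeros(shape, dtype=bool)
    _paint(mask, _disk_coords(soma_center, spec.px(spec.soma_radius_um), shape))

    a0, a1 = angle_range
    span = a1 - a0
    offsets = (np.arange(spec.n_branches) + rng.uniform(0.2, 0.8, spec.n_branches)) / spec.n_branches
    angles = a0 + span * offsets
    length_px = spec.px(length_um)
    r0 = spec.px(spec.soma_radius_um) * 0.6
    half_w = max(1, int(round(spec.px(spec.dendrite_width_um) / 2)))
    centerlines: list[np.ndarray] = []
    skel = np.zeros(shape, dtype=bool)
    for ang in angles:
        start = (
            soma_center[0] + r0 * math.sin(ang),
            soma_center[1] + r0 * math.cos(ang),
        )
        end = (
            soma_center[0] + (r0 + length_px) * math.sin(ang),
            soma_center[1] + (r0 + length_px) * math.cos(ang),
        )
        end = (min(max(end[0], 0), shape[0] - 1), min(max(end[1], 0), shape[1] - 1))
        rr, cc = draw_line(
            int(round(start[0])), int(round(start[1])),
            int(round(end[0])), int(round(end[1])),
        )
        skel[rr, cc] = True
        centerlines.append(np.stack([rr, cc], axis=1))
    mask |= dilation(skel, disk_se(half_w))
    total_len_um = spec.n_branches * length_um
    return mask, centerlines, total_len_um


class _Placer:
    """Greedy punctum placement with a global minimum centre separation."""

    def __init__(self, spec: SceneSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.min_sep_px = spec.px(spec.min_separation_um)
        # keep whole puncta inside the raster so planted areas stay in-band
        self.border_px = spec.px(spec.punctum_radius_um) + 3
        self.centers: list[tuple[int, int]] = []

    def _ok(self, r: int, c: int) -> bool:
        nr, nc = self.spec.shape
        if not (self.border_px <= r < nr - self.border_px):
            return False
        if not (self.border_px <= c < nc - self.border_px):
            return False
        for pr, pc in self.centers:
            if (pr - r) ** 2 + (pc - c) ** 2 < self.min_sep_px**2:
                return False
        return True

    def place_on_path(self, centerlines: list[np.ndarray], n: int) -> list[tuple[int, int]]:
        """Place n centres on dendrite centre-line pixels."""
        candidates = np.concatenate(centerlines, axis=0)
        order = self.rng.permutation(len(candidates))
        out: list[tuple[int, int]] = []
        for idx in order:
            if len(out) == n:
                break
            r, c = int(candidates[idx, 0]), int(candidates[idx, 1])
            if self._ok(r, c):
                out.append((r, c))
                self.centers.append((r, c))
        if len(out) < n:
            raise PlacementError(
                f"could only place {len(out)}/{n} puncta at "
                f"min separation {self.spec.min_separation_um} um"
            )
        return out


# ---------------------------------------------------------------------------
# doublet scenes
# ---------------------------------------------------------------------------

def generate_doublet_scene(
    spec: SceneSpec,
    params: CompetitionParams,
    scene_seed: int | None = None,
) -> tuple[dict[str, CalibratedImage], GroundTruth]:
    """Render a microisland doublet (or singlet) scene.

    Cell 0 is the transfected neuron (tdTomato fill; its postsynaptic puncta
    appear in both the ``psd95`` and ``psd95gfp`` channels).  Cell 1, when
    present, is untransfected (puncta in ``psd95`` only).  Every allocated
    synapse is a presynaptic ``vglut1`` punctum; a fraction
    ``spec.coloc_fraction`` of presynaptic puncta receive an overlapping
    postsynaptic partner (>= 1 shared pixel by construction).

    Synapse counts per cell follow :func:`allocate_synapses` seeded from
    ``params.seed``; punctum placement and noise use ``scene_seed``
    (default: derived from ``params.seed``), so two scenes with the same
    allocation seed but different scene seeds carry identical per-cell
    counts at different pixel positions.
    """
    n = params.n_cells
    if n not in (1, 2):
        raise ValueError("doublet scenes support 1 or 2 cells")
    counts = allocate_synapses(params)
    scene_rng = np.random.default_rng(
        scene_seed if scene_seed is not None else params.seed + 1_000_003
    )
    shape = spec.shape
    gt = GroundTruth()

    # somata on the horizontal midline, facing away from each other
    cy = shape[1] / 2
    if n == 1:
        centers = [(shape[0] / 2, cy)]
        ranges = [(0.0, 2 * math.pi)]
    else:
        off = spec.px(spec.field_size_um[1] / 4)
        centers = [(shape[0] / 2, cy - off), (shape[0] / 2, cy + off)]
        # each cell's branches point into its own half-plane
        ranges = [(math.pi / 2 + 0.3, 3 * math.pi / 2 - 0.3),
                  (-math.pi / 2 + 0.3, math.pi / 2 - 0.3)]

    post_masks = {"psd95": np.zeros(shape, bool), "psd95gfp": np.zeros(shape, bool)}
    vglut_mask = np.zeros(shape, bool)
    td_mask = np.zeros(shape, bool)
    placer = _Placer(spec, scene_rng)
    r_px = spec.px(spec.punctum_radius_um)

    for cell in range(n):
        mask, lines, length_um = _dendrite_arbor(spec, centers[cell], scene_rng, ranges[cell])
        gt.cell_masks[cell] = mask
        gt.cell_channels[cell] = "tdtomato" if cell == 0 else "unlabeled"
        gt.dendrite_length_um[cell] = length_um
        gt.per_cell_counts[cell] = int(counts[cell])
        if length_um < 50.0:
            gt.warnings.append(
                f"cell {cell}: dendrite length {length_um:.1f} um below the 50 um analysis minimum"
            )
        if cell == 0:
            td_mask |= mask

        n_syn = int(counts[cell])
        n_coloc = int(round(spec.coloc_fraction * n_syn))
        centers_syn = placer.place_on_path(lines, n_syn)
        for k, (r, c) in enumerate(centers_syn):
            pre_coords = _disk_coords((r, c), r_px, shape)
            _paint(vglut_mask, pre_coords)
            pre_idx = len(gt.puncta)
            if k < n_coloc:
                # partner centre shifted by ~one radius: guaranteed overlap
                pr, pc = r + int(round(r_px * 0.8)), c
                post_coords = _disk_coords((pr, pc), r_px, shape)
                _paint(post_masks["psd95"], post_coords)
                if cell == 0:
                    _paint(post_masks["psd95gfp"], post_coords)
                post_idx = pre_idx + 1
                gt.puncta.append(
                    PlantedPunctum("vglut1", (r, c), pre_coords, cell, post_idx)
                )
                post_channel = "psd95gfp" if cell == 0 else "psd95"
                gt.puncta.append(
                    PlantedPunctum(post_channel, (pr, pc), post_coords, cell, pre_idx)
                )
            else:
                gt.puncta.append(PlantedPunctum("vglut1", (r, c), pre_coords, cell, None))

    channels = {
        "tdtomato": td_mask,
        "psd95": post_masks["psd95"],
        "psd95gfp": post_masks["psd95gfp"],
        "vglut1": vglut_mask,
    }
    images = {
        name: CalibratedImage(
            _render_channel(m, spec, scene_rng), spec.pixel_size_um, name
        )
        for name, m in channels.items()
    }
    return images, gt


# ---------------------------------------------------------------------------
# field scenes
# ---------------------------------------------------------------------------

def generate_field_scene(
    spec: SceneSpec,
    params: CompetitionParams,
    scene_seed: int | None = None,
) -> tuple[dict[str, CalibratedImage], GroundTruth]:
    """Render a culture field of red/green neurons with allocated vGlut1 puncta.

    Cells are laid out on a jittered grid so their masks stay disjoint;
    cell colours alternate red (tdTomato) / green (EGFP) unless
    ``spec.cell_colors`` says otherwise.  Each cell's allocated puncta are
    planted on its own dendrites, so ground-truth ownership equals the
    largest-overlap assignment on noiseless rasters.  Optional thin axon-like
    fragments (area below the axon-removal threshold) are added to the cell
    channels but are not part of the ground-truth cell masks.
    """
    n = params.n_cells
    counts = allocate_synapses(params)
    scene_rng = np.random.default_rng(
        scene_seed if scene_seed is not None else params.seed + 2_000_003
    )
    shape = spec.shape
    colors = spec.cell_colors or tuple(
        "tdtomato" if i % 2 == 0 else "egfp" for i in range(n)
    )
    if len(colors) != n:
        raise ValueError("cell_colors length must equal the number of cells")

    # grid layout guaranteeing disjoint cell masks
    grid = int(math.ceil(math.sqrt(n)))
    pitch_r, pitch_c = shape[0] / grid, shape[1] / grid
    reach_px = spec.px(spec.soma_radius_um) + spec.px(spec.branch_length_um) + spec.px(
        spec.dendrite_width_um
    )
    max_reach = min(pitch_r, pitch_c) / 2 - 2
    branch_um = spec.branch_length_um
    if reach_px > max_reach:
        branch_um = max(
            5.0,
            (max_reach - spec.px(spec.soma_radius_um) - spec.px(spec.dendrite_width_um))
            * spec.pixel_size_um,
        )

    gt = GroundTruth()
    red_mask = np.zeros(shape, bool)
    green_mask = np.zeros(shape, bool)
    vglut_mask = np.zeros(shape, bool)
    placer = _Placer(spec, scene_rng)
    r_px = spec.px(spec.punctum_radius_um)

    order = scene_rng.permutation(grid * grid)[:n]
    for cell in range(n):
        gr, gc = divmod(int(order[cell]), grid)
        jitter = spec.px(2.0)
        center = (
            (gr + 0.5) * pitch_r + scene_rng.uniform(-jitter, jitter),
            (gc + 0.5) * pitch_c + scene_rng.uniform(-jitter, jitter),
        )
        mask, lines, length_um = _dendrite_arbor(
            spec, center, scene_rng, branch_length_um=branch_um
        )
        gt.cell_masks[cell] = mask
        gt.cell_channels[cell] = colors[cell]
        gt.dendrite_length_um[cell] = length_um
        gt.per_cell_counts[cell] = int(counts[cell])
        if colors[cell] == "tdtomato":
            red_mask |= mask
        else:
            green_mask |= mask
        centers_syn = placer.place_on_path(lines, int(counts[cell]))
        for r, c in centers_syn:
            coords = _disk_coords((r, c), r_px, shape)
            _paint(vglut_mask, coords)
            gt.puncta.append(PlantedPunctum("vglut1", (r, c), coords, cell, None))

    # axon-like fragments: thin short bars in otherwise empty space
    occupied = red_mask | green_mask
    frag_half_w = max(0, int(round(spec.px(spec.axon_width_um) / 2)))
    n_frag_placed = 0
    for _ in range(spec.n_axon_fragments * spec.max_placement_tries):
        if n_frag_placed == spec.n_axon_fragments:
            break
        r0 = scene_rng.integers(5, shape[0] - 5)
        c0 = scene_rng.integers(5, shape[1] - 5)
        ang = scene_rng.uniform(0, math.pi)
        dr = spec.px(spec.axon_length_um) * math.sin(ang)
        dc = spec.px(spec.axon_length_um) * math.cos(ang)
        r1 = int(np.clip(r0 + dr, 0, shape[0] - 1))
        c1 = int(np.clip(c0 + dc, 0, shape[1] - 1))
        rr, cc = draw_line(int(r0), int(c0), r1, c1)
        frag = np.zeros(shape, bool)
        frag[rr, cc] = True
        if frag_half_w:
            frag = dilation(frag, disk_se(frag_half_w))
        if (frag & occupied).any():
            continue
        target = red_mask if scene_rng.random() < 0.5 else green_mask
        target |= frag
        occupied |= frag
        n_frag_placed += 1
    gt.extra["n_axon_fragments"] = n_frag_placed
    gt.extra["n_red_cells"] = sum(1 for c in colors if c == "tdtomato")
    gt.extra["n_green_cells"] = sum(1 for c in colors if c == "egfp")

    images = {
        name: CalibratedImage(
            _render_channel(m, spec, scene_rng), spec.pixel_size_um, name
        )
        for name, m in (
            ("tdtomato", red_mask),
            ("egfp", green_mask),
            ("vglut1", vglut_mask),
        )
    }
    return images, gt


# ---------------------------------------------------------------------------
# RNAscope scenes
# ---------------------------------------------------------------------------

def generate_rnascope_scene(
    spec: SceneSpec,
    class_params: list[RnascopeClassParams],
    seed: int = 0,
) -> tuple[dict[str, CalibratedImage], GroundTruth]:
    """Render a section of nuclei with per-probe RNAscope dots.

    Nuclei are non-overlapping ellipses in the DAPI channel; each nucleus
    carries CTIP2, SATB2 and ephrin-B3 dots whose counts follow its class's
    distribution.  Ground truth records the true class and true per-probe
    counts per nucleus.  Raises :class:`PlacementError` if the requested
    nuclei cannot be placed after bounded retries.
    """
    rng = np.random.default_rng(seed)
    shape = spec.shape
    gt = GroundTruth()
    dapi = np.zeros(shape, bool)
    probes = {
        "probe_ctip2": np.zeros(shape, bool),
        "probe_satb2": np.zeros(shape, bool),
        "probe_efnb3": np.zeros(shape, bool),
    }
    margin = spec.px(1.0)
    nuclei: list[dict] = []
    occupied = np.zeros(shape, bool)

    for cp in class_params:
        if cp.distribution not in ("poisson", "fixed"):
            raise ValueError("distribution must be 'poisson' or 'fixed'")
        for _ in range(cp.n_nuclei):
            placed = False
            for _try in range(spec.max_placement_tries):
                a = spec.px(rng.uniform(*spec.nucleus_radii_um))
                b = spec.px(rng.uniform(*spec.nucleus_radii_um))
                r = rng.uniform(a + margin, shape[0] - a - margin)
                c = rng.uniform(b + margin, shape[1] - b - margin)
                rr, cc = draw_ellipse(r, c, a, b, shape=shape)
                grown_rr, grown_cc = draw_ellipse(
                    r, c, a + margin, b + margin, shape=shape
                )
                if occupied[grown_rr, grown_cc].any():
                    continue
                nucleus_mask = np.zeros(shape, bool)
                nucleus_mask[rr, cc] = True
                dapi |= nucleus_mask
                occupied[grown_rr, grown_cc] = True
                if cp.distribution == "poisson":
                    nc = int(rng.poisson(cp.ctip2_mean))
                    ns = int(rng.poisson(cp.satb2_mean))
                    ne = int(rng.poisson(cp.efnb3_mean))
                else:
                    nc = int(round(cp.ctip2_mean))
                    ns = int(round(cp.satb2_mean))
                    ne = int(round(cp.efnb3_mean))
                dot_counts = {
                    "probe_ctip2": nc, "probe_satb2": ns, "probe_efnb3": ne
                }
                _place_dots(
                    probes, dot_counts, (r, c), (a, b), spec, rng, gt,
                    cell_index=len(nuclei),
                )
                nuclei.append(
                    {
                        "class": cp.name,
                        "center_px": (float(r), float(c)),
                        "radii_px": (float(a), float(b)),
                        "counts": dot_counts,
                    }
                )
                gt.cell_masks[len(nuclei) - 1] = nucleus_mask
                gt.cell_channels[len(nuclei) - 1] = "dapi"
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place nucleus of class {cp.name!r} "
                    f"after {spec.max_placement_tries} tries"
                )
    gt.extra["nuclei"] = nuclei

    images = {"dapi": CalibratedImage(
        _render_channel(dapi, spec, rng), spec.pixel_size_um, "dapi"
    )}
    for name, m in probes.items():
        images[name] = CalibratedImage(
            _render_channel(m, spec, rng), spec.pixel_size_um, name
        )
    return images, gt


def _place_dots(
    probes: dict[str, np.ndarray],
    dot_counts: dict[str, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    spec: SceneSpec,
    rng: np.random.Generator,
    gt: GroundTruth,
    cell_index: int,
) -> None:
    """Plant non-merging dots inside one elliptical nucleus, per probe."""
    r0, c0 = center
    a, b = radii
    min_sep = 2 * spec.dot_radius_px + 2.0
    for probe, n_dots in dot_counts.items():
        placed: list[tuple[float, float]] = []
        tries = 0
        limit = spec.max_placement_tries * max(n_dots, 1)
        while len(placed) < n_dots and tries < limit:
            tries += 1
            rho = math.sqrt(rng.uniform(0, 1))
            theta = rng.uniform(0, 2 * math.pi)
            r = r0 + rho * (a - spec.dot_radius_px - 1) * math.sin(theta)
            c = c0 + rho * (b - spec.dot_radius_px - 1) * math.cos(theta)
            if any((r - pr) ** 2 + (c - pc) ** 2 < min_sep**2 for pr, pc in placed):
                continue
            coords = _disk_coords((r, c), spec.dot_radius_px, probes[probe].shape)
            _paint(probes[probe], coords)
            placed.append((r, c))
            gt.puncta.append(
                PlantedPunctum(
                    probe, (int(round(r)), int(round(c))), coords, cell_index, None
                )
            )
        if len(placed) < n_dots:
            raise PlacementError(
                f"could only fit {len(placed)}/{n_dots} {probe} dots in nucleus "
                f"{cell_index}"
            )
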