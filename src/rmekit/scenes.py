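"""Synthetic two-channel micrographs and plate-reader data with known ground truth.

The generator emulates the experimental inputs of a tonicity-challenge
translocation study: single adherent cells imaged by confocal microscopy with
a bright plasma-membrane ring, diffuse cytoplasmic signal, a dim nucleus and
optional ER puncta in the tagged-protein channel; a membrane-dye channel that
stains every cell; and 96-well biotinylation-ELISA plates read as absorbance
at 450 nm.

Every quantity that the analysis modules estimate (relative membrane
expression, cross-sectional area change, translocation time constant, surface
expression fold change) is a direct, controllable parameter of the generator,
so the whole pipeline can be validated against ground truth without any
external data.

Signal placement model
----------------------
``membrane_fraction`` (f) interpolates between the two anchor distributions of
the RME statistic: a fraction ``f`` of ``total_signal`` is placed exclusively
in the membrane ring, and the remaining ``1 - f`` is spread uniformly over the
whole cell footprint (ring included, nucleus dimmed to 20%).  Hence ``f = 0``
renders a cell with exactly even intensity across ring and interior (RME 0 by
definition) and ``f = 1`` confines all signal to the ring (RME 100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CellSpec",
    "SceneSpec",
    "Scene",
    "ElisaTruth",
    "ElisaPlate",
    "render_scene",
    "render_timecourse",
    "simulate_elisa_plate",
]

SUPERSAMPLE = 4
NUCLEUS_DIMMING = 0.2  # nucleus intensity relative to cytoplasm
ER_SPOT_SIGMA_PX = 2.0  # Gaussian sigma; visible radius ~4 px


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth parameters of one synthetic cell.

    Lengths are in micrometres except ``center`` which is in pixels
    (row, col). ``total_signal`` is the integrated tagged-protein intensity
    in arbitrary units (a.u.) over the whole cell, before noise.
    """

    center: tuple[float, float]
    radius: float = 5.0
    membrane_thickness: float = 0.6
    membrane_fraction: float = 0.0
    nucleus_radius: float = 1.5
    total_signal: float = 1.0e5
    er_fraction: float = 0.0
    transfected: bool = True
    swelling_area_ratio: float = 1.0
    n_er_spots: int = 24

    def validate(self) -> None:
        if not 0.0 <= self.membrane_fraction <= 1.0:
            raise ValueError("membrane_fraction must lie in [0, 1]")
        if not 0.0 <= self.er_fraction <= 1.0:
            raise ValueError("er_fraction must lie in [0, 1]")
        if self.radius <= 0 or self.membrane_thickness <= 0:
            raise ValueError("radius and membrane_thickness must be positive")
        if self.nucleus_radius >= self.radius - self.membrane_thickness:
            raise ValueError(
                "nucleus_radius must be smaller than radius - membrane_thickness"
            )
        if self.total_signal < 0:
            raise ValueError("total_signal must be non-negative")
        if self.swelling_area_ratio < 0:
            raise ValueError("swelling_area_ratio must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic micrograph (all channels)."""

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.2  # µm per pixel
    cells: tuple[CellSpec, ...] = ()
    background_level: float = 0.0  # a.u., added to every channel
    dye_level: float = 150.0  # membrane-dye ring intensity, a.u.
    noise_gaussian_sd: float = 0.0  # a.u.
    noise_poisson: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))

    def validate(self) -> None:
        if self.image_shape[0] <= 0 or self.image_shape[1] <= 0:
            raise ValueError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_gaussian_sd < 0:
            raise ValueError("noise_gaussian_sd must be >= 0")
        for cell in self.cells:
            cell.validate()
            r_px = cell.radius / self.pixel_size
            r, c = cell.center
            h, w = self.image_shape
            if r - r_px < 0 or c - r_px < 0 or r + r_px > h - 1 or c + r_px > w - 1:
                raise ValueError(
                    f"cell at {cell.center} (radius {r_px:.1f} px) does not lie "
                    "fully inside the image"
                )
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < (a.radius + b.radius) / self.pixel_size:
                    raise ValueError(
                        f"cell footprints at {a.center} and {b.center} overlap"
                    )


@dataclass
class CellTruth:
    """Per-cell ground-truth masks at image resolution."""

    spec: CellSpec
    cell: np.ndarray  # whole-cell footprint (ring included)
    membrane: np.ndarray  # ring only
    interior: np.ndarray  # cell minus ring
    nucleus: np.ndarray
    er: np.ndarray


@dataclass
class Scene:
    """Rendered multichannel image plus the ground truth that produced it."""

    spec: SceneSpec
    channels: dict[str, np.ndarray]
    truth: list[CellTruth]

    @property
    def cell_labels(self) -> np.ndarray:
        """Label image: 0 = background, i+1 = cell i (footprints are disjoint)."""
        lab = np.zeros(self.spec.image_shape, dtype=np.int32)
        for i, t in enumerate(self.truth):
            lab[t.cell] = i + 1
        return lab


def _cell_fields(spec: SceneSpec, cell: CellSpec, rng: np.random.Generator):
    """Supersampled intensity and masks for one cell, on its bounding box.

    Returns (row0, col0, protein_ss, dye_ss, er_ss, masks_ss) where the *_ss
    arrays live on the supersampled bounding-box grid and intensities are in
    a.u. per image pixel (i.e. block-averaging then summing over image pixels
    conserves the integrated signal).
    """
    ss = SUPERSAMPLE
    px = spec.pixel_size
    r_px = cell.radius / px
    t_px = cell.membrane_thickness / px
    rn_px = cell.nucleus_radius / px
    cr, cc = cell.center

    row0 = max(int(math.floor(cr - r_px - 2)), 0)
    row1 = min(int(math.ceil(cr + r_px + 2)), spec.image_shape[0])
    col0 = max(int(math.floor(cc - r_px - 2)), 0)
    col1 = min(int(math.ceil(cc + r_px + 2)), spec.image_shape[1])

    rows = row0 + (np.arange((row1 - row0) * ss) + 0.5) / ss - 0.5
    cols = col0 + (np.arange((col1 - col0) * ss) + 0.5) / ss - 0.5
    dr = rows[:, None] - cr
    dc = cols[None, :] - cc
    dist = np.hypot(dr, dc)

    cell_m = dist <= r_px
    interior_m = dist <= r_px - t_px
    ring_m = cell_m & ~interior_m
    nucleus_m = dist <= rn_px  # nucleus concentric with the cell

    # weights of the uniform component: cytoplasm+ring 1.0, nucleus dimmed
    weights = cell_m.astype(np.float64)
    weights[nucleus_m] = NUCLEUS_DIMMING

    protein = np.zeros_like(weights)
    er_chan = np.zeros_like(weights)
    er_m = np.zeros_like(cell_m)

    if cell.transfected and cell.total_signal > 0:
        f = cell.membrane_fraction
        s_total = cell.total_signal
        s_uniform = (1.0 - f) * s_total
        s_er = cell.er_fraction * s_uniform
        s_uniform -= s_er
        s_ring = f * s_total

        # per-supersample values scaled so that block-mean then pixel-sum == S
        w_area = weights.sum() / ss**2
        if w_area > 0 and s_uniform > 0:
            protein += weights * (s_uniform / w_area)
        ring_area = ring_m.sum() / ss**2
        if ring_area > 0 and s_ring > 0:
            protein[ring_m] += s_ring / ring_area

        if s_er > 0 and cell.n_er_spots > 0:
            spot = np.zeros_like(protein)
            # seeded spot centres in the cytoplasm, clear of ring and nucleus
            max_r = r_px - t_px - 3.0 * ER_SPOT_SIGMA_PX
            min_r = rn_px + 3.0 * ER_SPOT_SIGMA_PX
            if max_r <= min_r:
                raise ValueError("cell too small to place ER puncta")
            for _ in range(cell.n_er_spots):
                rad = math.sqrt(rng.uniform(min_r**2, max_r**2))
                ang = rng.uniform(0, 2 * math.pi)
                sr = cr + rad * math.sin(ang)
                sc = cc + rad * math.cos(ang)
                g = np.exp(
                    -((rows[:, None] - sr) ** 2 + (cols[None, :] - sc) ** 2)
                    / (2 * ER_SPOT_SIGMA_PX**2)
                )
                spot += g
                er_m |= np.hypot(rows[:, None] - sr, cols[None, :] - sc) <= (
                    2.0 * ER_SPOT_SIGMA_PX
                )
            spot_sum = spot.sum() / ss**2
            spot *= s_er / spot_sum
            protein += spot
            er_chan += spot  # same puncta in the ER-marker channel

    dye = np.zeros_like(weights)
    dye[ring_m] = spec.dye_level

    masks = dict(
        cell=cell_m, ring=ring_m, interior=interior_m & ~ring_m,
        nucleus=nucleus_m, er=er_m,
    )
    return row0, col0, protein, dye, er_chan, masks


def _block_mean(a: np.ndarray) -> np.ndarray:
    ss = SUPERSAMPLE
    h, w = a.shape[0] // ss, a.shape[1] // ss
    return a.reshape(h, ss, w, ss).mean(axis=(1, 3))


def render_scene(spec: SceneSpec) -> Scene:
    """Render the protein, membrane-dye and ER-marker channels of a scene.

    Rendering is done at 4x supersampling and block-averaged so that partial
    pixel coverage at circle edges is correct and the integrated noise-free
    protein signal equals the sum of ``total_signal`` over transfected cells
    (to well under 1%). Noise (optional Poisson, then additive Gaussian) is
    applied last; identical specs (including seed) give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    protein = np.zeros((h, w), dtype=np.float64)
    dye = np.zeros((h, w), dtype=np.float64)
    er = np.zeros((h, w), dtype=np.float64)
    truth: list[CellTruth] = []

    for cell in spec.cells:
        row0, col0, p_ss, d_ss, e_ss, masks = _cell_fields(spec, cell, rng)
        sl = (
            slice(row0, row0 + p_ss.shape[0] // SUPERSAMPLE),
            slice(col0, col0 + p_ss.shape[1] // SUPERSAMPLE),
        )
        protein[sl] += _block_mean(p_ss)
        dye[sl] += _block_mean(d_ss)
        er[sl] += _block_mean(e_ss)

        def full(m):
            out = np.zeros((h, w), dtype=bool)
            out[sl] = _block_mean(m.astype(np.float64)) >= 0.5
            return out

        truth.append(
            CellTruth(
                spec=cell,
                cell=full(masks["cell"]),
                membrane=full(masks["ring"]),
                interior=full(masks["interior"]),
                nucleus=full(masks["nucleus"]),
                er=full(masks["er"]),
            )
        )

    channels = {"protein": protein, "membrane_dye": dye, "er_marker": er}
    for name, img in channels.items():
        img += spec.background_level
        if spec.noise_poisson:
            img[:] = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if spec.noise_gaussian_sd > 0:
            img += rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
    return Scene(spec=spec, channels=channels, truth=truth)


def render_timecourse(
    spec: SceneSpec,
    f_start: float,
    f_end: float,
    tau: float,
    frame_rate: float = 0.1,
    duration: float = 120.0,
    swell: bool = False,
) -> list[Scene]:
    """Render a time-lapse in which the membrane fraction relaxes exponentially.

    Frame k is rendered at t_k = k / frame_rate for all t_k <= duration, with
    membrane_fraction f(t) = f_end + (f_start - f_end) * exp(-t / tau) applied
    to every transfected cell. With ``swell=True`` each cell's cross-sectional
    area also relaxes toward ``swelling_area_ratio`` times its initial area
    with the same time constant. Per-frame noise is seeded independently but
    deterministically from ``spec.seed``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(math.floor(duration * frame_rate + 1e-9)) + 1
    frame_seeds = np.random.SeedSequence(spec.seed).generate_state(n_frames)
    scenes = []
    for k in range(n_frames):
        t = k / frame_rate
        decay = math.exp(-t / tau)
        f_t = f_end + (f_start - f_end) * decay
        cells = []
        for cell in spec.cells:
            new = cell
            if cell.transfected:
                new = replace(new, membrane_fraction=f_t)
            if swell and cell.swelling_area_ratio != 1.0:
                area_ratio_t = 1.0 + (cell.swelling_area_ratio - 1.0) * (1 - decay)
                new = replace(new, radius=cell.radius * math.sqrt(area_ratio_t))
            cells.append(new)
        frame_spec = replace(
            spec, cells=tuple(cells), seed=int(frame_seeds[k] % 2**31)
        )
        scenes.append(render_scene(frame_spec))
    return scenes


# --------------------------------------------------------------------------
# ELISA plate simulation
# --------------------------------------------------------------------------

_PLATE_ROWS = "ABCDEFGH"
_PLATE_COLS = range(1, 13)


@dataclass(frozen=True)
class ElisaTruth:
    """Ground truth for a simulated biotinylation-ELISA plate.

    ``conditions`` maps condition labels to true surface-expression levels
    (a.u., proportional to expected blank-subtracted absorbance). Each
    biological repeat is an independent lysate loaded in ``n_replicate_wells``
    wells; well noise is multiplicative log-normal with coefficient of
    variation ``cv``.
    """

    conditions: dict[str, float] = field(default_factory=dict)
    cv: float = 0.1
    n_replicate_wells: int = 3
    n_repeats: int = 3
    blank_level: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if any(v <= 0 for v in self.conditions.values()):
            raise ValueError("condition levels must be > 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_replicate_wells < 1 or self.n_repeats < 1:
            raise ValueError("n_replicate_wells and n_repeats must be >= 1")
        if self.blank_level < 0:
            raise ValueError("blank_level must be >= 0")


@dataclass
class ElisaPlate:
    """Well table of one simulated (or loaded) 96-well plate.

    ``wells`` has columns: well, row, col, condition, repeat, replicate,
    absorbance. Blank wells carry condition "blank" with repeat/replicate 0.
    """

    wells: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def blanks(self) -> pd.DataFrame:
        return self.wells[self.wells["condition"] == "blank"]


def simulate_elisa_plate(truth: ElisaTruth) -> ElisaPlate:
    """Simulate absorbances at 450 nm for a 96-well biotinylation ELISA.

    Each (condition, repeat) lysate occupies ``n_replicate_wells`` consecutive
    wells with absorbance ``blank_level + level * exp(eps)``,
    eps ~ Normal(0, cv). One triplicate of blank wells is added at the end
    with absorbance ``blank_level`` perturbed by the same relative noise.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n_wells = (
        len(truth.conditions) * truth.n_repeats + 1
    ) * truth.n_replicate_wells
    if n_wells > 96:
        raise ValueError("layout exceeds a 96-well plate")

    records = []
    idx = 0

    def well_id(i):
        return f"{_PLATE_ROWS[i // 12]}{i % 12 + 1}"

    for cond, level in truth.conditions.items():
        for rep in range(1, truth.n_repeats + 1):
            for k in range(1, truth.n_replicate_wells + 1):
                eps = rng.normal(0.0, truth.cv) if truth.cv > 0 else 0.0
                ab = truth.blank_level + level * math.exp(eps)
                records.append(
                    dict(
                        well=well_id(idx), row=_PLATE_ROWS[idx // 12],
                        col=idx % 12 + 1, condition=cond, repeat=rep,
                        replicate=k, absorbance=ab,
                    )
                )
                idx += 1
    for k in range(1, truth.n_replicate_wells + 1):
        noise = (
            rng.normal(0.0, truth.cv * truth.blank_level) if truth.cv > 0 else 0.0
        )
        records.append(
            dict(
                well=well_id(idx), row=_PLATE_ROWS[idx // 12], col=idx % 12 + 1,
                condition="blank", repeat=0, replicate=k,
                absorbance=max(truth.blank_level + noise, 0.0),
            )
        )
        idx += 1
    wells = pd.DataFrame.from_records(records)
    meta = dict(
        seed=truth.seed, cv=truth.cv, n_repeats=truth.n_repeats,
        n_replicate_wells=truth.n_replicate_wells,
        true_levels=dict(truth.conditions),
    )
    return ElisaPlate(wells=wells, meta=meta)
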