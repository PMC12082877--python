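"""Ground-truthed synthetic data: two-channel mitochondria images and cohorts.

Two generators live here.

``generate_mito_image`` renders a field of rod/ellipse-shaped mitochondrial
objects (capsules: rectangles with semicircular caps) in two partially
overlapping channels.  The matrix channel (IMM) is the capsule interior; the
OMM channel is the capsule plus a dimmer outer rim produced by dilating the
capsule mask, emulating the membrane envelope extending slightly beyond the
matrix signal.  An ``integrity_prob`` parameter controls the fraction of
objects rendered in both channels; the remainder appear in only one channel
(OMM-only or IMM-only), emulating organelles with lost membrane integrity.
Noise is optional Poisson resampling followed by additive Gaussian read
noise over a constant background.

``generate_cohort_table`` draws per-neuron measurement tables with the
hierarchical structure the downstream mixed models assume: animals nested in
sex x genotype cells, neurons nested in animals, with a between-animal
random intercept and residual noise per response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .errors import ConfigError, PlacementError
from .image import DEFAULT_PIXEL_SIZE_UM, TwoChannelImage

INTACT = "both"
OMM_ONLY = "OMM_only"
IMM_ONLY = "IMM_only"

#: relative intensity of the OMM rim outside the matrix footprint — the
#: out-of-focus tail of the membrane envelope is dimmer than the in-plane
#: signal, which keeps the noiseless overlap fractions in the 0.8-1 range
#: observed for intact organelles.
RIM_AMPLITUDE_FRACTION = 0.7


@dataclass(frozen=True)
class ImageSimConfig:
    """Parameters of the two-channel mitochondria image simulator.

    Defaults reflect the imaging regime the quantification rules assume:
    0.0467 µm pixels (15 px = 0.7 µm), objects 0.7-2.2 µm long and ~0.45 µm
    wide, moderate Poisson + Gaussian noise over a dim uniform background.
    """

    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_objects: int = 25
    length_range_um: tuple[float, float] = (0.7, 2.2)
    width_um: float = 0.45
    integrity_prob: float = 1.0
    single_channel_bias: float = 0.5
    shell_offset_px: int = 1
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = True
    background_level: float = 10.0
    amplitude: float = 120.0
    allow_overlap: bool = True
    max_place_tries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.field_size_px
        if ny <= 0 or nx <= 0:
            raise ConfigError("field_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.n_objects <= 0:
            raise ConfigError("n_objects must be positive")
        lo, hi = self.length_range_um
        if not (0 < lo <= hi <= 5):
            raise ConfigError("length_range_um must be ordered and within (0, 5]")
        if self.width_um <= 0:
            raise ConfigError("width_um must be positive")
        for name in ("integrity_prob", "single_channel_bias"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.shell_offset_px < 0:
            raise ConfigError("shell_offset_px must be nonnegative")
        if self.noise_gaussian_sd < 0 or self.background_level < 0:
            raise ConfigError("noise parameters must be nonnegative")
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be positive")


@dataclass(frozen=True)
class ObjectRecord:
    """Ground truth for one simulated object."""

    center: tuple[float, float]  # (row, col) px
    orientation_rad: float
    length_um: float
    channels_present: str  # INTACT | OMM_ONLY | IMM_ONLY


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless channels, per-object records and analytic overlap fractions.

    ``m1``/``m2`` are the intensity-overlap fractions computed on the
    noiseless grids (M1: matrix intensity on OMM-positive pixels; M2: OMM
    intensity on matrix-positive pixels).  An empty reference channel yields
    0.0 by convention (disjoint supports).
    """

    records: tuple[ObjectRecord, ...]
    omm_clean: np.ndarray
    imm_clean: np.ndarray
    m1: float
    m2: float


def analytic_overlap_fractions(imm: np.ndarray, omm: np.ndarray) -> tuple[float, float]:
    """Intensity-overlap fractions (M1, M2) of noiseless grids at threshold 0."""
    imm = np.asarray(imm, dtype=float)
    omm = np.asarray(omm, dtype=float)
    s_imm = imm.sum()
    s_omm = omm.sum()
    m1 = float(imm[omm > 0].sum() / s_imm) if s_imm > 0 else 0.0
    m2 = float(omm[imm > 0].sum() / s_omm) if s_omm > 0 else 0.0
    return m1, m2


def _capsule_mask(shape, center, theta, length_px, width_px):
    """Boolean mask of a capsule (segment of half-length h dilated to radius r)."""
    r = width_px / 2.0
    h = max(length_px / 2.0 - r, 0.0)
    cy, cx = center
    dy, dx = math.sin(theta), math.cos(theta)
    pad = int(math.ceil(h + r)) + 2
    y0 = max(int(cy) - pad, 0)
    y1 = min(int(cy) + pad + 1, shape[0])
    x0 = max(int(cx) - pad, 0)
    x1 = min(int(cx) + pad + 1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # distance from pixel centre to the axis segment
    py, px = yy - cy, xx - cx
    t = np.clip(py * dy + px * dx, -h, h)
    dist2 = (py - t * dy) ** 2 + (px - t * dx) ** 2
    local = dist2 <= r * r
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = local
    return mask


def generate_mito_image(config: ImageSimConfig) -> tuple[TwoChannelImage, GroundTruth]:
    """Render a two-channel field of capsule-shaped mitochondria.

    Returns the noisy :class:`TwoChannelImage` and a :class:`GroundTruth`
    carrying the noiseless grids, per-object records and analytic M1/M2.

    The placement, integrity and noise random streams are decoupled: the
    same seed places identical objects regardless of ``integrity_prob``, so
    lowering the integrity probability only flips objects from intact to
    single-channel (a monotone coupling).
    """
    shape = tuple(config.field_size_px)
    rng_place = np.random.default_rng([config.seed, 11])
    rng_fate = np.random.default_rng([config.seed, 23])
    rng_noise = np.random.default_rng([config.seed, 47])

    width_px = config.width_um / config.pixel_size_um
    lo_um, hi_um = config.length_range_um

    imm = np.zeros(shape, dtype=float)
    omm = np.zeros(shape, dtype=float)
    occupied = np.zeros(shape, dtype=bool)
    records: list[ObjectRecord] = []

    # integrity draws are coupled uniforms, independent of placement
    u_intact = rng_fate.random(config.n_objects)
    u_bias = rng_fate.random(config.n_objects)

    for i in range(config.n_objects):
        length_um = rng_place.uniform(lo_um, hi_um)
        length_px = length_um / config.pixel_size_um
        margin = length_px / 2.0 + width_px / 2.0 + config.shell_offset_px + 2
        if 2 * margin >= min(shape):
            raise PlacementError(
                f"objects of length {length_um:.2f} um do not fit the "
                f"{shape} field at {config.pixel_size_um} um/px ({config})"
            )
        placed = False
        for _ in range(config.max_place_tries):
            cy = rng_place.uniform(margin, shape[0] - margin)
            cx = rng_place.uniform(margin, shape[1] - margin)
            theta = rng_place.uniform(0, math.pi)
            mask = _capsule_mask(shape, (cy, cx), theta, length_px, width_px)
            if config.allow_overlap or not (mask & occupied).any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place object {i} after {config.max_place_tries} "
                f"tries with config {config}"
            )
        occupied |= mask
        if config.shell_offset_px > 0:
            dilated = binary_dilation(mask, iterations=config.shell_offset_px)
        else:
            dilated = mask
        rim = dilated & ~mask

        if u_intact[i] < config.integrity_prob:
            fate = INTACT
        elif u_bias[i] < config.single_channel_bias:
            fate = OMM_ONLY
        else:
            fate = IMM_ONLY

        amp = config.amplitude
        if fate in (INTACT, IMM_ONLY):
            imm[mask] += amp
        if fate in (INTACT, OMM_ONLY):
            omm[mask] += amp
            omm[rim] += amp * RIM_AMPLITUDE_FRACTION
        records.append(ObjectRecord((cy, cx), theta, length_um, fate))

    m1, m2 = analytic_overlap_fractions(imm, omm)
    truth = GroundTruth(tuple(records), omm.copy(), imm.copy(), m1, m2)

    noisy = []
    for clean in (omm, imm):
        signal = clean + config.background_level
        if config.noise_poisson:
            signal = rng_noise.poisson(signal).astype(float)
        if config.noise_gaussian_sd > 0:
            signal = signal + rng_noise.normal(0, config.noise_gaussian_sd, shape)
        noisy.append(np.clip(signal, 0, None))
    image = TwoChannelImage(noisy[0], noisy[1], config.pixel_size_um)
    return image, truth


# ---------------------------------------------------------------------------
# cohort tables


CELLS: tuple[tuple[str, str], ...] = (
    ("male", "WT"),
    ("female", "WT"),
    ("male", "KO"),
    ("female", "KO"),
)

RESPONSES = ("aspect_ratio", "m2", "mito_count")

#: study design: animals per sex x genotype cell and neurons per animal,
#: matching 90/60/120/90 neurons from 3/3/5/3 animals.
DEFAULT_N_ANIMALS: Mapping[tuple[str, str], int] = {
    ("male", "WT"): 3,
    ("female", "WT"): 3,
    ("male", "KO"): 5,
    ("female", "KO"): 3,
}
DEFAULT_NEURONS_PER_ANIMAL: Mapping[tuple[str, str], int] = {
    ("male", "WT"): 30,
    ("female", "WT"): 20,
    ("male", "KO"): 24,
    ("female", "KO"): 30,
}


def _default_cell_means() -> dict[str, dict[tuple[str, str], float]]:
    # female-KO integrity deficit; slight elongation tendency in KO; no
    # programmed mass differences.
    return {
        "aspect_ratio": {c: (1.95 if c[1] == "KO" else 1.90) for c in CELLS},
        "m2": {
            ("male", "WT"): 0.85,
            ("female", "WT"): 0.85,
            ("male", "KO"): 0.85,
            ("female", "KO"): 0.75,
        },
        "mito_count": {c: 60.0 for c in CELLS},
    }


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the hierarchical cohort simulator.

    ``sd_animal`` is the between-animal random-intercept SD and ``sd_resid``
    the neuron-level residual SD, per response.  M2 draws are truncated to
    [0, 1]; counts are rounded to nonnegative integers.
    """

    n_animals: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N_ANIMALS)
    )
    neurons_per_animal: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_NEURONS_PER_ANIMAL)
    )
    cell_means: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=_default_cell_means
    )
    sd_animal: Mapping[str, float] = field(
        default_factory=lambda: {"aspect_ratio": 0.08, "m2": 0.02, "mito_count": 5.0}
    )
    sd_resid: Mapping[str, float] = field(
        default_factory=lambda: {"aspect_ratio": 0.45, "m2": 0.05, "mito_count": 15.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cell in CELLS:
            if self.n_animals.get(cell, 0) <= 0:
                raise ConfigError(f"n_animals must be positive for cell {cell}")
            if self.neurons_per_animal.get(cell, 0) <= 0:
                raise ConfigError(
                    f"neurons_per_animal must be positive for cell {cell}"
                )
        for resp in RESPONSES:
            if resp not in self.cell_means:
                raise ConfigError(f"cell_means missing response {resp!r}")
            if self.sd_animal.get(resp, -1) < 0 or self.sd_resid.get(resp, -1) < 0:
                raise ConfigError(f"SDs for {resp!r} must be nonnegative")


def generate_cohort_table(config: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a per-neuron table of morphometric/integrity responses.

    Returns the table (one row per neuron: ``animal_id``, ``sex``,
    ``genotype``, ``aspect_ratio``, ``m2``, ``mito_count``) and a record of
    the true parameters used (cell means, variance components, seed).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for sex, genotype in CELLS:
        cell = (sex, genotype)
        for a in range(config.n_animals[cell]):
            animal_id = f"{genotype}_{sex[0]}{a + 1}"
            intercepts = {
                r: rng.normal(0, config.sd_animal[r]) for r in RESPONSES
            }
            n_neurons = config.neurons_per_animal[cell]
            for _ in range(n_neurons):
                row = {"animal_id": animal_id, "sex": sex, "genotype": genotype}
                for r in RESPONSES:
                    mu = config.cell_means[r][cell] + intercepts[r]
                    val = mu + rng.normal(0, config.sd_resid[r])
                    if r == "m2":
                        val = min(max(val, 0.0), 1.0)
                    elif r == "mito_count":
                        val = max(round(val), 0)
                    row[r] = val
                rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "cell_means": {r: dict(config.cell_means[r]) for r in RESPONSES},
        "sd_animal": dict(config.sd_animal),
        "sd_resid": dict(config.sd_resid),
        "seed": config.seed,
    }
    return table, truth


def with_integrity(config: ImageSimConfig, integrity_prob: float) -> ImageSimConfig:
    """Copy a config with a new integrity probability (placement unchanged)."""
    return replace(config, integrity_prob=integrity_prob)
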