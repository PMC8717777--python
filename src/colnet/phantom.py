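"""Synthetic multi-modal stroke-phantom generator.

Each phantom slice mimics the structure of acute-stroke perfusion MRI: an
elliptical "brain" on a dark background, containing an infarct core
(a filled ellipse, dark on the diffusion-like channel 0) surrounded by a
penumbra annulus (the segmentation target, brightest on the perfusion-like
channel 2). Modalities differ only in the mean intensity assigned to each
tissue region; Gaussian noise is added on top and intensities are clipped
to [-1, 1] to match the reconstructor's Tanh output range.

Everything is deterministic given ``(config.seed, case_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .image_io import LabelMask, MultiModalSlice

__all__ = [
    "PhantomConfig", "SampleRecord", "LesionGeometry", "DatasetSplit",
    "make_lesion_geometry", "render_modalities", "generate_dataset",
    "split_dataset", "sample_lesion_params",
]

ROLE_LABELED = "labeled"
ROLE_PSEUDO_UNLABELED = "pseudo_unlabeled"
ROLE_VALIDATION = "validation"
ROLE_TEST = "test"
_ROLES = {ROLE_LABELED, ROLE_PSEUDO_UNLABELED, ROLE_VALIDATION, ROLE_TEST}

# Mean intensity (brain, core, penumbra) per modality profile; channel k uses
# profile k mod 6. Profiles emulate DWI / CBV / Tmax / CBF / T2 / TTP ordering:
# core darkest on the DWI-like channel 0, penumbra contrast strongest on the
# Tmax-like perfusion channel 2. Background (air) is -1 in every channel.
_PROFILES = (
    (0.00, -0.60, 0.15),   # DWI-like: dark infarct core
    (0.10, -0.30, -0.10),  # CBV-like
    (-0.10, 0.45, 0.70),   # Tmax-like: bright penumbra (perfusion channel)
    (0.05, -0.35, -0.25),  # CBF-like
    (0.15, 0.30, 0.20),    # T2-like
    (-0.05, 0.35, 0.55),   # TTP-like
)
PERFUSION_CHANNEL = 2
_BACKGROUND = -1.0
_BRAIN_MARGIN = 3      # pixels between brain ellipse and image edge


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise settings for one phantom dataset."""

    n_cases: int = 30
    height: int = 64
    width: int = 64
    n_channels: int = 6
    spacing_mm: float = 2.0
    core_radius_range: tuple[float, float] = (3.0, 7.0)
    ring_width_range: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.height < 16 or self.width < 16:
            raise ValueError("height and width must be >= 16")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.core_radius_range[0] < 1:
            raise ValueError("core_radius_range.min must be >= 1")
        if self.ring_width_range[0] < 1:
            raise ValueError("ring_width_range.min must be >= 1")
        for lo, hi in (self.core_radius_range, self.ring_width_range):
            if hi < lo:
                raise ValueError("range max must be >= min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class LesionGeometry:
    """Binary masks for one case: infarct core, penumbra ring, brain."""

    core_mask: np.ndarray
    penumbra_mask: np.ndarray
    brain_mask: np.ndarray


@dataclass
class SampleRecord:
    """One phantom case: image, optional mask, and its training role."""

    case_id: str
    image: MultiModalSlice
    mask: Optional[LabelMask] = None
    role: Optional[str] = None
    spacing_mm: float = 1.0

    def __post_init__(self):
        if self.role is not None and self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in (ROLE_LABELED, ROLE_VALIDATION) and self.mask is None:
            raise ValueError(f"role {self.role!r} requires a mask")

    @property
    def effective_mask(self) -> Optional[LabelMask]:
        """The mask as training may see it: hidden for pseudo-unlabeled use."""
        if self.role == ROLE_PSEUDO_UNLABELED:
            return None
        return self.mask

    def with_role(self, role: str) -> "SampleRecord":
        return SampleRecord(case_id=self.case_id, image=self.image,
                            mask=self.mask, role=role, spacing_mm=self.spacing_mm)


@dataclass
class DatasetSplit:
    """Partition of records into the four training-time roles."""

    labeled: list[SampleRecord]
    pseudo_unlabeled: list[SampleRecord]
    validation: list[SampleRecord]
    test: list[SampleRecord] = field(default_factory=list)


def _case_rng(config: PhantomConfig, case_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, case_index, stream]))


def sample_lesion_params(config: PhantomConfig, case_index: int
                         ) -> tuple[float, float, float, float, float]:
    """Draw the continuous ellipse parameters for one case:
    (semi-axis rows, semi-axis cols, ring width, centre row, centre col)."""
    h, w = config.height, config.width
    brain_a = h / 2.0 - _BRAIN_MARGIN
    brain_b = w / 2.0 - _BRAIN_MARGIN
    rng = _case_rng(config, case_index, stream=0)
    a = rng.uniform(*config.core_radius_range)
    b = rng.uniform(*config.core_radius_range)
    ring = rng.uniform(*config.ring_width_range)
    # centre offset keeps the outer ellipse inside the brain ellipse
    free_a = brain_a - (a + ring) - 1.0
    free_b = brain_b - (b + ring) - 1.0
    while True:
        dy = rng.uniform(-free_a, free_a)
        dx = rng.uniform(-free_b, free_b)
        if (dy / free_a) ** 2 + (dx / free_b) ** 2 <= 1.0:
            break
    return a, b, ring, (h - 1) / 2.0 + dy, (w - 1) / 2.0 + dx


def make_lesion_geometry(config: PhantomConfig, case_index: int) -> LesionGeometry:
    """Draw core/penumbra ellipse parameters and rasterize the three masks.

    The core is a filled ellipse with semi-axes drawn from
    ``core_radius_range``; the penumbra is the annulus between that ellipse
    and the one grown by a ring width from ``ring_width_range``. The lesion
    centre is placed so the whole annulus stays inside the brain ellipse.
    """
    if case_index >= config.n_cases:
        raise ValueError(f"case_index {case_index} >= n_cases {config.n_cases}")
    h, w = config.height, config.width
    brain_a = h / 2.0 - _BRAIN_MARGIN
    brain_b = w / 2.0 - _BRAIN_MARGIN
    max_outer = config.core_radius_range[1] + config.ring_width_range[1]
    if max_outer + 2 > min(brain_a, brain_b):
        raise ValueError(
            f"lesion (core+ring up to {max_outer:.1f} px) cannot fit inside a "
            f"{h}x{w} image with a >=2-pixel margin")

    a, b, ring, cy, cx = sample_lesion_params(config, case_index)

    yy, xx = np.mgrid[0:h, 0:w]
    brain = (((yy - (h - 1) / 2.0) / brain_a) ** 2
             + ((xx - (w - 1) / 2.0) / brain_b) ** 2) <= 1.0
    core = (((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2) <= 1.0
    outer = (((yy - cy) / (a + ring)) ** 2 + ((xx - cx) / (b + ring)) ** 2) <= 1.0
    penumbra = outer & ~core
    return LesionGeometry(core_mask=core, penumbra_mask=penumbra, brain_mask=brain)


def render_modalities(geometry: LesionGeometry, config: PhantomConfig,
                      case_index: int) -> MultiModalSlice:
    """Paint per-region mean intensities channel by channel, add noise, clip."""
    h, w = geometry.brain_mask.shape
    if (h, w) != (config.height, config.width):
        raise ValueError("geometry shape does not match config dimensions")
    rng = _case_rng(config, case_index, stream=1)
    img = np.empty((config.n_channels, h, w), dtype=np.float32)
    brain_only = geometry.brain_mask & ~geometry.core_mask & ~geometry.penumbra_mask
    for ch in range(config.n_channels):
        brain_mu, core_mu, pen_mu = _PROFILES[ch % len(_PROFILES)]
        plane = np.full((h, w), _BACKGROUND, dtype=np.float32)
        plane[brain_only] = brain_mu
        plane[geometry.core_mask] = core_mu
        plane[geometry.penumbra_mask] = pen_mu
        img[ch] = plane
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape).astype(np.float32)
    np.clip(img, -1.0, 1.0, out=img)
    return MultiModalSlice(img, spacing_mm=config.spacing_mm,
                           case_id=f"case_{case_index:03d}")


def generate_dataset(config: PhantomConfig) -> list[SampleRecord]:
    """Generate ``config.n_cases`` phantom records (roles left unset)."""
    records = []
    for i in range(config.n_cases):
        geom = make_lesion_geometry(config, i)
        image = render_modalities(geom, config, i)
        mask = LabelMask(geom.penumbra_mask.astype(np.uint8),
                         spacing_mm=config.spacing_mm)
        records.append(SampleRecord(case_id=image.case_id, image=image,
                                    mask=mask, role=None,
                                    spacing_mm=config.spacing_mm))
    return records


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(records: list[SampleRecord], label_fraction: float,
                  validation_split: float = 0.2, seed: int = 0) -> DatasetSplit:
    """Partition training records into labeled / validation / pseudo-unlabeled.

    The labeled count is round-half-up of ``label_fraction * n`` (so 30
    records at fractions 0.1/0.2/0.5/0.8/1.0 give exactly 3/6/15/24/30);
    a ``validation_split`` fraction of the labeled set is reassigned to
    validation. Every training record, including labeled ones, additionally
    appears with its label withheld in the pseudo-unlabeled pool that feeds
    the reconstruction branch. Records already marked ``test`` pass through
    to the test partition. Selection is a seeded sample-level permutation.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if not 0.0 <= label_fraction <= 1.0:
        raise ValueError("label_fraction must lie in [0, 1]")
    if not 0.0 <= validation_split < 1.0:
        raise ValueError("validation_split must lie in [0, 1)")
    test = [r for r in records if r.role == ROLE_TEST]
    train_pool = [r for r in records if r.role != ROLE_TEST]
    n = len(train_pool)
    n_labeled = _round_half_up(label_fraction * n)
    if label_fraction > 0 and n_labeled == 0:
        raise ValueError(
            f"label_fraction {label_fraction} of {n} records rounds to 0 labeled "
            f"samples; provide more records or a larger fraction")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    chosen = [train_pool[i] for i in order[:n_labeled]]
    missing = [r.case_id for r in chosen if r.mask is None]
    if missing:
        raise ValueError(f"records selected as labeled have no mask: {missing}")
    n_val = _round_half_up(validation_split * n_labeled)
    n_val = min(n_val, n_labeled - 1) if n_labeled > 0 else 0
    validation = [r.with_role(ROLE_VALIDATION) for r in chosen[:n_val]]
    labeled = [r.with_role(ROLE_LABELED) for r in chosen[n_val:]]
    pseudo = [r.with_role(ROLE_PSEUDO_UNLABELED) for r in train_pool]
    return DatasetSplit(labeled=labeled, pseudo_unlabeled=pseudo,
                        validation=validation, test=test)
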