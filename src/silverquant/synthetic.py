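"""Synthetic ground-truth data: dark-field images and cohort count tables.

Two generators make every downstream stage testable without any microscopy
data:

* :func:`generate_image` renders a dark-field-like raster — a dim noisy
  background carrying sparse, bright, few-pixel precipitates at known
  positions — together with its ground truth.
* :func:`generate_cohort` simulates per-animal / per-section precipitate
  counts for the 2 (rearing: enriched vs deprived) x 2 (wheel running)
  x layer design, defaulting to the published group mean counts of the
  source cohort and realistic between-animal / between-section noise.

Neither generator models staining chemistry, optics (PSF) or section
thickness; images are flat-background with additive Gaussian noise, and
counts are truncated Gaussians around the cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fields import LayerLabel

__all__ = [
    "ImageSimSpec",
    "GroundTruth",
    "CohortSimSpec",
    "generate_image",
    "generate_cohort",
    "write_image",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_N_PER_GROUP",
    "DEFAULT_SECTIONS_PER_ANIMAL",
]


class SpotPlacementError(RuntimeError):
    """More non-overlapping spots were requested than the canvas admits."""


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimSpec:
    """Parameters of one synthetic dark-field field image.

    Intensities are fractions of the dynamic range [0, 1]. Spots are compact
    blobs of ``spot_size_range`` pixels (1-9 px fits within a 3 x 3
    neighbourhood, matching the few-pixel scale of silver precipitates at
    100x); ``artifact_count`` adds large bright disc confounders
    (vessel-like) that are *not* part of the ground truth.
    """

    width: int = 600
    height: int = 50
    n_spots: int = 100
    spot_size_range: tuple[int, int] = (1, 9)
    spot_intensity_range: tuple[float, float] = (0.6, 1.0)
    background_level: float = 0.05
    noise_sigma: float = 0.05
    artifact_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("canvas must be at least 1 x 1")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        lo, hi = self.spot_size_range
        if not (1 <= lo <= hi):
            raise ValueError("spot_size_range must satisfy 1 <= min <= max")
        ilo, ihi = self.spot_intensity_range
        if not (0.0 <= ilo <= ihi <= 1.0):
            raise ValueError("spot intensities must lie in [0, 1]")
        if not (0.0 <= self.background_level < ilo):
            raise ValueError("background must be below the dimmest spot")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.artifact_count < 0:
            raise ValueError("artifact_count must be >= 0")

    @property
    def spot_radius(self) -> int:
        """Half-extent (Chebyshev) of the largest spot footprint."""
        hi = self.spot_size_range[1]
        side = 1
        while side * side < hi:
            side += 2
        return side // 2

    @property
    def min_center_separation(self) -> int:
        """Chebyshev spot-centre separation enforced by the generator.

        ``2 r + 2`` leaves >= 2 background pixels between spot footprints,
        so spots never touch under 8-connectivity and the ground-truth
        count is unambiguous.
        """
        return 2 * self.spot_radius + 2

    @classmethod
    def from_config(cls, path) -> "ImageSimSpec":
        """Load a spec from a plain-text ``key: value`` (YAML) file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("spot_size_range", "spot_intensity_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """True spot positions and sizes of a generated image."""

    spot_centers: np.ndarray  # (n, 2) int, (row, col)
    spot_areas: np.ndarray  # (n,) int, pixels

    def __len__(self) -> int:
        return len(self.spot_centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.spot_centers[:, 0].astype(int)
                if len(self) else np.array([], dtype=int),
                "col": self.spot_centers[:, 1].astype(int)
                if len(self) else np.array([], dtype=int),
                "area_px": self.spot_areas.astype(int)
                if len(self) else np.array([], dtype=int),
            }
        )


def _spot_offsets(area: int, radius: int) -> np.ndarray:
    """First ``area`` pixel offsets of a centre-out spiral within the
    (2r+1)^2 footprint; the centre pixel is always included."""
    side = 2 * radius + 1
    rr, cc = np.meshgrid(np.arange(-radius, radius + 1), np.arange(-radius, radius + 1), indexing="ij")
    order = np.argsort(
        np.maximum(np.abs(rr), np.abs(cc)).ravel() * 1000
        + np.hypot(rr, cc).ravel() * 10
        + np.arange(side * side) * 1e-6
    )
    picks = order[:area]
    return np.stack([rr.ravel()[picks], cc.ravel()[picks]], axis=1)


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: int,
    min_sep: int,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Rejection-sample ``n`` points with pairwise Chebyshev distance >=
    ``min_sep`` (also to ``existing``), at least ``margin`` from the border."""
    h, w = shape
    if h - 2 * margin < 1 or w - 2 * margin < 1:
        raise SpotPlacementError(f"canvas {shape} too small for margin {margin}")
    placed: list[tuple[int, int]] = []
    others = existing if existing is not None and len(existing) else None
    budget = 300 * max(n, 1) + 1000
    while len(placed) < n:
        if budget <= 0:
            raise SpotPlacementError(
                f"could not place {n} spots with separation {min_sep} "
                f"on a {h} x {w} canvas"
            )
        budget -= 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        ok = True
        if placed:
            arr = np.asarray(placed)
            if np.max(np.abs(arr - (r, c)), axis=1).min() < min_sep:
                ok = False
        if ok and others is not None:
            if np.max(np.abs(others - (r, c)), axis=1).min() < min_sep:
                ok = False
        if ok:
            placed.append((r, c))
    return np.asarray(placed, dtype=int).reshape(n, 2)


def render_noiseless(spec: ImageSimSpec, truth: GroundTruth) -> np.ndarray:
    """Deterministic noise-free rendering of spots on the flat background."""
    rng = np.random.default_rng(spec.seed)  # replays the intensity stream
    img = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    intensities = rng.uniform(*spec.spot_intensity_range, size=len(truth))
    radius = spec.spot_radius
    for (r, c), area, inten in zip(truth.spot_centers, truth.spot_areas, intensities):
        off = _spot_offsets(int(area), radius)
        img[r + off[:, 0], c + off[:, 1]] = np.maximum(
            img[r + off[:, 0], c + off[:, 1]], inten
        )
    return img


def generate_image(spec: ImageSimSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic dark-field image and its ground truth.

    The raster is float64 in [0, 1]: flat background at
    ``background_level``, spots at their drawn intensity, additive Gaussian
    noise of ``noise_sigma`` clipped to the dynamic range. Identical specs
    (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    radius = spec.spot_radius
    centers = _place_points(
        rng,
        spec.n_spots,
        (spec.height, spec.width),
        margin=radius,
        min_sep=spec.min_center_separation,
    )
    lo, hi = spec.spot_size_range
    areas = rng.integers(lo, hi + 1, size=spec.n_spots)
    truth = GroundTruth(spot_centers=centers, spot_areas=areas)

    # a fresh stream with the same seed: intensities are drawn identically
    # inside render_noiseless so the noiseless render replays exactly
    img = render_noiseless(spec, truth)

    if spec.artifact_count:
        art_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
        art_radii = art_rng.integers(4, 9, size=spec.artifact_count)
        sep = 2 * int(art_radii.max()) + 2  # artifacts clear of spots and each other
        art_centers = _place_points(
            art_rng,
            spec.artifact_count,
            (spec.height, spec.width),
            margin=int(art_radii.max()),
            min_sep=sep,
            existing=centers,
        )
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        for (r, c), rad in zip(art_centers, art_radii):
            disc = (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
            img[disc] = np.maximum(img[disc], art_rng.uniform(0.3, 0.7))

    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
        img = img + noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), truth


def write_image(path, img: np.ndarray, bit_depth: int = 16) -> None:
    """Write a [0, 1] float raster as a single-channel TIFF or PNG."""
    path = str(path)
    if bit_depth == 16:
        arr = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.lower().endswith(".png"):
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image extension: {path}")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

# Published group mean precipitate counts per measuring field,
# (region, layer, blade): ER, DR, ER after wheel running, DR after wheel
# running. These parameterize the default simulated cohort.
_REFERENCE_ROWS: list[tuple[str, str, str | None, int, int, int, int]] = [
    ("DG", "oML", "spb", 224, 242, 195, 181),
    ("DG", "oML", "ipb", 217, 216, 167, 194),
    ("DG", "mML", "spb", 224, 240, 182, 182),
    ("DG", "mML", "ipb", 233, 240, 168, 184),
    ("DG", "iML", "spb", 270, 291, 205, 228),
    ("DG", "iML", "ipb", 258, 275, 190, 209),
    ("DG", "gcl", "spb", 92, 106, 70, 125),
    ("DG", "gcl", "ipb", 109, 131, 76, 129),
    ("DG", "sgl", "spb", 292, 334, 228, 265),
    ("DG", "sgl", "ipb", 344, 381, 250, 284),
    ("CA3", "So", None, 230, 265, 164, 171),
    ("CA3", "Sp", None, 91, 105, 127, 224),
    ("CA3", "Sl", None, 267, 292, 159, 208),
    ("CA3", "Sr", None, 333, 368, 221, 253),
    ("CA1", "So", None, 273, 284, 184, 169),
    ("CA1", "Sp", None, 57, 89, 62, 94),
    ("CA1", "Sr", None, 294, 302, 179, 195),
    ("CA1", "Slm", None, 335, 378, 250, 249),
    ("EC", "II", None, 213, 170, 201, 202),
    ("EC", "III", None, 269, 219, 195, 196),
    ("SUB", "III", None, 250, 267, 224, 237),
]

GROUPS: tuple[tuple[str, str], ...] = (
    ("ER", "no"),
    ("DR", "no"),
    ("ER", "yes"),
    ("DR", "yes"),
)

#: (region, layer, blade, rearing, wheel) -> mean precipitate count.
DEFAULT_GROUP_MEANS: dict[tuple[str, str, str | None, str, str], float] = {
    (region, layer, blade, rearing, wheel): float(value)
    for (region, layer, blade, er, dr, erw, drw) in _REFERENCE_ROWS
    for (rearing, wheel), value in zip(GROUPS, (er, dr, erw, drw))
}

#: Study design: 25 animals, 13 enriched- and 12 deprived-reared, of which
#: 6 and 5 respectively ran wheels in adulthood.
DEFAULT_N_PER_GROUP: dict[tuple[str, str], int] = {
    ("ER", "no"): 7,
    ("ER", "yes"): 6,
    ("DR", "no"): 7,
    ("DR", "yes"): 5,
}

#: Sections sampled per animal, by region.
DEFAULT_SECTIONS_PER_ANIMAL: dict[str, tuple[int, int]] = {
    "DG": (14, 20),
    "CA3": (14, 20),
    "CA1": (14, 20),
    "SUB": (6, 8),
    "EC": (6, 8),
}


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a simulated count cohort.

    ``animal_sd`` is a per-animal offset shared across all of that animal's
    layers (between-animal variability); ``section_sd`` is independent
    section-to-section noise. Counts are rounded and truncated at zero.
    """

    group_means: dict[tuple[str, str, str | None, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS)
    )
    animal_sd: float = 40.0
    section_sd: float = 60.0
    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    sections_per_animal: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SECTIONS_PER_ANIMAL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_means:
            raise ValueError("group_means must not be empty")
        if any(m < 0 for m in self.group_means.values()):
            raise ValueError("group means must be >= 0")
        if self.animal_sd < 0 or self.section_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("each group needs >= 2 animals")
        for region, (lo, hi) in self.sections_per_animal.items():
            if not (1 <= lo <= hi):
                raise ValueError(f"bad section range for {region}: {(lo, hi)}")

    @property
    def labels(self) -> list[tuple[str, str, str | None]]:
        """Distinct (region, layer, blade) keys covered by group_means."""
        seen: dict[tuple[str, str, str | None], None] = {}
        for region, layer, blade, _, _ in self.group_means:
            seen.setdefault((region, layer, blade))
        return list(seen)

    @classmethod
    def from_config(cls, path) -> "CohortSimSpec":
        """Load a cohort spec from a YAML config.

        ``group_means`` entries are ``region/layer[/blade]/rearing/wheel``
        keys mapping to means; omitted, the published defaults are used.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "group_means" in raw:
            means = {}
            for key, value in raw["group_means"].items():
                parts = key.split("/")
                if len(parts) == 4:
                    region, layer, rearing, wheel = parts
                    blade = None
                else:
                    region, layer, blade, rearing, wheel = parts
                means[(region, layer, blade, rearing, wheel)] = float(value)
            raw["group_means"] = means
        if "n_per_group" in raw:
            raw["n_per_group"] = {
                tuple(k.split("/")): int(v) for k, v in raw["n_per_group"].items()
            }
        if "sections_per_animal" in raw:
            raw["sections_per_animal"] = {
                k: tuple(v) for k, v in raw["sections_per_animal"].items()
            }
        return cls(**raw)


COUNT_COLUMNS = [
    "animal_id",
    "rearing",
    "wheel",
    "section_id",
    "region",
    "layer",
    "blade",
    "count",
]


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate one cohort; returns a tidy count table.

    One row per animal x section x (region, layer, blade). Per-group sample
    means converge to ``spec.group_means`` as the number of animals grows.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels
    regions = sorted({region for region, _, _ in labels})
    for region, layer, blade, *_ in spec.group_means:
        LayerLabel(region, layer, blade)  # validates the taxonomy
    for (region, layer, blade) in labels:
        for rearing, wheel in spec.n_per_group:
            if (region, layer, blade, rearing, wheel) not in spec.group_means:
                raise KeyError(
                    f"missing group mean for cell "
                    f"{(region, layer, blade, rearing, wheel)}"
                )
    rows: list[tuple] = []
    for (rearing, wheel), n_animals in spec.n_per_group.items():
        for a in range(n_animals):
            animal_id = f"{rearing}{'W' if wheel == 'yes' else ''}-{a + 1:02d}"
            offset = rng.normal(0.0, spec.animal_sd) if spec.animal_sd else 0.0
            for region in regions:
                lo, hi = spec.sections_per_animal.get(region, (1, 1))
                n_sec = int(rng.integers(lo, hi + 1))
                region_labels = [lab for lab in labels if lab[0] == region]
                for s in range(n_sec):
                    section_id = f"{animal_id}-{region}-s{s + 1:02d}"
                    for (reg, layer, blade) in region_labels:
                        mean = spec.group_means[(reg, layer, blade, rearing, wheel)]
                        noise = (
                            rng.normal(0.0, spec.section_sd)
                            if spec.section_sd
                            else 0.0
                        )
                        count = max(0.0, round(mean + offset + noise))
                        rows.append(
                            (
                                animal_id,
                                rearing,
                                wheel,
                                section_id,
                                reg,
                                layer,
                                blade,
                                int(count),
                            )
                        )
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    df["blade"] = df["blade"].astype(object).where(df["blade"].notna(), None)
    return df
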