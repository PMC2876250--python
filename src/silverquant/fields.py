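"""Laminar taxonomy and measuring-field geometry.

A measuring field is the counting ROI used for laminar quantification:
three rectangular subfields of 200 x h pixels joined edge to edge into a
600 x h strip (h defaults to 50 and is fitted per section to the thickness
of the cell layer). Fields are placed manually per section by anchor and
orientation; automated anatomical registration is out of scope.

Pixel conventions: 0-based row-major coordinates, rectangles half-open
``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

SUBFIELD_WIDTH = 200
N_SUBFIELDS = 3
DEFAULT_HEIGHT = 50

#: Region -> ordered layer names. DG layers exist in both blades.
REGION_LAYERS: dict[str, tuple[str, ...]] = {
    "DG": ("oML", "mML", "iML", "gcl", "sgl"),
    "CA3": ("So", "Sp", "Sl", "Sr"),
    "CA1": ("So", "Sp", "Sr", "Slm"),
    "EC": ("II", "III"),
    "SUB": ("III",),
}

#: Dentate gyrus blades: suprapyramidal and infrapyramidal.
DG_BLADES = ("spb", "ipb")

#: Region order used in reports.
REGION_ORDER = ("DG", "CA3", "CA1", "EC", "SUB")


class PlacementError(ValueError):
    """A measuring field (or one of its subfields) falls outside the image."""


@dataclass(frozen=True)
class LayerLabel:
    """Identity of one laminar measuring position.

    ``blade`` distinguishes the suprapyramidal ("spb") / infrapyramidal
    ("ipb") blades of the dentate gyrus and is ``None`` elsewhere.
    """

    region: str
    layer: str
    blade: str | None = None

    def __post_init__(self) -> None:
        if self.region not in REGION_LAYERS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.layer not in REGION_LAYERS[self.region]:
            raise ValueError(f"unknown layer {self.layer!r} for region {self.region}")
        if self.region == "DG":
            if self.blade not in DG_BLADES:
                raise ValueError("DG labels require blade 'spb' or 'ipb'")
        elif self.blade is not None:
            raise ValueError(f"blade must be None outside DG, got {self.blade!r}")

    def __str__(self) -> str:  # e.g. "DG/iML/spb", "CA1/Sr"
        parts = [self.region, self.layer] + ([self.blade] if self.blade else [])
        return "/".join(parts)


def enumerate_fields(region: str) -> list[LayerLabel]:
    """All measuring-field labels of one region, in report order.

    DG yields 10 labels (5 layers x 2 blades), CA3 and CA1 four strata
    each, the subiculum one field (layer III) and the entorhinal cortex
    two (laminae II and III).
    """
    if region not in REGION_LAYERS:
        raise ValueError(f"unknown region {region!r}")
    if region == "DG":
        return [
            LayerLabel(region, layer, blade)
            for layer in REGION_LAYERS[region]
            for blade in DG_BLADES
        ]
    return [LayerLabel(region, layer) for layer in REGION_LAYERS[region]]


def all_labels() -> list[LayerLabel]:
    """The full 21-label taxonomy over all five regions."""
    out: list[LayerLabel] = []
    for region in REGION_ORDER:
        out.extend(enumerate_fields(region))
    return out


@dataclass(frozen=True)
class MeasuringField:
    """A placed measuring field: three joined 200 x height subfields.

    The unrotated footprint spans rows ``[anchor_row, anchor_row+height)``
    and columns ``[anchor_col, anchor_col + 600)``; a nonzero orientation
    rotates that footprint about the anchor (counter-clockwise, degrees).
    """

    label: LayerLabel
    anchor: tuple[float, float]
    height: int = DEFAULT_HEIGHT
    orientation: float = 0.0
    subfield_width: int = field(default=SUBFIELD_WIDTH)

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError("height must be >= 1 pixel")
        if self.subfield_width < 1:
            raise ValueError("subfield width must be >= 1 pixel")

    @property
    def width(self) -> int:
        return N_SUBFIELDS * self.subfield_width

    @property
    def pixel_count(self) -> int:
        return N_SUBFIELDS * self.subfield_width * self.height

    @property
    def footprint_shape(self) -> tuple[int, int]:
        """(rows, cols) of the field raster in its own frame."""
        return (self.height, self.width)

    def subfield_slices(self) -> list[tuple[slice, slice]]:
        """Half-open (row, col) slices of the three subfields, field frame."""
        return [
            (
                slice(0, self.height),
                slice(i * self.subfield_width, (i + 1) * self.subfield_width),
            )
            for i in range(N_SUBFIELDS)
        ]

    def _sample_coords(self) -> np.ndarray:
        """Image coordinates of every field pixel, shape (2, height, width)."""
        rr, cc = np.meshgrid(
            np.arange(self.height, dtype=float),
            np.arange(self.width, dtype=float),
            indexing="ij",
        )
        theta = np.deg2rad(self.orientation)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        # rotate the (row, col) offsets about the anchor; rows grow downward,
        # so a CCW rotation in display space maps (dr, dc) -> image offsets
        r = self.anchor[0] + rr * cos_t - cc * sin_t
        c = self.anchor[1] + rr * sin_t + cc * cos_t
        return np.stack([r, c])

    def check_within(self, image_shape: tuple[int, int]) -> None:
        """Raise :class:`PlacementError` naming the first offending subfield."""
        coords = self._sample_coords()
        h, w = image_shape[:2]
        bad = (
            (coords[0] < -0.5)
            | (coords[0] > h - 0.5)
            | (coords[1] < -0.5)
            | (coords[1] > w - 0.5)
        )
        for i, (rs, cs) in enumerate(self.subfield_slices()):
            if bad[rs, cs].any():
                raise PlacementError(
                    f"subfield {i + 1} of field {self.label} at anchor "
                    f"{self.anchor} (orientation {self.orientation} deg) exceeds "
                    f"image bounds {image_shape[:2]}"
                )

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Resample the field's pixels from ``image`` into a height x 600 raster.

        Sampling is nearest-neighbour so intensities are never interpolated;
        for axis-aligned integer placements (orientation a multiple of 90 deg)
        every sample lands exactly on a pixel centre and the extraction is
        exact. The unrotated integer case is a plain array slice.
        """
        self.check_within(image.shape)
        r0, c0 = self.anchor
        if (
            self.orientation == 0.0
            and float(r0).is_integer()
            and float(c0).is_integer()
        ):
            r0, c0 = int(r0), int(c0)
            return image[r0 : r0 + self.height, c0 : c0 + self.width].copy()
        coords = self._sample_coords()
        return ndimage.map_coordinates(image, coords, order=0, mode="nearest")


def build_field(
    label: LayerLabel,
    anchor: tuple[float, float],
    height: int = DEFAULT_HEIGHT,
    orientation: float = 0.0,
    image_shape: tuple[int, int] | None = None,
) -> MeasuringField:
    """Place a measuring field at ``anchor`` and optionally bounds-check it."""
    fld = MeasuringField(label=label, anchor=anchor, height=height, orientation=orientation)
    if image_shape is not None:
        fld.check_within(image_shape)
    return fld


PLACEMENT_COLUMNS = [
    "section_id",
    "region",
    "layer",
    "blade",
    "anchor_row",
    "anchor_col",
    "height",
    "orientation_deg",
]


def read_placements(path) -> pd.DataFrame:
    """Read a field-placement table (CSV with header) and validate labels."""
    df = pd.read_csv(path, dtype={"section_id": str})
    missing = [c for c in PLACEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"placement table missing columns: {missing}")
    df["blade"] = df["blade"].where(pd.notna(df["blade"]), None)
    for _, row in df.iterrows():
        LayerLabel(row["region"], row["layer"], row["blade"] or None)
    return df


def placements_to_fields(df: pd.DataFrame) -> list[tuple[str, MeasuringField]]:
    """Turn a placement table into (section_id, MeasuringField) pairs."""
    out = []
    for _, row in df.iterrows():
        label = LayerLabel(row["region"], row["layer"], row["blade"] or None)
        fld = build_field(
            label,
            (float(row["anchor_row"]), float(row["anchor_col"])),
            height=int(row["height"]),
            orientation=float(row["orientation_deg"]),
        )
        out.append((row["section_id"], fld))
    return out
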