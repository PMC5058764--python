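"""Tumour and gland volumetry from whole-mount section planimetry.

Tumour volume is estimated by Cavalieri summation over serial transverse
whole-mount sections: the tumour cross-sectional area outlined on each slide
is multiplied by the sectioning interval and summed base to apex, then scaled
by a multiplicative correction for formalin-induced tissue shrinkage.
Gland volume is estimated from three orthogonal calliper dimensions with the
ellipsoid formula.

Units are fixed: section areas in mm^2, section spacing in mm, gland
dimensions in cm; all returned volumes are in cc (cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sectioning interval used for routine whole-mount processing (mm).
DEFAULT_SPACING_MM = 3.5
#: Multiplicative correction for formalin-induced shrinkage.
DEFAULT_SHRINKAGE_FACTOR = 1.25

_MM3_PER_CC = 1000.0


@dataclass(frozen=True)
class SectionStack:
    """Serial tumour cross-sections of one case, ordered base to apex.

    Parameters
    ----------
    section_areas
        Tumour cross-sectional area on each section, mm^2.
    spacing_mm
        Inter-section interval, mm. Each section represents a full slab of
        this thickness (no half-weighting of the terminal sections).
    shrinkage_factor
        Dimensionless multiplicative correction (>= 1) applied to the raw
        Cavalieri sum to undo fixation shrinkage.
    """

    section_areas: Sequence[float]
    spacing_mm: float = DEFAULT_SPACING_MM
    shrinkage_factor: float = DEFAULT_SHRINKAGE_FACTOR

    def __post_init__(self) -> None:
        areas = np.asarray(self.section_areas, dtype=float)
        if areas.ndim != 1 or areas.size == 0:
            raise ValidationError("section_areas must be a non-empty 1-D sequence")
        if np.any(~np.isfinite(areas)) or np.any(areas < 0):
            raise ValidationError("section areas must be finite and >= 0")
        if not np.isfinite(self.spacing_mm) or self.spacing_mm <= 0:
            raise ValidationError(f"spacing must be > 0, got {self.spacing_mm}")
        if not np.isfinite(self.shrinkage_factor) or self.shrinkage_factor < 1:
            raise ValidationError(
                f"shrinkage_factor must be >= 1, got {self.shrinkage_factor}"
            )


@dataclass(frozen=True)
class GlandDimensions:
    """Orthogonal prostate dimensions in cm (length, width, height)."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "height"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


def tumour_volume_from_sections(stack: SectionStack) -> float:
    """Cavalieri tumour volume (cc) with shrinkage correction.

    volume = (sum of areas * spacing) * shrinkage_factor / 1000, converting
    mm^3 to cc. Linear in every area and in the spacing; with
    ``shrinkage_factor=1`` this is the plain Cavalieri sum.
    """
    areas = np.asarray(stack.section_areas, dtype=float)
    raw_mm3 = float(areas.sum()) * stack.spacing_mm
    return raw_mm3 * stack.shrinkage_factor / _MM3_PER_CC


def ellipsoid_volume(dims: GlandDimensions) -> float:
    """Ellipsoid gland volume (cc): pi/6 * length * width * height."""
    return pi / 6.0 * dims.length * dims.width * dims.height


def read_section_table(
    path,
    spacing_mm: float = DEFAULT_SPACING_MM,
    shrinkage_factor: float = DEFAULT_SHRINKAGE_FACTOR,
) -> pd.Series:
    """Read a per-section TSV and return per-case tumour volumes (cc).

    The table has one row per section with columns ``case_id``,
    ``section_index`` and ``area_mm2``. Sections of a case are summed in
    ``section_index`` order (the order does not change the volume).
    """
    table = pd.read_csv(path, sep="\t")
    required = {"case_id", "section_index", "area_mm2"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"section table missing columns: {sorted(missing)}")
    volumes = {}
    for case_id, group in table.sort_values("section_index").groupby("case_id"):
        stack = SectionStack(
            group["area_mm2"].to_numpy(),
            spacing_mm=spacing_mm,
            shrinkage_factor=shrinkage_factor,
        )
        volumes[case_id] = tumour_volume_from_sections(stack)
    return pd.Series(volumes, name="tumour_volume_cc").rename_axis("case_id")
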