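"""Estimated retinal ganglion cell (eRGC) counts from perimetry and OCT.

Implements the combined structure–function RGC estimator used as the
glaucoma-severity outcome: a perimetry-based count (SAPrgc) obtained by
converting each visual-field sensitivity to a local ganglion cell
density via eccentricity-dependent linear maps and summing, an
OCT-based count (OCTrgc) obtained from mean circumpapillary RNFL
thickness with an age-dependent axon density and a mean-deviation
correction, and a final MD-weighted combination:

    eRGC = (1 + MD/30) * OCTrgc - (MD/30) * SAPrgc

which moves weight from the structural (OCT) estimate toward the
functional (SAP) estimate as field loss deepens over MD in [-30, 0] dB.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DomainError, EmptyFieldError

logger = logging.getLogger(__name__)

# Scan geometry constants of the circumpapillary RNFL circle scan:
# 21.2 px per unit length over a 10.87 mm (10870 um) scan circumference.
PIXELS_PER_UNIT = 21.2
SCAN_LENGTH_UM = 10870.0


def grid_24_2(exclude_blind_spot: bool = True) -> list[tuple[float, float]]:
    """Test-point coordinates (x, y in degrees) of the 24-2 perimetry pattern.

    Right-eye orientation: 54 points on a 6-degree lattice offset 3
    degrees from the meridians, with the nasal column extending to 27
    degrees. With ``exclude_blind_spot`` the two points at (15, +/-3)
    overlying the optic nerve head are dropped, leaving 52.
    """
    pts: list[tuple[float, float]] = []
    rows = {
        21: (-9, -3, 3, 9),
        15: (-15, -9, -3, 3, 9, 15),
        9: (-21, -15, -9, -3, 3, 9, 15, 21),
        3: (-21, -15, -9, -3, 3, 9, 15, 21, 27),
    }
    for ay, xs in rows.items():
        for y in (ay, -ay):
            for x in xs:
                pts.append((float(x), float(y)))
    if exclude_blind_spot:
        pts = [p for p in pts if p not in ((15.0, 3.0), (15.0, -3.0))]
    return sorted(pts, key=lambda p: (-p[1], p[0]))


@dataclass(frozen=True)
class FieldLocation:
    """One perimetry test location: eccentricity (degrees) and sensitivity (dB)."""

    ec: float
    s: float

    def __post_init__(self) -> None:
        if self.ec < 0:
            raise ValueError("eccentricity must be non-negative")
        if not -2.0 <= self.s <= 50.0:
            raise ValueError(f"sensitivity {self.s} dB outside perimeter dynamic range [-2, 50]")


@dataclass(frozen=True)
class VisualField:
    """A visual field test: K locations plus the global mean deviation (dB)."""

    locations: tuple[FieldLocation, ...]
    md: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "locations", tuple(self.locations))

    @classmethod
    def from_grid(
        cls, sensitivities: Sequence[float], md: float,
        coords: Sequence[tuple[float, float]] | None = None,
    ) -> "VisualField":
        """Build a field from per-point sensitivities on a coordinate grid
        (default: the 52-point 24-2 grid with blind spot excluded)."""
        if coords is None:
            coords = grid_24_2()
        if len(sensitivities) != len(coords):
            raise ValueError(
                f"{len(sensitivities)} sensitivities for {len(coords)} grid points"
            )
        locs = tuple(
            FieldLocation(ec=math.hypot(x, y), s=float(s))
            for (x, y), s in zip(coords, sensitivities)
        )
        return cls(locations=locs, md=float(md))


@dataclass(frozen=True)
class OCTSummary:
    """OCT-derived inputs: mean circumpapillary RNFL thickness (µm) and age (years).

    ``section_heights``/``section_px`` enable the sectionwise axon-count
    mode (per-section mean height mh in µm and length px in pixels);
    when absent the mean-RNFL closed form is used.
    """

    rnfl: float
    age: float
    section_heights: tuple[float, ...] | None = None
    section_px: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.rnfl <= 0:
            raise DomainError("mean RNFL thickness must be positive")
        if not 18 <= self.age <= 120:
            raise DomainError(f"age {self.age} outside supported range [18, 120]")


@dataclass(frozen=True)
class RGCEstimate:
    """Full eRGC estimate with per-stage intermediates for auditability."""

    sap_rgc: float
    oct_rgc: float
    ergc: float
    md: float
    d: float
    c: float
    gl: tuple[float, ...]
    m: tuple[float, ...]
    b: tuple[float, ...]
    a: float | None = None  # sectionwise total axon count, when computed

    def to_dict(self) -> dict:
        out = {
            "sap_rgc": self.sap_rgc,
            "oct_rgc": self.oct_rgc,
            "ergc": self.ergc,
            "md": self.md,
            "axon_density_d": self.d,
            "md_correction_c": self.c,
            "gl_per_location": list(self.gl),
            "m_per_location": list(self.m),
            "b_per_location": list(self.b),
        }
        if self.a is not None:
            out["axon_count_a"] = self.a
        return out


def gl_coefficients_human(ec: float) -> tuple[float, float]:
    """Slope m and intercept b of the human/SITA sensitivity-to-density map."""
    return 0.07128 * ec + 0.91, -1.98 * ec - 14.8


def gl_human(s: float, ec: float) -> float:
    """Local RGC density loss gl (dB) for a human SITA sensitivity.

    gl = (s - 1 - b)/m + 4.7 with m = 0.07128 ec + 0.91 and
    b = -1.98 ec - 14.8; the -1 dB and +4.7 dB offsets carry the
    full-threshold-to-SITA and eye-size translations from the primate map.
    """
    if ec < 0:
        raise DomainError("eccentricity must be non-negative")
    m, b = gl_coefficients_human(ec)
    return (s - 1.0 - b) / m + 4.7


def gl_primate(s: float, ec: float) -> float:
    """Local RGC density (dB) under the original non-human-primate map:
    m = 0.054 ec + 0.91, b = -1.5 ec - 14.8, gl = (s - b)/m."""
    if ec < 0:
        raise DomainError("eccentricity must be non-negative")
    m = 0.054 * ec + 0.91
    b = -1.5 * ec - 14.8
    return (s - b) / m


def sap_rgc_count(fieldv: VisualField) -> float:
    """Perimetry-based total RGC count: sum over locations of 10^(0.1 gl_k)."""
    if not fieldv.locations:
        raise EmptyFieldError("visual field has no test locations")
    return float(sum(10 ** (0.1 * gl_human(loc.s, loc.ec)) for loc in fieldv.locations))


def axon_density(age: float) -> float:
    """Age-dependent RGC axon density d (axons/µm²): d = -0.007 age + 1.4."""
    d = -0.007 * age + 1.4
    if d <= 0:
        raise DomainError(f"axon density non-positive at age {age}")
    return d


def md_correction(md: float) -> float:
    """Mean-deviation correction c (dB) for glaucomatous RNFL remodelling:
    c = -0.26 MD + 0.12."""
    return -0.26 * md + 0.12


def sectionwise_axon_count(
    section_heights: Sequence[float], section_px: Sequence[float], age: float
) -> float:
    """Total axon count from per-section scan data: a = sum 21.2 mh px d."""
    if len(section_heights) != len(section_px):
        raise ValueError("section heights and pixel lengths differ in length")
    d = axon_density(age)
    return float(sum(PIXELS_PER_UNIT * mh * px * d for mh, px in zip(section_heights, section_px)))


def oct_rgc_count(oct_summary: OCTSummary, md: float) -> float:
    """OCT-based RGC count from mean RNFL thickness.

    Computed in the printed log form
    OCTrgc = 10^{0.1 [10 log10(10870 d rnfl) - c]}, which simplifies to
    (10870 d rnfl) 10^(-0.1 c); both agree to machine precision and the
    log form is used.
    """
    d = axon_density(oct_summary.age)
    c = md_correction(md)
    return 10 ** (0.1 * (10 * math.log10(SCAN_LENGTH_UM * d * oct_summary.rnfl) - c))


def combine_ergc(md: float, oct_rgc: float, sap_rgc: float) -> float:
    """MD-weighted combination of the OCT and SAP counts.

    eRGC = (1 + MD/30) OCTrgc - (MD/30) SAPrgc. The weights sum to 1;
    for MD in [-30, 0] this is a convex combination (MD=0 gives the OCT
    count, MD=-30 the SAP count). MD outside that range is clamped with
    a warning.
    """
    if not -30.0 <= md <= 0.0:
        logger.warning("MD %.2f dB outside [-30, 0]; clamped for eRGC weighting", md)
        md = min(0.0, max(-30.0, md))
    w = md / 30.0
    return (1.0 + w) * oct_rgc - w * sap_rgc


def ergc_from_inputs(fieldv: VisualField, oct_summary: OCTSummary) -> RGCEstimate:
    """Full eRGC estimate from a visual field and an OCT summary.

    Populates every intermediate (per-location slope m_k, intercept
    b_k, density gl_k; axon density d; MD correction c; both counts)
    so the estimate can be audited stage by stage.
    """
    if not fieldv.locations:
        raise EmptyFieldError("visual field has no test locations")
    m, b, gl = [], [], []
    for loc in fieldv.locations:
        mk, bk = gl_coefficients_human(loc.ec)
        m.append(mk)
        b.append(bk)
        gl.append(gl_human(loc.s, loc.ec))
    sap = float(np.sum(10 ** (0.1 * np.asarray(gl))))
    octc = oct_rgc_count(oct_summary, fieldv.md)
    a = None
    if oct_summary.section_heights is not None and oct_summary.section_px is not None:
        a = sectionwise_axon_count(
            oct_summary.section_heights, oct_summary.section_px, oct_summary.age
        )
    return RGCEstimate(
        sap_rgc=sap,
        oct_rgc=octc,
        ergc=combine_ergc(fieldv.md, octc, sap),
        md=fieldv.md,
        d=axon_density(oct_summary.age),
        c=md_correction(fieldv.md),
        gl=tuple(gl),
        m=tuple(m),
        b=tuple(b),
        a=a,
    )
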