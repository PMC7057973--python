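"""Allometric conversion of measured dimensions to biomass.

The chain is: length/width [mm] -> biovolume [mm^3] -> wet mass [mg]
-> dry mass [ug].  Biovolume uses the Feller-Warwick shape formula
``V = L * W^2 * c`` for most soft-bodied taxa and a cylinder for
nematodes.  Wet mass applies a tissue specific gravity of 1.13 (so a
1 mm^3 biovolume weighs 1.13 mg); dry mass is 0.25 * WM for meiofauna
and macrofaunal nematodes, and a taxon-specific DM/WM factor for
macrofauna.  Crustaceans and ophiuroids may bypass the biovolume route
through a configured length -> WM regression.

Fragmented polychaetes get their intact length back from a per-taxon
linear calibration of body length on the width of a designated
chaetiger, fitted on intact specimens.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import ConversionConfig, ConversionError, OrganismRecord, StationSample

__all__ = [
    "MG_TO_UG",
    "FragmentCalibration",
    "biovolume_feller_warwick",
    "biovolume_cylinder",
    "wet_mass",
    "dry_mass",
    "direct_wet_mass",
    "fit_fragment_calibration",
    "estimate_fragment_length",
    "expand_subsample",
    "area_factor",
    "record_dry_mass",
    "convert_sample",
]

#: The single mg -> ug conversion point for wet mass.
MG_TO_UG = 1000.0

#: Taxa measured as cylinders rather than with the shape-coefficient formula.
CYLINDER_TAXA = frozenset({"nematoda"})


class MissingCalibrationError(ConversionError):
    """A fragmented specimen has no length calibration for its taxon."""


@dataclass(frozen=True)
class FragmentCalibration:
    """Linear model predicting intact body length (mm) from chaetiger width (mm)."""

    taxon: str
    slope: float
    intercept: float
    n_calibration: int
    r2: float
    chaetiger_index: int | None = None

    def __post_init__(self) -> None:
        if self.n_calibration < 5:
            raise ValueError(
                f"fragment calibration for {self.taxon!r} needs >= 5 intact "
                f"specimens, got {self.n_calibration}"
            )
        if not self.slope > 0:
            raise ValueError(
                f"fragment calibration slope must be positive, got {self.slope}"
            )
        if not 0 <= self.r2 <= 1:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")


def biovolume_feller_warwick(length_mm: float, width_mm: float, c: float) -> float:
    """Biovolume V = L * W^2 * c in mm^3."""
    if not (length_mm > 0 and width_mm > 0 and c > 0):
        raise ValueError(
            f"length_mm, width_mm and c must be positive, got "
            f"({length_mm}, {width_mm}, {c})"
        )
    return length_mm * width_mm**2 * c


def biovolume_cylinder(length_mm: float, width_mm: float) -> float:
    """Cylinder volume pi * (W/2)^2 * L in mm^3 (nematodes)."""
    if not (length_mm > 0 and width_mm > 0):
        raise ValueError(
            f"length_mm and width_mm must be positive, got ({length_mm}, {width_mm})"
        )
    return math.pi * (width_mm / 2.0) ** 2 * length_mm


def wet_mass(volume_mm3: float, specific_gravity: float = 1.13) -> float:
    """Wet mass in mg from biovolume in mm^3 (1 mm^3 water-equivalent = 1 mg)."""
    if not volume_mm3 > 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return volume_mm3 * specific_gravity


def dry_mass(record: OrganismRecord, wm_ug: float, config: ConversionConfig) -> float:
    """Dry mass in ug from wet mass in ug.

    Meiofauna and macrofaunal nematodes use the fixed DM = 0.25 * WM
    fraction; macrofauna use the configured taxon DM/WM factor.
    """
    if not wm_ug > 0:
        raise ValueError(f"wet mass must be positive, got {wm_ug}")
    if record.group in ("meiofauna", "macrofaunal_nematode"):
        return config.meiofauna_dm_fraction * wm_ug
    return config.dm_factor_for(record) * wm_ug


def direct_wet_mass(record: OrganismRecord, config: ConversionConfig) -> float | None:
    """WM in ug from a configured length regression, or None if not configured.

    Entries take the form ``{"slope_ug_per_mm": a, "intercept_ug": b}``;
    WM = b + a * L.  Used for taxa (Crustacea, Ophiuroidea) with published
    dimension-to-mass factors that skip the biovolume route.
    """
    entry = config.direct_mass_entry(record)
    if entry is None:
        return None
    wm = entry.get("intercept_ug", 0.0) + entry["slope_ug_per_mm"] * record.length_mm
    if not wm > 0:
        raise ConversionError(
            f"direct mass regression for {record.taxon_id!r} yields "
            f"non-positive WM ({wm} ug) at L={record.length_mm} mm"
        )
    return wm


def fit_fragment_calibration(
    taxon: str,
    widths_mm: Sequence[float],
    lengths_mm: Sequence[float],
    chaetiger_index: int | None = None,
) -> FragmentCalibration:
    """OLS of intact body length on chaetiger width for one taxon."""
    w = np.asarray(widths_mm, dtype=float)
    length = np.asarray(lengths_mm, dtype=float)
    if w.shape != length.shape or w.ndim != 1:
        raise ValueError("widths and lengths must be 1-D and the same size")
    if w.size < 5:
        raise ValueError(
            f"fragment calibration for {taxon!r} needs >= 5 intact specimens, "
            f"got {w.size}"
        )
    res = stats.linregress(w, length)
    return FragmentCalibration(
        taxon=taxon,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_calibration=int(w.size),
        r2=float(res.rvalue**2),
        chaetiger_index=chaetiger_index,
    )


def estimate_fragment_length(width_mm: float, calibration: FragmentCalibration) -> float:
    """Predicted intact length L = intercept + slope * width; must be positive."""
    if not width_mm > 0:
        raise ValueError(f"width must be positive, got {width_mm}")
    length = calibration.intercept + calibration.slope * width_mm
    if not length > 0:
        raise ConversionError(
            f"fragment length prediction for {calibration.taxon!r} is "
            f"non-positive ({length} mm) at width {width_mm} mm"
        )
    return length


def expand_subsample(
    measured: Sequence[OrganismRecord], total_count: float
) -> list[OrganismRecord]:
    """Scale subsample representatives up to the full per-sample count.

    When a species is too abundant to measure exhaustively, a fixed-size
    random subsample is measured; each measured record's ``count_weight``
    is then multiplied by ``total_count / n_measured`` so that summed
    weights reproduce the counted total exactly.
    """
    n = len(measured)
    if n == 0:
        raise ValueError("no measured records to expand")
    if total_count < n:
        raise ValueError(
            f"total_count ({total_count}) is smaller than the number of "
            f"measured records ({n})"
        )
    factor = total_count / n
    return [replace(r, count_weight=r.count_weight * factor) for r in measured]


def area_factor(sampled_area_cm2: float) -> float:
    """Multiplier standardising per-sample quantities to 0.1 m^2 (= 1000 cm^2)."""
    if not sampled_area_cm2 > 0:
        raise ValueError(f"sampled area must be positive, got {sampled_area_cm2}")
    return 1000.0 / sampled_area_cm2


def record_dry_mass(
    record: OrganismRecord,
    config: ConversionConfig,
    calibrations: Mapping[str, FragmentCalibration] | None = None,
) -> float:
    """Dry mass in ug for one record, running the full conversion chain."""
    if record.dry_mass_ug is not None:
        return record.dry_mass_ug

    length = record.length_mm
    if record.is_fragment:
        cal = (calibrations or {}).get(record.taxon_id.lower())
        if cal is None:
            raise MissingCalibrationError(
                f"no fragment-length calibration for taxon {record.taxon_id!r}"
            )
        length = estimate_fragment_length(record.width_mm, cal)

    wm_ug = direct_wet_mass(record, config)
    if wm_ug is None:
        if record.taxon_id.lower() in CYLINDER_TAXA:
            volume = biovolume_cylinder(length, record.width_mm)
        else:
            volume = biovolume_feller_warwick(
                length, record.width_mm, config.coefficient_for(record)
            )
        wm_ug = wet_mass(volume, config.specific_gravity) * MG_TO_UG
    return dry_mass(record, wm_ug, config)


def convert_sample(
    sample: StationSample,
    config: ConversionConfig | None = None,
    calibrations: Mapping[str, FragmentCalibration] | None = None,
) -> StationSample:
    """Return a copy of ``sample`` with ``dry_mass_ug`` filled on every record.

    Fragments lacking a length calibration are excluded with a warning
    rather than aborting the sample.
    """
    config = config or ConversionConfig()
    out: list[OrganismRecord] = []
    for rec in sample.records:
        try:
            dm = record_dry_mass(rec, config, calibrations)
        except MissingCalibrationError as exc:
            warnings.warn(f"{exc}; record excluded", stacklevel=2)
            continue
        out.append(replace(rec, dry_mass_ug=dm))
    return replace(sample, records=out)
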