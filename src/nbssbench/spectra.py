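"""Log2 dry-mass size classes and (normalized) biomass size spectra.

An organism of dry mass ``m`` ug belongs to the integer size class ``n``
with ``2**n <= m < 2**(n+1)``; class 4 spans [16, 32) ug and has width
16 ug.  A spectrum maps populated classes to abundance and biomass per
0.1 m^2; empty classes are absent, not zero.  Normalizing divides each
class's biomass by its width 2**n, which makes an equal-biomass spectrum
fall off with slope exactly -1 on a log2 axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import area_factor
from .data_model import StationSample

__all__ = [
    "ClassBin",
    "SizeSpectrum",
    "NormalizedSpectrum",
    "size_class",
    "size_classes",
    "class_width",
    "build_spectrum",
    "combine_components",
    "normalize",
    "pool_stations",
    "total_benthic_dm",
    "spectra_table",
]


def size_class(dm_ug: float) -> int:
    """Size class index n with 2**n <= dm_ug < 2**(n+1).

    Uses the float's binary exponent (``math.frexp``) so the boundary at
    exact powers of two is bit-exact: 16 ug is class 4, not 3.
    """
    if not dm_ug > 0:
        raise ValueError(f"dry mass must be positive, got {dm_ug}")
    mantissa, exponent = math.frexp(dm_ug)  # dm = mantissa * 2**exponent, 0.5 <= mantissa < 1
    return exponent - 1


def size_classes(dm_ug: Sequence[float]) -> np.ndarray:
    """Vectorised :func:`size_class`."""
    m = np.asarray(dm_ug, dtype=float)
    if np.any(~(m > 0)):
        raise ValueError("dry masses must all be positive")
    _, exponent = np.frexp(m)
    return exponent.astype(int) - 1


def class_width(n: int) -> float:
    """Width of size class n: 2**n ug."""
    return 2.0**n


@dataclass(frozen=True)
class ClassBin:
    abundance: float
    biomass_ug: float

    def __add__(self, other: "ClassBin") -> "ClassBin":
        return ClassBin(self.abundance + other.abundance, self.biomass_ug + other.biomass_ug)


@dataclass
class SizeSpectrum:
    """Per-station (or pooled) size spectrum, standardised to 0.1 m^2."""

    classes: dict[int, ClassBin]
    fjord_id: str | None = None
    station_id: str | None = None
    components: tuple[str, ...] = ()

    @property
    def support(self) -> list[int]:
        return sorted(self.classes)

    @property
    def total_biomass_ug(self) -> float:
        return sum(b.biomass_ug for b in self.classes.values())

    @property
    def total_abundance(self) -> float:
        return sum(b.abundance for b in self.classes.values())

    def truncate(self, lo: int, hi: int) -> "SizeSpectrum":
        """Restrict the spectrum to classes lo..hi inclusive."""
        return SizeSpectrum(
            classes={n: b for n, b in self.classes.items() if lo <= n <= hi},
            fjord_id=self.fjord_id,
            station_id=self.station_id,
            components=self.components,
        )


@dataclass
class NormalizedSpectrum:
    """Normalized biomass NB_n = biomass_n / 2**n for populated classes."""

    classes: dict[int, float]
    fjord_id: str | None = None
    station_id: str | None = None

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        """(class index, NB) arrays ordered by class, for NBSS fitting."""
        ns = np.array(sorted(self.classes), dtype=float)
        nb = np.array([self.classes[int(n)] for n in ns], dtype=float)
        return ns, nb

    def denormalize(self) -> dict[int, float]:
        return {n: nb * class_width(n) for n, nb in self.classes.items()}


def build_spectrum(
    sample: StationSample,
    groups: Iterable[str] | None = None,
) -> SizeSpectrum:
    """Bin a converted sample into a size spectrum per 0.1 m^2.

    ``groups`` optionally restricts to a faunal component (e.g. only
    meiofauna).  Every record must carry ``dry_mass_ug``; abundance is the
    sum of count weights and biomass the weighted sum of dry masses, both
    multiplied by the 1000 / sampled_area_cm2 area factor.
    """
    wanted = set(groups) if groups is not None else None
    factor = area_factor(sample.sampled_area_cm2)
    classes: dict[int, ClassBin] = {}
    comps: set[str] = set()
    for rec in sample.records:
        if wanted is not None and rec.group not in wanted:
            continue
        if rec.dry_mass_ug is None:
            raise ValueError(
                f"record for taxon {rec.taxon_id!r} has no dry_mass_ug; run "
                f"allometry.convert_sample first"
            )
        n = size_class(rec.dry_mass_ug)
        add = ClassBin(rec.count_weight * factor, rec.count_weight * rec.dry_mass_ug * factor)
        classes[n] = classes[n] + add if n in classes else add
        comps.add(rec.group)
    return SizeSpectrum(
        classes=classes,
        fjord_id=sample.fjord_id,
        station_id=sample.station_id,
        components=tuple(sorted(comps)),
    )


def combine_components(*spectra: SizeSpectrum) -> SizeSpectrum:
    """Classwise sum of component spectra (meio + macrofaunal nematodes + macro).

    All inputs must already be standardised to the common 0.1 m^2 unit
    area; class support of the result is the union of the inputs'.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = {(s.fjord_id, s.station_id) for s in spectra}
    if len(ids) > 1:
        raise ValueError(f"cannot combine spectra from different stations: {sorted(ids)}")
    classes: dict[int, ClassBin] = {}
    comps: list[str] = []
    for s in spectra:
        comps.extend(s.components)
        for n, b in s.classes.items():
            classes[n] = classes[n] + b if n in classes else b
    first = spectra[0]
    return SizeSpectrum(
        classes=classes,
        fjord_id=first.fjord_id,
        station_id=first.station_id,
        components=tuple(sorted(set(comps))),
    )


def normalize(spectrum: SizeSpectrum) -> NormalizedSpectrum:
    """NB_n = biomass_n / class width; empty classes carry no value."""
    if not spectrum.classes:
        raise ValueError("cannot normalize an empty spectrum")
    return NormalizedSpectrum(
        classes={n: b.biomass_ug / class_width(n) for n, b in spectrum.classes.items()},
        fjord_id=spectrum.fjord_id,
        station_id=spectrum.station_id,
    )


def pool_stations(spectra: Sequence[SizeSpectrum], how: str = "mean") -> SizeSpectrum:
    """Pool station spectra to a fjord-level spectrum (classwise mean or sum).

    The default classwise mean keeps the pooled spectrum on the per-0.1 m^2
    scale of a single station.  Classes absent at a station count as zero
    in the mean.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    if how not in ("mean", "sum"):
        raise ValueError(f"how must be 'mean' or 'sum', got {how!r}")
    fjords = {s.fjord_id for s in spectra}
    if len(fjords) > 1:
        raise ValueError(f"cannot pool across fjords: {sorted(fjords)}")
    k = len(spectra)
    classes: dict[int, ClassBin] = {}
    for s in spectra:
        for n, b in s.classes.items():
            classes[n] = classes[n] + b if n in classes else b
    if how == "mean":
        classes = {n: ClassBin(b.abundance / k, b.biomass_ug / k) for n, b in classes.items()}
    comps = tuple(sorted({c for s in spectra for c in s.components}))
    return SizeSpectrum(classes=classes, fjord_id=spectra[0].fjord_id, station_id=None, components=comps)


#: ug per 0.1 m^2  ->  g per m^2:  x10 to a full m^2, x1e-6 ug to g.
UG_PER_01M2_TO_G_PER_M2 = 10.0 * 1e-6


def total_benthic_dm(component_spectra: Mapping[str, SizeSpectrum]) -> tuple[float, dict[str, float]]:
    """Total standing stock in g DM m^-2 with per-component fractions.

    ``component_spectra`` maps component names (e.g. ``meiofauna``,
    ``macrofauna``, ``macrofaunal_nematode``) to spectra on the 0.1 m^2
    scale.  Returns ``(total_g_m2, {component: fraction of total DM})``.
    """
    totals = {name: s.total_biomass_ug for name, s in component_spectra.items()}
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total biomass is zero; no organisms?")
    fractions = {name: t / grand for name, t in totals.items()}
    return grand * UG_PER_01M2_TO_G_PER_M2, fractions


def spectra_table(spectra: Iterable[SizeSpectrum]) -> pd.DataFrame:
    """Tidy long-form table (fjord, station, class_index, abundance, biomass_ug, nb)."""
    rows = []
    for s in spectra:
        for n in s.support:
            b = s.classes[n]
            rows.append(
                {
                    "fjord_id": s.fjord_id,
                    "station_id": s.station_id,
                    "class_index": n,
                    "abundance": b.abundance,
                    "biomass_ug": b.biomass_ug,
                    "nb": b.biomass_ug / class_width(n),
                }
            )
    return pd.DataFrame(rows)
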