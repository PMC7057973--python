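"""Domain types, tabular I/O and unit conventions shared by the pipeline.

Conventions used throughout the package:

* organism dimensions are millimetres, biovolumes mm^3;
* wet mass (WM) is derived from biovolume at a single conversion point
  (1 mm^3 of water-equivalent tissue = 1 mg);
* dry mass (DM) is micrograms everywhere downstream — size classes are
  defined on individual DM in ug;
* abundance and biomass are standardised to 0.1 m^2 of seabed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GROUPS",
    "GEARS",
    "FEEDING_TYPES",
    "GEAR_AREAS_CM2",
    "OrganismRecord",
    "StationSample",
    "EnvProfile",
    "ConversionConfig",
    "SchemaError",
    "ConversionError",
    "DesignFlag",
    "read_samples",
    "write_samples",
    "read_environment",
    "write_environment",
    "validate_design",
]

GROUPS = ("meiofauna", "macrofauna", "macrofaunal_nematode")
GEARS = ("van_veen_grab", "syringe_core")
FEEDING_TYPES = (
    "surface_deposit",
    "subsurface_deposit",
    "carnivore",
    "omnivore",
    "suspension",
    "herbivore",
    "grazer",
)

#: Nominal sampled area per gear in paper-faithful mode: a 0.1 m^2 van Veen
#: grab for macrofauna and a 10 cm^2 syringe core for meiofauna.
GEAR_AREAS_CM2 = {"van_veen_grab": 1000.0, "syringe_core": 10.0}


class SchemaError(ValueError):
    """A delimited-text table violates the documented column schema."""


class ConversionError(ValueError):
    """A record cannot be converted to mass (missing coefficient etc.)."""


@dataclass
class OrganismRecord:
    """One measured individual, or a subsample representative.

    ``count_weight`` is the number of individuals this record stands for
    (>= 1); subsample expansion and area standardisation act on it.
    ``dry_mass_ug`` is filled by the allometry stage unless supplied.
    """

    taxon_id: str
    group: str
    length_mm: float | None = None
    width_mm: float | None = None
    count_weight: float = 1.0
    is_fragment: bool = False
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    feeding_type: str | None = None
    dry_mass_ug: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"unknown group {self.group!r} for taxon {self.taxon_id!r}; "
                f"expected one of {GROUPS}"
            )
        if self.feeding_type is not None and self.feeding_type not in FEEDING_TYPES:
            raise SchemaError(
                f"unknown feeding_type {self.feeding_type!r} for taxon "
                f"{self.taxon_id!r}"
            )
        if self.count_weight < 1:
            raise SchemaError(
                f"count_weight must be >= 1, got {self.count_weight} "
                f"(taxon {self.taxon_id!r})"
            )
        if self.dry_mass_ug is None:
            # mass must be derivable from dimensions
            for name, value in (("length_mm", self.length_mm), ("width_mm", self.width_mm)):
                if value is None or not value > 0:
                    raise SchemaError(
                        f"{name} must be a positive number when dry_mass_ug is "
                        f"absent, got {value!r} (taxon {self.taxon_id!r})"
                    )
        elif not self.dry_mass_ug > 0:
            raise SchemaError(
                f"dry_mass_ug must be positive, got {self.dry_mass_ug} "
                f"(taxon {self.taxon_id!r})"
            )


@dataclass
class StationSample:
    """A station's faunal collection for one gear; the unit of replication."""

    fjord_id: str
    station_id: str
    gear: str
    sampled_area_cm2: float
    records: list[OrganismRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gear not in GEARS:
            raise SchemaError(f"unknown gear {self.gear!r}; expected one of {GEARS}")
        if not self.sampled_area_cm2 > 0:
            raise SchemaError(
                f"sampled_area_cm2 must be positive, got {self.sampled_area_cm2}"
            )

    @property
    def total_count(self) -> float:
        return sum(r.count_weight for r in self.records)


@dataclass
class EnvProfile:
    """Station-level environmental covariates (predictors for DistLM)."""

    fjord_id: str
    station_id: str
    temperature_C: float
    salinity: float
    c_org_pct: float
    delta13C: float
    chl_a_ug_g: float
    cpe_ug_g: float
    mud_pct: float

    def __post_init__(self) -> None:
        if self.c_org_pct < 0 or self.chl_a_ug_g < 0 or self.cpe_ug_g < 0:
            raise SchemaError("c_org_pct, chl_a_ug_g and cpe_ug_g must be >= 0")
        if not 0 <= self.mud_pct <= 100:
            raise SchemaError(f"mud_pct must be in [0, 100], got {self.mud_pct}")
        if self.chl_a_ug_g > self.cpe_ug_g:
            # Chl a is one component of the chloroplastic pigment pool
            raise SchemaError(
                f"chl_a_ug_g ({self.chl_a_ug_g}) cannot exceed cpe_ug_g "
                f"({self.cpe_ug_g}) at station {self.station_id!r}"
            )

    PREDICTORS = (
        "temperature_C",
        "salinity",
        "c_org_pct",
        "delta13C",
        "chl_a_ug_g",
        "cpe_ug_g",
        "mud_pct",
    )


# ---------------------------------------------------------------------------
# conversion configuration
# ---------------------------------------------------------------------------

#: Example Feller-Warwick shape coefficients c (dimensionless; V = L*W^2*c with
#: L, W in mm and V in mm^3), in the range published for meiobenthic shapes
#: (Feller & Warwick 1988).  These are documented defaults for testing and
#: simulation; site studies should supply their own table.
DEFAULT_TAXON_COEFFICIENTS: dict[str, float] = {
    "nematoda": 0.53,
    "copepoda": 0.23,
    "harpacticoida": 0.23,
    "nauplii": 0.72,
    "ostracoda": 0.45,
    "kinorhyncha": 0.295,
    "tardigrada": 0.614,
    "turbellaria": 0.55,
    "gastrotricha": 0.55,
    "halacaroidea": 0.399,
    "polychaeta": 0.53,
    "oligochaeta": 0.53,
    "bivalvia": 0.372,
    # vermiform polychaete families take the generic polychaete shape
    "maldanidae": 0.53,
    "spionidae": 0.53,
    "cirratulidae": 0.53,
    "paraonidae": 0.53,
    "oweniidae": 0.53,
    "nephtyidae": 0.53,
    "cossuridae": 0.53,
    "onuphidae": 0.53,
    "capitellidae": 0.53,
    "amphipoda": 0.4,
}

#: Example macrofaunal DM/WM ratios (Brey-style body-composition factors).
#: Documented defaults, overridable per study.
DEFAULT_MACROFAUNA_DM_FACTORS: dict[str, float] = {
    "polychaeta": 0.155,
    "maldanidae": 0.155,
    "spionidae": 0.155,
    "cirratulidae": 0.155,
    "paraonidae": 0.155,
    "oweniidae": 0.155,
    "nephtyidae": 0.155,
    "cossuridae": 0.155,
    "onuphidae": 0.155,
    "capitellidae": 0.155,
    "oligochaeta": 0.15,
    "nemertea": 0.15,
    "sipuncula": 0.154,
    "mollusca": 0.09,
    "bivalvia": 0.09,
    "gastropoda": 0.154,
    "crustacea": 0.22,
    "amphipoda": 0.22,
    "isopoda": 0.22,
    "cumacea": 0.22,
    "ophiuroidea": 0.26,
    "echinodermata": 0.26,
    "nematoda": 0.25,
}


@dataclass
class ConversionConfig:
    """Constants of the dimension -> biovolume -> WM -> DM conversion chain.

    Parameters
    ----------
    taxon_coefficients
        Feller-Warwick shape coefficient ``c`` per taxon (dimensionless).
    specific_gravity
        Tissue specific gravity; WM [mg] = V [mm^3] * specific_gravity.
    meiofauna_dm_fraction
        DM/WM ratio applied to meiofauna and macrofaunal nematodes.
    macrofauna_dm_factors
        DM/WM ratio per macrofaunal taxon.
    direct_mass_taxa
        Taxa (e.g. Crustacea, Ophiuroidea) whose WM comes straight from a
        published length regression ``WM_ug = intercept + slope * L_mm``
        instead of the biovolume route.
    subsample_threshold, subsample_size
        Macrofaunal species with more than ``subsample_threshold``
        individuals per sample are represented by a measured subsample of
        ``subsample_size`` specimens.
    nematode_subsample_size
        Analogous fixed subsample size for meiofaunal nematodes.
    """

    taxon_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_COEFFICIENTS)
    )
    specific_gravity: float = 1.13
    meiofauna_dm_fraction: float = 0.25
    macrofauna_dm_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MACROFAUNA_DM_FACTORS)
    )
    direct_mass_taxa: dict[str, dict[str, float]] = field(default_factory=dict)
    subsample_threshold: int = 250
    subsample_size: int = 200
    nematode_subsample_size: int = 500

    def __post_init__(self) -> None:
        if self.specific_gravity <= 0:
            raise SchemaError("specific_gravity must be positive")
        if not 0 < self.meiofauna_dm_fraction <= 1:
            raise SchemaError("meiofauna_dm_fraction must be in (0, 1]")
        for name, table in (
            ("taxon_coefficients", self.taxon_coefficients),
            ("macrofauna_dm_factors", self.macrofauna_dm_factors),
        ):
            for taxon, value in table.items():
                if not value > 0:
                    raise SchemaError(f"{name}[{taxon!r}] must be positive, got {value}")
        if self.subsample_size > self.subsample_threshold:
            raise SchemaError("subsample_size must be <= subsample_threshold")
        # canonical lower-case keys for case-insensitive lookup
        self.taxon_coefficients = {k.lower(): v for k, v in self.taxon_coefficients.items()}
        self.macrofauna_dm_factors = {
            k.lower(): v for k, v in self.macrofauna_dm_factors.items()
        }
        self.direct_mass_taxa = {k.lower(): v for k, v in self.direct_mass_taxa.items()}

    # -- lookups ------------------------------------------------------------

    def _lookup(self, table: Mapping[str, float], record: OrganismRecord, what: str):
        for key in (record.taxon_id, record.genus, record.family, record.group):
            if key and key.lower() in table:
                return table[key.lower()]
        raise ConversionError(f"no {what} configured for taxon {record.taxon_id!r}")

    def coefficient_for(self, record: OrganismRecord) -> float:
        """Feller-Warwick c, resolved taxon -> genus -> family -> group."""
        return self._lookup(self.taxon_coefficients, record, "Feller-Warwick coefficient")

    def dm_factor_for(self, record: OrganismRecord) -> float:
        return self._lookup(self.macrofauna_dm_factors, record, "DM/WM factor")

    def direct_mass_entry(self, record: OrganismRecord) -> dict[str, float] | None:
        for key in (record.taxon_id, record.genus, record.family):
            if key and key.lower() in self.direct_mass_taxa:
                return self.direct_mass_taxa[key.lower()]
        return None

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ConversionConfig":
        """Load from JSON or YAML, depending on extension."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

ORGANISM_COLUMNS = {
    "fjord_id": str,
    "station_id": str,
    "gear": str,
    "taxon_id": str,
    "group": str,
    "count_weight": float,
}
ORGANISM_OPTIONAL = (
    "species",
    "genus",
    "family",
    "length_mm",
    "width_mm",
    "is_fragment",
    "feeding_type",
    "dry_mass_ug",
)

ENV_COLUMNS = (
    "fjord_id",
    "station_id",
    "temperature_C",
    "salinity",
    "c_org_pct",
    "delta13C",
    "chl_a_ug_g",
    "cpe_ug_g",
    "mud_pct",
)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def _opt(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return value


def read_samples(
    path: str | Path,
    stations_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> list[StationSample]:
    """Parse an organism measurement table into station samples.

    ``schema`` optionally maps canonical column names to the file's column
    names.  One :class:`StationSample` is produced per (fjord, station,
    gear).  Sampled areas come from ``stations_path`` when given, otherwise
    from the gear's nominal area.  Rows violating the schema raise
    :class:`SchemaError` naming the offending column and 1-based data row.
    """
    df = _read_table(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})

    missing = [c for c in ORGANISM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    areas: dict[tuple[str, str, str], float] = {}
    if stations_path is not None:
        st = _read_table(stations_path)
        for col in ("fjord_id", "station_id", "gear", "sampled_area_cm2"):
            if col not in st.columns:
                raise SchemaError(f"missing required column {col!r} in {stations_path}")
        for row in st.itertuples(index=False):
            areas[(str(row.fjord_id), str(row.station_id), str(row.gear))] = float(
                row.sampled_area_cm2
            )

    grouped: dict[tuple[str, str, str], list[OrganismRecord]] = {}
    order: list[tuple[str, str, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            rec = OrganismRecord(
                taxon_id=str(row["taxon_id"]),
                group=str(row["group"]),
                length_mm=_opt(row.get("length_mm")),
                width_mm=_opt(row.get("width_mm")),
                count_weight=float(row["count_weight"]),
                is_fragment=bool(row.get("is_fragment", False)),
                species=_opt(row.get("species")),
                genus=_opt(row.get("genus")),
                family=_opt(row.get("family")),
                feeding_type=_opt(row.get("feeding_type")),
                dry_mass_ug=_opt(row.get("dry_mass_ug")),
            )
        except (SchemaError, TypeError, ValueError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
        key = (str(row["fjord_id"]), str(row["station_id"]), str(row["gear"]))
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(rec)

    samples = []
    for key in order:
        fjord, station, gear = key
        if gear not in GEARS:
            raise SchemaError(f"unknown gear {gear!r} at station {station!r}")
        area = areas.get(key, GEAR_AREAS_CM2[gear])
        samples.append(
            StationSample(
                fjord_id=fjord,
                station_id=station,
                gear=gear,
                sampled_area_cm2=area,
                records=grouped[key],
            )
        )
    return samples


def write_samples(
    samples: Iterable[StationSample],
    path: str | Path,
    stations_path: str | Path | None = None,
) -> None:
    """Write samples back to the delimited organism (and station) schema."""
    rows = []
    st_rows = []
    for s in samples:
        st_rows.append(
            {
                "fjord_id": s.fjord_id,
                "station_id": s.station_id,
                "gear": s.gear,
                "sampled_area_cm2": s.sampled_area_cm2,
            }
        )
        for r in s.records:
            rows.append(
                {
                    "fjord_id": s.fjord_id,
                    "station_id": s.station_id,
                    "gear": s.gear,
                    "taxon_id": r.taxon_id,
                    "group": r.group,
                    "species": r.species,
                    "genus": r.genus,
                    "family": r.family,
                    "length_mm": r.length_mm,
                    "width_mm": r.width_mm,
                    "count_weight": r.count_weight,
                    "is_fragment": r.is_fragment,
                    "feeding_type": r.feeding_type,
                    "dry_mass_ug": r.dry_mass_ug,
                }
            )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    if stations_path is not None:
        pd.DataFrame(st_rows).to_csv(stations_path, sep=sep, index=False)


def read_environment(path: str | Path) -> list[EnvProfile]:
    df = _read_table(path)
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    profiles = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            profiles.append(
                EnvProfile(
                    fjord_id=str(row["fjord_id"]),
                    station_id=str(row["station_id"]),
                    **{c: float(row[c]) for c in ENV_COLUMNS[2:]},
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return profiles


def write_environment(profiles: Iterable[EnvProfile], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(p, c) for c in ENV_COLUMNS} for p in profiles]
    ).to_csv(path, index=False)


def env_table(profiles: Sequence[EnvProfile]) -> pd.DataFrame:
    """Environmental covariates as a station-indexed predictor DataFrame."""
    df = pd.DataFrame([{c: getattr(p, c) for c in ENV_COLUMNS} for p in profiles])
    return df.set_index("station_id")


# ---------------------------------------------------------------------------
# design validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignFlag:
    kind: str
    fjord_id: str
    detail: str


def validate_design(
    samples: Sequence[StationSample],
    expected_stations: int = 3,
    area_tolerance: float = 0.5,
) -> list[DesignFlag]:
    """Report-only check of the sampling design.

    Flags fjords with a station count other than ``expected_stations``,
    fjords missing one of the two gear types, and samples whose recorded
    area deviates from the gear's nominal area by more than
    ``area_tolerance`` (relative).  Never mutates its input.
    """
    if not samples:
        raise ValueError("validate_design requires a non-empty sample list")
    flags: list[DesignFlag] = []
    by_fjord: dict[str, list[StationSample]] = {}
    for s in samples:
        by_fjord.setdefault(s.fjord_id, []).append(s)
    for fjord, ss in sorted(by_fjord.items()):
        stations = sorted({s.station_id for s in ss})
        if len(stations) != expected_stations:
            flags.append(
                DesignFlag(
                    "station_count",
                    fjord,
                    f"{len(stations)} stations (expected {expected_stations})",
                )
            )
        gears = {s.gear for s in ss}
        for gear in GEARS:
            if gear not in gears:
                flags.append(DesignFlag("missing_gear", fjord, f"no {gear} sample"))
        for s in ss:
            nominal = GEAR_AREAS_CM2[s.gear]
            if abs(s.sampled_area_cm2 - nominal) > area_tolerance * nominal:
                flags.append(
                    DesignFlag(
                        "area_anomaly",
                        fjord,
                        f"station {s.station_id} {s.gear} area "
                        f"{s.sampled_area_cm2} cm2 (nominal {nominal})",
                    )
                )
    return flags
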