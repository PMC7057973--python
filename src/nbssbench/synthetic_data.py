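"""Synthetic benthic communities with known size-spectrum truth.

The generator works target-first: for every station and size class it
fixes an expected log2 normalized biomass on the line
``intercept + slope * n``, adds a slope- and intercept-neutral shape
profile (meiofaunal mode, abundance trough near classes 2-5, macrofaunal
mode) plus Gaussian class noise, splits the class biomass among faunal
components (meiofauna, macrofaunal nematodes, macrofauna), realises it
as individual organisms with dry masses drawn uniform in log2 within the
class, and finally back-computes body length and width through the
configured allometry so that the conversion chain reproduces the
intended masses.  The shape profile is orthogonalised against {1, n}
over the station's class set, so the OLS-fitted slope and intercept are
unbiased for the configured truth by construction.

Meiofauna are emitted as 10 cm^2 syringe-core samples and macrofauna
(including macrofaunal nematodes) as 0.1 m^2 van Veen grab samples, so
area standardisation is exercised end to end.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .allometry import MG_TO_UG
from .data_model import ConversionConfig, EnvProfile, OrganismRecord, StationSample

__all__ = [
    "TaxonSpec",
    "ScenarioConfig",
    "Truth",
    "generate_community",
    "inject_perturbation",
]


@dataclass(frozen=True)
class TaxonSpec:
    """A taxon available to the generator, with its inversion geometry."""

    taxon_id: str
    group: str
    weight: float
    aspect_ratio: float  # L / W used to invert volume to dimensions
    family: str | None = None
    feeding_type: str | None = None
    shape: str = "feller_warwick"  # or "cylinder"


# The macrofaunal pool is seeded with the polychaete families that dominate
# Norwegian/Svalbard fjord soft-bottom communities, so taxon- and
# trait-partitioned ordinations are non-degenerate.
DEFAULT_MEIOFAUNA_POOL = (
    TaxonSpec("Nematoda", "meiofauna", 0.55, 22.0, shape="cylinder"),
    TaxonSpec("Harpacticoida", "meiofauna", 0.25, 3.2),
    TaxonSpec("Ostracoda", "meiofauna", 0.08, 1.8),
    TaxonSpec("Kinorhyncha", "meiofauna", 0.07, 4.0),
    TaxonSpec("Turbellaria", "meiofauna", 0.05, 5.0),
)
DEFAULT_MACROFAUNA_POOL = (
    TaxonSpec("Maldanidae", "macrofauna", 0.16, 12.0, "Maldanidae", "subsurface_deposit"),
    TaxonSpec("Spionidae", "macrofauna", 0.15, 10.0, "Spionidae", "surface_deposit"),
    TaxonSpec("Cirratulidae", "macrofauna", 0.12, 9.0, "Cirratulidae", "surface_deposit"),
    TaxonSpec("Paraonidae", "macrofauna", 0.11, 11.0, "Paraonidae", "subsurface_deposit"),
    TaxonSpec("Oweniidae", "macrofauna", 0.10, 10.0, "Oweniidae", "suspension"),
    TaxonSpec("Nephtyidae", "macrofauna", 0.09, 8.0, "Nephtyidae", "carnivore"),
    TaxonSpec("Cossuridae", "macrofauna", 0.08, 12.0, "Cossuridae", "subsurface_deposit"),
    TaxonSpec("Onuphidae", "macrofauna", 0.07, 9.0, "Onuphidae", "omnivore"),
    TaxonSpec("Bivalvia", "macrofauna", 0.07, 1.6, None, "suspension"),
    TaxonSpec("Amphipoda", "macrofauna", 0.05, 2.8, None, "surface_deposit"),
)
DEFAULT_NEMATODE_POOL = (
    TaxonSpec("Nematoda", "macrofaunal_nematode", 1.0, 28.0, shape="cylinder"),
)


@dataclass
class ScenarioConfig:
    """Generator parameters; the defaults emulate the study conditions.

    ``true_slope`` / ``true_intercept`` may be scalars or one value per
    fjord.  ``noise_sd`` is the SD of the Gaussian class-level noise on
    log2 NB.  The ``*_coef`` fields link station NBSS intercepts to the
    environmental covariates (positive for chlorophyll a, negative for
    delta13C: biomass is higher where fresh food is abundant and where
    terrestrial/degraded organic matter depresses delta13C readings
    least).
    """

    n_fjords: int = 6
    n_stations: int = 3
    true_slope: float | Sequence[float] = -0.53
    true_intercept: float | Sequence[float] = 11.0
    class_range: tuple[int, int] = (-11, 21)
    noise_sd: float = 0.5
    station_intercept_sd: float = 0.25
    # shape profile (log2 units, before orthogonalisation): a meiofaunal
    # mode above the line, a dip at the under-sampled smallest classes, the
    # abundance trough between the faunal components, and a macrofaunal
    # mode.  The default heights balance to near-zero slope/intercept
    # projection over the default station class ranges.
    meio_mode_height: float = 5.2
    meio_mode_center: float = -5.5
    meio_mode_width: float = 2.0
    edge_dip_depth: float = 6.7
    edge_dip_center: float = -11.0
    edge_dip_width: float = 1.5
    trough_depth: float = 3.0
    trough_center: float = 3.8
    trough_width: float = 1.9
    macro_mode_height: float = 0.94
    macro_mode_center: float = 8.5
    macro_mode_width: float = 1.8
    # component split
    crossover_class: float = 2.0
    crossover_width: float = 1.2
    meio_class_max: int = 5
    macro_class_min: int = 0
    nematode_frac: float = 0.2
    nematode_class_range: tuple[int, int] = (-6, 6)
    # realisation
    reps_per_class: int = 3
    #: per-station top class, cycled over the stations of each fjord; the
    #: largest classes hold only a few specimens and are not reached at
    #: every station
    station_hi_pattern: tuple[int, ...] | None = (21, 16, 14)
    top_class_clamp: float = 0.5  # emit a single minimum-mass organism if
    # the class target biomass is at least this fraction of the class floor
    # environmental model
    chl_coef: float = 0.8
    d13c_coef: float = -0.6
    env_intercept_link: bool = True
    # taxa
    meiofauna_pool: tuple[TaxonSpec, ...] = DEFAULT_MEIOFAUNA_POOL
    macrofauna_pool: tuple[TaxonSpec, ...] = DEFAULT_MACROFAUNA_POOL
    nematode_pool: tuple[TaxonSpec, ...] = DEFAULT_NEMATODE_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.class_range
        if not (-11 <= lo < hi <= 21):
            raise ValueError(
                f"class_range must be within [-11, 21] with lo < hi, got {self.class_range}"
            )
        if self.n_stations < 2:
            raise ValueError("n_stations must be >= 2")
        for pool in (self.meiofauna_pool, self.macrofauna_pool, self.nematode_pool):
            total = sum(t.weight for t in pool)
            if pool and not np.isclose(total, 1.0):
                raise ValueError(f"taxon pool weights must sum to 1, got {total}")

    def slopes(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.true_slope, float), (self.n_fjords,)).copy()

    def intercepts(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.true_intercept, float), (self.n_fjords,)
        ).copy()

    @classmethod
    def paper_like(cls, **overrides) -> "ScenarioConfig":
        """The default scenario: 6 fjords x 3 stations, slope -0.53,
        intercept 11, classes -11..21, class noise SD 0.5."""
        return cls(**overrides)

    @classmethod
    def noiseless(
        cls,
        slope: float = -1.0,
        intercept: float = 16.0,
        class_range: tuple[int, int] = (0, 15),
        **overrides,
    ) -> "ScenarioConfig":
        """Deterministic single-component scenario for closed-form round trips.

        All shape terms and noise are zero and every class is macrofauna,
        so the pipeline must recover the configured line exactly.
        """
        return cls(
            true_slope=slope,
            true_intercept=intercept,
            class_range=class_range,
            noise_sd=0.0,
            station_intercept_sd=0.0,
            meio_mode_height=0.0,
            edge_dip_depth=0.0,
            trough_depth=0.0,
            macro_mode_height=0.0,
            crossover_class=-100.0,  # meiofaunal share ~ 0 everywhere
            meio_class_max=class_range[0] - 1,
            macro_class_min=class_range[0],
            nematode_frac=0.0,
            station_hi_pattern=None,
            env_intercept_link=False,
            **overrides,
        )


@dataclass
class Truth:
    """Ground truth emitted alongside a generated community."""

    true_slope: dict[str, float]
    true_intercept: dict[str, float]
    station_intercept: dict[str, float]  # fjord intercept + env shift + station noise
    noise_sd: float
    class_range: tuple[int, int]
    station_class_hi: dict[str, int]
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _component_shares(cfg: ScenarioConfig, ns: np.ndarray) -> dict[str, np.ndarray]:
    """Split each class's biomass among meio / macrofaunal nematode / macro."""
    meio = _sigmoid((cfg.crossover_class - ns) / cfg.crossover_width)
    meio = np.where(ns > cfg.meio_class_max, 0.0, meio)
    other = 1.0 - meio
    nem_lo, nem_hi = cfg.nematode_class_range
    in_nem = (ns >= nem_lo) & (ns <= nem_hi)
    below_macro = ns < cfg.macro_class_min
    nem = np.where(in_nem & below_macro, other, 0.0)
    nem = np.where(in_nem & ~below_macro, cfg.nematode_frac * other, nem)
    # non-meiofaunal biomass below both the nematode and macrofaunal ranges
    # has no carrier; fold it back into meiofauna
    orphan = ~in_nem & below_macro
    meio = np.where(orphan, meio + other, meio)
    nem = np.where(orphan, 0.0, nem)
    macro = 1.0 - meio - nem
    macro = np.clip(macro, 0.0, None)
    return {"meiofauna": meio, "macrofaunal_nematode": nem, "macrofauna": macro}


def _gauss(ns: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((ns - center) ** 2) / (2.0 * width**2))


def _raw_shape(cfg: ScenarioConfig, ns: np.ndarray) -> np.ndarray:
    return (
        cfg.meio_mode_height * _gauss(ns, cfg.meio_mode_center, cfg.meio_mode_width)
        - cfg.edge_dip_depth * _gauss(ns, cfg.edge_dip_center, cfg.edge_dip_width)
        - cfg.trough_depth * _gauss(ns, cfg.trough_center, cfg.trough_width)
        + cfg.macro_mode_height * _gauss(ns, cfg.macro_mode_center, cfg.macro_mode_width)
    )


def _shape_coefficients(cfg: ScenarioConfig, basis_ns: np.ndarray) -> np.ndarray:
    """{1, n} projection coefficients of the raw profile over ``basis_ns``.

    Subtracting this projection makes the profile slope- and
    intercept-neutral: the OLS expectation over the basis class multiset
    (all stations of a fjord stacked) equals the configured line exactly.
    """
    delta = _raw_shape(cfg, basis_ns.astype(float))
    if np.allclose(delta, 0.0):
        return np.zeros(2)
    X = np.column_stack([np.ones_like(basis_ns, dtype=float), basis_ns.astype(float)])
    coef, *_ = np.linalg.lstsq(X, delta, rcond=None)
    return coef


def _shape_profile(cfg: ScenarioConfig, ns: np.ndarray, coef: np.ndarray) -> np.ndarray:
    ns = ns.astype(float)
    return _raw_shape(cfg, ns) - (coef[0] + coef[1] * ns)


def _invert_allometry(
    dm_ug: float, spec: TaxonSpec, conv: ConversionConfig
) -> tuple[float, float]:
    """Length and width (mm) that the conversion chain maps back to dm_ug."""
    if spec.group in ("meiofauna", "macrofaunal_nematode"):
        dm_fraction = conv.meiofauna_dm_fraction
    else:
        probe = OrganismRecord(
            taxon_id=spec.taxon_id, group=spec.group, length_mm=1.0, width_mm=1.0,
            family=spec.family,
        )
        dm_fraction = conv.dm_factor_for(probe)
    wm_ug = dm_ug / dm_fraction
    volume_mm3 = (wm_ug / MG_TO_UG) / conv.specific_gravity
    r = spec.aspect_ratio
    if spec.shape == "cylinder":
        width = (4.0 * volume_mm3 / (np.pi * r)) ** (1.0 / 3.0)
    else:
        probe = OrganismRecord(
            taxon_id=spec.taxon_id, group=spec.group, length_mm=1.0, width_mm=1.0,
            family=spec.family,
        )
        c = conv.coefficient_for(probe)
        width = (volume_mm3 / (r * c)) ** (1.0 / 3.0)
    return r * width, width


def _realize_class(
    rng: np.random.Generator,
    biomass_ug: float,
    n: int,
    reps: int,
    clamp: float,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Masses and count weights whose weighted sum equals ``biomass_ug``.

    Masses are uniform in log2 within [2**n, 2**(n+1)); the shared count
    weight is chosen so the class biomass is met exactly.  When the target
    cannot hold a single organism of the class's minimum mass, a lone
    individual at the class floor is emitted if the target is at least
    ``clamp`` of the floor, otherwise the class stays empty.
    """
    lo = 2.0**n
    hi = 2.0 ** (n + 1)
    if biomass_ug < lo:
        if biomass_ug >= clamp * lo:
            return np.array([lo]), np.array([1.0])
        return None
    if biomass_ug < hi:
        return np.array([biomass_ug]), np.array([1.0])
    k = int(biomass_ug / hi)  # >= 1, guarantees per-record weight >= 1
    n_rep = min(reps, k)
    masses = 2.0 ** (n + rng.uniform(0.0, 1.0, n_rep))
    w = biomass_ug / masses.sum()
    return masses, np.full(n_rep, w)


def _pick_taxon(rng: np.random.Generator, pool: Sequence[TaxonSpec]) -> TaxonSpec:
    weights = np.array([t.weight for t in pool])
    return pool[rng.choice(len(pool), p=weights / weights.sum())]


def generate_community(
    config: ScenarioConfig | None = None,
    seed: int | None = None,
    conversion: ConversionConfig | None = None,
) -> tuple[list[StationSample], list[EnvProfile], Truth]:
    """Generate station samples, environmental profiles and the truth record.

    Returns one syringe-core (meiofauna) and one van Veen grab
    (macrofauna + macrofaunal nematodes) sample per station.  Records
    carry dimensions only; running the allometry stage reproduces the
    masses the spectra were built from.
    """
    cfg = config or ScenarioConfig()
    conv = conversion or ConversionConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    slopes = cfg.slopes()
    intercepts = cfg.intercepts()
    lo, hi = cfg.class_range

    samples: list[StationSample] = []
    profiles: list[EnvProfile] = []
    station_intercepts: dict[str, float] = {}
    station_hi: dict[str, int] = {}

    # fjord-level environmental means: a latitudinal temperature gradient
    # plus food-availability covariates
    fjord_temp = np.linspace(7.7, -1.6, cfg.n_fjords)
    fjord_ln_chl = rng.normal(np.log(4.0), 0.6, cfg.n_fjords)
    fjord_d13c = rng.uniform(-23.6, -21.2, cfg.n_fjords)
    fjord_salinity = rng.uniform(33.4, 35.3, cfg.n_fjords)
    fjord_corg = rng.uniform(1.7, 3.8, cfg.n_fjords)
    fjord_mud = rng.uniform(40.0, 90.0, cfg.n_fjords)

    # per-station top classes (cycled within each fjord) and the shape
    # profile's projection coefficients over the fjord-stacked class set
    if cfg.station_hi_pattern:
        his = [
            min(hi, cfg.station_hi_pattern[st % len(cfg.station_hi_pattern)])
            for st in range(cfg.n_stations)
        ]
    else:
        his = [hi] * cfg.n_stations
    basis = np.concatenate([np.arange(lo, h + 1) for h in his])
    shape_coef = _shape_coefficients(cfg, basis)

    for fj in range(cfg.n_fjords):
        fjord_id = f"F{fj + 1}"
        for st in range(cfg.n_stations):
            station_id = f"{fjord_id}S{st + 1}"

            ln_chl = fjord_ln_chl[fj] + rng.normal(0.0, 0.15)
            chl = float(np.exp(ln_chl))
            d13c = float(fjord_d13c[fj] + rng.normal(0.0, 0.15))
            env = EnvProfile(
                fjord_id=fjord_id,
                station_id=station_id,
                temperature_C=float(fjord_temp[fj] + rng.normal(0.0, 0.2)),
                salinity=float(fjord_salinity[fj] + rng.normal(0.0, 0.05)),
                c_org_pct=float(max(0.1, fjord_corg[fj] + rng.normal(0.0, 0.1))),
                delta13C=d13c,
                chl_a_ug_g=chl,
                cpe_ug_g=chl * float(rng.uniform(4.0, 7.0)),
                mud_pct=float(np.clip(fjord_mud[fj] + rng.normal(0.0, 3.0), 0, 100)),
            )
            profiles.append(env)

            b0 = intercepts[fj]
            if cfg.env_intercept_link:
                z_chl = (ln_chl - np.log(4.0)) / 0.6
                z_d13 = (d13c + 22.4) / 0.7
                b0 = b0 + cfg.chl_coef * z_chl + cfg.d13c_coef * z_d13
            b0 = float(b0 + rng.normal(0.0, cfg.station_intercept_sd))
            station_intercepts[station_id] = b0

            st_hi = his[st]
            station_hi[station_id] = st_hi
            ns = np.arange(lo, st_hi + 1)
            profile = _shape_profile(cfg, ns, shape_coef)
            shares = _component_shares(cfg, ns)

            y = b0 + slopes[fj] * ns + profile
            if cfg.noise_sd > 0:
                y = y + rng.normal(0.0, cfg.noise_sd, ns.size)
            class_biomass = 2.0 ** (y + ns)  # ug per 0.1 m^2

            grab_records: list[OrganismRecord] = []
            core_records: list[OrganismRecord] = []
            for i, n in enumerate(ns):
                targets = []
                meio_b = shares["meiofauna"][i] * class_biomass[i]
                if meio_b > 0:
                    # syringe-core scale is 1/100 of the 0.1 m^2 reference;
                    # classes whose core-scale biomass cannot hold one
                    # organism fall to the grab-sampled macrofauna instead
                    if meio_b / 100.0 >= 2.0**n:
                        targets.append(("meiofauna", cfg.meiofauna_pool, meio_b / 100.0, core_records))
                    else:
                        shares["macrofauna"][i] += shares["meiofauna"][i]
                nem_b = shares["macrofaunal_nematode"][i] * class_biomass[i]
                if nem_b > 0:
                    targets.append(("macrofaunal_nematode", cfg.nematode_pool, nem_b, grab_records))
                macro_b = shares["macrofauna"][i] * class_biomass[i]
                if macro_b > 0:
                    targets.append(("macrofauna", cfg.macrofauna_pool, macro_b, grab_records))

                for group, pool, target, sink in targets:
                    if not pool:
                        raise ValueError(f"no taxon pool for component {group!r}")
                    realised = _realize_class(
                        rng, target, int(n), cfg.reps_per_class, cfg.top_class_clamp
                    )
                    if realised is None:
                        continue
                    masses, weights = realised
                    for m, w in zip(masses, weights):
                        spec = _pick_taxon(rng, pool)
                        length, width = _invert_allometry(float(m), spec, conv)
                        sink.append(
                            OrganismRecord(
                                taxon_id=spec.taxon_id,
                                group=group,
                                length_mm=length,
                                width_mm=width,
                                count_weight=float(w),
                                family=spec.family,
                                feeding_type=spec.feeding_type,
                            )
                        )

            samples.append(
                StationSample(fjord_id, station_id, "van_veen_grab", 1000.0, grab_records)
            )
            samples.append(
                StationSample(fjord_id, station_id, "syringe_core", 10.0, core_records)
            )

    truth = Truth(
        true_slope={f"F{j + 1}": float(slopes[j]) for j in range(cfg.n_fjords)},
        true_intercept={f"F{j + 1}": float(intercepts[j]) for j in range(cfg.n_fjords)},
        station_intercept=station_intercepts,
        noise_sd=cfg.noise_sd,
        class_range=cfg.class_range,
        station_class_hi=station_hi,
        seed=int(cfg.seed if seed is None else seed),
        config={
            k: v
            for k, v in asdict(cfg).items()
            if not k.endswith("_pool")
        },
    )
    return samples, profiles, truth


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def inject_perturbation(
    samples: Sequence[StationSample],
    kind: str,
    conversion: ConversionConfig | None = None,
    class_threshold: int | None = None,
    factor: float = 4.0,
) -> list[StationSample]:
    """Deterministic perturbations for sensitivity analyses.

    ``remove_large`` drops organisms above ``class_threshold`` (default
    17); ``inflate_small`` multiplies the abundance of classes below
    ``class_threshold`` (default 5) by ``factor``; ``outlier`` inflates
    the single largest organism's mass by ``factor``; ``identity``
    returns an equal deep copy.
    """
    from .allometry import record_dry_mass
    from .spectra import size_class

    conv = conversion or ConversionConfig()
    out = copy.deepcopy(list(samples))
    if kind == "identity":
        return out
    if kind == "remove_large":
        thr = 17 if class_threshold is None else class_threshold
        for s in out:
            s.records = [
                r for r in s.records if size_class(record_dry_mass(r, conv)) <= thr
            ]
        return out
    if kind == "inflate_small":
        thr = 5 if class_threshold is None else class_threshold
        for s in out:
            for r in s.records:
                if size_class(record_dry_mass(r, conv)) < thr:
                    r.count_weight *= factor
        return out
    if kind == "outlier":
        best: tuple[float, OrganismRecord] | None = None
        for s in out:
            for r in s.records:
                dm = record_dry_mass(r, conv)
                if best is None or dm > best[0]:
                    best = (dm, r)
        if best is not None:
            rec = best[1]
            scale = factor ** (1.0 / 3.0)  # mass ~ L * W^2
            rec.length_mm *= scale
            rec.width_mm *= scale
            if rec.dry_mass_ug is not None:
                rec.dry_mass_ug *= factor
        return out
    raise ValueError(f"unknown perturbation kind {kind!r}")
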