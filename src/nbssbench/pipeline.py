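"""End-to-end orchestration: raw samples -> spectra -> NBSS comparison.

Thin convenience layer over the stage modules, used by the CLI and by
batch analyses; nothing here adds statistical behaviour.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import allometry, nbss, spectra
from .data_model import ConversionConfig, StationSample

__all__ = [
    "convert_samples",
    "station_component_spectra",
    "station_spectra",
    "fjord_spectra",
    "grouped_normalized",
    "totals_table",
    "fit_stations",
]


def convert_samples(
    samples: Sequence[StationSample],
    config: ConversionConfig | None = None,
    calibrations=None,
) -> list[StationSample]:
    config = config or ConversionConfig()
    return [allometry.convert_sample(s, config, calibrations) for s in samples]


def station_component_spectra(
    converted: Sequence[StationSample],
) -> dict[str, dict[str, spectra.SizeSpectrum]]:
    """Per-station spectra keyed by faunal component.

    Gears are merged per station: each gear contributes the components it
    samples, already standardised to 0.1 m^2 by :func:`spectra.build_spectrum`.
    """
    out: dict[str, dict[str, spectra.SizeSpectrum]] = {}
    for s in converted:
        comps = out.setdefault(s.station_id, {})
        for group in {r.group for r in s.records}:
            spec = spectra.build_spectrum(s, groups=[group])
            if group in comps:
                comps[group] = spectra.combine_components(comps[group], spec)
            else:
                comps[group] = spec
    return out


def station_spectra(converted: Sequence[StationSample]) -> dict[str, spectra.SizeSpectrum]:
    """Combined (all components) spectrum per station."""
    return {
        st: spectra.combine_components(*comps.values())
        for st, comps in station_component_spectra(converted).items()
    }


def fjord_spectra(
    converted: Sequence[StationSample], how: str = "mean"
) -> dict[str, spectra.SizeSpectrum]:
    """Fjord-level spectra: classwise mean (default) of station spectra."""
    by_fjord: dict[str, list[spectra.SizeSpectrum]] = {}
    fjord_of = {s.station_id: s.fjord_id for s in converted}
    for st, spec in station_spectra(converted).items():
        by_fjord.setdefault(fjord_of[st], []).append(spec)
    return {fj: spectra.pool_stations(specs, how=how) for fj, specs in by_fjord.items()}


def grouped_normalized(
    converted: Sequence[StationSample],
) -> dict[str, list[spectra.NormalizedSpectrum]]:
    """Normalized station spectra grouped by fjord, ready for compare_slopes."""
    fjord_of = {s.station_id: s.fjord_id for s in converted}
    groups: dict[str, list[spectra.NormalizedSpectrum]] = {}
    for st, spec in station_spectra(converted).items():
        groups.setdefault(fjord_of[st], []).append(spectra.normalize(spec))
    return groups


def totals_table(converted: Sequence[StationSample]) -> pd.DataFrame:
    """Station totals: g DM m^-2 and the macrofaunal share of dry mass."""
    fjord_of = {s.station_id: s.fjord_id for s in converted}
    rows = []
    for st, comps in station_component_spectra(converted).items():
        total, fractions = spectra.total_benthic_dm(comps)
        macro = fractions.get("macrofauna", 0.0) + fractions.get("macrofaunal_nematode", 0.0)
        rows.append(
            {
                "fjord_id": fjord_of[st],
                "station_id": st,
                "total_g_dm_m2": total,
                "macrofauna_fraction": macro,
                "meiofauna_fraction": fractions.get("meiofauna", 0.0),
            }
        )
    return pd.DataFrame(rows).sort_values("station_id").reset_index(drop=True)


def fit_stations(converted: Sequence[StationSample]) -> pd.DataFrame:
    """Free-slope NBSS fit per station."""
    fjord_of = {s.station_id: s.fjord_id for s in converted}
    rows = []
    for st, spec in sorted(station_spectra(converted).items()):
        fit = nbss.fit_nbss(spectra.normalize(spec))
        rows.append(
            {
                "fjord_id": fjord_of[st],
                "station_id": st,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "r2": fit.r2,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)
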