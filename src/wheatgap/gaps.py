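"""Genetic yield potential and genetic yield gap arithmetic.

For a location, Y_W is the mean water-limited yield of the current cultivar
under optimal management, Y_iW the mean water-limited yield of the optimized
ideotype (the genetic yield potential).  The genetic yield gap is

    Y_iG (t ha-1) = Y_iW - Y_W
    Y_iG (%)      = 100 * Y_iG / Y_iW

Percent values are carried at full precision and rounded half-up to integers
only in the printed-precision reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .crop import CultivarParams, Management, ModelConfig, DEFAULT_CONFIG, \
    SoilProfile, simulate_multi_year
from .optimize import DEFAULT_TRAIT_RANGES, OptimizationResult, TraitRanges, \
    optimize_ideotype
from .weather import SiteClimateParams, generate_weather

__all__ = [
    "GapResult",
    "SummaryRow",
    "AggregateSummary",
    "genetic_yield_gap",
    "run_site_analysis",
    "aggregate",
    "round_half_up",
    "gap_table",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


@dataclass(frozen=True)
class GapResult:
    """Genetic yield gap of one site and one ideotype mode (iS or iT)."""

    site_id: str
    mode: str
    y_w: float       # current-cultivar water-limited yield, t ha-1
    y_iw: float      # genetic yield potential, t ha-1
    y_ig_abs: float  # gap, t ha-1 (y_iw - y_w exactly; negative allowed)
    y_ig_pct: float  # gap as % of genetic yield potential


def genetic_yield_gap(y_iw: float, y_w: float, site_id: str = "",
                      mode: str = "") -> GapResult:
    """Gap between genetic yield potential and current-cultivar yield.

    A negative gap (ideotype underperforming the cultivar) is reported, not
    clipped; it flags an optimizer run worth inspecting.
    """
    if y_iw <= 0:
        raise ValueError("genetic yield potential y_iw must be > 0")
    abs_gap = y_iw - y_w
    return GapResult(
        site_id=site_id, mode=mode, y_w=y_w, y_iw=y_iw,
        y_ig_abs=abs_gap, y_ig_pct=100.0 * abs_gap / y_iw,
    )


@dataclass(frozen=True)
class SummaryRow:
    group: str
    mode: str
    y_w: float
    y_iw: float
    y_ig_abs: float
    y_ig_pct: float


@dataclass(frozen=True)
class AggregateSummary:
    """Across-site means per mode plus the iT-vs-iS contrast."""

    rows: tuple[SummaryRow, ...]
    contrast_abs: float   # mean iT gap minus mean iS gap, t ha-1
    contrast_pct: float   # contrast as % of the mean iS gap


def aggregate(results: Sequence[GapResult]) -> AggregateSummary:
    """Arithmetic means of the gap quantities across sites, per mode."""
    if not results:
        raise ValueError("no gap results to aggregate")
    rows = []
    mode_gap_means: dict[str, float] = {}
    for mode in dict.fromkeys(r.mode for r in results):  # stable order
        sel = [r for r in results if r.mode == mode]
        row = SummaryRow(
            group="all",
            mode=mode,
            y_w=float(np.mean([r.y_w for r in sel])),
            y_iw=float(np.mean([r.y_iw for r in sel])),
            y_ig_abs=float(np.mean([r.y_ig_abs for r in sel])),
            y_ig_pct=float(np.mean([r.y_ig_pct for r in sel])),
        )
        rows.append(row)
        mode_gap_means[mode] = row.y_ig_abs
    if {"iS", "iT"} <= set(mode_gap_means):
        contrast_abs = mode_gap_means["iT"] - mode_gap_means["iS"]
        contrast_pct = (100.0 * contrast_abs / mode_gap_means["iS"]
                        if mode_gap_means["iS"] != 0 else math.nan)
    else:
        contrast_abs = math.nan
        contrast_pct = math.nan
    return AggregateSummary(
        rows=tuple(rows), contrast_abs=contrast_abs, contrast_pct=contrast_pct
    )


def gap_table(results: Sequence[GapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(site=r.site_id, mode=r.mode, y_w=r.y_w, y_iw=r.y_iw,
                 y_ig_abs=r.y_ig_abs, y_ig_pct=r.y_ig_pct)
            for r in results
        ]
    )


def run_site_analysis(site: SiteClimateParams, base: CultivarParams,
                      soil: SoilProfile, mgmt: Management, seed: int,
                      years: int = 100, n_starts: int = 25,
                      n_candidates: int = 16, patience: int = 20,
                      max_gen: int = 200,
                      ranges: TraitRanges = DEFAULT_TRAIT_RANGES,
                      config: ModelConfig = DEFAULT_CONFIG,
                      ) -> tuple[GapResult, GapResult,
                                 OptimizationResult, OptimizationResult]:
    """Full analysis for one site: cultivar baseline, iS and iT ideotypes.

    ``years`` counts harvested seasons; ``years + 1`` calendar years of
    weather are generated so every season has a complete 365-day run from
    sowing.  The cultivar and both optimizations share the one weather
    series.
    """
    mgmt = Management(sowing_doy=site.sowing_doy, co2_ppm=mgmt.co2_ppm,
                      water_regime=mgmt.water_regime, nutrients=mgmt.nutrients)
    ss = np.random.SeedSequence(seed)
    weather_ss, is_ss, it_ss = ss.spawn(3)
    series = generate_weather(
        site, years + 1, int(weather_ss.generate_state(1)[0] % 2**31)
    )
    baseline = simulate_multi_year(base, series, soil, mgmt, config)
    try:
        opt_is = optimize_ideotype(
            series, soil, mgmt, base, "iS", ranges=ranges, seed=is_ss,
            n_starts=n_starts, n_candidates=n_candidates,
            patience=patience, max_gen=max_gen, config=config,
        )
        opt_it = optimize_ideotype(
            series, soil, mgmt, base, "iT", ranges=ranges, seed=it_ss,
            n_starts=n_starts, n_candidates=n_candidates,
            patience=patience, max_gen=max_gen, config=config,
        )
    except Exception as exc:
        raise RuntimeError(f"ideotype optimization failed at site "
                           f"{site.site_id!r}") from exc
    gap_is = genetic_yield_gap(opt_is.best.fitness, baseline.mean_yield,
                               site_id=site.site_id, mode="iS")
    gap_it = genetic_yield_gap(opt_it.best.fitness, baseline.mean_yield,
                               site_id=site.site_id, mode="iT")
    return gap_is, gap_it, opt_is, opt_it
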