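"""Growth-parameter sensitivity engine.

SPR estimates are sensitive to the assumed von Bertalanffy parameters, and
for krill those parameters track environmental conditions.  This module
re-fits the LBSPR model across a grid of asymptotic-length and growth-rate
scenarios per management stratum and summarises the per-stratum annual SPR
estimates (median and SD), mirroring the usual sensitivity-table layout.

Two presets are shipped: the default enumerates 10 asymptotic lengths
(55-64 mm by 1 mm) plus three growth-rate scenarios (k = 0.2 low / 0.7
medium / 1.2 high, with m fixed at 0.4) per stratum, i.e. 13 x 5 = 65
scenario-stratum combinations; an alternative uses the 11-value sweep
55-65 mm (70 combinations).  The two counts are internally inconsistent in
the source material for this design, so both are provided and the
alternative logs a note when built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biology import LifeHistory, ParameterError, base_krill
from .lbspr import LengthComposition, fit_series

__all__ = [
    "Scenario",
    "ScenarioGrid",
    "ScenarioResults",
    "build_grid",
    "default_grid",
    "table2_grid",
    "run_sensitivity",
    "DEFAULT_STRATA",
    "K_SCENARIOS",
]

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("BS", "EI", "GS", "JOIN", "SSWI")
K_SCENARIOS = {"Low": 0.2, "Med": 0.7, "High": 1.2}
M_FIXED = 0.4


@dataclass(frozen=True)
class Scenario:
    """One modified life history with a label such as ``Linf58`` or ``Low``."""

    label: str
    kind: str  # "linf" | "k"
    value: float
    life_history: LifeHistory


@dataclass(frozen=True)
class ScenarioGrid:
    """Scenario list crossed with strata."""

    scenarios: tuple[Scenario, ...]
    strata: tuple[str, ...]
    base: LifeHistory

    @property
    def n_combinations(self) -> int:
        return len(self.scenarios) * len(self.strata)


def build_grid(
    linf_values: Sequence[float],
    k_values: dict[str, float] = K_SCENARIOS,
    strata: Sequence[str] = DEFAULT_STRATA,
    base: Optional[LifeHistory] = None,
    m_fixed: float = M_FIXED,
) -> ScenarioGrid:
    """Enumerate one scenario per L_inf value (k at base) plus one per k value
    (L_inf at base), crossed with strata.

    L_inf scenarios keep the base M/K; k scenarios recompute M/K as
    ``m_fixed / k`` (only the ratio enters the model).  Maturity and
    selectivity stay in absolute mm.
    """
    if base is None:
        base = base_krill()
    linf_values = list(linf_values)
    if not linf_values or not k_values:
        raise ParameterError("linf_values and k_values must be non-empty")
    if not list(strata):
        raise ParameterError("strata must be non-empty")
    if any(np.diff(linf_values) <= 0):
        raise ParameterError("linf_values must be strictly increasing")
    if any(k <= 0 for k in k_values.values()):
        raise ParameterError("k values must be positive")
    scens = [
        Scenario(f"Linf{v:g}", "linf", float(v), base.with_linf(float(v)))
        for v in linf_values
    ]
    scens += [
        Scenario(label, "k", float(k), base.with_k(float(k), m=m_fixed))
        for label, k in k_values.items()
    ]
    return ScenarioGrid(tuple(scens), tuple(strata), base)


def default_grid(
    strata: Sequence[str] = DEFAULT_STRATA, base: Optional[LifeHistory] = None
) -> ScenarioGrid:
    """Default preset: 10 L_inf values 55-64 mm + 3 k scenarios = 65 combos."""
    return build_grid(np.arange(55.0, 65.0, 1.0), strata=strata, base=base)


def table2_grid(
    strata: Sequence[str] = DEFAULT_STRATA, base: Optional[LifeHistory] = None
) -> ScenarioGrid:
    """Alternative preset with the 11-value L_inf sweep 55-65 mm (70 combos).

    The 10-value and 11-value readings of the sweep are mutually
    inconsistent in the source design; this preset is provided alongside the
    default and logs a note when built.
    """
    logger.info(
        "table2 preset: 11 L_inf values (55-65 mm) -> %d combinations; the "
        "default preset uses 10 values (55-64 mm) -> 65",
        (11 + len(K_SCENARIOS)) * len(list(strata)),
    )
    return build_grid(np.arange(55.0, 66.0, 1.0), strata=strata, base=base)


@dataclass(frozen=True)
class ScenarioResults:
    """Per-stratum scenario summaries plus the retained annual estimates."""

    summary: pd.DataFrame  # stratum, label, kind, value, spr_median, spr_sd, n_years
    annual: pd.DataFrame  # stratum, label, kind, value, year, spr, ...


def run_sensitivity(
    grid: ScenarioGrid,
    comps: Sequence[LengthComposition],
    min_n: int = 100,
) -> ScenarioResults:
    """Re-fit every scenario x stratum and summarise annual SPR estimates.

    For each scenario the life history is modified, :func:`fit_series` is run
    on that stratum's annual compositions, and the median and SD of the
    annual SPR values are reported.  Per-cell fit failures propagate as
    missing annual values; a scenario with no successful fit yields an
    explicit empty (NaN) summary row.  The base life history is never
    mutated.
    """
    by_stratum: dict[str, list[LengthComposition]] = {s: [] for s in grid.strata}
    for comp in comps:
        if comp.stratum in by_stratum:
            by_stratum[comp.stratum].append(comp)
    summary_rows = []
    annual_rows = []
    for scen in grid.scenarios:
        for stratum in grid.strata:
            table = fit_series(by_stratum[stratum], scen.life_history, min_n=min_n)
            ok = table[table["status"] == "ok"] if not table.empty else table
            sprs = ok["spr"].to_numpy(float) if not ok.empty else np.array([])
            for _, row in table.iterrows():
                annual_rows.append(
                    {
                        "stratum": stratum,
                        "label": scen.label,
                        "kind": scen.kind,
                        "value": scen.value,
                        "year": row["year"],
                        "spr": row["spr"],
                        "spr_sd": row["spr_sd"],
                        "status": row["status"],
                    }
                )
            summary_rows.append(
                {
                    "stratum": stratum,
                    "label": scen.label,
                    "kind": scen.kind,
                    "value": scen.value,
                    "spr_median": float(np.median(sprs)) if sprs.size else np.nan,
                    "spr_sd": float(np.std(sprs, ddof=1)) if sprs.size > 1 else np.nan,
                    "n_years": int(sprs.size),
                }
            )
    return ScenarioResults(
        summary=pd.DataFrame(summary_rows), annual=pd.DataFrame(annual_rows)
    )
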