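"""Synthetic SISO-like fishery data with known ground truth.

The generator emulates the structure of the observer length-monitoring
programme: per-animal total lengths grouped by month, year and management
stratum (five strata, with the Joinville Island stratum present only in its
two monitored years), plus a monthly environmental panel (SST, SIC, Chla)
with a configured correlation and effect structure.

Lengths for a stratum-year cell are drawn multinomially from the equilibrium
model's expected catch composition under that stratum's true fleet
parameters, so every downstream estimate can be checked against a known
truth.  Environmental effects act on the cell mean-length scale of the panel
(they do not distort the within-cell composition shape), which keeps the
LBSPR truth interpretable; this simplification is documented in the methods
note.

One global seed expands into independent substreams (environment, year
effects, cell noise, length sampling) so modules can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .biology import FleetPars, LifeHistory, ParameterError, base_krill
from .equilibrium import LengthGrid, build_gtg, equilibrium_numbers, expected_catch_composition, spr
from .lbspr import LengthComposition

__all__ = [
    "TruthConfig",
    "SimulatedStudy",
    "default_truth",
    "simulate_length_composition",
    "simulate_panel",
]

DEFAULT_STRATA = ("BS", "EI", "GS", "JOIN", "SSWI")
JOIN_YEARS = (2016, 2017)


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth configuration for one synthetic study.

    The defaults are the study conditions the package is exercised under:
    five strata over 2000-2020 (JOIN only 2016-2017), a shared life history,
    stratum-specific fishing pressure, and an environmental panel whose
    correlation and coefficient structure matches the documented presets.
    """

    seed: int
    life_history: LifeHistory = field(default_factory=base_krill)
    fleet_by_stratum: Mapping[str, FleetPars] = field(
        default_factory=lambda: {
            "BS": FleetPars(38.0, 45.0, 2.0),
            "EI": FleetPars(38.0, 45.0, 0.8),
            "GS": FleetPars(38.0, 45.0, 2.5),
            "JOIN": FleetPars(38.0, 45.0, 1.0),
            "SSWI": FleetPars(38.0, 45.0, 0.9),
        }
    )
    years_by_stratum: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {
            "BS": tuple(range(2000, 2021)),
            "EI": tuple(range(2000, 2021)),
            "GS": tuple(range(2000, 2021)),
            "JOIN": JOIN_YEARS,
            "SSWI": tuple(range(2000, 2021)),
        }
    )
    n_per_cell: int = 8000  # animals per stratum-year
    months: Sequence[int] = (1, 2, 3, 4, 5, 6)
    # environmental panel structure
    beta0: float = 45.0
    stratum_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "BS": 0.0,
            "EI": 1.8,
            "GS": 4.07,
            "JOIN": 0.49,
            "SSWI": 1.2,
        }
    )
    beta_sic: float = -0.0086
    beta_sst: float = 0.25
    beta_chla: float = -1.6
    beta_sst_chla: float = -0.11
    sst_mean: float = 0.5
    sst_sd: float = 1.5
    chla_mean: float = 1.2
    chla_sd: float = 0.5
    sic_mean: float = 45.0
    sic_sd: float = 25.0
    corr_chla_sst: float = -0.73
    var_year: float = 0.5
    var_resid: float = 1.0

    def __post_init__(self):
        if self.n_per_cell < 0:
            raise ParameterError("n_per_cell must be non-negative")
        if not -1 < self.corr_chla_sst < 1:
            raise ParameterError("corr_chla_sst must lie in (-1, 1)")
        if self.var_year < 0 or self.var_resid < 0:
            raise ParameterError("variance components must be non-negative")
        for s in self.years_by_stratum:
            if s not in self.fleet_by_stratum:
                raise ParameterError(f"no fleet truth for stratum {s!r}")


def default_truth(seed: int, **overrides) -> TruthConfig:
    """The default study conditions with a caller-supplied seed."""
    return TruthConfig(seed=seed, **overrides)


def simulate_length_composition(
    lh: LifeHistory,
    fleet: FleetPars,
    n: int,
    seed,
    grid: Optional[LengthGrid] = None,
    **meta,
) -> LengthComposition:
    """Draw one binned composition multinomially from the model's expectation.

    ``seed`` may be an int, a SeedSequence or a Generator; identical seeds
    give identical counts.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = LengthGrid.for_life_history(lh)
    gtg = build_gtg(lh)
    numbers = equilibrium_numbers(lh, fleet, grid, gtg)
    p = expected_catch_composition(numbers, fleet, grid)
    counts = rng.multinomial(n, p)
    return LengthComposition(counts.astype(float), grid, **meta)


@dataclass(frozen=True)
class SimulatedStudy:
    """Per-animal records, environmental panel and the truth ledger."""

    records: pd.DataFrame
    env_panel: pd.DataFrame
    truth: dict


def _cell_index(cfg: TruthConfig) -> pd.DataFrame:
    rows = [
        {"stratum": s, "year": int(y), "month": int(m)}
        for s in sorted(cfg.years_by_stratum)
        for y in sorted(cfg.years_by_stratum[s])
        for m in cfg.months
    ]
    return pd.DataFrame(rows)


def simulate_panel(cfg: TruthConfig) -> SimulatedStudy:
    """Generate one full synthetic study from a truth configuration.

    Returns per-animal length records (one row per animal with date and
    stratum), the monthly environmental panel with cell mean lengths built
    from the linear predictor plus year and residual noise, and a truth
    ledger holding every parameter, the per-stratum true SPR values and the
    substream seeds.
    """
    ss = np.random.SeedSequence(cfg.seed)
    env_ss, year_ss, noise_ss, len_ss = ss.spawn(4)
    r_env = np.random.default_rng(env_ss)
    r_year = np.random.default_rng(year_ss)
    r_noise = np.random.default_rng(noise_ss)

    cells = _cell_index(cfg)
    ncell = len(cells)

    # correlated (SST, Chla) via a Cholesky factor; SIC independent
    z = r_env.standard_normal((ncell, 2))
    rho = cfg.corr_chla_sst
    z_sst = z[:, 0]
    z_chla = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    cells["sst"] = cfg.sst_mean + cfg.sst_sd * z_sst
    cells["chla"] = np.clip(cfg.chla_mean + cfg.chla_sd * z_chla, 0.01, None)
    cells["sic"] = np.clip(
        r_env.normal(cfg.sic_mean, cfg.sic_sd, ncell), 0.0, 100.0
    )

    years_all = np.sort(cells["year"].unique())
    year_eff = dict(
        zip(years_all, r_year.normal(0.0, np.sqrt(cfg.var_year), years_all.size))
    )
    offsets = cells["stratum"].map(cfg.stratum_offsets).to_numpy(float)
    lin = (
        cfg.beta0
        + offsets
        + cfg.beta_sic * cells["sic"].to_numpy()
        + cfg.beta_sst * cells["sst"].to_numpy()
        + cfg.beta_chla * cells["chla"].to_numpy()
        + cfg.beta_sst_chla * (cells["sst"] * cells["chla"]).to_numpy()
    )
    lin = lin + cells["year"].map(year_eff).to_numpy(float)
    cells["mean_length"] = lin + r_noise.normal(
        0.0, np.sqrt(cfg.var_resid), ncell
    )
    cells["n_obs"] = (
        cfg.n_per_cell // len(cfg.months) if cfg.n_per_cell else 0
    )

    # per-animal records, one composition draw per stratum-year
    rec_frames = []
    true_spr = {}
    if cfg.n_per_cell > 0:
        grid = LengthGrid.for_life_history(cfg.life_history)
        months = np.asarray(cfg.months)
        children = len_ss.spawn(
            sum(len(cfg.years_by_stratum[s]) for s in sorted(cfg.years_by_stratum))
        )
        child_iter = iter(children)
        for stratum in sorted(cfg.years_by_stratum):
            fleet = cfg.fleet_by_stratum[stratum]
            true_spr[stratum] = spr(cfg.life_history, fleet, grid)
            for year in sorted(cfg.years_by_stratum[stratum]):
                child = next(child_iter)
                rng = np.random.default_rng(child)
                comp = simulate_length_composition(
                    cfg.life_history, fleet, cfg.n_per_cell, rng, grid=grid
                )
                lengths = np.repeat(grid.lower_edges, comp.counts.astype(int))
                lengths = lengths + rng.uniform(0.0, grid.bin_width, lengths.size)
                month = rng.choice(months, lengths.size)
                rec_frames.append(
                    pd.DataFrame(
                        {
                            "length_mm": np.round(lengths, 2),
                            "date": pd.to_datetime(
                                {
                                    "year": np.full(lengths.size, year),
                                    "month": month,
                                    "day": np.full(lengths.size, 15),
                                }
                            ),
                            "stratum": stratum,
                            "vessel": "SYN-01",
                            "nationality": "SYN",
                        }
                    )
                )
    else:
        for stratum in sorted(cfg.years_by_stratum):
            true_spr[stratum] = np.nan
    records = (
        pd.concat(rec_frames, ignore_index=True)
        if rec_frames
        else pd.DataFrame(
            columns=["length_mm", "date", "stratum", "vessel", "nationality"]
        )
    )

    truth = {
        "config": _config_dict(cfg),
        "true_spr_by_stratum": true_spr,
        "year_effects": {int(y): float(v) for y, v in year_eff.items()},
        "substreams": {
            "env": env_ss.entropy,
            "year": year_ss.entropy,
            "noise": noise_ss.entropy,
            "lengths": len_ss.entropy,
        },
    }
    return SimulatedStudy(records=records, env_panel=cells, truth=truth)


def _config_dict(cfg: TruthConfig) -> dict:
    d = asdict(cfg)
    d["life_history"] = {
        k: v for k, v in asdict(cfg.life_history).items() if v is not None
    }
    d["fleet_by_stratum"] = {
        s: asdict(f) for s, f in cfg.fleet_by_stratum.items()
    }
    d["years_by_stratum"] = {
        s: list(map(int, ys)) for s, ys in cfg.years_by_stratum.items()
    }
    d["months"] = list(map(int, cfg.months))
    d["stratum_offsets"] = dict(cfg.stratum_offsets)
    return d
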