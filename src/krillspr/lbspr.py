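"""Maximum-likelihood LBSPR fitting from binned length compositions.

The :class:`LBSPR` model object pairs one binned length composition with a
life history; :meth:`LBSPR.fit` estimates the fleet parameters (SL50, SL95,
F/M) by minimising a multinomial negative log-likelihood over the expected
catch composition from the equilibrium model, and reports SPR at the optimum
with a delta-method standard deviation.

Optimisation is carried out in transformed space
``theta = (log F/M, SL50, log(SL95 - SL50))`` so the constraints fm > 0 and
sl50 < sl95 hold automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .biology import FleetPars, LifeHistory, ParameterError
from .equilibrium import (
    DEFAULT_N_GTG,
    DegenerateCompositionError,
    GTGStructure,
    LengthGrid,
    build_gtg,
    equilibrium_numbers,
    expected_catch_composition,
    spr as _spr,
)

__all__ = [
    "LengthComposition",
    "InsufficientSampleError",
    "LBSPR",
    "LBSPRResults",
    "SPREstimate",
    "negloglik",
    "fit_lbspr",
    "fit_series",
]

PROB_FLOOR = 1e-12
DEFAULT_MIN_N = 100
# fewer informative bins than this cannot pin down three fleet parameters
MIN_INFORMATIVE_BINS = 4


class InsufficientSampleError(ValueError):
    """Composition has fewer measured animals than the configured minimum."""


@dataclass(frozen=True)
class LengthComposition:
    """2-mm-binned counts for one stratum x year (x optional month) cell."""

    counts: np.ndarray
    grid: LengthGrid
    stratum: Optional[str] = None
    year: Optional[int] = None
    month: Optional[int] = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size != self.grid.n_bins:
            raise ParameterError("counts must align one-to-one with the grid bins")
        if (counts < 0).any():
            raise ParameterError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ParameterError("composition must contain at least one animal")
        counts.flags.writeable = False
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(round(self.counts.sum()))

    @classmethod
    def from_bins(
        cls,
        lower_edges: Sequence[float],
        counts: Sequence[float],
        bin_width: float = 2.0,
        **meta,
    ) -> "LengthComposition":
        """Build from (possibly unordered) lower-edge/count pairs.

        The bins are sorted by lower edge and densified onto a contiguous
        uniform grid, so estimates are invariant to the input bin order.
        """
        edges = np.asarray(lower_edges, dtype=float)
        vals = np.asarray(counts, dtype=float)
        if edges.size != vals.size:
            raise ParameterError("lower_edges and counts must have equal length")
        order = np.argsort(edges)
        edges, vals = edges[order], vals[order]
        grid = LengthGrid.from_range(
            upper=edges[-1] + bin_width, bin_width=bin_width, lower=edges[0]
        )
        dense = np.zeros(grid.n_bins)
        idx = np.round((edges - grid.lower_edges[0]) / bin_width).astype(int)
        if not np.allclose(grid.lower_edges[idx], edges, atol=1e-9):
            raise ParameterError("bin edges are not aligned to a uniform grid")
        np.add.at(dense, idx, vals)
        return cls(dense, grid, **meta)

    @classmethod
    def from_lengths(
        cls, lengths: Sequence[float], bin_width: float = 2.0, **meta
    ) -> "LengthComposition":
        """Bin raw lengths (mm) into half-open [edge, edge + width) bins at 0."""
        arr = np.asarray(lengths, dtype=float)
        lower = np.floor(arr / bin_width) * bin_width
        edges, counts = np.unique(lower, return_counts=True)
        return cls.from_bins(edges, counts, bin_width=bin_width, **meta)

    def counts_on(self, grid: LengthGrid) -> np.ndarray:
        """Counts mapped onto another uniform grid of the same bin width."""
        if not math.isclose(grid.bin_width, self.grid.bin_width):
            raise ParameterError("bin widths differ; cannot align compositions")
        out = np.zeros(grid.n_bins)
        idx = np.round(
            (self.grid.lower_edges - grid.lower_edges[0]) / grid.bin_width
        ).astype(int)
        inside = (idx >= 0) & (idx < grid.n_bins)
        if not inside.all() and self.counts[~inside].sum() > 0:
            raise ParameterError("composition extends beyond the model grid")
        np.add.at(out, idx[inside], self.counts[inside])
        return out

    def pooled_with(self, other: "LengthComposition") -> "LengthComposition":
        """Pool counts with another composition on a shared grid."""
        lo = min(self.grid.lower_edges[0], other.grid.lower_edges[0])
        hi = max(self.grid.edges[-1], other.grid.edges[-1])
        grid = LengthGrid.from_range(upper=hi, bin_width=self.grid.bin_width, lower=lo)
        return LengthComposition(
            self.counts_on(grid) + other.counts_on(grid),
            grid,
            stratum=self.stratum,
            year=self.year,
            month=None,
        )


def _pack(fleet: FleetPars) -> np.ndarray:
    return np.array(
        [math.log(max(fleet.fm, 1e-8)), fleet.sl50, math.log(fleet.sl95 - fleet.sl50)]
    )


def _unpack(theta: np.ndarray) -> FleetPars:
    fm = math.exp(min(theta[0], 20.0))
    sl50 = theta[1]
    sl95 = sl50 + math.exp(min(theta[2], 20.0))
    return FleetPars(sl50=sl50, sl95=sl95, fm=fm)


class LBSPR:
    """LBSPR model for one length composition under a fixed life history.

    Parameters
    ----------
    comp : LengthComposition
        Observed 2-mm-binned counts.
    life_history : LifeHistory
        Biological parameters (L_inf, CV of L_inf, M/K, maturity, fecundity).
    n_gtg : int
        Number of growth-type groups.
    grid : LengthGrid, optional
        Model grid; defaults to a grid spanning both the life history and the
        observed lengths.
    """

    def __init__(
        self,
        comp: LengthComposition,
        life_history: LifeHistory,
        n_gtg: int = DEFAULT_N_GTG,
        grid: Optional[LengthGrid] = None,
    ):
        self.comp = comp
        self.life_history = life_history
        if grid is None:
            model_grid = LengthGrid.for_life_history(
                life_history, bin_width=comp.grid.bin_width
            )
            upper = max(model_grid.edges[-1], comp.grid.edges[-1])
            grid = LengthGrid.from_range(upper=upper, bin_width=comp.grid.bin_width)
        self.grid = grid
        self.gtg = build_gtg(life_history, n_gtg)
        self.obs_counts = comp.counts_on(grid)
        self.nobs = comp.n

    def predict(self, fleet: FleetPars) -> np.ndarray:
        """Expected catch proportions per bin for one fleet parameter set."""
        numbers = equilibrium_numbers(self.life_history, fleet, self.grid, self.gtg)
        return expected_catch_composition(numbers, fleet, self.grid)

    def negloglik(self, fleet: FleetPars) -> float:
        """Multinomial NLL (up to an additive constant); +inf when infeasible."""
        try:
            p = self.predict(fleet)
        except DegenerateCompositionError:
            return math.inf
        return float(-np.sum(self.obs_counts * np.log(p + PROB_FLOOR)))

    def spr(self, fleet: FleetPars) -> float:
        return _spr(self.life_history, fleet, self.grid, self.gtg)

    def _nll_theta(self, theta: np.ndarray) -> float:
        try:
            return self.negloglik(_unpack(theta))
        except (ParameterError, ValueError, OverflowError):
            return math.inf

    def default_start(self) -> FleetPars:
        """SL50/SL95 from the 25th/75th percentiles of the data, F/M = 1."""
        cum = np.cumsum(self.obs_counts) / self.obs_counts.sum()
        mids = self.grid.mids
        sl50 = float(np.interp(0.25, cum, mids))
        sl95 = float(np.interp(0.75, cum, mids))
        if sl95 - sl50 < self.grid.bin_width:
            sl95 = sl50 + self.grid.bin_width
        return FleetPars(sl50=sl50, sl95=sl95, fm=1.0)

    def fit(
        self,
        start: Optional[FleetPars] = None,
        min_n: int = DEFAULT_MIN_N,
        maxiter: int = 3000,
    ) -> "LBSPRResults":
        """Minimise the multinomial NLL and return an :class:`LBSPRResults`.

        Raises
        ------
        InsufficientSampleError
            If the composition holds fewer than ``min_n`` animals.
        """
        if self.nobs < min_n:
            raise InsufficientSampleError(
                f"insufficient sample: n={self.nobs} < minimum {min_n}"
            )
        if int((self.obs_counts > 0).sum()) < MIN_INFORMATIVE_BINS:
            return self._degenerate_result("insufficient_information")

        x0 = _pack(start if start is not None else self.default_start())
        res = minimize(
            self._nll_theta,
            x0,
            method="Nelder-Mead",
            options=dict(maxiter=maxiter, xatol=1e-5, fatol=1e-8),
        )
        if not res.success:
            # one restart from a perturbed start (+25% on F/M)
            x1 = x0.copy()
            x1[0] += math.log(1.25)
            res2 = minimize(
                self._nll_theta,
                x1,
                method="Nelder-Mead",
                options=dict(maxiter=maxiter, xatol=1e-5, fatol=1e-8),
            )
            if res2.fun < res.fun:
                res = res2
        theta = res.x
        fleet = _unpack(theta)
        spr_hat = self.spr(fleet)
        spr_sd, hessian_ok = self._delta_sd(theta, spr_hat)
        return LBSPRResults(
            model=self,
            fm=fleet.fm,
            sl50=fleet.sl50,
            sl95=fleet.sl95,
            spr=spr_hat,
            spr_sd=spr_sd,
            nll=float(res.fun),
            converged=bool(res.success),
            hessian_ok=hessian_ok,
            n=self.nobs,
            stratum=self.comp.stratum,
            year=self.comp.year,
            status="ok" if res.success else "not_converged",
        )

    def _degenerate_result(self, status: str) -> "LBSPRResults":
        return LBSPRResults(
            model=self,
            fm=math.nan,
            sl50=math.nan,
            sl95=math.nan,
            spr=math.nan,
            spr_sd=math.nan,
            nll=math.nan,
            converged=False,
            hessian_ok=False,
            n=self.nobs,
            stratum=self.comp.stratum,
            year=self.comp.year,
            status=status,
        )

    def _delta_sd(self, theta: np.ndarray, spr_hat: float):
        """Delta-method SD of SPR from the numerical Hessian in theta-space."""
        k = theta.size
        h = 1e-3 * (1.0 + np.abs(theta))
        hess = np.empty((k, k))
        f0 = self._nll_theta(theta)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    fpp = self._nll_theta(theta + ei)
                    fmm = self._nll_theta(theta - ei)
                    hess[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = self._nll_theta(theta + ei + ej)
                    fpm = self._nll_theta(theta + ei - ej)
                    fmp = self._nll_theta(theta - ei + ej)
                    fmm = self._nll_theta(theta - ei - ej)
                    hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                        4 * h[i] * h[j]
                    )
        if not np.all(np.isfinite(hess)):
            return math.nan, False
        try:
            eigvals = np.linalg.eigvalsh(hess)
            if eigvals.min() <= 0:
                return math.nan, False
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return math.nan, False
        grad = np.empty(k)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            try:
                sp = self.spr(_unpack(theta + ei))
                sm = self.spr(_unpack(theta - ei))
            except (ParameterError, ValueError):
                return math.nan, False
            grad[i] = (sp - sm) / (2 * h[i])
        var = float(grad @ cov @ grad)
        if var < 0:
            return math.nan, False
        return math.sqrt(var), True


@dataclass(frozen=True)
class LBSPRResults:
    """Fitted SPR with uncertainty and fleet parameters for one cell."""

    model: LBSPR = field(repr=False)
    fm: float
    sl50: float
    sl95: float
    spr: float
    spr_sd: float
    nll: float
    converged: bool
    hessian_ok: bool
    n: int
    stratum: Optional[str]
    year: Optional[int]
    status: str

    @property
    def fleet(self) -> FleetPars:
        return FleetPars(sl50=self.sl50, sl95=self.sl95, fm=self.fm)

    def to_record(self) -> dict:
        return {
            "stratum": self.stratum,
            "year": self.year,
            "spr": self.spr,
            "spr_sd": self.spr_sd,
            "sl50": self.sl50,
            "sl95": self.sl95,
            "fm": self.fm,
            "nll": self.nll,
            "converged": self.converged,
            "n": self.n,
            "status": self.status,
        }

    def summary(self) -> str:
        lh = self.model.life_history
        lines = [
            "LBSPR fit",
            "=" * 46,
            f"cell:        stratum={self.stratum} year={self.year}",
            f"n measured:  {self.n}",
            f"life hist.:  Linf={lh.linf:.1f} mm  M/K={lh.mk:.3f}  CV={lh.cv_linf:.2f}",
            "-" * 46,
            f"SPR:         {self.spr:.3f} (sd {self.spr_sd:.3f})",
            f"F/M:         {self.fm:.3f}",
            f"SL50:        {self.sl50:.2f} mm",
            f"SL95:        {self.sl95:.2f} mm",
            f"NLL:         {self.nll:.2f}",
            f"converged:   {self.converged} ({self.status})",
        ]
        return "\n".join(lines)


#: Spec-facing alias: the per-cell estimate record type.
SPREstimate = LBSPRResults


def negloglik(fleet: FleetPars, comp: LengthComposition, lh: LifeHistory) -> float:
    """Multinomial negative log-likelihood of ``fleet`` for one composition."""
    return LBSPR(comp, lh).negloglik(fleet)


def fit_lbspr(
    comp: LengthComposition,
    lh: LifeHistory,
    start: Optional[FleetPars] = None,
    n_gtg: int = DEFAULT_N_GTG,
    min_n: int = DEFAULT_MIN_N,
) -> LBSPRResults:
    """Fit (SL50, SL95, F/M) and SPR to one binned length composition."""
    return LBSPR(comp, lh, n_gtg=n_gtg).fit(start=start, min_n=min_n)


def fit_series(
    comps: Iterable[LengthComposition],
    lh: LifeHistory,
    n_gtg: int = DEFAULT_N_GTG,
    min_n: int = DEFAULT_MIN_N,
    pool_months: bool = True,
) -> pd.DataFrame:
    """Fit every stratum x year cell and tabulate the estimates.

    Monthly compositions are pooled to annual cells before fitting unless
    ``pool_months`` is False (in which case each month is fitted separately
    and reported with its month).  Rows are ordered by stratum then year;
    cells whose fit is skipped (insufficient sample) or fails appear as rows
    with NaN estimates and an explanatory ``status``.
    """
    comps = list(comps)
    if not comps:
        return pd.DataFrame(
            columns=[
                "stratum",
                "year",
                "spr",
                "spr_sd",
                "sl50",
                "sl95",
                "fm",
                "nll",
                "converged",
                "n",
                "status",
            ]
        )
    cells: dict = {}
    for comp in comps:
        key = (comp.stratum, comp.year) if pool_months else (
            comp.stratum,
            comp.year,
            comp.month,
        )
        cells[key] = comp if key not in cells else cells[key].pooled_with(comp)
    rows = []
    for key in sorted(cells, key=lambda k: tuple(str(x) for x in k)):
        comp = cells[key]
        try:
            res = LBSPR(comp, lh, n_gtg=n_gtg).fit(min_n=min_n)
            rec = res.to_record()
        except InsufficientSampleError:
            rec = {
                "stratum": comp.stratum,
                "year": comp.year,
                "spr": math.nan,
                "spr_sd": math.nan,
                "sl50": math.nan,
                "sl95": math.nan,
                "fm": math.nan,
                "nll": math.nan,
                "converged": False,
                "n": comp.n,
                "status": "insufficient_sample",
            }
        if not pool_months:
            rec["month"] = comp.month
        rows.append(rec)
    return pd.DataFrame(rows).reset_index(drop=True)
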