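"""Life-history and fleet parameter containers for the krill per-recruit model.

The equilibrium length-structured model is driven entirely by dimensionless
ratios: M/K (natural mortality over von Bertalanffy growth rate) and F/M
(fishing over natural mortality).  Absolute ``m`` and ``k`` are carried as
bookkeeping so that growth-rate scenarios ("low k" etc.) can be expressed in
the units practitioners use, but only their ratio ever enters the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ParameterError",
    "logistic_ogive",
    "LifeHistory",
    "FleetPars",
    "base_krill",
    "management_krill",
    "type_i_krill",
]

LOG19 = math.log(19.0)


class ParameterError(ValueError):
    """Raised when a biological or fleet parameter violates its constraints."""


def logistic_ogive(length, x50: float, x95: float):
    """Two-point logistic ogive: 0.5 at ``x50`` and 0.95 at ``x95``.

    Used for both maturity-at-length and gear selectivity-at-length.

    Parameters
    ----------
    length : array_like
        Length(s) in mm at which to evaluate the ogive.
    x50, x95 : float
        Lengths (mm) at 50% and 95% probability; ``x50 < x95`` required.

    Returns
    -------
    ndarray or float
        Proportion in (0, 1), strictly increasing in length.
    """
    if not x50 < x95:
        raise ParameterError(f"require x50 < x95, got x50={x50}, x95={x95}")
    length = np.asarray(length, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow saturates to 0 correctly
        out = 1.0 / (1.0 + np.exp(-LOG19 * (length - x50) / (x95 - x50)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LifeHistory:
    """Biological parameter set for the per-recruit model.

    Attributes
    ----------
    linf : float
        von Bertalanffy asymptotic total length, mm.
    cv_linf : float
        CV of asymptotic length across growth-type groups (dimensionless).
    mk : float
        M/K ratio.  May be supplied directly or derived from ``m`` and ``k``.
    l50_mat, l95_mat : float
        Lengths (mm) at 50% and 95% maturity.
    fec_exp : float
        Fecundity-length exponent b (egg output proportional to L^b).
    m, k : float, optional
        Absolute natural mortality (1/yr) and growth coefficient (1/yr);
        bookkeeping only, the model uses only their ratio.
    """

    linf: float = 60.0
    cv_linf: float = 0.1
    mk: Optional[float] = None
    l50_mat: float = 35.0
    l95_mat: float = 40.0
    fec_exp: float = 3.0
    m: Optional[float] = None
    k: Optional[float] = None

    def __post_init__(self):
        if self.mk is None:
            if self.m is None or self.k is None:
                raise ParameterError("either mk or both m and k must be given")
            object.__setattr__(self, "mk", self.m / self.k)
        elif self.m is not None and self.k is not None:
            if abs(self.mk - self.m / self.k) >= 1e-9:
                raise ParameterError(
                    f"inconsistent ratio: mk={self.mk} but m/k={self.m / self.k}"
                )
        if self.linf <= 0:
            raise ParameterError("linf must be positive")
        if self.cv_linf < 0:
            raise ParameterError("cv_linf must be non-negative")
        if self.mk <= 0:
            raise ParameterError("mk must be positive")
        if not (0 < self.l50_mat < self.l95_mat < self.linf):
            raise ParameterError(
                "maturity ogive must satisfy 0 < l50_mat < l95_mat < linf"
            )
        if self.fec_exp <= 0:
            raise ParameterError("fec_exp must be positive")

    def maturity(self, length):
        """Maturity ogive evaluated at ``length`` (mm)."""
        return logistic_ogive(length, self.l50_mat, self.l95_mat)

    def with_linf(self, linf: float) -> "LifeHistory":
        """Copy with a new asymptotic length; M/K (and m, k) unchanged."""
        return replace(self, linf=linf)

    def with_k(self, k: float, m: Optional[float] = None) -> "LifeHistory":
        """Copy with a new growth coefficient, recomputing M/K.

        ``m`` defaults to the stored natural mortality (which must then be set).
        """
        m = self.m if m is None else m
        if m is None:
            raise ParameterError("with_k requires an absolute m")
        return replace(self, mk=m / k, m=m, k=k)


@dataclass(frozen=True)
class FleetPars:
    """Logistic gear selectivity and relative fishing pressure.

    Attributes
    ----------
    sl50, sl95 : float
        Lengths (mm) at 50% and 95% selectivity; ``0 < sl50 < sl95``.
    fm : float
        F/M ratio (fishing over natural mortality), >= 0.
    """

    sl50: float
    sl95: float
    fm: float

    def __post_init__(self):
        if not (0 < self.sl50 < self.sl95):
            raise ParameterError("require 0 < sl50 < sl95")
        if self.fm < 0:
            raise ParameterError("fm must be non-negative")

    def selectivity(self, length):
        """Selectivity ogive evaluated at ``length`` (mm)."""
        return logistic_ogive(length, self.sl50, self.sl95)


# ---------------------------------------------------------------------------
# Named life-history presets for Antarctic krill (Euphausia superba).
# All use L_inf = 60 mm, maturity 35/40 mm and a cubic fecundity law; they
# differ only in the growth coefficient anchoring the M/K ratio.


def base_krill(**overrides) -> LifeHistory:
    """Base configuration: m = 0.4, k = 0.45 (M/K ~ 0.889)."""
    kw = dict(linf=60.0, cv_linf=0.1, m=0.4, k=0.45)
    kw.update(overrides)
    return LifeHistory(**kw)


def management_krill(**overrides) -> LifeHistory:
    """Growth coefficient currently used in krill management: k = 0.7."""
    kw = dict(linf=60.0, cv_linf=0.1, m=0.4, k=0.7)
    kw.update(overrides)
    return LifeHistory(**kw)


def type_i_krill(**overrides) -> LifeHistory:
    """Type-I (r-strategy) anchor with M/k ~ 1 (m = 0.4, k = 0.43)."""
    kw = dict(linf=60.0, cv_linf=0.1, m=0.4, k=0.43)
    kw.update(overrides)
    return LifeHistory(**kw)
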