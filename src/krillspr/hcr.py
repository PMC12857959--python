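"""SPR reference points, status classification and the harvest control rule.

The limit reference point is SPR 20% and the target SPR 75%, matching the
depletion and escapement levels of the CCAMLR krill management scheme.  The
hockey-stick harvest control rule maps the ratio SPR/SPR_MSY (SPR_MSY is
identified with the 75% target) to a recommended fishing mortality:

    F = FMSY                          if ratio >= 0.75
    F = FMSY * (ratio - 0.2) / 0.75   if 0.2 <= ratio < 0.75   (printed form)
    F = 0                             if ratio < 0.2

The printed form divides by 0.75 and is therefore discontinuous at the
target (F jumps from FMSY*0.55/0.75 to FMSY).  A ``continuous`` variant that
divides by (0.75 - 0.2) instead is provided; the printed form is the default
to stay faithful to the rule as stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .biology import ParameterError

__all__ = ["Status", "HCRConfig", "classify_status", "hcr_f", "status_table"]


class Status(str, Enum):
    BELOW_LIMIT = "below_limit"
    INTERMEDIATE = "intermediate"
    AT_OR_ABOVE_TARGET = "at_or_above_target"


@dataclass(frozen=True)
class HCRConfig:
    """Reference points and rule variant.

    ``spr_limit``/``spr_target`` are on the SPR (or SPR-ratio) scale;
    ``fmsy`` sets the scale of the recommended F; ``variant`` selects the
    printed or the continuity-corrected rule.
    """

    spr_limit: float = 0.20
    spr_target: float = 0.75
    fmsy: float = 1.0
    variant: str = "printed"

    def __post_init__(self):
        if not (0 < self.spr_limit < self.spr_target <= 1):
            raise ParameterError("require 0 < spr_limit < spr_target <= 1")
        if self.fmsy < 0:
            raise ParameterError("fmsy must be non-negative")
        if self.variant not in ("printed", "continuous"):
            raise ParameterError("variant must be 'printed' or 'continuous'")


def classify_status(spr: float, cfg: HCRConfig = HCRConfig()) -> Status:
    """Classify a value against the limit/target thresholds.

    Below the limit is exclusive (``spr < limit``); the target is inclusive
    (``spr >= target``); the limit boundary itself is intermediate, matching
    the control rule's ``0.2 <=`` branch.
    """
    if not 0 <= spr <= 1:
        raise ParameterError("spr must lie in [0, 1]")
    if spr < cfg.spr_limit:
        return Status.BELOW_LIMIT
    if spr >= cfg.spr_target:
        return Status.AT_OR_ABOVE_TARGET
    return Status.INTERMEDIATE


def hcr_f(spr_ratio: float, cfg: HCRConfig = HCRConfig()) -> float:
    """Recommended fishing mortality for one SPR/SPR_MSY ratio.

    Non-decreasing in the ratio and bounded in [0, fmsy] for both variants.
    """
    if spr_ratio < 0:
        raise ParameterError("spr_ratio must be non-negative")
    if spr_ratio >= cfg.spr_target:
        return cfg.fmsy
    if spr_ratio < cfg.spr_limit:
        return 0.0
    denom = (
        cfg.spr_target
        if cfg.variant == "printed"
        else cfg.spr_target - cfg.spr_limit
    )
    return cfg.fmsy * (spr_ratio - cfg.spr_limit) / denom


def status_table(
    estimates: pd.DataFrame, cfg: HCRConfig = HCRConfig()
) -> pd.DataFrame:
    """One status record per SPR estimate row.

    ``estimates`` needs columns ``stratum``, ``year``, ``spr``.  The ratio
    ``spr / spr_target`` (SPR_MSY identified with the target) is classified
    and passed through the control rule; rows with missing SPR keep NaN/None
    outputs.  Deterministic.
    """
    if estimates.empty:
        raise ParameterError("estimates table must be non-empty")
    rows = []
    for _, row in estimates.iterrows():
        spr = row["spr"]
        if pd.isna(spr):
            rows.append(
                {
                    "stratum": row["stratum"],
                    "year": row["year"],
                    "spr": spr,
                    "spr_ratio": np.nan,
                    "status": None,
                    "recommended_f": np.nan,
                }
            )
            continue
        ratio = float(spr) / cfg.spr_target
        rows.append(
            {
                "stratum": row["stratum"],
                "year": row["year"],
                "spr": float(spr),
                "spr_ratio": ratio,
                "status": classify_status(min(ratio, 1.0), cfg).value,
                "recommended_f": hcr_f(ratio, cfg),
            }
        )
    return pd.DataFrame(rows)
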