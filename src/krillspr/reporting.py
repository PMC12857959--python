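"""Tables, figures and run manifests for the assessment pipeline.

Output layouts mirror the usual reporting surfaces of a strata-by-year SPR
assessment: a wide SPR table (rows = year, one value and one SD column per
stratum, explicit gaps for unmonitored cells), a tidy sensitivity summary,
an HCR status table, and time-series / box-summary figures with the 0.20
limit and 0.75 target reference lines.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .hcr import HCRConfig

__all__ = [
    "spr_wide_table",
    "write_csv",
    "plot_spr_timeseries",
    "plot_sensitivity",
    "build_manifest",
    "write_manifest",
]

FLOAT_FORMAT = "%.6g"


def spr_wide_table(estimates: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy estimates into the wide by-year layout with SD columns.

    Missing stratum-year cells appear as explicit empty entries.  Numbers
    are rounded to 3 decimals; the SD travels in its own column per stratum.
    """
    if estimates.empty:
        return pd.DataFrame()
    val = estimates.pivot_table(
        index="year", columns="stratum", values="spr", aggfunc="first"
    ).round(3)
    sd = estimates.pivot_table(
        index="year", columns="stratum", values="spr_sd", aggfunc="first"
    ).round(3)
    out = pd.DataFrame(index=val.index)
    for stratum in val.columns:
        out[stratum] = val[stratum]
        out[f"{stratum}_sd"] = sd[stratum]
    return out.sort_index()


def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic CSV write (fixed float format, no timestamps)."""
    frame.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def plot_spr_timeseries(
    estimates: pd.DataFrame, cfg: HCRConfig = HCRConfig(), path=None
):
    """SPR time series per stratum with dashed limit/target reference lines.

    Returns ``(figure, metadata)`` where the metadata records the reference
    levels drawn, for inclusion in the run manifest.
    """
    strata = sorted(estimates["stratum"].dropna().unique())
    fig, axes = plt.subplots(
        len(strata), 1, figsize=(7, 2.2 * max(len(strata), 1)), sharex=True,
        squeeze=False,
    )
    for ax, stratum in zip(axes.ravel(), strata):
        sub = estimates[estimates["stratum"] == stratum].sort_values("year")
        ax.errorbar(
            sub["year"], sub["spr"], yerr=sub["spr_sd"], fmt="o-", ms=4, lw=1
        )
        ax.axhline(cfg.spr_target, color="green", ls="--", lw=1)
        ax.axhline(cfg.spr_limit, color="red", ls="--", lw=1)
        ax.set_ylim(0, 1)
        ax.set_ylabel("SPR")
        ax.set_title(stratum, fontsize=9)
    axes.ravel()[-1].set_xlabel("year")
    fig.tight_layout()
    meta = {"reference_limit": cfg.spr_limit, "reference_target": cfg.spr_target}
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, meta


def plot_sensitivity(annual: pd.DataFrame, cfg: HCRConfig = HCRConfig(), path=None):
    """Box summaries of annual SPR per scenario, split by scenario kind."""
    kinds = [k for k in ("linf", "k") if (annual["kind"] == k).any()]
    fig, axes = plt.subplots(
        1, max(len(kinds), 1), figsize=(5.5 * max(len(kinds), 1), 4), squeeze=False
    )
    for ax, kind in zip(axes.ravel(), kinds):
        sub = annual[(annual["kind"] == kind) & annual["spr"].notna()]
        labels = list(dict.fromkeys(sub["label"]))
        data = [sub.loc[sub["label"] == lab, "spr"].to_numpy() for lab in labels]
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(cfg.spr_target, color="green", ls="--", lw=1)
        ax.axhline(cfg.spr_limit, color="red", ls="--", lw=1)
        ax.set_ylabel("SPR")
        ax.set_title(f"{kind} scenarios", fontsize=10)
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    meta = {"reference_limit": cfg.spr_limit, "reference_target": cfg.spr_target}
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig, meta


def build_manifest(
    config: dict,
    seed: Optional[int],
    subcommand: str,
    outputs: list[str],
    warnings: Optional[list[str]] = None,
    extra: Optional[dict] = None,
) -> dict:
    """Machine-readable run manifest: config hash, seed, versions, outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "subcommand": subcommand,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "krillspr": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(outputs),
        "warnings": warnings or [],
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
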