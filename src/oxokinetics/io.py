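"""CSV and JSON interchange for rate panels and fit results.

The tidy rate-table schema has one row per measurement:
``preparation_id, substrate_id, substrate_conc_mM, inhibitor_id,
inhibitor_conc_uM, rate_umol_min_mg, replicate`` plus an optional
``below_floor`` flag (absent flags default to reliable).
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .fitting import OneSiteFit, RateMeasurement, SaturationSeries, TwoSiteFit

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "panel_to_frame",
    "frame_to_panel",
    "read_panel_csv",
    "write_panel_csv",
    "fit_record",
]

REQUIRED_COLUMNS = (
    "preparation_id",
    "substrate_id",
    "substrate_conc_mM",
    "inhibitor_id",
    "inhibitor_conc_uM",
    "rate_umol_min_mg",
    "replicate",
)


class SchemaError(ValueError):
    """The input table does not match the rate-measurement schema."""


def panel_to_frame(series_list: list[SaturationSeries]) -> pd.DataFrame:
    rows = []
    for series in series_list:
        for m in series.measurements:
            rows.append(
                {
                    "preparation_id": series.preparation_id,
                    "substrate_id": series.substrate_id,
                    "substrate_conc_mM": m.substrate_conc,
                    "inhibitor_id": m.inhibitor_id or "",
                    "inhibitor_conc_uM": m.inhibitor_conc,
                    "rate_umol_min_mg": m.rate,
                    "replicate": m.replicate,
                    "below_floor": m.below_floor,
                }
            )
    return pd.DataFrame(rows)


def frame_to_panel(df: pd.DataFrame) -> list[SaturationSeries]:
    """Group a tidy rate table into SaturationSeries (one per inhibitor × [I])."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad = df.index[df["rate_umol_min_mg"].isna() | df["substrate_conc_mM"].isna()]
    if len(bad):
        raise SchemaError(
            f"non-numeric rate/substrate values at row(s): {list(bad[:10])}"
        )
    if "below_floor" not in df.columns:
        df = df.assign(below_floor=False)
    out = []
    keys = ["preparation_id", "substrate_id", "inhibitor_id", "inhibitor_conc_uM"]
    for (prep, sub, inh, conc), grp in df.groupby(keys, sort=True, dropna=False):
        inh_id = None if (not isinstance(inh, str) or inh == "") else inh
        ms = tuple(
            RateMeasurement(
                substrate_conc=float(r.substrate_conc_mM),
                rate=float(r.rate_umol_min_mg),
                inhibitor_id=inh_id,
                inhibitor_conc=float(conc),
                replicate=int(r.replicate),
                below_floor=bool(r.below_floor),
            )
            for r in grp.itertuples()
        )
        out.append(
            SaturationSeries(
                measurements=ms,
                substrate_id=str(sub),
                preparation_id=str(prep),
                inhibitor_id=inh_id,
                inhibitor_conc=float(conc),
            )
        )
    return out


def read_panel_csv(path: str | Path) -> list[SaturationSeries]:
    return frame_to_panel(pd.read_csv(path))


def write_panel_csv(series_list: list[SaturationSeries], path: str | Path) -> None:
    panel_to_frame(series_list).to_csv(path, index=False)


def fit_record(fit: OneSiteFit | TwoSiteFit, series: SaturationSeries) -> dict:
    """JSON-ready record of one fit (one per series × method)."""
    base = {
        "preparation_id": series.preparation_id,
        "substrate_id": series.substrate_id,
        "inhibitor_id": series.inhibitor_id,
        "inhibitor_conc_uM": series.inhibitor_conc,
        "method": fit.method.table_label,
        "r2": _clean(fit.r2),
        "n_points_used": fit.n_points_used,
    }
    if isinstance(fit, TwoSiteFit):
        p = fit.params
        base.update(
            model="two_site",
            km1_mM=p.site1.km,
            amax1=p.site1.amax,
            se_km1=_clean(fit.se_km1),
            se_amax1=_clean(fit.se_amax1),
            km2_mM=p.site2.km,
            amax2=p.site2.amax,
            se_km2=_clean(fit.se_km2),
            se_amax2=_clean(fit.se_amax2),
            degenerate=fit.degenerate,
        )
    else:
        base.update(
            model="one_site",
            km_mM=fit.km,
            amax=fit.amax,
            se_km=_clean(fit.se_km),
            se_amax=_clean(fit.se_amax),
        )
    return base


def _clean(x: float):
    return None if (x is None or not math.isfinite(x)) else float(x)
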