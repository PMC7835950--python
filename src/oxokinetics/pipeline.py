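"""Config-driven orchestration: simulate or ingest → fit → select → Ki → report.

`run_analysis` turns a :class:`RunConfig` into a :class:`Report` holding a
saturation-parameter table (per preparation × substrate, at [I] = 0), a Ki
table (per inhibitor × site × coordinate method plus the cross-method Average),
and mechanism verdicts.  Single-series failures degrade to flagged missing
cells; they never abort the run.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .fitting import (
    FitError,
    OneSiteFit,
    SaturationSeries,
    fit_linearized,
    fit_one_site_nls,
    select_model,
)
from .inhibition import (
    SITE_HIGH,
    SITE_LOW,
    SITE_SINGLE,
    KiEstimate,
    average_ki,
    diagnose_mechanism,
    effective_param_series,
    fit_secondary_plot,
    two_site_ki,
)
from .io import fit_record, frame_to_panel, read_panel_csv
from .models import CoordinateMethod
from .simulate import heart_liver_presets, simulate_inhibition_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "run_analysis", "round_display"]

DEFAULT_METHODS = (CoordinateMethod.NLS, CoordinateMethod.LB, CoordinateMethod.EH)


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings; defaults reproduce the reference analysis
    (threshold 0.98, ranges 0–0.05 / 0.1–10 mM, methods NLS+LB+EH)."""

    mode: str = "simulate"  # "simulate" | "csv"
    preset: str = "heart_OG"
    input_csv: str | None = None
    inhibitors: tuple[str, ...] | None = None  # None = all in the panel
    inhibitor_grids: Mapping[str, tuple[float, ...]] | None = None
    cv: float = 0.03
    replicates: int = 3
    seed: int = 0
    threshold: float = 0.98
    low_max: float = 0.05
    high_min: float = 0.1
    high_max: float = 10.0
    methods: tuple[CoordinateMethod, ...] = DEFAULT_METHODS
    mechanism_i_max: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "csv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "csv" and not self.input_csv:
            raise ValueError("csv mode requires input_csv")
        if self.mode == "simulate" and self.preset not in heart_liver_presets():
            raise ValueError(f"unknown preset {self.preset!r}")
        if not self.low_max < self.high_min:
            raise ValueError("low_max must be < high_min")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if not self.methods:
            raise ValueError("at least one coordinate method is required")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "methods" in raw:
            raw["methods"] = tuple(CoordinateMethod[m] for m in raw["methods"])
        for key in ("inhibitors",):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("inhibitor_grids") is not None:
            raw["inhibitor_grids"] = {
                k: tuple(v) for k, v in raw["inhibitor_grids"].items()
            }
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = {
            "mode": self.mode,
            "preset": self.preset,
            "input_csv": self.input_csv,
            "inhibitors": list(self.inhibitors) if self.inhibitors else None,
            "inhibitor_grids": (
                {k: list(v) for k, v in self.inhibitor_grids.items()}
                if self.inhibitor_grids
                else None
            ),
            "cv": self.cv,
            "replicates": self.replicates,
            "seed": self.seed,
            "threshold": self.threshold,
            "low_max": self.low_max,
            "high_min": self.high_min,
            "high_max": self.high_max,
            "methods": [m.name for m in self.methods],
            "mechanism_i_max": self.mechanism_i_max,
        }
        return d


@dataclass
class Report:
    """Full-precision analysis results plus provenance."""

    saturation_rows: list[dict] = field(default_factory=list)
    ki_rows: list[dict] = field(default_factory=list)
    mechanism: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "saturation": self.saturation_rows,
                "ki": self.ki_rows,
                "mechanism": self.mechanism,
                "failures": self.failures,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
            allow_nan=False,
        )

    def ki_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ki_rows)
        if not df.empty:
            disp = df.apply(
                lambda r: round_display(r.get("ki_uM"), r.get("se_uM")), axis=1
            )
            df["ki_display"] = [d[0] for d in disp]
            df["se_display"] = [d[1] for d in disp]
        return df

    def write(self, out_dir: str | Path, stem: str = "report") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{stem}.json").write_text(self.to_json())
        self.ki_frame().to_csv(out / f"{stem}_ki.csv", index=False)
        pd.DataFrame(self.saturation_rows).to_csv(
            out / f"{stem}_saturation.csv", index=False
        )


def round_display(mean: float | None, sem: float | None) -> tuple[str, str]:
    """Compact display strings: mean to 4 significant figures, SEM to 2.

    Cosmetic only — the JSON report keeps full precision.
    """

    def sig(x: float, n: int) -> str:
        if x == 0:
            return "0"
        exp = math.floor(math.log10(abs(x)))
        decimals = max(0, n - 1 - exp)
        return f"{round(x, n - 1 - exp):.{decimals}f}"

    if mean is None or not math.isfinite(mean):
        return "", ""
    mean_s = sig(mean, 4)
    if sem is None or not math.isfinite(sem):
        return mean_s, ""
    return mean_s, sig(sem, 2)


def _panel_from_config(
    config: RunConfig,
) -> dict[str, dict[float, SaturationSeries]]:
    if config.mode == "simulate":
        sim = heart_liver_presets(cv=config.cv, replicates=config.replicates)[
            config.preset
        ]
        if config.inhibitor_grids:
            grids = dict(sim.inhibitor_grids)
            grids.update({k: tuple(v) for k, v in config.inhibitor_grids.items()})
            sim = dc_replace(sim, inhibitor_grids=grids)
        if config.inhibitors:
            sim = dc_replace(
                sim,
                inhibitor_grids={
                    k: v
                    for k, v in sim.inhibitor_grids.items()
                    if k in config.inhibitors
                },
            )
        return simulate_inhibition_panel(sim, seed=config.seed)
    series_list = read_panel_csv(config.input_csv)
    panel: dict[str, dict[float, SaturationSeries]] = {}
    for series in series_list:
        key = series.inhibitor_id or ""
        panel.setdefault(key, {})[series.inhibitor_conc] = series
    if config.inhibitors:
        panel = {k: v for k, v in panel.items() if k in config.inhibitors}
    return panel


def _one_site_ki(
    series_by_conc: Mapping[float, SaturationSeries],
    config: RunConfig,
    inhibitor_id: str,
    reaction_id: str,
    report: Report,
) -> tuple[KiEstimate | None, list]:
    per_method: dict[CoordinateMethod, tuple[float, float]] = {}
    nls_points = None
    for method in config.methods:
        fits: dict[float, OneSiteFit] = {}
        for conc, series in series_by_conc.items():
            try:
                if method is CoordinateMethod.NLS:
                    fits[conc] = fit_one_site_nls(series)
                else:
                    fits[conc] = fit_linearized(series, method)
            except FitError as exc:
                report.failures.append(
                    {
                        "stage": "primary_fit",
                        "inhibitor_id": inhibitor_id,
                        "inhibitor_conc_uM": conc,
                        "method": method.table_label,
                        "reason": str(exc),
                    }
                )
        if len(fits) < 3 or 0.0 not in fits:
            report.failures.append(
                {
                    "stage": "secondary_fit",
                    "inhibitor_id": inhibitor_id,
                    "method": method.table_label,
                    "reason": "fewer than 3 usable inhibitor concentrations",
                }
            )
            continue
        points = effective_param_series(fits)
        if method is CoordinateMethod.NLS:
            nls_points = points
        sec = fit_secondary_plot(points)
        if sec.no_inhibition:
            report.failures.append(
                {
                    "stage": "secondary_fit",
                    "inhibitor_id": inhibitor_id,
                    "method": method.table_label,
                    "reason": "no measurable inhibition (slope <= 0)",
                }
            )
            continue
        per_method[method] = (sec.ki, sec.se_ki)
        report.ki_rows.append(
            {
                "reaction_id": reaction_id,
                "inhibitor_id": inhibitor_id,
                "site": SITE_SINGLE,
                "method": method.table_label,
                "ki_uM": sec.ki,
                "se_uM": sec.se_ki,
                "secondary_intercept": sec.intercept,
                "secondary_slope": sec.slope,
                "n_points": sec.n_points,
            }
        )
    if not per_method:
        return None, nls_points
    est = average_ki(
        per_method, inhibitor_id=inhibitor_id, reaction_id=reaction_id
    )
    return est, nls_points


def run_analysis(config: RunConfig) -> Report:
    """Run the full analysis described by ``config`` and return the report.

    Deterministic given (config, seed).  The baseline ([I] = 0) series decides
    between the one- and two-site models per inhibitor panel; Ki estimation
    then follows the corresponding single-site or site-resolved path.
    """
    report = Report()
    panel = _panel_from_config(config)
    if not panel or all(not v for v in panel.values()):
        raise FitError("empty panel: nothing to analyze")

    for inhibitor_id in sorted(panel):
        series_by_conc = panel[inhibitor_id]
        if 0.0 not in series_by_conc:
            report.failures.append(
                {
                    "stage": "baseline",
                    "inhibitor_id": inhibitor_id,
                    "reason": "missing [I]=0 series",
                }
            )
            continue
        baseline = series_by_conc[0.0]
        reaction_id = f"{baseline.preparation_id}_{baseline.substrate_id}"
        choice = select_model(baseline, threshold=config.threshold)
        for method in config.methods:
            try:
                if method is CoordinateMethod.NLS:
                    fit = (
                        choice.two_site_fit
                        if choice.selected == "two_site"
                        else choice.one_site_fit
                    )
                else:
                    fit = fit_linearized(baseline, method)
            except FitError as exc:
                report.failures.append(
                    {
                        "stage": "saturation",
                        "inhibitor_id": inhibitor_id,
                        "method": method.table_label,
                        "reason": str(exc),
                    }
                )
                continue
            rec = fit_record(fit, baseline)
            rec.update(
                selected_model=choice.selected,
                r2_one_site=choice.r2_one_site,
                r2_two_site=choice.r2_two_site,
            )
            report.saturation_rows.append(rec)

        if choice.selected == "two_site":
            try:
                high, low = two_site_ki(
                    series_by_conc,
                    methods=config.methods,
                    low_max=config.low_max,
                    high_min=config.high_min,
                    high_max=config.high_max,
                    threshold=config.threshold,
                    inhibitor_id=inhibitor_id,
                    reaction_id=reaction_id,
                )
            except FitError as exc:
                report.failures.append(
                    {
                        "stage": "two_site_ki",
                        "inhibitor_id": inhibitor_id,
                        "reason": str(exc),
                    }
                )
                continue
            for est in (high, low):
                if est is None:
                    continue
                for method, (ki, se) in est.per_method.items():
                    report.ki_rows.append(
                        {
                            "reaction_id": reaction_id,
                            "inhibitor_id": inhibitor_id,
                            "site": est.site_label,
                            "method": method.table_label,
                            "ki_uM": ki,
                            "se_uM": se,
                        }
                    )
                report.ki_rows.append(
                    {
                        "reaction_id": reaction_id,
                        "inhibitor_id": inhibitor_id,
                        "site": est.site_label,
                        "method": "Average",
                        "ki_uM": est.mean_ki,
                        "se_uM": est.sem_ki,
                    }
                )
        else:
            est, nls_points = _one_site_ki(
                series_by_conc, config, inhibitor_id, reaction_id, report
            )
            if est is not None:
                report.ki_rows.append(
                    {
                        "reaction_id": reaction_id,
                        "inhibitor_id": inhibitor_id,
                        "site": SITE_SINGLE,
                        "method": "Average",
                        "ki_uM": est.mean_ki,
                        "se_uM": est.sem_ki,
                    }
                )
            if nls_points is not None:
                try:
                    diag = diagnose_mechanism(
                        nls_points, i_max=config.mechanism_i_max
                    )
                    report.mechanism.append(
                        {
                            "reaction_id": reaction_id,
                            "inhibitor_id": inhibitor_id,
                            "verdict": diag.verdict,
                            "amax_trend_slope": diag.amax_trend_slope,
                            "amax_trend_ci": list(diag.amax_trend_ci),
                        }
                    )
                except FitError as exc:
                    report.failures.append(
                        {
                            "stage": "mechanism",
                            "inhibitor_id": inhibitor_id,
                            "reason": str(exc),
                        }
                    )

    report.ki_rows = _sanitize(report.ki_rows)
    report.saturation_rows = _sanitize(report.saturation_rows)
    report.provenance = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "package": "oxokinetics",
        "version": __version__,
    }
    return report


def _sanitize(rows: list[dict]) -> list[dict]:
    out = []
    for row in rows:
        out.append(
            {
                k: (None if isinstance(v, float) and not math.isfinite(v) else v)
                for k, v in row.items()
            }
        )
    return out
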