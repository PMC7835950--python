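"""Competitive Ki estimation from secondary plots, with error propagation.

For a competitive inhibitor the apparent Michaelis parameters obey

    Km_eff / Amax_eff = (Km / Amax) · (1 + [I]/Ki),

so an ordinary least-squares line of q = Km_eff/Amax_eff against [I] has
intercept Km/Amax and slope Km/(Amax·Ki); Ki is the intercept-to-slope ratio.
Ki values obtained in the three fitting coordinate systems (NLS/LB/EH) are
averaged and reported as mean ± SEM, mirroring how multi-method kinetic tables
are usually presented.

The mechanism itself is diagnosed from the Amax_eff trend: a competitive
inhibitor raises Km_eff but leaves Amax_eff flat over the tested [I] range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .fitting import (
    FitError,
    OneSiteFit,
    SaturationSeries,
    TwoSiteFit,
    fit_linearized,
    fit_two_site_nls,
    select_model,
    split_concentration_ranges,
)
from .models import CoordinateMethod

logger = logging.getLogger(__name__)

__all__ = [
    "EffectiveParamPoint",
    "SecondaryFit",
    "KiEstimate",
    "MechanismDiagnosis",
    "ratio_standard_error",
    "effective_param_series",
    "two_site_effective_series",
    "fit_secondary_plot",
    "average_ki",
    "two_site_ki",
    "diagnose_mechanism",
    "selectivity_ratio",
]

SITE_SINGLE = "single"
SITE_HIGH = "high_affinity"
SITE_LOW = "low_affinity"


def ratio_standard_error(a: float, se_a: float, b: float, se_b: float) -> float:
    """SE of a/b by relative-error quadrature: |a/b|·sqrt((se_a/a)² + (se_b/b)²).

    With a = 0 the relative error of the numerator is undefined and the SE
    degrades gracefully to se_a/|b|.
    """
    if b == 0:
        raise ZeroDivisionError("ratio undefined for b = 0")
    if a == 0:
        return se_a / abs(b)
    return abs(a / b) * math.sqrt((se_a / a) ** 2 + (se_b / b) ** 2)


@dataclass(frozen=True)
class EffectiveParamPoint:
    """Apparent (Km_eff, Amax_eff) at one inhibitor concentration, plus their ratio q."""

    inhibitor_conc: float  # µM
    km_eff: float  # mM
    amax_eff: float
    se_km_eff: float
    se_amax_eff: float
    q: float  # km_eff / amax_eff
    se_q: float
    method: CoordinateMethod
    site_label: str = SITE_SINGLE


@dataclass(frozen=True)
class SecondaryFit:
    """OLS line of q = Km_eff/Amax_eff against [I]; Ki = intercept/slope (µM)."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ki: float  # µM; +inf when no inhibition is measurable
    se_ki: float
    r: float
    n_points: int
    no_inhibition: bool = False


@dataclass(frozen=True)
class KiEstimate:
    """Per-method Ki values and their cross-method mean ± SEM."""

    per_method: Mapping[CoordinateMethod, tuple[float, float]]
    mean_ki: float
    sem_ki: float  # nan when only one method contributed
    site_label: str = SITE_SINGLE
    inhibitor_id: str | None = None
    reaction_id: str | None = None


@dataclass(frozen=True)
class MechanismDiagnosis:
    """Verdict on the inhibition mechanism from the Amax_eff-vs-[I] trend."""

    amax_trend_slope: float
    amax_trend_ci: tuple[float, float]  # 95% CI on the slope
    verdict: str  # "competitive" | "mixed"


def _point_from_fit(
    conc: float,
    km: float,
    se_km: float,
    amax: float,
    se_amax: float,
    method: CoordinateMethod,
    site_label: str,
) -> EffectiveParamPoint:
    q = km / amax
    return EffectiveParamPoint(
        inhibitor_conc=conc,
        km_eff=km,
        amax_eff=amax,
        se_km_eff=se_km,
        se_amax_eff=se_amax,
        q=q,
        se_q=ratio_standard_error(km, se_km, amax, se_amax),
        method=method,
        site_label=site_label,
    )


def effective_param_series(
    fits_by_conc: Mapping[float, OneSiteFit],
    site_label: str = SITE_SINGLE,
) -> list[EffectiveParamPoint]:
    """Turn per-[I] one-site fits into an (Km_eff/Amax_eff, [I]) point series.

    Requires at least three distinct inhibitor concentrations including the
    uninhibited baseline ([I] = 0).
    """
    concs = sorted(fits_by_conc)
    if len(concs) < 3:
        raise FitError("secondary analysis needs >= 3 inhibitor concentrations")
    if 0.0 not in concs:
        raise FitError("missing [I] = 0 baseline fit")
    methods = {f.method for f in fits_by_conc.values()}
    if len(methods) != 1:
        raise FitError("all fits in one series must share the coordinate method")
    return [
        _point_from_fit(
            c,
            fits_by_conc[c].km,
            fits_by_conc[c].se_km,
            fits_by_conc[c].amax,
            fits_by_conc[c].se_amax,
            fits_by_conc[c].method,
            site_label,
        )
        for c in concs
    ]


def _matched_sites(
    fits_by_conc: Mapping[float, TwoSiteFit],
) -> dict[float, tuple[tuple, tuple]]:
    """Per-[I] site tuples (km, se_km, amax, se_amax) with identity tracked by Amax.

    A competitive inhibitor shifts Km_eff but leaves Amax unchanged, so site
    identity across inhibitor concentrations is assigned by Amax proximity to
    the uninhibited baseline, not by Km ordering — strong inhibition of the
    high-affinity site can push its Km_eff past the other site's.
    The first tuple of each pair is the site matched to the baseline
    high-affinity (smaller-Km) site.
    """
    if 0.0 not in fits_by_conc:
        raise FitError("missing [I] = 0 baseline fit")
    f0 = fits_by_conc[0.0]
    a1_0, a2_0 = f0.params.site1.amax, f0.params.site2.amax
    out = {}
    for c, f in fits_by_conc.items():
        p = f.params
        s1 = (p.site1.km, f.se_km1, p.site1.amax, f.se_amax1)
        s2 = (p.site2.km, f.se_km2, p.site2.amax, f.se_amax2)
        direct = abs(s1[2] - a1_0) + abs(s2[2] - a2_0)
        swapped = abs(s2[2] - a1_0) + abs(s1[2] - a2_0)
        out[c] = (s1, s2) if direct <= swapped else (s2, s1)
    return out


def two_site_effective_series(
    fits_by_conc: Mapping[float, TwoSiteFit],
) -> tuple[list[EffectiveParamPoint], list[EffectiveParamPoint]]:
    """Split per-[I] two-site fits into parallel high- and low-affinity point series.

    Site identity is carried across concentrations by Amax matching to the
    baseline (see :func:`_matched_sites`).
    """
    concs = sorted(fits_by_conc)
    if len(concs) < 3:
        raise FitError("secondary analysis needs >= 3 inhibitor concentrations")
    matched = _matched_sites(fits_by_conc)
    high, low = [], []
    for c in concs:
        (hk, hsk, ha, hsa), (lk, lsk, la, lsa) = matched[c]
        method = fits_by_conc[c].method
        high.append(_point_from_fit(c, hk, hsk, ha, hsa, method, SITE_HIGH))
        low.append(_point_from_fit(c, lk, lsk, la, lsa, method, SITE_LOW))
    return high, low


def fit_secondary_plot(
    points: Sequence[EffectiveParamPoint], *, weighted: bool = False
) -> SecondaryFit:
    """Regress q = Km_eff/Amax_eff on [I] and invert to Ki = intercept/slope.

    A non-positive slope means the inhibitor produced no measurable increase in
    q over the tested range; that is reported as ``no_inhibition`` (Ki = +inf)
    rather than as a negative constant.  ``weighted=True`` uses 1/se_q² weights
    (off by default).
    """
    if len(points) < 3:
        raise FitError("secondary plot needs >= 3 points")
    if len({p.method for p in points}) != 1 or len({p.site_label for p in points}) != 1:
        raise FitError("secondary plot points must share method and site label")
    x = np.array([p.inhibitor_conc for p in points])
    y = np.array([p.q for p in points])
    if weighted:
        w = 1.0 / np.array([max(p.se_q, 1e-300) for p in points]) ** 2
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta, cov = _wls(X, y, W)
        intercept, slope = beta
        se_intercept, se_slope = np.sqrt(np.diag(cov))
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        res = stats.linregress(x, y)
        intercept, slope = res.intercept, res.slope
        se_intercept, se_slope = res.intercept_stderr, res.stderr
        r = float(res.rvalue)

    if slope <= 0:
        logger.info("secondary plot slope <= 0: no measurable inhibition")
        return SecondaryFit(
            intercept=float(intercept),
            slope=float(slope),
            se_intercept=float(se_intercept),
            se_slope=float(se_slope),
            ki=math.inf,
            se_ki=math.nan,
            r=r,
            n_points=len(points),
            no_inhibition=True,
        )
    ki = intercept / slope
    se_ki = ratio_standard_error(intercept, se_intercept, slope, se_slope)
    return SecondaryFit(
        intercept=float(intercept),
        slope=float(slope),
        se_intercept=float(se_intercept),
        se_slope=float(se_slope),
        ki=float(ki),
        se_ki=float(se_ki),
        r=r,
        n_points=len(points),
    )


def _wls(X, y, W):
    XtW = X.T @ W
    cov_unscaled = np.linalg.inv(XtW @ X)
    beta = cov_unscaled @ XtW @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    scale = float(resid @ W @ resid) / dof if dof > 0 else math.nan
    return beta, cov_unscaled * scale


def average_ki(
    per_method: Mapping[CoordinateMethod, tuple[float, float] | float],
    *,
    site_label: str = SITE_SINGLE,
    inhibitor_id: str | None = None,
    reaction_id: str | None = None,
) -> KiEstimate:
    """Cross-method mean ± SEM of Ki (sample SD with n−1, divided by √n).

    With a single contributing method the mean is returned and the SEM flagged
    undefined (nan).
    """
    if not per_method:
        raise FitError("no Ki values to average")
    norm: dict[CoordinateMethod, tuple[float, float]] = {}
    for m, v in per_method.items():
        ki, se = v if isinstance(v, tuple) else (v, math.nan)
        if not math.isfinite(ki):
            raise ValueError(f"non-finite Ki for method {m}")
        norm[m] = (float(ki), float(se))
    kis = np.array([v[0] for v in norm.values()])
    mean = float(kis.mean())
    sem = float(kis.std(ddof=1) / math.sqrt(len(kis))) if len(kis) > 1 else math.nan
    if len(kis) == 1:
        logger.info("single-method Ki: SEM undefined")
    return KiEstimate(
        per_method=norm,
        mean_ki=mean,
        sem_ki=sem,
        site_label=site_label,
        inhibitor_id=inhibitor_id,
        reaction_id=reaction_id,
    )


def two_site_ki(
    series_by_conc: Mapping[float, SaturationSeries],
    *,
    methods: Sequence[CoordinateMethod] = (
        CoordinateMethod.NLS,
        CoordinateMethod.LB,
        CoordinateMethod.EH,
    ),
    low_max: float = 0.05,
    high_min: float = 0.1,
    high_max: float = 10.0,
    threshold: float = 0.98,
    inhibitor_id: str | None = None,
    reaction_id: str | None = None,
) -> tuple[KiEstimate, KiEstimate]:
    """Site-resolved Ki for a biphasic preparation.

    The NLS path fits the full-range two-site model at each [I] and follows
    each site's (Km_eff, Amax_eff) through its own secondary plot, with site
    identity tracked across concentrations by Amax (unchanged under competitive
    inhibition).  The linearized paths (LB/EH) cannot fit two sites at once;
    because the two Km values differ by orders of magnitude, each series is
    split into low and high substrate ranges that isolate one site class
    apiece.  Within each range the other site class still contributes a
    non-negligible background, so its per-[I] fitted contribution is subtracted
    before the one-site linearized fit — without this correction the
    high-affinity Ki is systematically overestimated by tens of percent.

    Per-[I] fit failures (site collapse, too few usable points) exclude that
    concentration from the affected method with a log entry; a method with
    fewer than three surviving concentrations is dropped.  Requires the
    uninhibited baseline to actually select the two-site model.

    Returns ``(high_affinity, low_affinity)`` Ki estimates; a site the dose
    grid did not usefully probe (no method survived, or no measurable
    inhibition) comes back as ``None``.
    """
    if 0.0 not in series_by_conc:
        raise FitError("missing [I] = 0 baseline series")
    baseline = select_model(series_by_conc[0.0], threshold=threshold)
    if baseline.selected != "two_site":
        raise FitError(
            "two_site_ki requires a preparation whose baseline saturation "
            f"selects the two-site model (one-site R2={baseline.r2_one_site:.4f})"
        )

    # Shared per-[I] two-site NLS fits: the NLS secondary plots read them
    # directly, and the linearized paths use them to subtract the other site's
    # contribution from each substrate range.
    nls_fits: dict[float, TwoSiteFit] = {}
    for conc, series in series_by_conc.items():
        try:
            f = fit_two_site_nls(series)
        except FitError as exc:
            logger.warning("[I]=%g excluded from two-site fits: %s", conc, exc)
            continue
        if f.degenerate:
            logger.warning("[I]=%g excluded: site collapse in two-site fit", conc)
            continue
        nls_fits[conc] = f
    if len(nls_fits) < 3 or 0.0 not in nls_fits:
        raise FitError("too few inhibitor concentrations with resolvable sites")
    matched = _matched_sites(nls_fits)

    per_method_high: dict[CoordinateMethod, tuple[float, float]] = {}
    per_method_low: dict[CoordinateMethod, tuple[float, float]] = {}

    for method in methods:
        if method is CoordinateMethod.NLS:
            high_pts, low_pts = two_site_effective_series(nls_fits)
        else:
            high_pts, low_pts = [], []
            for conc in sorted(nls_fits):
                series = series_by_conc[conc]
                (hk, _, ha, _), (lk, _, la, _) = matched[conc]
                try:
                    low_series, high_series = split_concentration_ranges(
                        series, low_max=low_max, high_min=high_min, high_max=high_max
                    )
                except FitError as exc:
                    logger.warning(
                        "[I]=%g excluded from %s path: %s", conc, method.value, exc
                    )
                    continue
                # each range is corrected for the other site class's fitted
                # contribution so the one-site line sees a single site; the
                # ranges fail independently (e.g. strong inhibition can push a
                # whole range below the detection floor)
                for rng, other, pts, label in (
                    (low_series, (lk, la), high_pts, SITE_HIGH),
                    (high_series, (hk, ha), low_pts, SITE_LOW),
                ):
                    try:
                        f = fit_linearized(_subtract_site(rng, *other), method)
                    except FitError as exc:
                        logger.warning(
                            "[I]=%g %s excluded from %s path: %s",
                            conc, label, method.value, exc,
                        )
                        continue
                    pts.append(
                        _point_from_fit(
                            conc, f.km, f.se_km, f.amax, f.se_amax, method, label
                        )
                    )

        for pts, store in ((high_pts, per_method_high), (low_pts, per_method_low)):
            concs = {p.inhibitor_conc for p in pts}
            if len(concs) < 3 or 0.0 not in concs:
                logger.warning(
                    "%s/%s dropped: too few usable concentrations",
                    method.value,
                    pts[0].site_label if pts else "?",
                )
                continue
            sec = fit_secondary_plot(pts)
            if sec.no_inhibition:
                logger.info(
                    "%s/%s: no measurable inhibition", method.value, pts[0].site_label
                )
                continue
            store[method] = (sec.ki, sec.se_ki)

    if not per_method_high and not per_method_low:
        raise FitError("no coordinate method produced a usable secondary plot")
    mk = lambda d, label: (
        average_ki(
            d, site_label=label, inhibitor_id=inhibitor_id, reaction_id=reaction_id
        )
        if d
        else None
    )
    return mk(per_method_high, SITE_HIGH), mk(per_method_low, SITE_LOW)


def _subtract_site(series: SaturationSeries, km: float, amax: float) -> SaturationSeries:
    """Series with one fitted site's Michaelis contribution removed from each rate."""
    from dataclasses import replace

    ms = tuple(
        replace(
            m,
            rate=m.rate - amax * m.substrate_conc / (km + m.substrate_conc),
        )
        for m in series.measurements
    )
    return replace(series, measurements=ms)


def diagnose_mechanism(
    points: Sequence[EffectiveParamPoint],
    i_max: float = 200.0,
    alpha: float = 0.05,
) -> MechanismDiagnosis:
    """Competitive vs mixed inhibition from the Amax_eff trend over [I] ≤ i_max.

    The verdict is ``competitive`` unless the 95% confidence interval of the
    Amax_eff-vs-[I] slope lies entirely below zero (a significant loss of
    maximal activity, pointing to a mixed mechanism).
    """
    pts = [p for p in points if p.inhibitor_conc <= i_max]
    if len(pts) < 3:
        raise FitError("mechanism diagnosis needs >= 3 points within i_max")
    x = np.array([p.inhibitor_conc for p in pts])
    y = np.array([p.amax_eff for p in pts])
    if np.allclose(y, y[0]):
        return MechanismDiagnosis(0.0, (0.0, 0.0), "competitive")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - alpha / 2, len(pts) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    verdict = "mixed" if ci[1] < 0 else "competitive"
    return MechanismDiagnosis(float(res.slope), (float(ci[0]), float(ci[1])), verdict)


def selectivity_ratio(ki_a: KiEstimate, ki_b: KiEstimate) -> tuple[float, float]:
    """Ratio of two mean Ki values with its propagated SE — the selectivity summary."""
    if ki_b.mean_ki == 0:
        raise ZeroDivisionError("selectivity ratio undefined for zero denominator")
    if ki_a.mean_ki <= 0 or ki_b.mean_ki <= 0:
        raise ValueError("selectivity ratio requires positive mean Ki values")
    ratio = ki_a.mean_ki / ki_b.mean_ki
    sem_a = ki_a.sem_ki if math.isfinite(ki_a.sem_ki) else 0.0
    sem_b = ki_b.sem_ki if math.isfinite(ki_b.sem_ki) else 0.0
    se = ratio_standard_error(ki_a.mean_ki, sem_a, ki_b.mean_ki, sem_b)
    return ratio, se
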