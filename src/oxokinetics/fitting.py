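"""One- and two-site saturation fitting in three coordinate systems.

A :class:`SaturationSeries` — all rate measurements at one fixed inhibitor
concentration — is the unit of curve fitting.  Each series can be fitted by
direct nonlinear least squares on the Michaelis-Menten hyperbola (NLS), or by
linear regression after the Lineweaver-Burk (LB) or Eadie-Hofstee (EH)
transformation.  A biphasic series is fitted by a sum of two hyperbolas; the
model is escalated from one to two site classes only when the one-site fit is
poor (R² below a threshold, 0.98 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .models import (
    CoordinateMethod,
    SiteParams,
    TwoSiteParams,
    eh_transform,
    lb_transform,
    mm_rate,
    two_site_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitError",
    "FitConvergenceError",
    "RateMeasurement",
    "SaturationSeries",
    "OneSiteFit",
    "TwoSiteFit",
    "ModelChoice",
    "r_squared",
    "fit_one_site_nls",
    "fit_two_site_nls",
    "fit_linearized",
    "split_concentration_ranges",
    "select_model",
]

R2_THRESHOLD_DEFAULT = 0.98
#: minimum distinct substrate concentrations for a defensible one-site fit
MIN_DISTINCT_ONE_SITE = 4
MIN_DISTINCT_TWO_SITE = 7


class FitError(RuntimeError):
    """A fit could not produce physically meaningful estimates."""


class FitConvergenceError(FitError):
    """Optimizer failed to converge from any starting point."""


@dataclass(frozen=True)
class RateMeasurement:
    """One assay point: substrate concentration, inhibitor dose, specific activity."""

    substrate_conc: float  # mM
    rate: float  # µmol·min⁻¹·mg⁻¹
    inhibitor_id: str | None = None
    inhibitor_conc: float = 0.0  # µM
    replicate: int = 0
    below_floor: bool = False

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValueError("substrate_conc must be non-negative")
        if self.inhibitor_conc < 0:
            raise ValueError("inhibitor_conc must be non-negative")


@dataclass(frozen=True)
class SaturationSeries:
    """All measurements at one fixed (inhibitor, [I]); the unit of curve fitting."""

    measurements: tuple[RateMeasurement, ...]
    substrate_id: str = "S"
    preparation_id: str = ""
    inhibitor_id: str | None = None
    inhibitor_conc: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        for m in self.measurements:
            if (m.inhibitor_id, m.inhibitor_conc) != (
                self.inhibitor_id,
                self.inhibitor_conc,
            ):
                raise ValueError(
                    "all measurements in a series must share inhibitor identity "
                    "and concentration"
                )

    @classmethod
    def from_arrays(
        cls,
        s,
        rate,
        *,
        below_floor=None,
        substrate_id: str = "S",
        preparation_id: str = "",
        inhibitor_id: str | None = None,
        inhibitor_conc: float = 0.0,
        replicate=None,
    ) -> "SaturationSeries":
        s = np.asarray(s, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if s.shape != rate.shape:
            raise ValueError("s and rate must have the same shape")
        below = (
            np.zeros(s.shape, dtype=bool)
            if below_floor is None
            else np.asarray(below_floor, dtype=bool)
        )
        rep = np.zeros(s.shape, dtype=int) if replicate is None else np.asarray(replicate)
        ms = [
            RateMeasurement(
                substrate_conc=float(si),
                rate=float(ai),
                inhibitor_id=inhibitor_id,
                inhibitor_conc=inhibitor_conc,
                replicate=int(ri),
                below_floor=bool(bi),
            )
            for si, ai, bi, ri in zip(s, rate, below, rep)
        ]
        return cls(
            measurements=tuple(ms),
            substrate_id=substrate_id,
            preparation_id=preparation_id,
            inhibitor_id=inhibitor_id,
            inhibitor_conc=inhibitor_conc,
        )

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def s(self) -> np.ndarray:
        return np.array([m.substrate_conc for m in self.measurements])

    @property
    def rate(self) -> np.ndarray:
        return np.array([m.rate for m in self.measurements])

    @property
    def below_floor(self) -> np.ndarray:
        return np.array([m.below_floor for m in self.measurements])

    def n_distinct_s(self) -> int:
        return len({m.substrate_conc for m in self.measurements})

    def transform_points(self) -> np.ndarray:
        """(s, a) pairs eligible for linearized fits: below-floor rates dropped.

        Reciprocal-style transforms amplify noise of the smallest rates, so
        measurements flagged below the detection floor are withheld from them
        (they remain in the nonlinear fits).
        """
        keep = [m for m in self.measurements if not m.below_floor]
        n_floor = len(self.measurements) - len(keep)
        if n_floor:
            logger.info(
                "series %s/%s [I]=%g: %d below-floor point(s) withheld from "
                "linearized fits",
                self.preparation_id,
                self.substrate_id,
                self.inhibitor_conc,
                n_floor,
            )
        return np.array([[m.substrate_conc, m.rate] for m in keep]).reshape(-1, 2)


@dataclass(frozen=True)
class OneSiteFit:
    """Single-site Michaelis fit: Km/Amax with asymptotic SEs and R²."""

    km: float
    amax: float
    se_km: float
    se_amax: float
    r2: float
    method: CoordinateMethod
    n_points_used: int
    n_excluded: int = 0

    @property
    def params(self) -> SiteParams:
        return SiteParams(km=self.km, amax=self.amax)


@dataclass(frozen=True)
class TwoSiteFit:
    """Two-site fit with canonical site ordering (km1 < km2)."""

    params: TwoSiteParams
    se_km1: float
    se_amax1: float
    se_km2: float
    se_amax2: float
    r2: float
    method: CoordinateMethod
    n_points_used: int
    degenerate: bool = False  # km2 within 2x of km1: sites not resolved


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of the one- vs two-site escalation rule."""

    selected: str  # "one_site" | "two_site"
    r2_one_site: float
    r2_two_site: float | None
    threshold: float
    one_site_fit: OneSiteFit
    two_site_fit: TwoSiteFit | None


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed rates have zero variance; R² undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _check_series(series: SaturationSeries, min_distinct: int, what: str) -> None:
    if series.n_distinct_s() < min_distinct:
        raise FitError(
            f"{what} needs >= {min_distinct} distinct substrate concentrations, "
            f"got {series.n_distinct_s()}"
        )


def _weights(series: SaturationSeries, weighted: bool) -> np.ndarray | None:
    if not weighted:
        return None
    # 1/rate sigma proxy for multiplicative error; zero rates get unit weight
    r = np.abs(series.rate)
    r[r == 0] = np.median(r[r > 0]) if np.any(r > 0) else 1.0
    return r


def fit_one_site_nls(
    series: SaturationSeries, *, weighted: bool = False
) -> OneSiteFit:
    """Nonlinear least-squares Michaelis-Menten fit of one series.

    Multi-start over a log-spaced Km grid guards against bad local minima.
    Raises :class:`FitConvergenceError` when no start converges and
    :class:`FitError` when the solution is unidentifiable (Km at the numerical
    lower bound, as happens for saturation-free or decreasing data).
    """
    _check_series(series, MIN_DISTINCT_ONE_SITE, "one-site fit")
    s, a = series.s, series.rate
    if np.ptp(a) == 0.0:
        raise FitError("rates carry no saturation information (zero variance)")
    amax0 = max(float(a.max()), 1e-12)
    pos = s[s > 0]
    gm = float(np.exp(np.log(pos).mean()))
    sigma = _weights(series, weighted)

    best = None
    for km0 in gm * np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0]):
        try:
            popt, pcov = optimize.curve_fit(
                lambda s_, amax_, km_: amax_ * s_ / (km_ + s_),
                s,
                a,
                p0=[amax0, km0],
                sigma=sigma,
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((a - popt[0] * s / (popt[1] + s)) ** 2))
        if best is None or sse < best[0] - 1e-15 * (1 + best[0]):
            best = (sse, popt, pcov)
    if best is None:
        raise FitConvergenceError("one-site fit did not converge from any start")
    _, popt, pcov = best
    amax, km = popt
    if km <= 2e-9:
        raise FitError("Km collapsed to the lower bound; saturation not identifiable")
    se = np.sqrt(np.diag(pcov))
    r2 = r_squared(a, amax * s / (km + s))
    return OneSiteFit(
        km=float(km),
        amax=float(amax),
        se_km=float(se[1]),
        se_amax=float(se[0]),
        r2=r2,
        method=CoordinateMethod.NLS,
        n_points_used=len(series),
    )


def _two_site_model(s, a1, k1, a2, k2):
    return a1 * s / (k1 + s) + a2 * s / (k2 + s)


def fit_two_site_nls(series: SaturationSeries, *, weighted: bool = False) -> TwoSiteFit:
    """Four-parameter sum-of-two-hyperbolas fit with multi-start.

    Km starting values are placed at {1/100, 1/10, 1, 10} times the geometric
    mean of the substrate grid and tried in all ordered pairs; the best SSE
    wins, ties broken toward the smaller Km1.  The returned fit has the
    high-affinity site first; when the two Km estimates lie within a factor of
    two of each other the sites are not resolved and the fit is flagged
    ``degenerate``.
    """
    _check_series(series, MIN_DISTINCT_TWO_SITE, "two-site fit")
    s, a = series.s, series.rate
    amax0 = max(float(a.max()), 1e-12)
    pos = s[s > 0]
    gm = float(np.exp(np.log(pos).mean()))
    km_seeds = gm * np.array([0.01, 0.1, 1.0, 10.0])
    sigma = _weights(series, weighted)

    best = None
    for i in range(len(km_seeds)):
        for j in range(i + 1, len(km_seeds)):
            p0 = [0.3 * amax0, km_seeds[i], 0.7 * amax0, km_seeds[j]]
            try:
                popt, pcov = optimize.curve_fit(
                    _two_site_model,
                    s,
                    a,
                    p0=p0,
                    sigma=sigma,
                    bounds=([0.0, 1e-9, 0.0, 1e-9], [np.inf] * 4),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((a - _two_site_model(s, *popt)) ** 2))
            km1_cand = min(popt[1], popt[3])
            key = (sse, km1_cand)
            if best is None or key < best[0]:
                best = (key, popt, pcov)
    if best is None:
        raise FitConvergenceError("two-site fit did not converge from any start")
    _, popt, pcov = best
    se = np.sqrt(np.diag(pcov))
    sites = [(popt[1], popt[0], se[1], se[0]), (popt[3], popt[2], se[3], se[2])]
    sites.sort(key=lambda t: t[0])
    (k1, a1, sk1, sa1), (k2, a2, sk2, sa2) = sites
    # collapsed solutions: unresolved affinities, or one site carrying a
    # negligible share of the activity (the data are effectively one-site)
    total_amax = a1 + a2
    degenerate = k2 < 2.0 * k1 or (
        total_amax > 0 and min(a1, a2) / total_amax < 0.01
    )
    if degenerate:
        logger.warning(
            "two-site fit degenerate: km1=%.4g (amax %.3g), km2=%.4g (amax %.3g)",
            k1, a1, k2, a2,
        )
    if k1 == k2:  # canonical ordering needs strict inequality
        k2 = np.nextafter(k2, np.inf)
    params = TwoSiteParams(
        site1=SiteParams(km=float(k1), amax=float(a1)),
        site2=SiteParams(km=float(k2), amax=float(a2)),
    )
    r2 = r_squared(a, _two_site_model(s, *popt))
    return TwoSiteFit(
        params=params,
        se_km1=float(sk1),
        se_amax1=float(sa1),
        se_km2=float(sk2),
        se_amax2=float(sa2),
        r2=r2,
        method=CoordinateMethod.NLS,
        n_points_used=len(series),
        degenerate=degenerate,
    )


def fit_linearized(
    series: SaturationSeries, method: CoordinateMethod
) -> OneSiteFit:
    """Km/Amax from a straight-line fit in LB or EH coordinates.

    LB: 1/a = 1/Amax + (Km/Amax)·(1/[S])  → Km = slope/intercept, Amax = 1/intercept.
    EH: a = Amax − Km·(a/[S])             → Km = −slope, Amax = intercept.

    Standard errors are propagated from the line coefficients by the delta
    method (relative-error quadrature for the LB ratio).  Points outside the
    transform domain or below the detection floor are excluded and counted.
    """
    if method is CoordinateMethod.LB:
        transform = lb_transform
    elif method is CoordinateMethod.EH:
        transform = eh_transform
    else:
        raise ValueError("fit_linearized requires method LB or EH")

    pts = series.transform_points()
    n_floor = len(series) - len(pts)
    if len(pts) < 3:
        raise FitError(
            f"fewer than 3 usable points for {method.value} fit after "
            "floor exclusion"
        )
    try:
        xy, n_dom = transform(pts)
    except ValueError as exc:
        raise FitError(str(exc)) from None
    x, y = xy[:, 0], xy[:, 1]
    if len(np.unique(x)) < 2:
        raise FitError(f"{method.value} fit needs >= 2 distinct abscissa values")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    se_slope, se_intercept = res.stderr, res.intercept_stderr

    if method is CoordinateMethod.LB:
        if intercept <= 0:
            raise FitError("Lineweaver-Burk intercept <= 0: Amax not physical")
        if slope <= 0:
            raise FitError("Lineweaver-Burk slope <= 0: Km not physical")
        amax = 1.0 / intercept
        km = slope / intercept
        se_amax = se_intercept / intercept**2
        se_km = km * math.sqrt(
            (se_slope / slope) ** 2 + (se_intercept / intercept) ** 2
        )
    else:
        if slope >= 0 or intercept <= 0:
            raise FitError("Eadie-Hofstee line not consistent with saturation")
        km = -slope
        amax = intercept
        se_km = se_slope
        se_amax = se_intercept

    r2 = float(res.rvalue**2)
    return OneSiteFit(
        km=float(km),
        amax=float(amax),
        se_km=float(se_km),
        se_amax=float(se_amax),
        r2=r2,
        method=method,
        n_points_used=len(x),
        n_excluded=n_floor + n_dom,
    )


def split_concentration_ranges(
    series: SaturationSeries,
    low_max: float = 0.05,
    high_min: float = 0.1,
    high_max: float = 10.0,
) -> tuple[SaturationSeries, SaturationSeries]:
    """Partition a series into low ([0, low_max]) and high ([high_min, high_max]) ranges.

    Both intervals are closed; points strictly between ``low_max`` and
    ``high_min`` (or above ``high_max``) belong to neither and are counted in a
    log entry.  Used when the two site classes differ so much in affinity that
    linearized fits must treat the ranges separately.
    """
    if not low_max < high_min:
        raise ValueError("low_max must be < high_min")
    if not len(series):
        raise FitError("cannot split an empty series")
    low = [m for m in series.measurements if m.substrate_conc <= low_max]
    high = [
        m
        for m in series.measurements
        if high_min <= m.substrate_conc <= high_max
    ]
    n_orphan = len(series) - len(low) - len(high)
    if n_orphan:
        logger.info(
            "range split left %d point(s) between %g and %g mM unassigned",
            n_orphan,
            low_max,
            high_min,
        )
    if len(low) < 3 or len(high) < 3:
        raise FitError(
            f"range split leaves too few points (low={len(low)}, high={len(high)})"
        )
    mk = lambda ms: replace(series, measurements=tuple(ms))
    return mk(low), mk(high)


def select_model(
    series: SaturationSeries, threshold: float = R2_THRESHOLD_DEFAULT
) -> ModelChoice:
    """One- vs two-site model selection by the R² escalation rule.

    The one-site model is fitted first; only when its R² falls below
    ``threshold`` (default 0.98) and the series supports four more parameters
    is the two-site model fitted.  Both R² values are recorded.
    """
    one = fit_one_site_nls(series)
    two = None
    selected = "one_site"
    if one.r2 < threshold and series.n_distinct_s() >= MIN_DISTINCT_TWO_SITE:
        try:
            two = fit_two_site_nls(series)
        except FitError as exc:
            logger.warning("two-site escalation failed: %s", exc)
        else:
            if not two.degenerate:
                selected = "two_site"
    return ModelChoice(
        selected=selected,
        r2_one_site=one.r2,
        r2_two_site=None if two is None else two.r2,
        threshold=threshold,
        one_site_fit=one,
        two_site_fit=two,
    )
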