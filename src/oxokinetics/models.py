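"""Rate laws and linearizing transforms for 2-oxo acid dehydrogenase kinetics.

The enzyme preparations studied here are not homogeneous, so maximal rates are
expressed as maximal *specific activities* (``amax``, µmol·min⁻¹·mg⁻¹ protein)
rather than true Vmax values.  Substrate concentrations are in mM; inhibitor
concentrations and inhibition constants in µM.  Ratios such as ``[I]/Ki`` are
dimensionless, so the two scales never mix in the arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateMethod",
    "SiteParams",
    "TwoSiteParams",
    "mm_rate",
    "two_site_rate",
    "competitive_km_eff",
    "lb_transform",
    "eh_transform",
]


class CoordinateMethod(Enum):
    """Coordinate system in which a saturation curve is fitted.

    ``NLS``: direct nonlinear least squares on the Michaelis-Menten hyperbola
    (reported as "MM" in result tables); ``LB``: Lineweaver-Burk double
    reciprocal; ``EH``: Eadie-Hofstee.
    """

    NLS = "NLS"
    LB = "LB"
    EH = "EH"

    @property
    def table_label(self) -> str:
        return "MM" if self is CoordinateMethod.NLS else self.value


@dataclass(frozen=True)
class SiteParams:
    """Michaelis parameters of one class of active sites.

    Parameters
    ----------
    km : float
        Substrate half-saturation constant, mM.
    amax : float
        Maximal specific activity, µmol·min⁻¹·mg⁻¹.
    ki_by_inhibitor : mapping, optional
        Competitive inhibition constant (µM) per inhibitor identifier.
    """

    km: float
    amax: float
    ki_by_inhibitor: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.km > 0:
            raise ValueError(f"km must be positive, got {self.km}")
        if self.amax < 0:
            raise ValueError(f"amax must be non-negative, got {self.amax}")
        for name, ki in self.ki_by_inhibitor.items():
            if not ki > 0:
                raise ValueError(f"Ki for {name!r} must be positive, got {ki}")

    def ki(self, inhibitor_id: str) -> float:
        try:
            return self.ki_by_inhibitor[inhibitor_id]
        except KeyError:
            raise KeyError(
                f"no Ki defined for inhibitor {inhibitor_id!r}"
            ) from None


@dataclass(frozen=True)
class TwoSiteParams:
    """Two independent site classes; ``site1`` is the high-affinity one (km1 < km2)."""

    site1: SiteParams
    site2: SiteParams

    def __post_init__(self) -> None:
        if not self.site1.km < self.site2.km:
            raise ValueError(
                "canonical ordering violated: site1.km must be < site2.km "
                f"({self.site1.km} vs {self.site2.km})"
            )


def _as_conc(s, name: str = "s"):
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError(f"{name} must be non-negative")
    return s


def mm_rate(s, p: SiteParams):
    """Michaelis-Menten rate a = Amax·[S]/(Km + [S]).

    ``s`` may be a scalar or array of substrate concentrations (mM); the return
    matches its shape.  Monotone in ``s`` with supremum ``p.amax``.
    """
    s = _as_conc(s)
    out = p.amax * s / (p.km + s)
    return out if out.ndim else float(out)


def two_site_rate(s, p: TwoSiteParams):
    """Sum of two independent Michaelis-Menten terms (biphasic saturation)."""
    s = _as_conc(s)
    out = p.site1.amax * s / (p.site1.km + s) + p.site2.amax * s / (p.site2.km + s)
    return out if out.ndim else float(out)


def competitive_km_eff(km: float, i, ki: float):
    """Apparent Km under competitive inhibition: Km·(1 + [I]/Ki).

    ``km`` in mM, ``i`` and ``ki`` in µM; Amax is unchanged by a purely
    competitive inhibitor.
    """
    if not ki > 0:
        raise ValueError(f"ki must be positive, got {ki}")
    i = _as_conc(i, "inhibitor concentration")
    out = km * (1.0 + i / ki)
    return out if out.ndim else float(out)


def _transform(points, fx, fy, require_pos_s: bool, require_pos_a: bool):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (s, a) pairs")
    s, a = pts[:, 0], pts[:, 1]
    ok = np.ones(len(pts), dtype=bool)
    if require_pos_s:
        ok &= s > 0
    if require_pos_a:
        ok &= a > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("transform excluded %d point(s) outside its domain", n_excluded)
    if ok.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable points after domain exclusion ({int(ok.sum())})"
        )
    return np.column_stack([fx(s[ok], a[ok]), fy(s[ok], a[ok])]), n_excluded


def lb_transform(points):
    """Lineweaver-Burk coordinates (1/[S], 1/a).

    Points with [S] ≤ 0 or a ≤ 0 (reciprocal undefined) are excluded; the
    exclusion count is returned alongside the transformed array.

    Returns
    -------
    (ndarray of shape (n, 2), int)
        Transformed points and the number excluded.
    """
    return _transform(
        points, lambda s, a: 1.0 / s, lambda s, a: 1.0 / a, True, True
    )


def eh_transform(points):
    """Eadie-Hofstee coordinates (a/[S], a); slope of the line is −Km, intercept Amax."""
    return _transform(points, lambda s, a: a / s, lambda s, a: a, True, True)
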