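"""Reynolds number, geometric-hindrance score, and flow-regime classification.

Flow over a brush-like surface is organised by two dimensionless numbers:
the Reynolds number Re = v·L/ν measuring the energy carried by the flow, and
a geometric score Geo = a0·N + Σ a_i·x_i measuring the steric hindrance of
the obstacles (N the obstacle/sugar-chain count, x_i optional geometric
features).  States where the two balance trace a *balance curve* in the
(Geo, Re) plane; points above it are velocity-dominant (flow energy
overwhelms hindrance), points below are obstacle-dominant (hindrance
dissipates the flow toward static equilibrium).

No functional form for the balance curve is assumed: it is interpolated
piecewise-linearly through user-supplied calibration points, constant
beyond their range, with a relative tolerance band (default 10%) counted
as "balance".  The characteristic length L and kinematic viscosity ν are
required inputs — this module bakes in no physics constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeoModel",
    "RegimePoint",
    "BalanceCurve",
    "reynolds",
    "geo_number",
    "classify_regime",
    "plot_regime_diagram",
]

REGIME_LABELS = ("balance", "obstacle-dominant", "velocity-dominant")


def reynolds(v: float, L: float, nu: float) -> float:
    """Re = v·L/ν with v in m/s, L in m, ν in m²/s."""
    if L <= 0:
        raise ValueError("characteristic length L must be positive")
    if nu <= 0:
        raise ValueError("kinematic viscosity nu must be positive")
    if v < 0:
        raise ValueError("flow speed v must be non-negative")
    return v * L / nu


@dataclass(frozen=True)
class GeoModel:
    """Linear score of obstacle geometry: Geo = a0·N + Σ a_i·x_i.

    The count-only special case Geo = N is ``GeoModel(a0=1)``.
    """

    a0: float = 1.0
    feature_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a0 == 0 and not any(w != 0 for w in self.feature_weights.values()):
            raise ValueError("GeoModel needs at least one nonzero weight")


def geo_number(
    n_obstacles: int, features: dict[str, float] | None = None, model: GeoModel | None = None
) -> float:
    """Evaluate the geometric score for ``n_obstacles`` and named features."""
    model = model or GeoModel()
    features = features or {}
    total = model.a0 * n_obstacles
    for name, weight in model.feature_weights.items():
        if name not in features:
            raise ValueError(f"missing feature {name!r} required by the Geo model")
        total += weight * features[name]
    return float(total)


@dataclass
class BalanceCurve:
    """Calibration points where flow energy and hindrance balance.

    ``points`` is a sequence of (geo, re) pairs with distinct geo values;
    ``tolerance`` is the relative half-width of the "balance" band.
    """

    points: list[tuple[float, float]]
    tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("balance curve needs at least one calibration point")
        geos = [g for g, _ in self.points]
        if len(set(geos)) != len(geos):
            raise ValueError("calibration geo values must be distinct")
        if any(r < 0 for _, r in self.points):
            raise ValueError("calibration re values must be non-negative")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        self.points = sorted((float(g), float(r)) for g, r in self.points)

    def re_balance(self, geo: float) -> float:
        """Balance Re at ``geo``: piecewise-linear, constant extrapolation."""
        geos = np.array([g for g, _ in self.points])
        res = np.array([r for _, r in self.points])
        return float(np.interp(geo, geos, res))


@dataclass(frozen=True)
class RegimePoint:
    """One case placed on the regime diagram."""

    re: float
    geo: float
    label: str
    case_name: str = ""

    def __post_init__(self) -> None:
        if self.re < 0:
            raise ValueError("re must be non-negative")
        if self.label not in REGIME_LABELS:
            raise ValueError(f"unknown label {self.label!r}; valid: {REGIME_LABELS}")


def classify_regime(point: tuple[float, float], curve: BalanceCurve) -> str:
    """Label ``point = (geo, re)`` relative to the balance curve.

    "balance" within the relative tolerance band around the interpolated
    balance Re, "velocity-dominant" above, "obstacle-dominant" below.  A
    zero balance Re makes a relative band degenerate: classification then
    falls back to the sign of re (with a warning).
    """
    geo, re = point
    if re < 0:
        raise ValueError("re must be non-negative")
    rb = curve.re_balance(geo)
    if rb == 0.0 and curve.tolerance > 0.0:
        warnings.warn(
            "balance Re is 0 at this geo; classifying by the sign of re alone",
            stacklevel=2,
        )
        return "balance" if re == 0.0 else "velocity-dominant"
    if abs(re - rb) <= curve.tolerance * rb:
        return "balance"
    return "velocity-dominant" if re > rb else "obstacle-dominant"


def plot_regime_diagram(
    points: list[RegimePoint], curve: BalanceCurve, path: str | None = None
):
    """Render the (Geo, Re) diagram with the balance curve and labelled cases."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    geos = np.array([g for g, _ in curve.points])
    lo = min(geos.min(), min((p.geo for p in points), default=geos.min())) - 1
    hi = max(geos.max(), max((p.geo for p in points), default=geos.max())) + 1
    gg = np.linspace(lo, hi, 200)
    rr = np.array([curve.re_balance(g) for g in gg])
    ax.plot(gg, rr, "k-", label="balance curve")
    ax.fill_between(
        gg, rr * (1 - curve.tolerance), rr * (1 + curve.tolerance), alpha=0.2, color="grey"
    )
    markers = {"balance": "o", "velocity-dominant": "^", "obstacle-dominant": "v"}
    for p in points:
        ax.plot(p.geo, p.re, markers[p.label], label=f"{p.case_name} ({p.label})")
    ax.set_xlabel("Geo (obstacle score)")
    ax.set_ylabel("Re")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
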