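"""Averted-mortality arithmetic for PM2.5 exposure reductions.

Follows the standard integrated exposure-response (IER) chain used in global
burden-of-disease work: a cause-specific relative risk

    RR(z) = 1 + α·(1 − exp(−γ·(z − z_cf)^δ))   for z > z_cf, else 1,

a population attributable fraction PAF = (RR − 1)/RR, attributable deaths
``B_c × PAF`` against a background mortality rate ``B_c`` (per 100,000
person-years), and averted deaths as the difference between the pre- and
post-intervention attributable burden.  Five causes are tracked: COPD,
ischaemic heart disease, stroke and lung cancer for all ages, and acute lower
respiratory infection in children under five (scaled by the under-five
population fraction).

The coefficient and background-rate tables bundled here are SYNTHETIC,
order-of-magnitude illustrations; real GBD tables can be supplied through the
CSV loaders for faithful burden numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CAUSES = ("copd", "ihd", "stroke", "lung_cancer", "alri_under5")

__all__ = [
    "CAUSES",
    "IERCurve",
    "IERCoefficients",
    "BurdenTable",
    "MortalityResult",
    "relative_risk",
    "paf",
    "attributable_rates",
    "averted_burden",
    "default_ier",
    "default_burden",
    "load_ier_csv",
    "load_burden_csv",
]


@dataclass(frozen=True)
class IERCurve:
    """IER parameters for one cause: saturation α, rate γ, shape δ, counterfactual z_cf."""

    alpha: float
    gamma: float
    delta: float
    z_cf: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0 or self.delta <= 0:
            raise ValueError("alpha, gamma, delta must be positive")
        if self.z_cf < 0:
            raise ValueError("counterfactual concentration must be non-negative")


@dataclass(frozen=True)
class IERCoefficients:
    """Per-cause IER curves."""

    curves: dict[str, IERCurve]

    def __post_init__(self) -> None:
        missing = set(CAUSES) - set(self.curves)
        if missing:
            raise ValueError(f"missing IER curves for causes: {sorted(missing)}")


@dataclass(frozen=True)
class BurdenTable:
    """Background cause-specific mortality for the target population.

    ``rates_per_100k[c]`` is deaths per 100,000 person-years; the ALRI rate is
    the under-five rate and is scaled by ``under5_fraction`` when attributed
    to the whole population.
    """

    rates_per_100k: dict[str, float]
    population: int = 19_000_000
    under5_fraction: float = 0.09

    def __post_init__(self) -> None:
        missing = set(CAUSES) - set(self.rates_per_100k)
        if missing:
            raise ValueError(f"missing background rates for causes: {sorted(missing)}")
        if any(v < 0 for v in self.rates_per_100k.values()):
            raise ValueError("background rates must be non-negative")
        if not 0 <= self.under5_fraction <= 1:
            raise ValueError("under5_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MortalityResult:
    """Attributable and averted deaths per cause and in total.

    All rates per 100,000 person-years; ``averted_per_million_total`` is the
    total averted rate scaled to a million people, and
    ``percent_of_avoidable`` is the share of the pre-intervention attributable
    burden removed by the intervention.
    """

    attributable_pre: dict[str, float]
    attributable_post: dict[str, float]
    averted: dict[str, float]
    averted_total_per_100k: float
    averted_per_million_total: float
    percent_of_avoidable: float


# --------------------------------------------------------------------------- #
# core arithmetic
# --------------------------------------------------------------------------- #

def relative_risk(z: float, curve: IERCurve) -> float:
    """IER relative risk at long-term exposure ``z`` (µg/m³).

    Equals 1 at or below the counterfactual, rises monotonically and
    saturates at ``1 + α``.
    """
    import math

    if z < 0:
        raise ValueError("exposure must be non-negative")
    if z <= curve.z_cf:
        return 1.0
    return 1.0 + curve.alpha * (1.0 - math.exp(-curve.gamma * (z - curve.z_cf) ** curve.delta))


def paf(rr: float) -> float:
    """Population attributable fraction (RR − 1)/RR."""
    if rr < 1.0:
        raise ValueError("relative risk must be >= 1")
    return (rr - 1.0) / rr


def attributable_rates(
    z: float, coefs: IERCoefficients, burden: BurdenTable
) -> dict[str, float]:
    """Cause-specific attributable deaths per 100,000 person-years at exposure z."""
    out: dict[str, float] = {}
    for cause in CAUSES:
        rate = burden.rates_per_100k[cause]
        if cause == "alri_under5":
            rate *= burden.under5_fraction
        out[cause] = rate * paf(relative_risk(z, coefs.curves[cause]))
    return out


def averted_burden(
    z_pre: float,
    z_post: float,
    coefs: IERCoefficients | None = None,
    burden: BurdenTable | None = None,
) -> MortalityResult:
    """Averted mortality when annual exposure drops from ``z_pre`` to ``z_post``."""
    if z_post > z_pre:
        raise ValueError("z_post exceeds z_pre: pre/post arguments reversed?")
    coefs = coefs if coefs is not None else default_ier()
    burden = burden if burden is not None else default_burden()

    pre = attributable_rates(z_pre, coefs, burden)
    post = attributable_rates(z_post, coefs, burden)
    averted = {c: pre[c] - post[c] for c in CAUSES}
    total_pre = sum(pre.values())
    total_averted = sum(averted.values())
    pct = 100.0 * total_averted / total_pre if total_pre > 0 else 0.0
    return MortalityResult(
        attributable_pre=pre,
        attributable_post=post,
        averted=averted,
        averted_total_per_100k=total_averted,
        averted_per_million_total=10.0 * total_averted,
        percent_of_avoidable=pct,
    )


# --------------------------------------------------------------------------- #
# bundled synthetic tables and CSV loaders
# --------------------------------------------------------------------------- #

# SYNTHETIC illustrative IER curves: GBD-like orders of magnitude, shared
# counterfactual 5.9 µg/m³.  Not the published GBD draws.
_SYNTHETIC_IER = {
    "copd": IERCurve(alpha=0.60, gamma=0.030, delta=0.70, z_cf=5.9),
    "ihd": IERCurve(alpha=1.40, gamma=0.050, delta=0.60, z_cf=5.9),
    "stroke": IERCurve(alpha=1.60, gamma=0.040, delta=0.55, z_cf=5.9),
    "lung_cancer": IERCurve(alpha=0.80, gamma=0.020, delta=0.75, z_cf=5.9),
    "alri_under5": IERCurve(alpha=2.20, gamma=0.070, delta=0.50, z_cf=5.9),
}

# SYNTHETIC illustrative Delhi-like background mortality, deaths per 100k/yr
# (ALRI rate is the under-five rate).
_SYNTHETIC_BURDEN = {
    "copd": 60.0,
    "ihd": 160.0,
    "stroke": 75.0,
    "lung_cancer": 9.0,
    "alri_under5": 120.0,
}


def default_ier() -> IERCoefficients:
    """The bundled synthetic (illustrative) IER coefficient set."""
    return IERCoefficients(curves=dict(_SYNTHETIC_IER))


def default_burden() -> BurdenTable:
    """The bundled synthetic (illustrative) background-burden table."""
    return BurdenTable(rates_per_100k=dict(_SYNTHETIC_BURDEN))


def load_ier_csv(path: str | Path) -> IERCoefficients:
    """Load IER curves from CSV with columns ``cause,alpha,gamma,delta,zcf``."""
    df = pd.read_csv(path)
    required = {"cause", "alpha", "gamma", "delta", "zcf"}
    if not required <= set(df.columns):
        raise ValueError(f"IER CSV needs columns {sorted(required)}")
    curves = {
        row["cause"]: IERCurve(
            alpha=row["alpha"], gamma=row["gamma"], delta=row["delta"], z_cf=row["zcf"]
        )
        for _, row in df.iterrows()
    }
    return IERCoefficients(curves=curves)


def load_burden_csv(
    path: str | Path, *, population: int = 19_000_000, under5_fraction: float = 0.09
) -> BurdenTable:
    """Load background rates from CSV with columns ``cause,deaths_per_100k``."""
    df = pd.read_csv(path)
    if not {"cause", "deaths_per_100k"} <= set(df.columns):
        raise ValueError("burden CSV needs columns cause,deaths_per_100k")
    rates = dict(zip(df["cause"], df["deaths_per_100k"].astype(float)))
    return BurdenTable(
        rates_per_100k=rates, population=population, under5_fraction=under5_fraction
    )


def write_ier_csv(coefs: IERCoefficients, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"cause": c, "alpha": k.alpha, "gamma": k.gamma, "delta": k.delta, "zcf": k.z_cf}
            for c, k in coefs.curves.items()
        ]
    ).to_csv(path, index=False)


def write_burden_csv(burden: BurdenTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"cause": c, "deaths_per_100k": r} for c, r in burden.rates_per_100k.items()]
    ).to_csv(path, index=False)
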