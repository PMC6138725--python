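"""Cooperativity metrics for two-agent combination experiments.

Effects are inhibition fractions in [0, 1] (1 − viability, viability being
the fraction of the vehicle control). Two combination indices are
implemented:

* **Highest single agent (HSA)** — ``CI = max(E_cur, E_opc) / E_combo``;
  the combination must beat the better single agent.
* **Bliss independence** — ``CI = (E_cur + E_opc − E_cur·E_opc) / E_combo``;
  the reference assumes probabilistically independent action.

In both, ``CI < 1`` indicates cooperativity. The dose reduction index
``DRI50 = IC50_single / concentration_in_combination_at_50%_inhibition``
measures how far an agent's dose can drop in the combination while keeping
50% inhibition; ``DRI > 1`` is beneficial. IC50s come from a
four-parameter-logistic least-squares fit with a log-linear interpolation
fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    InsufficientDataError,
    NotReachedError,
    UndefinedCombinationEffectError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CI_METHODS = ("hsa", "bliss")


def inhibition_from_viability(viability: float, clamp: bool = True) -> float:
    """Convert fractional viability to inhibition ``E = 1 − v``.

    With ``clamp`` (default) the result is restricted to [0, 1]; growth
    stimulation (viability > 1) then maps to zero inhibition.
    """
    v = float(viability)
    if not math.isfinite(v):
        raise ValidationError("viability must be finite")
    e = 1.0 - v
    if clamp:
        e = min(max(e, 0.0), 1.0)
    return e


@dataclass(frozen=True)
class EffectTriple:
    """Matched single-agent and combination inhibition effects."""

    e_cur: float
    e_opc: float
    e_combo: float
    dose_cur: float = float("nan")
    dose_opc: float = float("nan")
    cell_line: str = ""

    def __post_init__(self):
        for name in ("e_cur", "e_opc", "e_combo"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v!r} must be a fraction in [0, 1]")


@dataclass(frozen=True)
class CIResult:
    method: str
    ci: float
    cooperative: bool = field(init=False)

    def __post_init__(self):
        if self.method not in CI_METHODS:
            raise ValidationError(f"method must be one of {CI_METHODS}")
        if self.ci < 0:
            raise ValidationError("CI cannot be negative")
        object.__setattr__(self, "cooperative", self.ci < 1.0)


def _require_combo_effect(t: EffectTriple) -> None:
    if t.e_combo == 0.0:
        raise UndefinedCombinationEffectError(
            "combination effect is zero; the combination index is undefined"
        )


def ci_hsa(t: EffectTriple) -> CIResult:
    """Highest-single-agent combination index ``max(E_cur, E_opc) / E_combo``."""
    _require_combo_effect(t)
    return CIResult(method="hsa", ci=max(t.e_cur, t.e_opc) / t.e_combo)


def ci_bliss(t: EffectTriple) -> CIResult:
    """Bliss-independence combination index ``(E_cur + E_opc − E_cur·E_opc) / E_combo``."""
    _require_combo_effect(t)
    predicted = t.e_cur + t.e_opc - t.e_cur * t.e_opc
    return CIResult(method="bliss", ci=predicted / t.e_combo)


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit (or interpolation fallback) of viability vs dose.

    The curve is ``v(d) = bottom + (top − bottom) / (1 + (d / ic50)^hill)``,
    so ``ic50`` is the midpoint between the asymptotes. For the
    interpolation fallback ``ic50`` is the log-linear 50%-viability
    crossing and ``hill`` is NaN.
    """

    ic50: float
    hill: float
    top: float
    bottom: float
    fit_method: str
    rss: float

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValidationError("ic50 must be positive")
        if self.fit_method not in ("four_parameter_logistic", "interpolation"):
            raise ValidationError("unknown fit_method")
        if self.fit_method == "four_parameter_logistic" and self.bottom > self.top:
            raise ValidationError("bottom asymptote exceeds top")

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (d / self.ic50) ** self.hill)

    def dose_at_viability(self, level: float = 0.5) -> float:
        """Dose at which the fitted curve crosses an absolute viability level."""
        if self.fit_method == "interpolation":
            if not math.isclose(level, 0.5):
                raise ValidationError("interpolation fallback only locates the 50% crossing")
            return self.ic50
        if not (self.bottom < level < self.top):
            raise NotReachedError(
                f"viability {level} outside fitted asymptotes ({self.bottom:.3g}, {self.top:.3g})"
            )
        return self.ic50 * ((self.top - level) / (level - self.bottom)) ** (1.0 / self.hill)


def _mean_by_dose(doses, viabilities) -> tuple[np.ndarray, np.ndarray]:
    df = pd.DataFrame({"dose": np.asarray(doses, float), "v": np.asarray(viabilities, float)})
    if df.isna().any().any():
        raise ValidationError("doses and viabilities must be finite")
    g = df.groupby("dose", sort=True)["v"].mean()
    return g.index.to_numpy(), g.to_numpy()


def _interpolate_ic50(d: np.ndarray, v: np.ndarray) -> float:
    """Log-linear interpolation of the first 50%-viability crossing."""
    for (d1, v1), (d2, v2) in zip(zip(d, v), zip(d[1:], v[1:])):
        if v1 >= 0.5 >= v2 and v1 != v2:
            frac = (v1 - 0.5) / (v1 - v2)
            if d1 > 0:
                return float(10 ** (np.log10(d1) + frac * (np.log10(d2) - np.log10(d1))))
            return float(d1 + frac * (d2 - d1))  # crossing below the lowest positive dose
    raise InsufficientDataError("no adjacent dose pair brackets 50% viability")


def _4pl(d, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


def fit_dose_response(doses, viabilities) -> DoseResponseFit:
    """Fit viability vs dose; report the curve and which estimator ran.

    Replicates (repeated doses) are averaged first. A bounded
    four-parameter-logistic least-squares fit is attempted when at least 4
    distinct doses bracket 50% viability; on failure, or with sparser
    designs, the estimate falls back to log-linear interpolation between
    the doses bracketing the 50% crossing.
    """
    d, v = _mean_by_dose(doses, viabilities)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 distinct doses")
    if v.min() > 0.5:
        raise NotReachedError("no dose reaches 50% inhibition; IC50 undefined")
    if v.max() < 0.5:
        raise InsufficientDataError("all viabilities below 50%; doses do not bracket the crossing")

    pos = d > 0
    if pos.sum() >= 4:
        p0 = [min(v.max(), 1.0), max(v.min(), 0.0), _interpolate_ic50(d, v), 1.0]
        lo = [0.0, 0.0, d[pos].min() / 100.0, 0.05]
        hi = [1.5, 1.0, d.max() * 100.0, 20.0]
        p0 = [min(max(p, a), b) for p, a, b in zip(p0, lo, hi)]
        try:
            popt, _ = curve_fit(
                _4pl, d, v, p0=p0, bounds=(lo, hi), method="trf",
                ftol=1e-10, xtol=1e-10, maxfev=20000,
            )
            top, bottom, ic50, hill = popt
            if bottom < 0.5 < top:
                rss = float(np.sum((v - _4pl(d, *popt)) ** 2))
                return DoseResponseFit(
                    ic50=float(ic50), hill=float(hill), top=float(top),
                    bottom=float(bottom), fit_method="four_parameter_logistic", rss=rss,
                )
            logger.warning("4PL asymptotes do not bracket 50%% viability; falling back to interpolation")
        except RuntimeError:
            logger.warning("4PL fit did not converge; falling back to interpolation")

    ic50 = _interpolate_ic50(d, v)
    return DoseResponseFit(
        ic50=ic50, hill=float("nan"), top=float(v.max()), bottom=float(v.min()),
        fit_method="interpolation", rss=float("nan"),
    )


@dataclass(frozen=True)
class DRIResult:
    """Dose reduction index of one agent at 50% inhibition."""

    agent: str
    ic50_single: float
    conc_in_combo_50: float
    dri: float = field(init=False)
    beneficial: bool = field(init=False)

    def __post_init__(self):
        if self.ic50_single <= 0 or self.conc_in_combo_50 <= 0:
            raise ValidationError("both 50%-inhibition concentrations must be positive")
        object.__setattr__(self, "dri", self.ic50_single / self.conc_in_combo_50)
        object.__setattr__(self, "beneficial", self.dri > 1.0)


def dri50(single_fit: DoseResponseFit, combo_doses, combo_viabilities, agent: str = "") -> DRIResult:
    """Dose reduction index from a single-agent fit and an in-combination series.

    The combination series holds the partner's dose fixed while this
    agent's dose varies; its 50%-inhibition concentration is estimated with
    the same fitting machinery as the single agent.
    """
    combo_fit = fit_dose_response(combo_doses, combo_viabilities)
    return DRIResult(
        agent=agent,
        ic50_single=single_fit.dose_at_viability(0.5),
        conc_in_combo_50=combo_fit.dose_at_viability(0.5),
    )


def grid_ci(grid: pd.DataFrame, method: str = "bliss", clamp: bool = True) -> pd.DataFrame:
    """Combination indices over every dose pair of a checkerboard experiment.

    ``grid`` needs columns ``cell_line, dose_cur, dose_opc, replicate,
    viability``; rows with exactly one nonzero dose are the single-agent
    anchors. Replicates are averaged before effects are computed. Dose
    pairs whose single-agent anchors are missing, or whose combination
    effect is zero, are skipped with a logged warning. ``method`` may be
    ``"hsa"``, ``"bliss"`` or ``"both"``.
    """
    required = {"cell_line", "dose_cur", "dose_opc", "replicate", "viability"}
    if grid is None or len(grid) == 0:
        raise ValidationError("empty dose-response grid")
    missing = required - set(grid.columns)
    if missing:
        raise ValidationError(f"grid missing columns: {sorted(missing)}")
    methods = CI_METHODS if method == "both" else (method,)
    for m in methods:
        if m not in CI_METHODS:
            raise ValidationError(f"unknown CI method {m!r}")

    mean = (
        grid.groupby(["cell_line", "dose_cur", "dose_opc"], sort=True)["viability"]
        .mean()
        .reset_index()
    )
    out_rows = []
    for cell_line, sub in mean.groupby("cell_line", sort=True):
        single_cur = {
            row.dose_cur: inhibition_from_viability(row.viability, clamp)
            for row in sub.itertuples()
            if row.dose_cur > 0 and row.dose_opc == 0
        }
        single_opc = {
            row.dose_opc: inhibition_from_viability(row.viability, clamp)
            for row in sub.itertuples()
            if row.dose_opc > 0 and row.dose_cur == 0
        }
        combos = sub[(sub["dose_cur"] > 0) & (sub["dose_opc"] > 0)]
        for row in combos.itertuples():
            if row.dose_cur not in single_cur or row.dose_opc not in single_opc:
                logger.warning(
                    "%s: no single-agent anchor for pair (%g, %g); skipped",
                    cell_line, row.dose_cur, row.dose_opc,
                )
                continue
            triple = EffectTriple(
                e_cur=single_cur[row.dose_cur],
                e_opc=single_opc[row.dose_opc],
                e_combo=inhibition_from_viability(row.viability, clamp),
                dose_cur=row.dose_cur,
                dose_opc=row.dose_opc,
                cell_line=str(cell_line),
            )
            for m in methods:
                try:
                    res = ci_hsa(triple) if m == "hsa" else ci_bliss(triple)
                except UndefinedCombinationEffectError:
                    logger.warning(
                        "%s: zero combination effect at (%g, %g); skipped",
                        cell_line, row.dose_cur, row.dose_opc,
                    )
                    continue
                out_rows.append(
                    {
                        "cell_line": cell_line,
                        "dose_cur": row.dose_cur,
                        "dose_opc": row.dose_opc,
                        "e_cur": triple.e_cur,
                        "e_opc": triple.e_opc,
                        "e_combo": triple.e_combo,
                        "method": m,
                        "ci": res.ci,
                        "cooperative": res.cooperative,
                    }
                )
    return pd.DataFrame(
        out_rows,
        columns=[
            "cell_line", "dose_cur", "dose_opc", "e_cur", "e_opc", "e_combo",
            "method", "ci", "cooperative",
        ],
    )
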