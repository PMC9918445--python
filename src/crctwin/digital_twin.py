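"""Digital-twin prediction and the overdiagnosis statistic.

The screened twin of an unscreened control population is recreated by
pushing the natural-history parameters learned from a screened
population through the screening design: the expected CRC count S(t) is
the cohort-weighted sum of the detection-mode expectations over rounds
plus post-round clinical surfacing (screen-detected, interval,
unconfirmed-positive, post-program, and refuser-equivalent components).
Overdiagnosis is the excess proportion

    (S(t) / U(t) - 1) x 100%

against the observed (or trend-imputed) control count U(t).  Because the
onset intensity learned from a screened population contains the
non-progressive excess, S(t) exceeds the control expectation; the
statistic isolates that excess.

Uncertainty propagates by pushing posterior parameter draws through the
twin prediction.  An optional competing-risk adjustment depletes the
control expectation by the other-cause hazard before surfacing (see
``competing_risk_adjustment``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimation import McmcResult, credible_interval, param_names_from_frame
from .natural_history import (
    ModelSpec,
    MortalitySchedule,
    RateParameters,
    probability_over,
)
from .screening_likelihood import ScreeningDesign, mode_probabilities
from .screening_likelihood import _entry_distribution  # shared entry convention

__all__ = [
    "TwinPrediction",
    "OverdiagnosisReport",
    "predict_screened_twin",
    "project_control_incidence",
    "overdiagnosis_proportion",
    "competing_risk_adjustment",
    "overdiagnosis_interval",
    "adenoma_sensitivity_sweep",
]


@dataclass(frozen=True)
class TwinPrediction:
    """Expected CRC count of the digitally screened twin, by component."""

    components: dict[str, float]
    cohort_size: float
    followup_mean: float
    u_depletion: float = 1.0  # control-side competing-risk factor (kappa)
    competing_risk_adjusted: bool = False

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.components.values()):
            raise ValueError("prediction components must be >= 0")
        if not (0.0 < self.u_depletion <= 1.0 + 1e-12):
            raise ValueError("u_depletion must lie in (0, 1]")


@dataclass(frozen=True)
class OverdiagnosisReport:
    """Overdiagnosis percentage with interval and component bookkeeping."""

    percentage: float
    interval: tuple[float, float] | None
    S_t: float
    U_t: float
    components: dict[str, float]
    competing_risk_adjusted: bool = False
    includes_HGD: bool = False
    includes_adenoma_removal: bool = False

    def __post_init__(self) -> None:
        if self.interval is not None:
            lo, hi = self.interval
            if not (lo <= self.percentage + 1e-9 and self.percentage - 1e-9 <= hi):
                raise ValueError("interval must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "percentage": self.percentage,
            "interval": list(self.interval) if self.interval else None,
            "S_t": self.S_t,
            "U_t": self.U_t,
            "components": dict(self.components),
            "competing_risk_adjusted": self.competing_risk_adjusted,
            "includes_HGD": self.includes_HGD,
            "includes_adenoma_removal": self.includes_adenoma_removal,
        }


def predict_screened_twin(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    design: ScreeningDesign,
    cohort_size: float | None = None,
    followup_T: float | None = None,
) -> TwinPrediction:
    """Expected CRC cases S(t) of the virtually screened twin.

    ``cohort_size`` and ``followup_T`` override the design (the twin
    mirrors the control population, whose size and mean follow-up need
    not equal the fitting design's).
    """
    n = float(cohort_size if cohort_size is not None else design.cohort_size)
    T = float(followup_T if followup_T is not None else design.followup_T)
    if T < design.screen_times[-1]:
        raise ValueError("follow-up horizon shorter than the last screen time")
    d = design.replace(followup_T=T, cohort_size=max(int(round(n)), 1))
    probs = mode_probabilities(spec, rates, mort, d)
    n_part = n * d.participation
    n_ref = n - n_part
    p = probs.participant
    components = {
        "screen_detected": n_part * (p["prevalent_crc"] + p["repeat_crc"]),
        "interval": n_part * p["interval_crc"],
        "unconfirmed_surfaced": n_part * (p["pos_unconf_first"] + p["pos_unconf_repeat"]),
        "post_program": n_part * p["post_program_crc"],
        "refuser_clinical": n_ref * probs.refuser["refuser_crc"],
    }
    if spec.has_adenoma:
        # cancers offset by polypectomy: removed adenomas that would have
        # surfaced clinically within follow-up are excess detections of the
        # screened twin and are counted into S(t)
        components["adenoma_removal_offset"] = n_part * float(
            sum(probs.per_round["adenoma_offset"])
        )
    return TwinPrediction(components=components, cohort_size=n, followup_mean=T)


def project_control_incidence(
    baseline: float, growth_rate: float, years: float | Sequence[float]
) -> float | np.ndarray:
    """Geometric projection baseline x (1 + growth)^years.

    A pre-screening baseline count or rate is carried forward with the
    secular growth of CRC incidence (default 4.5%/year in the service
    program's setting).  Passing a sequence of year offsets projects each
    year of a multi-year window (sum the result for a window total).
    """
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    if growth_rate <= -1.0:
        raise ValueError("growth rate must exceed -1")
    y = np.asarray(years, dtype=float)
    if np.any(y < 0):
        raise ValueError("years must be >= 0")
    out = baseline * (1.0 + growth_rate) ** y
    if np.isscalar(years) or y.ndim == 0:
        return float(out)
    return out


def overdiagnosis_proportion(S_t: float, U_t: float) -> float:
    """The excess proportion (S(t)/U(t) - 1) x 100%."""
    if not U_t > 0:
        raise ValueError("U_t must be > 0")
    return (S_t / U_t - 1.0) * 100.0


def _clinical_by_T(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    design: ScreeningDesign,
) -> float:
    """P(clinical by T) under the no-screening chain from entry."""
    entry = _entry_distribution(spec, rates, design.lead_in)
    w = entry @ probability_over(spec, rates, mort, 0.0, design.followup_T)
    return float(w[spec.index("clinical")])


def competing_risk_adjustment(
    prediction: TwinPrediction,
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    design: ScreeningDesign,
) -> TwinPrediction:
    """Competing-risk adjustment of the overdiagnosis ratio.

    Screen-detected cases whose other-cause death precedes the latent
    clinical surfacing are already retained in S(t) (they are
    overdiagnosed by definition), while a death-free control expectation
    overstates U(t).  The adjustment multiplies U by the depletion factor

        kappa = P(clinical by T | delta) / P(clinical by T | delta = 0)

    computed from the no-screening chain; kappa = 1 when delta is
    identically 0 (the adjustment is then the identity) and decreases as
    delta grows, so the adjusted percentage is never below the raw one.
    """
    p_with = _clinical_by_T(spec, rates, mort, design)
    p_free = _clinical_by_T(spec, rates, MortalitySchedule.constant(0.0), design)
    kappa = 1.0 if p_free <= 0 else min(p_with / p_free, 1.0)
    return replace(prediction, u_depletion=kappa, competing_risk_adjusted=True)


def build_report(
    prediction: TwinPrediction,
    U_t: float,
    interval: tuple[float, float] | None = None,
    includes_HGD: bool = False,
    includes_adenoma_removal: bool = False,
) -> OverdiagnosisReport:
    """Assemble the overdiagnosis report from a twin prediction and U(t)."""
    U_eff = U_t * prediction.u_depletion
    pct = overdiagnosis_proportion(prediction.total, U_eff)
    return OverdiagnosisReport(
        percentage=pct,
        interval=interval,
        S_t=prediction.total,
        U_t=U_t,
        components=dict(prediction.components),
        competing_risk_adjusted=prediction.competing_risk_adjusted,
        includes_HGD=includes_HGD,
        includes_adenoma_removal=includes_adenoma_removal,
    )


def overdiagnosis_interval(
    posterior: McmcResult | pd.DataFrame,
    U_t: float,
    spec: ModelSpec,
    mort: MortalitySchedule,
    design: ScreeningDesign,
    cohort_size: float | None = None,
    followup_T: float | None = None,
    adjust_competing_risk: bool = False,
    level: float = 0.95,
    max_draws: int = 400,
    nonprog_fraction: float = 0.0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Equal-tailed interval of the overdiagnosis percentage.

    Each posterior draw is pushed through the twin prediction (U(t) held
    fixed); returns (median percentage, (lo, hi), all pushed percentages).
    Draws are thinned deterministically to at most ``max_draws``.
    """
    draws = posterior.draws if isinstance(posterior, McmcResult) else posterior
    names = param_names_from_frame(draws)
    n = len(draws)
    if n < 100:
        raise ValueError("need at least 100 posterior draws")
    stride = max(n // max_draws, 1)
    sub = draws.iloc[::stride]
    pcts = np.empty(len(sub))
    for i, (_, row) in enumerate(sub.iterrows()):
        kw = {k: float(row[k]) for k in names}
        kw["nonprog_fraction"] = nonprog_fraction
        rates = RateParameters(**kw)
        pred = predict_screened_twin(spec, rates, mort, design, cohort_size, followup_T)
        if adjust_competing_risk:
            pred = competing_risk_adjustment(pred, spec, rates, mort, design)
        pcts[i] = overdiagnosis_proportion(pred.total, U_t * pred.u_depletion)
    if np.ptp(pcts) == 0.0:
        lo = hi = float(pcts[0])
    else:
        lo, hi = credible_interval(pcts, level=level) if len(pcts) >= 100 else (
            float(np.min(pcts)),
            float(np.max(pcts)),
        )
    return float(np.median(pcts)), (lo, hi), pcts


def adenoma_sensitivity_sweep(
    rates: RateParameters,
    mort: MortalitySchedule,
    design: ScreeningDesign,
    sens_grid: Iterable[float],
    U_t: float | None = None,
    spec: ModelSpec | None = None,
    cohort_size: float | None = None,
    followup_T: float | None = None,
) -> pd.DataFrame:
    """Overdiagnosis percentage across a grid of adenoma sensitivities.

    The scenario is otherwise fixed; if U(t) is not supplied it is the
    no-screening clinical expectation of the same chain (so the sweep
    isolates the effect of the adenoma-detection sensitivity on the
    screened twin).  Returns a table with a config echo.
    """
    spec = spec or ModelSpec("adenoma_overdiag" if rates.nonprog_fraction > 0 else "adenoma_4state")
    if not spec.has_adenoma:
        raise ValueError("the sensitivity sweep requires an adenoma model variant")
    grid = [float(s) for s in sens_grid]
    if any(not (0.0 < s < 1.0) for s in grid):
        raise ValueError("sens_adenoma grid values must lie strictly in (0, 1)")
    n = float(cohort_size if cohort_size is not None else design.cohort_size)
    T = float(followup_T if followup_T is not None else design.followup_T)
    if U_t is None:
        U_t = n * _clinical_by_T(
            spec, rates, mort, design.replace(followup_T=T)
        )
    rows = []
    for s in grid:
        r = rates.replace(sens_adenoma=s)
        pred = predict_screened_twin(spec, r, mort, design, n, T)
        rows.append(
            {
                "sens_adenoma": s,
                "S_t": pred.total,
                "U_t": U_t,
                "overdiagnosis_pct": overdiagnosis_proportion(pred.total, U_t),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["config"] = {
        "rates": rates.to_dict(),
        "cohort_size": n,
        "followup_T": T,
        "variant": spec.variant,
    }
    return out
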