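"""Individual-level generative simulator of screening cohorts.

The simulator draws the latent event history of every subject
(exponential waiting times per transition intensity, a non-progressive
label for a configurable fraction of PCDP onsets, an independent
other-cause death time), applies the screening design (all-or-none
participation, per-screen Bernoulli detection, confirmation, polypectomy
for detected adenomas) and tallies the realised detection modes in the
same bookkeeping the analytic layer uses -- so analytic mode
probabilities can be validated against empirical frequencies, and the
overdiagnosis pipeline can be validated against labelled truth.

A subject is labelled overdiagnosed iff screen-detected AND
(non-progressive OR other-cause death precedes the latent clinical
surfacing date).

Subjects enter conditionally cancer-free after a ``lead_in`` accrual
period, mirroring the analytic entry-state distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .natural_history import ModelSpec, MortalitySchedule, RateParameters
from .screening_likelihood import DetectionModeCounts, ScreeningDesign
from . import datasets

__all__ = [
    "SimulationConfig",
    "SimulationOutput",
    "simulate_cohort",
    "simulate_control",
    "make_rct_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated-cohort scenario; the seed is mandatory."""

    spec: ModelSpec
    rates: RateParameters
    mort: MortalitySchedule
    design: ScreeningDesign
    seed: int

    def __post_init__(self) -> None:
        self.rates.require(self.spec)
        if self.design.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")


@dataclass
class SimulationOutput:
    counts: DetectionModeCounts
    truth: dict
    individuals: Optional[pd.DataFrame] = None


def _draw_death(rng: np.random.Generator, mort: MortalitySchedule, n: int, horizon: float) -> np.ndarray:
    """Other-cause death times from entry; inf beyond the horizon/grid."""
    if mort.is_constant:
        d = mort.values[0]
        if d == 0.0:
            return np.full(n, np.inf)
        return rng.exponential(1.0 / d, n)
    if mort.edges[0] > 0.0 or mort.edges[-1] < horizon:
        raise ValueError("mortality grid must cover [0, followup_T] for simulation")
    u = rng.exponential(1.0, n)  # target cumulative hazards
    death = np.full(n, np.inf)
    H = 0.0
    for lo, hi, d in mort.segments(0.0, mort.edges[-1]):
        seg = d * (hi - lo)
        hit = (u <= H + seg) & np.isinf(death)
        if d > 0:
            death[hit] = lo + (u[hit] - H) / d
        H += seg
    return death


def _draw_histories_crc(
    rng: np.random.Generator, n: int, rates: RateParameters, lead_in: float
):
    """Latent (onset, nonprog, clinical) for the non-adenoma chains,
    conditioned on no clinical surfacing before entry (time 0)."""
    lam1, lam2, f = rates.lambda1, rates.lambda2, rates.nonprog_fraction
    onset = np.empty(n)
    nonprog = np.zeros(n, dtype=bool)
    clinical = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        x = -lead_in + (rng.exponential(1.0 / lam1, m) if lam1 > 0 else np.full(m, np.inf))
        np_mask = rng.random(m) < f
        soj = rng.exponential(1.0 / lam2, m) if lam2 > 0 else np.full(m, np.inf)
        clin = np.where(np_mask, np.inf, x + soj)
        ok = clin > 0.0
        idx = pending[ok]
        onset[idx] = x[ok]
        nonprog[idx] = np_mask[ok]
        clinical[idx] = clin[ok]
        pending = pending[~ok]
    return onset, nonprog, clinical


def _draw_histories_adenoma(
    rng: np.random.Generator, n: int, rates: RateParameters, lead_in: float
):
    """Latent (adenoma onset, pcdp onset, nonprog, clinical), conditioned
    on no clinical surfacing before entry."""
    l1a, l1b, lam2, f = (
        rates.lambda1a,
        rates.lambda1b,
        rates.lambda2,
        rates.nonprog_fraction,
    )
    aden = np.empty(n)
    onset = np.empty(n)
    nonprog = np.zeros(n, dtype=bool)
    clinical = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        a = -lead_in + (rng.exponential(1.0 / l1a, m) if l1a > 0 else np.full(m, np.inf))
        x = a + (rng.exponential(1.0 / l1b, m) if l1b > 0 else np.full(m, np.inf))
        np_mask = rng.random(m) < f
        soj = rng.exponential(1.0 / lam2, m) if lam2 > 0 else np.full(m, np.inf)
        clin = np.where(np_mask, np.inf, x + soj)
        ok = clin > 0.0
        idx = pending[ok]
        aden[idx] = a[ok]
        onset[idx] = x[ok]
        nonprog[idx] = np_mask[ok]
        clinical[idx] = clin[ok]
        pending = pending[~ok]
    return aden, onset, nonprog, clinical


def simulate_cohort(
    config: SimulationConfig, return_individuals: bool = False
) -> SimulationOutput:
    """Simulate one screened cohort; deterministic under a fixed seed."""
    spec, rates, mort, design = (
        config.spec,
        config.rates,
        config.mort,
        config.design,
    )
    if rates.sens_crc is None:
        raise ValueError("simulation requires sens_crc")
    rng = np.random.default_rng(config.seed)
    n = design.cohort_size
    T = design.followup_T
    screens = np.asarray(design.screen_times)
    sens = rates.sens_crc
    conf = design.confirmation_rate

    if spec.has_adenoma:
        aden, onset, nonprog, clinical = _draw_histories_adenoma(
            rng, n, rates, design.lead_in
        )
        sens_a = rates.sens_adenoma
    else:
        onset, nonprog, clinical = _draw_histories_crc(rng, n, rates, design.lead_in)
        aden = None
    death = _draw_death(rng, mort, n, T)
    participant = rng.random(n) < design.participation

    MODE_NONE = 0
    MODE_PREV = 1
    MODE_REPEAT = 2
    MODE_INTERVAL = 3
    MODE_UNC_FIRST = 4
    MODE_UNC_REPEAT = 5
    MODE_PRESCREEN = 6
    MODE_POST = 7
    MODE_REFUSER = 8
    mode = np.zeros(n, dtype=np.int8)
    screen_detected = np.zeros(n, dtype=bool)
    in_program = participant.copy()  # still eligible for further screens
    unconf_round = np.full(n, -1, dtype=np.int8)
    neg_screens = np.zeros(len(screens), dtype=np.int64)
    att_screens = np.zeros(len(screens), dtype=np.int64)
    detect_by_round = np.zeros(len(screens), dtype=np.int64)

    for r, t in enumerate(screens):
        att = in_program & (death > t) & (clinical > t)
        att_screens[r] = int(att.sum())
        in_pcdp = att & (onset <= t) & (nonprog | (clinical > t))
        positive = in_pcdp & (rng.random(n) < sens)
        confirmed = positive & (rng.random(n) < conf)
        unconf = positive & ~confirmed
        mode[confirmed] = MODE_PREV if r == 0 else MODE_REPEAT
        screen_detected[confirmed] = True
        detect_by_round[r] = int(confirmed.sum())
        in_program[confirmed | unconf] = False
        unconf_round[unconf] = r
        negatives = att & ~positive
        if spec.has_adenoma:
            in_aden = att & ~positive & (aden <= t) & (onset > t)
            aden_pos = in_aden & (rng.random(n) < sens_a)
            aden_conf = aden_pos & (rng.random(n) < conf)
            aden_unc = aden_pos & ~aden_conf
            # polypectomy: back to Normal, future history redrawn from t
            k = int(aden_conf.sum())
            if k:
                new_a = t + rng.exponential(1.0 / rates.lambda1a, k)
                new_x = new_a + rng.exponential(1.0 / rates.lambda1b, k)
                new_np = rng.random(k) < rates.nonprog_fraction
                new_c = np.where(
                    new_np, np.inf, new_x + rng.exponential(1.0 / rates.lambda2, k)
                )
                aden[aden_conf] = new_a
                onset[aden_conf] = new_x
                nonprog[aden_conf] = new_np
                clinical[aden_conf] = new_c
            in_program[aden_unc] = False
            unconf_round[aden_unc] = r
            negatives = negatives & ~aden_pos
        neg_screens[r] = int(negatives.sum())

    # unconfirmed positives: counted if the cancer surfaces within follow-up
    unc = unconf_round >= 0
    surf = unc & (clinical <= np.minimum(T, death))
    mode[surf & (unconf_round == 0)] = MODE_UNC_FIRST
    mode[surf & (unconf_round > 0)] = MODE_UNC_REPEAT

    # clinical surfacing among the still-undetected
    open_mask = (mode == MODE_NONE) & ~unc & (clinical <= np.minimum(T, death))
    ref = open_mask & ~participant
    mode[ref] = MODE_REFUSER
    part_clin = open_mask & participant
    t1, tK = screens[0], screens[-1]
    cap = min(design.final_interval_years, T - tK)
    mode[part_clin & (clinical < t1)] = MODE_PRESCREEN
    between = part_clin & (clinical >= t1) & (clinical <= tK)
    mode[between] = MODE_INTERVAL
    tail = part_clin & (clinical > tK)
    mode[tail & (clinical <= tK + cap)] = MODE_INTERVAL
    mode[tail & (clinical > tK + cap)] = MODE_POST

    overdiagnosed = screen_detected & (nonprog | (death < clinical))

    counts = DetectionModeCounts(
        counts={
            "prevalent_normal": int(neg_screens[0]),
            "prevalent_crc": int((mode == MODE_PREV).sum()),
            "interval_crc": int((mode == MODE_INTERVAL).sum()),
            "pos_unconf_first": int((mode == MODE_UNC_FIRST).sum()),
            "pos_unconf_repeat": int((mode == MODE_UNC_REPEAT).sum()),
            "repeat_normal": int(neg_screens[1:].sum()),
            "repeat_crc": int((mode == MODE_REPEAT).sum()),
            "refuser_normal": int((~participant).sum() - (mode == MODE_REFUSER).sum()),
            "refuser_crc": int((mode == MODE_REFUSER).sum()),
        },
        n_participants=int(participant.sum()),
        n_refusers=int((~participant).sum()),
    )

    diagnosed_by_T = (mode != MODE_NONE) & (mode != MODE_PRESCREEN)
    truth = {
        "seed": config.seed,
        "rates": rates.to_dict(),
        "n_overdiagnosed": int(overdiagnosed.sum()),
        "n_screen_detected": int(screen_detected.sum()),
        "n_diagnosed_by_T": int(diagnosed_by_T.sum()),
        "n_pre_screen_clinical": int((mode == MODE_PRESCREEN).sum()),
        "n_post_program": int((mode == MODE_POST).sum()),
        "attendance_by_round": att_screens.tolist(),
        "detections_by_round": detect_by_round.tolist(),
    }

    individuals = None
    if return_individuals:
        individuals = pd.DataFrame(
            {
                "onset": onset,
                "clinical": clinical,
                "death": death,
                "nonprog": nonprog,
                "participant": participant,
                "mode": mode,
                "screen_detected": screen_detected,
                "overdiagnosed": overdiagnosed,
            }
        )
        if aden is not None:
            individuals["adenoma_onset"] = aden

    return SimulationOutput(counts=counts, truth=truth, individuals=individuals)


def simulate_control(config: SimulationConfig) -> dict:
    """Clinical CRC count of the same cohort in the absence of screening.

    Non-progressive lesions never surface; subjects count iff the latent
    clinical date precedes both the follow-up horizon and other-cause
    death.
    """
    spec, rates, mort, design = (
        config.spec,
        config.rates,
        config.mort,
        config.design,
    )
    rng = np.random.default_rng(config.seed)
    n = design.cohort_size
    T = design.followup_T
    if spec.has_adenoma:
        _, _, _, clinical = _draw_histories_adenoma(rng, n, rates, design.lead_in)
    else:
        _, _, clinical = _draw_histories_crc(rng, n, rates, design.lead_in)
    death = _draw_death(rng, mort, n, T)
    n_clin = int((clinical <= np.minimum(T, death)).sum())
    return {"n_clinical": n_clin, "cohort_size": n, "followup_T": T, "seed": config.seed}


def make_rct_fixture(style: str) -> DetectionModeCounts:
    """The detection-mode layout (and observed counts) of one trial table."""
    if style == "nottingham":
        return datasets.nottingham_counts()
    if style == "funen":
        return datasets.funen_counts()
    raise ValueError(f"unknown style {style!r}; choose 'nottingham' or 'funen'")
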