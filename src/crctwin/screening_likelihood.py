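"""Detection-mode probabilities and the aggregate-count likelihood.

A screening program partitions the cohort into lifelong participants and
refusers (all-or-none attendance).  Within the participant stratum every
subject realises exactly one of a set of exhaustive, mutually exclusive
cancer modes -- screen-detected at the prevalent (first) screen, detected
at a repeat screen, interval cancer between screens, cancer following an
unconfirmed positive test, clinical cancer after the program, or none of
these by the end of follow-up.  Refusers realise clinical cancer or not.
The probabilities are obtained exactly (for the Markov model) by
propagating a sub-distribution over the transient disease states between
screens and applying a detection operator at each screen:

* a subject in PCDP tests positive with probability ``sens_crc``; a
  positive is confirmed (diagnosed, exits) with probability
  ``confirmation_rate``, otherwise the subject drops out of screening and
  the cancer is counted in a positive-unconfirmed mode if and when it
  surfaces clinically within follow-up;
* a subject with an adenoma tests positive with probability
  ``sens_adenoma``; a confirmed positive has the adenoma removed by
  polypectomy and returns to the Normal state;
* misses carry no memory beyond the state itself (exponential sojourns).

The likelihood over a table of detection-mode counts is the multinomial
kernel sum(n_m log p_m) per stratum, with an implicit remainder category
(stratum size minus the observed cancer-mode counts).  Negative-screen
cells are not multinomial categories (one subject can contribute several
negative screens); their expectations are reproduced separately for
goodness-of-fit tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .natural_history import (
    ModelSpec,
    MortalitySchedule,
    RateParameters,
    probability_over,
)

__all__ = [
    "ScreeningDesign",
    "DetectionModeCounts",
    "ModeProbabilities",
    "PARTICIPANT_MODES",
    "REFUSER_MODES",
    "mode_probabilities",
    "expected_counts",
    "log_likelihood",
]

#: participant-stratum cancer modes, in table order
PARTICIPANT_MODES = (
    "prevalent_crc",
    "interval_crc",
    "pos_unconf_first",
    "pos_unconf_repeat",
    "repeat_crc",
)
REFUSER_MODES = ("refuser_crc",)

#: all count cells a detection-mode table may carry
ALL_CELLS = (
    "prevalent_normal",
    "prevalent_crc",
    "interval_crc",
    "pos_unconf_first",
    "pos_unconf_repeat",
    "repeat_normal",
    "repeat_crc",
    "refuser_normal",
    "refuser_crc",
)


@dataclass(frozen=True)
class ScreeningDesign:
    """Screen schedule, attendance and follow-up of one program.

    ``screen_times`` are years since entry (first screen at 0 by
    convention); ``followup_T`` the common follow-up horizon;
    ``participation`` the all-or-none probability of being a lifelong
    participant; ``confirmation_rate`` the probability that a positive
    test receives diagnostic confirmation; ``lead_in`` the pre-entry
    accumulation period that sets the entry-state distribution
    (conditionally cancer-free at entry); ``final_interval_years`` how
    long after the last screen clinical surfacing still counts as an
    interval cancer (the rest is post-program).
    """

    screen_times: tuple[float, ...]
    followup_T: float
    cohort_size: int
    participation: float
    confirmation_rate: float = 1.0
    lead_in: float = 30.0
    final_interval_years: float = 0.0
    exclude_pre_screen_clinical: bool = True

    def __post_init__(self) -> None:
        st = self.screen_times
        if len(st) == 0:
            raise ValueError("need at least one screen time")
        if st[0] < 0 or any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("screen times must be strictly increasing, starting >= 0")
        if self.followup_T < st[-1]:
            raise ValueError("follow-up horizon must reach the last screen")
        if not (0.0 < self.participation <= 1.0):
            raise ValueError("participation must lie in (0, 1]")
        if not (0.0 <= self.confirmation_rate <= 1.0):
            raise ValueError("confirmation_rate must lie in [0, 1]")
        if self.lead_in < 0 or self.final_interval_years < 0:
            raise ValueError("lead_in and final_interval_years must be >= 0")

    @property
    def n_rounds(self) -> int:
        return len(self.screen_times)

    @property
    def n_participants(self) -> float:
        return self.cohort_size * self.participation

    @property
    def n_refusers(self) -> float:
        return self.cohort_size * (1.0 - self.participation)

    def replace(self, **kw) -> "ScreeningDesign":
        return replace(self, **kw)


@dataclass
class DetectionModeCounts:
    """Observed counts by detection mode; missing cells are None, not 0."""

    counts: dict[str, int | None]
    n_participants: int
    n_refusers: int

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if k not in ALL_CELLS:
                raise ValueError(f"unknown detection-mode cell {k!r}")
            if v is not None and v < 0:
                raise ValueError(f"count {k} must be >= 0")
        if self.n_participants < 0 or self.n_refusers < 0:
            raise ValueError("stratum sizes must be >= 0")
        present = sum(
            v
            for k, v in self.counts.items()
            if v is not None and k in PARTICIPANT_MODES
        )
        if present > self.n_participants:
            raise ValueError("participant cancer counts exceed stratum size")

    def present(self, modes=None) -> dict[str, int]:
        keys = modes if modes is not None else self.counts.keys()
        return {k: self.counts[k] for k in keys if self.counts.get(k) is not None}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode, n in self.counts.items():
            if n is None:
                continue
            stratum = "refuser" if mode.startswith("refuser") else "participant"
            rows.append({"stratum": stratum, "mode": mode, "observed": n})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DetectionModeCounts":
        df = pd.read_csv(path)
        counts: dict[str, int | None] = {}
        for _, row in df.iterrows():
            counts[str(row["mode"])] = int(row["observed"])
        n_part = sum(
            counts.get(k) or 0
            for k in ("prevalent_normal", "prevalent_crc", "pos_unconf_first")
        )
        n_ref = (counts.get("refuser_normal") or 0) + (counts.get("refuser_crc") or 0)
        return cls(counts=counts, n_participants=n_part, n_refusers=n_ref)


@dataclass
class ModeProbabilities:
    """Per-subject probabilities of the exhaustive outcome partitions.

    ``participant`` and ``refuser`` each sum to 1 over their categories
    (cancer modes plus remainder).  ``per_round`` carries the per-round /
    per-window decomposition and the expected number of negative screens
    per participant, used for expected-count tables.
    """

    participant: dict[str, float]
    refuser: dict[str, float]
    per_round: dict[str, list[float]] = field(default_factory=dict)

    def check(self, tol: float = 1e-9) -> None:
        for name, d in (("participant", self.participant), ("refuser", self.refuser)):
            s = sum(d.values())
            if abs(s - 1.0) > tol:
                raise AssertionError(f"{name} partition sums to {s}, not 1")
            for k, v in d.items():
                if not (-tol <= v <= 1 + tol):
                    raise AssertionError(f"{name} probability {k}={v} outside [0, 1]")


def _entry_distribution(
    spec: ModelSpec, rates: RateParameters, lead_in: float
) -> np.ndarray:
    """State distribution at entry, conditional on being cancer-free.

    The cohort accrues disease for ``lead_in`` years before entry and is
    enrolled conditional on not having surfaced clinically.  Under a
    constant other-cause hazard the death conditioning cancels across
    alive states, so the lead-in is propagated death-free.
    """
    v = np.zeros(spec.n_states)
    v[spec.index("normal")] = 1.0
    if lead_in > 0:
        P = probability_over(
            spec, rates, MortalitySchedule.constant(0.0), 0.0, lead_in
        )
        v = v @ P
    v[spec.index("clinical")] = 0.0
    v[spec.index("death")] = 0.0
    total = v.sum()
    if total <= 0:
        raise ValueError("entry distribution degenerate: no transient mass")
    return v / total


def _surface_by(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    state: str,
    a: float,
    b: float,
) -> float:
    """P(clinical surfacing by b | in `state` at a, alive)."""
    if b <= a:
        return 0.0
    unit = np.zeros(spec.n_states)
    unit[spec.index(state)] = 1.0
    P = probability_over(spec, rates, mort, a, b)
    return float((unit @ P)[spec.index("clinical")])


def mode_probabilities(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    design: ScreeningDesign,
) -> ModeProbabilities:
    """Exact detection-mode probabilities under the Markov model."""
    rates.require(spec)
    if rates.sens_crc is None:
        raise ValueError("screening layer requires sens_crc")
    if spec.has_adenoma and rates.sens_adenoma is None:
        raise ValueError("adenoma variants require sens_adenoma")

    sens = rates.sens_crc
    sens_a = rates.sens_adenoma if spec.has_adenoma else 0.0
    conf = design.confirmation_rate
    iC = spec.index("clinical")
    iD = spec.index("death")
    iN = spec.index("normal")
    iP = spec.index("pcdp")
    iA = spec.index("adenoma") if spec.has_adenoma else None
    iNP = spec.index("pcdp_nonprog") if spec.has_nonprog else None

    entry = _entry_distribution(spec, rates, design.lead_in)
    v = entry.copy()

    T = design.followup_T
    screens = design.screen_times
    detected: list[float] = []  # confirmed screen detections per round
    negatives: list[float] = []  # expected negative screens per round
    intervals: list[float] = []  # clinical flow per inter-screen window
    pos_unconf: list[float] = []  # unconfirmed-positive cancers per round
    aden_offset: list[float] = []  # removed adenomas destined for clinical CRC by T
    pre_screen = 0.0
    post_program = 0.0

    # within one evaluation, equal-length windows share one P matrix
    _pcache: dict[tuple[float, float], np.ndarray] = {}

    def window_P(a: float, b: float) -> np.ndarray:
        key = (b - a, 0.0) if mort.is_constant else (a, b)
        if key not in _pcache:
            _pcache[key] = probability_over(spec, rates, mort, a, b)
        return _pcache[key]

    def advance(a: float, b: float) -> float:
        """Propagate v over [a, b]; return the clinical flow gained."""
        nonlocal v
        if b <= a:
            return 0.0
        before = v[iC]
        v = v @ window_P(a, b)
        return float(v[iC] - before)

    t_prev = 0.0
    if screens[0] > 0.0:
        pre_screen = advance(0.0, screens[0])
        t_prev = screens[0]

    for r, t_r in enumerate(screens):
        if r > 0:
            intervals.append(advance(t_prev, t_r))
        # --- screen operator at t_r ---
        pos_prog = v[iP] * sens
        pos_nonp = v[iNP] * sens if iNP is not None else 0.0
        det = conf * (pos_prog + pos_nonp)
        unconf_cancer = 0.0
        if conf < 1.0:
            unconf_cancer = (1.0 - conf) * pos_prog * _surface_by(
                spec, rates, mort, "pcdp", t_r, T
            )
        neg = v[iN] + v[iP] * (1.0 - sens)
        if iNP is not None:
            neg += v[iNP] * (1.0 - sens)
        if iA is not None:
            pos_aden = v[iA] * sens_a
            if conf < 1.0:
                unconf_cancer += (1.0 - conf) * pos_aden * _surface_by(
                    spec, rates, mort, "adenoma", t_r, T
                )
            # polypectomy offset: removed adenomas that would have surfaced
            # as clinical CRC within follow-up had they not been removed
            aden_offset.append(
                conf * pos_aden * _surface_by(spec, rates, mort, "adenoma", t_r, T)
            )
            neg += v[iA] * (1.0 - sens_a)
            v[iN] += conf * pos_aden  # polypectomy returns the subject to Normal
            v[iA] *= 1.0 - sens_a
        v[iP] *= 1.0 - sens
        if iNP is not None:
            v[iNP] *= 1.0 - sens
        detected.append(det)
        negatives.append(neg)
        pos_unconf.append(unconf_cancer)
        t_prev = t_r

    cap = min(design.final_interval_years, T - screens[-1])
    final_interval = advance(screens[-1], screens[-1] + cap)
    if cap > 0:
        intervals.append(final_interval)
    post_program = advance(screens[-1] + cap, T)

    p_prevalent = detected[0]
    p_repeat = float(sum(detected[1:]))
    p_interval = float(sum(intervals))
    p_unc_first = pos_unconf[0]
    p_unc_repeat = float(sum(pos_unconf[1:]))

    event_modes = {
        "prevalent_crc": p_prevalent,
        "repeat_crc": p_repeat,
        "interval_crc": p_interval,
        "pos_unconf_first": p_unc_first,
        "pos_unconf_repeat": p_unc_repeat,
        "post_program_crc": post_program,
        "pre_screen_crc": pre_screen,
    }
    if any(p < -1e-12 or p > 1 + 1e-12 for p in event_modes.values()):
        raise ValueError(
            f"mode probabilities outside [0, 1]; rates/design inconsistent: {event_modes}"
        )

    if design.exclude_pre_screen_clinical and pre_screen > 0:
        # subjects surfacing before the first screen are excluded from the
        # participant denominator; renormalise the remaining partition
        scale = 1.0 / (1.0 - pre_screen)
        for k in event_modes:
            if k != "pre_screen_crc":
                event_modes[k] *= scale
        event_modes["pre_screen_crc"] = 0.0
        negatives = [n * scale for n in negatives]
        detected = [d * scale for d in detected]
        intervals = [i * scale for i in intervals]
        pos_unconf = [u * scale for u in pos_unconf]
        aden_offset = [o * scale for o in aden_offset]

    participant = dict(event_modes)
    participant["none"] = 1.0 - sum(event_modes.values())

    # refuser stratum: pure natural history to T
    w = entry @ probability_over(spec, rates, mort, 0.0, T)
    p_ref = float(w[iC])
    refuser = {"refuser_crc": p_ref, "refuser_none": 1.0 - p_ref}

    probs = ModeProbabilities(
        participant=participant,
        refuser=refuser,
        per_round={
            "screen_detected": detected,
            "negative_screens": negatives,
            "interval_windows": intervals,
            "pos_unconf": pos_unconf,
            "adenoma_offset": aden_offset,
        },
    )
    probs.check()
    return probs


def expected_counts(
    probs: ModeProbabilities, design: ScreeningDesign
) -> dict[str, float]:
    """Expected detection-mode table cells under the model."""
    n_part = design.n_participants
    n_ref = design.n_refusers
    neg = probs.per_round["negative_screens"]
    return {
        "prevalent_normal": n_part * neg[0],
        "prevalent_crc": n_part * probs.participant["prevalent_crc"],
        "interval_crc": n_part * probs.participant["interval_crc"],
        "pos_unconf_first": n_part * probs.participant["pos_unconf_first"],
        "pos_unconf_repeat": n_part * probs.participant["pos_unconf_repeat"],
        "repeat_normal": n_part * float(sum(neg[1:])),
        "repeat_crc": n_part * probs.participant["repeat_crc"],
        "refuser_normal": n_ref * probs.refuser["refuser_none"],
        "refuser_crc": n_ref * probs.refuser["refuser_crc"],
    }


def log_likelihood(counts: DetectionModeCounts, probs: ModeProbabilities) -> float:
    """Multinomial log-likelihood kernel sum(n log p) per stratum.

    The remainder category per stratum is the stratum size minus the
    observed cancer-mode counts; a positive count on a zero-probability
    mode yields -inf with a warning (never an exception), so optimisers
    can treat it as a rejected point.
    """
    total = 0.0

    def kernel(pairs: list[tuple[str, float, float]]) -> float:
        s = 0.0
        for name, n, p in pairs:
            if n == 0:
                continue
            if p <= 0.0:
                warnings.warn(
                    f"count {n} observed for mode {name!r} with probability 0",
                    RuntimeWarning,
                    stacklevel=3,
                )
                return -math.inf
            s += n * math.log(p)
        return s

    part_present = counts.present(PARTICIPANT_MODES)
    pairs = [(m, n, probs.participant[m]) for m, n in part_present.items()]
    rem_n = counts.n_participants - sum(part_present.values())
    rem_p = 1.0 - sum(probs.participant[m] for m in part_present)
    pairs.append(("participant_remainder", rem_n, rem_p))
    total += kernel(pairs)

    ref_present = counts.present(REFUSER_MODES)
    pairs = [(m, n, probs.refuser[m]) for m, n in ref_present.items()]
    rem_n = counts.n_refusers - sum(ref_present.values())
    rem_p = 1.0 - sum(probs.refuser[m] for m in ref_present)
    pairs.append(("refuser_remainder", rem_n, rem_p))
    total += kernel(pairs)
    return total
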