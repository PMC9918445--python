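"""Continuous-time Markov natural-history models for colorectal cancer.

The disease process runs Normal -> (Adenoma ->) pre-clinical detectable
phase (PCDP) -> Clinical, with an optional non-progressive PCDP branch
(lesions that never surface clinically) and a competing other-cause death
hazard from every alive state.  Clinical and Death are absorbing.  All
rates are per person-year; all times are in years.

Four model variants are supported:

``progressive_3state``
    Normal -> PCDP -> Clinical.  The hidden natural history of an
    unscreened (control) population.
``overdiag_embedded``
    Adds a non-progressive PCDP state entered from Normal with a fraction
    ``nonprog_fraction`` of the onset intensity.  This is the
    overdiagnosis-embedded model a screened population is fitted with
    (the fraction defaults to 0 in estimation; it is a generative knob of
    the simulator).
``adenoma_4state`` / ``adenoma_overdiag``
    Prepend a Normal -> Adenoma -> PCDP pathway, so that screen-detected
    adenomas removed by polypectomy interrupt the route to cancer.

Transition probabilities use closed-form sums of exponentials for the
non-adenoma chains (with an explicit analytic branch for the equal-rate
degeneracy) and the matrix exponential for the adenoma chains; the two
routes agree to ~1e-12 and are cross-checked in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "VARIANTS",
    "ModelSpec",
    "RateParameters",
    "MortalitySchedule",
    "TransitionProbabilities",
    "intensity_matrix",
    "transition_probability",
    "probability_over",
    "mean_sojourn_time",
]

#: ordered state labels per model variant
VARIANTS: dict[str, tuple[str, ...]] = {
    "progressive_3state": ("normal", "pcdp", "clinical", "death"),
    "overdiag_embedded": ("normal", "pcdp", "pcdp_nonprog", "clinical", "death"),
    "adenoma_4state": ("normal", "adenoma", "pcdp", "clinical", "death"),
    "adenoma_overdiag": (
        "normal",
        "adenoma",
        "pcdp",
        "pcdp_nonprog",
        "clinical",
        "death",
    ),
}

_ABSORBING = ("clinical", "death")


@dataclass(frozen=True)
class ModelSpec:
    """One natural-history model variant with its state space."""

    variant: str

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )

    @property
    def states(self) -> tuple[str, ...]:
        return VARIANTS[self.variant]

    @property
    def transient_states(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s not in _ABSORBING)

    @property
    def has_adenoma(self) -> bool:
        return "adenoma" in self.states

    @property
    def has_nonprog(self) -> bool:
        return "pcdp_nonprog" in self.states

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)


@dataclass(frozen=True)
class RateParameters:
    """Transition intensities and per-screen test sensitivities.

    ``lambda1`` is the Normal->PCDP onset intensity (for adenoma variants
    it is unused and must be None); ``lambda2`` the PCDP->Clinical
    progression intensity (its reciprocal is the mean sojourn time);
    ``sens_crc`` the per-screen probability of detecting a PCDP cancer.
    ``lambda1a``/``lambda1b``/``sens_adenoma`` belong to the adenoma
    variants only.  ``nonprog_fraction`` is the share of PCDP onsets that
    are non-progressive; it is a generative knob of the simulator and
    defaults to 0 in estimation.
    """

    lambda1: float | None = None
    lambda2: float | None = None
    sens_crc: float | None = None
    lambda1a: float | None = None
    lambda1b: float | None = None
    sens_adenoma: float | None = None
    nonprog_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda1a", "lambda1b"):
            v = getattr(self, name)
            if v is not None and not v >= 0.0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("sens_crc", "sens_adenoma"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.nonprog_fraction <= 1.0):
            raise ValueError("nonprog_fraction must lie in [0, 1]")

    def require(self, spec: ModelSpec) -> None:
        """Check that exactly the fields the variant needs are present.

        Fields a variant does not use must be absent, never silently
        defaulted; a missing required rate is an error.
        """
        if spec.has_adenoma:
            needed = ("lambda1a", "lambda1b", "lambda2")
            banned = ("lambda1",)
        else:
            needed = ("lambda1", "lambda2")
            banned = ("lambda1a", "lambda1b", "sens_adenoma")
        for name in needed:
            if getattr(self, name) is None:
                raise ValueError(f"{spec.variant} requires rate {name!r}")
        for name in banned:
            if getattr(self, name) is not None:
                raise ValueError(f"{spec.variant} does not use {name!r}; remove it")
        if self.nonprog_fraction > 0.0 and not spec.has_nonprog:
            raise ValueError(
                f"{spec.variant} has no non-progressive state; nonprog_fraction must be 0"
            )

    def replace(self, **kw) -> "RateParameters":
        d = self.to_dict()
        d.update(kw)
        return RateParameters(**d)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "lambda1",
                "lambda2",
                "sens_crc",
                "lambda1a",
                "lambda1b",
                "sens_adenoma",
                "nonprog_fraction",
            )
        }

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in self.to_dict().items() if v is not None})

    @classmethod
    def from_json(cls, text: str) -> "RateParameters":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class MortalitySchedule:
    """Other-cause death hazard, constant or piecewise-constant in time.

    A piecewise schedule is defined by ``edges`` (len k+1, strictly
    increasing) and ``values`` (len k).  Evaluation outside the grid is
    an error, not an extrapolation.
    """

    values: tuple[float, ...]
    edges: tuple[float, ...] | None = None  # None -> constant everywhere

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise ValueError("death hazard must be >= 0 everywhere")
        if self.edges is None:
            if len(self.values) != 1:
                raise ValueError("constant schedule takes exactly one value")
        else:
            if len(self.edges) != len(self.values) + 1:
                raise ValueError("need len(edges) == len(values) + 1")
            if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError("edges must be strictly increasing")

    @classmethod
    def constant(cls, delta: float) -> "MortalitySchedule":
        return cls(values=(float(delta),))

    @classmethod
    def piecewise(
        cls, edges: Sequence[float], values: Sequence[float]
    ) -> "MortalitySchedule":
        return cls(values=tuple(float(v) for v in values), edges=tuple(float(e) for e in edges))

    @property
    def is_constant(self) -> bool:
        return self.edges is None

    def delta_at(self, t: float) -> float:
        if self.edges is None:
            return self.values[0]
        if t < self.edges[0] or t > self.edges[-1]:
            raise ValueError(
                f"t={t} outside mortality grid [{self.edges[0]}, {self.edges[-1]}]"
            )
        i = int(np.searchsorted(self.edges, t, side="right")) - 1
        return self.values[min(i, len(self.values) - 1)]

    def segments(self, a: float, b: float) -> Iterator[tuple[float, float, float]]:
        """Yield (start, stop, delta) pieces covering [a, b]."""
        if b < a:
            raise ValueError("need b >= a")
        if self.edges is None:
            if b > a:
                yield a, b, self.values[0]
            return
        if a < self.edges[0] or b > self.edges[-1]:
            raise ValueError(
                f"[{a}, {b}] outside mortality grid [{self.edges[0]}, {self.edges[-1]}]"
            )
        cuts = [a] + [e for e in self.edges if a < e < b] + [b]
        for lo, hi in zip(cuts, cuts[1:]):
            yield lo, hi, self.delta_at(0.5 * (lo + hi))


@dataclass(frozen=True)
class TransitionProbabilities:
    """P(t) over the ordered states of a ModelSpec."""

    t: float
    states: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.states), len(self.states)):
            raise ValueError("matrix shape does not match state labels")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities outside [0, 1]")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-10:
            raise ValueError("rows of P(t) must sum to 1")

    def __getitem__(self, key: tuple[str, str]) -> float:
        i = self.states.index(key[0])
        j = self.states.index(key[1])
        return float(self.matrix[i, j])


def intensity_matrix(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule | float,
    at_time: float | None = None,
) -> np.ndarray:
    """Generator matrix Q of the chosen variant.

    Off-diagonals are the transition intensities, every alive state feeds
    the Death column with the other-cause hazard, the non-progressive
    PCDP row has no exit other than Death, and rows sum to zero.  For a
    piecewise mortality schedule ``at_time`` selects the piece.
    """
    rates.require(spec)
    if isinstance(mort, (int, float)):
        delta = float(mort)
        if delta < 0:
            raise ValueError("death hazard must be >= 0")
    elif mort.is_constant:
        delta = mort.values[0]
    else:
        if at_time is None:
            raise ValueError("piecewise mortality needs at_time to build Q")
        delta = mort.delta_at(at_time)

    n = spec.n_states
    Q = np.zeros((n, n))
    ix = spec.index
    f = rates.nonprog_fraction if spec.has_nonprog else 0.0
    if spec.has_adenoma:
        Q[ix("normal"), ix("adenoma")] = rates.lambda1a
        Q[ix("adenoma"), ix("pcdp")] = (1.0 - f) * rates.lambda1b
        if spec.has_nonprog:
            Q[ix("adenoma"), ix("pcdp_nonprog")] = f * rates.lambda1b
    else:
        Q[ix("normal"), ix("pcdp")] = (1.0 - f) * rates.lambda1
        if spec.has_nonprog:
            Q[ix("normal"), ix("pcdp_nonprog")] = f * rates.lambda1
    Q[ix("pcdp"), ix("clinical")] = rates.lambda2
    for s in spec.transient_states:
        Q[ix(s), ix("death")] = delta
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _x1mexp(x: float) -> float:
    """(1 - exp(-x)) / x with the x -> 0 limit."""
    if abs(x) < 1e-8:
        return 1.0 - 0.5 * x
    return -math.expm1(-x) / x


#: relative threshold below which the equal-rate limit formula is used
_EQUAL_RATE_TOL = 1e-9


def _ptrans_closed(
    spec: ModelSpec, rates: RateParameters, delta: float, t: float
) -> np.ndarray:
    """Closed-form P(t) for the non-adenoma chains with constant delta."""
    lam1, lam2 = rates.lambda1, rates.lambda2
    f = rates.nonprog_fraction if spec.has_nonprog else 0.0
    lam1p = (1.0 - f) * lam1
    a = lam1 + delta  # total exit rate from Normal
    b = lam2 + delta  # total exit rate from progressive PCDP
    ea, eb, ed = math.exp(-a * t), math.exp(-b * t), math.exp(-delta * t)

    p_nn = ea
    if b == 0.0:  # lambda2 = delta = 0: PCDP is absorbing
        p_np = lam1p * t * _x1mexp(lam1 * t) if lam1 > 0 else 0.0
        p_nc = 0.0
    elif abs(b - a) < _EQUAL_RATE_TOL * max(a, b, 1e-300):
        # lambda2 == lambda1 degeneracy: limit lam * t * exp(-lam t)
        p_np = lam1p * t * ea
        p_nc = (lam1p * lam2 / b) * (t * _x1mexp(a * t) - t * ea)
    else:
        p_np = lam1p * (ea - eb) / (b - a)
        p_nc = (lam1p * lam2 / b) * (t * _x1mexp(a * t) - (ea - eb) / (b - a))
    p_nnp = f * lam1 * t * _x1mexp(lam1 * t) * ed  # f * e^{-dt} * (1-e^{-l1 t})

    p_pp = eb
    p_pc = lam2 * t * _x1mexp(b * t)

    n = spec.n_states
    P = np.zeros((n, n))
    ix = spec.index
    iN, iP, iC, iD = ix("normal"), ix("pcdp"), ix("clinical"), ix("death")
    P[iN, iN] = p_nn
    P[iN, iP] = p_np
    P[iN, iC] = p_nc
    if spec.has_nonprog:
        iNP = ix("pcdp_nonprog")
        P[iN, iNP] = p_nnp
        P[iNP, iNP] = ed
        P[iNP, iD] = 1.0 - ed
    P[iN, iD] = 1.0 - P[iN].sum()
    P[iP, iP] = p_pp
    P[iP, iC] = p_pc
    P[iP, iD] = 1.0 - p_pp - p_pc
    P[iC, iC] = 1.0
    P[iD, iD] = 1.0
    return P


def _ptrans_const(
    spec: ModelSpec, rates: RateParameters, delta: float, t: float
) -> np.ndarray:
    """P(t) for one time-homogeneous piece."""
    if t == 0.0:
        return np.eye(spec.n_states)
    if spec.has_adenoma:
        Q = intensity_matrix(spec, rates, delta)
        P = expm(Q * t)
        np.clip(P, 0.0, 1.0, out=P)
        return P
    return _ptrans_closed(spec, rates, delta, t)


def probability_over(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    a: float,
    b: float,
) -> np.ndarray:
    """Transition matrix over the window [a, b] (product over mortality pieces)."""
    rates.require(spec)
    P = np.eye(spec.n_states)
    for lo, hi, delta in mort.segments(a, b):
        P = P @ _ptrans_const(spec, rates, delta, hi - lo)
    return P


def transition_probability(
    spec: ModelSpec,
    rates: RateParameters,
    mort: MortalitySchedule,
    t: float,
) -> TransitionProbabilities:
    """P(t) from study entry (time 0)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    P = probability_over(spec, rates, mort, 0.0, t)
    # guard tiny negative round-off before the row-sum check
    P = np.clip(P, 0.0, 1.0)
    P = P / P.sum(axis=1, keepdims=True)
    return TransitionProbabilities(t=t, states=spec.states, matrix=P)


def mean_sojourn_time(rates_or_lambda2) -> float | tuple[float, float]:
    """Mean sojourn time in the progressive PCDP, 1/lambda2.

    Accepts a RateParameters, a positive rate, or an interval (lo, hi) of
    rates, for which the reciprocal bounds are returned in reversed order
    (so the result is again an ordered interval).
    """
    x = rates_or_lambda2
    if isinstance(x, RateParameters):
        x = x.lambda2
    if isinstance(x, (tuple, list)):
        lo, hi = x
        if not (lo > 0 and hi > 0):
            raise ValueError("lambda2 bounds must be > 0")
        return (1.0 / hi, 1.0 / lo)
    if x is None or not x > 0:
        raise ValueError("lambda2 must be > 0")
    return 1.0 / x
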