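"""Bundled study inputs: printed detection-mode tables and fitted rates.

Two guaiac fecal-occult-blood RCTs (Nottingham/UK and Funen/Denmark) are
shipped as verbatim detection-mode count tables together with their
published model-predicted cells, published parameter estimates with 95%
intervals, and documented design assumptions.  The trials' exact round
structure is not published; the designs below are the package's own
reconstruction (biennial screens, follow-up horizons equal to the
published mean follow-up) and can be overridden by the user.

The Taiwan fecal-immunochemical-test service program presets carry the
published transition parameters (with and without the adenoma pathway)
and the published twin/control case totals; the underlying registry data
are not public, so these presets parameterise synthetic scenarios only.
"""

from __future__ import annotations

from .natural_history import ModelSpec, MortalitySchedule, RateParameters
from .screening_likelihood import DetectionModeCounts, ScreeningDesign

__all__ = [
    "nottingham_counts",
    "funen_counts",
    "printed_predicted",
    "rct_design",
    "fitted_rates",
    "fitted_intervals",
    "published_twin_totals",
    "taiwan_like_design",
    "N_FIT_PARAMS",
]

#: free parameters of the CRC-only fit (lambda1, lambda2, sens_crc)
N_FIT_PARAMS = 3

_NOTTINGHAM_OBSERVED = {
    "prevalent_normal": 44733,
    "prevalent_crc": 104,
    "interval_crc": 164,
    "pos_unconf_first": 28,
    "pos_unconf_repeat": 57,
    "repeat_normal": 88008,
    "repeat_crc": 132,
    "refuser_normal": 30015,
    "refuser_crc": 400,
}

_NOTTINGHAM_PREDICTED = {
    "prevalent_normal": 44735.42,
    "prevalent_crc": 101.58,
    "interval_crc": 140.04,
    "pos_unconf_first": 27.76,
    "pos_unconf_repeat": 66.03,
    "repeat_normal": 87977.51,
    "repeat_crc": 109.69,
    "refuser_normal": 30014.06,
    "refuser_crc": 400.94,
}

_FUNEN_OBSERVED = {
    "prevalent_normal": 20635,
    "prevalent_crc": 37,
    "interval_crc": 148,
    "pos_unconf_first": None,  # cells absent from the Funen layout
    "pos_unconf_repeat": None,
    "repeat_normal": 66025,
    "repeat_crc": 83,
    "refuser_normal": 9895,
    "refuser_crc": 195,
}

_FUNEN_PREDICTED = {
    "prevalent_normal": 20630.24,
    "prevalent_crc": 41.76,
    "interval_crc": 147.23,
    "repeat_normal": 66014.12,
    "repeat_crc": 67.74,
    "refuser_normal": 9895.71,
    "refuser_crc": 194.29,
}


def _strata(observed: dict) -> tuple[int, int]:
    n_part = sum(
        observed.get(k) or 0
        for k in ("prevalent_normal", "prevalent_crc", "pos_unconf_first")
    )
    n_ref = (observed.get("refuser_normal") or 0) + (observed.get("refuser_crc") or 0)
    return n_part, n_ref


def nottingham_counts() -> DetectionModeCounts:
    """Observed Nottingham (UK) detection-mode counts."""
    n_part, n_ref = _strata(_NOTTINGHAM_OBSERVED)
    return DetectionModeCounts(
        counts=dict(_NOTTINGHAM_OBSERVED), n_participants=n_part, n_refusers=n_ref
    )


def funen_counts() -> DetectionModeCounts:
    """Observed Funen (Denmark) detection-mode counts."""
    n_part, n_ref = _strata(_FUNEN_OBSERVED)
    return DetectionModeCounts(
        counts=dict(_FUNEN_OBSERVED), n_participants=n_part, n_refusers=n_ref
    )


def printed_predicted(style: str) -> dict[str, float]:
    """Published model-predicted cells of the chosen trial."""
    if style == "nottingham":
        return dict(_NOTTINGHAM_PREDICTED)
    if style == "funen":
        return dict(_FUNEN_PREDICTED)
    raise ValueError(f"unknown trial style {style!r}")


def rct_design(style: str) -> ScreeningDesign:
    """Documented design assumptions for the two trials.

    Three (UK) / four (Funen) biennial screens, follow-up horizon at the
    published mean follow-up, participation derived from the table's
    stratum totals, colonoscopy confirmation 80% (UK; the trial reported
    substantial non-compliance with diagnostic follow-up) or 100%
    (Funen, whose table has no unconfirmed-positive rows).
    """
    if style == "nottingham":
        n_part, n_ref = _strata(_NOTTINGHAM_OBSERVED)
        return ScreeningDesign(
            screen_times=(0.0, 2.0, 4.0),
            followup_T=8.5,
            cohort_size=n_part + n_ref,
            participation=n_part / (n_part + n_ref),
            confirmation_rate=0.80,
        )
    if style == "funen":
        n_part, n_ref = _strata(_FUNEN_OBSERVED)
        return ScreeningDesign(
            screen_times=(0.0, 2.0, 4.0, 6.0),
            followup_T=10.0,
            cohort_size=n_part + n_ref,
            participation=n_part / (n_part + n_ref),
            confirmation_rate=1.0,
        )
    raise ValueError(f"unknown trial style {style!r}")


def fitted_rates(study: str, with_adenoma: bool = False) -> RateParameters:
    """Published point estimates of the natural-history parameters."""
    if with_adenoma:
        if study != "taiwan":
            raise ValueError("adenoma-extended estimates exist for Taiwan only")
        return RateParameters(
            lambda1a=0.00149,
            lambda1b=0.0839,
            lambda2=0.5300,
            sens_adenoma=0.6348,
            sens_crc=0.8286,
        )
    table = {
        "taiwan": RateParameters(lambda1=0.00141, lambda2=0.3860, sens_crc=0.8025),
        "uk": RateParameters(lambda1=0.00147, lambda2=0.3475, sens_crc=0.5340),
        "funen": RateParameters(lambda1=0.00172, lambda2=0.4433, sens_crc=0.5205),
    }
    if study not in table:
        raise ValueError(f"unknown study {study!r}")
    return table[study]


def fitted_intervals(study: str) -> dict[str, tuple[float, float]]:
    """Published 95% intervals of the CRC-only fits."""
    table = {
        "taiwan": {
            "lambda1": (0.00139, 0.00143),
            "lambda2": (0.3726, 0.3997),
            "sens_crc": (0.7812, 0.8232),
        },
        "uk": {
            "lambda1": (0.00136, 0.00159),
            "lambda2": (0.2437, 0.4513),
            "sens_crc": (0.3426, 0.6955),
        },
        "funen": {
            "lambda1": (0.00155, 0.00189),
            "lambda2": (0.3226, 0.5639),
            "sens_crc": (0.3553, 0.6856),
        },
    }
    if study not in table:
        raise ValueError(f"unknown study {study!r}")
    return table[study]


def published_twin_totals(study: str) -> dict[str, float]:
    """Published screened-twin prediction S(t) and control count U(t)."""
    table = {
        "uk": {"S": 931.0, "U": 856.0, "cohort": 74998, "followup": 8.5},
        "funen": {"S": 528.0, "U": 483.0, "cohort": 30966, "followup": 10.0},
        "taiwan_invasive": {"S": 66339.0, "U": 63616.0, "cohort": 5417699, "followup": 11.0},
        "taiwan_hgd": {"S": 79469.0, "U": 72587.0, "cohort": 5417699, "followup": 11.0},
        "taiwan_adenoma": {"S": 84425.0, "U": 72587.0, "cohort": 5417699, "followup": 11.0},
    }
    if study not in table:
        raise ValueError(f"unknown study {study!r}")
    return dict(table[study])


def taiwan_like_design(cohort_size: int = 1_000_000) -> ScreeningDesign:
    """A Taiwan-like biennial FIT service-screening scenario.

    An ongoing service program: biennial screens offered throughout the
    11-year follow-up window, participation 70%, full diagnostic
    confirmation.
    """
    return ScreeningDesign(
        screen_times=(0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
        followup_T=11.0,
        cohort_size=cohort_size,
        participation=0.70,
        confirmation_rate=1.0,
    )


def taiwan_published_design() -> ScreeningDesign:
    """The published Taiwan program's structure, as a fixed-horizon design.

    Recruitment with biennial screens over the first program years
    (2004-2009) and passive registry follow-up to 11 years (2014);
    participation 3,811,011 / 5,417,699.
    """
    return ScreeningDesign(
        screen_times=(0.0, 2.0, 4.0),
        followup_T=11.0,
        cohort_size=5_417_699,
        participation=3_811_011 / 5_417_699,
        confirmation_rate=1.0,
    )


def default_mortality() -> MortalitySchedule:
    """Constant 0.01/person-year other-cause hazard (ages 50-69 order of magnitude)."""
    return MortalitySchedule.constant(0.01)


def spec_for(study: str, with_adenoma: bool = False) -> ModelSpec:
    if with_adenoma:
        return ModelSpec("adenoma_overdiag")
    return ModelSpec("overdiag_embedded")
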