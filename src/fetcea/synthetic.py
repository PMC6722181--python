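"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: a latent true
response state per clinical endpoint, two imperfect imaging
classifiers described by their sensitivity and specificity for the
non-response state, continuous measurements constructed to be
consistent with the intended imaging calls, and per-modality
missingness.

Generation per patient:

1. Draw the true overall-survival and progression-free-survival
   response states from their configured non-responder prevalences.
2. Draw survival times from the lognormal stratum matching each true
   state, rejection-sampled onto the correct side of the clinical
   cut-off (>10 months OS responders, >=6 months PFS responders) and
   constrained to PFS <= OS.
3. Draw the intended PET and MRI calls from the confusion
   probabilities against the true state of the *call endpoint*
   (default: overall survival) — sensitivity is the probability that
   a true non-responder is called non-responder, specificity that a
   true responder is called responder.
4. Synthesise measurements that the classification rules map back to
   the intended calls: TBRmax ratios and Gd-volume ratios are drawn
   from bands with a guard margin around the rule boundaries (the PET
   ratio band excludes (0.78, 0.82) around the 0.80 cut-off), so a
   classifier applied to the measurements recovers every intended
   call exactly.
5. Blank second-scan values independently per modality with the
   configured missingness rates.

Because measurement synthesis never flips an intended call, the
empirical chance nodes of a generated cohort converge, as the cohort
grows, to closed-form targets computable from prevalence and the
confusion probabilities — the basis of the parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, PatientRecord
from .classify import (
    OS_CUTOFF_MONTHS,
    PFS_CUTOFF_MONTHS,
)

__all__ = [
    "SyntheticConfig",
    "SurvivalStratum",
    "generate",
    "table1_like_config",
    "expected_chance_nodes",
]

_MAX_REJECTION_TRIES = 10_000


@dataclass(frozen=True)
class SurvivalStratum:
    """Lognormal survival-time distribution for one response stratum.

    ``median`` is in months; ``sigma`` is the log-scale standard
    deviation.  The stratum must place non-negligible mass on its side
    of the clinical cut-off, otherwise generation fails.
    """

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.lognormal(math.log(self.median), self.sigma, size)


def _default_strata() -> dict[str, SurvivalStratum]:
    # medians loosely matching published glioblastoma follow-up series:
    # responders well above, non-responders well below each cut-off
    return {
        "os_responder": SurvivalStratum(median=17.0, sigma=0.30),
        "os_non_responder": SurvivalStratum(median=7.0, sigma=0.35),
        "pfs_responder": SurvivalStratum(median=11.0, sigma=0.35),
        "pfs_non_responder": SurvivalStratum(median=4.5, sigma=0.35),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults mimic the reference cohort."""

    n_patients: int = 25
    # prevalence of TRUE NON-RESPONSE per endpoint
    os_nonresponder_prevalence: float = 9 / 23
    pfs_nonresponder_prevalence: float = 11 / 25
    # confusion probabilities w.r.t. the call endpoint's true state
    pet_sensitivity: float = 1.0
    pet_specificity: float = 10 / 14
    mri_sensitivity: float = 3 / 7
    mri_specificity: float = 10 / 14
    call_endpoint: str = "os"
    pet_missing_rate: float = 0.0
    mri_missing_rate: float = 0.0
    survival: dict[str, SurvivalStratum] = field(default_factory=_default_strata)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "os_nonresponder_prevalence",
            "pfs_nonresponder_prevalence",
            "pet_sensitivity",
            "pet_specificity",
            "mri_sensitivity",
            "mri_specificity",
            "pet_missing_rate",
            "mri_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.call_endpoint not in ("os", "pfs"):
            raise ValueError("call_endpoint must be 'os' or 'pfs'")
        missing = {
            "os_responder",
            "os_non_responder",
            "pfs_responder",
            "pfs_non_responder",
        } - set(self.survival)
        if missing:
            raise ValueError(f"survival strata missing {sorted(missing)}")


def _sample_conditional(
    rng: np.random.Generator,
    stratum: SurvivalStratum,
    responder: bool,
    cutoff: float,
    inclusive: bool,
    upper: float | None = None,
) -> float:
    """One survival time on the required side of the cut-off (and <= upper)."""
    for _ in range(_MAX_REJECTION_TRIES):
        x = float(stratum.sample(rng, 1)[0])
        if responder:
            ok = x >= cutoff if inclusive else x > cutoff
        else:
            ok = x < cutoff if inclusive else x <= cutoff
        if ok and (upper is None or x <= upper):
            return x
    raise ValueError(
        "survival stratum places (almost) no mass on its side of the "
        f"cut-off {cutoff} (median={stratum.median}, sigma={stratum.sigma})"
    )


def _sample_survival(
    rng: np.random.Generator, config: SyntheticConfig, os_resp: bool, pfs_resp: bool
) -> tuple[float, float]:
    """(os_months, pfs_months) honouring both states and PFS <= OS."""
    os_stratum = config.survival["os_responder" if os_resp else "os_non_responder"]
    pfs_stratum = config.survival[
        "pfs_responder" if pfs_resp else "pfs_non_responder"
    ]
    for _ in range(_MAX_REJECTION_TRIES):
        os_months = _sample_conditional(
            rng, os_stratum, os_resp, OS_CUTOFF_MONTHS, inclusive=False
        )
        # a PFS responder needs pfs in [6, os]; infeasible when os < 6
        if pfs_resp and os_months < PFS_CUTOFF_MONTHS:
            continue
        try:
            pfs_months = _sample_conditional(
                rng,
                pfs_stratum,
                pfs_resp,
                PFS_CUTOFF_MONTHS,
                inclusive=True,
                upper=os_months,
            )
        except ValueError:
            continue
        return os_months, pfs_months
    raise ValueError(
        "could not draw a survival pair consistent with the configured strata"
    )


def generate(config: SyntheticConfig) -> Cohort:
    """Generate a synthetic cohort; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    records = []
    for pid in range(1, config.n_patients + 1):
        os_resp = rng.random() >= config.os_nonresponder_prevalence
        pfs_resp = rng.random() >= config.pfs_nonresponder_prevalence
        os_months, pfs_months = _sample_survival(rng, config, os_resp, pfs_resp)

        truth_resp = os_resp if config.call_endpoint == "os" else pfs_resp
        if truth_resp:
            pet_calls_nr = rng.random() >= config.pet_specificity
            mri_calls_nr = rng.random() >= config.mri_specificity
        else:
            pet_calls_nr = rng.random() < config.pet_sensitivity
            mri_calls_nr = rng.random() < config.mri_sensitivity

        # measurements consistent with the intended calls, with a guard
        # band around the rule boundaries
        tbr1 = rng.uniform(2.0, 5.0)
        ratio = rng.uniform(0.82, 1.30) if pet_calls_nr else rng.uniform(0.40, 0.78)
        tbr2 = tbr1 * ratio
        gd1 = rng.uniform(0.1, 30.0)
        gd2 = gd1 * (rng.uniform(1.02, 5.0) if mri_calls_nr else rng.uniform(0.0, 1.0))

        pet_missing = rng.random() < config.pet_missing_rate
        mri_missing = rng.random() < config.mri_missing_rate
        records.append(
            PatientRecord(
                patient_id=pid,
                gd_vol_1=gd1,
                gd_vol_2=None if mri_missing else gd2,
                tbr_max_1=tbr1,
                tbr_max_2=None if pet_missing else tbr2,
                os_months=os_months,
                pfs_months=pfs_months,
            )
        )
    return Cohort(tuple(records))


def table1_like_config(n_patients: int = 25, seed: int = 0) -> SyntheticConfig:
    """A configuration whose large-sample chance nodes match the
    reference cohort's overall-survival tree.

    The confusion probabilities are the reference cohort's empirical
    rates (PET sensitivity 9/9, specificity 10/14; MRI sensitivity
    3/7, specificity 10/14) with a true non-responder prevalence of
    9/23, so that for large ``n_patients`` the estimated N1 tends to
    10/23 ~= 0.4348 and N2 to 2/3, and the incremental identification
    rate to 0.5714.
    """
    return SyntheticConfig(
        n_patients=n_patients,
        pet_missing_rate=2 / 25,
        mri_missing_rate=4 / 25,
        seed=seed,
    )


def expected_chance_nodes(config: SyntheticConfig) -> dict[str, float]:
    """Closed-form large-sample chance nodes implied by a configuration.

    With non-response prevalence ``pi`` and a test's sensitivity
    ``se`` / specificity ``sp`` (both for the call endpoint), the call
    and conditional-truth probabilities follow from Bayes' rule; used
    as the oracle in parameter-recovery tests.  Missingness is
    independent of everything, so availability does not shift the
    targets.
    """
    pi = (
        config.os_nonresponder_prevalence
        if config.call_endpoint == "os"
        else config.pfs_nonresponder_prevalence
    )

    def nodes(se: float, sp: float) -> tuple[float, float, float]:
        p_call_r = (1 - pi) * sp + pi * (1 - se)
        p_call_nr = 1.0 - p_call_r
        true_r_given_r = (1 - pi) * sp / p_call_r if p_call_r > 0 else float("nan")
        true_nr_given_nr = pi * se / p_call_nr if p_call_nr > 0 else float("nan")
        return p_call_r, true_r_given_r, true_nr_given_nr

    n1, n3, n4 = nodes(config.pet_sensitivity, config.pet_specificity)
    n2, n5, n6 = nodes(config.mri_sensitivity, config.mri_specificity)
    return {"n1": n1, "n2": n2, "n3": n3, "n4": n4, "n5": n5, "n6": n6}
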