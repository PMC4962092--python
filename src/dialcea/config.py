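"""Ground-truth configuration for the synthetic national-cohort generator.

Every knob the generator uses — covariate prevalences, the true propensity
model for modality assignment, the constant excess hazards, the cost process
and the latent utility trajectory — lives here, so parameter-recovery tests
can compare pipeline estimates against known truth.

Defaults emulate a national dialysis cohort: a middle-aged, comorbidity-heavy
population accrued over 1998-2010 and followed administratively for 14 years
(168 months), with hemodialysis (HD) the majority modality, near-equal excess
mortality in the two arms, outpatient care (the dialysis sessions themselves)
carrying roughly 90% of monthly spending, and a slowly declining mean EQ-5D
utility with time on dialysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

MODALITIES = ("HD", "PD")

#: Comorbidity flags carried on every subject record.
COVARIATES = (
    "diabetes",
    "hypertension",
    "chf",
    "mi",
    "stroke",
    "chronic_liver",
    "cad",
    "dysrhythmia",
    "pvd",
    "hyperlipidemia",
    "rheumatologic",
)

#: Covariates entering the true propensity model for PD assignment.
PS_COVARIATES = ("hypertension", "cad", "dysrhythmia", "pvd", "hyperlipidemia", "rheumatologic")


@dataclass
class CostParams:
    """Monthly healthcare cost process, split outpatient / inpatient.

    Outpatient costs (dialysis sessions, clinic visits, drugs) recur every
    alive month around a modality-specific mean; inpatient costs are sparse
    hospitalization spikes.  Defaults put the outpatient share of total
    spending near 0.9.  ``first_month_multiplier`` scales month 1 (vascular
    access / catheter placement).  Currency units are arbitrary but constant.
    """

    outpatient_mean: dict[str, float] = field(
        default_factory=lambda: {"HD": 1150.0, "PD": 1000.0}
    )
    inpatient_event_rate: float = 0.05  # probability of a hospitalization per alive month
    inpatient_event_mean: dict[str, float] = field(
        default_factory=lambda: {"HD": 2500.0, "PD": 2200.0}
    )
    first_month_multiplier: float = 2.0
    noise_cv: float = 0.3  # coefficient of variation of the gamma cost noise; 0 = degenerate


@dataclass
class UtilityParams:
    """Latent EQ-5D utility trajectory for the cross-sectional survey.

    Latent utility = intercept + slope * vintage + covariate effects + noise,
    truncated to the value set's range and snapped to the nearest scorable
    five-domain profile.  The slope is mildly negative: quality of life
    erodes slowly with years on dialysis.
    """

    intercept: float = 0.92
    slope_per_month: float = -0.0006
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"diabetes": -0.05, "stroke": -0.10}
    )
    modality_effect: dict[str, float] = field(
        default_factory=lambda: {"HD": 0.0, "PD": 0.0}
    )
    noise_sd: float = 0.08
    n_records: int = 1600
    pd_fraction: float = 0.17
    vintage_range: tuple[int, int] = (3, 180)


@dataclass
class IneligibleFractions:
    """Fractions of raw-cohort subjects planted to exercise each exclusion rule."""

    underage: float = 0.01
    short_dialysis: float = 0.015
    malignancy: float = 0.02
    modality_switch: float = 0.01
    prior_transplant: float = 0.005
    transplant_during_followup: float = 0.04  # retained but censored at transplantation


@dataclass
class SimulationConfig:
    """Full ground truth for one synthetic cohort.

    ``excess_hazard`` is the constant monthly excess hazard added to the
    age-sex reference hazard for each modality — the quantity the lifetime
    extrapolation assumes constant and the recovery tests try to get back.
    """

    n_subjects: int = 5000
    seed: int = 0
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "diabetes": 0.435,
            "hypertension": 0.876,
            "chf": 0.22,
            "mi": 0.032,
            "stroke": 0.116,
            "chronic_liver": 0.226,
            "cad": 0.291,
            "dysrhythmia": 0.137,
            "pvd": 0.11,
            "hyperlipidemia": 0.50,
            "rheumatologic": 0.07,
        }
    )
    propensity_intercept: float = -1.45
    propensity_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.35,
            "cad": -0.30,
            "dysrhythmia": -0.20,
            "pvd": -0.45,
            "hyperlipidemia": 0.30,
            "rheumatologic": 0.10,
        }
    )
    excess_hazard: dict[str, float] = field(
        default_factory=lambda: {"HD": 0.002, "PD": 0.002}
    )
    censor_horizon_months: int = 168
    age_mean: float = 55.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 90.0)
    p_male: float = 0.45
    urbanization_probs: tuple[float, float, float] = (0.26, 0.29, 0.45)
    accrual_years: tuple[int, int] = (1998, 2010)
    cost: CostParams = field(default_factory=CostParams)
    utility: UtilityParams = field(default_factory=UtilityParams)
    ineligible: IneligibleFractions = field(default_factory=IneligibleFractions)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, p in self.covariate_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name!r} must be in [0,1], got {p}")
        for m, lam in self.excess_hazard.items():
            if lam < 0:
                raise ValueError(f"excess hazard for {m!r} must be >= 0, got {lam}")
        if self.censor_horizon_months < 1:
            raise ValueError("censor horizon must be >= 1 month")
        if not 0.0 <= self.p_male <= 1.0:
            raise ValueError("p_male must be in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("cost", CostParams), ("utility", UtilityParams), ("ineligible", IneligibleFractions)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                })
        for key in ("age_range", "urbanization_probs", "accrual_years"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
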