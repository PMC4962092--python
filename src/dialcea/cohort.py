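"""Cohort construction from raw tables: comorbidity flags and eligibility.

Comorbidity ascertainment follows the standard claims-based rule: a condition
counts as present at dialysis start if, within the 365 days before the index
date, the subject has at least one inpatient discharge claim carrying a
mapped diagnosis code, or at least two ambulatory claims with a mapped code
whose dates lie >= 30 days apart.  Codes are matched by string prefix against
a user-supplied code map (a toy map is packaged; a licensed ICD-9 dictionary
is deliberately not).

Eligibility mirrors an incident-dialysis study design: adults (>18 y at
index) on a single modality for more than three consecutive months, never
diagnosed with malignancy, never switched modality for a sustained spell
(>3 months), and not transplanted before dialysis.  Subjects transplanted
during follow-up stay in the cohort with their survival time truncated at
transplantation and treated as censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "load_code_map",
    "toy_code_map",
    "flag_comorbidities",
    "EligibilityReport",
    "apply_eligibility",
]

#: Days in the pre-index ascertainment window (closed, ending the day before index).
LOOKBACK_DAYS = 365
#: Minimum separation (days) between the two qualifying ambulatory claims.
MIN_AMBULATORY_GAP_DAYS = 30


def load_code_map(path) -> dict[str, tuple[str, ...]]:
    """Read a comorbidity -> diagnosis-code-prefix map from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, prefixes in raw.items():
        if not prefixes:
            raise ValueError(f"code map entry {name!r} has an empty prefix set")
        out[name] = tuple(str(p) for p in prefixes)
    return out


def toy_code_map() -> dict[str, tuple[str, ...]]:
    """The packaged toy ICD-9-style prefix map used by the synthetic pipeline."""
    ref = resources.files("dialcea").joinpath("data/toy_code_map.yaml")
    with resources.as_file(ref) as path:
        return load_code_map(path)


def flag_comorbidities(
    claims: pd.DataFrame,
    index_dates: pd.Series,
    code_map: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Per-subject comorbidity flags from pre-index claims.

    Parameters
    ----------
    claims:
        Columns ``id``, ``date`` (datetime-like, no missing values),
        ``setting`` ('inpatient'/'ambulatory'), ``code`` (string).
    index_dates:
        Series of index dates indexed by subject id; every claim must
        reference a known subject.
    code_map:
        Comorbidity name -> tuple of code prefixes (string prefix match).

    Returns
    -------
    DataFrame indexed by subject id (one row per subject in ``index_dates``),
    one boolean column per comorbidity.  The result is invariant to the order
    of the claims table.
    """
    claims = claims.copy()
    claims["date"] = pd.to_datetime(claims["date"])
    if claims["date"].isna().any():
        raise ValueError("claims contain undated records")
    unknown = set(claims["id"]) - set(index_dates.index)
    if unknown:
        raise ValueError(f"claims reference unknown subject ids: {sorted(unknown)[:5]}")

    flags = pd.DataFrame(
        False, index=index_dates.index, columns=list(code_map), dtype=bool
    )
    if claims.empty:
        return flags
    idx = index_dates.loc[claims["id"]].to_numpy()
    delta = (idx - claims["date"].to_numpy()).astype("timedelta64[D]").astype(int)
    in_window = (delta >= 1) & (delta <= LOOKBACK_DAYS)
    windowed = claims.loc[in_window]

    code = windowed["code"].astype(str)
    for comorbidity, prefixes in code_map.items():
        hit = windowed.loc[code.str.startswith(tuple(prefixes))]
        inpat_ids = hit.loc[hit["setting"] == "inpatient", "id"].unique()
        flags.loc[flags.index.isin(inpat_ids), comorbidity] = True
        amb = hit.loc[hit["setting"] == "ambulatory"]
        span = amb.groupby("id")["date"].agg(lambda d: (d.max() - d.min()).days)
        ok = span.index[span >= MIN_AMBULATORY_GAP_DAYS]
        flags.loc[flags.index.isin(ok), comorbidity] = True
    return flags


@dataclass
class EligibilityReport:
    """Accounting of the eligibility filter: every input subject lands somewhere."""

    n_input: int
    excluded: dict[str, int] = field(default_factory=dict)
    n_censored_at_transplant: int = 0
    final_n: dict[str, int] = field(default_factory=dict)

    @property
    def n_final(self) -> int:
        return sum(self.final_n.values())

    def check_partition(self) -> None:
        if self.n_input != self.n_final + sum(self.excluded.values()):
            raise AssertionError("eligibility report does not conserve subjects")


#: Exclusion reasons, applied in this order (one reason per subject).
EXCLUSION_REASONS = (
    "age<18",
    "<=3 months dialysis",
    "malignancy",
    "modality switch",
    "prior transplant",
)


def apply_eligibility(
    cohort: pd.DataFrame, index_mode: str = "index_at_qualification"
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the eligibility and censoring rules to a raw cohort table.

    Expects the raw cohort columns produced by the generator (or equivalent
    readers): ``age_at_index``, ``time``, ``event``, ``modality``,
    ``dialysis_months``, ``switch_months``, ``malignancy``,
    ``prior_transplant``, ``transplant_month``.

    ``index_mode`` selects the survival time origin: with
    ``"index_at_qualification"`` (default) the input times are taken to be
    measured from the qualification date (after three sustained months of
    dialysis) and used as-is; with ``"index_at_start"`` times are shifted to
    measure from dialysis day 1 (three months added, ages rolled back 0.25 y).

    Returns the eligible cohort (with transplant truncation applied) and an
    :class:`EligibilityReport` that accounts for every input subject.
    """
    if index_mode not in ("index_at_qualification", "index_at_start"):
        raise ValueError(f"unknown index mode {index_mode!r}")
    if (cohort["time"] < 0).any() or (cohort["dialysis_months"] < 0).any():
        raise ValueError("negative durations in cohort table")

    report = EligibilityReport(n_input=len(cohort))
    remaining = cohort.copy()
    rules = {
        "age<18": remaining["age_at_index"] < 18.0,
        "<=3 months dialysis": remaining["dialysis_months"] <= 3.0,
        "malignancy": remaining["malignancy"].astype(bool),
        "modality switch": remaining["switch_months"] > 3.0,
        "prior transplant": remaining["prior_transplant"].astype(bool),
    }
    excluded = pd.Series(False, index=remaining.index)
    for reason in EXCLUSION_REASONS:
        hit = rules[reason] & ~excluded
        report.excluded[reason] = int(hit.sum())
        excluded |= hit
    eligible = remaining.loc[~excluded].copy()

    tx = eligible["transplant_month"].notna() & (
        eligible["transplant_month"] < eligible["time"]
    )
    eligible.loc[tx, "time"] = eligible.loc[tx, "transplant_month"]
    eligible.loc[tx, "event"] = "censored"
    eligible["censored_at_transplant"] = tx
    report.n_censored_at_transplant = int(tx.sum())

    if index_mode == "index_at_start":
        eligible["time"] = eligible["time"] + 3.0
        eligible["age_at_index"] = eligible["age_at_index"] - 0.25

    report.final_n = eligible["modality"].value_counts().to_dict()
    report.check_partition()
    return eligible.reset_index(drop=True), report
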