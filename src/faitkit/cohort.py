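"""Synthetic two-arm screening cohorts.

The individual-level data behind a community CVD screening trial are rarely
deposited; what a published impact assessment carries forward are arm-level
summaries — screening coverage, the high-risk fraction, medication coverage
by arm, and the between-arm difference in mean systolic blood pressure (SBP)
among high-risk individuals.  This module generates person-level cohorts with
exactly that statistical structure, so the downstream projection and
economics stages can be exercised (and tested) end to end at desk scale.

Generative model, per person in a target cohort of ``n_target``:

* arm          ~ Bernoulli(allocation_fraction)  (intervention vs control)
* screened     ~ Bernoulli(p_screen)
* high_risk    ~ Bernoulli(p_highrisk), only if screened
* treated      ~ Bernoulli(p_treated_<arm>), only if high-risk
* sbp          ~ Normal(sbp_mean_control, sbp_sd), minus a medication effect
  for treated high-risk individuals (both arms — medication lowers blood
  pressure wherever it is taken)
* age          ~ Normal(59, 8) truncated below at 18

``treatment_effect_sbp`` parameterises the *expected between-arm contrast*
in mean SBP among high-risk individuals, because that contrast is what trial
reports print and what the impact model consumes.  The per-treated-person
reduction is derived internally as
``treatment_effect_sbp / (p_treated_intervention - p_treated_control)``, so
the empirical contrast recovers the parameter in expectation.
"""

from __future__ import annotations

from typing import Annotated

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

__all__ = ["CohortParams", "TrialSummary", "generate_cohort", "summarize_cohort"]

Probability = Annotated[float, Field(ge=0.0, le=1.0)]

#: Columns of a cohort table, in canonical order.
COHORT_COLUMNS = ["id", "arm", "screened", "high_risk", "treated", "sbp", "age"]

_AGE_MEAN = 59.0
_AGE_SD = 8.0
_AGE_MIN = 18.0


class CohortParams(BaseModel):
    """Parameters of the synthetic screening cohort.

    Defaults are calibrated to the SMARThealth-style trial summary:
    a target cohort of 12,088 people of whom 91% are screened (~11,000),
    22% of the screened flagged high-risk, 80% vs 16% appropriate-medication
    coverage among high-risk individuals by arm, and a 13 mmHg between-arm
    difference in mean SBP among high-risk individuals.
    """

    model_config = ConfigDict(frozen=True)

    n_target: int = Field(default=12_088, ge=1)
    p_screen: Probability = 0.91
    p_highrisk: Probability = 0.22
    p_treated_intervention: Probability = 0.80
    p_treated_control: Probability = 0.16
    sbp_mean_control: float = Field(default=140.0, gt=0.0)
    sbp_sd: float = Field(default=15.0, gt=0.0)
    treatment_effect_sbp: float = Field(default=13.0, ge=0.0)
    allocation_fraction: Probability = 0.5
    seed: int = 0

    @model_validator(mode="after")
    def _contrast_identifiable(self) -> "CohortParams":
        if self.treatment_effect_sbp > 0 and (
            self.p_treated_intervention <= self.p_treated_control
        ):
            raise ValueError(
                "treatment_effect_sbp > 0 requires p_treated_intervention > "
                "p_treated_control: the between-arm SBP contrast is generated "
                "through differential medication coverage"
            )
        return self

    @property
    def per_treated_sbp_reduction(self) -> float:
        """Medication effect applied to each treated high-risk person (mmHg)."""
        if self.treatment_effect_sbp == 0:
            return 0.0
        return self.treatment_effect_sbp / (
            self.p_treated_intervention - self.p_treated_control
        )


class TrialSummary(BaseModel):
    """Arm-level summary of a cohort, the projection model's input."""

    n_screened: int
    screening_coverage: float
    highrisk_fraction: float
    n_highrisk: dict[str, int]
    treated_fraction_by_arm: dict[str, float]
    delta_sbp_highrisk: float  # control mean minus intervention mean, mmHg

    @model_validator(mode="after")
    def _bounds(self) -> "TrialSummary":
        for name in ("screening_coverage", "highrisk_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for arm, frac in self.treated_fraction_by_arm.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"treated fraction for arm {arm!r} outside [0, 1]")
        if sum(self.n_highrisk.values()) > self.n_screened:
            raise ValueError("more high-risk individuals than screened individuals")
        return self


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a person-level cohort table; deterministic given ``params.seed``.

    Returns a DataFrame with columns ``id, arm, screened, high_risk, treated,
    sbp, age``; ``high_risk`` implies ``screened`` and ``treated`` implies
    ``high_risk`` by construction.
    """
    n = params.n_target
    rng = np.random.default_rng(params.seed)

    arm = np.where(
        rng.random(n) < params.allocation_fraction, "intervention", "control"
    )
    screened = rng.random(n) < params.p_screen
    high_risk = screened & (rng.random(n) < params.p_highrisk)
    p_treat = np.where(
        arm == "intervention", params.p_treated_intervention, params.p_treated_control
    )
    treated = high_risk & (rng.random(n) < p_treat)

    sbp = rng.normal(params.sbp_mean_control, params.sbp_sd, size=n)
    sbp[treated] -= params.per_treated_sbp_reduction

    a, b = (_AGE_MIN - _AGE_MEAN) / _AGE_SD, np.inf
    age = stats.truncnorm.rvs(
        a, b, loc=_AGE_MEAN, scale=_AGE_SD, size=n, random_state=rng
    )

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": arm,
            "screened": screened,
            "high_risk": high_risk,
            "treated": treated,
            "sbp": sbp,
            "age": age,
        }
    )


def summarize_cohort(cohort: pd.DataFrame) -> TrialSummary:
    """Reduce a cohort table to the arm-level summary the projection consumes.

    Raises ``ValueError`` on an empty cohort or when either arm contributes no
    high-risk individuals (the between-arm SBP contrast is then undefined).
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")

    screened = cohort["screened"]
    high = cohort[cohort["high_risk"]]
    n_high = {
        arm: int((high["arm"] == arm).sum()) for arm in ("intervention", "control")
    }
    if min(n_high.values()) == 0:
        raise ValueError(
            "between-arm contrast undefined: an arm has no high-risk individuals"
        )

    treated_frac = {
        arm: float(high.loc[high["arm"] == arm, "treated"].mean())
        for arm in ("intervention", "control")
    }
    mean_sbp = {
        arm: float(high.loc[high["arm"] == arm, "sbp"].mean())
        for arm in ("intervention", "control")
    }

    return TrialSummary(
        n_screened=int(screened.sum()),
        screening_coverage=float(screened.mean()),
        highrisk_fraction=float(high_risk_fraction(cohort)),
        n_highrisk=n_high,
        treated_fraction_by_arm=treated_frac,
        delta_sbp_highrisk=mean_sbp["control"] - mean_sbp["intervention"],
    )


def high_risk_fraction(cohort: pd.DataFrame) -> float:
    """Fraction of *screened* individuals flagged high-risk."""
    screened = cohort[cohort["screened"]]
    if len(screened) == 0:
        raise ValueError("no screened individuals in cohort")
    return float(screened["high_risk"].mean())


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (header row, one record per person)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]
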