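"""Cohort-level projection of CVD events, deaths and DALYs averted.

The model converts a sustained systolic blood-pressure (SBP) reduction into
expected cardiovascular events averted over a fixed horizon, then into
disability-adjusted life years (DALYs) averted:

* risk scaling is log-linear in SBP: a relative risk ``rr_per_10`` (default
  0.80) applies multiplicatively per 10 mmHg of SBP reduction, so
  ``RR(d) = rr_per_10 ** (d / 10)``;
* ``events_control = n_exposed * baseline_event_risk`` (cumulative risk over
  the horizon, no annual compounding) and
  ``events_intervention = events_control * RR(delta_sbp)``;
* a case-fatality fraction splits events averted into deaths and non-fatal
  events;
* years of life lost (YLL) per death averted span mean age to life
  expectancy at the dead-state weight (1.0); years lived with disability
  (YLD) per non-fatal event use the survived-CVD disability weight (0.39,
  a Global Burden of Disease myocardial-infarction/stroke average) over
  ``nonfatal_duration`` years.

All quantities are expectations; fractional events are meaningful.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "EpiParams",
    "EventProjection",
    "relative_risk",
    "project_events",
    "dalys_averted",
    "scale_projection",
]


class EpiParams(BaseModel):
    """Epidemiological assumptions for the event/DALY projection.

    ``baseline_event_risk`` and ``case_fatality`` are literature parameters
    the user must supply (they vary by setting); the remainder default to the
    published assumption set: RR 0.80 per 10 mmHg, disability weight 0.39 for
    survived CVD, 1.0 for death, cohort mean age 59, life expectancy 69,
    a 5-year horizon, and no discounting.
    """

    model_config = ConfigDict(frozen=True)

    rr_per_10: float = Field(default=0.80, gt=0.0, le=1.0)
    baseline_event_risk: float = Field(ge=0.0, le=1.0)
    case_fatality: float = Field(ge=0.0, le=1.0)
    dw_nonfatal: float = Field(default=0.39, ge=0.0, le=1.0)
    dw_fatal: float = Field(default=1.0, ge=0.0, le=1.0)
    nonfatal_duration: Optional[float] = Field(default=None, ge=0.0)
    mean_age: float = Field(default=59.0, gt=0.0)
    life_expectancy: float = Field(default=69.0, gt=0.0)
    horizon: float = Field(default=5.0, gt=0.0)
    discount_rate: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _consistent(self) -> "EpiParams":
        if self.life_expectancy < self.mean_age:
            raise ValueError("life_expectancy must be >= mean_age")
        if self.dw_nonfatal > self.dw_fatal:
            raise ValueError("dw_nonfatal must not exceed dw_fatal")
        return self

    @property
    def yll_per_death(self) -> float:
        """Undiscounted years of life lost per death averted."""
        return self.life_expectancy - self.mean_age

    @property
    def effective_nonfatal_duration(self) -> float:
        """YLD duration; defaults to the YLL window (life expectancy - age)."""
        if self.nonfatal_duration is not None:
            return self.nonfatal_duration
        return self.yll_per_death


class EventProjection(BaseModel):
    """Expected events, deaths and DALYs averted for an exposed cohort."""

    n_exposed: float
    delta_sbp: float
    rr_applied: float
    events_control: float
    events_intervention: float
    events_averted: float
    deaths_averted: float
    yll_averted: float = 0.0
    yld_averted: float = 0.0
    dalys_averted: float = 0.0


def relative_risk(delta_sbp: float, rr_per_10: float = 0.80) -> float:
    """Relative risk of a CVD event after a ``delta_sbp`` mmHg SBP reduction.

    Log-linear in the reduction: ``rr_per_10 ** (delta_sbp / 10)``, hence
    multiplicative across increments and equal to ``rr_per_10`` at exactly
    10 mmHg.  A negative reduction (blood pressure increase) is outside the
    model and rejected.
    """
    if not 0.0 < rr_per_10 <= 1.0:
        raise ValueError(f"rr_per_10 must lie in (0, 1], got {rr_per_10}")
    if delta_sbp < 0:
        raise ValueError(
            "delta_sbp must be >= 0: risk under a blood-pressure increase "
            "is outside the model's scope"
        )
    return rr_per_10 ** (delta_sbp / 10.0)


def project_events(
    n_exposed: float, delta_sbp: float, params: EpiParams
) -> EventProjection:
    """Expected CVD events and deaths averted over the horizon.

    Closed-form expectation of the per-person Bernoulli model: each exposed
    person has probability ``baseline_event_risk`` of an event over the
    horizon without the intervention, scaled by ``RR(delta_sbp)`` with it.
    """
    if n_exposed < 0:
        raise ValueError("n_exposed must be >= 0")
    rr = relative_risk(delta_sbp, params.rr_per_10)
    events_control = n_exposed * params.baseline_event_risk
    events_intervention = events_control * rr
    events_averted = events_control - events_intervention
    return EventProjection(
        n_exposed=n_exposed,
        delta_sbp=delta_sbp,
        rr_applied=rr,
        events_control=events_control,
        events_intervention=events_intervention,
        events_averted=events_averted,
        deaths_averted=events_averted * params.case_fatality,
    )


def _discounted_years(duration: float, rate: float) -> float:
    # Present value of one life-year per year over `duration` years
    # (continuous-time annuity); equals `duration` at rate 0.
    if rate == 0.0:
        return duration
    import math

    return (1.0 - math.exp(-rate * duration)) / rate


def dalys_averted(projection: EventProjection, params: EpiParams) -> EventProjection:
    """Attach YLL, YLD and DALYs averted to an event projection.

    YLL = deaths averted x dead-state weight x (life expectancy - mean age);
    YLD = non-fatal events averted x disability weight x duration;
    DALYs averted = YLL + YLD (healthy life years gained).  With the default
    discount rate of 0 the year streams are undiscounted.
    """
    yll = (
        projection.deaths_averted
        * params.dw_fatal
        * _discounted_years(params.yll_per_death, params.discount_rate)
    )
    nonfatal = projection.events_averted - projection.deaths_averted
    yld = (
        nonfatal
        * params.dw_nonfatal
        * _discounted_years(params.effective_nonfatal_duration, params.discount_rate)
    )
    return projection.model_copy(
        update={"yll_averted": yll, "yld_averted": yld, "dalys_averted": yll + yld}
    )


def scale_projection(projection: EventProjection, scale_factor: float) -> EventProjection:
    """Linearly scale a projection to a larger (or smaller) population.

    All expectation-scale fields are multiplied by ``scale_factor``;
    ``delta_sbp`` and the applied relative risk are population-invariant and
    kept as-is.
    """
    if scale_factor < 0:
        raise ValueError("scale_factor must be >= 0")
    scaled = {
        field: getattr(projection, field) * scale_factor
        for field in (
            "n_exposed",
            "events_control",
            "events_intervention",
            "events_averted",
            "deaths_averted",
            "yll_averted",
            "yld_averted",
            "dalys_averted",
        )
    }
    return projection.model_copy(update=scaled)
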