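"""Time-to-event likelihood weights for incompletely followed patients.

A patient who has not yet completed the full DLT observation window
contributes to the weighted likelihood with a weight ``w`` in [0.6, 1]
reflecting elapsed follow-up.  The weight is piecewise linear in days of
post-treatment follow-up ``u``:

* ``w = 0.6`` up to the minimum follow-up of 8 weeks (56 days) — the
  earliest point at which an escalation decision may use the patient;
* rising linearly to ``0.8`` at 12 weeks (84 days), i.e. +5 percentage
  points per week, covering the acute-toxicity window;
* rising linearly to ``1.0`` at 52 weeks (364 days), i.e. +0.5 points per
  week, covering late-onset radiotherapy toxicity;
* a patient with an observed DLT always contributes with full weight 1.

The follow-up clock starts at the end of the 7-week radiotherapy course;
patients still on treatment carry the floor weight.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["WeightConfig", "FollowUpClock", "weight"]


@dataclass(frozen=True)
class WeightConfig:
    """Knots and levels of the piecewise-linear weight function.

    Times are days of follow-up counted from the end of treatment.
    """

    t1: float = 56.0
    t2: float = 84.0
    t3: float = 364.0
    w_floor: float = 0.6
    w_mid: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.t1 < self.t2 < self.t3):
            raise ValueError("knots must satisfy 0 < t1 < t2 < t3")
        if not (0.0 < self.w_floor <= self.w_mid < 1.0):
            raise ValueError("need 0 < w_floor <= w_mid < 1")


@dataclass(frozen=True)
class FollowUpClock:
    """Converts trial-time days into post-treatment follow-up days."""

    treatment_end_offset: float = 49.0  # 7 weeks of radiotherapy

    def followup_days(self, days_since_enrollment: float) -> float:
        return max(0.0, days_since_enrollment - self.treatment_end_offset)


def weight(u: float, cfg: WeightConfig = WeightConfig(), dlt: bool = False) -> float:
    """Likelihood weight of a patient with ``u`` days of post-treatment follow-up.

    ``dlt=True`` forces a full contribution of 1 regardless of follow-up.
    Raises ``ValueError`` for negative ``u``; a patient still on treatment
    should be passed ``u = 0`` (see :class:`FollowUpClock`).
    """
    if dlt:
        return 1.0
    if u < 0.0:
        raise ValueError("follow-up time must be non-negative")
    c = cfg
    if u <= c.t1:
        return c.w_floor
    if u <= c.t2:
        return c.w_floor + (c.w_mid - c.w_floor) * (u - c.t1) / (c.t2 - c.t1)
    if u <= c.t3:
        return c.w_mid + (1.0 - c.w_mid) * (u - c.t2) / (c.t3 - c.t2)
    return 1.0
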