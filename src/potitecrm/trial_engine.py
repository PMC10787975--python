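"""Two-stage trial state machine: escalation, model allocation, stopping.

Stage I walks a pre-defined escalation path in cohorts (default: dose 0,
then 1, 2a, 2b, 3) as long as no DLT has been observed.  The first observed
DLT — at any decision point, including a late-onset event from an earlier
cohort — switches the trial permanently to stage II, where each cohort is
allocated by the partial-order TITE-CRM model.

Stopping rules, checked in this order at every model-based decision:

1. *Safety*: if the posterior probability that the lowest dose's DLT rate
   exceeds 0.35 is above 0.80, and at least one full cohort (3 patients) has
   been treated at the lowest dose, the trial stops without selecting a dose.
2. *Success*: once 15 patients have been treated at a dose and the next
   allocation is that same dose again, the trial stops recruiting.
3. *Sample-size cap*: at 60 treated patients the trial stops recruiting.

Whenever recruitment ends without a safety stop, a final analysis is run on
the *fully observed* data — every patient followed to the end of the window,
so all weights are 1 and late-onset events are counted.  The target dose is
the final model recommendation, and the safety rule is applied once more to
that complete-data fit (a trial whose full data show the lowest dose to be
overly toxic ends without declaring a target dose).

Decisions are gated on the last patient of the current cohort having at
least the minimum follow-up (56 days post-treatment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .inference_engine import DecisionOutcome, ObservedData, PriorBeta, decide
from .model_core import DoseGrid, Ordering, Skeleton, build_adept_design
from .tite_weighting import WeightConfig, weight

__all__ = [
    "DesignConfig",
    "PatientRecord",
    "TrialState",
    "AdvanceOutcome",
    "default_design",
    "stage1_next_dose",
    "advance",
    "check_safety_stop",
    "check_success_stop",
    "observed_data_at",
]


@dataclass(frozen=True)
class DesignConfig:
    """Full parameterisation of the two-stage design."""

    grid: DoseGrid
    orderings: tuple[Ordering, ...]
    skeleton: Skeleton
    theta: float = 0.25
    cohort_size: int = 3
    max_n: int = 60
    start_dose: str = "0"
    stage1_path: tuple[str, ...] = ("0", "1", "2a", "2b", "3")
    success_rule_n: int = 15
    safety_threshold: float = 0.35
    safety_confidence: float = 0.80
    safety_min_patients_lowest: int = 3
    min_followup_days: float = 56.0
    treatment_days: float = 49.0
    weight_cfg: WeightConfig = field(default_factory=WeightConfig)
    prior: PriorBeta = field(default_factory=PriorBeta)
    overtox_draws: int = 10_000
    lowest_dose: str = "-1"

    def __post_init__(self) -> None:
        if self.success_rule_n % self.cohort_size != 0:
            raise ValueError("success_rule_n must be a multiple of cohort_size")
        if self.start_dose not in self.stage1_path:
            raise ValueError("start_dose must lie on the stage-1 path")
        if self.max_n < self.cohort_size:
            raise ValueError("max_n must admit at least one cohort")
        for lab in self.stage1_path + (self.lowest_dose,):
            if lab not in self.grid.labels:
                raise ValueError(f"unknown dose label {lab!r}")
        if abs(sum(o.prior_weight for o in self.orderings) - 1.0) > 1e-9:
            raise ValueError("ordering prior weights must sum to 1")


def default_design(rounded_skeleton: bool = True, **overrides) -> DesignConfig:
    """The ADePT-DDR design: 6 doses, 2 orderings, published skeleton."""
    grid, orderings, skeleton = build_adept_design(rounded=rounded_skeleton)
    return DesignConfig(grid=grid, orderings=orderings, skeleton=skeleton, **overrides)


@dataclass(frozen=True)
class PatientRecord:
    """One treated patient, in absolute trial days.

    ``dlt_day`` is the day the DLT occurs (None if never); it is only
    *observable* at a decision time t once t >= dlt_day.  Follow-up is capped
    at ``last_followup_day``.
    """

    patient_id: int
    cohort: int
    dose_label: str
    enroll_day: float
    treat_end_day: float
    dlt: bool
    dlt_day: float | None
    last_followup_day: float

    def status_at(self, t: float, cfg: WeightConfig) -> tuple[int, float]:
        """(DLT indicator, likelihood weight) as known at decision time ``t``."""
        t_eff = min(t, self.last_followup_day)
        if self.dlt and self.dlt_day is not None and self.dlt_day <= t_eff:
            return 1, 1.0
        u = min(max(t_eff - self.treat_end_day, 0.0), cfg.t3)
        return 0, weight(u, cfg)


@dataclass
class TrialState:
    """Mutable accumulated trial state."""

    design: DesignConfig
    stage: int = 1
    patients: list[PatientRecord] = field(default_factory=list)
    current_dose: str = ""
    stop_status: str | None = None  # td_found | safety_stop | max_n
    selected_dose: str | None = None
    decision_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.current_dose:
            self.current_dose = self.design.start_dose

    @property
    def n(self) -> int:
        return len(self.patients)

    def counts(self) -> dict[str, int]:
        c = {lab: 0 for lab in self.design.grid.labels}
        for p in self.patients:
            c[p.dose_label] += 1
        return c

    def add_patient(self, rec: PatientRecord) -> None:
        if self.stop_status is not None:
            raise RuntimeError("trial has stopped; no further allocation")
        if self.n >= self.design.max_n:
            raise RuntimeError("sample-size cap reached")
        self.patients.append(rec)


@dataclass(frozen=True)
class AdvanceOutcome:
    """Result of one decision point: either a next dose or a terminal status."""

    stopped: bool
    dose_label: str | None
    status: str | None
    decision: DecisionOutcome | None


def observed_data_at(state: TrialState, t: float) -> ObservedData:
    """Snapshot of (dose, DLT, weight) for every treated patient at time t."""
    cfg = state.design.weight_cfg
    idx, ys, ws = [], [], []
    for p in state.patients:
        y, w = p.status_at(t, cfg)
        idx.append(state.design.grid.index(p.dose_label))
        ys.append(y)
        ws.append(w)
    return ObservedData(tuple(idx), tuple(ys), tuple(ws))


def stage1_next_dose(state: TrialState) -> str:
    """Next dose on the stage-1 escalation path; stay at the top once there."""
    path = state.design.stage1_path
    i = path.index(state.current_dose)
    return path[min(i + 1, len(path) - 1)]


def check_safety_stop(state: TrialState, decision: DecisionOutcome) -> bool:
    """Excess toxicity at the lowest dose, gated on one cohort treated there."""
    d = state.design
    return (
        decision.overtox_prob > d.safety_confidence
        and state.counts()[d.lowest_dose] >= d.safety_min_patients_lowest
    )


def check_success_stop(state: TrialState, recommended_dose: str) -> bool:
    """Enough patients already treated at the dose the design allocates next."""
    return state.counts()[recommended_dose] >= state.design.success_rule_n


def advance(
    state: TrialState,
    decision_time: float,
    rng: np.random.Generator,
) -> AdvanceOutcome:
    """Run one decision point at ``decision_time`` and update the state.

    Recomputes every patient's weight, switches to stage II on the first
    observed DLT, applies the stopping checks (safety, success, cap, in that
    order), and otherwise returns the next cohort's dose.
    """
    d = state.design
    if state.stop_status is not None:
        raise RuntimeError("trial already stopped")
    last = state.patients[-1]
    if decision_time < last.treat_end_day + d.min_followup_days - 1e-9:
        raise RuntimeError(
            "decision before the last patient completed minimum follow-up"
        )

    data = observed_data_at(state, decision_time)
    if state.stage == 1 and any(data.y):
        state.stage = 2

    def _fit(obs):
        return decide(
            obs,
            d.orderings,
            d.skeleton,
            d.theta,
            prior=d.prior,
            rng=rng,
            lowest_dose_idx=d.grid.index(d.lowest_dose),
            safety_threshold=d.safety_threshold,
            overtox_draws=d.overtox_draws,
        )

    decision: DecisionOutcome | None = None
    if state.stage == 2:
        decision = _fit(data)
        rec_label = d.grid.labels[decision.recommended_dose]
        if check_safety_stop(state, decision):
            state.stop_status, state.selected_dose = "safety_stop", None
        elif check_success_stop(state, rec_label):
            state.stop_status = "td_found"
    else:
        rec_label = stage1_next_dose(state)
        if check_success_stop(state, rec_label):
            state.stop_status = "td_found"

    if state.stop_status is None and state.n >= d.max_n:
        state.stop_status = "max_n"

    final: DecisionOutcome | None = None
    if state.stop_status in ("td_found", "max_n"):
        # Recruitment has ended: the target dose is the model recommendation
        # on the fully observed data, with the safety rule re-applied.
        final = _fit(observed_data_at(state, math.inf))
        if check_safety_stop(state, final):
            state.stop_status, state.selected_dose = "safety_stop", None
        else:
            state.selected_dose = d.grid.labels[final.recommended_dose]

    stopped = state.stop_status is not None
    if not stopped:
        state.current_dose = rec_label

    state.decision_log.append(
        {
            "time": decision_time,
            "n": state.n,
            "stage": state.stage,
            "n_dlt_observed": int(sum(data.y)),
            "next_dose": None if stopped else rec_label,
            "status": state.stop_status,
            "selected_dose": state.selected_dose,
            "decision": decision,
            "final_decision": final,
        }
    )
    return AdvanceOutcome(
        stopped=stopped,
        dose_label=None if stopped else rec_label,
        status=state.stop_status,
        decision=final if final is not None else decision,
    )
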