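"""Positive-control gating for drug-target instruments.

Before trusting a cis-instrument set to proxy a drug, it must reproduce the
drug's established effects on control outcomes.  Every glucose-lowering
drug class should lower type-2-diabetes risk; incretin mimetics (GLP-1
receptor agonists) and SGLT2 inhibitors cause weight loss while insulin,
thiazolidinediones and sulfonylureas cause weight gain and DPP-4 inhibitors
are weight-neutral; thiazolidinediones improve insulin sensitivity; GLP-1
receptor agonists and sulfonylureas stimulate insulin secretion (fasting
proinsulin as the readout).  The gate checks sign concordance of the scaled
MR point estimate with each expectation; a class whose instruments behave
discordantly is excluded from the primary analysis.

Estimates are kept on the glucose-lowering scale (negative scale factor),
so an expected "decrease" of the control outcome means scaled OR < 1
(equivalently a negative scaled log-OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .estimators import MrResult

__all__ = ["ControlExpectation", "GateResult", "default_expectations", "evaluate_gate"]

DECREASE, INCREASE, NEUTRAL = "decrease", "increase", "neutral"


@dataclass(frozen=True)
class ControlExpectation:
    drug_class: str
    outcome: str
    direction: str  # decrease | increase | neutral

    def __post_init__(self) -> None:
        if self.direction not in (DECREASE, INCREASE, NEUTRAL):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class ConcordanceRecord:
    outcome: str
    expected: str
    observed_sign: int | None  # sign of the scaled log-OR; None = untested
    concordant: bool | None  # None for neutral expectations or untested


@dataclass
class GateResult:
    drug_class: str
    checks: list[ConcordanceRecord] = field(default_factory=list)
    passed: bool = True
    reasons: list[str] = field(default_factory=list)


def default_expectations() -> list[ControlExpectation]:
    """The built-in expectation table for the six antidiabetic drug classes."""
    weight_outcomes = ("BMI", "hip circumference", "waist circumference")
    rows: list[ControlExpectation] = []
    classes = {
        "GLP-1 receptor agonists": DECREASE,
        "SGLT2 inhibitors": DECREASE,
        "DPP-4 inhibitors": NEUTRAL,
        "Insulin and its analogues": INCREASE,
        "Thiazolidinediones": INCREASE,
        "Sulfonylureas": INCREASE,
    }
    for drug_class, weight_dir in classes.items():
        rows.append(ControlExpectation(drug_class, "T2DM", DECREASE))
        for outcome in weight_outcomes:
            rows.append(ControlExpectation(drug_class, outcome, weight_dir))
    rows.append(ControlExpectation("Thiazolidinediones", "insulin resistance", DECREASE))
    # secretagogue classes: stimulated beta-cell secretion raises the
    # fasting proinsulin readout
    rows.append(ControlExpectation("GLP-1 receptor agonists", "fasting proinsulin", INCREASE))
    rows.append(ControlExpectation("Sulfonylureas", "fasting proinsulin", INCREASE))
    return rows


def _observed_sign(res: MrResult) -> int:
    log_or = math.log(res.or_scaled) if res.or_scaled > 0 else res.scale_factor * res.theta
    if log_or > 0:
        return 1
    if log_or < 0:
        return -1
    return 0


def evaluate_gate(
    drug_class: str,
    control_results: dict[str, MrResult],
    expectations: list[ControlExpectation] | None = None,
    strict: bool = False,
    alpha: float = 0.05,
) -> GateResult:
    """Check sign concordance of control-outcome MR results with expectations.

    ``control_results`` maps control outcome name to that outcome's MR
    result for this drug class.  Outcomes without a result are recorded as
    untested, never as failures; neutral expectations never fail the gate.
    With ``strict=True`` a concordant estimate must additionally reach
    nominal significance (p < alpha) to count.
    """
    gate = GateResult(drug_class=drug_class)
    expect = [
        e for e in (expectations if expectations is not None else default_expectations())
        if e.drug_class == drug_class
    ]
    for e in sorted(expect, key=lambda e: e.outcome):
        res = control_results.get(e.outcome)
        if res is None:
            gate.checks.append(ConcordanceRecord(e.outcome, e.direction, None, None))
            continue
        sign = _observed_sign(res)
        if e.direction == NEUTRAL:
            gate.checks.append(ConcordanceRecord(e.outcome, e.direction, sign, None))
            continue
        expected_sign = -1 if e.direction == DECREASE else 1
        ok = sign == expected_sign
        if ok and strict and res.pval >= alpha:
            ok = False
        gate.checks.append(ConcordanceRecord(e.outcome, e.direction, sign, ok))
        if not ok:
            gate.passed = False
            gate.reasons.append(
                f"{e.outcome}: expected {e.direction}, observed scaled OR "
                f"{'>' if sign >= 0 else '<'} 1"
            )
    return gate
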