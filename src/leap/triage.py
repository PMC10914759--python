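"""Deterministic expected-value model of screening triage.

Compares low-dose CT (LDCT) screening at its observed real-world compliance
with a blood-test-triaged pathway in which a higher-compliance assay refers
its positives to LDCT. All quantities are expected counts in a fixed
population; no Monte-Carlo sampling. Defaults encode a population of
100,000 at-risk individuals with 0.91% lung-cancer prevalence, 3.9% LDCT
compliance versus 75% blood-test compliance, a 90%-sensitive / 82%-specific
blood assay, and the Lung-RADS LDCT operating point (84.9% sensitivity,
87.2% specificity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .stats import BinomialCI, clopper_pearson


class TriageParameterError(ValueError):
    pass


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class TriageParams:
    population: int = 100_000
    prevalence: float = 0.0091
    ldct_compliance: float = 0.039
    leap_compliance: float = 0.75
    leap_sensitivity: float = 0.90
    leap_specificity: float = 0.82
    ldct_sensitivity: float = 0.849
    ldct_specificity: float = 0.872

    def validate(self) -> "TriageParams":
        if self.population < 1:
            raise TriageParameterError("population must be >= 1")
        for name in (
            "prevalence",
            "ldct_compliance",
            "leap_compliance",
            "leap_sensitivity",
            "leap_specificity",
            "ldct_sensitivity",
            "ldct_specificity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TriageParameterError(f"{name} must lie in [0, 1]")
        return self


@dataclass
class TriageResult:
    scenario: str
    screened: float
    expected_cancers: float           # cancers among the screened
    true_positives: float             # unrounded expected TP
    false_positives: float            # unrounded expected FP
    detected: int                     # TP under the scenario's reporting rule
    ppv: float | None
    ppv_ci: BinomialCI | None = field(default=None)


def _ppv_with_ci(tp: float, fp: float):
    if tp + fp <= 0:
        return None, None
    ppv = tp / (tp + fp)
    # exact CI on the rounded confusion counts
    ci = clopper_pearson(_round_half_up(tp), _round_half_up(tp) + _round_half_up(fp))
    return ppv, ci


def simulate_ldct_only(params: TriageParams) -> TriageResult:
    """LDCT screening alone; detected count reported to the nearest integer."""
    params.validate()
    screened = params.population * params.ldct_compliance
    cancers = screened * params.prevalence
    tp = cancers * params.ldct_sensitivity
    fp = screened * (1 - params.prevalence) * (1 - params.ldct_specificity)
    ppv, ci = _ppv_with_ci(tp, fp)
    return TriageResult(
        "ldct_only", screened, cancers, tp, fp, _round_half_up(tp), ppv, ci
    )


def simulate_leap_triage(params: TriageParams) -> TriageResult:
    """Blood-test triage followed by LDCT of triage positives.

    A cancer is detected when both tests call it; a false positive must pass
    both tests falsely. Detected count is reported to the nearest ten,
    matching the precision at which such projections are stated.
    """
    params.validate()
    screened = params.population * params.leap_compliance
    cancers = screened * params.prevalence
    tp = cancers * params.leap_sensitivity * params.ldct_sensitivity
    fp = (
        screened
        * (1 - params.prevalence)
        * (1 - params.leap_specificity)
        * (1 - params.ldct_specificity)
    )
    ppv, ci = _ppv_with_ci(tp, fp)
    return TriageResult(
        "leap_triage",
        screened,
        cancers,
        tp,
        fp,
        10 * _round_half_up(tp / 10.0),
        ppv,
        ci,
    )


def fold_increase(baseline: TriageResult, triaged: TriageResult) -> int:
    """Detection fold-change, computed on unrounded expected counts."""
    if baseline.true_positives <= 0:
        raise TriageParameterError("baseline detects no cancers; fold undefined")
    return _round_half_up(triaged.true_positives / baseline.true_positives)


def triage_result_to_dict(res: TriageResult) -> dict:
    return {
        "scenario": res.scenario,
        "screened": res.screened,
        "expected_cancers": res.expected_cancers,
        "true_positives": res.true_positives,
        "false_positives": res.false_positives,
        "detected": res.detected,
        "ppv": res.ppv,
        "ppv_ci": None
        if res.ppv_ci is None
        else [res.ppv_ci.lower, res.ppv_ci.upper],
    }
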