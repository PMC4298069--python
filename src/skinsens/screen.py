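"""Screening approved drugs for skin-sensitization potential.

The drug stage runs the same discriminant behind a stricter applicability
filter: in addition to the chemical structural alerts, sulfonamide drugs
are removed because they sensitize through a distinct bioactivation route
(hydroxylamine/nitroso metabolites). Retained aniline/phenol drugs are
scored and classified at the 0.50 threshold and compared against
allergic-dermatitis adverse-event flags. Only positive-label concordance
is meaningful — adverse-event databases carry no explicit negative labels,
so no specificity is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .domain import DEFAULT_DRUG_RULES, AlertRule, DomainDecision, in_applicability_domain
from .errors import SkinsensError
from .model import LinearSensitizerModel, Prediction, classify, predict_score

__all__ = ["DrugScreenRow", "ScreenReport", "screen_drugs", "confusion_counts"]

#: A per-score discrepancy between supplied P and model(epsilon) above this
#: is flagged in the row (the supplied epsilon still wins).
P_DISCREPANCY_TOL = 1e-3


@dataclass(frozen=True)
class DrugScreenRow:
    drugbank_id: str
    name: str
    decision: DomainDecision
    prediction: Prediction | None
    adverse_event_flag: str
    exclusion_reason: str | None = None
    p_discrepancy: float | None = None


@dataclass
class ScreenReport:
    rows: list[DrugScreenRow] = field(default_factory=list)

    @property
    def screened(self) -> int:
        return len(self.rows)

    @property
    def excluded(self) -> int:
        return sum(1 for r in self.rows if r.prediction is None)

    @property
    def predicted_sensitizers(self) -> int:
        return sum(
            1
            for r in self.rows
            if r.prediction is not None
            and r.prediction.predicted_class == "sensitizer"
        )

    @property
    def agreement(self) -> int:
        return confusion_counts(self)[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            rows.append(
                {
                    "drugbank_id": r.drugbank_id,
                    "name": r.name,
                    "in_domain": r.decision.in_domain,
                    "has_aniline": r.decision.has_aniline,
                    "has_phenol": r.decision.has_phenol,
                    "exclusion_reason": r.exclusion_reason or "",
                    "p": r.prediction.p_score if r.prediction else None,
                    "predicted_class": r.prediction.predicted_class
                    if r.prediction
                    else "",
                    "adverse_event_flag": r.adverse_event_flag,
                }
            )
        return pd.DataFrame(rows)


def screen_drugs(
    table,
    model: LinearSensitizerModel,
    rules: Iterable[AlertRule] = DEFAULT_DRUG_RULES,
) -> ScreenReport:
    """Filter, score and classify a drug table.

    Each drug passes the applicability-domain check under the drug rule set;
    excluded drugs get a recorded reason and no prediction. Retained drugs
    are scored from their HOMO energy when available, else from a supplied
    precomputed P (``p_published``); when both exist the HOMO energy wins
    and a discrepancy beyond ``P_DISCREPANCY_TOL`` is flagged on the row.
    """
    rules = tuple(rules)
    report = ScreenReport()
    for drug in table:
        decision = in_applicability_domain(drug, rules)
        if not decision.in_domain:
            if decision.hits:
                reason = "alert:" + ",".join(
                    sorted({h.rule_id for h in decision.hits})
                )
            else:
                reason = "no aniline/phenol moiety"
            report.rows.append(
                DrugScreenRow(
                    drug.drugbank_id,
                    drug.name,
                    decision,
                    None,
                    drug.adverse_event_flag,
                    exclusion_reason=reason,
                )
            )
            continue
        eps = getattr(drug, "epsilon_homo", None)
        p_pre = getattr(drug, "p_published", None)
        discrepancy = None
        if eps is not None:
            p = predict_score(model, float(eps))
            if p_pre is not None and abs(p - float(p_pre)) > P_DISCREPANCY_TOL:
                discrepancy = abs(p - float(p_pre))
        elif p_pre is not None:
            p = float(p_pre)
        else:
            raise SkinsensError(
                f"drug {drug.drugbank_id!r}: neither epsilon_homo nor a "
                "precomputed P available"
            )
        prediction = Prediction(p, classify(p, model.class_threshold))
        report.rows.append(
            DrugScreenRow(
                drug.drugbank_id,
                drug.name,
                decision,
                prediction,
                drug.adverse_event_flag,
                p_discrepancy=discrepancy,
            )
        )
    return report


def confusion_counts(report: ScreenReport) -> tuple[int, int, int]:
    """(agree, disagree, unlabeled) over drugs that received a prediction.

    A reported adverse-event flag agrees with a sensitizer call; drugs with
    no report are unlabeled, never counted as negatives.
    """
    agree = disagree = unlabeled = 0
    for r in report.rows:
        if r.prediction is None:
            continue
        if r.adverse_event_flag == "reported":
            if r.prediction.predicted_class == "sensitizer":
                agree += 1
            else:
                disagree += 1
        else:
            unlabeled += 1
    return agree, disagree, unlabeled
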