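"""Relating the discriminant score to LLNA potency (EC3).

EC3 is the concentration (%) giving a three-fold lymph-node proliferation
in the murine local lymph node assay: lower EC3 means a more potent
sensitizer. Potency is analyzed on the -log10(EC3) scale, the standard
LLNA convention, against the continuous discriminant score P. The
reference data carry nine sensitizers with measured EC3; aniline is the
known outlier (its measured potency is far weaker than its score
suggests), so the correlation functions take an exclusion list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SkinsensError

__all__ = ["PotencyRecord", "neg_log_ec3", "potency_records", "potency_correlation", "potency_report"]


@dataclass(frozen=True)
class PotencyRecord:
    id: str
    ec3: float
    p_score: float

    @property
    def neg_log_ec3(self) -> float:
        return neg_log_ec3(self.ec3)


def neg_log_ec3(ec3: float) -> float:
    """-log10 of the EC3 percentage; higher means more potent."""
    if not ec3 > 0:
        raise SkinsensError(f"EC3 must be > 0, got {ec3!r}")
    return -math.log10(ec3)


def potency_records(table, model=None) -> list[PotencyRecord]:
    """Collect (id, EC3, P) for every record with a measured EC3.

    P comes from the record's published score when present, otherwise from
    ``model`` applied to its descriptors.
    """
    from .model import predict_score  # local import avoids cycle

    out = []
    for r in table:
        ec3 = getattr(r, "ec3", None)
        if ec3 is None:
            continue
        if r.p_published is not None:
            p = r.p_published
        elif model is not None and r.descriptors is not None:
            p = predict_score(model, r.descriptors)
        else:
            raise SkinsensError(f"record {r.id!r}: no score and no model")
        out.append(PotencyRecord(r.id, float(ec3), float(p)))
    return out


def potency_correlation(
    records: Sequence[PotencyRecord],
    method: str = "pearson",
    exclude: Iterable[str] = (),
) -> tuple[float, int, tuple[str, ...]]:
    """Correlation of -logEC3 with P. Returns (coefficient, n, excluded_ids)."""
    excluded = tuple(sorted(set(exclude)))
    kept = [r for r in records if r.id not in excluded]
    if len(kept) < 3:
        raise SkinsensError(f"need at least 3 records, have {len(kept)}")
    x = np.array([r.neg_log_ec3 for r in kept])
    y = np.array([r.p_score for r in kept])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SkinsensError("zero variance; correlation undefined")
    if method == "pearson":
        coef = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        coef = stats.spearmanr(x, y).statistic
    else:
        raise SkinsensError(f"unknown method {method!r}")
    return float(coef), len(kept), excluded


def _band(ec3: float) -> str:
    # usage follows the reference analysis: weak 100 > EC3 > 10, moderate <= 10
    if ec3 <= 10:
        return "moderate"
    if ec3 < 100:
        return "weak"
    return ""


def potency_report(records: Sequence[PotencyRecord]) -> pd.DataFrame:
    """Records ordered by P descending (ties by id), with potency bands."""
    if not records:
        raise SkinsensError("no potency records")
    rows = [
        {
            "id": r.id,
            "ec3": r.ec3,
            "neg_log_ec3": r.neg_log_ec3,
            "p_score": r.p_score,
            "band": _band(r.ec3),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["p_score", "id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
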