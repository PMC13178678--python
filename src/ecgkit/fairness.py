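"""Equalized-odds fairness audit over age and sex strata.

Per protected group, decisions at fixed per-label thresholds are pooled over
all labels (micro-averaging) into one confusion matrix; TPR/FPR parity is
summarized by the maximum absolute pairwise gap within each partition (for
the two sexes this is the simple difference).  Age is stratified into
under 55 / 55–75 / over 75, with both endpoints assigned to the middle bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import PredictionSet
from .metrics import BinaryRates, ThresholdTable, binary_rates

logger = logging.getLogger(__name__)

AGE_GROUPS = ("<55", "55–75", ">75")


def assign_age_groups(ages) -> pd.Series:
    """Map ages to the three audit strata.

    age < 55 -> "<55"; 55 <= age <= 75 -> "55–75"; age > 75 -> ">75".
    Negative or missing ages are excluded (NaN) with a logged count.
    """
    ages = pd.Series(np.asarray(ages, dtype=float))
    groups = pd.Series(pd.NA, index=ages.index, dtype="object")
    valid = ages.notna() & (ages >= 0)
    groups[valid & (ages < 55)] = "<55"
    groups[valid & (ages >= 55) & (ages <= 75)] = "55–75"
    groups[valid & (ages > 75)] = ">75"
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("excluded %d records with negative or missing age", n_excluded)
    return groups


@dataclass
class FairnessReport:
    """Per-group micro rates and the max-pairwise TPR/FPR gaps per partition."""

    group_table: pd.DataFrame  # partition, group, tpr, fpr, tp, fp, tn, fn, n_records
    tpr_gap: dict[str, float] = field(default_factory=dict)
    fpr_gap: dict[str, float] = field(default_factory=dict)
    excluded_groups: list[tuple[str, str, str]] = field(default_factory=list)


def _max_pairwise_gap(values: list[float]) -> float:
    values = [v for v in values if np.isfinite(v)]
    if len(values) < 2:
        return float("nan")
    return float(max(values) - min(values))


def equalized_odds_report(
    preds: PredictionSet,
    thresholds: ThresholdTable,
    groups: pd.DataFrame,
) -> FairnessReport:
    """Micro-averaged per-group TPR/FPR at fixed thresholds, with gaps.

    ``groups`` must carry columns record_id, age, sex covering every record;
    decisions use score >= threshold.  A group where TPR (or FPR) is
    undefined is flagged and excluded from that gap with a warning.
    """
    missing = set(preds.record_ids) - set(groups["record_id"].astype(str))
    if missing:
        raise ParameterError(
            f"{len(missing)} records lack group assignments, e.g. "
            f"{sorted(missing)[:3]}"
        )
    g = groups.set_index(groups["record_id"].astype(str))
    g = g.loc[preds.record_ids]
    age_group = assign_age_groups(g["age"].to_numpy()).to_numpy()
    sex = g["sex"].astype(str).to_numpy()

    thr = thresholds.as_vector(preds.label_names)
    decisions = preds.scores >= thr[None, :]

    partitions = {"age": age_group, "sex": sex}
    rows = []
    tpr_gap: dict[str, float] = {}
    fpr_gap: dict[str, float] = {}
    excluded: list[tuple[str, str, str]] = []
    for name, assignment in partitions.items():
        tprs, fprs = [], []
        for group in pd.unique(assignment[pd.notna(assignment)]):
            mask = assignment == group
            rates: BinaryRates = binary_rates(decisions[mask], preds.truths[mask])
            rows.append(
                {
                    "partition": name,
                    "group": group,
                    "tpr": rates.tpr,
                    "fpr": rates.fpr,
                    "tp": rates.tp,
                    "fp": rates.fp,
                    "tn": rates.tn,
                    "fn": rates.fn,
                    "n_records": int(mask.sum()),
                }
            )
            if rates.tpr_defined:
                tprs.append(rates.tpr)
            else:
                excluded.append((name, str(group), "tpr"))
                logger.warning("group %s/%s has no positives; excluded from TPR gap", name, group)
            if rates.fpr_defined:
                fprs.append(rates.fpr)
            else:
                excluded.append((name, str(group), "fpr"))
                logger.warning("group %s/%s has no negatives; excluded from FPR gap", name, group)
        tpr_gap[name] = _max_pairwise_gap(tprs)
        fpr_gap[name] = _max_pairwise_gap(fprs)
    table = pd.DataFrame(rows).sort_values(["partition", "group"]).reset_index(drop=True)
    return FairnessReport(table, tpr_gap, fpr_gap, excluded)
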