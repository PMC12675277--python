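"""qPCR relative expression and nonparametric group comparisons.

Relative expression of a target gene against two reference genes is the
standard delta-Ct quantity with an assumed amplification efficiency of 2:

    REL = 2^((CP_R1 + CP_R2)/2) / 2^CP = 2^((CP_R1 + CP_R2)/2 - CP)

where CP is the crossing point of the target and CP_R1, CP_R2 those of the
reference genes.  Group differences are assessed with the Kruskal-Wallis
rank test, with the usual significance classes (n.s. for P >= 0.05, * for
P < 0.05, ** for P < 0.01, *** for P < 0.001).  No multiple-testing
correction is applied; comparisons are reported individually.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .errors import ValidationError

__all__ = [
    "QpcrRecord",
    "compute_rel",
    "compute_rel_table",
    "group_compare",
    "GroupComparison",
    "significance_class",
]


@dataclass(frozen=True)
class QpcrRecord:
    """Crossing points of one sample: target gene plus two reference genes."""

    sample_id: str
    cp_target: float
    cp_ref1: float
    cp_ref2: float
    genotype: str = ""

    def __post_init__(self) -> None:
        for name in ("cp_target", "cp_ref1", "cp_ref2"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name} must be finite and > 0, got {v!r}"
                )


def compute_rel(rec: QpcrRecord) -> float:
    """Relative expression level 2^((CP_R1 + CP_R2)/2 - CP); always positive."""
    return float(2.0 ** ((rec.cp_ref1 + rec.cp_ref2) / 2.0 - rec.cp_target))


def compute_rel_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rel`` column to a crossing-point table.

    Expects columns ``sample_id, cp_target, cp_ref1, cp_ref2`` (extra columns
    such as ``genotype`` are passed through).
    """
    required = {"sample_id", "cp_target", "cp_ref1", "cp_ref2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s) {sorted(missing)}")
    out = df.copy()
    rels = [
        compute_rel(
            QpcrRecord(
                sample_id=str(r.sample_id),
                cp_target=float(r.cp_target),
                cp_ref1=float(r.cp_ref1),
                cp_ref2=float(r.cp_ref2),
            )
        )
        for r in df.itertuples()
    ]
    out["rel"] = rels
    return out


def significance_class(p: float) -> str:
    """Figure-caption star notation for a p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


class GroupComparison(NamedTuple):
    statistic: float
    pvalue: float
    significance: str


def group_compare(values: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H test across two or more groups of values."""
    if len(values) < 2:
        raise ValidationError("need at least two groups")
    groups = []
    for name, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValidationError(f"group {name!r} is empty")
        groups.append(arr)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # every observation tied: H is 0 by definition, scipy raises instead
        return GroupComparison(0.0, 1.0, "n.s.")
    stat, p = kruskal(*groups)
    return GroupComparison(float(stat), float(p), significance_class(float(p)))
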