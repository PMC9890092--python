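"""Per-taxon summed moment-arm magnitudes and opposing-action ratios.

Each joint DOF carries an opposing action pair (e.g. protraction /
retraction). A muscle contributes the magnitude of its *mean* normalized
moment arm to the column of the action matching the mean's sign; a mean of
exactly zero contributes to neither column. Sign variation within a sweep
is therefore collapsed before summation (magnitudes of means, not means of
magnitudes) -- this choice changes results and is deliberate.

Ratios are oriented positive-action / negative-action. A zero denominator
with a positive numerator is recorded as +inf and flagged; 0/0 is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .momentarms import MuscleActionSummary

GLENOHUMERAL_ACTIONS = ["protraction", "retraction", "abduction", "adduction",
                        "medial_rotation", "lateral_rotation"]
ELBOW_ACTIONS = ["extension", "flexion", "abduction", "adduction",
                 "medial_rotation", "lateral_rotation"]
DEFAULT_RATIO_PAIRS = [
    ("glenohumeral_protraction", "glenohumeral_retraction"),
    ("glenohumeral_adduction", "glenohumeral_abduction"),
    ("glenohumeral_medial_rotation", "glenohumeral_lateral_rotation"),
    ("elbow_flexion", "elbow_extension"),
    ("elbow_adduction", "elbow_abduction"),
    ("elbow_medial_rotation", "elbow_lateral_rotation"),
]


def action_columns(joints: Sequence[str] = ("glenohumeral", "elbow")) -> list[str]:
    cols = []
    for j in joints:
        actions = GLENOHUMERAL_ACTIONS if j != "elbow" else ELBOW_ACTIONS
        cols.extend(f"{j}_{a}" for a in actions)
    return cols


def classify_and_sum(summaries: Iterable[MuscleActionSummary], taxon: str) -> pd.Series:
    """One taxon's row of summed moment-arm magnitudes per named action."""
    seen = set()
    totals: dict[str, float] = {}
    for s in summaries:
        key = (s.muscle, s.joint, s.dof)
        if key in seen:
            raise ValidationError(f"duplicate summary for {key}")
        seen.add(key)
        pos, neg = s.action_pair
        for col in (f"{s.joint}_{pos}", f"{s.joint}_{neg}"):
            totals.setdefault(col, 0.0)
        if s.mean > 0:
            totals[f"{s.joint}_{pos}"] += abs(s.mean)
        elif s.mean < 0:
            totals[f"{s.joint}_{neg}"] += abs(s.mean)
        # exactly zero contributes to neither column
    row = pd.Series(totals, name=taxon, dtype=float)
    return row


@dataclass
class ActionSummaryTable:
    """Rows = taxa, columns = named joint actions (summed |mean r_norm|)."""

    data: pd.DataFrame
    ratio_flags: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: Iterable[pd.Series]) -> "ActionSummaryTable":
        df = pd.DataFrame(list(rows)).fillna(0.0)
        return cls(data=df)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def column(self, action: str) -> pd.Series:
        if action not in self.data.columns:
            raise ValidationError(f"unknown action column {action!r}")
        return self.data[action]

    def to_csv(self, path, protocol: str = "", version: str = "") -> None:
        with open(path, "w") as fh:
            fh.write(f"# ossomech action summary; protocol={protocol}; "
                     f"normalization=minimum humeral shaft circumference; "
                     f"version={version}; units=dimensionless\n")
            self.data.to_csv(fh, index_label="taxon")


def action_ratios(table: ActionSummaryTable,
                  pairs: Sequence[tuple[str, str]] = ()) -> pd.DataFrame:
    """Ratio columns positive/negative for each requested opposing pair."""
    pairs = list(pairs) or [p for p in DEFAULT_RATIO_PAIRS
                            if p[0] in table.data.columns and p[1] in table.data.columns]
    out = {}
    for pos, neg in pairs:
        if pos not in table.data.columns or neg not in table.data.columns:
            raise ValidationError(f"unknown ratio pair ({pos}, {neg})")
        num = table.data[pos].to_numpy(dtype=float)
        den = table.data[neg].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / den
        ratio = np.where((den == 0) & (num > 0), np.inf, ratio)
        ratio = np.where((den == 0) & (num == 0), np.nan, ratio)
        col = f"{pos}/{neg}"
        out[col] = pd.Series(ratio, index=table.data.index)
        for taxon, v in out[col].items():
            if np.isinf(v):
                table.ratio_flags[(taxon, col)] = "infinite (zero denominator)"
            elif np.isnan(v):
                table.ratio_flags[(taxon, col)] = "undefined (0/0)"
    return pd.DataFrame(out)
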