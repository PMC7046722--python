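"""Multi-tool pathogenicity consensus for missense variants.

Eight predictor scores per variant are thresholded with tool-specific
cutoff rules and the deleterious calls counted.  Default rules:

    SIFT         = 0        (damaging when the tolerance score is 0)
    PolyPhen-2   > 0.9
    PROVEAN      < -2.5
    I-Mutant 3.0 < -0.5     (ddG: destabilizing)
    FATHMM       |score| > 3.0
    MutPred      > 0.75
    CADD         > 20
    Condel       > 0.8

Scores are user-supplied input; no external predictor is queried.  The
SIFT equality is implemented as score <= 1e-9 since the tool emits 0.00
for fully intolerant positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_SIFT_EPS = 1e-9

_DIRECTIONS = ("eq", "gt", "lt", "abs_gt")


@dataclass(frozen=True)
class CutoffRule:
    """Deleteriousness rule for one predictor, in its native score units."""

    tool: str
    direction: str     # eq | gt | lt | abs_gt
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def flags(self, score: float) -> bool:
        if self.direction == "eq":
            return score <= self.threshold + _SIFT_EPS
        if self.direction == "gt":
            return score > self.threshold
        if self.direction == "lt":
            return score < self.threshold
        return abs(score) > self.threshold


DEFAULT_RULES: list[CutoffRule] = [
    CutoffRule("SIFT", "eq", 0.0),
    CutoffRule("PolyPhen-2", "gt", 0.9),
    CutoffRule("PROVEAN", "lt", -2.5),
    CutoffRule("I-Mutant", "lt", -0.5),
    CutoffRule("FATHMM", "abs_gt", 3.0),
    CutoffRule("MutPred", "gt", 0.75),
    CutoffRule("CADD", "gt", 20.0),
    CutoffRule("Condel", "gt", 0.8),
]


def load_rules(path: str | Path) -> list[CutoffRule]:
    """Read cutoff rules from a YAML file (list of tool/direction/threshold)."""
    data = yaml.safe_load(Path(path).read_text())
    return [CutoffRule(d["tool"], d["direction"], float(d["threshold"]))
            for d in data]


def save_rules(rules: list[CutoffRule], path: str | Path) -> None:
    payload = [{"tool": r.tool, "direction": r.direction,
                "threshold": r.threshold} for r in rules]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a variant x tool score table (wide or long CSV).

    Wide: first column ``variant``, one column per tool.  Long: columns
    ``variant, tool, score``.  Missing scores stay NaN.
    """
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["variant", "tool", "score"]:
        df.columns = cols[:3] + list(df.columns[3:])
        wide = df.pivot(index="variant", columns="tool", values="score")
        wide.columns.name = None
        return wide
    df = df.set_index(df.columns[0])
    df.index.name = "variant"
    return df.astype(float)


def classify_variant(scores: pd.Series, rules: list[CutoffRule] | None = None,
                     ) -> tuple[dict[str, bool], int, int]:
    """Per-tool deleterious flags for one variant row.

    Returns (flags, deleterious_count, n_tools_scored).  A score for a
    tool with no configured rule is a configuration error; missing (NaN)
    scores are excluded from both the count and the denominator.
    """
    if rules is None:
        rules = DEFAULT_RULES
    rule_of = {r.tool: r for r in rules}
    unknown = [t for t in scores.index if t not in rule_of]
    if unknown:
        raise ValueError(f"no cutoff rule configured for tool(s): {unknown}")
    flags: dict[str, bool] = {}
    n_scored = 0
    for tool, score in scores.items():
        if pd.isna(score):
            continue
        n_scored += 1
        flags[tool] = rule_of[tool].flags(float(score))
    return flags, sum(flags.values()), n_scored


def consensus_rank(table: pd.DataFrame, rules: list[CutoffRule] | None = None,
                   ) -> pd.DataFrame:
    """Rank variants by deleterious call count (descending, then label).

    Output columns: one boolean flag per scored tool, plus
    ``deleterious_count``, ``n_tools_scored`` and ``rank`` (1-based, ties
    share order but not rank value; ordering is deterministic).
    """
    if table.empty:
        raise ValueError("empty variant score table")
    rows = []
    for variant, scores in table.iterrows():
        flags, count, n_scored = classify_variant(scores, rules)
        row = {f"{t}_deleterious": v for t, v in flags.items()}
        row.update({"variant": variant, "deleterious_count": count,
                    "n_tools_scored": n_scored})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variant")
    out = out.sort_values(["deleterious_count", "variant"],
                          ascending=[False, True],
                          key=lambda s: s if s.name == "deleterious_count"
                          else s.astype(str))
    out["rank"] = np.arange(1, len(out) + 1)
    return out
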