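"""Assay arithmetic for single compounds and two-compound combinations.

Percent inhibition from a spectrophotometric endpoint:

    % inhibition = (A_control − A_sample) / A_control × 100

and the combination percent-improvement statistic: the relative increase of
a two-compound combination's readout over each of its single components,

    plain mode:     (combined − single) / single × 100
    magnitude mode: (|combined| − |single|) / |single| × 100

Plain mode applies to inhibition percentages; magnitude mode to docking
scores, where more-negative means stronger predicted binding and the
improvement is an increase in binding-energy magnitude. Reported values are
rounded half-away-from-zero to integers; unrounded values are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


def percent_inhibition(a_control: float, a_sample: float) -> float:
    """Percent inhibition from control/sample absorbances.

    Negative results (activation) are legitimate readouts.
    """
    if a_control <= 0:
        raise ValueError(f"control absorbance must be positive, got {a_control}")
    return (a_control - a_sample) / a_control * 100.0


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def improvement_pct(combined: float, single: float, mode: str = "plain") -> float:
    """Percent improvement of a combination over one of its single agents.

    Returns the unrounded value; use :func:`round_half_away` for report
    columns.
    """
    if mode not in ("plain", "magnitude"):
        raise ValueError(f"mode must be 'plain' or 'magnitude', got {mode!r}")
    if single == 0:
        raise ValueError("single-agent value of 0 cannot be an improvement denominator")
    if mode == "plain":
        return (combined - single) / single * 100.0
    return (abs(combined) - abs(single)) / abs(single) * 100.0


@dataclass
class SynergyTable:
    """Single-agent values, pairwise combination values, and improvements.

    ``improvements`` is keyed by (pair, reference agent) with both the raw
    and the integer-rounded percent improvement, so the reference of every
    bracket is explicit rather than positional.
    """

    singles: dict[str, float]
    combos: dict[tuple[str, str], float]
    mode: str = "plain"
    improvements: dict[tuple[tuple[str, str], str], tuple[float, int]] = field(default_factory=dict)

    def rounded_improvements(self) -> dict[tuple[tuple[str, str], str], int]:
        return {key: rounded for key, (_, rounded) in self.improvements.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pair, ref), (raw, rounded) in self.improvements.items():
            rows.append(
                {
                    "agent_a": pair[0],
                    "agent_b": pair[1],
                    "combined_value": self.combos[pair],
                    "reference_agent": ref,
                    "single_value": self.singles[ref],
                    "improvement_pct": raw,
                    "improvement_pct_rounded": rounded,
                }
            )
        return pd.DataFrame(rows)


def build_synergy_table(
    singles: dict[str, float],
    combos: dict[tuple[str, str], float],
    mode: str = "plain",
) -> SynergyTable:
    """Compute improvements of every combination against both of its agents."""
    table = SynergyTable(singles=dict(singles), combos=dict(combos), mode=mode)
    for pair, combined in table.combos.items():
        if len(pair) != 2:
            raise ValueError(f"combination key must name two agents, got {pair}")
        for agent in pair:
            if agent not in table.singles:
                raise ValueError(f"combination references unknown single agent {agent!r}")
            raw = improvement_pct(combined, table.singles[agent], mode=mode)
            table.improvements[(pair, agent)] = (raw, round_half_away(raw))
    return table


def read_singles(path) -> dict[str, float]:
    """agent,value CSV -> mapping."""
    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def read_combos(path) -> dict[tuple[str, str], float]:
    """agent_a,agent_b,value CSV -> mapping keyed by the listed pair order."""
    df = pd.read_csv(path)
    return {
        (str(row.iloc[0]), str(row.iloc[1])): float(row.iloc[2])
        for _, row in df.iterrows()
    }
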