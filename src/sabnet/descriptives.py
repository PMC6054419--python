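"""Wave-level network and behavior summary statistics for school panels.

Structural-zero actors are excluded at the waves where they are zeroed:
graduates cannot hold ties, and behavior distributions are tallied over
observed students only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel_io import SchoolPanel


class UndefinedStatisticError(ValueError):
    """The statistic's denominator is empty (e.g. no ties, no 2-paths)."""


def _wave_adj(panel: SchoolPanel, wave: int) -> np.ndarray:
    present = ~panel.structural_zero[wave]
    adj = panel.networks[wave].astype(float)
    adj[~present, :] = 0.0
    adj[:, ~present] = 0.0
    return adj


def outgoing_ties(panel: SchoolPanel, wave: int) -> int:
    """Number of directed nominations present at a wave."""
    return int(_wave_adj(panel, wave).sum())


def reciprocity_index(panel: SchoolPanel, wave: int) -> float:
    """Proportion of ties that are reciprocated."""
    adj = _wave_adj(panel, wave)
    ties = adj.sum()
    if ties == 0:
        raise UndefinedStatisticError(f"no ties at wave {wave + 1}")
    return float((adj * adj.T).sum() / ties)


def transitivity_index(panel: SchoolPanel, wave: int) -> float:
    """Proportion of 2-paths i->j->k (i != k) that are closed by i->k."""
    adj = _wave_adj(panel, wave)
    two_paths = (adj @ adj).sum() - (adj * adj.T).sum()  # drop i == k paths
    if two_paths == 0:
        raise UndefinedStatisticError(f"no 2-paths at wave {wave + 1}")
    closed = ((adj @ adj) * adj).sum()
    return float(closed / two_paths)


def jaccard_stability(panel: SchoolPanel, wave_a: int, wave_b: int) -> float:
    """Tie-set intersection over union between two consecutive waves.

    Computed over ordered pairs of actors that are non-structural-zero at
    BOTH waves, so composition change does not masquerade as tie change.
    """
    if abs(wave_a - wave_b) != 1:
        raise ValueError("Jaccard stability is defined for consecutive waves")
    joint = ~(panel.structural_zero[wave_a] | panel.structural_zero[wave_b])
    a = panel.networks[wave_a][np.ix_(joint, joint)].astype(bool)
    b = panel.networks[wave_b][np.ix_(joint, joint)].astype(bool)
    union = (a | b).sum()
    if union == 0:
        raise UndefinedStatisticError("no ties at either wave")
    return float((a & b).sum() / union)


def behavior_distribution(panel: SchoolPanel, substance: str,
                          wave: int) -> dict[int, float]:
    """Percentage of non-structural-zero actors in each ordinal category."""
    lo, hi = panel.behavior_ranges[substance]
    present = ~panel.structural_zero[wave]
    values = panel.behaviors[substance][wave][present]
    n = len(values)
    return {c: float(100.0 * (values == c).sum() / n) for c in range(lo, hi + 1)}


def limited_nomination_pct(panel: SchoolPanel, period: int) -> float:
    """Share of actors with a nonzero limited-nomination code in a period."""
    codes = panel.limited_nomination[period]
    return float(100.0 * (codes != 0).mean())


def describe_panel(panel: SchoolPanel) -> pd.DataFrame:
    """Long-format summary table mirroring the usual school-panel report."""
    rows: list[dict] = []
    for w in range(panel.n_waves):
        rows.append({"statistic": "outgoing_ties", "wave": w + 1,
                     "value": outgoing_ties(panel, w)})
        try:
            rows.append({"statistic": "reciprocity_index", "wave": w + 1,
                         "value": reciprocity_index(panel, w)})
            rows.append({"statistic": "transitivity_index", "wave": w + 1,
                         "value": transitivity_index(panel, w)})
        except UndefinedStatisticError:
            pass
        for sub in panel.behaviors:
            for cat, pct in behavior_distribution(panel, sub, w).items():
                rows.append({"statistic": f"{sub}_pct", "wave": w + 1,
                             "category": cat, "value": pct})
    for p in range(panel.n_periods):
        try:
            rows.append({"statistic": "jaccard_index", "wave": p + 1,
                         "value": jaccard_stability(panel, p, p + 1)})
        except UndefinedStatisticError:
            pass
        rows.append({"statistic": "limited_nomination_pct", "wave": p + 1,
                     "value": limited_nomination_pct(panel, p)})
    return pd.DataFrame(rows)
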