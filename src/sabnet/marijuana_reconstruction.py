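"""Reconstruction of wave-1 marijuana use from retrospective survey items.

Marijuana questions were only fielded from the second wave onward, so the
wave-1 category (pot_t1 in {0, 1, 2}) is rebuilt from four wave-2 items:

- H1TO30: age at first marijuana use (0 = never tried),
- S1:     the respondent's age at wave 1 (years),
- H1TO31: lifetime number of uses,
- H1TO32: number of uses in the past 30 days.

Decision procedure: never-triers and those whose onset age postdates wave 1
are certain zeros; among earlier-onset respondents, a zero difference between
lifetime and past-month counts is read as a reporting artifact (all use was
recent) and coded zero; otherwise the difference is averaged over the roughly
five months separating the surveys, m = (H1TO31 - H1TO32) / 5, and m < 1 maps
to non-use, 1 <= m <= 10 to light use, m > 10 to heavy use.  The two user
categories are flagged *uncertain* (use outside the five-month window can
inflate m), and a randomized sensitivity analysis reassigns them uniformly to
light/heavy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCENARIOS: tuple[str, ...] = (
    "never_tried",
    "onset_after_t1",
    "zero_diff",
    "monthly_lt1",
    "monthly_1_10",
    "monthly_gt10",
)

#: Scenarios whose assigned category is flagged uncertain.
UNCERTAIN_SCENARIOS: frozenset[str] = frozenset({"monthly_1_10", "monthly_gt10"})


class ReconstructionError(ValueError):
    pass


@dataclass
class ReconstructionRecord:
    """One respondent's items plus the reconstruction outcome."""

    H1TO30: float
    S1: float
    H1TO31: float
    H1TO32: float
    pot_t1: int | None = None
    scenario: str | None = None

    @property
    def uncertain(self) -> bool:
        return self.scenario in UNCERTAIN_SCENARIOS


def reconstruct_record(record: ReconstructionRecord
                       ) -> tuple[int, str]:
    """Apply the decision procedure to one record; returns (pot_t1, scenario).

    Boundary reading: monthly averages of exactly 1 and exactly 10 are light
    use ("between 1 and 10" inclusive); strictly above 10 is heavy use.
    Raises :class:`ReconstructionError` when past-month use exceeds lifetime
    use or any item is negative.
    """
    h30, s1, h31, h32 = (record.H1TO30, record.S1, record.H1TO31, record.H1TO32)
    for name, v in (("H1TO30", h30), ("S1", s1), ("H1TO31", h31),
                    ("H1TO32", h32)):
        if v < 0 or not np.isfinite(v):
            raise ReconstructionError(f"{name} must be nonnegative, got {v}")
    if h32 > h31:
        raise ReconstructionError(
            f"past-30-day count {h32} exceeds lifetime count {h31}")

    if h30 == 0:
        out = (0, "never_tried")
    elif h30 > s1:
        out = (0, "onset_after_t1")
    elif h31 - h32 == 0:
        out = (0, "zero_diff")
    else:
        monthly = (h31 - h32) / 5.0
        if monthly < 1.0:
            out = (0, "monthly_lt1")
        elif monthly <= 10.0:
            out = (1, "monthly_1_10")
        else:
            out = (2, "monthly_gt10")
    record.pot_t1, record.scenario = out
    return out


def reconstruct_panel(records: list[ReconstructionRecord]
                      ) -> tuple[np.ndarray, pd.DataFrame]:
    """Reconstruct every record; returns the pot_t1 column and a scenario
    frequency table (count and percent per scenario).

    Validation failures are aggregated and reported together.
    """
    values = np.empty(len(records), dtype=int)
    scenarios = []
    failures = []
    for k, rec in enumerate(records):
        try:
            values[k], scenario = reconstruct_record(rec)
            scenarios.append(scenario)
        except ReconstructionError as exc:
            failures.append(f"record {k}: {exc}")
    if failures:
        raise ReconstructionError(
            f"{len(failures)} invalid records: " + "; ".join(failures[:5]))
    counts = pd.Series(scenarios).value_counts()
    table = pd.DataFrame({
        "scenario": list(SCENARIOS),
        "count": [int(counts.get(s, 0)) for s in SCENARIOS],
    })
    table["percent"] = 100.0 * table["count"] / len(records)
    return values, table


def sensitivity_randomize(records: list[ReconstructionRecord],
                          rng: np.random.Generator,
                          n_samples: int) -> np.ndarray:
    """Randomized sensitivity analysis for the uncertain user categories.

    Returns an ``(n_samples, n_records)`` array of alternative pot_t1
    columns in which each uncertain record is independently reassigned
    uniformly to light (1) or heavy (2) use; all other records keep their
    reconstructed value.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    base = np.empty(len(records), dtype=int)
    uncertain = np.zeros(len(records), dtype=bool)
    for k, rec in enumerate(records):
        if rec.scenario is None:
            reconstruct_record(rec)
        base[k] = rec.pot_t1
        uncertain[k] = rec.uncertain
    out = np.tile(base, (n_samples, 1))
    n_unc = int(uncertain.sum())
    if n_unc:
        out[:, uncertain] = rng.integers(1, 3, size=(n_samples, n_unc))
    return out
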