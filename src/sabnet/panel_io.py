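"""Longitudinal school-panel data model and delimited-text I/O.

A :class:`SchoolPanel` holds a three-wave directed friendship network together
with three ordinal substance-use series (smoking 0-3, drinking 0-4, marijuana
0-2), actor covariates, and the bookkeeping needed for school panels of this
kind: structural zeros (actors administratively absent at a wave, e.g.
graduates) and limited-nomination codes in {-1, 0, +1} marking transitions
between the full (5 female + 5 male) and restricted (1 + 1) friend-nomination
instruments.

On disk a panel is a set of plain CSV files (one edge list per wave, one
attribute table, one behavior table) plus a small YAML metadata file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

SUBSTANCES: tuple[str, ...] = ("smoking", "drinking", "marijuana")

#: Ordinal category ranges (inclusive) for the three substances.
DEFAULT_BEHAVIOR_RANGES: dict[str, tuple[int, int]] = {
    "smoking": (0, 3),
    "drinking": (0, 4),
    "marijuana": (0, 2),
}

#: Covariates with categorical code sets (value -> allowed codes).
CATEGORICAL_COVARIATES: dict[str, tuple[int, ...]] = {
    "gender": (0, 1),
    "grade": (7, 8, 9, 10, 11, 12),
    "parental_education": (1, 2, 3, 4),
}

REAL_COVARIATES: tuple[str, ...] = (
    "depressive_symptoms",
    "parental_support",
    "parental_monitoring",
)


class PanelFormatError(ValueError):
    """A panel file could not be parsed (carries file and line number)."""


class PanelValidationError(ValueError):
    """A panel violates a structural invariant."""


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str
    actor: str | None = None
    wave: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = []
        if self.actor is not None:
            loc.append(f"actor {self.actor}")
        if self.wave is not None:
            loc.append(f"wave {self.wave + 1}")
        where = f" ({', '.join(loc)})" if loc else ""
        return f"{self.field}{where}: {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, field_name: str, message: str, actor: str | None = None,
            wave: int | None = None) -> None:
        self.issues.append(ValidationIssue(field_name, message, actor, wave))

    def raise_if_invalid(self) -> None:
        if not self.ok:
            head = "; ".join(str(i) for i in self.issues[:5])
            more = f" (+{len(self.issues) - 5} more)" if len(self.issues) > 5 else ""
            raise PanelValidationError(f"invalid panel: {head}{more}")

    def __len__(self) -> int:
        return len(self.issues)


@dataclass
class SchoolPanel:
    """Three-wave directed friendship panel with ordinal behaviors.

    Attributes
    ----------
    actor_ids:
        Opaque string identifiers; internal indexing is dense 0-based.
    networks:
        ``(waves, n, n)`` 0/1 array, ``networks[w, i, j] = 1`` iff ``i``
        nominates ``j`` at wave ``w``.  Waves are 0-based internally and
        1-based in files.
    behaviors:
        substance -> ``(waves, n)`` ordinal values.
    covariates:
        One row per actor, indexed by actor id.
    structural_zero:
        ``(waves, n)`` boolean mask; a zeroed actor can neither send nor
        receive ties at that wave.
    limited_nomination:
        ``(waves - 1, n)`` codes in {-1, 0, +1}, one per transition.
    period_spans:
        Months per period; metadata only.
    """

    actor_ids: list[str]
    networks: np.ndarray
    behaviors: dict[str, np.ndarray]
    covariates: pd.DataFrame
    structural_zero: np.ndarray
    limited_nomination: np.ndarray
    behavior_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_RANGES))
    period_spans: list[float] = field(default_factory=list)

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    @property
    def n_waves(self) -> int:
        return int(self.networks.shape[0])

    @property
    def n_periods(self) -> int:
        return self.n_waves - 1

    def index(self, actor_id: str) -> int:
        return self.actor_ids.index(actor_id)

    def active_mask(self, period: int) -> np.ndarray:
        """Actors present at both endpoint waves of a period."""
        return ~(self.structural_zero[period] | self.structural_zero[period + 1])

    def copy(self) -> "SchoolPanel":
        return SchoolPanel(
            actor_ids=list(self.actor_ids),
            networks=self.networks.copy(),
            behaviors={s: z.copy() for s, z in self.behaviors.items()},
            covariates=self.covariates.copy(),
            structural_zero=self.structural_zero.copy(),
            limited_nomination=self.limited_nomination.copy(),
            behavior_ranges=dict(self.behavior_ranges),
            period_spans=list(self.period_spans),
        )


def validate_panel(panel: SchoolPanel) -> ValidationReport:
    """Check every structural invariant; an empty report means valid."""
    report = ValidationReport()
    n = panel.n_actors
    ids = panel.actor_ids

    if panel.networks.shape != (panel.n_waves, n, n):
        report.add("networks", f"shape {panel.networks.shape} != "
                   f"({panel.n_waves}, {n}, {n})")
        return report

    for w in range(panel.n_waves):
        diag = np.flatnonzero(np.diag(panel.networks[w]))
        for i in diag:
            report.add("networks", "self-tie", actor=ids[i], wave=w)
        zeroed = np.flatnonzero(panel.structural_zero[w])
        for i in zeroed:
            if panel.networks[w, i, :].any() or panel.networks[w, :, i].any():
                report.add("structural_zero",
                           "structural-zero actor has incident ties",
                           actor=ids[i], wave=w)

    for sub, series in panel.behaviors.items():
        lo, hi = panel.behavior_ranges[sub]
        for w in range(panel.n_waves):
            bad = np.flatnonzero((series[w] < lo) | (series[w] > hi))
            for i in bad:
                report.add(f"behavior:{sub}",
                           f"value {series[w, i]} out of range {lo}–{hi}",
                           actor=ids[i], wave=w)

    bad_codes = ~np.isin(panel.limited_nomination, (-1, 0, 1))
    for p, i in zip(*np.nonzero(bad_codes)):
        report.add("limited_nomination",
                   f"code {panel.limited_nomination[p, i]} not in {{-1, 0, +1}}",
                   actor=ids[i], wave=p)

    for name, codes in CATEGORICAL_COVARIATES.items():
        if name not in panel.covariates.columns:
            continue
        vals = panel.covariates[name]
        for actor_id, v in vals.items():
            if v not in codes:
                report.add(name, f"code {v} outside {codes}", actor=str(actor_id))
    for name in REAL_COVARIATES:
        if name not in panel.covariates.columns:
            continue
        vals = panel.covariates[name].to_numpy(dtype=float)
        for i in np.flatnonzero(~np.isfinite(vals)):
            report.add(name, "non-finite score", actor=ids[i])
    return report


# ---------------------------------------------------------------------------
# Reading


def _parse_edge_file(path: Path, wave_expected: int, index: Mapping[str, int],
                     n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.int8)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != [
                "wave", "ego", "alter"]:
            raise PanelFormatError(f"{path}: expected header wave,ego,alter")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise PanelFormatError(f"{path}:{lineno}: expected 3 fields, "
                                       f"got {len(row)}")
            try:
                wave = int(row[0])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: malformed wave {row[0]!r}") from exc
            if wave != wave_expected:
                raise PanelFormatError(
                    f"{path}:{lineno}: wave {wave} in file for wave "
                    f"{wave_expected}")
            ego, alter = row[1].strip(), row[2].strip()
            if ego == alter:
                raise PanelFormatError(f"{path}:{lineno}: self-tie {ego!r}")
            try:
                i, j = index[ego], index[alter]
            except KeyError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: unknown actor id {exc.args[0]!r}") from exc
            adj[i, j] = 1
    return adj


def read_panel(edge_paths: Sequence[str | Path], attr_path: str | Path,
               behavior_path: str | Path, meta_path: str | Path) -> SchoolPanel:
    """Read and validate a panel from its CSV/YAML file set.

    ``edge_paths`` lists one edge file per wave, in wave order.  Raises
    :class:`PanelFormatError` on malformed rows (with line numbers) and
    :class:`PanelValidationError` on invariant violations.
    """
    meta = yaml.safe_load(Path(meta_path).read_text())
    ranges = {s: tuple(v) for s, v in meta.get(
        "behavior_ranges", DEFAULT_BEHAVIOR_RANGES).items()}
    period_spans = list(meta.get("period_spans", []))
    n_waves = len(edge_paths)

    attrs = pd.read_csv(attr_path, dtype={"actor_id": str}).set_index("actor_id")
    behav = pd.read_csv(behavior_path, dtype={"actor_id": str}).set_index("actor_id")
    actor_ids = [str(a) for a in attrs.index]
    if behav.index.tolist() != actor_ids:
        behav = behav.reindex(attrs.index)
        if behav.isna().any().any():
            raise PanelFormatError(
                f"{behavior_path}: actor ids do not match attribute table")
    n = len(actor_ids)
    index = {a: i for i, a in enumerate(actor_ids)}

    networks = np.stack([
        _parse_edge_file(Path(p), w + 1, index, n)
        for w, p in enumerate(edge_paths)
    ])

    behaviors: dict[str, np.ndarray] = {}
    for sub in ranges:
        cols = [f"{sub}_w{w + 1}" for w in range(n_waves)]
        missing = [c for c in cols if c not in behav.columns]
        if missing:
            raise PanelFormatError(
                f"{behavior_path}: missing columns {missing}")
        behaviors[sub] = behav[cols].to_numpy(dtype=np.int64).T

    sz_cols = [f"structural_zero_w{w + 1}" for w in range(n_waves)]
    if all(c in attrs.columns for c in sz_cols):
        structural_zero = attrs[sz_cols].to_numpy(dtype=bool).T
    else:
        structural_zero = np.zeros((n_waves, n), dtype=bool)
    ln_cols = [f"limited_nomination_p{p + 1}" for p in range(n_waves - 1)]
    if all(c in attrs.columns for c in ln_cols):
        limited = attrs[ln_cols].to_numpy(dtype=np.int8).T
    else:
        limited = np.zeros((n_waves - 1, n), dtype=np.int8)
    covariates = attrs.drop(columns=sz_cols + ln_cols, errors="ignore")

    panel = SchoolPanel(
        actor_ids=actor_ids,
        networks=networks,
        behaviors=behaviors,
        covariates=covariates,
        structural_zero=structural_zero,
        limited_nomination=limited,
        behavior_ranges=ranges,
        period_spans=period_spans,
    )
    validate_panel(panel).raise_if_invalid()
    return panel


# ---------------------------------------------------------------------------
# Writing


def write_panel(panel: SchoolPanel, directory: str | Path) -> dict[str, Path]:
    """Write a panel as the CSV/YAML file set that :func:`read_panel` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edge_paths = []
    for w in range(panel.n_waves):
        p = directory / f"edges_w{w + 1}.csv"
        with open(p, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["wave", "ego", "alter"])
            for i, j in zip(*np.nonzero(panel.networks[w])):
                writer.writerow([w + 1, panel.actor_ids[i], panel.actor_ids[j]])
        edge_paths.append(p)
    paths["edges"] = edge_paths  # type: ignore[assignment]

    attrs = panel.covariates.copy()
    for w in range(panel.n_waves):
        attrs[f"structural_zero_w{w + 1}"] = panel.structural_zero[w].astype(int)
    for p in range(panel.n_periods):
        attrs[f"limited_nomination_p{p + 1}"] = panel.limited_nomination[p]
    attr_path = directory / "attributes.csv"
    attrs.rename_axis("actor_id").to_csv(attr_path)
    paths["attributes"] = attr_path

    behav = pd.DataFrame(index=pd.Index(panel.actor_ids, name="actor_id"))
    for sub, series in panel.behaviors.items():
        for w in range(panel.n_waves):
            behav[f"{sub}_w{w + 1}"] = series[w]
    behavior_path = directory / "behaviors.csv"
    behav.to_csv(behavior_path)
    paths["behaviors"] = behavior_path

    meta_path = directory / "meta.yaml"
    meta = {
        "waves": panel.n_waves,
        "behavior_ranges": {s: list(r) for s, r in panel.behavior_ranges.items()},
        "period_spans": list(panel.period_spans),
    }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    paths["meta"] = meta_path
    return paths


def panel_paths(directory: str | Path, n_waves: int = 3) -> dict:
    """File-set layout used by :func:`write_panel`, for symmetric reading."""
    directory = Path(directory)
    return {
        "edge_paths": [directory / f"edges_w{w + 1}.csv" for w in range(n_waves)],
        "attr_path": directory / "attributes.csv",
        "behavior_path": directory / "behaviors.csv",
        "meta_path": directory / "meta.yaml",
    }


def write_results(result, path: str | Path) -> None:
    """Write an estimation or distribution result as a delimited table.

    Any result object exposing ``to_frame()`` (coefficient tables shaped
    name/beta/se/tconv, or long-format scenario x substance x category
    percentage tables) is accepted; an empty result yields a header-only file.
    """
    frame = result.to_frame()
    frame.to_csv(path, index=False)
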