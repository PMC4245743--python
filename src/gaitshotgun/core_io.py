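"""Domain containers and file I/O for gait recordings and measure tables.

Recordings are plain column-oriented delimited text (CSV/TSV) accompanied by a
YAML manifest that maps file columns onto channel roles (vertical ground
reaction force ``fz``, center-of-pressure ``cop_x``/``cop_y``, trunk
accelerations ``acc_x``/``acc_y``/``acc_z``, per-muscle EMG) and states the
sampling rate and units.  Measure tables are CSV with one row per observation
(subject x condition) and one column per measure; missing cells are empty
fields on disk and NaN in memory.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeSeries",
    "MetabolicRecord",
    "StudyDesign",
    "Recording",
    "read_recording",
    "write_recording",
    "read_measure_table",
    "write_measure_table",
    "read_design",
    "write_design",
    "get_logger",
]

# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

_LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "gaitshotgun") -> logging.Logger:
    """Package logger writing to stderr with levels info/warn/error."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


log = get_logger()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """Uniformly sampled single-channel signal.

    Sample indices are 0-based; time ``t = index / rate`` seconds.
    """

    values: np.ndarray
    rate: float
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValueError(
                f"non-finite value in channel {self.label!r} at sample {bad}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.values.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate

    def copy_with(self, values: np.ndarray, label: str | None = None,
                  units: str | None = None) -> "TimeSeries":
        return TimeSeries(
            values=np.asarray(values, dtype=float),
            rate=self.rate,
            label=self.label if label is None else label,
            units=self.units if units is None else units,
        )


@dataclass
class MetabolicRecord:
    """Breath-by-breath metabolic variables plus anthropometrics.

    Each variable (``ve`` ventilation L/min, ``vo2``/``vco2`` mL/min, ``rer``,
    ``bf`` breaths/min, ``hr`` beats/min) is a 1-d array of per-breath values
    or a scalar.  ``body_mass`` is in kg, ``walking_speed`` in m/s.
    """

    variables: dict[str, np.ndarray]
    body_mass: float | None = None
    walking_speed: float | None = None

    NONNEGATIVE = ("hr", "bf", "vo2", "vco2", "ve")

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, vals in self.variables.items():
            arr = np.atleast_1d(np.asarray(vals, dtype=float))
            if name.lower() in self.NONNEGATIVE and np.any(arr < 0):
                raise ValueError(f"metabolic variable {name!r} must be >= 0")
            clean[name.lower()] = arr
        self.variables = clean
        if self.body_mass is not None and self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.walking_speed is not None and self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")


@dataclass
class StudyDesign:
    """Observation map of a (possibly multi-group) repeated-measures study.

    ``observations`` holds one (subject, group, condition) triple per
    observation.  Every subject belongs to exactly one group and is observed
    at most once per condition.
    """

    observations: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        groups_of: dict[str, set[str]] = {}
        seen: set[tuple[str, str]] = set()
        for subj, group, cond in self.observations:
            groups_of.setdefault(subj, set()).add(group)
            key = (subj, cond)
            if key in seen:
                raise ValueError(
                    f"subject {subj!r} appears more than once in condition {cond!r}"
                )
            seen.add(key)
        for subj, gs in groups_of.items():
            if len(gs) > 1:
                raise ValueError(f"subject {subj!r} assigned to multiple groups: {sorted(gs)}")

    @property
    def subjects(self) -> list[str]:
        out: list[str] = []
        for s, _, _ in self.observations:
            if s not in out:
                out.append(s)
        return out

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for _, g, _ in self.observations:
            if g not in out:
                out.append(g)
        return out

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for _, _, c in self.observations:
            if c not in out:
                out.append(c)
        return out

    def group_of(self, subject: str) -> str:
        for s, g, _ in self.observations:
            if s == subject:
                return g
        raise KeyError(subject)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observations, columns=["subject", "group", "condition"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDesign":
        cols = {c.lower(): c for c in df.columns}
        for needed in ("subject", "condition"):
            if needed not in cols:
                raise ValueError(f"design table lacks a {needed!r} column")
        group_col = cols.get("group")
        obs = [
            (str(r[cols["subject"]]),
             str(r[group_col]) if group_col else "all",
             str(r[cols["condition"]]))
            for _, r in df.iterrows()
        ]
        return cls(obs)


@dataclass
class Recording:
    """One observation's worth of raw data: signals plus metabolic record."""

    signals: dict[str, TimeSeries] = field(default_factory=dict)
    metabolic: MetabolicRecord | None = None
    meta: dict = field(default_factory=dict)

    def channel(self, role: str) -> TimeSeries:
        try:
            return self.signals[role]
        except KeyError:
            raise KeyError(
                f"recording lacks mandatory channel {role!r}; available: "
                f"{sorted(self.signals)}"
            ) from None


# ---------------------------------------------------------------------------
# recordings on disk
# ---------------------------------------------------------------------------

def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_recording(path: str | Path, manifest: Mapping | str | Path) -> Recording:
    """Load a delimited-text recording according to a channel manifest.

    The manifest (mapping or YAML file) must provide ``rate`` (Hz) and
    ``channels``: a map from file column name to a role, either a string or a
    ``{role: ..., units: ...}`` mapping.  Unmapped columns are ignored with a
    log line.  Non-numeric cells raise with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    rate = float(manifest["rate"])
    channels: Mapping = manifest["channels"]

    df = pd.read_csv(path, sep=_delimiter_for(path))
    n_rows = len(df)

    signals: dict[str, TimeSeries] = {}
    for col in df.columns:
        if col not in channels:
            log.info("ignoring unmapped column %r in %s", col, path.name)
            continue
        spec = channels[col]
        if isinstance(spec, str):
            role, units = spec, ""
        else:
            role, units = spec["role"], spec.get("units", "")
        raw = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(raw))
        if bad.size:
            # +2: header line plus 1-based numbering of data rows on disk
            raise ValueError(
                f"non-numeric or non-finite value in column {col!r} "
                f"(role {role!r}) at data row {bad[0] + 1} of {path.name}"
            )
        ch_rate = float(spec.get("rate", rate)) if isinstance(spec, Mapping) else rate
        signals[role] = TimeSeries(values=raw, rate=ch_rate, label=role, units=units)
        if len(signals[role]) != n_rows:
            raise AssertionError("loader dropped rows")  # pragma: no cover

    metabolic = None
    if "metabolic" in manifest:
        mspec = manifest["metabolic"]
        metabolic = MetabolicRecord(
            variables={k: np.asarray(v, dtype=float) for k, v in mspec.get("variables", {}).items()},
            body_mass=mspec.get("body_mass"),
            walking_speed=mspec.get("walking_speed"),
        )
    return Recording(signals=signals, metabolic=metabolic,
                     meta={k: v for k, v in manifest.items()
                           if k not in ("channels", "metabolic")})


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording's signals as delimited text (one column per channel).

    All signal channels written to one file must share a sampling rate and
    length; the matching manifest is written alongside as ``<stem>.manifest.yaml``.
    """
    path = Path(path)
    rates = {ts.rate for ts in rec.signals.values()}
    lengths = {len(ts) for ts in rec.signals.values()}
    if len(rates) > 1 or len(lengths) > 1:
        raise ValueError("write_recording requires equal rates and lengths across channels")
    df = pd.DataFrame({role: ts.values for role, ts in rec.signals.items()})
    df.to_csv(path, index=False, sep=_delimiter_for(path), float_format="%.17g")

    manifest: dict = {
        "rate": float(next(iter(rates))),
        "channels": {
            role: {"role": role, "units": ts.units}
            for role, ts in rec.signals.items()
        },
    }
    if rec.metabolic is not None:
        manifest["metabolic"] = {
            "variables": {k: [float(x) for x in v] for k, v in rec.metabolic.variables.items()},
            "body_mass": rec.metabolic.body_mass,
            "walking_speed": rec.metabolic.walking_speed,
        }
    mpath = path.parent / (path.stem + ".manifest.yaml")
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return mpath


# ---------------------------------------------------------------------------
# measure tables and design tables on disk
# ---------------------------------------------------------------------------

def write_measure_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a MeasureTable (rows = observations, columns = measures) as CSV.

    The (subject, condition) row key is stored in leading ``subject`` and
    ``condition`` columns; missing cells become empty fields.
    """
    if table.empty:
        raise ValueError("refusing to write an empty measure table")
    out = table.reset_index() if isinstance(table.index, pd.MultiIndex) else table
    out.to_csv(Path(path), index=False, float_format="%.17g", na_rep="")


def read_measure_table(path: str | Path) -> pd.DataFrame:
    """Read a measure table written by :func:`write_measure_table`.

    If ``subject``/``condition`` columns are present they become the row
    MultiIndex, matching the in-memory layout produced by the measure layer.
    """
    df = pd.read_csv(Path(path))
    keys = [c for c in ("subject", "condition") if c in df.columns]
    if keys:
        df[keys] = df[keys].astype(str)
        df = df.set_index(keys)
    return df


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(Path(path), index=False)


def read_design(path: str | Path) -> StudyDesign:
    return StudyDesign.from_frame(pd.read_csv(Path(path), dtype=str))
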