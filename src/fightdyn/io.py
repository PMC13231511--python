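"""Domain types and file I/O for line-mounted jerk-tag capture events.

A capture event is logged by a tri-axial jerk accelerometer attached to the
fishing line: every 2 s the tag reports the mean jerk (rate of change of
acceleration, in g s^-1) along its X, Y and Z axes plus the activity vector
sum (ActVSum), the vectorial magnitude of jerk scaled to the tag range
[0, 2] g s^-1.  Traces are exchanged as plain CSV; the physical fish table
(species, fork length, girth, water temperature, blood chemistry) is a second
CSV.  Times are stored relative to hook-up: the first logged sample is t = 0.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CadenceError,
    DomainError,
    DuplicationError,
    IntegrityError,
    RangeError,
    SchemaError,
    SizeError,
    ValidationError,
)

#: Standard gravity used to convert tag units (g s^-1) to SI jerk (m s^-3).
STANDARD_GRAVITY = 9.81

#: Denominator of the fork-length/girth mass estimate (cm^3 per kg).
MASS_DENOMINATOR = 27120.0

TRACE_COLUMNS = ["fish_id", "time_s", "jerk_x", "jerk_y", "jerk_z", "actvsum"]
FISH_COLUMNS = [
    "fish_id",
    "species",
    "fork_length_cm",
    "girth_cm",
    "water_temp_c",
    "blood_ph",
    "lactate_mmol_l",
]
SPECIES = ("chinook", "coho")


def get_logger(name: str = "fightdyn", logfile: Optional[str] = None) -> logging.Logger:
    """Logger writing to stderr and, optionally, a file."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    return logger


def load_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


@dataclass
class JerkTrace:
    """One fish's tri-axial jerk + ActVSum time series.

    Parameters
    ----------
    fish_id
        Identifier shared with the fish table.
    times
        Seconds since hook-up (first sample is 0); strictly increasing and
        uniformly spaced at ``cadence``.
    jerk_x, jerk_y, jerk_z
        Per-axis jerk in g s^-1.
    actvsum
        Activity vector sum in g s^-1, bounded [0, 2].
    cadence
        Logging interval in seconds (tag default 2 s).
    """

    fish_id: str
    times: np.ndarray
    jerk_x: np.ndarray
    jerk_y: np.ndarray
    jerk_z: np.ndarray
    actvsum: np.ndarray
    cadence: float = 2.0

    def __post_init__(self) -> None:
        for name in ("times", "jerk_x", "jerk_y", "jerk_z", "actvsum"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if n < 2:
            raise SizeError(f"trace {self.fish_id!r}: need >= 2 samples, got {n}")
        for name in ("jerk_x", "jerk_y", "jerk_z", "actvsum"):
            if len(getattr(self, name)) != n:
                raise SchemaError(
                    f"trace {self.fish_id!r}: channel {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise CadenceError(f"trace {self.fish_id!r}: times not strictly increasing")
        if np.any(np.abs(steps - self.cadence) > 0.01 * self.cadence):
            raise CadenceError(
                f"trace {self.fish_id!r}: non-uniform spacing beyond 1% of the "
                f"{self.cadence}-s cadence"
            )
        bad = np.flatnonzero((self.actvsum < 0) | (self.actvsum > 2))
        if bad.size:
            raise RangeError(
                f"trace {self.fish_id!r}: actvsum outside [0, 2] at rows "
                f"{bad.tolist()}"
            )
        for name in ("times", "jerk_x", "jerk_y", "jerk_z", "actvsum"):
            if np.any(~np.isfinite(getattr(self, name))):
                raise ValidationError(f"trace {self.fish_id!r}: missing/non-finite {name}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Span covered by the logged samples, in seconds (n * cadence)."""
        return len(self) * self.cadence

    def axes(self) -> np.ndarray:
        """(n, 3) array of the X, Y, Z channels."""
        return np.column_stack([self.jerk_x, self.jerk_y, self.jerk_z])


@dataclass
class FishRecord:
    """Per-fish covariates and post-capture physiology."""

    fish_id: str
    species: str
    fork_length: float
    girth: Optional[float] = None
    body_mass: Optional[float] = None
    water_temp: Optional[float] = None
    blood_ph: Optional[float] = None
    lactate: Optional[float] = None
    fight_duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(
                f"fish {self.fish_id!r}: unknown species {self.species!r}; "
                f"expected one of {SPECIES}"
            )
        if not self.fork_length > 0:
            raise ValidationError(f"fish {self.fish_id!r}: fork_length must be > 0")
        if self.water_temp is not None and not (0 < self.water_temp < 40):
            raise ValidationError(
                f"fish {self.fish_id!r}: water_temp {self.water_temp} outside (0, 40) C"
            )
        if self.girth is not None and self.body_mass is None:
            self.body_mass = estimate_mass(self.fork_length, self.girth)
        if self.fight_duration is not None and not self.fight_duration > 0:
            raise ValidationError(f"fish {self.fish_id!r}: fight_duration must be > 0")


@dataclass
class CaptureDataset:
    """Traces and records keyed by fish id.

    ``traces`` and ``records`` must share the same key set once both are
    populated; ordination/clustering operations additionally require >= 3 fish.
    """

    traces: dict[str, JerkTrace] = field(default_factory=dict)
    records: dict[str, FishRecord] = field(default_factory=dict)

    @property
    def fish_ids(self) -> list[str]:
        return sorted(self.traces.keys() or self.records.keys())

    def validate(self) -> "CaptureDataset":
        if self.traces and self.records:
            if set(self.traces) != set(self.records):
                only_t = sorted(set(self.traces) - set(self.records))
                only_r = sorted(set(self.records) - set(self.traces))
                raise IntegrityError(
                    f"trace/record key mismatch: traces-only {only_t}, records-only {only_r}"
                )
        # Fights are timed from hook-up to netting; when the table does not
        # carry a timed duration, the logged span stands in for it.
        for fid, rec in self.records.items():
            if rec.fight_duration is None and fid in self.traces:
                rec.fight_duration = self.traces[fid].duration
        return self

    def __len__(self) -> int:
        return len(self.fish_ids)


def estimate_mass(fork_length: float, girth: float) -> float:
    """Estimate body mass (kg) from fork length and girth (cm).

    Uses the length-girth relationship mass = FL * girth^2 / 27120.
    """
    if not (fork_length > 0 and girth > 0):
        raise DomainError(
            f"fork_length and girth must be > 0, got ({fork_length}, {girth})"
        )
    return fork_length * girth**2 / MASS_DENOMINATOR


def jerk_to_si(values_g_per_s: np.ndarray) -> np.ndarray:
    """Convert tag-scale jerk (g s^-1) to SI jerk (m s^-3) via standard gravity."""
    return np.asarray(values_g_per_s, dtype=float) * STANDARD_GRAVITY


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_traces(path: str | Path, cadence: Optional[float] = None) -> CaptureDataset:
    """Read jerk traces from a CSV file or a directory of CSV files.

    Each file must have columns ``fish_id,time_s,jerk_x,jerk_y,jerk_z,actvsum``
    and may hold several fish.  Rows are sorted by time per fish; the cadence
    is inferred from the median time step unless given.  Absolute timestamps
    are shifted so the first sample of each fish is t = 0.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise SchemaError(f"no trace CSV files found under {path}")
    dataset = CaptureDataset()
    for f in files:
        df = pd.read_csv(f)
        _require_columns(df, TRACE_COLUMNS, f"trace file {f.name}")
        for col in TRACE_COLUMNS[1:]:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise SchemaError(f"trace file {f.name}: column {col} is not numeric")
        for fid, grp in df.groupby("fish_id", sort=True):
            fid = str(fid)
            if fid in dataset.traces:
                raise DuplicationError(f"fish id {fid!r} appears in more than one file")
            grp = grp.sort_values("time_s")
            t = grp["time_s"].to_numpy(dtype=float)
            bad = np.flatnonzero((grp["actvsum"].to_numpy() < 0) | (grp["actvsum"].to_numpy() > 2))
            if bad.size:
                rows = grp.index[bad].tolist()
                raise RangeError(
                    f"trace file {f.name}, fish {fid!r}: actvsum outside [0, 2] "
                    f"at row(s) {rows}"
                )
            cad = cadence if cadence is not None else float(np.median(np.diff(t)))
            dataset.traces[fid] = JerkTrace(
                fish_id=fid,
                times=t - t[0],
                jerk_x=grp["jerk_x"].to_numpy(dtype=float),
                jerk_y=grp["jerk_y"].to_numpy(dtype=float),
                jerk_z=grp["jerk_z"].to_numpy(dtype=float),
                actvsum=grp["actvsum"].to_numpy(dtype=float),
                cadence=cad,
            )
    return dataset


def read_fish_table(path: str | Path, dataset: Optional[CaptureDataset] = None) -> CaptureDataset:
    """Read the fish metadata/physiology table into FishRecords.

    Body mass is filled from the mass formula when girth is present.  An
    optional ``fight_duration_s`` column is honoured; otherwise durations are
    later taken from the logged trace span.
    """
    df = pd.read_csv(path)
    _require_columns(df, FISH_COLUMNS, f"fish table {Path(path).name}")
    dataset = dataset if dataset is not None else CaptureDataset()
    ids = df["fish_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise DuplicationError(f"duplicate fish id(s) in fish table: {dupes}")
    for _, row in df.iterrows():
        def opt(col: str) -> Optional[float]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        rec = FishRecord(
            fish_id=str(row["fish_id"]),
            species=str(row["species"]),
            fork_length=float(row["fork_length_cm"]),
            girth=opt("girth_cm"),
            water_temp=opt("water_temp_c"),
            blood_ph=opt("blood_ph"),
            lactate=opt("lactate_mmol_l"),
            fight_duration=opt("fight_duration_s"),
        )
        dataset.records[rec.fish_id] = rec
    return dataset


def write_traces(dataset: CaptureDataset, path: str | Path) -> None:
    """Write all traces to a single CSV in the canonical trace schema."""
    frames = []
    for fid in dataset.fish_ids:
        tr = dataset.traces[fid]
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": fid,
                    "time_s": tr.times,
                    "jerk_x": tr.jerk_x,
                    "jerk_y": tr.jerk_y,
                    "jerk_z": tr.jerk_z,
                    "actvsum": tr.actvsum,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fish_table(dataset: CaptureDataset, path: str | Path) -> None:
    recs = [dataset.records[fid] for fid in sorted(dataset.records)]
    pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in recs],
            "species": [r.species for r in recs],
            "fork_length_cm": [r.fork_length for r in recs],
            "girth_cm": [r.girth for r in recs],
            "water_temp_c": [r.water_temp for r in recs],
            "blood_ph": [r.blood_ph for r in recs],
            "lactate_mmol_l": [r.lactate for r in recs],
            "fight_duration_s": [r.fight_duration for r in recs],
        }
    ).to_csv(path, index=False)


def write_matrix(matrix, path: str | Path) -> None:
    """Write a labelled symmetric dissimilarity matrix as CSV.

    The matrix must be square, symmetric to 1e-9 and zero-diagonal; the
    round-trip through :func:`read_matrix` preserves values to 12 significant
    digits.
    """
    values = np.asarray(matrix.values, dtype=float)
    ids = list(matrix.ids)
    if len(ids) < 1 or values.size == 0:
        raise SizeError("cannot write an empty dissimilarity matrix (need >= 1 fish)")
    if values.shape != (len(ids), len(ids)):
        raise IntegrityError(f"matrix shape {values.shape} does not match {len(ids)} ids")
    if np.max(np.abs(values - values.T)) > 1e-9:
        raise IntegrityError("dissimilarity matrix asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(values))) > 1e-9:
        raise IntegrityError("dissimilarity matrix diagonal is not zero")
    pd.DataFrame(values, index=ids, columns=ids).to_csv(
        path, index_label="fish_id", float_format="%.17g"
    )


def read_matrix(path: str | Path, variant: tuple[str, str] | None = None):
    """Read a labelled dissimilarity matrix written by :func:`write_matrix`."""
    from .dtw import DissimilarityMatrix

    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise IntegrityError(f"matrix file {path}: row/column labels differ")
    return DissimilarityMatrix(ids=ids, values=df.to_numpy(dtype=float), variant=variant)
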