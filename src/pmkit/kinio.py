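"""Reading, validating and writing marker-trajectory data and tabular output.

The on-disk trial format is wide delimited text: one row per frame, three
columns per marker.  Two dialects are accepted:

``labeled``
    A header row of ``<label>.X,<label>.Y,<label>.Z`` triplets.
``headerless``
    No header (raw motion-capture export with time columns already
    stripped); markers receive generated labels ``m01, m02, ...``.

Missing samples are encoded as empty cells or the token ``NaN`` and are
tracked in :attr:`MarkerDataset.missing_mask`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerDataset",
    "MassModel",
    "FormatError",
    "ParseError",
    "read_trial",
    "write_trial",
    "write_table",
    "read_table",
    "build_mass_model",
]

#: Decimal format used for all text output; round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"

_NA_TOKEN = "NA"


class FormatError(ValueError):
    """Structural problem with an input file (e.g. columns not in triplets)."""


class ParseError(ValueError):
    """A body cell could not be interpreted as a number or missing value."""


@dataclass
class MarkerDataset:
    """One trial of 3D marker trajectories.

    ``data`` is a ``T x N`` float array with ``N = 3 * len(marker_labels)``
    and column order x, y, z per marker, markers in label order.
    ``missing_mask`` flags gap samples; masked entries of ``data`` carry NaN.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    marker_labels: list[str]
    data: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    units: str = "mm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.data)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def n_markers(self) -> int:
        return len(self.marker_labels)

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_frames / self.sampling_rate

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be strictly positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D array")
        T, N = self.data.shape
        if T < 2:
            raise ValueError("a trial needs at least 2 frames")
        if N != 3 * len(self.marker_labels):
            raise ValueError(
                f"data has {N} columns but {len(self.marker_labels)} marker "
                "labels (expected 3 columns per marker)"
            )
        if self.missing_mask.shape != self.data.shape:
            raise ValueError("missing_mask shape must match data shape")
        observed = self.data[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-finite values outside the missing mask")

    def has_gaps(self) -> bool:
        return bool(self.missing_mask.any())

    def marker_columns(self, label: str) -> slice:
        """Column slice (x, y, z) of one marker."""
        j = self.marker_labels.index(label)
        return slice(3 * j, 3 * j + 3)

    def copy(self, data: np.ndarray | None = None,
             missing_mask: np.ndarray | None = None) -> "MarkerDataset":
        return MarkerDataset(
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            sampling_rate=self.sampling_rate,
            marker_labels=list(self.marker_labels),
            data=self.data.copy() if data is None else np.asarray(data, float),
            missing_mask=(self.missing_mask.copy() if missing_mask is None
                          else np.asarray(missing_mask, bool)),
            units=self.units,
        )


@dataclass
class MassModel:
    """Per-marker body-mass fractions expanded to per-column weights."""

    name: str
    per_marker_mass: dict[str, float]
    column_weights: np.ndarray

    def __post_init__(self) -> None:
        self.column_weights = np.asarray(self.column_weights, dtype=float)
        if np.any(self.column_weights < 0):
            raise ValueError("mass weights must be non-negative")
        total = sum(self.per_marker_mass.values())
        if total > 1.0 + 1e-6:
            raise ValueError(
                f"per-marker mass fractions sum to {total:.4f} > 1"
            )
        w = self.column_weights
        if w.size % 3:
            raise ValueError("column_weights length must be a multiple of 3")
        trip = w.reshape(-1, 3)
        if not np.all(trip == trip[:, :1]):
            raise ValueError("x, y, z weights of each marker must be equal")

    @property
    def marker_weights(self) -> np.ndarray:
        """Length-n vector of per-marker weights (one per column triplet)."""
        return self.column_weights[::3]


def build_mass_model(spec: dict[str, float], marker_labels: list[str],
                     name: str = "custom") -> MassModel:
    """Expand a marker-label -> mass-fraction mapping to column weights.

    Markers absent from ``spec`` receive weight 0 with a logged warning.
    """
    unknown = set(spec) - set(marker_labels)
    if unknown:
        raise ValueError(f"mass spec names unknown markers: {sorted(unknown)}")
    for label, frac in spec.items():
        if frac < 0:
            raise ValueError(f"negative mass fraction for {label!r}")
    missing = [m for m in marker_labels if m not in spec]
    if missing:
        logger.warning(
            "markers %s missing from mass model %r; assigned weight 0",
            missing, name)
    weights = np.repeat([spec.get(m, 0.0) for m in marker_labels], 3)
    return MassModel(name=name, per_marker_mass=dict(spec),
                     column_weights=weights)


# ---------------------------------------------------------------------------
# trial I/O
# ---------------------------------------------------------------------------

def _parse_labeled_header(columns: list[str]) -> list[str]:
    if len(columns) % 3:
        raise FormatError(
            f"{len(columns)} data columns; expected a multiple of 3")
    labels: list[str] = []
    for j in range(0, len(columns), 3):
        trip = columns[j:j + 3]
        stems, suffixes = [], []
        for c in trip:
            stem, _, suf = c.rpartition(".")
            stems.append(stem if stem else c)
            suffixes.append(suf.upper())
        if suffixes == ["X", "Y", "Z"] and len(set(stems)) == 1:
            labels.append(stems[0])
        else:
            # header gives one bare label per triplet
            labels.append(trip[0])
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate marker labels in header")
    return labels


def read_trial(path, sampling_rate: float, dialect: str = "labeled",
               subject_id: str = "", trial_id: str = "",
               delimiter: str = ",", units: str = "mm") -> MarkerDataset:
    """Read one trial from wide delimited text.

    Parameters
    ----------
    path : path-like
        Input file.
    sampling_rate : float
        Frames per second (not stored in the text format).
    dialect : {"labeled", "headerless"}
        Whether the first row is a ``label.X,label.Y,label.Z`` header.
    """
    if dialect not in ("labeled", "headerless"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header = 0 if dialect == "labeled" else None
    df = pd.read_csv(path, header=header, delimiter=delimiter, dtype=str,
                     skip_blank_lines=True, keep_default_na=False)
    if dialect == "labeled":
        labels = _parse_labeled_header([str(c) for c in df.columns])
    else:
        if df.shape[1] % 3:
            raise FormatError(
                f"{df.shape[1]} data columns; expected a multiple of 3")
        labels = [f"m{j + 1:02d}" for j in range(df.shape[1] // 3)]

    raw = df.to_numpy(dtype=object)
    data = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (r, c), cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text == "" or text.lower() == "nan" or text == _NA_TOKEN:
            data[r, c] = np.nan
            mask[r, c] = True
            continue
        try:
            data[r, c] = float(text)
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-numeric cell {text!r} at data row {r}, "
                f"column {c}") from exc

    trial_id = trial_id or _stem(path)
    return MarkerDataset(subject_id=subject_id, trial_id=trial_id,
                         sampling_rate=sampling_rate, marker_labels=labels,
                         data=data, missing_mask=mask, units=units)


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def write_trial(trial: MarkerDataset, path, dialect: str = "labeled",
                delimiter: str = ",") -> None:
    """Write a trial as wide delimited text (inverse of :func:`read_trial`)."""
    with open(path, "w", newline="") as fh:
        if dialect == "labeled":
            header = [f"{m}.{ax}" for m in trial.marker_labels
                      for ax in ("X", "Y", "Z")]
            fh.write(delimiter.join(header) + "\n")
        for r in range(trial.n_frames):
            cells = []
            for c in range(trial.n_columns):
                if trial.missing_mask[r, c]:
                    cells.append("")
                else:
                    cells.append(_FLOAT_FMT % trial.data[r, c])
            fh.write(delimiter.join(cells) + "\n")


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_table(rows, path, delimiter: str = ",") -> None:
    """Write a table of labelled numbers as delimited text.

    ``rows`` may be a DataFrame, a single mapping, or a list of mappings.
    NaN is serialized as the explicit token ``NA``; the decimal separator is
    always ``.`` regardless of locale.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    elif isinstance(rows, dict):
        df = pd.DataFrame([rows])
    else:
        df = pd.DataFrame(list(rows))
    if df.empty:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep=delimiter, index=False, na_rep=_NA_TOKEN,
              float_format=_FLOAT_FMT)


def read_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=delimiter, na_values=[_NA_TOKEN])
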