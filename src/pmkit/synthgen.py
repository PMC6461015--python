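"""Seeded generator of synthetic multi-trial marker data with planted modes.

Trials are built as ``base_posture + sum_k a_k(t) * v_k + noise`` from
mutually orthonormal displacement modes v_k and zero-mean amplitude series
a_k(t) (sinusoids or band-limited noise), so that ground truth is available
for parameter-recovery tests.  A fixed seed makes output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinio import MarkerDataset

__all__ = [
    "SineAmplitude",
    "NoiseAmplitude",
    "PlantedModel",
    "humanoid_labels",
    "humanoid_base_posture",
    "humanoid_swap_map",
    "random_orthonormal_modes",
    "generate_trial",
    "generate_cohort",
    "generate_arc_trial",
    "generate_gappy_trial",
]


@dataclass
class SineAmplitude:
    """a(t) = amplitude * sin(2*pi*frequency*t + phase) — zero-mean over
    whole periods."""
    frequency: float
    amplitude: float
    phase: float = 0.0

    def series(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.amplitude * np.sin(2 * np.pi * self.frequency * t
                                       + self.phase)


@dataclass
class NoiseAmplitude:
    """Low-pass-filtered Gaussian noise rescaled to a target SD, demeaned."""
    sd: float
    cutoff: float | None = None  # Hz; None = white

    def series(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = rng.standard_normal(t.size)
        if self.cutoff is not None and t.size > 30:
            fs = 1.0 / (t[1] - t[0])
            sos = signal.butter(4, self.cutoff, btype="low", fs=fs,
                                output="sos")
            x = signal.sosfiltfilt(sos, x)
        x = x - x.mean()
        s = x.std()
        if s > 0:
            x = x / s * self.sd
        return x


@dataclass
class PlantedModel:
    """Ground-truth recipe for one synthetic trial family."""

    base_posture: np.ndarray
    modes: np.ndarray                 # K x N, rows orthonormal
    amplitude_specs: list
    marker_labels: list[str]
    noise_sd: float = 0.0
    sampling_rate: float = 100.0
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_posture = np.asarray(self.base_posture, dtype=float)
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(self.modes.shape[0]), atol=1e-10):
            raise ValueError("planted modes must be mutually orthonormal")
        if self.modes.shape[1] != self.base_posture.size:
            raise ValueError("mode length must match base posture length")
        if len(self.amplitude_specs) != self.modes.shape[0]:
            raise ValueError("one amplitude spec per mode required")
        if self.base_posture.size != 3 * len(self.marker_labels):
            raise ValueError("base posture must be 3 entries per marker")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.sampling_rate))


# ---------------------------------------------------------------------------
# default humanoid scaffold: 28 markers, bilaterally symmetric about x = 0
# ---------------------------------------------------------------------------

# (name stem, |x|, y, z) in mm; stems are prefixed L/R, midline markers bare.
_PAIRED = [
    ("SHO", 180, 0, 1450),   # shoulders
    ("ELB", 230, 0, 1150),   # elbows
    ("WRI", 250, 0, 900),    # wrists
    ("FIN", 255, 0, 800),    # hands
    ("ASI", 120, 60, 1000),  # anterior pelvis
    ("PSI", 60, -80, 1020),  # posterior pelvis
    ("THI", 110, 20, 750),   # thighs
    ("KNE", 100, 0, 500),    # knees
    ("TIB", 90, 10, 300),    # shanks
    ("ANK", 80, 0, 90),      # ankles
    ("HEE", 85, -60, 40),    # heels
    ("TOE", 80, 130, 30),    # toes
]
_MIDLINE = [
    ("HEAD", 0, 0, 1720),
    ("C7", 0, -50, 1500),
    ("STRN", 0, 80, 1350),
    ("SACR", 0, -90, 1010),
]


def humanoid_labels() -> list[str]:
    """28 marker labels: 12 left/right pairs plus 4 midline markers."""
    labels = []
    for stem, *_ in _PAIRED:
        labels += [f"L{stem}", f"R{stem}"]
    labels += [name for name, *_ in _MIDLINE]
    return labels


def humanoid_base_posture() -> np.ndarray:
    """Length-84 vector of the static 28-marker standing posture (mm)."""
    coords = []
    for _, ax, y, z in _PAIRED:
        coords += [[-ax, y, z], [ax, y, z]]
    for _, x, y, z in _MIDLINE:
        coords += [[x, y, z]]
    return np.asarray(coords, dtype=float).reshape(-1)


def humanoid_swap_map() -> dict[str, str]:
    """Left -> right marker pairing for mirror tests."""
    return {f"L{stem}": f"R{stem}" for stem, *_ in _PAIRED}


def random_orthonormal_modes(n_modes: int, n_columns: int,
                             seed: int = 0) -> np.ndarray:
    """Rows of a random orthonormal K x N matrix (QR of Gaussian draws)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n_columns, n_modes))
    Q, _ = np.linalg.qr(A)
    return Q.T


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_trial(model: PlantedModel, subject_id: str = "synth",
                   trial_id: str = "trial01",
                   seed: int | None = None) -> MarkerDataset:
    """One trial from the planted model; same seed gives identical output."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    T = model.n_frames
    t = np.arange(T) / model.sampling_rate
    data = np.tile(model.base_posture, (T, 1))
    for spec, mode in zip(model.amplitude_specs, model.modes):
        data += np.outer(spec.series(t, rng), mode)
    if model.noise_sd > 0:
        data += rng.normal(0.0, model.noise_sd, size=data.shape)
    return MarkerDataset(subject_id=subject_id, trial_id=trial_id,
                         sampling_rate=model.sampling_rate,
                         marker_labels=list(model.marker_labels), data=data)


def generate_cohort(model: PlantedModel, n_trials: int,
                    subject_id: str = "synth") -> list[MarkerDataset]:
    """Several trials from one model, seeds derived from the model seed."""
    return [generate_trial(model, subject_id=subject_id,
                           trial_id=f"trial{i + 1:02d}",
                           seed=model.seed + 1000 * i)
            for i in range(n_trials)]


def generate_arc_trial(radius: float = 500.0, arc_degrees: float = 120.0,
                       frames: int = 500, origin=(0.0, 0.0, 0.0),
                       z: float = 0.0, sampling_rate: float = 100.0
                       ) -> MarkerDataset:
    """A single marker sweeping a planar circular arc at constant speed.

    In Cartesian coordinates the arc needs two components; after a
    cylindrical or spherical transform about the arc's center the motion is
    one-dimensional (azimuth only).
    """
    if not 0 < arc_degrees < 360:
        raise ValueError("arc_degrees must lie in (0, 360)")
    theta = np.linspace(0.0, np.radians(arc_degrees), frames)
    pt = np.asarray(origin, dtype=float)
    data = np.column_stack([
        pt[0] + radius * np.cos(theta),
        pt[1] + radius * np.sin(theta),
        np.full(frames, pt[2] + z),
    ])
    return MarkerDataset(subject_id="synth", trial_id="arc",
                         sampling_rate=sampling_rate, marker_labels=["ARC"],
                         data=data)


def generate_gappy_trial(model: PlantedModel,
                         gap_spec: list[tuple[str, int, int]],
                         subject_id: str = "synth",
                         trial_id: str = "trial01",
                         seed: int | None = None,
                         whole_marker: bool = True) -> MarkerDataset:
    """A planted-model trial with missing-sample windows.

    ``gap_spec`` lists (marker_label, start_frame, length) windows.  With
    ``whole_marker`` the full (x, y, z) triplet is masked; otherwise only
    the x column.  Masked cells are set to NaN; generate the same model with
    the same seed via :func:`generate_trial` to keep the ground truth.
    """
    trial = generate_trial(model, subject_id=subject_id, trial_id=trial_id,
                           seed=seed)
    mask = trial.missing_mask.copy()
    for label, start, length in gap_spec:
        cols = trial.marker_columns(label)
        if start < 0 or start + length > trial.n_frames:
            raise ValueError(f"gap ({label}, {start}, {length}) out of bounds")
        if whole_marker:
            mask[start:start + length, cols] = True
        else:
            mask[start:start + length, cols.start] = True
    if np.any(mask.all(axis=0)):
        raise ValueError("gap_spec would leave a fully missing column")
    data = trial.data.copy()
    data[mask] = np.nan
    return trial.copy(data=data, missing_mask=mask)
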