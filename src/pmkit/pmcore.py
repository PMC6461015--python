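"""Posture-space fitting and projection.

Fits an orthonormal movement basis to the vertically concatenated,
preprocessed trial matrices via SVD of the (implicitly formed) covariance
matrix, projects trials onto it to obtain principal-position time-series,
differentiates them into velocities and accelerations, and reconstructs
amplified single-component marker motion for visualization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .kinio import MarkerDataset
from .preprocess import PreprocessedTrial

logger = logging.getLogger(__name__)

__all__ = [
    "AssembledMatrix",
    "PostureSpace",
    "PMTimeSeries",
    "assemble",
    "fit_posture_space",
    "project",
    "differentiate",
    "reconstruct_pm",
    "subspace_angle_deg",
]


@dataclass
class AssembledMatrix:
    """All trials stacked vertically into one (sum T_x) x N matrix."""

    matrix: np.ndarray
    trial_ids: list[str]
    trial_spans: list[tuple[int, int]]
    marker_labels: list[str]
    sampling_rate: float

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def rows_of(self, trial_id: str) -> np.ndarray:
        i = self.trial_ids.index(trial_id)
        lo, hi = self.trial_spans[i]
        return self.matrix[lo:hi]


@dataclass
class PostureSpace:
    """The fitted basis: eigenvectors, eigenvalues and their percentages.

    ``components`` is N x K with orthonormal columns PC_k sorted by
    descending eigenvalue.  ``rel_eigenvalues`` are percentages of the total
    variance over *all* min(rows-1, N) eigenvalues, independent of how many
    components were retained.  ``grand_mean`` is the residual column mean
    removed before the SVD (near zero for per-trial-centered input) and is
    subtracted again when projecting new data.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    rel_eigenvalues: np.ndarray
    grand_mean: np.ndarray
    marker_labels: list[str]
    n_rows_fit: int
    fingerprint: str = ""

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_columns(self) -> int:
        return self.components.shape[0]

    # -- persistence (plain JSON so artifacts stay text) ----------------
    def save(self, path) -> None:
        payload = {
            "components": self.components.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "rel_eigenvalues": self.rel_eigenvalues.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "marker_labels": self.marker_labels,
            "n_rows_fit": self.n_rows_fit,
            "fingerprint": self.fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PostureSpace":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            components=np.asarray(payload["components"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            rel_eigenvalues=np.asarray(payload["rel_eigenvalues"],
                                       dtype=float),
            grand_mean=np.asarray(payload["grand_mean"], dtype=float),
            marker_labels=list(payload["marker_labels"]),
            n_rows_fit=int(payload["n_rows_fit"]),
            fingerprint=payload.get("fingerprint", ""),
        )


@dataclass
class PMTimeSeries:
    """Per-trial score time-series in posture-space coordinates.

    ``PP`` holds positions (T x K); ``PV`` and ``PA`` the first and second
    time derivatives once :func:`differentiate` has been applied.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    PP: np.ndarray
    PV: np.ndarray | None = None
    PA: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.PP.shape[0]

    @property
    def n_components(self) -> int:
        return self.PP.shape[1]


# ---------------------------------------------------------------------------
# assembly and fitting
# ---------------------------------------------------------------------------

def assemble(trials: list[PreprocessedTrial]) -> AssembledMatrix:
    """Concatenate preprocessed trials vertically, recording row spans."""
    if not trials:
        raise ValueError("need at least one trial")
    first = trials[0]
    for t in trials[1:]:
        if t.n_columns != first.n_columns or \
                t.marker_labels != first.marker_labels:
            raise ValueError(
                f"trial {t.trial_id!r} does not match {first.trial_id!r} "
                "in column count or marker labels")
    spans, lo = [], 0
    for t in trials:
        spans.append((lo, lo + t.n_frames))
        lo += t.n_frames
    matrix = np.vstack([t.matrix for t in trials])
    return AssembledMatrix(
        matrix=matrix,
        trial_ids=[t.trial_id for t in trials],
        trial_spans=spans,
        marker_labels=list(first.marker_labels),
        sampling_rate=first.sampling_rate,
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude coefficient of each column positive."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def _stabilize_ties(components: np.ndarray,
                    eigenvalues: np.ndarray) -> np.ndarray:
    """Order exactly tied eigenvalues by lexicographic vector comparison."""
    out = components.copy()
    k = 0
    K = eigenvalues.size
    while k < K:
        j = k
        while j + 1 < K and eigenvalues[j + 1] == eigenvalues[k]:
            j += 1
        if j > k:
            block = out[:, k:j + 1]
            order = np.lexsort(block[::-1])
            out[:, k:j + 1] = block[:, order]
        k = j + 1
    return out


def fit_posture_space(assembled: AssembledMatrix,
                      K: int | None = None,
                      fingerprint: str = "") -> PostureSpace:
    """Fit the orthonormal movement basis by SVD of the assembled matrix.

    Any residual grand column mean is removed (and logged) before the SVD;
    eigenvalues use the sample-covariance divisor rows - 1.
    """
    M = assembled.matrix
    rows, N = M.shape
    if rows < 2:
        raise ValueError("need at least 2 rows to fit")
    if K is not None and K > N:
        raise ValueError(f"K={K} exceeds the {N} available dimensions")

    grand_mean = M.mean(axis=0)
    resid = float(np.max(np.abs(grand_mean)))
    if resid > 1e-9 * max(1.0, float(np.max(np.abs(M)))):
        logger.info("removing residual grand mean (max |mean| = %.3e)", resid)
    Mc = M - grand_mean

    _, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    ev = s ** 2 / (rows - 1)
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    rel = ev / total * 100.0 if total > 0 else np.zeros_like(ev)

    comps = _fix_signs(Vt.T)
    comps = _stabilize_ties(comps, ev)
    if K is not None:
        comps, ev_out, rel_out = comps[:, :K], ev[:K], rel[:K]
    else:
        ev_out, rel_out = ev, rel
    return PostureSpace(
        components=comps,
        eigenvalues=ev_out,
        rel_eigenvalues=rel_out,
        grand_mean=grand_mean,
        marker_labels=list(assembled.marker_labels),
        n_rows_fit=rows,
        fingerprint=fingerprint,
    )


# ---------------------------------------------------------------------------
# projection and derivatives
# ---------------------------------------------------------------------------

def project(trial: PreprocessedTrial, space: PostureSpace,
            fingerprint: str | None = None) -> PMTimeSeries:
    """Project one preprocessed trial onto the shared posture-space basis."""
    if trial.n_columns != space.n_columns:
        raise ValueError(
            f"trial has {trial.n_columns} columns, posture space expects "
            f"{space.n_columns}")
    fp = space.fingerprint
    if fp and fingerprint is not None and fingerprint != fp:
        import warnings
        warnings.warn(
            "trial preprocessing fingerprint does not match the posture "
            "space; scores may not be comparable", UserWarning, stacklevel=2)
    PP = (trial.matrix - space.grand_mean) @ space.components
    return PMTimeSeries(subject_id=trial.subject_id, trial_id=trial.trial_id,
                        sampling_rate=trial.sampling_rate, PP=PP)


def differentiate(pm: PMTimeSeries) -> PMTimeSeries:
    """Fill PV and PA by central differences (one-sided at the endpoints)."""
    if pm.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    dt = 1.0 / pm.sampling_rate
    PV = np.gradient(pm.PP, dt, axis=0)
    PA = np.gradient(PV, dt, axis=0)
    return PMTimeSeries(subject_id=pm.subject_id, trial_id=pm.trial_id,
                        sampling_rate=pm.sampling_rate, PP=pm.PP,
                        PV=PV, PA=PA)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def reconstruct_pm(space: PostureSpace, k: int, pp_track: np.ndarray,
                   amplification: float = 1.0,
                   mean_posture: np.ndarray | None = None,
                   norm_factor: float = 1.0,
                   column_weights: np.ndarray | None = None,
                   sampling_rate: float = 100.0,
                   subject_id: str = "", trial_id: str = "reconstruction"
                   ) -> MarkerDataset:
    """Marker trajectories of a single, optionally amplified component.

    Builds ``mean_posture + amplification * pp_track(t) * PC_k^T``, undoing
    the stored normalization divisor and column weights so the output lives
    in raw coordinate units — the stream a stick-figure animation consumes.

    ``mean_posture``, ``norm_factor`` and ``column_weights`` come from the
    :class:`~pmkit.preprocess.PreprocessedTrial` whose preprocessing is to
    be inverted (``center_offset``, ``norm_factor``, ``column_weights``).
    """
    if not 1 <= k <= space.n_components:
        raise ValueError(f"component index k={k} out of range")
    if amplification <= 0:
        raise ValueError("amplification must be positive")
    pp_track = np.asarray(pp_track, dtype=float).reshape(-1)
    pc = space.components[:, k - 1]
    displ = amplification * np.outer(pp_track, pc)  # normalized units
    displ = displ * norm_factor
    if column_weights is not None:
        w = np.asarray(column_weights, dtype=float)
        if np.any(w == 0):
            raise ValueError(
                "cannot invert zero column weights during reconstruction")
        displ = displ / w
    if mean_posture is None:
        mean_posture = np.zeros(space.n_columns)
    data = np.asarray(mean_posture, dtype=float) + displ
    return MarkerDataset(subject_id=subject_id, trial_id=trial_id,
                         sampling_rate=sampling_rate,
                         marker_labels=list(space.marker_labels), data=data)


# ---------------------------------------------------------------------------
# small shared utility
# ---------------------------------------------------------------------------

def subspace_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Sign-invariant angle between two unit vectors, in degrees [0, 90]."""
    dot = abs(float(np.dot(u, v)))
    dot /= (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(min(1.0, dot))))
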