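"""Basis-stability and filtering diagnostics.

Leave-one-out cross-validation of the posture-space eigenvectors (angles
between full-cohort and leave-one-trial-out components as an inclusion
criterion), Welch power-spectral-density estimation for choosing a filter
cutoff, and a cutoff-frequency sweep re-running the whole pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment

from .kinio import MarkerDataset, write_table
from .pmcore import (PMTimeSeries, assemble, differentiate,
                     fit_posture_space, project, subspace_angle_deg)
from .preprocess import PreprocessConfig, PreprocessedTrial, run_pipeline
from .pmvars import trial_metrics

__all__ = [
    "LoocvReport",
    "loocv_angles",
    "welch_psd",
    "cutoff_sweep",
]


@dataclass
class LoocvReport:
    """Angles (degrees) between full-fit and leave-one-out eigenvectors.

    ``angles`` is (X trials) x (K components); row i holds the angles when
    trial ``trial_ids[i]`` is left out.  Both aggregations across left-out
    trials (max and mean) are reported.
    """

    trial_ids: list[str]
    angles: np.ndarray
    matching: str

    @property
    def max_angle(self) -> np.ndarray:
        return self.angles.max(axis=0)

    @property
    def mean_angle(self) -> np.ndarray:
        return self.angles.mean(axis=0)

    def included(self, threshold_deg: float) -> np.ndarray:
        """Per-component inclusion flags: max angle below the threshold."""
        return self.max_angle < threshold_deg

    def to_frame(self) -> pd.DataFrame:
        K = self.angles.shape[1]
        rows = []
        for i, tid in enumerate(self.trial_ids):
            for k in range(K):
                rows.append({"left_out": tid, "component": k + 1,
                             "angle_deg": self.angles[i, k]})
        return pd.DataFrame.from_records(rows)


def loocv_angles(trials: list[PreprocessedTrial], K: int | None = None,
                 matching: str = "order") -> LoocvReport:
    """Refit the posture space with each trial left out and measure angles.

    Components are matched by rank order by default; ``matching="best"``
    pairs them by maximum absolute dot product (useful when eigenvalues are
    near-degenerate).  Angles are sign-invariant and lie in [0, 90] degrees.
    """
    if len(trials) < 3:
        raise ValueError("leave-one-out validation needs at least 3 trials")
    if matching not in ("order", "best"):
        raise ValueError(f"unknown matching mode {matching!r}")
    full = fit_posture_space(assemble(trials), K=K)
    Kc = full.n_components
    angles = np.empty((len(trials), Kc))
    for i in range(len(trials)):
        rest = trials[:i] + trials[i + 1:]
        part = fit_posture_space(assemble(rest), K=K)
        A, B = full.components, part.components[:, :Kc]
        if matching == "order":
            for k in range(Kc):
                angles[i, k] = subspace_angle_deg(A[:, k], B[:, k])
        else:
            cost = -np.abs(A.T @ B)
            rows, cols = linear_sum_assignment(cost)
            for k, j in zip(rows, cols):
                angles[i, k] = subspace_angle_deg(A[:, k], B[:, j])
    return LoocvReport(trial_ids=[t.trial_id for t in trials],
                       angles=angles, matching=matching)


# ---------------------------------------------------------------------------
# Welch PSD
# ---------------------------------------------------------------------------

def welch_psd(data, sampling_rate: float | None = None,
              segment_length: int | None = None,
              overlap: float = 0.5, window: str = "hann") -> pd.DataFrame:
    """Welch power-spectral-density estimate for a series or matrix.

    Accepts a :class:`MarkerDataset`, a :class:`PMTimeSeries` (its PP), a
    1-D series, or a 2-D (frames x columns) array.  For matrix input one
    PSD column per input column is returned plus their mean (``mean``
    column).  Defaults: segment length min(256, T // 4), 50% overlap,
    Hann window.
    """
    if isinstance(data, MarkerDataset):
        arr, fs = data.data, data.sampling_rate
    elif isinstance(data, PMTimeSeries):
        arr, fs = data.PP, data.sampling_rate
    else:
        arr = np.asarray(data, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for raw array input")
        fs = sampling_rate
    if arr.ndim == 1:
        arr = arr[:, None]
    T = arr.shape[0]
    if segment_length is None:
        segment_length = min(256, max(8, T // 4))
    if segment_length > T:
        raise ValueError(
            f"segment_length {segment_length} exceeds series length {T}")
    noverlap = int(round(segment_length * overlap))
    freqs, psd = signal.welch(arr, fs=fs, window=window,
                              nperseg=segment_length, noverlap=noverlap,
                              axis=0)
    out = pd.DataFrame(psd, columns=[f"col{j + 1}"
                                     for j in range(arr.shape[1])])
    out.insert(0, "frequency_hz", freqs)
    if arr.shape[1] > 1:
        out["mean"] = psd.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# cutoff sweep
# ---------------------------------------------------------------------------

def _run_cohort(raw_trials: list[MarkerDataset], config: PreprocessConfig,
                m: int):
    pre = [run_pipeline(t, config) for t in raw_trials]
    space = fit_posture_space(assemble(pre))
    metrics = []
    for t in pre:
        pm = differentiate(project(t, space))
        metrics.append(trial_metrics(pm, m=min(m, pm.n_components)))
    return space, metrics


def cutoff_sweep(raw_trials: list[MarkerDataset], config: PreprocessConfig,
                 cutoffs: list[float], m: int = 3,
                 out_dir=None) -> pd.DataFrame:
    """Re-run the full pipeline once per cutoff frequency.

    Returns a combined long-format table (cutoff, trial, component,
    variable, value) for stability inspection; when ``out_dir`` is given,
    per-cutoff variable tables and eigenvalue spectra are additionally
    written into cutoff-labelled subfolders.
    """
    import dataclasses
    nyq = raw_trials[0].sampling_rate / 2.0
    for c in cutoffs:
        if not 0 < c < nyq:
            raise ValueError(f"cutoff {c} Hz not below Nyquist {nyq} Hz")
    frames = []
    for c in cutoffs:
        cfg = dataclasses.replace(config, filter_cutoff=c)
        space, metrics = _run_cohort(raw_trials, cfg, m)
        for tm in metrics:
            df = tm.to_frame()
            df.insert(0, "cutoff_hz", c)
            frames.append(df)
        if out_dir is not None:
            sub = os.path.join(str(out_dir), f"cutoff_{c:g}Hz")
            os.makedirs(sub, exist_ok=True)
            spec = pd.DataFrame({
                "component": np.arange(1, space.eigenvalues.size + 1),
                "EV": space.eigenvalues,
                "rEV": space.rel_eigenvalues,
            })
            write_table(spec, os.path.join(sub, "eigenvalues.csv"))
            combined = pd.concat([tm.to_frame() for tm in metrics],
                                 ignore_index=True)
            write_table(combined, os.path.join(sub, "variables.csv"))
    result = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        write_table(result, os.path.join(str(out_dir), "sweep_combined.csv"))
    return result
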