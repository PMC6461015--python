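"""Per-trial movement-structure and movement-control variables.

Movement structure: per-component variances of the principal-position
time-series as percentages of the trial total (rVAR), the analogous
standard-deviation shares (rSTD), their cumulative versions, and the
residual variance RV_m left unexplained by the first m components.

Movement control: the number of zero-crossings N_k of the principal
acceleration (how often the net control action changes direction) and the
standard deviation sigma_k of the intervals between crossings.

All sums run over the K components actually computed; when K < N the
percentages are relative to the retained subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pmcore import PMTimeSeries
from .preprocess import DegenerateTrialError

__all__ = [
    "TrialMetrics",
    "movement_structure",
    "control_metrics",
    "count_zero_crossings",
    "zero_crossing_times",
    "summary_stats",
    "trial_metrics",
]


@dataclass
class TrialMetrics:
    """Variable table for one trial.

    Per-component arrays are indexed k = 1..K in component order.  ``N_k``
    uses NaN-free integer counts; ``sigma_k`` is NaN where fewer than three
    crossings were found.
    """

    subject_id: str
    trial_id: str
    VAR: np.ndarray
    rVAR: np.ndarray
    rSTD: np.ndarray
    CUM_rVAR: np.ndarray
    CUM_rSTD: np.ndarray
    totVAR: float
    RV_m: float
    m: int
    N_k: np.ndarray | None = None
    sigma_k: np.ndarray | None = None
    summary: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (component, variable)."""
        K = self.VAR.size
        cols = {
            "VAR": self.VAR, "rVAR": self.rVAR, "rSTD": self.rSTD,
            "CUM_rVAR": self.CUM_rVAR, "CUM_rSTD": self.CUM_rSTD,
        }
        if self.N_k is not None:
            cols["N"] = self.N_k
        if self.sigma_k is not None:
            cols["sigma"] = self.sigma_k
        records = []
        for name, arr in cols.items():
            for k in range(K):
                records.append({
                    "subject_id": self.subject_id, "trial_id": self.trial_id,
                    "component": k + 1, "variable": name,
                    "value": float(arr[k]),
                })
        records.append({"subject_id": self.subject_id,
                        "trial_id": self.trial_id, "component": 0,
                        "variable": "totVAR", "value": self.totVAR})
        records.append({"subject_id": self.subject_id,
                        "trial_id": self.trial_id, "component": self.m,
                        "variable": "RV_m", "value": self.RV_m})
        return pd.DataFrame.from_records(records)


def movement_structure(pm: PMTimeSeries, m: int = 3) -> TrialMetrics:
    """Compute the trial's variance-share variables from its PP matrix.

    Variances use the sample divisor (T - 1), matching the posture-space
    eigenvalue convention so that for a single-trial cohort rVAR_k equals
    the relative eigenvalue rEV_k exactly.
    """
    K = pm.n_components
    if not 1 <= m <= K:
        raise ValueError(f"residual-variance order m={m} out of range 1..{K}")
    VAR = np.var(pm.PP, axis=0, ddof=1)
    totVAR = float(VAR.sum())
    if totVAR <= 0:
        raise DegenerateTrialError(
            f"trial {pm.trial_id!r} has zero total variance")
    rVAR = VAR / totVAR * 100.0
    SD = np.sqrt(VAR)
    rSTD = SD / SD.sum() * 100.0
    CUM_rVAR = np.cumsum(rVAR)
    CUM_rSTD = np.cumsum(rSTD)
    RV_m = 100.0 - CUM_rVAR[m - 1]
    return TrialMetrics(subject_id=pm.subject_id, trial_id=pm.trial_id,
                        VAR=VAR, rVAR=rVAR, rSTD=rSTD, CUM_rVAR=CUM_rVAR,
                        CUM_rSTD=CUM_rSTD, totVAR=totVAR, RV_m=float(RV_m),
                        m=m)


# ---------------------------------------------------------------------------
# zero-crossing control metrics
# ---------------------------------------------------------------------------

def _crossing_list(x: np.ndarray, dt: float, interpolate: bool):
    """Times of sign changes of ``x``.

    A strict sign change between consecutive samples is one crossing; a run
    of exact zeros counts as a single crossing only when the flanking signs
    differ (a change of direction).  Crossing times are located by linear
    interpolation between the bracketing samples, or at the first sample of
    the bracketing pair when ``interpolate`` is off.
    """
    nz = np.flatnonzero(x != 0.0)
    times = []
    for a, b in zip(nz[:-1], nz[1:]):
        if np.sign(x[a]) == np.sign(x[b]):
            continue
        if interpolate:
            if b == a + 1:
                t = a + x[a] / (x[a] - x[b])
            else:
                t = 0.5 * (a + b)  # midpoint of the zero run
        else:
            t = float(a)
        times.append(t * dt)
    return times


def count_zero_crossings(x: np.ndarray) -> int:
    """Brute-force count of sign changes in a series (zeros skipped)."""
    return len(_crossing_list(np.asarray(x, float), 1.0, interpolate=False))


def zero_crossing_times(x: np.ndarray, sampling_rate: float,
                        interpolate: bool = True) -> np.ndarray:
    """Crossing instants in seconds, linearly interpolated by default."""
    return np.asarray(_crossing_list(np.asarray(x, float),
                                     1.0 / sampling_rate, interpolate))


def control_metrics(pm: PMTimeSeries, k: int,
                    interpolate: bool = True) -> tuple[int, float]:
    """(N_k, sigma_k) for component ``k`` (1-based) of the PA series.

    ``sigma_k`` is the sample (n-1) standard deviation of successive
    inter-crossing intervals in seconds; with fewer than 3 crossings it is
    undefined and returned as NaN with a warning.
    """
    if pm.PA is None:
        raise ValueError("PA not computed; call differentiate() first")
    if not 1 <= k <= pm.n_components:
        raise ValueError(f"component index k={k} out of range")
    x = pm.PA[:, k - 1]
    times = zero_crossing_times(x, pm.sampling_rate, interpolate)
    n = len(times)
    if n < 3:
        warnings.warn(
            f"component {k}: only {n} zero-crossing(s); sigma undefined",
            RuntimeWarning, stacklevel=2)
        return n, float("nan")
    intervals = np.diff(times)
    return n, float(np.std(intervals, ddof=1))


def summary_stats(pm: PMTimeSeries,
                  series: tuple[str, ...] = ("PP", "PV", "PA")
                  ) -> pd.DataFrame:
    """RMS, mean and SD per component for each requested score series.

    SD uses the sample divisor, so RMS^2 = mean^2 + SD^2 * (T-1)/T.
    """
    records = []
    for name in series:
        arr = getattr(pm, name)
        if arr is None:
            raise ValueError(f"series {name!r} not computed")
        for k in range(pm.n_components):
            col = arr[:, k]
            records.append({
                "series": name, "component": k + 1,
                "rms": float(np.sqrt(np.mean(col ** 2))),
                "mean": float(np.mean(col)),
                "sd": float(np.std(col, ddof=1)),
            })
    return pd.DataFrame.from_records(records)


def trial_metrics(pm: PMTimeSeries, m: int = 3,
                  interpolate: bool = True) -> TrialMetrics:
    """Full per-trial table: structure, control and summary descriptors."""
    metrics = movement_structure(pm, m=m)
    if pm.PA is not None:
        N = np.empty(pm.n_components, dtype=float)
        sig = np.empty(pm.n_components, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for k in range(pm.n_components):
                N[k], sig[k] = control_metrics(pm, k + 1, interpolate)
        metrics.N_k = N
        metrics.sigma_k = sig
        metrics.summary = summary_stats(pm)
    else:
        metrics.summary = summary_stats(pm, series=("PP",))
    return metrics
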