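"""Per-trial transformations applied before matrix assembly.

The pipeline order is fixed (each step optional):

    gap_fill -> mirror -> com_recenter -> transform_coordinates
             -> lowpass_filter -> center_weight_normalize

Geometric steps act on raw coordinates; statistical steps act last.  Every
applied step is echoed, with its parameters, into the provenance list of
the resulting :class:`PreprocessedTrial`.

Angle and radial columns produced by a coordinate transform carry different
units; weighting and MED normalization treat them identically (no
unit-harmonization rule is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .kinio import MarkerDataset, MassModel

__all__ = [
    "PreprocessConfig",
    "PreprocessedTrial",
    "DegenerateTrialError",
    "gap_fill",
    "mirror_trial",
    "transform_coordinates",
    "inverse_transform_coordinates",
    "lowpass_filter",
    "center_weight_normalize",
    "com_recenter",
    "run_pipeline",
]

_EPS_RADIUS = 1e-9


class DegenerateTrialError(ValueError):
    """A trial carries no usable motion for the requested operation."""


@dataclass
class PreprocessConfig:
    """Declarative description of the full per-trial preprocessing chain."""

    do_gapfill: bool = False
    gapfill_rank: int | None = None
    mirror_axis: str | None = None          # "x" | "y" | "z" | None
    mirror_swap_map: dict[str, str] = field(default_factory=dict)
    coord_system: str = "cartesian"         # "cartesian"|"spherical"|"cylindrical"
    coord_origin: str | tuple = "centroid"  # fixed point or per-frame centroid
    filter_cutoff: float | None = None      # Hz
    filter_order: int = 4
    weighting: MassModel | None = None
    normalization: str = "none"             # "none"|"med"|"height"|"range"
    subject_height: float | None = None
    range_axis: str | None = None
    com_recenter: bool = False

    def validate(self, sampling_rate: float) -> None:
        if self.filter_cutoff is not None and \
                self.filter_cutoff >= sampling_rate / 2:
            raise ValueError("filter_cutoff must be below the Nyquist rate")
        if self.normalization == "height" and \
                (self.subject_height is None or self.subject_height <= 0):
            raise ValueError("height normalization requires a positive "
                             "subject height")


@dataclass
class PreprocessedTrial:
    """A trial after the full chain: centered, optionally weighted/normalized.

    ``center_offset`` holds the subtracted column means, ``norm_factor`` the
    scalar divisor, and ``column_weights`` the applied per-column weights
    (ones when weighting was off) — everything needed to invert the linear
    part of the chain when reconstructing marker motion.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    marker_labels: list[str]
    matrix: np.ndarray
    center_offset: np.ndarray
    norm_factor: float
    column_weights: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.norm_factor <= 0:
            raise ValueError("norm_factor must be positive")
        # scale includes the removed offsets: a centered near-constant
        # column legitimately retains only rounding jitter
        scale = max(float(np.max(np.abs(self.matrix), initial=0.0)),
                    float(np.max(np.abs(self.center_offset), initial=0.0)),
                    1e-300)
        resid = np.abs(self.matrix.mean(axis=0)) / scale
        if np.any(resid > 1e-9):
            raise ValueError("matrix columns are not centered")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# gap filling
# ---------------------------------------------------------------------------

def _interpolate_gaps(column: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linear interpolation over gaps; edge gaps take the nearest sample."""
    out = column.copy()
    obs = np.flatnonzero(~mask)
    out[mask] = np.interp(np.flatnonzero(mask), obs, column[obs])
    return out


def gap_fill(trial: MarkerDataset, rank: int | None = None,
             tol: float = 1e-6, max_iter: int = 100) -> MarkerDataset:
    """Fill missing samples by iterated low-rank PCA reconstruction.

    Gaps are initialized by linear interpolation (edge gaps by the nearest
    observed value), then {center, SVD, reconstruct with the top ``rank``
    components, overwrite the missing cells} is repeated until the relative
    change of the filled values falls below ``tol`` or ``max_iter`` is
    reached.  Observed cells are never modified.

    If ``rank`` is None it is chosen as the number of components explaining
    at least 99% of the variance of the interpolated matrix.
    """
    if not trial.has_gaps():
        return trial
    mask = trial.missing_mask
    if np.any(mask.all(axis=0)):
        bad = [trial.marker_labels[c // 3]
               for c in np.flatnonzero(mask.all(axis=0))]
        raise DegenerateTrialError(
            f"fully missing column(s) for marker(s) {sorted(set(bad))}; "
            "gap cannot be recovered")

    X = trial.data.copy()
    for c in np.flatnonzero(mask.any(axis=0)):
        X[:, c] = _interpolate_gaps(X[:, c], mask[:, c])

    if rank is None:
        mu = X.mean(axis=0)
        s = np.linalg.svd(X - mu, compute_uv=False)
        ev = s ** 2
        frac = np.cumsum(ev) / ev.sum()
        rank = int(np.searchsorted(frac, 0.99) + 1)
    if rank >= min(trial.n_frames, trial.n_columns):
        raise ValueError("rank must be below min(T, N)")

    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = mu + (U[:, :rank] * s[:rank]) @ Vt[:rank]
        delta = np.abs(recon[mask] - X[mask])
        # change measured against the centered signal magnitude, not the
        # raw coordinates (which carry large static offsets)
        scale = max(float(np.max(np.abs(Xc))), 1e-30)
        X[mask] = recon[mask]
        if np.max(delta) / scale < tol:
            converged = True
            break
    if not converged:
        warnings.warn("gap_fill did not converge; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    out = trial.copy(data=X, missing_mask=np.zeros_like(mask))
    return out


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

_AXES = {"x": 0, "y": 1, "z": 2}


def mirror_trial(trial: MarkerDataset, axis: str,
                 swap_map: dict[str, str] | None = None) -> MarkerDataset:
    """Reflect the trial across the plane normal to ``axis``.

    The coordinate along ``axis`` is negated for every marker and the column
    triplets of left/right paired markers are exchanged.  Applying the same
    mirror twice is the identity.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    swap_map = dict(swap_map or {})
    for a, b in swap_map.items():
        if a not in trial.marker_labels or b not in trial.marker_labels:
            raise ValueError(f"swap pair ({a!r}, {b!r}) not among markers")

    # symmetric closure so each pair is swapped exactly once
    pairs = {}
    for a, b in swap_map.items():
        pairs[a] = b
        pairs[b] = a

    data = trial.data.copy()
    mask = trial.missing_mask.copy()
    data[:, _AXES[axis]::3] *= -1.0
    out_data = data.copy()
    out_mask = mask.copy()
    for a, b in pairs.items():
        ja = trial.marker_labels.index(a)
        jb = trial.marker_labels.index(b)
        out_data[:, 3 * ja:3 * ja + 3] = data[:, 3 * jb:3 * jb + 3]
        out_mask[:, 3 * ja:3 * ja + 3] = mask[:, 3 * jb:3 * jb + 3]
    return trial.copy(data=out_data, missing_mask=out_mask)


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def _resolve_origin(trial: MarkerDataset, origin):
    if isinstance(origin, str) and origin == "centroid":
        xyz = trial.data.reshape(trial.n_frames, trial.n_markers, 3)
        return xyz.mean(axis=1)  # per-frame centroid, (T, 3)
    pt = np.asarray(origin, dtype=float).reshape(3)
    return np.broadcast_to(pt, (trial.n_frames, 3))


def transform_coordinates(trial: MarkerDataset, system: str,
                          origin="centroid") -> MarkerDataset:
    """Replace each marker's (x, y, z) with polar coordinates about an origin.

    ``spherical`` yields (r, azimuth, elevation): azimuth in the x-y plane
    measured from +x, elevation from the x-y plane.  ``cylindrical`` yields
    (rho, azimuth, z).  Azimuth is unwrapped along time per marker so that
    downstream PCA never sees a 2*pi branch-cut jump.  Column count is
    unchanged.
    """
    if system not in ("spherical", "cylindrical"):
        raise ValueError(f"unknown coordinate system {system!r}")
    if trial.has_gaps():
        raise ValueError("fill gaps before transforming coordinates")
    org = _resolve_origin(trial, origin)
    xyz = trial.data.reshape(trial.n_frames, trial.n_markers, 3) \
        - org[:, None, :]
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    rho = np.hypot(x, y)
    out = np.empty_like(xyz)
    if system == "spherical":
        r = np.sqrt(x * x + y * y + z * z)
        _check_radius(r, trial, "spherical")
        out[..., 0] = r
        out[..., 1] = np.unwrap(np.arctan2(y, x), axis=0)
        # arctan2(z, rho) == arcsin(z/r) but stays accurate near the poles
        out[..., 2] = np.arctan2(z, rho)
    else:
        _check_radius(rho, trial, "cylindrical")
        out[..., 0] = rho
        out[..., 1] = np.unwrap(np.arctan2(y, x), axis=0)
        out[..., 2] = z
    return trial.copy(data=out.reshape(trial.n_frames, trial.n_columns))


def inverse_transform_coordinates(trial: MarkerDataset, system: str,
                                  origin=(0.0, 0.0, 0.0)) -> MarkerDataset:
    """Map (r/rho, azimuth, elevation/z) columns back to Cartesian.

    Only a fixed-point origin can be inverted (a per-frame centroid origin
    is not stored in the transformed data).
    """
    if isinstance(origin, str):
        raise ValueError("inverse transform requires a fixed origin point")
    pt = np.asarray(origin, dtype=float).reshape(3)
    cur = trial.data.reshape(trial.n_frames, trial.n_markers, 3)
    out = np.empty_like(cur)
    if system == "spherical":
        r, az, el = cur[..., 0], cur[..., 1], cur[..., 2]
        out[..., 0] = r * np.cos(el) * np.cos(az)
        out[..., 1] = r * np.cos(el) * np.sin(az)
        out[..., 2] = r * np.sin(el)
    elif system == "cylindrical":
        rho, az, z = cur[..., 0], cur[..., 1], cur[..., 2]
        out[..., 0] = rho * np.cos(az)
        out[..., 1] = rho * np.sin(az)
        out[..., 2] = z
    else:
        raise ValueError(f"unknown coordinate system {system!r}")
    out += pt
    return trial.copy(data=out.reshape(trial.n_frames, trial.n_columns))


def _check_radius(r: np.ndarray, trial: MarkerDataset, system: str) -> None:
    bad = np.argwhere(r < _EPS_RADIUS)
    if bad.size:
        frame, marker = bad[0]
        raise ValueError(
            f"{system} transform degenerate: marker "
            f"{trial.marker_labels[marker]!r} coincides with the origin at "
            f"frame {frame}")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass_filter(trial: MarkerDataset, cutoff: float,
                   order: int = 4) -> MarkerDataset:
    """Zero-phase low-pass Butterworth filter applied column-wise.

    Forward-backward application (``sosfiltfilt``) gives zero phase lag and
    exact unit DC gain; the effective attenuation is that of a filter of
    twice the design ``order``.
    """
    nyq = trial.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    if trial.has_gaps():
        raise ValueError("fill gaps before filtering")
    sos = signal.butter(order, cutoff, btype="low", fs=trial.sampling_rate,
                        output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trial.n_frames <= padlen:
        raise ValueError(
            f"trial too short for filter warm-up ({trial.n_frames} frames, "
            f"need > {padlen})")
    filtered = signal.sosfiltfilt(sos, trial.data, axis=0)
    return trial.copy(data=filtered)


# ---------------------------------------------------------------------------
# centering / weighting / normalization
# ---------------------------------------------------------------------------

def center_weight_normalize(trial: MarkerDataset,
                            config: PreprocessConfig,
                            provenance: list[dict] | None = None
                            ) -> PreprocessedTrial:
    """Center columns, apply mass weights, divide by the trial norm factor.

    Order: (1) subtract column means; (2) multiply column i by its weight
    w_i when a mass model is set; (3) compute the normalization divisor on
    the centered (and weighted) matrix and divide the whole matrix by it.

    Divisors: ``med`` — mean over frames of the Euclidean norm of the
    posture row vector; ``height`` — the subject's stature; ``range`` — the
    largest per-column peak-to-peak excursion, optionally restricted to one
    axis; ``none`` — 1.
    """
    if trial.has_gaps():
        raise ValueError("fill gaps before center_weight_normalize")
    config.validate(trial.sampling_rate)

    center_offset = trial.data.mean(axis=0)
    M = trial.data - center_offset

    if config.weighting is not None:
        w = np.asarray(config.weighting.column_weights, dtype=float)
        if w.size != trial.n_columns:
            raise ValueError(
                f"mass model has {w.size} column weights, trial has "
                f"{trial.n_columns} columns")
        M = M * w
    else:
        w = np.ones(trial.n_columns)

    norm = config.normalization.lower()
    if norm == "none":
        d_norm = 1.0
    elif norm == "med":
        d_norm = float(np.mean(np.linalg.norm(M, axis=1)))
        if d_norm <= 0:
            raise DegenerateTrialError(
                f"trial {trial.trial_id!r} is motionless; MED divisor is 0")
    elif norm == "height":
        d_norm = float(config.subject_height)
    elif norm == "range":
        if config.range_axis is None:
            cols = M
        else:
            cols = M[:, _AXES[config.range_axis]::3]
        d_norm = float(np.max(np.ptp(cols, axis=0)))
        if d_norm <= 0:
            raise DegenerateTrialError(
                f"trial {trial.trial_id!r} is motionless; range divisor is 0")
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")

    prov = list(provenance or [])
    prov.append({"step": "center_weight_normalize",
                 "weighting": None if config.weighting is None
                 else config.weighting.name,
                 "normalization": norm, "d_norm": d_norm})
    return PreprocessedTrial(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        sampling_rate=trial.sampling_rate,
        marker_labels=list(trial.marker_labels),
        matrix=M / d_norm,
        center_offset=center_offset,
        norm_factor=d_norm,
        column_weights=w,
        provenance=prov,
    )


def com_recenter(trial: MarkerDataset, mass: MassModel) -> MarkerDataset:
    """Subtract the mass-weighted mean marker position from every frame.

    Removes whole-body displacement so that it is not represented as a
    movement component.
    """
    mw = mass.marker_weights
    if mw.size != trial.n_markers:
        raise ValueError("mass model does not match trial markers")
    total = mw.sum()
    if total <= 0:
        raise ValueError("mass weights must sum to a positive total")
    xyz = trial.data.reshape(trial.n_frames, trial.n_markers, 3)
    com = (xyz * mw[None, :, None]).sum(axis=1) / total
    out = xyz - com[:, None, :]
    return trial.copy(data=out.reshape(trial.n_frames, trial.n_columns))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(trial: MarkerDataset,
                 config: PreprocessConfig) -> PreprocessedTrial:
    """Apply the full, fixed-order preprocessing chain to one trial."""
    config.validate(trial.sampling_rate)
    prov: list[dict] = []
    cur = trial
    if config.do_gapfill and cur.has_gaps():
        cur = gap_fill(cur, rank=config.gapfill_rank)
        prov.append({"step": "gap_fill", "rank": config.gapfill_rank})
    if cur.has_gaps():
        raise ValueError(
            f"trial {trial.trial_id!r} still has gaps; enable gap filling")
    if config.mirror_axis is not None:
        cur = mirror_trial(cur, config.mirror_axis, config.mirror_swap_map)
        prov.append({"step": "mirror", "axis": config.mirror_axis})
    if config.com_recenter:
        if config.weighting is None:
            raise ValueError("com_recenter requires a mass model")
        cur = com_recenter(cur, config.weighting)
        prov.append({"step": "com_recenter",
                     "mass_model": config.weighting.name})
    if config.coord_system != "cartesian":
        cur = transform_coordinates(cur, config.coord_system,
                                    config.coord_origin)
        prov.append({"step": "transform_coordinates",
                     "system": config.coord_system,
                     "origin": str(config.coord_origin)})
    if config.filter_cutoff is not None:
        cur = lowpass_filter(cur, config.filter_cutoff, config.filter_order)
        prov.append({"step": "lowpass_filter",
                     "cutoff_hz": config.filter_cutoff,
                     "order": config.filter_order})
    return center_weight_normalize(cur, config, provenance=prov)
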