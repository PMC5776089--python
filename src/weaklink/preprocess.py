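"""Denoising and condition segmentation of ROI time series.

Fixed pipeline order: ROI extraction → zero-phase bandpass (0.008–0.09 Hz)
→ nuisance regression (motion, tissue signals and their temporal
derivatives) → per-condition segmentation of task volumes after a
hemodynamic shift.  Every applied step is recorded in the output's
provenance list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .design import DesignParadigm
from .roster import RoiDefinition
from .synthetic import SubjectTimeSeries

__all__ = [
    "CleanSeries",
    "extract_roi_series",
    "bandpass",
    "regress_confounds",
    "select_condition_volumes",
    "preprocess_subject",
]


@dataclass(frozen=True)
class CleanSeries:
    """Denoised, condition-segmented node time series."""

    values: np.ndarray  # T' x N
    tr_s: float
    condition: str | None = None
    node_names: tuple[str, ...] | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def with_step(self, values: np.ndarray, step: str, **kw) -> "CleanSeries":
        from dataclasses import replace

        return replace(self, values=values, provenance=self.provenance + (step,), **kw)


def extract_roi_series(volume4d, roster: list[RoiDefinition]) -> np.ndarray:
    """Mean time course over the voxels of each ROI sphere (inclusive boundary).

    `volume4d` is a nibabel spatial image (or a path to one) with a valid
    voxel→mm affine; returns a T × N matrix in roster order.
    """
    import nibabel as nib

    img = nib.load(volume4d) if isinstance(volume4d, (str, bytes)) or hasattr(
        volume4d, "__fspath__"
    ) else volume4d
    data = np.asarray(img.dataobj)
    affine = img.affine
    shape = data.shape[:3]
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    mm = grid @ affine[:3, :3].T + affine[:3, 3]
    flat = data.reshape(-1, data.shape[3])

    out = np.empty((data.shape[3], len(roster)))
    for k, roi in enumerate(roster):
        d2 = ((mm - np.array(roi.center)) ** 2).sum(axis=1)
        inside = d2 <= roi.radius**2 + 1e-9
        if not inside.any():
            raise ValueError(f"ROI {roi.name!r}: no voxel center within its sphere")
        out[:, k] = flat[inside].mean(axis=0)
    return out


def bandpass(
    ts: np.ndarray,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    tr_s: float = 3.0,
    order: int = 2,
    pad_volumes: int = 30,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass, column-wise, with reflective edge padding."""
    nyq = 0.5 / tr_s
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 <= low < high < "
            f"Nyquist = {nyq:.4f} Hz"
        )
    ts = np.asarray(ts, float)
    if low_hz > 0:
        b, a = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    else:
        b, a = signal.butter(order, high_hz / nyq, btype="low")
    padlen = min(pad_volumes, ts.shape[0] - 1)
    out = signal.filtfilt(b, a, ts, axis=0, padtype="even", padlen=padlen)
    if low_hz == 0:  # lowpass keeps DC; remove it to match the band contract
        out = out - out.mean(axis=0, keepdims=True)
    return out


def regress_confounds(
    ts: np.ndarray,
    confounds: np.ndarray,
    add_derivatives_for: list[int] | None = None,
) -> np.ndarray:
    """Least-squares residuals of each node series on the confound model.

    The model contains an intercept, every confound column, and the first
    difference (backward, zero-padded) of the columns listed in
    `add_derivatives_for` — by convention the tissue signals.
    """
    ts = np.asarray(ts, float)
    confounds = np.asarray(confounds, float)
    if confounds.shape[0] != ts.shape[0]:
        raise ValueError("confound rows must match time-series rows")
    cols = [np.ones((ts.shape[0], 1)), confounds]
    if add_derivatives_for:
        deriv = np.vstack(
            [np.zeros((1, len(add_derivatives_for))),
             np.diff(confounds[:, add_derivatives_for], axis=0)]
        )
        cols.append(deriv)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn(
            "confound design is rank deficient; using pseudoinverse",
            RuntimeWarning, stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(x, ts, rcond=None)
    return ts - x @ beta


def select_condition_volumes(
    ts: np.ndarray,
    design: DesignParadigm,
    condition: str,
    shift_volumes: int = 2,
    tr_s: float | None = None,
    node_names: tuple[str, ...] | None = None,
) -> CleanSeries:
    """Concatenate, in session order, the task volumes of one condition.

    The first `shift_volumes` volumes of each task period are dropped to
    absorb the hemodynamic rise (default 2 volumes = 6 s at TR 3 s).
    """
    if shift_volumes < 0:
        raise ValueError("shift_volumes must be >= 0")
    blocks = design.task_blocks(condition)
    if not blocks:
        raise ValueError(f"condition {condition!r} has no task periods in the design")
    idx = np.concatenate(
        [np.arange(start + shift_volumes, start + n) for start, n in blocks]
    )
    return CleanSeries(
        values=np.asarray(ts, float)[idx],
        tr_s=tr_s if tr_s is not None else design.tr_s,
        condition=condition,
        node_names=node_names,
        provenance=(f"segment({condition}, shift={shift_volumes})",),
    )


def preprocess_subject(
    ts: SubjectTimeSeries,
    low_hz: float = 0.008,
    high_hz: float = 0.09,
    shift_volumes: int = 2,
    filter_first: bool = True,
) -> dict[str, CleanSeries]:
    """Full denoising of one subject, returning one CleanSeries per condition.

    `filter_first` selects whether the bandpass precedes the nuisance
    regression (the default) or follows it; the applied order is logged in
    each output's provenance.
    """
    tissue_cols = [
        i for i, name in enumerate(ts.confound_names) if name.startswith("tissue")
    ]
    steps: list[str] = []
    x = ts.values
    ops = [
        (f"bandpass({low_hz}, {high_hz})",
         lambda v: bandpass(v, low_hz, high_hz, ts.tr_s)),
        ("confound_regression",
         lambda v: regress_confounds(v, ts.confounds, tissue_cols)),
    ]
    if not filter_first:
        ops.reverse()
    for label, op in ops:
        x = op(x)
        steps.append(label)

    out: dict[str, CleanSeries] = {}
    for cond in ts.design.conditions:
        seg = select_condition_volumes(
            x, ts.design, cond, shift_volumes, node_names=ts.node_names
        )
        out[cond] = CleanSeries(
            values=seg.values, tr_s=seg.tr_s, condition=cond,
            node_names=ts.node_names,
            provenance=tuple(steps) + seg.provenance,
        )
    return out
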