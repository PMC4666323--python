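"""Per-run voxelwise preprocessing: standardize, detrend, high-pass.

Each run is processed independently; the chain never mixes information
across runs.  The high-pass filter projects out a discrete cosine basis
spanning frequencies below the cutoff (zero phase distortion, exact nulling
of modeled drifts).
"""

from __future__ import annotations

import logging

import numpy as np

from .timeseries import RoiTimeSeries

logger = logging.getLogger(__name__)

_CONST_TOL = 1e-12


def standardize_runwise(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Zero mean, unit SD (N-1 denominator) per voxel per run.

    Constant voxel-runs map to zeros with a logged warning, keeping the
    sample matrices dense and the classifier well-defined.
    """
    out = ts.data.copy()
    for run, sel in ts.iter_runs():
        block = out[sel]
        if block.shape[0] < 2:
            raise ValueError(f"run {run} has fewer than 2 volumes")
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        const = sd <= _CONST_TOL
        if const.any():
            logger.warning(
                "run %d: %d constant voxel(s) set to zero during standardization",
                run,
                int(const.sum()),
            )
        sd_safe = np.where(const, 1.0, sd)
        block = (block - mean) / sd_safe
        block[:, const] = 0.0
        out[sel] = block
    return ts.copy_with(out)


def detrend_runwise(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Residual of an OLS fit on intercept + linear time, per voxel per run."""
    out = ts.data.copy()
    for run, sel in ts.iter_runs():
        block = out[sel]
        n = block.shape[0]
        if n < 3:
            raise ValueError(f"run {run} too short to detrend ({n} volumes)")
        t = np.arange(n, dtype=float)
        design = np.column_stack([np.ones(n), t])
        coef, *_ = np.linalg.lstsq(design, block, rcond=None)
        out[sel] = block - design @ coef
    return ts.copy_with(out)


def dct_highpass_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal DCT-II columns at frequencies below ``cutoff_hz``.

    Basis function k has frequency k / (2 N TR); the DC column (k = 0) is
    always included so the filter removes any residual mean.  A 0.01 Hz
    cutoff at TR = 3 s, N = 117 keeps k = 0..7 (the 100 s-period drift
    regime).
    """
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    k_max = int(np.floor(2.0 * n * tr * cutoff_hz))
    grid = np.arange(n)
    cols = [np.full(n, 1.0 / np.sqrt(n))]
    cols += [
        np.cos(np.pi * k * (2 * grid + 1) / (2.0 * n)) * np.sqrt(2.0 / n)
        for k in range(1, k_max + 1)
        if k / (2.0 * n * tr) < cutoff_hz
    ]
    return np.column_stack(cols)


def highpass_runwise(ts: RoiTimeSeries, cutoff_hz: float = 0.01) -> RoiTimeSeries:
    """Project out sub-cutoff discrete cosine components, per voxel per run."""
    out = ts.data.copy()
    for run, sel in ts.iter_runs():
        block = out[sel]
        basis = dct_highpass_basis(block.shape[0], ts.tr, cutoff_hz)
        if basis.shape[1]:
            out[sel] = block - basis @ (basis.T @ block)
    return ts.copy_with(out)


def preprocess_chain(
    ts: RoiTimeSeries,
    cutoff_hz: float = 0.01,
    standardize: bool = True,
    detrend: bool = True,
    highpass: bool = True,
) -> RoiTimeSeries:
    """Standardize -> detrend -> high-pass, each per run."""
    if standardize:
        ts = standardize_runwise(ts)
    if detrend:
        ts = detrend_runwise(ts)
    if highpass:
        ts = highpass_runwise(ts, cutoff_hz=cutoff_hz)
    return ts
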