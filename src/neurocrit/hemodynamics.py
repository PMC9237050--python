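"""BOLD synthesis from simulated node activity and functional-connectivity summaries.

The binary activity indicator of each node is convolved with a canonical
double-gamma hemodynamic response function and band-pass filtered
(0.01-0.1 Hz, zero-lag FIR) before Pearson functional connectivity is
computed.  One model step maps to dt = 0.45 s so a 2000-step run spans ~15
minutes of scanner time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal

from neurocrit.dynamics import STATE_A
from neurocrit.synthetic import Parcellation

__all__ = [
    "HRFParams",
    "FCMatrix",
    "hrf_kernel",
    "bandpass_taps",
    "states_to_bold",
    "fc_pearson",
    "fc_summaries",
]


@dataclass
class HRFParams:
    """Double-gamma HRF constants; delays are d_i = a_i * b_i."""

    a1: float = 6.0
    a2: float = 12.0
    b1: float = 0.9
    b2: float = 0.9
    c: float = 0.35
    dt: float = 0.45       # seconds per model step

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "c", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def d1(self) -> float:
        return self.a1 * self.b1

    @property
    def d2(self) -> float:
        return self.a2 * self.b2


@dataclass
class FCMatrix:
    """Pearson functional-connectivity matrix with scalar summaries."""

    FC: np.ndarray
    mean_fc: float = float("nan")        # mean upper-triangular |FC|
    homotopic_fc: float = float("nan")   # mean signed FC over homotopic pairs
    entropy: float = float("nan")        # normalized entropy of |FC|, m=20 bins


def hrf_kernel(params: Optional[HRFParams] = None, duration: float = 30.0) -> np.ndarray:
    """Sample the double-gamma HRF on the model-step grid over [0, duration]."""
    params = params or HRFParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    tau = np.arange(0.0, duration, params.dt)
    main = (tau / params.d1) ** params.a1 * np.exp(-(tau - params.d1) / params.b1)
    under = (tau / params.d2) ** params.a2 * np.exp(-(tau - params.d2) / params.b2)
    return main - params.c * under


def bandpass_taps(
    dt: float, band: tuple[float, float] = (0.01, 0.1), numtaps: int = 877
) -> np.ndarray:
    """Linear-phase FIR band-pass taps for the given sampling interval."""
    fs = 1.0 / dt
    low, high = band
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def states_to_bold(
    states: np.ndarray,
    params: Optional[HRFParams] = None,
    band: tuple[float, float] = (0.01, 0.1),
    numtaps: int = 877,
    trim_edges: bool = True,
) -> np.ndarray:
    """Convolve node activity with the HRF and band-pass filter, per node.

    ``states`` is a (t, N) trajectory (values in {0, 1, 2}) or an already
    binary activity array.  The causal convolution's kernel-length warm-up
    is discarded; the symmetric FIR taps are applied with a centered
    convolution, which is zero-lag, and half a filter length is trimmed from
    each end when ``trim_edges`` is set.
    """
    params = params or HRFParams()
    states = np.asarray(states)
    activity = (states == STATE_A).astype(float) if states.dtype != float else states
    kernel = hrf_kernel(params)
    if activity.shape[0] <= kernel.size:
        raise ValueError("trajectory must be longer than the HRF kernel")
    bold = signal.fftconvolve(activity, kernel[:, None], mode="full", axes=0)
    bold = bold[kernel.size : activity.shape[0]]      # drop warm-up samples
    taps = bandpass_taps(params.dt, band=band, numtaps=numtaps)
    filtered = signal.fftconvolve(bold, taps[:, None], mode="same", axes=0)
    if trim_edges:
        half = taps.size // 2
        if filtered.shape[0] <= 2 * half:
            warnings.warn("signal shorter than filter; edges not trimmed", stacklevel=2)
        else:
            filtered = filtered[half:-half]
    return filtered


def fc_pearson(signals: np.ndarray) -> FCMatrix:
    """Pearson correlation matrix across node signals (time x node).

    Zero-variance nodes yield NaN correlations and are excluded from the
    scalar summaries computed later.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (time x node) array with >= 2 time points")
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (x - x.mean(axis=0)) / sd
        fc = (xc.T @ xc) / x.shape[0]
    fc[sd == 0, :] = np.nan
    fc[:, sd == 0] = np.nan
    np.fill_diagonal(fc, 1.0)
    fc = np.clip(fc, -1.0, 1.0, out=fc)
    return FCMatrix(FC=fc)


def fc_summaries(
    fc: FCMatrix,
    parcellation: Optional[Parcellation] = None,
    bins: int = 20,
) -> FCMatrix:
    """Populate mean |FC|, homotopic FC and normalized entropy on the matrix.

    mean_fc averages the upper-triangular absolute correlations; homotopic_fc
    averages signed FC over the parcellation's homotopic pairs (NaN when no
    pairs are defined); entropy bins upper-triangular |FC| on [0, 1] with
    ``bins`` bins, normalized by log(bins).
    """
    F = fc.FC
    n = F.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.abs(F[iu, ju])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite off-diagonal correlations")
    fc.mean_fc = float(vals.mean())

    counts, _ = np.histogram(vals, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    nz = p[p > 0]
    fc.entropy = float(-(nz * np.log(nz)).sum() / math.log(bins))

    if parcellation is not None:
        pairs = parcellation.homotopic_pairs()
        if pairs.size:
            hvals = F[pairs[:, 0], pairs[:, 1]]
            hvals = hvals[np.isfinite(hvals)]
            fc.homotopic_fc = float(hvals.mean()) if hvals.size else float("nan")
        else:
            fc.homotopic_fc = float("nan")
    return fc
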