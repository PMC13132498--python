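"""Neighbour-bin SNR, per-eye ssVEP curves, and the AUC summary.

The SNR statistic divides the power in the bin at the reversal frequency by
the mean of its second and third neighbours on either side (immediate
neighbours excluded, to keep residual leakage out of the noise estimate) and
expresses the ratio in dB.  On the 1/3 Hz grid of 3-s epochs the four noise
bins for 15 Hz sit at 14, 14.33, 15.67 and 16 Hz.

The per-eye curve collects the SNR of every grating condition in ascending
spatial frequency; full-screen flicker (0 cpd) is held as a separate
endpoint and never enters the curve or its AUC.  The AUC is the signed
trapezoidal area between the curve and the 0 dB noise threshold on a linear
cpd axis, so it can be negative when most of the curve lies below noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .preprocess import PSDSpectrum

__all__ = ["SSVEPCurve", "snr_db", "build_ssvep_curve", "curve_auc"]


def snr_db(psd: PSDSpectrum, target_freq: float) -> float:
    """Eq.-style neighbour-bin SNR at ``target_freq`` in dB.

    ``10*log10(m_t / mean(m_{t-3}, m_{t-2}, m_{t+2}, m_{t+3}))`` with bin
    offsets in units of the grid spacing.
    """
    b = psd.bin_index(target_freq)
    if b - 3 < 0 or b + 3 >= len(psd.power):
        raise ValueError("target frequency too close to the edge of the spectrum")
    num = float(psd.power[b])
    noise = float(np.mean(psd.power[[b - 3, b - 2, b + 2, b + 3]]))
    tiny = np.finfo(float).tiny
    if noise <= tiny:
        if num <= tiny:
            raise ValueError("degenerate spectrum: signal and noise bins are all zero")
        warnings.warn("noise-bin power at machine floor; clamping denominator", stacklevel=2)
        noise = tiny
    return float(10.0 * np.log10(num / noise))


@dataclass(frozen=True)
class SSVEPCurve:
    """Per-eye SNR-vs-spatial-frequency samples plus summary endpoints."""

    eye: str
    spatial_frequencies: np.ndarray  # cpd, ascending, all > 0
    snr: np.ndarray  # dB, aligned with spatial_frequencies
    flicker_snr: float | None
    auc: float
    below_noise_fraction: float


def curve_auc(spatial_frequencies: np.ndarray, snr: np.ndarray) -> float:
    """Signed trapezoidal integral of SNR over cpd (linear axis, no extrapolation)."""
    sf = np.asarray(spatial_frequencies, dtype=float)
    y = np.asarray(snr, dtype=float)
    if sf.size < 2:
        raise ValueError("AUC needs at least two samples")
    if np.any(np.diff(sf) <= 0):
        raise ValueError("spatial frequencies must be strictly ascending")
    return float(np.trapezoid(y, sf))


def build_ssvep_curve(
    snr_by_condition: Mapping[float, float] | Iterable[tuple[float, float]],
    eye: str = "",
) -> SSVEPCurve:
    """Assemble a curve from per-condition SNRs; 0 cpd routes to the flicker slot."""
    pairs = list(snr_by_condition.items()) if isinstance(snr_by_condition, Mapping) else list(snr_by_condition)
    sfs = [float(sf) for sf, _ in pairs]
    if len(set(sfs)) != len(sfs):
        raise ValueError("duplicate spatial frequency in curve input")
    flicker = [s for sf, s in pairs if sf == 0.0]
    if len(flicker) > 1:
        raise ValueError("at most one flicker (0 cpd) condition allowed")
    pattern = sorted((sf, s) for sf, s in pairs if sf > 0.0)
    sf_arr = np.array([sf for sf, _ in pattern])
    snr_arr = np.array([s for _, s in pattern])
    return SSVEPCurve(
        eye=eye,
        spatial_frequencies=sf_arr,
        snr=snr_arr,
        flicker_snr=float(flicker[0]) if flicker else None,
        auc=curve_auc(sf_arr, snr_arr) if sf_arr.size >= 2 else float("nan"),
        below_noise_fraction=float(np.mean(snr_arr < 0.0)) if sf_arr.size else float("nan"),
    )
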