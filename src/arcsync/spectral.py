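"""Frequency-resolved intersubject correlation.

Spectral ISC between two subjects at a channel is the magnitude-squared
coherence of the homologous channel signals,

    ISC(f) = |Gxy(f)|^2 / (Gxx(f) * Gyy(f)),

with Gxy the Welch cross-spectral density and Gxx, Gyy the auto-spectra.
Pair-averaged coherence is summarised within the canonical delta, theta,
alpha and beta bands and slid over the recording in windows long enough to
resolve the lowest band (a 15-sample correlation window cannot; the
spectral stream therefore uses its own, longer window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import CohortEEG
from .isc import bh_fdr, permutation_test_correlation

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "CrossSpectralEstimate",
    "welch_spectra",
    "msc",
    "disc_bands",
    "band_engagement_test",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band (lo_hz, hi_hz]."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band must satisfy lo < hi")

    def mask(self, freqs_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs_hz, float)
        return (f > self.lo_hz) & (f <= self.hi_hz)


#: Canonical EEG bands; note the deliberate 7-8 Hz gap between theta and alpha.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
)


@dataclass
class CrossSpectralEstimate:
    freqs_hz: np.ndarray
    Gxy: np.ndarray
    Gxx: np.ndarray
    Gyy: np.ndarray
    n_segments: int

    def coherence(self) -> np.ndarray:
        denom = self.Gxx * self.Gyy
        with np.errstate(invalid="ignore", divide="ignore"):
            coh = np.abs(self.Gxy) ** 2 / denom
        return np.where(denom > 0, np.clip(coh.real, 0.0, 1.0), 0.0)


def _segment_ffts(x: np.ndarray, seg_len: int, step: int) -> np.ndarray:
    """Hann-tapered, mean-detrended FFTs of overlapping segments (last axis)."""
    n = x.shape[-1]
    starts = np.arange(0, n - seg_len + 1, step)
    segs = np.stack([x[..., s : s + seg_len] for s in starts], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    from scipy.signal.windows import hann

    return np.fft.rfft(segs * hann(seg_len, sym=False), axis=-1)


def welch_spectra(x, y, fs: float, seg_len: int, overlap: float = 0.5) -> CrossSpectralEstimate:
    """Welch auto- and cross-spectra of two equal-length signals.

    ``x`` and ``y`` may carry leading batch axes.  At least two segments are
    required: a single-segment coherence estimate is identically one and is
    refused.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical shape")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    step = max(1, int(round(seg_len * (1 - overlap))))
    n_seg = 1 + (x.shape[-1] - seg_len) // step if x.shape[-1] >= seg_len else 0
    if n_seg < 2:
        raise ValueError("need at least 2 Welch segments for a coherence estimate")
    X = _segment_ffts(x, seg_len, step)
    Y = _segment_ffts(y, seg_len, step)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    return CrossSpectralEstimate(
        freqs_hz=freqs,
        Gxy=(X * np.conj(Y)).mean(axis=-2),
        Gxx=(np.abs(X) ** 2).mean(axis=-2),
        Gyy=(np.abs(Y) ** 2).mean(axis=-2),
        n_segments=n_seg,
    )


def msc(x, y, fs: float, seg_len: int, overlap: float = 0.5):
    """Magnitude-squared coherence; returns (CrossSpectralEstimate, coherence)."""
    est = welch_spectra(x, y, fs, seg_len, overlap)
    return est, est.coherence()


def disc_bands(
    cohort_data: np.ndarray,
    fs: float,
    bands=DEFAULT_BANDS,
    win_s: float = 4.0,
    step_s: float = 0.5,
    seg_s: float = 1.0,
    overlap: float = 0.5,
):
    """Sliding-window pair-averaged band coherence.

    Returns ``(stack, window_centers_s)`` with ``stack`` of shape
    band x channel x window: per window the coherence of every subject pair
    at every channel, averaged over pairs, then averaged over the band's
    frequency bins.
    """
    data = np.asarray(cohort_data.data if isinstance(cohort_data, CohortEEG) else cohort_data, float)
    fs = float(cohort_data.fs_hz) if isinstance(cohort_data, CohortEEG) else float(fs)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need subjects x channels x time with >= 2 subjects")
    if win_s < 2 * seg_s:
        raise ValueError("window must hold at least two segments (win_s >= 2*seg_s)")
    seg_len = int(round(seg_s * fs))
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    resolution = 1.0 / seg_s
    for band in bands:
        if band.lo_hz < resolution or not band.mask(freqs).any():
            raise ValueError(f"band {band.name} unresolvable at segment length {seg_s} s")
    S, C, T = data.shape
    win = int(round(win_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, T - win + 1, step)
    centers = (starts + (win - 1) / 2.0) / fs
    seg_step = max(1, int(round(seg_len * (1 - overlap))))
    pairs = [(i, j) for i in range(S) for j in range(i + 1, S)]
    masks = [band.mask(freqs) for band in bands]
    stack = np.zeros((len(bands), C, len(starts)))
    for w, s0 in enumerate(starts):
        # FFT every subject/channel segment once, then form pair cross-spectra
        F = _segment_ffts(data[:, :, s0 : s0 + win], seg_len, seg_step)  # S,C,K,nf
        P = (np.abs(F) ** 2).mean(axis=2)  # S,C,nf auto-spectra
        coh_sum = np.zeros((C, len(freqs)))
        for i, j in pairs:
            Gxy = (F[i] * np.conj(F[j])).mean(axis=1)
            denom = P[i] * P[j]
            with np.errstate(invalid="ignore", divide="ignore"):
                coh = np.abs(Gxy) ** 2 / denom
            coh_sum += np.where(denom > 0, np.clip(coh.real, 0, 1), 0.0)
        coh_mean = coh_sum / len(pairs)
        for b, mask in enumerate(masks):
            stack[b, :, w] = coh_mean[:, mask].mean(axis=1)
    return stack, centers


def band_engagement_test(
    band_stack: np.ndarray,
    window_centers_s: np.ndarray,
    engagement: np.ndarray,
    engagement_fs: float,
    bands=DEFAULT_BANDS,
    channel_names=None,
    n_perm: int = 1000,
    tails: str = "one",
    seed=None,
):
    """Permutation test of every band x channel ISC course against engagement.

    The engagement trace is sampled at the window centres; BH-FDR is
    applied across the full band x channel family.  Returns a list of
    result records (band, channel, r, p, p_fdr, r2, mse).
    """
    rng = np.random.default_rng(seed)
    idx = np.clip(
        np.round(np.asarray(window_centers_s) * engagement_fs).astype(int),
        0,
        len(engagement) - 1,
    )
    eng = np.asarray(engagement, float)[idx]
    n_bands, n_ch, _ = band_stack.shape
    records = []
    for b in range(n_bands):
        for c in range(n_ch):
            res = permutation_test_correlation(
                band_stack[b, c], eng, n_perm=n_perm, tails=tails,
                seed=rng.integers(2**31),
            )
            records.append(
                {
                    "band": bands[b].name,
                    "channel": channel_names[c] if channel_names else c,
                    "r": res.empirical_r,
                    "p": res.p,
                    "r2": res.r2,
                    "mse": res.mse,
                }
            )
    p_adj, _ = bh_fdr([r["p"] for r in records])
    for rec, pa in zip(records, p_adj):
        rec["p_fdr"] = float(pa)
    return records
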