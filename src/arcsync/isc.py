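"""Tapered sliding-window intersubject correlation and surrogate inference.

Dynamic intersubject correlation (dISC) quantifies moment-to-moment
similarity of homologous EEG channels across subjects: a short tapered
window slides over the recordings and, at each position, the weighted
Pearson correlation between every unordered subject pair is computed,
Fisher z-transformed, and averaged over pairs.  Significance against a
reference series (e.g. group-averaged engagement) is assessed with
phase-randomised surrogates, which preserve the amplitude spectrum (and
hence the autocorrelation) of the series while destroying its phase
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Taper",
    "DiscStack",
    "PermutationResult",
    "make_taper",
    "weighted_pearson",
    "sliding_weighted_corr",
    "disc",
    "phase_randomize",
    "phase_randomize_batch",
    "permutation_test_correlation",
    "bh_fdr",
    "fisher_z",
    "inverse_fisher_z",
]

#: Correlations are clipped to this magnitude before arctanh so that
#: identical signals map to a large finite z instead of infinity.
R_CLIP = 1.0 - 1e-12


def fisher_z(r):
    """arctanh with clipping at ``|r| <= 1 - 1e-12``."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def inverse_fisher_z(z):
    return np.tanh(z)


@dataclass(frozen=True)
class Taper:
    """Symmetric nonnegative window weights summing to one."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a 1-D vector")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        return len(self.weights)


def make_taper(length: int = 15, sigma: float = 3.0) -> Taper:
    """Rectangular window convolved with a Gaussian, central part kept.

    ``length`` ones are convolved with a discrete Gaussian of width
    ``sigma`` samples (support +/- 4 sigma); the central ``length`` samples
    of the full convolution are retained and normalised to sum to one.
    ``sigma=0`` degenerates to the uniform window.
    """
    if length < 3:
        raise ValueError("taper length must be >= 3")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Taper(np.full(length, 1.0 / length))
    half = int(np.ceil(4 * sigma))
    j = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (j / sigma) ** 2)
    full = np.convolve(np.ones(length), g, mode="full")
    start = (len(full) - length) // 2
    w = full[start : start + length]
    w = 0.5 * (w + w[::-1])  # enforce exact symmetry
    return Taper(w / w.sum())


def weighted_pearson(x, y, w) -> float:
    """Weighted-moment Pearson correlation of two equal-length vectors.

    Returns NaN if either series has zero weighted variance (the caller is
    expected to skip such windows).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(getattr(w, "weights", w), float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and weights must have equal length")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        return np.nan
    cov = w @ ((x - mx) * (y - my))
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def _window_moments(data: np.ndarray, w: np.ndarray, step: int):
    """Taper-weighted sliding means of ``data`` and ``data**2`` (last axis)."""
    v = sliding_window_view(data, len(w), axis=-1)[..., ::step, :]
    return v @ w, (v**2) @ w


def sliding_weighted_corr(x: np.ndarray, y: np.ndarray, taper: Taper, step: int = 1):
    """Weighted Pearson r in every sliding window position.

    ``x`` and ``y`` may carry leading batch axes; correlation runs along the
    last axis.  Windows with non-positive weighted variance yield NaN.
    """
    w = taper.weights
    mx, mxx = _window_moments(np.asarray(x, float), w, step)
    my, myy = _window_moments(np.asarray(y, float), w, step)
    mxy = sliding_window_view(np.asarray(x, float) * np.asarray(y, float), len(w), axis=-1)[
        ..., ::step, :
    ] @ w
    vx = mxx - mx**2
    vy = myy - my**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mxy - mx * my) / np.sqrt(vx * vy)
    r = np.where((vx > 0) & (vy > 0), r, np.nan)
    return np.clip(r, -1.0, 1.0)


@dataclass
class DiscStack:
    """Pair-averaged dynamic ISC: Fisher-z values per channel per window."""

    values: np.ndarray  # channels x windows, pair-averaged Fisher z
    window_centers_s: np.ndarray
    fs_hz: float
    step_samples: int
    channel_names: Optional[list] = None
    pairwise: Optional[np.ndarray] = None  # pairs x channels x windows

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def pair_mean_r(self) -> np.ndarray:
        """Pair-averaged correlation on the r scale (inverse Fisher)."""
        return inverse_fisher_z(self.values)


def window_centers(n_samples: int, length: int, step: int, fs_hz: float) -> np.ndarray:
    starts = np.arange(0, n_samples - length + 1, step)
    return (starts + (length - 1) / 2.0) / fs_hz


def disc(
    data: np.ndarray,
    fs_hz: float,
    taper: Optional[Taper] = None,
    step: int = 1,
    keep_pairwise: bool = False,
    channel_names=None,
) -> DiscStack:
    """Dynamic intersubject correlation of a subjects x channels x time array.

    For every window position, channel and unordered subject pair the
    taper-weighted Pearson correlation between the two subjects' windowed
    channel signals is Fisher z-transformed; the pair average is returned.
    """
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("data must be subjects x channels x time")
    n_sub = data.shape[0]
    if n_sub < 2:
        raise ValueError("dISC needs at least two subjects")
    taper = taper or make_taper()
    pairs = [(i, j) for i in range(n_sub) for j in range(i + 1, n_sub)]
    z_sum = None
    z_cnt = None
    pairwise = [] if keep_pairwise else None
    for i, j in pairs:
        r = sliding_weighted_corr(data[i], data[j], taper, step)  # channels x windows
        z = fisher_z(r)
        if pairwise is not None:
            pairwise.append(z)
        valid = np.isfinite(z)
        z0 = np.where(valid, z, 0.0)
        if z_sum is None:
            z_sum, z_cnt = z0.copy(), valid.astype(float)
        else:
            z_sum += z0
            z_cnt += valid
    with np.errstate(invalid="ignore"):
        values = z_sum / z_cnt
    centers = window_centers(data.shape[-1], taper.length, step, fs_hz)
    return DiscStack(
        values=values,
        window_centers_s=centers,
        fs_hz=fs_hz,
        step_samples=step,
        channel_names=list(channel_names) if channel_names is not None else None,
        pairwise=np.asarray(pairwise) if pairwise is not None else None,
    )


def phase_randomize(series: np.ndarray, seed=None) -> np.ndarray:
    """Fourier phase-randomised surrogate of a 1-D series.

    The amplitude spectrum is preserved bin-wise; phases of all bins except
    DC (and Nyquist, for even length) are replaced by i.i.d. uniform draws.
    """
    x = np.asarray(series, float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("series must be 1-D with length >= 4")
    return phase_randomize_batch(x, 1, seed)[0]


def phase_randomize_batch(series: np.ndarray, n: int, seed=None) -> np.ndarray:
    """``n`` independent phase-randomised surrogates, stacked as rows."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = np.asarray(series, float)
    T = len(x)
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    nb = len(spec)
    # randomizable bins: exclude DC; exclude Nyquist when T is even
    hi = nb - 1 if T % 2 == 0 else nb
    phases = rng.uniform(0, 2 * np.pi, size=(n, hi - 1))
    surr_spec = np.empty((n, nb), complex)
    surr_spec[:, 0] = spec[0]
    surr_spec[:, 1:hi] = amp[1:hi] * np.exp(1j * phases)
    if hi < nb:
        surr_spec[:, nb - 1] = spec[nb - 1]
    return np.fft.irfft(surr_spec, n=T, axis=1)


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("zero-variance series has no z-score")
    return (v - v.mean()) / sd


@dataclass
class PermutationResult:
    """Outcome of a surrogate permutation test on a correlation statistic."""

    empirical_r: float
    null_r: np.ndarray
    n_perm: int
    p: float
    tails: str
    r2: float = np.nan
    mse: float = np.nan
    p_fdr: Optional[float] = None

    def __post_init__(self):
        lo = 1.0 / (1.0 + self.n_perm)
        assert lo - 1e-12 <= self.p <= 1.0 + 1e-12


def permutation_p(empirical: float, null: np.ndarray, tails: str = "one") -> float:
    """p = (1 + #{null >= empirical}) / (1 + n_perm); two-tailed on |r|."""
    null = np.asarray(null, float)
    if tails == "two":
        exceed = np.sum(np.abs(null) >= abs(empirical))
    elif tails == "one":
        exceed = np.sum(null >= empirical)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float((1 + exceed) / (1 + len(null)))


def permutation_test_correlation(
    x, y, n_perm: int = 1000, tails: str = "one", seed=None
) -> PermutationResult:
    """Correlation of ``x`` and ``y`` tested against phase-randomised ``y``.

    The null sample is built by correlating ``x`` with ``n_perm``
    phase-randomised surrogates of ``y``.  R-squared and MSE are reported on
    the common z-scale of the two series.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    zx, zy = _zscore(x), _zscore(y)
    T = len(x)
    empirical = float(zx @ zy / T)
    surr = phase_randomize_batch(y, n_perm, seed)
    surr = surr - surr.mean(axis=1, keepdims=True)
    sd = surr.std(axis=1)
    sd[sd == 0] = np.inf
    null = (surr / sd[:, None]) @ zx / T
    mse = float(np.mean((zx - zy) ** 2))
    return PermutationResult(
        empirical_r=empirical,
        null_r=null,
        n_perm=n_perm,
        p=permutation_p(empirical, null, tails),
        tails=tails,
        r2=1.0 - mse,
        mse=mse,
    )


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up adjusted p-values and rejection mask."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.array([]), np.array([], bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return p_adj.reshape(p.shape), reject.reshape(p.shape)
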