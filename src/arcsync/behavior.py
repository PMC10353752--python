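"""Behavioral analyses: ratings, event segmentation, recall similarity.

Continuous engagement ratings are step-function resampled onto the EEG
clock, z-normalised and summarised by pairwise rater synchrony (Fisher-
averaged correlation, BH-FDR).  Phase-boundary stamps from independent
raters are tested for above-chance coincidence within a short window
against a shuffle null.  Free-recall transcripts are compared across
subjects per narrative phase with latent semantic analysis: a truncated
SVD of the term-document count matrix, document similarity as the cosine
of the low-rank score vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.metrics.pairwise import cosine_similarity

from .isc import bh_fdr, fisher_z, inverse_fisher_z

logger = logging.getLogger(__name__)

__all__ = [
    "resample_ratings",
    "resample_rater_table",
    "rating_synchrony",
    "CoincidenceTest",
    "segmentation_agreement",
    "RecallSimilarity",
    "recall_similarity",
    "phase_sd_comparison",
    "STOP_WORDS",
]

#: Minimal English stop-word list applied before LSA.
STOP_WORDS = (
    "a an and are as at be but by for from had has have he her his i in is it its "
    "of on or she so that the then there they this to was were with"
).split()


def resample_ratings(times_s, values, fs_hz: float, duration_s: float,
                     scale=(1.0, 9.0), znorm: bool = True) -> np.ndarray:
    """Sample-and-hold resampling of rating events onto a uniform grid.

    Samples before the first event take the scale midpoint.  The trace is
    z-normalised over time unless ``znorm=False``; a constant trace cannot
    be z-normalised and raises (degenerate rater).
    """
    times = np.asarray(times_s, float)
    values = np.asarray(values, float)
    if len(times) == 0:
        raise ValueError("empty rating event list")
    if np.any(np.diff(times) < 0):
        raise ValueError("rating events must be time-sorted")
    if times[0] < 0 or times[-1] > duration_s:
        raise ValueError("rating events outside [0, duration]")
    grid = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    idx = np.searchsorted(times, grid, side="right") - 1
    midpoint = 0.5 * (scale[0] + scale[1])
    trace = np.where(idx >= 0, values[np.clip(idx, 0, None)], midpoint)
    if not znorm:
        return trace
    sd = trace.std()
    if sd == 0:
        raise ValueError("degenerate rater: constant rating trace")
    return (trace - trace.mean()) / sd


def resample_rater_table(df: pd.DataFrame, fs_hz: float, duration_s: float,
                         znorm: bool = True):
    """Long CSV table (rater_id,time_s,value) -> raters x time matrix.

    Degenerate (constant) raters are excluded with a logged warning.
    Returns ``(matrix, rater_ids)``.
    """
    rows, ids = [], []
    for rid, g in df.groupby("rater_id", sort=True):
        g = g.sort_values("time_s")
        try:
            rows.append(resample_ratings(g["time_s"], g["value"], fs_hz, duration_s,
                                         znorm=znorm))
            ids.append(rid)
        except ValueError as err:
            logger.warning("rater %s excluded: %s", rid, err)
    if not rows:
        raise ValueError("no usable raters")
    return np.asarray(rows), ids


def rating_synchrony(raters: np.ndarray, q: float = 0.05) -> dict:
    """Pairwise rating synchrony across raters.

    Returns the pairwise r matrix, the Fisher-averaged mean r, per-pair
    correlation-test p-values with BH-FDR, and the fraction of pairs that
    are significantly positive after correction.
    """
    R = np.asarray(raters, float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two raters")
    sds = R.std(axis=1)
    keep = np.flatnonzero(sds > 0)
    if len(keep) < n:
        logger.warning("excluding %d degenerate raters", n - len(keep))
    R = R[keep]
    n = len(keep)
    rmat = np.corrcoef(R)
    iu = np.triu_indices(n, k=1)
    pair_r = rmat[iu]
    pvals = np.array(
        [stats.pearsonr(R[i], R[j]).pvalue for i, j in zip(iu[0], iu[1])]
    )
    p_adj, reject = bh_fdr(pvals, q)
    sig_pos = float(np.mean(reject & (pair_r > 0))) if len(pair_r) else np.nan
    return {
        "r_matrix": rmat,
        "pair_r": pair_r,
        "mean_r": float(inverse_fisher_z(np.mean(fisher_z(pair_r)))),
        "sd_r": float(np.std(pair_r)),
        "p": pvals,
        "p_fdr": p_adj,
        "frac_significant_positive": sig_pos,
        "n_pairs": len(pair_r),
        "rater_index": keep,
    }


@dataclass
class CoincidenceTest:
    window_s: float
    n_shuffles: int
    alpha: float
    min_count: int
    boundaries: list  # (time_s, count), sorted by time
    null_max_counts: np.ndarray
    counts_at_stamps: np.ndarray
    stamp_times: np.ndarray


def _coincidence_counts(stamps_by_rater, candidates, half_w):
    counts = np.zeros(len(candidates), int)
    for stamps in stamps_by_rater:
        lo = np.searchsorted(stamps, candidates - half_w, side="left")
        hi = np.searchsorted(stamps, candidates + half_w, side="right")
        counts += (hi > lo)
    return counts


def segmentation_agreement(
    stamps: pd.DataFrame,
    duration_s: float,
    window_s: float = 3.0,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed=None,
    half_window: bool = False,
    grid_step_s: float = 0.25,
) -> CoincidenceTest:
    """Above-chance coincidence of phase-boundary stamps across raters.

    Candidate boundary times are scanned on a uniform grid; at each
    candidate the number of raters with any stamp within +/- ``window_s``
    of it is counted (``half_window=True`` narrows this to
    +/- ``window_s``/2).  The null shuffles each rater's stamps uniformly
    over the stimulus (preserving per-rater stamp counts) and records the
    maximum coincidence count over the same grid per shuffle, so the
    acceptance threshold — the smallest count exceeded by chance with
    probability < alpha — controls false acceptance anywhere in the
    stimulus.  Accepted boundaries are count maxima at or above threshold,
    greedily de-duplicated within one window width.
    """
    raters = sorted(stamps["rater_id"].unique())
    if len(raters) < 5:
        raise ValueError("need at least 5 raters")
    rng = np.random.default_rng(seed)
    half_w = window_s / 2.0 if half_window else window_s
    by_rater = [np.sort(stamps.loc[stamps["rater_id"] == r, "start_s"].to_numpy(float))
                for r in raters]
    grid = np.arange(0.0, duration_s + grid_step_s, grid_step_s)
    counts = _coincidence_counts(by_rater, grid, half_w)
    null_max = np.empty(n_shuffles, int)
    sizes = [len(s) for s in by_rater]
    for k in range(n_shuffles):
        shuffled = [np.sort(rng.uniform(0, duration_s, size=m)) for m in sizes]
        null_max[k] = _coincidence_counts(shuffled, grid, half_w).max()
    # smallest count whose chance exceedance probability is below alpha
    min_count = int(null_max.max()) + 1
    for c in range(1, int(null_max.max()) + 2):
        if np.mean(null_max >= c) < alpha:
            min_count = c
            break
    order = np.argsort(-counts)
    accepted = []
    for i in order:
        if counts[i] < min_count:
            break
        t = grid[i]
        if all(abs(t - b[0]) > 2 * half_w for b in accepted):
            accepted.append((float(t), int(counts[i])))
    accepted.sort()
    return CoincidenceTest(
        window_s=window_s,
        n_shuffles=n_shuffles,
        alpha=alpha,
        min_count=min_count,
        boundaries=accepted,
        null_max_counts=null_max,
        counts_at_stamps=counts,
        stamp_times=grid,
    )


@dataclass
class RecallSimilarity:
    phase: str
    subjects: list
    similarity: np.ndarray  # subject x subject cosine matrix, diagonal 1
    mean: float
    sd: float
    subject_sd: np.ndarray  # SD of each subject's similarities to the others
    n_components: int


def _lsa_scores(texts, k: int, min_count: int, stop_words):
    vec = CountVectorizer(stop_words=list(stop_words), token_pattern=r"(?u)\b\w+\b")
    X = vec.fit_transform(texts)
    keep = np.asarray(X.sum(axis=0)).ravel() >= min_count
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValueError("no terms survive the frequency floor")
    max_rank = min(X.shape) - 1
    if k > max_rank:
        logger.warning("k=%d exceeds matrix rank; clamped to %d", k, max_rank)
        k = max(1, max_rank)
    svd = TruncatedSVD(n_components=k, random_state=0)
    return svd.fit_transform(X)


def recall_similarity(
    docs: dict,
    k: int = 20,
    min_count: int = 2,
    merge_last_two: bool = False,
    stop_words=STOP_WORDS,
    phase_order=None,
) -> dict:
    """Per-phase LSA cosine similarity between subjects' recall documents.

    ``docs`` maps subject -> phase -> text.  With ``merge_last_two`` the
    final two phases are concatenated into one (short-phase pooling).
    Returns phase -> :class:`RecallSimilarity`.
    """
    subjects = sorted(docs)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects")
    phases = list(phase_order) if phase_order else list(docs[subjects[0]].keys())
    if merge_last_two and len(phases) >= 2:
        a, b = phases[-2], phases[-1]
        merged = f"{a}+{b}"
        docs = {
            s: {**{p: docs[s][p] for p in phases[:-2]},
                merged: docs[s].get(a, "") + " " + docs[s].get(b, "")}
            for s in subjects
        }
        phases = phases[:-2] + [merged]
    out = {}
    for phase in phases:
        texts = [docs[s][phase] for s in subjects]
        scores = _lsa_scores(texts, k, min_count, stop_words)
        sim = cosine_similarity(scores)
        np.fill_diagonal(sim, 1.0)
        iu = np.triu_indices(len(subjects), k=1)
        off = sim[iu]
        mask = ~np.eye(len(subjects), dtype=bool)
        subject_sd = np.array([sim[i][mask[i]].std() for i in range(len(subjects))])
        out[phase] = RecallSimilarity(
            phase=phase,
            subjects=subjects,
            similarity=sim,
            mean=float(off.mean()),
            sd=float(off.std()),
            subject_sd=subject_sd,
            n_components=scores.shape[1],
        )
    return out


def phase_sd_comparison(similarities: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA over phases on per-subject recall-similarity SDs.

    Pairwise follow-up comparisons use Welch t-tests with Sidak
    correction.  Returns F, p, and the pairwise table with directions.
    """
    phases = list(similarities)
    if len(phases) < 2:
        raise ValueError("need at least two phases")
    groups = [similarities[p].subject_sd for p in phases]
    F, p = stats.f_oneway(*groups)
    m = len(phases) * (len(phases) - 1) // 2
    pairwise = []
    for i in range(len(phases)):
        for j in range(i + 1, len(phases)):
            t, pij = stats.ttest_ind(groups[i], groups[j], equal_var=False)
            p_sidak = 1.0 - (1.0 - pij) ** m
            pairwise.append(
                {
                    "phase_a": phases[i],
                    "phase_b": phases[j],
                    "t": float(t),
                    "p": float(pij),
                    "p_sidak": float(min(1.0, p_sidak)),
                    "direction": "a<b" if t < 0 else "a>b",
                    "significant": bool(p_sidak < alpha),
                }
            )
    return {"F": float(F), "p": float(p), "pairwise": pairwise, "phases": phases}
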