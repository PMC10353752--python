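"""Leave-one-subject-out decoding of continuous engagement from EEG features.

For each held-out subject an RBF support vector regression is trained on
the remaining subjects' window-feature vectors (pooled over windows) to
predict the group-averaged engagement value of each window, then tested on
the held-out subject.  Fold performance is the Fisher-z Pearson
correlation between predicted and observed engagement; fold z's are
averaged and mapped back to r.  A fold-wise feature-selection step keeps
only features whose per-subject correlation with engagement is
consistently non-zero (one-sample t-test on Fisher z's, p < 0.01), with
the sign of the mean z recorded.  Significance of the mean prediction
correlation is assessed against re-fits on phase-randomised engagement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .arc import PhaseSegmentation
from .isc import (
    PermutationResult,
    bh_fdr,
    fisher_z,
    inverse_fisher_z,
    permutation_p,
    phase_randomize_batch,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTensor",
    "LooResult",
    "ProportionScore",
    "engagement_at_windows",
    "select_features",
    "loo_predict",
    "permutation_null_prediction",
    "proportion_scores",
    "per_phase_prediction",
]


@dataclass
class FeatureTensor:
    """subjects x windows x features with labels on a shared window grid."""

    values: np.ndarray
    feature_labels: list
    window_centers_s: np.ndarray
    source: str = "features"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x windows x features")
        if self.values.shape[2] != len(self.feature_labels):
            raise ValueError("one label per feature required")
        if self.values.shape[1] != len(self.window_centers_s):
            raise ValueError("window grid mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subset_windows(self, idx) -> "FeatureTensor":
        return FeatureTensor(
            values=self.values[:, idx, :],
            feature_labels=list(self.feature_labels),
            window_centers_s=np.asarray(self.window_centers_s)[idx],
            source=self.source,
        )


@dataclass
class LooResult:
    fold_r: np.ndarray  # Fisher-z per held-out subject
    mean_r: float  # inverse-Fisher average across folds
    mse: float
    r2: float
    selected_features_per_fold: list  # list of {label: sign}
    permutation: Optional[PermutationResult] = None


@dataclass
class ProportionScore:
    unit: str
    count: float
    possible: int
    score: float
    sign: str = "all"
    p: Optional[float] = None
    p_fdr: Optional[float] = None


def engagement_at_windows(engagement: np.ndarray, fs_hz: float, centers_s) -> np.ndarray:
    """Sample an engagement trace at window-centre times."""
    eng = np.asarray(engagement, float)
    idx = np.clip(np.round(np.asarray(centers_s) * fs_hz).astype(int), 0, len(eng) - 1)
    return eng[idx]


def _corr_cols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X (windows x F) with y; NaN for flat columns."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (len(y) * sx * sy)
    r[sx == 0] = np.nan
    return np.clip(r, -1, 1)


def select_features(train_values: np.ndarray, engagement: np.ndarray,
                    alpha: float = 0.01, feature_labels=None):
    """Features consistently correlated with engagement across training subjects.

    Per feature: each training subject's window course is correlated with
    the engagement values, Fisher z-transformed, and the z's tested against
    zero with a one-sample t-test.  Features with p < alpha are kept; the
    sign is the sign of the mean z.  Returns (indices, signs) or, with
    labels, a dict label -> sign.
    """
    V = np.asarray(train_values, float)
    if V.ndim != 3 or V.shape[0] < 3:
        raise ValueError("need subjects x windows x features with >= 3 subjects")
    y = np.asarray(engagement, float)
    zs = np.stack([fisher_z(np.nan_to_num(_corr_cols(V[s], y), nan=0.0)) for s in range(V.shape[0])])
    flat = np.any([np.isnan(_corr_cols(V[s], y)) for s in range(V.shape[0])], axis=0)
    if flat.any():
        logger.warning("excluding %d zero-variance features from selection", int(flat.sum()))
    t, p = stats.ttest_1samp(zs, 0.0, axis=0)
    keep = (p < alpha) & ~flat
    idx = np.flatnonzero(keep)
    signs = np.sign(zs.mean(axis=0))[idx]
    if feature_labels is not None:
        return {feature_labels[i]: int(s) for i, s in zip(idx, signs)}
    return idx, signs


def _fit_fold(train_X, train_y, test_X, svr_params):
    mu, sd = train_X.mean(axis=0), train_X.std(axis=0)
    sd[sd == 0] = 1.0
    model = SVR(kernel="rbf", **svr_params)
    model.fit((train_X - mu) / sd, train_y)
    return model.predict((test_X - mu) / sd)


def loo_predict(
    features: FeatureTensor,
    engagement: np.ndarray,
    select: str = "on",
    alpha: float = 0.01,
    svr_params: Optional[dict] = None,
    empty_mode: str = "all",
) -> LooResult:
    """Leave-one-subject-out SVR prediction of window-wise engagement.

    ``engagement`` must already live on the tensor's window grid and is
    z-scored internally.  ``select`` toggles fold-wise feature selection;
    an empty selected set falls back to all features (``empty_mode='all'``)
    or skips the fold (``'skip'``).
    """
    svr_params = dict(C=1.0, epsilon=0.1, gamma="scale") | (svr_params or {})
    V = features.values
    S = V.shape[0]
    if S < 3:
        raise ValueError("LOO prediction needs at least 3 subjects")
    y = np.asarray(engagement, float)
    if len(y) != V.shape[1]:
        raise ValueError("engagement must be aligned to the window grid")
    sd = y.std()
    if sd == 0:
        raise ValueError("engagement is constant on this window grid")
    zy = (y - y.mean()) / sd
    fold_z, preds, selected = [], [], []
    for held in range(S):
        train_subjects = [s for s in range(S) if s != held]
        if select == "on":
            idx, signs = select_features(V[train_subjects], zy, alpha=alpha)
            selected.append(
                {features.feature_labels[i]: int(s) for i, s in zip(idx, signs)}
            )
            if len(idx) == 0:
                if empty_mode == "skip":
                    logger.warning("fold %d: empty selection, skipped", held)
                    fold_z.append(np.nan)
                    continue
                idx = np.arange(V.shape[2])
        else:
            idx = np.arange(V.shape[2])
            selected.append({})
        train_X = V[train_subjects][:, :, idx].reshape(-1, len(idx))
        train_y = np.tile(zy, len(train_subjects))
        pred = _fit_fold(train_X, train_y, V[held][:, idx], svr_params)
        preds.append(pred)
        if pred.std() == 0 or zy.std() == 0:
            fold_z.append(0.0)
        else:
            fold_z.append(float(fisher_z(np.corrcoef(pred, zy)[0, 1])))
    fold_z = np.asarray(fold_z, float)
    mean_r = float(inverse_fisher_z(np.nanmean(fold_z)))
    if preds:
        all_pred = np.concatenate(preds)
        mse = float(np.mean((all_pred - np.tile(zy, len(preds))) ** 2))
    else:
        mse = np.nan
    return LooResult(
        fold_r=fold_z,
        mean_r=mean_r,
        mse=mse,
        r2=1.0 - mse,
        selected_features_per_fold=selected,
    )


def permutation_null_prediction(
    features: FeatureTensor,
    engagement: np.ndarray,
    n_perm: int = 1000,
    seed=None,
    select: str = "on",
    alpha: float = 0.01,
    svr_params: Optional[dict] = None,
    fast_null_windows: Optional[int] = None,
    tails: str = "one",
) -> LooResult:
    """LOO prediction with a phase-randomised-engagement null.

    Each iteration re-runs the full train/test procedure (selection
    included) against a surrogate engagement trace.  ``fast_null_windows``
    re-fits the null (and the empirical statistic it is compared to) on an
    evenly spaced window subsample to keep the refit count tractable; the
    subsampling is applied identically to both, so the comparison is fair.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(engagement, float)
    if fast_null_windows is not None and fast_null_windows < features.values.shape[1]:
        idx = np.linspace(0, features.values.shape[1] - 1, fast_null_windows).astype(int)
        features = features.subset_windows(idx)
        y = y[idx]
    result = loo_predict(features, y, select=select, alpha=alpha, svr_params=svr_params)
    surrogates = phase_randomize_batch(y, n_perm, rng)
    null = np.empty(n_perm)
    for k in range(n_perm):
        if surrogates[k].std() == 0:
            null[k] = 0.0
            continue
        null[k] = loo_predict(
            features, surrogates[k], select=select, alpha=alpha, svr_params=svr_params
        ).mean_r
    result.permutation = PermutationResult(
        empirical_r=result.mean_r,
        null_r=null,
        n_perm=n_perm,
        p=permutation_p(result.mean_r, null, tails),
        tails=tails,
        r2=result.r2,
        mse=result.mse,
    )
    return result


def _block_of(label: str, region: dict) -> tuple:
    """Region block of a feature label ('A-B' pair -> region pair, else single)."""
    if "-" in label:
        a, b = label.split("-", 1)
        return tuple(sorted((region[a], region[b])))
    return (region[label],)


def proportion_scores(
    loo: LooResult,
    feature_labels: list,
    region: dict,
    n_perm: int = 1000,
    seed=None,
    q: float = 0.05,
) -> list:
    """Fold-selection frequency per region block, tested against random draws.

    Each feature label is assigned to a region block (region pair for
    channel-pair features, single region for node features).  The score of
    a block is the mean over folds of (selected features in block) /
    (possible features in block).  The null redraws each fold's selected
    set uniformly at random with the same size; p is one-tailed with
    BH-FDR across blocks.
    """
    rng = np.random.default_rng(seed)
    blocks = [_block_of(lab, region) for lab in feature_labels]
    unique_blocks = sorted(set(blocks))
    possible = {b: blocks.count(b) for b in unique_blocks}
    n_features = len(feature_labels)
    fold_sets = [set(d.keys()) for d in loo.selected_features_per_fold]
    n_folds = max(1, len(fold_sets))
    label_to_i = {lab: i for i, lab in enumerate(feature_labels)}

    def block_counts(index_sets):
        counts = dict.fromkeys(unique_blocks, 0.0)
        for s in index_sets:
            for i in s:
                counts[blocks[i]] += 1
        return counts

    obs_sets = [{label_to_i[l] for l in s} for s in fold_sets]
    obs = block_counts(obs_sets)
    scores = {b: obs[b] / (n_folds * possible[b]) for b in unique_blocks}
    sizes = [len(s) for s in obs_sets]
    null_scores = {b: np.empty(n_perm) for b in unique_blocks}
    for k in range(n_perm):
        rand_sets = [set(rng.choice(n_features, size=m, replace=False)) for m in sizes]
        counts = block_counts(rand_sets)
        for b in unique_blocks:
            null_scores[b][k] = counts[b] / (n_folds * possible[b])
    pvals = [
        permutation_p(scores[b], null_scores[b], tails="one") for b in unique_blocks
    ]
    p_adj, _ = bh_fdr(pvals, q)
    return [
        ProportionScore(
            unit="-".join(b),
            count=obs[b],
            possible=possible[b],
            score=scores[b],
            p=float(p),
            p_fdr=float(pa),
        )
        for b, p, pa in zip(unique_blocks, pvals, p_adj)
    ]


def per_phase_prediction(
    features: FeatureTensor,
    engagement: np.ndarray,
    segmentation: PhaseSegmentation,
    n_perm: int = 1000,
    seed=None,
    min_windows: int = 10,
    **loo_kwargs,
) -> dict:
    """Independent LOO prediction and permutation null per arc phase.

    Too-short or degenerate (constant-engagement) phases are skipped with a
    logged reason; BH-FDR runs across the tested phases.
    """
    rng = np.random.default_rng(seed)
    masks = segmentation.slices(features.window_centers_s)
    y = np.asarray(engagement, float)
    results: dict = {}
    tested = []
    for name, mask in masks.items():
        idx = np.flatnonzero(mask)
        if len(idx) < min_windows:
            logger.warning("phase %s: only %d windows, skipped", name, len(idx))
            results[name] = None
            continue
        if y[idx].std() == 0:
            logger.warning("phase %s: constant engagement, skipped", name)
            results[name] = None
            continue
        sub = features.subset_windows(idx)
        res = permutation_null_prediction(
            sub, y[idx], n_perm=n_perm, seed=rng.integers(2**31), **loo_kwargs
        )
        results[name] = res
        tested.append(name)
    if tested:
        p_adj, _ = bh_fdr([results[n].permutation.p for n in tested])
        for name, pa in zip(tested, p_adj):
            results[name].permutation.p_fdr = float(pa)
    return results
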