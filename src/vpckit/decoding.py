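"""Time-resolved Gaussian Bayesian decoding of VPC versus control stares.

The classifier models class-conditional densities as Gaussians with a shared
covariance (the unweighted mean of the two class covariances, shrinkage
regularized), with an uninformative prior; the posterior is a softmax over
theta_c(x) = W_c^T x + w_c0 with W_c = Sigma^{-1} mu_c and
w_c0 = -1/2 mu_c^T Sigma^{-1} mu_c.  Features are band-averaged LFP power
(5 bands x 5 areas = 25 features) per 1 s time bin on a -10.5 ... +4.5 s grid
around event onset.  Cross-validation uses repeated stratified 60/40 splits;
feature importance is mean decrease in accuracy under permutation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.model_selection import StratifiedShuffleSplit

from .spectral import DECODER_BANDS, band_average, spectrogram
from .stats import holm_bonferroni

DECODER_AREAS = ("CN", "F_s", "F_d", "L_s", "L_d")
SHRINKAGE_GRID = (0.0, 0.01, 0.1, 0.3, 0.5, 0.9)
TIME_GRID = np.round(np.arange(-10.5, 4.5 + 1e-9, 0.5), 3)   # 31 bins


@dataclass
class BayesModel:
    classes: np.ndarray
    means: np.ndarray                # n_classes x n_features
    cov: np.ndarray                  # shared, shrinkage-regularized
    weights: np.ndarray              # n_classes x n_features
    offsets: np.ndarray
    shrinkage: float = 0.0

    def decision(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.weights.shape[1]:
            raise ValueError(f"expected {self.weights.shape[1]} features, got {x.shape[1]}")
        return x @ self.weights.T + self.offsets


def _shrink(cov: np.ndarray, lam: float) -> np.ndarray:
    p = cov.shape[0]
    return (1 - lam) * cov + lam * (np.trace(cov) / p) * np.eye(p)


def fit_bayes(x: np.ndarray, y: np.ndarray, shrinkage: float | str = "auto",
              rng: np.random.Generator | int | None = None) -> BayesModel:
    """Fit the equal-covariance Gaussian classifier.

    ``shrinkage`` is either a fixed intensity in [0, 1] or "auto", in which
    case it is selected from a small grid by inner-loop validation accuracy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes in training data")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    if shrinkage == "auto":
        lam = _select_shrinkage(x, y, rng)
    else:
        lam = float(shrinkage)

    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    covs = [np.cov(x[y == c].T, ddof=1) for c in classes]
    cov = _shrink(np.mean([np.atleast_2d(c) for c in covs], axis=0), lam)
    weights = np.linalg.solve(cov, means.T).T
    offsets = -0.5 * np.einsum("ij,ij->i", means, weights)
    return BayesModel(classes=classes, means=means, cov=cov, weights=weights,
                      offsets=offsets, shrinkage=lam)


def _select_shrinkage(x: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator | int | None) -> float:
    rng = np.random.default_rng(rng)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 4:
        return 0.1
    splitter = StratifiedShuffleSplit(n_splits=5, train_size=0.6,
                                      random_state=int(rng.integers(2**31)))
    best_lam, best_acc = SHRINKAGE_GRID[0], -np.inf
    for lam in SHRINKAGE_GRID:
        accs = []
        for tr, te in splitter.split(x, y):
            try:
                m = fit_bayes(x[tr], y[tr], shrinkage=lam)
            except np.linalg.LinAlgError:
                accs.append(0.0)
                continue
            accs.append(float(np.mean(predict(m, x[te]) == y[te])))
        acc = np.mean(accs)
        if acc > best_acc + 1e-12:
            best_lam, best_acc = lam, acc
    return best_lam


def posterior(model: BayesModel, x: np.ndarray) -> np.ndarray:
    """Class posterior probabilities (rows sum to 1)."""
    theta = model.decision(x)
    theta = theta - theta.max(axis=1, keepdims=True)
    e = np.exp(theta)
    return e / e.sum(axis=1, keepdims=True)


def predict(model: BayesModel, x: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(model.decision(x), axis=1)]


# ---------------------------------------------------------------------------
# Feature construction

def build_features(event_arrays: dict, fs: float, channel_areas: pd.DataFrame,
                   t_range: tuple[float, float] = (-10.5, 4.5),
                   stride: float = 0.5) -> dict:
    """Band power features per time bin from event-aligned bipolar LFPs.

    ``event_arrays`` maps event id -> (channels x samples array, label); each
    array spans ``t_range`` around onset.  ``channel_areas`` provides a
    "part" column (CN, F_s, F_d, L_s, L_d) per channel; channels of other
    areas are ignored.  Returns ``{"times": grid, "X": bins x events x 25,
    "y": labels, "feature_names": [...]}``.  Events missing one of the five
    areas are excluded.
    """
    parts = channel_areas["part"].to_numpy()
    keep_areas = [a for a in DECODER_AREAS if np.any(parts == a)]
    if len(keep_areas) < len(DECODER_AREAS):
        import warnings
        missing = sorted(set(DECODER_AREAS) - set(keep_areas))
        warnings.warn(f"areas absent from channel table: {missing}")
    grid = np.round(np.arange(t_range[0], t_range[1] + 1e-9, stride), 3)
    names = [f"{a}_{b}" for a in keep_areas for b in DECODER_BANDS]
    rows, labels = [], []
    for key, (arr, label) in event_arrays.items():
        need = int(round((t_range[1] - t_range[0] + 1.0) * fs))
        if arr.shape[1] < need - int(fs):
            import warnings
            warnings.warn(f"event {key} does not cover the analysis range; excluded")
            continue
        feats = np.empty((len(grid), len(names)))
        col = 0
        for a in keep_areas:
            ch = np.nonzero(parts == a)[0]
            grams = [band_average(
                spectrogram(arr[c], fs, window=1.0, stride=stride, t0=t_range[0]),
                DECODER_BANDS) for c in ch]
            area_power = np.mean([g.values for g in grams], axis=0)
            times = grams[0].times - 0.5   # bin label = window start
            for bi in range(len(DECODER_BANDS)):
                feats[:, col] = np.interp(grid, times, area_power[:, bi])
                col += 1
        rows.append(feats)
        labels.append(label)
    if not rows:
        raise ValueError("no events usable for feature construction")
    X = np.stack(rows, axis=1)   # bins x events x features
    return {"times": grid, "X": X, "y": np.array(labels), "feature_names": names}


# ---------------------------------------------------------------------------
# Cross-validation and feature importance

@dataclass
class CVResult:
    accuracy: float
    se: float
    split_accuracies: np.ndarray
    shrinkage: float


def cross_validate(x: np.ndarray, y: np.ndarray, n_splits: int = 10,
                   train_frac: float = 0.6,
                   rng: np.random.Generator | int | None = None) -> CVResult:
    """Repeated stratified 60/40 splits; mean and SE of test accuracy."""
    rng = np.random.default_rng(rng)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) != 2 or counts.min() < 10:
        raise ValueError("need at least 10 samples per class")
    splitter = StratifiedShuffleSplit(n_splits=n_splits, train_size=train_frac,
                                      random_state=int(rng.integers(2**31)))
    accs, lams = [], []
    for tr, te in splitter.split(x, y):
        model = fit_bayes(x[tr], y[tr], shrinkage="auto", rng=rng)
        accs.append(float(np.mean(predict(model, x[te]) == y[te])))
        lams.append(model.shrinkage)
    accs = np.array(accs)
    return CVResult(accuracy=float(accs.mean()),
                    se=float(accs.std(ddof=1) / np.sqrt(len(accs))),
                    split_accuracies=accs, shrinkage=float(np.median(lams)))


def accuracy_significance(accuracies_per_bin: list, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """One-sample t-test of per-split accuracies against chance (0.5) per time
    bin, Holm-corrected across bins."""
    rows = []
    for i, accs in enumerate(accuracies_per_bin):
        accs = np.asarray(accs, dtype=float)
        if accs.std() == 0:
            t, p = (np.inf, 0.0) if accs.mean() != 0.5 else (0.0, 1.0)
        else:
            t, p = scipy_stats.ttest_1samp(accs, 0.5)
        rows.append({"bin": i, "accuracy": accs.mean(), "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    df["p_corrected"], df["significant"] = holm_bonferroni(df.p.to_numpy(), alpha)
    return df


def mda(x: np.ndarray, y: np.ndarray, n_perm: int = 1000, n_splits: int = 10,
        train_frac: float = 0.6, mode: str = "feature",
        rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Mean decrease in accuracy per feature.

    ``mode="feature"`` (default) permutes one feature's values across the test
    samples, erasing its relationship with the outcome and the other features;
    ``mode="label"`` instead permutes the labels of the test samples and
    reports the same contrast (a global, feature-unspecific variant).
    """
    rng = np.random.default_rng(rng)
    splitter = StratifiedShuffleSplit(n_splits=n_splits, train_size=train_frac,
                                      random_state=int(rng.integers(2**31)))
    n_features = x.shape[1]
    perm_per_split = max(1, n_perm // n_splits)
    base, drops = [], np.zeros((n_splits, n_features))
    perm_sd = np.zeros((n_splits, n_features))
    for si, (tr, te) in enumerate(splitter.split(x, y)):
        model = fit_bayes(x[tr], y[tr], shrinkage="auto", rng=rng)
        acc0 = float(np.mean(predict(model, x[te]) == y[te]))
        base.append(acc0)
        for f in range(n_features):
            accs = np.empty(perm_per_split)
            for p in range(perm_per_split):
                xt = x[te].copy()
                if mode == "feature":
                    xt[:, f] = xt[rng.permutation(len(te)), f]
                    yt = y[te]
                elif mode == "label":
                    yt = y[te][rng.permutation(len(te))]
                else:
                    raise ValueError("mode must be 'feature' or 'label'")
                accs[p] = float(np.mean(predict(model, xt) == yt))
            drops[si, f] = acc0 - accs.mean()
            perm_sd[si, f] = accs.std(ddof=1) if perm_per_split > 1 else np.nan
    return pd.DataFrame({
        "feature": np.arange(n_features),
        "mda": drops.mean(axis=0),
        "se": drops.std(axis=0, ddof=1) / np.sqrt(n_splits),
        "perm_sd": np.nanmean(perm_sd, axis=0),
        "baseline_accuracy": np.mean(base),
    })
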