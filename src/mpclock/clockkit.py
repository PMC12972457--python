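"""Cross-validated epigenetic clock training and evaluation.

The protocol is two-layered: an outer loop of resampled 75/25
train/test splits (default 100 iterations), and, within each training
split only, mutual-information feature pre-selection (Kraskov k-NN
estimate against age, threshold 0.20 nats) followed by elastic-net
regression with internal 2-fold cross-validation over the penalty
path.  Each iteration also fits null conditions on the identical
split: a dummy model predicting the training-mean age, and a permuted
model given age labels shuffled across samples before splitting.
Conditions are compared by one-way ANOVA plus Tukey HSD on the
distributions of test score (coefficient of determination) and test
MAE across iterations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import KNNImputer
from sklearn.linear_model import ElasticNetCV
from sklearn.metrics import mean_absolute_error, r2_score

from .config import ClockConfig
from .containers import BetaMatrix, ClockReplicate, EvaluationSummary
from .errors import InputError

logger = logging.getLogger(__name__)

#: conditions that are always evaluated alongside the data channels
NULL_CONDITIONS = ("dummy", "permuted")


# ---------------------------------------------------------------------------
# mutual information (Kraskov/KSG estimator, k nearest neighbours)

def ksg_mi(X: np.ndarray, y: np.ndarray, n_neighbors: int = 3, seed: int = 0) -> np.ndarray:
    """KSG mutual information of each column of ``X`` with ``y`` (nats).

    Vectorized over features: the univariate feature-vs-target case
    allows all pairwise Chebyshev distances to be formed by
    broadcasting, which makes thousands of loci per call cheap.
    Conventions follow the standard k-NN estimator: each marginal is
    variance-scaled first (the joint Chebyshev metric couples the two
    scales), the k-th-neighbour radius in the joint space is shrunk by
    one ulp, marginal neighbour counts use <= that radius excluding
    self, negative estimates clip to 0, and a tiny seeded noise (1e-10
    of the mean absolute value) breaks ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, n_features = X.shape
    if n <= n_neighbors:
        raise InputError(f"need more than {n_neighbors} samples, got {n}")
    if not np.isfinite(X).all():
        raise InputError("features contain non-finite values; impute first")
    rng = np.random.default_rng(seed)
    x_std = np.std(X, axis=0)
    X = X / np.where(x_std == 0, 1.0, x_std)
    y_std = np.std(y)
    y = y / (y_std if y_std > 0 else 1.0)
    X = X + 1e-10 * np.maximum(1.0, np.mean(np.abs(X), axis=0)) * rng.standard_normal(X.shape)
    y = y + 1e-10 * max(1.0, float(np.mean(np.abs(y)))) * rng.standard_normal(n)

    dy = np.abs(y[:, None] - y[None, :])  # (n, n)
    out = np.empty(n_features)
    base = digamma(n) + digamma(n_neighbors)
    diag = np.arange(n)
    chunk = max(1, int(2e7 // (n * n)))
    for start in range(0, n_features, chunk):
        xs = X[:, start : start + chunk].T  # (c, n)
        dx = np.abs(xs[:, :, None] - xs[:, None, :])  # (c, n, n)
        dz = np.maximum(dx, dy[None, :, :])
        dz[:, diag, diag] = np.inf
        radius = np.partition(dz, n_neighbors - 1, axis=2)[:, :, n_neighbors - 1]
        radius = np.nextafter(radius, 0)[:, :, None]
        nx = (dx <= radius).sum(axis=2) - 1
        ny = (dy[None, :, :] <= radius).sum(axis=2) - 1
        mi = base - (digamma(nx + 1) + digamma(ny + 1)).mean(axis=1)
        out[start : start + chunk] = np.maximum(0.0, mi)
    return out


def select_features_mi(
    train_matrix: BetaMatrix | pd.DataFrame,
    ages: pd.Series | np.ndarray,
    mi_threshold: float = 0.20,
    seed: int = 0,
) -> list[str]:
    """Loci whose estimated MI with age reaches ``mi_threshold``.

    ``train_matrix`` is loci x training-samples; the estimate must only
    ever see training samples (the caller guarantees the split).
    """
    values = train_matrix.values if isinstance(train_matrix, BetaMatrix) else train_matrix
    y = np.asarray(ages.to_numpy() if isinstance(ages, pd.Series) else ages, dtype=float)
    if values.shape[1] != len(y):
        raise InputError("number of samples differs between matrix and ages")
    if values.shape[1] < 8:
        raise InputError(f"need >= 8 training samples, got {values.shape[1]}")
    if np.ptp(y) == 0:
        raise InputError("training ages are constant; MI against age is undefined")
    if mi_threshold == float("inf"):
        return []
    mi = ksg_mi(values.to_numpy().T, y, n_neighbors=3, seed=seed)
    return [locus for locus, v in zip(values.index, mi) if v >= mi_threshold]


# ---------------------------------------------------------------------------
# imputation

def impute_missing(matrix: BetaMatrix, k: int = 5) -> BetaMatrix:
    """KNN-impute missing entries across samples.

    Neighbours are samples, compared by Euclidean distance over their
    shared observed loci; an imputed entry is the mean of the locus over
    the k nearest samples with an observed value.  Loci missing in all
    samples cannot be imputed and are dropped (logged).  Observed
    entries are returned unchanged.
    """
    if k <= 0:
        raise InputError("k must be positive")
    values = matrix.values
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d loci missing in all samples", int(all_missing.sum()))
        values = values[~all_missing]
    if not values.isna().to_numpy().any():
        return BetaMatrix(values=values.copy(), ages=matrix.ages.copy(), channel=matrix.channel)
    n_samples = values.shape[1]
    imputer = KNNImputer(n_neighbors=min(k, n_samples - 1), weights="uniform")
    imputed = imputer.fit_transform(values.to_numpy().T).T
    out = pd.DataFrame(imputed, index=values.index, columns=values.columns)
    return BetaMatrix(values=out, ages=matrix.ages.copy(), channel=matrix.channel)


# ---------------------------------------------------------------------------
# model fitting

def _mean_predictor_replicate(
    iteration: int,
    condition: str,
    y_train: np.ndarray,
    y_test: np.ndarray,
    train_samples: list[str],
    test_samples: list[str],
    selected: list[str] | None = None,
) -> ClockReplicate:
    mean_age = float(np.mean(y_train))
    pred = np.full(len(y_test), mean_age)
    return ClockReplicate(
        iteration=iteration,
        condition=condition,
        selected_loci=list(selected or []),
        coefficients=np.zeros(len(selected)) if selected else np.array([]),
        intercept=mean_age,
        test_score=float(r2_score(y_test, pred)),
        test_mae=float(mean_absolute_error(y_test, pred)),
        train_samples=train_samples,
        test_samples=test_samples,
        predictions=pd.Series(pred, index=test_samples),
    )


def fit_clock(
    X_train: pd.DataFrame,
    y_train: pd.Series | np.ndarray,
    config: ClockConfig,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | np.ndarray | None = None,
    iteration: int = 0,
    condition: str = "converted",
    seed: int | None = None,
) -> ClockReplicate:
    """Fit one elastic-net clock on pre-selected features.

    ``X_train``/``X_test`` are samples x features.  The penalty mixing
    and strength are chosen by ``cv_folds``-fold cross-validation within
    the training split only.  Non-convergence within
    ``max_iterations`` is recorded on the replicate, not raised.  With
    zero features the model degrades to the training-mean predictor.
    """
    y_train = np.asarray(y_train, dtype=float)
    if len(X_train) < 2 * config.cv_folds:
        raise InputError(
            f"need >= {2 * config.cv_folds} training samples for {config.cv_folds}-fold CV"
        )
    train_samples = list(X_train.index)
    test_samples = list(X_test.index) if X_test is not None else []
    y_test_arr = np.asarray(y_test, dtype=float) if y_test is not None else np.array([])
    if X_train.shape[1] == 0:
        return _mean_predictor_replicate(
            iteration, condition, y_train, y_test_arr, train_samples, test_samples
        )

    model = ElasticNetCV(
        l1_ratio=list(config.l1_ratios),
        cv=config.cv_folds,
        max_iter=config.max_iterations,
        random_state=seed if seed is not None else config.seed,
        alphas=60,  # length of the auto-scaled penalty-strength path
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X_train.to_numpy(), y_train)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)

    if X_test is not None and len(X_test):
        pred = model.predict(X_test.to_numpy())
        score = float(r2_score(y_test_arr, pred))
        mae = float(mean_absolute_error(y_test_arr, pred))
    else:
        pred, score, mae = np.array([]), float("nan"), 0.0
    return ClockReplicate(
        iteration=iteration,
        condition=condition,
        selected_loci=list(X_train.columns),
        coefficients=np.asarray(model.coef_),
        intercept=float(model.intercept_),
        test_score=score,
        test_mae=mae,
        train_samples=train_samples,
        test_samples=test_samples,
        predictions=pd.Series(pred, index=test_samples),
        converged=converged,
    )


def _fit_condition(
    values: pd.DataFrame,
    y: np.ndarray,
    samples: list[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ClockConfig,
    iteration: int,
    condition: str,
    mi_seed: int,
) -> ClockReplicate:
    """MI-select on the training split, then fit and score one clock."""
    train_samples = [samples[i] for i in train_idx]
    test_samples = [samples[i] for i in test_idx]
    y_train, y_test = y[train_idx], y[test_idx]
    train_block = values[train_samples]
    selected = select_features_mi(train_block, pd.Series(y_train, index=train_samples),
                                  config.mi_threshold, seed=mi_seed)
    if not selected:
        return _mean_predictor_replicate(
            iteration, condition, y_train, y_test, train_samples, test_samples
        )
    X_train = values.loc[selected, train_samples].T
    X_test = values.loc[selected, test_samples].T
    return fit_clock(
        X_train, y_train, config, X_test, y_test,
        iteration=iteration, condition=condition, seed=mi_seed,
    )


def repeated_evaluation(
    channels: dict[str, BetaMatrix], config: ClockConfig
) -> list[ClockReplicate]:
    """Run the resampled multi-condition clock protocol.

    Per iteration, every condition shares the identical train/test
    split: one clock per supplied channel, a ``both`` clock on the
    column-wise union of converted and unconverted features (labels
    tagged by channel), a ``dummy`` mean-age predictor, and a
    ``permuted`` clock (converted channel refit after shuffling age
    labels across samples).  All matrices must share samples and ages,
    with missing values already imputed.
    """
    if not channels:
        raise InputError("at least one channel is required")
    names = list(channels)
    ref = channels[names[0]]
    samples = ref.samples
    for name, bm in channels.items():
        if bm.samples != samples:
            raise InputError(f"channel {name!r} has mismatched samples")
        if not np.allclose(bm.ages.to_numpy(), ref.ages.to_numpy()):
            raise InputError(f"channel {name!r} has mismatched ages")
        if bm.values.isna().to_numpy().any():
            raise InputError(f"channel {name!r} has missing values; impute first")
    y = ref.ages.to_numpy(dtype=float)
    n = len(samples)
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, 2 * config.cv_folds), n - 1)

    both = None
    if "converted" in channels and "unconverted" in channels:
        both = pd.concat(
            [
                channels["converted"].values.rename(index=lambda s: f"conv:{s}"),
                channels["unconverted"].values.rename(index=lambda s: f"unconv:{s}"),
            ]
        )
    permute_base = "converted" if "converted" in channels else names[0]

    replicates: list[ClockReplicate] = []
    for i in range(config.n_iterations):
        rng = np.random.default_rng([int(config.seed), 1000 + i])
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        mi_seed = int(rng.integers(2**31 - 1))
        y_permuted = y[rng.permutation(n)]

        for name in names:
            replicates.append(
                _fit_condition(
                    channels[name].values, y, samples, train_idx, test_idx,
                    config, i, name, mi_seed,
                )
            )
        if both is not None:
            replicates.append(
                _fit_condition(
                    both, y, samples, train_idx, test_idx, config, i, "both", mi_seed
                )
            )
        replicates.append(
            _mean_predictor_replicate(
                i, "dummy", y[train_idx], y[test_idx],
                [samples[j] for j in train_idx], [samples[j] for j in test_idx],
            )
        )
        replicates.append(
            _fit_condition(
                channels[permute_base].values, y_permuted, samples,
                train_idx, test_idx, config, i, "permuted", mi_seed,
            )
        )
    return replicates


# ---------------------------------------------------------------------------
# comparison across conditions

def _metric_groups(
    replicates: list[ClockReplicate], metric: str
) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for rep in replicates:
        groups.setdefault(rep.condition, []).append(getattr(rep, metric))
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def compare_conditions(
    replicates: list[ClockReplicate], metric: str = "test_score", alpha: float = 0.05
) -> EvaluationSummary:
    """One-way ANOVA plus Tukey HSD across conditions for one metric.

    Conditions with a single replicate carry no variance information and
    are excluded (logged).  If every value is identical the ANOVA is
    reported as F = 0, p = 1 with no rejections.
    """
    if metric not in ("test_score", "test_mae"):
        raise InputError(f"unknown metric {metric!r}")
    groups = _metric_groups(replicates, metric)
    excluded = [k for k, v in groups.items() if len(v) < 2]
    for k in excluded:
        logger.info("excluding condition %r with n=%d from comparison", k, len(groups[k]))
        del groups[k]
    if len(groups) < 2:
        raise InputError("need >= 2 conditions with >= 2 replicates each")
    names = sorted(groups)
    arrays = [groups[k] for k in names]

    pooled = np.concatenate(arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if np.ptp(pooled) == 0:
        f_stat, p_val = 0.0, 1.0
        tukey = pd.DataFrame(
            [(a, b, 0.0, 1.0, False) for a, b in pairs],
            columns=["cond_a", "cond_b", "mean_diff", "p_adj", "reject"],
        )
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        hsd = stats.tukey_hsd(*arrays)
        rows = []
        for ia, a in enumerate(names):
            for ib in range(ia + 1, len(names)):
                b = names[ib]
                diff = float(np.mean(arrays[ia]) - np.mean(arrays[ib]))
                p_adj = float(hsd.pvalue[ia, ib])
                rows.append((a, b, diff, p_adj, p_adj < alpha))
        tukey = pd.DataFrame(rows, columns=["cond_a", "cond_b", "mean_diff", "p_adj", "reject"])
    return EvaluationSummary(
        metric=metric,
        groups=groups,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# age acceleration

def age_acceleration(replicate: ClockReplicate, ages: pd.Series) -> pd.Series:
    """Predicted minus chronological age for each test sample."""
    missing = [s for s in replicate.test_samples if s not in ages.index]
    if missing:
        raise InputError(f"ages missing for test samples {missing}")
    return replicate.predictions - ages.loc[replicate.test_samples]


def correlate_acceleration(resid_a: pd.Series, resid_b: pd.Series) -> tuple[float, float]:
    """Pearson r (and two-tailed p) of age acceleration across modalities.

    Computed over the shared samples; undefined (NaN, NaN) with fewer
    than 3 shared samples or zero variance.
    """
    common = resid_a.index.intersection(resid_b.index)
    if len(common) < 3:
        return float("nan"), float("nan")
    a = resid_a.loc[common].to_numpy(dtype=float)
    b = resid_b.loc[common].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def selected_union(replicates: list[ClockReplicate], condition: str) -> set[str]:
    """Loci selected in at least one replicate of a condition."""
    out: set[str] = set()
    for rep in replicates:
        if rep.condition == condition:
            out.update(rep.selected_loci)
    return out
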