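"""Amplitude-ratio features and O-PLS-DA with permutation validation.

Implements the discriminant-analysis pipeline applied to the extracted
biomarker amplitudes: ratio features (GlycB/SPC, GlycA/GlycB, SPC/GlycA,
SPC/(GlycA+GlycB)), mean centering with univariate (unit-variance) scaling,
orthogonal projections to latent structures discriminant analysis
(O-PLS-DA), stratified cross-validated Q², and label-permutation null
distributions for R²Y/Q². Class labels are coded y in {0, 1} and centered;
a fitted model reports R²Y (goodness of fit) and cross-validation reports
Q² (predictability); a valid model has Q² below R²Y and an original Q² well
above its permutation null.

The O-PLS deflation removes, before the final single predictive component,
score directions orthogonal to y. Because each orthogonal score t_o = X w_o
satisfies w_o ⟂ X'y, the orthogonal scores have exactly zero covariance
with y, and X'y — hence the predictive weight — is invariant under the
deflation. With n_ortho = 0 the model is exactly single-component PLS-DA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .craft_workflow import AmplitudeTable

__all__ = [
    "FeatureMatrix",
    "RatioSpec",
    "OplsModel",
    "PermutationReport",
    "BUILTIN_RATIOS",
    "build_features",
    "preprocess",
    "fit_opls_da",
    "cross_validate",
    "permutation_test",
    "exclude_outliers",
]

log = logging.getLogger(__name__)

CONTROL, CASE = 0, 1


@dataclass(frozen=True)
class RatioSpec:
    """A named amplitude ratio: sum(numerator) / sum(denominator)."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be non-empty")


#: The ratio features examined in the study, GlycB/SPC first (the best
#: separator among them).
BUILTIN_RATIOS: list[RatioSpec] = [
    RatioSpec("GlycB/SPC", ("GlycB",), ("SPC",)),
    RatioSpec("GlycA/GlycB", ("GlycA",), ("GlycB",)),
    RatioSpec("SPC/GlycA", ("SPC",), ("GlycA",)),
    RatioSpec("SPC/(GlycA+GlycB)", ("SPC",), ("GlycA", "GlycB")),
]


@dataclass
class FeatureMatrix:
    """Samples x features with binary class labels (control=0, case=1)."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("X shape inconsistent with names/ids")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if len(self.y) != len(self.sample_ids):
            raise ValueError("y length != number of samples")
        if self.X.shape[0] < 4:
            raise ValueError("need at least 4 samples")
        if self.X.shape[1] < 1:
            raise ValueError("need at least 1 feature")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.X[idx], list(self.feature_names), self.y[idx],
            [self.sample_ids[i] for i in idx],
        )


@dataclass
class OplsModel:
    """Fitted O-PLS-DA model: one predictive + n_ortho orthogonal components."""

    w: np.ndarray  # predictive weights (p,)
    p: np.ndarray  # predictive loadings (p,)
    q: float  # y-loading of the predictive score
    t: np.ndarray  # predictive scores on training data (n,)
    w_ortho: np.ndarray  # (n_ortho, p)
    p_ortho: np.ndarray  # (n_ortho, p)
    t_ortho: np.ndarray  # (n_ortho, n)
    means: np.ndarray
    scales: np.ndarray
    y_mean: float
    R2Y: float
    n_ortho: int
    feature_names: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores for (raw, unscaled) feature rows."""
        Xs = (np.atleast_2d(X) - self.means) / self.scales
        for wo, po in zip(self.w_ortho, self.p_ortho):
            t_o = Xs @ wo
            Xs = Xs - np.outer(t_o, po)
        return Xs @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class value; threshold at 0.5 for a call."""
        return self.transform(X) * self.q + self.y_mean


@dataclass
class PermutationReport:
    """Null R²Y/Q² distributions from label permutation."""

    n_perm: int
    permuted_R2Y: np.ndarray
    permuted_Q2: np.ndarray
    original_R2Y: float
    original_Q2: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.permuted_R2Y) != self.n_perm or len(self.permuted_Q2) != self.n_perm:
            raise ValueError("permuted lists must have length n_perm")

    def q2_percentile(self) -> float:
        """Fraction of the null Q² distribution below the original Q²."""
        return float(np.mean(self.permuted_Q2 < self.original_Q2))


def build_features(
    table: AmplitudeTable | pd.DataFrame,
    ratios: list[RatioSpec] | None = None,
    labels: dict[str, str] | pd.Series | None = None,
) -> FeatureMatrix:
    """Amplitude table -> ratio feature matrix.

    ``labels`` maps sample_id to "control"/"case" (or 0/1). Samples with any
    zero denominator are dropped with a logged warning.
    """
    ratios = ratios if ratios is not None else BUILTIN_RATIOS
    wide = table.to_wide() if isinstance(table, AmplitudeTable) else table
    available = set(wide.columns) - {"sample_id"}
    for spec in ratios:
        unknown = (set(spec.numerator) | set(spec.denominator)) - available
        if unknown:
            raise ValueError(
                f"ratio {spec.name!r} references unknown targets: {sorted(unknown)}"
            )
    cols = {}
    keep = np.ones(len(wide), dtype=bool)
    for spec in ratios:
        num = wide[list(spec.numerator)].sum(axis=1).to_numpy(float)
        den = wide[list(spec.denominator)].sum(axis=1).to_numpy(float)
        bad = den == 0
        if bad.any():
            dropped = wide.loc[bad, "sample_id"].tolist()
            log.warning("ratio %r: zero denominator for samples %s; dropped",
                        spec.name, dropped)
            keep &= ~bad
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[spec.name] = num / den
    wide = wide[keep]
    X = np.column_stack([cols[s.name][keep] for s in ratios])
    ids = wide["sample_id"].tolist()
    if labels is None:
        y = np.full(len(ids), np.nan)
    else:
        get = labels.get if hasattr(labels, "get") else labels.__getitem__
        coded = {"control": CONTROL, "case": CASE, 0: CONTROL, 1: CASE,
                 "0": CONTROL, "1": CASE}
        y = np.array([coded[get(i)] for i in ids], dtype=float)
    return FeatureMatrix(X, [s.name for s in ratios], y, ids)


def preprocess(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean centering + univariate (unit-variance) scaling, column-wise.

    Constant columns get scale 1 (with a warning) so they center to zero
    without dividing by zero. Returns (X_scaled, means, scales).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to scale")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    constant = scales == 0
    if constant.any():
        log.warning("%d constant feature column(s); scale forced to 1",
                    int(constant.sum()))
        scales = np.where(constant, 1.0, scales)
    return (X - means) / scales, means, scales


def _effective_n_ortho(n_ortho: int, n_features: int) -> int:
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_features == 1 and n_ortho > 0:
        log.warning("single feature: orthogonal components impossible; "
                    "n_ortho forced to 0 (model degenerates to PLS-DA)")
        return 0
    if n_ortho + 1 > n_features:
        raise ValueError(
            f"n_ortho={n_ortho} too large for {n_features} feature(s)"
        )
    return n_ortho


def fit_opls_da(F: FeatureMatrix, n_ortho: int = 0) -> OplsModel:
    """Fit O-PLS-DA: n_ortho orthogonal components + 1 predictive component."""
    classes = np.unique(F.y)
    if len(classes) < 2:
        raise ValueError("need two classes to fit a discriminant model")
    n_ortho = _effective_n_ortho(n_ortho, F.n_features)
    Xs, means, scales = preprocess(F.X)
    y_mean = float(F.y.mean())
    yc = F.y - y_mean

    w = Xs.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no covariance with y")
    w = w / norm

    X_work = Xs.copy()
    w_o_list, p_o_list, t_o_list = [], [], []
    for _ in range(n_ortho):
        t = X_work @ w
        p = X_work.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        no = np.linalg.norm(w_o)
        if no < 1e-12:
            log.warning("no orthogonal variation left; stopping at %d "
                        "orthogonal component(s)", len(w_o_list))
            break
        w_o /= no
        t_o = X_work @ w_o
        p_o = X_work.T @ t_o / (t_o @ t_o)
        X_work = X_work - np.outer(t_o, p_o)
        w_o_list.append(w_o)
        p_o_list.append(p_o)
        t_o_list.append(t_o)

    t = X_work @ w
    p = X_work.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    y_hat = t * q + y_mean
    ss_res = float(np.sum((F.y - y_hat) ** 2))
    ss_tot = float(np.sum(yc**2))
    r2y = 1 - ss_res / ss_tot
    n_feat, n_obs = F.n_features, F.n_samples
    return OplsModel(
        w=w, p=p, q=q, t=t,
        w_ortho=np.array(w_o_list, dtype=float).reshape(len(w_o_list), n_feat),
        p_ortho=np.array(p_o_list, dtype=float).reshape(len(p_o_list), n_feat),
        t_ortho=np.array(t_o_list, dtype=float).reshape(len(t_o_list), n_obs),
        means=means, scales=scales, y_mean=y_mean,
        R2Y=float(r2y), n_ortho=len(w_o_list),
        feature_names=list(F.feature_names),
    )


def cross_validate(
    F: FeatureMatrix, n_ortho: int = 0, n_folds: int = 7, seed: int = 0
) -> float:
    """Stratified k-fold cross-validated Q² = 1 - PRESS / SS_tot.

    The scaler and model are refit on every training fold; held-out samples
    are predicted with the training fold's preprocessing. Fold assignment is
    deterministic given ``seed``; folds that would isolate a single class
    are re-drawn (up to 10 attempts) before giving up.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = F.y
    press = 0.0
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed + attempt * 7919) % 2**31)
        try:
            splits = list(skf.split(F.X, y))
        except ValueError as exc:
            raise ValueError(f"cannot stratify {n_folds} folds: {exc}") from exc
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
    else:
        raise ValueError("could not draw folds with both classes present")
    press = 0.0
    for train_idx, test_idx in splits:
        model = fit_opls_da(F.subset(train_idx), n_ortho)
        y_pred = model.predict(F.X[test_idx])
        press += float(np.sum((y[test_idx] - y_pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1 - press / ss_tot


def permutation_test(
    F: FeatureMatrix, n_ortho: int = 0, n_perm: int = 50, seed: int = 0,
    n_folds: int = 7,
) -> PermutationReport:
    """Label-permutation null distribution of R²Y and Q².

    The identity permutation is excluded from the null draws. Deterministic
    given ``seed``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable null")
    rng = np.random.default_rng(seed)
    original = fit_opls_da(F, n_ortho)
    original_q2 = cross_validate(F, n_ortho, n_folds=n_folds, seed=seed)
    r2s, q2s = [], []
    while len(r2s) < n_perm:
        perm = rng.permutation(F.n_samples)
        y_perm = F.y[perm]
        if np.array_equal(y_perm, F.y):
            continue
        Fp = FeatureMatrix(F.X, list(F.feature_names), y_perm,
                           list(F.sample_ids))
        r2s.append(fit_opls_da(Fp, n_ortho).R2Y)
        cv_seed = int(rng.integers(0, 2**31 - 1))
        q2s.append(cross_validate(Fp, n_ortho, n_folds=n_folds, seed=cv_seed))
    return PermutationReport(
        n_perm=n_perm, permuted_R2Y=np.array(r2s), permuted_Q2=np.array(q2s),
        original_R2Y=original.R2Y, original_Q2=original_q2, seed=seed,
    )


def exclude_outliers(
    F: FeatureMatrix, threshold: float = 4.0, n_ortho: int = 0
) -> tuple[FeatureMatrix, list[str]]:
    """Iterative MAD-based outlier exclusion on predictive scores.

    Repeatedly fits a provisional model and removes the sample whose
    predictive-score deviation from the median most exceeds ``threshold``
    robust standard deviations (1.4826 x median absolute deviation). At most
    10% of samples are removable; excluded ids are returned, never silently
    dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    excluded: list[str] = []
    current = F
    max_removals = int(np.floor(0.10 * F.n_samples))
    while len(excluded) < max_removals:
        model = fit_opls_da(current, n_ortho)
        scores = model.t
        med = np.median(scores)
        mad = np.median(np.abs(scores - med)) * 1.4826
        if mad == 0:
            break
        dev = np.abs(scores - med) / mad
        worst = int(np.argmax(dev))
        if dev[worst] <= threshold:
            break
        excluded.append(current.sample_ids[worst])
        keep = [i for i in range(current.n_samples) if i != worst]
        current = current.subset(keep)
    if excluded:
        log.info("excluded %d outlier(s): %s", len(excluded), excluded)
    return current, excluded
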