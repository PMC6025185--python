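"""PSSM-profile scorer: auto-covariance features, per-term SVM classifiers,
and sigmoid calibration of margins into probabilities P3.

A PSSM profile is a variable-length L x 20 matrix of log-odds scores.  The
auto-covariance (AC) transform compresses it into a fixed-length vector:
for each of the 20 descriptor columns and each lag 1..l,

    AC(j, lag) = 1/(DL - lag) * sum_{i=1}^{DL-lag} (X_ij - Xbar_j)(X_{i+lag,j} - Xbar_j)

with Xbar_j the column mean over the full sequence and DL the sequence
length.  With the default lag l = 10 this yields 200 features per domain.
Cross-covariance between distinct descriptor columns is available behind a
flag (the full ACC feature set) but off by default.

One binary SVM is trained per GO term on the AC vectors; its margin f is
mapped to a probability with a sigmoid

    P3 = 1 / (1 + exp(A*f + B))

whose parameters (A, B) are fitted by the robust Newton procedure of
Lin, Lin & Weng (2007) on out-of-fold margins, with the usual
prior-smoothed targets.  A < 0 after a successful fit, so P3 increases
with the margin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .io_formats import PssmProfile

logger = logging.getLogger(__name__)

DEFAULT_LAG = 10


@dataclass(frozen=True)
class AccVector:
    """Fixed-length auto-covariance feature vector of one domain, ordered
    descriptor-major, lag-minor (col 0 lags 1..l, then col 1, ...)."""

    domain_id: str
    values: np.ndarray
    lag: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.domain_id}: non-finite AC values")


@dataclass
class SigmoidParams:
    term: str
    A: float
    B: float

    def probability(self, margin) -> np.ndarray | float:
        return _sigmoid(np.asarray(margin, dtype=float), self.A, self.B)


def _sigmoid(f, A, B):
    # numerically safe 1/(1+exp(A f + B)); scipy.special.expit of -z
    from scipy.special import expit

    z = np.asarray(A * f + B, dtype=float)
    return expit(-z)


def acc_transform(profile: PssmProfile, lag: int = DEFAULT_LAG,
                  cross: bool = False) -> AccVector:
    """Auto-covariance transform of a PSSM profile.

    Raises a length error when the sequence is not longer than the maximal
    lag.  With ``cross=True`` the cross-covariance terms between every
    ordered pair of distinct descriptor columns are appended (same
    1/(DL - lag) normalization).
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    X = np.asarray(profile.matrix, dtype=float)
    DL = X.shape[0]
    if DL <= lag:
        raise ValueError(
            f"domain {profile.domain_id!r}: sequence length {DL} must exceed lag {lag}"
        )
    centered = X - X.mean(axis=0, keepdims=True)
    vals = np.empty((20, lag), dtype=float)
    for k in range(1, lag + 1):
        prods = centered[:-k] * centered[k:]        # (DL-k, 20)
        vals[:, k - 1] = prods.sum(axis=0) / (DL - k)
    out = vals.ravel()  # descriptor-major, lag-minor
    if cross:
        cc = np.empty((20, 20, lag), dtype=float)
        for k in range(1, lag + 1):
            cc[:, :, k - 1] = centered[:-k].T @ centered[k:] / (DL - k)
        mask = ~np.eye(20, dtype=bool)
        out = np.concatenate([out, cc[mask].ravel()])
    return AccVector(profile.domain_id, out, lag)


# ---------------------------------------------------------------------------
# sigmoid calibration (Lin, Lin & Weng 2007 robust Newton)
# ---------------------------------------------------------------------------

def fit_sigmoid(margins, labels, max_iter: int = 100,
                min_step: float = 1e-10, tol: float = 1e-5) -> tuple[float, float]:
    """Fit (A, B) of P = 1/(1+exp(A f + B)) to margins and 0/1 labels.

    Robust Newton descent on the regularized maximum-likelihood problem,
    with prior-smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2).
    Returns A < 0 for any informative margin/label relation.
    """
    f = np.asarray(margins, dtype=float)
    y = np.asarray(labels)
    prior1 = int(np.sum(y == 1))
    prior0 = int(np.sum(y == 0))
    if prior1 == 0 or prior0 == 0:
        raise ValueError("sigmoid fit needs both positive and negative labels")
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)

    A = 0.0
    B = math.log((prior0 + 1.0) / (prior1 + 1.0))
    sigma = 1e-12  # Hessian ridge

    def objective(A, B):
        z = A * f + B
        # t*z + log(1+exp(-z)) computed stably for either sign of z
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1) * z + np.log1p(np.exp(z)))))

    fval = objective(A, B)
    for _ in range(max_iter):
        p = _sigmoid(f, A, B)
        d1 = t - p                       # gradient pieces
        g1 = float(np.sum(f * d1))
        g2 = float(np.sum(d1))
        if abs(g1) < tol and abs(g2) < tol:
            break
        d2 = p * (1 - p)
        h11 = float(np.sum(f * f * d2)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            newA, newB = A + step * dA, B + step * dB
            newf = objective(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            logger.debug("sigmoid line search stalled; returning current fit")
            break
    return A, B


# ---------------------------------------------------------------------------
# per-term classifiers
# ---------------------------------------------------------------------------

@dataclass
class TermClassifier:
    """A trained margin function plus calibration for one GO term."""

    term: str
    scaler: StandardScaler
    model: object
    sigmoid: SigmoidParams

    def margin(self, vectors: list[AccVector]) -> np.ndarray:
        X = np.vstack([v.values for v in vectors])
        if X.shape[1] != self.scaler.mean_.shape[0]:
            raise ValueError(
                f"feature length {X.shape[1]} != trained {self.scaler.mean_.shape[0]}"
            )
        return self.model.decision_function(self.scaler.transform(X))

    def probability(self, vectors: list[AccVector]) -> np.ndarray:
        return self.sigmoid.probability(self.margin(vectors))


@dataclass
class PssmTrainConfig:
    min_pos: int = 10
    min_neg: int = 10
    kernel: str = "linear"   # "linear" (LinearSVC) or "rbf"
    C: float = 1.0
    calibration_folds: int = 5
    seed: int = 0


def _make_svm(config: PssmTrainConfig):
    if config.kernel == "linear":
        return LinearSVC(C=config.C, random_state=config.seed)
    return SVC(kernel=config.kernel, C=config.C, random_state=config.seed)


def train_term_classifier(
    features: list[AccVector],
    labels: dict[str, int] | list[int],
    term: str,
    config: PssmTrainConfig | None = None,
) -> TermClassifier | None:
    """Train one binary SVM for ``term`` and calibrate its margin.

    ``labels`` is a 0/1 label per feature vector (dict keyed by domain id,
    or a parallel list).  Returns ``None`` when the positive/negative class
    floors are unmet (insufficient training data), logging the reason.
    Calibration (A, B) is fitted on out-of-fold margins from a stratified
    ``calibration_folds``-fold split to avoid optimistic probabilities.
    """
    config = config or PssmTrainConfig()
    if isinstance(labels, dict):
        y = np.array([labels[v.domain_id] for v in features], dtype=int)
    else:
        y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < config.min_pos or n_neg < config.min_neg:
        logger.info(
            "skipping term %s: %d positives / %d negatives below floor %d/%d",
            term, n_pos, n_neg, config.min_pos, config.min_neg,
        )
        return None

    X = np.vstack([v.values for v in features])
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    # out-of-fold margins for calibration
    n_folds = min(config.calibration_folds, n_pos, n_neg)
    oof = np.zeros(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    for train_idx, test_idx in skf.split(Xs, y):
        m = _make_svm(config).fit(Xs[train_idx], y[train_idx])
        oof[test_idx] = m.decision_function(Xs[test_idx])

    A, B = fit_sigmoid(oof, y)
    model = _make_svm(config).fit(Xs, y)
    return TermClassifier(term=term, scaler=scaler, model=model,
                          sigmoid=SigmoidParams(term=term, A=A, B=B))


class LinearMargin:
    """A deserialized linear decision function (coef . x + intercept)."""

    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def save_models(models: dict[str, TermClassifier], stream) -> None:
    """Serialize linear term models (+ scaler and sigmoid) to JSON text.

    Only linear margins serialize; kernel models must be retrained from the
    profiles instead.
    """
    import json

    payload = {}
    for term, clf in models.items():
        model = clf.model
        if isinstance(model, LinearSVC):
            coef, intercept = model.coef_.ravel(), float(model.intercept_[0])
        elif isinstance(model, LinearMargin):
            coef, intercept = model.coef, model.intercept
        else:
            raise NotImplementedError("only linear-kernel models serialize to JSON")
        payload[term] = {
            "A": clf.sigmoid.A, "B": clf.sigmoid.B,
            "coef": [float(c) for c in coef], "intercept": intercept,
            "scaler_mean": [float(v) for v in clf.scaler.mean_],
            "scaler_scale": [float(v) for v in clf.scaler.scale_],
        }
    json.dump(payload, stream, indent=1)


def load_models(stream) -> dict[str, TermClassifier]:
    import json

    payload = json.load(stream)
    out: dict[str, TermClassifier] = {}
    for term, p in payload.items():
        scaler = StandardScaler()
        scaler.mean_ = np.array(p["scaler_mean"])
        scaler.scale_ = np.array(p["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(p["scaler_mean"])
        out[term] = TermClassifier(
            term=term, scaler=scaler,
            model=LinearMargin(p["coef"], p["intercept"]),
            sigmoid=SigmoidParams(term=term, A=p["A"], B=p["B"]),
        )
    return out


def score_pssm(
    features: AccVector | list[AccVector],
    models: dict[str, TermClassifier],
) -> list[tuple[str, str, float]]:
    """Score domains against every calibrated term model.

    Returns (domain_id, term, p3) triples with p3 in (0, 1), strictly
    increasing in the margin whenever A < 0.
    """
    vectors = [features] if isinstance(features, AccVector) else list(features)
    if not vectors:
        return []
    out: list[tuple[str, str, float]] = []
    for term, clf in sorted(models.items()):
        probs = np.atleast_1d(clf.probability(vectors))
        for v, p in zip(vectors, probs):
            out.append((v.domain_id, term, float(p)))
    return out
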