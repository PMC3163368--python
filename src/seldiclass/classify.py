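"""Classifiers operating on selected-feature amplitude matrices.

Two models are provided:

* a feed-forward multilayer perceptron with one hidden layer (five sigmoid
  units by default) and a single sigmoid output, trained by full-batch
  gradient descent on the mean binary cross-entropy — the backpropagation
  gradients are derived and implemented here, not delegated;
* linear discriminant analysis: the maximum-posterior rule for two
  Gaussian classes sharing one pooled covariance matrix.  LDA requires
  fewer features than observations, which is enforced.

Features are standardized internally (training-set mean and SD stored in
the model) because raw SELDI intensities span orders of magnitude; the
stored constants make prediction self-contained.  Labels are the strings
``cancer`` (positive class) and ``control``; a score >= 0.5 classifies a
sample as cancer.

Models serialize to a small versioned plain-text key-value document so a
trained run is auditable with a pager.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    ConfigError,
    DataError,
    DimensionalityError,
    DivergenceError,
    FormatError,
    InsufficientDataError,
    NumericError,
    ShapeError,
)
from .spectra import CANCER, CONTROL

__all__ = [
    "TrainConfig",
    "MLPModel",
    "LDAModel",
    "mlp_forward",
    "mlp_loss_and_grads",
    "train_mlp",
    "train_lda",
    "predict",
    "save_model",
    "load_model",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def labels_to_binary(labels) -> np.ndarray:
    """Map cancer/control label strings to 1/0."""
    labels = np.asarray(labels)
    y = np.empty(labels.shape, dtype=float)
    for value in np.unique(labels):
        if value not in (CANCER, CONTROL):
            raise DataError(f"unknown class label {value!r}")
    y[:] = labels == CANCER
    return y


@dataclass(frozen=True)
class TrainConfig:
    """MLP training hyperparameters (all engineering choices, all exposed)."""

    hidden_size: int = 5
    learning_rate: float = 0.5
    max_epochs: int = 2000
    tol: float = 1e-6
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ConfigError("hidden_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")


@dataclass
class MLPModel:
    """Weights, biases and standardization constants of the trained MLP."""

    w1: np.ndarray  # (hidden, features)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    mean: np.ndarray  # per-feature standardization constants
    sd: np.ndarray
    feature_indices: tuple[int, ...] = ()
    feature_mz: tuple[float, ...] = ()

    @property
    def n_features(self) -> int:
        return self.w1.shape[1]

    @property
    def hidden_size(self) -> int:
        return self.w1.shape[0]


@dataclass
class LDAModel:
    """Class means, pooled covariance, priors and discriminant direction."""

    mean_cancer: np.ndarray
    mean_control: np.ndarray
    covariance: np.ndarray  # pooled within-class, shared by both classes
    prior_cancer: float
    direction: np.ndarray  # Sigma^{-1} (mu_cancer - mu_control)
    feature_indices: tuple[int, ...] = ()
    feature_mz: tuple[float, ...] = ()

    @property
    def n_features(self) -> int:
        return self.mean_cancer.size

    @property
    def prior_control(self) -> float:
        return 1.0 - self.prior_cancer


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------


def _check_matrix(x: np.ndarray, n_features: int) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != n_features:
        raise ShapeError(f"expected {n_features} features, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise DataError("feature matrix contains non-finite values")
    return x


def mlp_forward(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Cancer probability sigma(w2 . sigma(W1 x + b1) + b2) per sample.

    ``features`` may be one vector or a samples-by-features matrix; values
    are standardized with the model's stored training constants first.
    """
    single = np.asarray(features).ndim == 1
    x = _check_matrix(features, model.n_features)
    xs = (x - model.mean) / model.sd
    hidden = sigmoid(xs @ model.w1.T + model.b1)
    prob = sigmoid(hidden @ model.w2 + model.b2)
    return float(prob[0]) if single else prob


def mlp_loss_and_grads(
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: float,
    x: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, float]:
    """Mean cross-entropy and its analytic backprop gradients.

    The loss uses the logit form mean(softplus(z2) - y*z2), which equals
    the binary cross-entropy of sigmoid(z2) but stays finite for extreme
    logits.  Exposed so the gradients can be checked against finite
    differences.
    """
    n = x.shape[0]
    z1 = x @ w1.T + b1
    a1 = sigmoid(z1)
    z2 = a1 @ w2 + b2
    loss = float(np.mean(np.logaddexp(0.0, z2) - y * z2))
    dz2 = (sigmoid(z2) - y) / n  # (n,)
    g_w2 = a1.T @ dz2
    g_b2 = float(dz2.sum())
    dz1 = np.outer(dz2, w2) * a1 * (1.0 - a1)  # (n, hidden)
    g_w1 = dz1.T @ x
    g_b1 = dz1.sum(axis=0)
    return loss, g_w1, g_b1, g_w2, g_b2


def train_mlp(
    features_matrix: np.ndarray,
    labels,
    config: TrainConfig = TrainConfig(),
    feature_indices: tuple[int, ...] = (),
    feature_mz: tuple[float, ...] = (),
) -> tuple[MLPModel, list[float]]:
    """Train the one-hidden-layer MLP by full-batch gradient descent.

    Weights start uniform(-init_scale, init_scale) from a seeded stream;
    descent stops when the loss change falls below ``tol`` or after
    ``max_epochs``.  Returns the model and the per-epoch loss trace.
    """
    x = np.atleast_2d(np.asarray(features_matrix, dtype=float))
    y = labels_to_binary(labels)
    if y.size != x.shape[0]:
        raise ShapeError(f"{x.shape[0]} samples but {y.size} labels")
    if np.all(y == 1) or np.all(y == 0):
        raise InsufficientDataError("training needs samples from both classes")
    if not np.all(np.isfinite(x)):
        raise DataError("feature matrix contains non-finite values")

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    xs = (x - mean) / sd

    rng = np.random.default_rng(config.seed)
    h, d = config.hidden_size, x.shape[1]
    s = config.init_scale
    w1 = rng.uniform(-s, s, size=(h, d))
    b1 = rng.uniform(-s, s, size=h)
    w2 = rng.uniform(-s, s, size=h)
    b2 = float(rng.uniform(-s, s))

    losses: list[float] = []
    prev = np.inf
    for epoch in range(config.max_epochs):
        loss, g_w1, g_b1, g_w2, g_b2 = mlp_loss_and_grads(w1, b1, w2, b2, xs, y)
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        losses.append(loss)
        w1 -= config.learning_rate * g_w1
        b1 -= config.learning_rate * g_b1
        w2 -= config.learning_rate * g_w2
        b2 -= config.learning_rate * g_b2
        if abs(prev - loss) < config.tol:
            break
        prev = loss
    model = MLPModel(
        w1=w1, b1=b1, w2=w2, b2=b2, mean=mean, sd=sd,
        feature_indices=tuple(int(i) for i in feature_indices),
        feature_mz=tuple(float(v) for v in feature_mz),
    )
    return model, losses


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def train_lda(
    features_matrix: np.ndarray,
    labels,
    ridge: float | None = None,
    feature_indices: tuple[int, ...] = (),
    feature_mz: tuple[float, ...] = (),
) -> LDAModel:
    """Fit two-class LDA with a pooled within-class covariance.

    The feature count must be strictly smaller than the number of
    observations — with p >= n the pooled covariance is singular and the
    discriminant is undefined.  ``ridge`` (a fraction, e.g. 1e-6) adds
    lambda*I with lambda = ridge * trace(Sigma)/p to stabilize a
    near-singular covariance; left at None, a singular matrix raises.
    """
    x = np.atleast_2d(np.asarray(features_matrix, dtype=float))
    y = labels_to_binary(labels)
    n, p = x.shape
    if y.size != n:
        raise ShapeError(f"{n} samples but {y.size} labels")
    if p >= n:
        raise DimensionalityError(
            f"LDA needs fewer features than observations; got p={p}, n={n}"
        )
    n_can = int(y.sum())
    n_con = n - n_can
    if n_can < 1 or n_con < 1:
        raise InsufficientDataError("LDA needs samples from both classes")
    xc = x[y == 1]
    xn = x[y == 0]
    mu_c = xc.mean(axis=0)
    mu_n = xn.mean(axis=0)
    scatter = (xc - mu_c).T @ (xc - mu_c) + (xn - mu_n).T @ (xn - mu_n)
    cov = scatter / (n - 2)
    if ridge is not None:
        cov = cov + (ridge * np.trace(cov) / p) * np.eye(p)
    try:
        direction = np.linalg.solve(cov, mu_c - mu_n)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"pooled covariance is singular: {exc}") from exc
    return LDAModel(
        mean_cancer=mu_c,
        mean_control=mu_n,
        covariance=cov,
        prior_cancer=n_can / n,
        direction=direction,
        feature_indices=tuple(int(i) for i in feature_indices),
        feature_mz=tuple(float(v) for v in feature_mz),
    )


def lda_posterior(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Posterior probability of the cancer class under the shared-covariance
    Gaussian model (posteriors over the two classes sum to 1)."""
    single = np.asarray(features).ndim == 1
    x = _check_matrix(features, model.n_features)
    # log-posterior difference reduces to a linear score for shared Sigma
    mid = 0.5 * (model.mean_cancer + model.mean_control)
    score = (x - mid) @ model.direction + np.log(
        model.prior_cancer / model.prior_control
    )
    post = sigmoid(score)
    return float(post[0]) if single else post


# ---------------------------------------------------------------------------
# Unified prediction
# ---------------------------------------------------------------------------


def predict(model, features_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and scores for either model type.

    The score is the cancer probability (MLP output, or LDA posterior);
    a score of exactly 0.5 classifies as cancer — the documented tie rule.
    """
    if isinstance(model, MLPModel):
        scores = np.atleast_1d(mlp_forward(model, features_matrix))
    elif isinstance(model, LDAModel):
        scores = np.atleast_1d(lda_posterior(model, features_matrix))
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    labels = np.where(scores >= 0.5, CANCER, CONTROL)
    return labels, scores


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

_FORMAT_MLP = "seldiclass-mlp-v1"
_FORMAT_LDA = "seldiclass-lda-v1"


def _fmt_vector(v: np.ndarray) -> str:
    return " ".join(repr(float(x)) for x in np.asarray(v, dtype=float).ravel())


def _fmt_matrix(m: np.ndarray) -> str:
    return ";".join(_fmt_vector(row) for row in np.atleast_2d(m))


def _parse_vector(text: str) -> np.ndarray:
    return np.array([float(tok) for tok in text.split()]) if text.strip() else np.array([])


def _parse_matrix(text: str) -> np.ndarray:
    return np.vstack([_parse_vector(row) for row in text.split(";")])


def save_model(path: Path | str, model) -> None:
    """Write a model as a versioned plain-text key-value document."""
    lines: list[str] = []
    if isinstance(model, MLPModel):
        lines.append(f"format: {_FORMAT_MLP}")
        lines.append(f"hidden_size: {model.hidden_size}")
        lines.append(f"w1: {_fmt_matrix(model.w1)}")
        lines.append(f"b1: {_fmt_vector(model.b1)}")
        lines.append(f"w2: {_fmt_vector(model.w2)}")
        lines.append(f"b2: {model.b2!r}")
        lines.append(f"mean: {_fmt_vector(model.mean)}")
        lines.append(f"sd: {_fmt_vector(model.sd)}")
    elif isinstance(model, LDAModel):
        lines.append(f"format: {_FORMAT_LDA}")
        lines.append(f"mean_cancer: {_fmt_vector(model.mean_cancer)}")
        lines.append(f"mean_control: {_fmt_vector(model.mean_control)}")
        lines.append(f"covariance: {_fmt_matrix(model.covariance)}")
        lines.append(f"prior_cancer: {model.prior_cancer!r}")
        lines.append(f"direction: {_fmt_vector(model.direction)}")
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    lines.append("feature_indices: " + " ".join(str(i) for i in model.feature_indices))
    lines.append("feature_mz: " + " ".join(repr(v) for v in model.feature_mz))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: Path | str):
    """Read back a model written by :func:`save_model`."""
    fields: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if ": " not in line and not line.endswith(":"):
            raise FormatError(f"{path}: malformed line {lineno}: {line!r}")
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    fmt = fields.get("format")
    indices = tuple(int(t) for t in fields.get("feature_indices", "").split())
    mzs = tuple(float(t) for t in fields.get("feature_mz", "").split())
    if fmt == _FORMAT_MLP:
        return MLPModel(
            w1=_parse_matrix(fields["w1"]),
            b1=_parse_vector(fields["b1"]),
            w2=_parse_vector(fields["w2"]),
            b2=float(fields["b2"]),
            mean=_parse_vector(fields["mean"]),
            sd=_parse_vector(fields["sd"]),
            feature_indices=indices,
            feature_mz=mzs,
        )
    if fmt == _FORMAT_LDA:
        mu_c = _parse_vector(fields["mean_cancer"])
        mu_n = _parse_vector(fields["mean_control"])
        return LDAModel(
            mean_cancer=mu_c,
            mean_control=mu_n,
            covariance=_parse_matrix(fields["covariance"]),
            prior_cancer=float(fields["prior_cancer"]),
            direction=_parse_vector(fields["direction"]),
            feature_indices=indices,
            feature_mz=mzs,
        )
    raise FormatError(f"{path}: unknown model format {fmt!r}")
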