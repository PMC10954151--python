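"""Feed-forward network linking meteorology to element concentrations.

A small multilayer perceptron (nine covariates -> two sigmoid hidden
layers -> one sigmoid output) is trained per target with full-batch
gradient descent on SSE = sum((y - yhat)^2) / 2, an adaptive ("bold
driver") step size that keeps the training loss monotone non-increasing,
and early stopping on validation SSE.  Covariates are standardised and
the target min-max scaled into (eps, 1-eps) so the sigmoid output can
attain it.  Covariate influence is measured by permutation importance
(mean increase in test SSE when one covariate is shuffled), normalised so
the most influential covariate scores exactly 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError
from .synth import MET_COLUMNS


@dataclass(frozen=True)
class AnnConfig:
    hidden: tuple[int, int] = (4, 3)
    train_fraction: float = 0.7
    seed: int = 0
    max_epochs: int = 2000
    learning_rate: float = 0.5
    patience: int = 50
    importance_reps: int = 30
    eps: float = 0.01          # target scaled into (eps, 1 - eps)

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if len(self.hidden) != 2 or any(h < 1 for h in self.hidden):
            raise ValidationError("two positive hidden-layer sizes required")


@dataclass
class Design:
    """Scaled covariates and target, with the scalers kept for inversion."""

    X: np.ndarray                 # n x m standardized covariates
    y: np.ndarray                 # n, scaled to (eps, 1-eps)
    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_min: float
    y_max: float
    eps: float

    def inverse_y(self, y_scaled: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min
        return (y_scaled - self.eps) / (1 - 2 * self.eps) * span + self.y_min


def prepare_features(met: pd.DataFrame, target, eps: float = 0.01,
                     covariates=MET_COLUMNS) -> Design:
    """Standardise covariates; min-max the target into (eps, 1-eps)."""
    missing = [c for c in covariates if c not in met.columns]
    if missing:
        raise ValidationError(f"missing covariate column(s): {missing}")
    X = met[list(covariates)].to_numpy(float)
    y = np.asarray(target, float)
    if len(y) != len(X):
        raise ValidationError("target length must match covariate table")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = [covariates[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValidationError(f"constant covariate(s): {bad}")
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        y_scaled = np.full_like(y, 0.5)
    else:
        y_scaled = eps + (1 - 2 * eps) * (y - y_min) / (y_max - y_min)
    return Design((X - mean) / sd, y_scaled, tuple(covariates),
                  mean, sd, y_min, y_max, eps)


def split_train_test(n: int, fraction: float = 0.7, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random index partition with round(fraction * n) training rows."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie in (0, 1)")
    if n < 10:
        raise ValidationError("need at least 10 samples to split")
    n_train = min(n - 1, max(1, round(fraction * n)))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def sse(y, yhat) -> float:
    """Half the summed squared error (the training loss)."""
    return float(0.5 * np.sum((np.asarray(y) - np.asarray(yhat)) ** 2))


def relative_error(y, yhat) -> float:
    """Squared error relative to the mean model: SSE / TSS = 1 - R^2."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if len(y) < 2 or len(y) != len(yhat):
        raise ValidationError("need two same-length vectors")
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        warnings.warn("zero target variance: relative error undefined",
                      RuntimeWarning)
        return float("nan")
    return float(np.sum((y - yhat) ** 2) / tss)


class Mlp:
    """Two-hidden-layer perceptron, sigmoid throughout, seed-deterministic."""

    def __init__(self, n_inputs: int, hidden: tuple[int, int], seed: int = 0):
        rng = np.random.default_rng(seed)
        sizes = (n_inputs, *hidden, 1)
        self.weights = [rng.normal(0.0, 1.0 / np.sqrt(sizes[i]),
                                   (sizes[i], sizes[i + 1]))
                        for i in range(len(sizes) - 1)]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.history: list[float] = []

    def _forward(self, X):
        acts = [np.asarray(X, float)]
        for W, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ W + b))
        return acts

    def predict(self, X) -> np.ndarray:
        return self._forward(X)[-1].ravel()

    def _gradients(self, X, y):
        acts = self._forward(X)
        out = acts[-1]
        delta = (out - y[:, None]) * out * (1 - out)
        gW, gb = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            gW.append(acts[layer].T @ delta)
            gb.append(delta.sum(axis=0))
            if layer > 0:
                a = acts[layer]
                delta = (delta @ self.weights[layer].T) * a * (1 - a)
        return gW[::-1], gb[::-1]

    def fit(self, X, y, X_val=None, y_val=None, lr: float = 0.5,
            max_epochs: int = 2000, patience: int = 50) -> "Mlp":
        """Full-batch gradient descent; steps that would raise the training
        loss are rejected and the step size halved, so the recorded loss is
        non-increasing.  With validation data, stops after ``patience``
        epochs without validation improvement and restores the best state."""
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        loss = sse(y, self.predict(X))
        if not np.isfinite(loss):
            raise ValidationError("non-finite loss at initialisation")
        best_val = np.inf
        best_state = None
        stall = 0
        self.history = [loss]
        for _ in range(max_epochs):
            gW, gb = self._gradients(X, y)
            stepped = False
            while lr > 1e-12:
                trial_W = [W - lr * g for W, g in zip(self.weights, gW)]
                trial_b = [b - lr * g for b, g in zip(self.biases, gb)]
                saved = (self.weights, self.biases)
                self.weights, self.biases = trial_W, trial_b
                new_loss = sse(y, self.predict(X))
                if np.isfinite(new_loss) and new_loss <= loss:
                    loss = new_loss
                    lr *= 1.05
                    stepped = True
                    break
                self.weights, self.biases = saved
                lr *= 0.5
            self.history.append(loss)
            if not stepped:
                break
            if X_val is not None and len(np.asarray(X_val)):
                val = sse(np.asarray(y_val, float), self.predict(X_val))
                if val < best_val - 1e-12:
                    best_val = val
                    best_state = ([W.copy() for W in self.weights],
                                  [b.copy() for b in self.biases])
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
        if best_state is not None:
            self.weights, self.biases = best_state
        return self


@dataclass
class FittedNetwork:
    net: Mlp
    design: Design
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: AnnConfig

    @property
    def train_pct(self) -> float:
        return 100.0 * len(self.train_idx) / len(self.design.y)

    @property
    def test_pct(self) -> float:
        return 100.0 * len(self.test_idx) / len(self.design.y)

    def summary(self) -> dict:
        d = self.design
        yhat_tr = self.net.predict(d.X[self.train_idx])
        yhat_te = self.net.predict(d.X[self.test_idx])
        return {
            "train_pct": self.train_pct, "test_pct": self.test_pct,
            "train_sse": sse(d.y[self.train_idx], yhat_tr),
            "test_sse": sse(d.y[self.test_idx], yhat_te),
            "train_relative_error": relative_error(d.y[self.train_idx], yhat_tr),
            "test_relative_error": relative_error(d.y[self.test_idx], yhat_te),
        }


def train_mlp(design: Design, cfg: AnnConfig | None = None) -> FittedNetwork:
    cfg = cfg or AnnConfig()
    n = len(design.y)
    tr, te = split_train_test(n, cfg.train_fraction, cfg.seed)
    net = Mlp(design.X.shape[1], cfg.hidden, seed=cfg.seed)
    net.fit(design.X[tr], design.y[tr], design.X[te], design.y[te],
            lr=cfg.learning_rate, max_epochs=cfg.max_epochs,
            patience=cfg.patience)
    return FittedNetwork(net, design, tr, te, cfg)


def variable_importance(fitted: FittedNetwork, reps: int | None = None,
                        seed: int | None = None) -> dict[str, float]:
    """Permutation importance on the test split, normalised to max = 100.

    For each covariate the increase in test SSE under ``reps`` independent
    permutations of that column is averaged; negative means are clipped to
    zero; the largest (first, on ties) covariate is scaled to exactly 100.
    """
    cfg = fitted.config
    reps = cfg.importance_reps if reps is None else reps
    if reps < 1:
        raise ValidationError("need at least one permutation repetition")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    d = fitted.design
    Xte = d.X[fitted.test_idx]
    yte = d.y[fitted.test_idx]
    base = sse(yte, fitted.net.predict(Xte))
    raw = np.zeros(len(d.feature_names))
    for j in range(len(d.feature_names)):
        deltas = []
        for _ in range(reps):
            Xp = Xte.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(sse(yte, fitted.net.predict(Xp)) - base)
        raw[j] = max(0.0, float(np.mean(deltas)))
    if raw.max() == 0:
        norm = np.zeros_like(raw)
        norm[0] = 100.0
    else:
        norm = raw / raw.max() * 100.0
        top = int(np.argmax(raw))          # ties broken by covariate order
        for j in np.nonzero(raw == raw.max())[0]:
            if j != top:
                norm[j] = np.nextafter(100.0, 0.0)
        norm[top] = 100.0
    return dict(zip(d.feature_names, norm))


def ann_table(met: pd.DataFrame, targets: pd.DataFrame,
              cfg: AnnConfig | None = None) -> pd.DataFrame:
    """Per-target model summaries plus normalised covariate importance,
    one column per target (the layout of the campaign's network table)."""
    cfg = cfg or AnnConfig()
    rows = {}
    for col in targets.columns:
        design = prepare_features(met, targets[col].to_numpy(float), eps=cfg.eps)
        fitted = train_mlp(design, cfg)
        info = fitted.summary()
        info.update({f"importance_{k}": v
                     for k, v in variable_importance(fitted).items()})
        rows[col] = info
    return pd.DataFrame(rows)
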