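"""Multi-layer perceptron surrogate for transfer times and efficiencies.

The network maps a flattened Frenkel Hamiltonian to the pair
(transfer time, efficiency).  The output layer always uses the softplus
activation so predictions are strictly positive; hidden layers choose from
five activations.  Training minimizes, by default, the mean squared *relative*
residual on scaled targets — the L2 form of the relative-error metric used
for validation — plus an L2 penalty on all hidden-layer weights (output
weights are exempt), with the ADAM optimizer, mini-batches of 200, and
early stopping
once the validation relative error has increased over three full
consecutive epochs; the best-validation weights are restored.

Hyperparameters (learning rate, L2 strength, number of layers, neurons per
layer, per-layer activation, number of training points) are searched with
Gaussian-process Bayesian optimization using expected improvement, with a
random-search fallback for quick runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from scipy.stats import norm, qmc

from .dataset import ScalerPair, fit_scalers

__all__ = [
    "ACTIVATIONS",
    "MLPSurrogate",
    "HyperparameterSpace",
    "bayes_optimize",
    "validation_relative_error",
    "save_model",
    "load_model",
]


def _softplus(x):
    return np.logaddexp(0.0, x)


ACTIVATIONS = {
    "rectifier": (lambda x: np.maximum(x, 0.0), lambda x, a: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a ** 2),
    "logistic": (expit, lambda x, a: a * (1.0 - a)),
    "softsign": (lambda x: x / (1.0 + np.abs(x)),
                 lambda x, a: 1.0 / (1.0 + np.abs(x)) ** 2),
    "softplus": (_softplus, lambda x, a: expit(x)),
}


def validation_relative_error(predicted, reference) -> float:
    """Mean relative absolute error over all targets (fraction, not %)."""
    predicted = np.atleast_2d(predicted)
    reference = np.atleast_2d(reference)
    return float(np.mean(np.abs(predicted - reference) / np.abs(reference)))


class MLPSurrogate(BaseEstimator, RegressorMixin):
    """Feed-forward network predicting (transfer_time_ps, efficiency).

    Parameters follow scikit-learn conventions; fitted state lives in
    trailing-underscore attributes.  ``fit`` accepts an explicit validation
    set (the protocol used throughout); without one a fraction of the
    training data is held out.

    Parameters
    ----------
    hidden_widths : tuple of int
        Neurons per hidden layer.
    activations : tuple of str
        One activation name per hidden layer (see :data:`ACTIVATIONS`).
    learning_rate : float
        Initial ADAM learning rate ``mu``.
    l2 : float
        L2 strength on hidden-layer weights (output weights exempt).
    batch_size, max_epochs, patience : int
        Mini-batch size, epoch cap, and the early-stopping patience in
        consecutive epochs of increasing validation error.
    seed : int
        Seeds weight initialization and batch shuffling.
    loss : {"relative_mse", "mse"}
        Training loss on scaled targets: squared relative residuals
        (default, aligned with the relative-error validation metric) or
        plain squared error.
    """

    def __init__(self, hidden_widths=(512,), activations=("rectifier",),
                 learning_rate=3e-4, l2=1e-4, batch_size=200, max_epochs=600,
                 patience=3, seed=0, val_fraction=0.1, loss="relative_mse"):
        self.hidden_widths = hidden_widths
        self.activations = activations
        self.learning_rate = learning_rate
        self.l2 = l2
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.val_fraction = val_fraction
        self.loss = loss

    # -- architecture -----------------------------------------------------
    def _layer_dims(self, n_in):
        return [n_in, *self.hidden_widths, 2]

    def _init_weights(self, n_in, rng):
        dims = self._layer_dims(n_in)
        weights, biases = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / (a + b))  # Glorot
            weights.append(rng.normal(0.0, scale, size=(a, b)))
            biases.append(np.zeros(b))
        return weights, biases

    def _forward(self, X, weights, biases):
        acts = [X]
        pres = []
        names = [*self.activations, "softplus"]
        h = X
        for W, b, name in zip(weights, biases, names):
            z = h @ W + b
            h = ACTIVATIONS[name][0](z)
            pres.append(z)
            acts.append(h)
        return pres, acts

    # -- training ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(int(len(X) * self.val_fraction), 1)
            order = rng.permutation(len(X))
            X_val, y_val = X[order[:n_val]], y[order[:n_val]]
            X, y = X[order[n_val:]], y[order[n_val:]]
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        if self.loss not in ("relative_mse", "mse"):
            raise ValueError(f"unknown loss '{self.loss}'")
        if len(self.activations) != len(self.hidden_widths):
            raise ValueError("need one activation per hidden layer")
        for name in self.activations:
            if name not in ACTIVATIONS:
                raise ValueError(f"unknown activation '{name}'")

        self.scalers_ = fit_scalers(X, y)
        Xs = self.scalers_.transform_features(X)
        ys = self.scalers_.transform_targets(y)
        Xv = self.scalers_.transform_features(X_val)

        self.n_features_in_ = X.shape[1]
        weights, biases = self._init_weights(X.shape[1], rng)

        # ADAM state
        mw = [np.zeros_like(w) for w in weights]
        vw = [np.zeros_like(w) for w in weights]
        mb = [np.zeros_like(b) for b in biases]
        vb = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_adam = 0

        names = [*self.activations, "softplus"]
        n = len(Xs)
        history = {"train_loss": [], "val_error": []}
        best_err = np.inf
        best_state = None
        increases = 0
        prev_err = None

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = Xs[idx], ys[idx]
                pres, acts = self._forward(xb, weights, biases)
                diff = acts[-1] - yb
                if self.loss == "relative_mse":
                    rel = diff / yb  # scaled targets are strictly positive
                    loss = np.mean(rel ** 2)
                    grad = 2.0 * rel / yb / rel.size
                else:
                    loss = np.mean(diff ** 2)
                    grad = 2.0 * diff / diff.size
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (learning rate {self.learning_rate})")
                epoch_loss += loss * len(idx)
                gw, gb = [None] * len(weights), [None] * len(weights)
                for li in range(len(weights) - 1, -1, -1):
                    dz = grad * ACTIVATIONS[names[li]][1](pres[li], acts[li + 1])
                    gw[li] = acts[li].T @ dz
                    gb[li] = dz.sum(axis=0)
                    if li > 0:
                        grad = dz @ weights[li].T
                for li in range(len(weights) - 1):  # L2 on hidden weights only
                    gw[li] += 2.0 * self.l2 * weights[li]
                t_adam += 1
                corr1 = 1.0 - beta1 ** t_adam
                corr2 = 1.0 - beta2 ** t_adam
                for li in range(len(weights)):
                    mw[li] = beta1 * mw[li] + (1 - beta1) * gw[li]
                    vw[li] = beta2 * vw[li] + (1 - beta2) * gw[li] ** 2
                    weights[li] -= (self.learning_rate * (mw[li] / corr1)
                                    / (np.sqrt(vw[li] / corr2) + eps))
                    mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                    biases[li] -= (self.learning_rate * (mb[li] / corr1)
                                   / (np.sqrt(vb[li] / corr2) + eps))

            _, acts_v = self._forward(Xv, weights, biases)
            pred_v = self.scalers_.inverse_targets(acts_v[-1])
            val_err = validation_relative_error(pred_v, y_val)
            history["train_loss"].append(epoch_loss / n)
            history["val_error"].append(val_err)

            if val_err < best_err:
                best_err = val_err
                best_state = ([w.copy() for w in weights],
                              [b.copy() for b in biases])
            if prev_err is not None and val_err > prev_err:
                increases += 1
                if increases >= self.patience:
                    break
            else:
                increases = 0
            prev_err = val_err

        if best_state is not None:
            weights, biases = best_state
        self.weights_ = weights
        self.biases_ = biases
        self.history_ = history
        self.best_val_error_ = best_err
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xs = self.scalers_.transform_features(X)
        _, acts = self._forward(Xs, self.weights_, self.biases_)
        return self.scalers_.inverse_targets(acts[-1])

    def parameter_count(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.weights_, self.biases_)))


# -- persistence ----------------------------------------------------------

def save_model(model: MLPSurrogate, path) -> None:
    """Persist architecture, scalers and weights as portable JSON."""
    payload = {
        "params": model.get_params(),
        "scalers": model.scalers_.to_dict(),
        "weights": [w.tolist() for w in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
        "history": model.history_,
        "n_features_in": model.n_features_in_,
    }
    payload["params"]["hidden_widths"] = list(model.hidden_widths)
    payload["params"]["activations"] = list(model.activations)
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> MLPSurrogate:
    payload = json.loads(Path(path).read_text())
    params = payload["params"]
    params["hidden_widths"] = tuple(params["hidden_widths"])
    params["activations"] = tuple(params["activations"])
    model = MLPSurrogate(**params)
    model.scalers_ = ScalerPair.from_dict(payload["scalers"])
    model.weights_ = [np.asarray(w) for w in payload["weights"]]
    model.biases_ = [np.asarray(b) for b in payload["biases"]]
    model.history_ = payload["history"]
    model.n_features_in_ = payload["n_features_in"]
    return model


# -- hyperparameter optimization ------------------------------------------

_ACT_NAMES = ("rectifier", "tanh", "logistic", "softsign", "softplus")


@dataclass
class HyperparameterSpace:
    """Six-dimensional search space for the surrogate.

    Learning rate and L2 strength are searched on a log scale; layers,
    width and training-set size are integers; the activation of each
    (potential) hidden layer is one of five options.
    """

    lr_bounds: tuple = (1e-5, 1e-2)
    l2_bounds: tuple = (1e-8, 1e-2)
    layer_bounds: tuple = (1, 5)
    width_bounds: tuple = (16, 1024)
    n_train_bounds: tuple = (500, 6000)
    activations: tuple = _ACT_NAMES

    @property
    def n_dims(self) -> int:
        # log_lr, log_l2, layers, width, n_train + one activation slot/layer
        return 5 + self.layer_bounds[1]

    def decode(self, u: np.ndarray) -> dict:
        """Map a unit-cube vector to a configuration dict."""
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        lo, hi = np.log10(self.lr_bounds[0]), np.log10(self.lr_bounds[1])
        lr = 10 ** (lo + u[0] * (hi - lo))
        lo, hi = np.log10(self.l2_bounds[0]), np.log10(self.l2_bounds[1])
        l2 = 10 ** (lo + u[1] * (hi - lo))
        n_layers = int(round(self.layer_bounds[0]
                             + u[2] * (self.layer_bounds[1] - self.layer_bounds[0])))
        width = int(round(self.width_bounds[0]
                          + u[3] * (self.width_bounds[1] - self.width_bounds[0])))
        n_train = int(round(self.n_train_bounds[0]
                            + u[4] * (self.n_train_bounds[1] - self.n_train_bounds[0])))
        acts = tuple(
            self.activations[min(int(u[5 + i] * len(self.activations)),
                                 len(self.activations) - 1)]
            for i in range(n_layers))
        return {"learning_rate": lr, "l2": l2,
                "hidden_widths": (width,) * n_layers, "activations": acts,
                "n_train": n_train}


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_optimize(objective, space: HyperparameterSpace, budget: int,
                   seed: int = 0, method: str = "gp", n_initial: int = 5,
                   penalty: float = 1e3):
    """Minimize ``objective(config)`` over the encoded hyperparameter space.

    A Gaussian-process surrogate with the expected-improvement acquisition
    scores 512 random candidates per iteration; the initial design is a
    seeded Sobol set.  ``method='random'`` falls back to pure random
    search.  Objective failures are penalized with a large finite value and
    the search continues.  Returns ``(best_config, trace)`` where the trace
    lists every evaluated configuration with its objective value.
    """
    if budget < 2:
        raise ValueError("budget must be at least 2")
    rng = np.random.default_rng(seed)
    sobol = qmc.Sobol(space.n_dims, scramble=True, rng=np.random.default_rng(seed))
    n_init = min(max(n_initial, 2), budget)
    n_pow2 = 1 << (n_init - 1).bit_length()  # Sobol balance wants powers of 2
    points = [np.asarray(p) for p in sobol.random(n_pow2)[:n_init]]

    evaluated_u, values, trace = [], [], []

    def run(u):
        config = space.decode(u)
        try:
            val = float(objective(config))
            if not np.isfinite(val):
                raise ValueError("non-finite objective")
        except Exception as exc:  # noqa: BLE001 - penalize and continue
            val = penalty
            config = dict(config, error=str(exc))
        evaluated_u.append(u)
        values.append(val)
        trace.append({"config": config, "objective": val})
        return val

    for u in points:
        run(u)

    while len(values) < budget:
        if method == "random":
            u = rng.random(space.n_dims)
        else:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5, length_scale=np.ones(space.n_dims)),
                normalize_y=True, alpha=1e-6, random_state=seed)
            gp.fit(np.vstack(evaluated_u), np.asarray(values))
            cand = rng.random((512, space.n_dims))
            mu, sigma = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sigma, np.min(values))
            u = cand[int(np.argmax(ei))]
        run(u)

    best = int(np.argmin(values))
    return trace[best]["config"], trace
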