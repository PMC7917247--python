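"""Conventional classifiers tuned by Bayesian optimization.

Four classical methods — logistic regression (LR), support-vector machine
(SVM), K-nearest neighbours (NN) and decision tree (DT) — are tuned by a
Gaussian-process expected-improvement search over their stated ranges,
maximizing validation accuracy:

* LR:  C in [1e-5, 1e5] (log10 scale)
* SVM: kernel in {polynomial, sigmoid, RBF}; C, gamma in [1e-5, 1e5] (log10)
* NN:  K in [1, 30] (integer)
* DT:  max_depth in [1, 30] (integer)

The surrogate is a Matern-5/2 Gaussian process on the encoded parameter
vector; one trial in ten is drawn uniformly at random to keep the search
space covered. Classifier fits themselves are scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

METHODS = ("LR", "SVM", "NN", "DT")
SVM_KERNELS = ("polynomial", "sigmoid", "RBF")
_SK_KERNEL = {"polynomial": "poly", "sigmoid": "sigmoid", "RBF": "rbf"}


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges of one method; C and gamma live on log10 scale."""

    method: str
    n_iterations: int = 200
    log_c_bounds: tuple = (-5.0, 5.0)
    log_gamma_bounds: tuple = (-5.0, 5.0)
    k_bounds: tuple = (1, 30)
    depth_bounds: tuple = (1, 30)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")

    def sample(self, rng: np.random.Generator) -> dict:
        if self.method == "LR":
            return {"logC": rng.uniform(*self.log_c_bounds)}
        if self.method == "SVM":
            return {"kernel": SVM_KERNELS[rng.integers(0, 3)],
                    "logC": rng.uniform(*self.log_c_bounds),
                    "logGamma": rng.uniform(*self.log_gamma_bounds)}
        if self.method == "NN":
            return {"K": int(rng.integers(self.k_bounds[0], self.k_bounds[1] + 1))}
        return {"max_depth": int(rng.integers(self.depth_bounds[0],
                                              self.depth_bounds[1] + 1))}

    def encode(self, params: dict) -> np.ndarray:
        """Map a parameter dict to a unit-scale vector for the GP surrogate."""
        if self.method == "LR":
            return np.array([params["logC"] / 5.0])
        if self.method == "SVM":
            onehot = [1.0 if params["kernel"] == k else 0.0 for k in SVM_KERNELS]
            return np.array(onehot + [params["logC"] / 5.0, params["logGamma"] / 5.0])
        if self.method == "NN":
            return np.array([params["K"] / 30.0])
        return np.array([params["max_depth"] / 30.0])


def make_estimator(method: str, params: dict, seed: int = 0):
    """Instantiate the scikit-learn classifier for one parameter setting."""
    if method == "LR":
        # default L2 penalty; quasi-Newton solver, generous iteration cap
        return LogisticRegression(C=10.0 ** params["logC"], solver="lbfgs",
                                  max_iter=5000)
    if method == "SVM":
        return SVC(kernel=_SK_KERNEL[params["kernel"]], C=10.0 ** params["logC"],
                   gamma=10.0 ** params["logGamma"], random_state=seed)
    if method == "NN":
        return KNeighborsClassifier(n_neighbors=params["K"])
    if method == "DT":
        return DecisionTreeClassifier(max_depth=params["max_depth"],
                                      random_state=seed)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TunedClassifier:
    """Best-trial estimator plus the full trial log."""

    method: str
    estimator: object
    best_params: dict
    best_val_accuracy: float
    trials: pd.DataFrame = field(repr=False, default=None)


def _expected_improvement(gp, cand: np.ndarray, best: float, xi: float = 0.01):
    mu, sd = gp.predict(cand, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (mu - best - xi) / sd
    return (mu - best - xi) * norm.cdf(z) + sd * norm.pdf(z)


def boa_tune(method: str, space: SearchSpace, train: tuple, validation: tuple,
             seed: int = 0, n_init: int = 8, epsilon: float = 0.1,
             n_candidates: int = 256) -> TunedClassifier:
    """Run ``space.n_iterations`` GP-EI evaluations maximizing validation
    accuracy; returns the best classifier refit on the training set together
    with the complete trial log. Deterministic for a fixed seed."""
    Xtr, ytr = np.asarray(train[0]), np.asarray(train[1])
    Xval, yval = np.asarray(validation[0]), np.asarray(validation[1])
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    kernel = ConstantKernel(1.0) * Matern(length_scale=0.5, nu=2.5) \
        + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-8, 1e-1))
    rows, encoded, scores = [], [], []
    for it in range(space.n_iterations):
        explore = it < n_init or rng.uniform() < epsilon
        if explore or not scores:
            params = space.sample(rng)
        else:
            gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-8,
                                          normalize_y=True,
                                          n_restarts_optimizer=0,
                                          random_state=int(seed) % (2 ** 31))
            with warnings.catch_warnings():
                # surrogate kernel bounds are deliberately wide; boundary
                # solutions are fine for an acquisition-only model
                warnings.simplefilter("ignore")
                gp.fit(np.array(encoded), np.array(scores))
            cands = [space.sample(rng) for _ in range(n_candidates)]
            ei = _expected_improvement(gp, np.array([space.encode(c) for c in cands]),
                                       max(scores))
            params = cands[int(np.argmax(ei))]
        if method == "NN":
            # K cannot exceed the number of training samples
            params["K"] = min(params["K"], len(Xtr))
        est = make_estimator(method, params, seed=seed)
        est.fit(Xtr, ytr)
        acc = float((est.predict(Xval) == yval).mean())
        encoded.append(space.encode(params))
        scores.append(acc)
        rows.append({"iteration": it + 1, **params, "val_accuracy": acc})
    trials = pd.DataFrame(rows)
    best_idx = int(np.argmax(scores))
    best_params = {k: rows[best_idx][k] for k in rows[best_idx]
                   if k not in ("iteration", "val_accuracy")}
    best = make_estimator(method, best_params, seed=seed)
    best.fit(Xtr, ytr)
    return TunedClassifier(method=method, estimator=best, best_params=best_params,
                           best_val_accuracy=float(scores[best_idx]), trials=trials)


def evaluate_on_test(fitted, test: tuple):
    """2x2 confusion matrix (rows = true class 0/1) and accuracy in percent."""
    Xte, yte = np.asarray(test[0]), np.asarray(test[1])
    if len(Xte) == 0:
        raise ValueError("test set is empty")
    est = fitted.estimator if isinstance(fitted, TunedClassifier) else fitted
    pred = est.predict(Xte)
    cm = confusion_matrix(yte, pred, labels=[0, 1])
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    return cm, float(accuracy)
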