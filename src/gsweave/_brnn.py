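"""Bayesian-regularized feed-forward neural network regression.

A single hidden layer of tanh units trained by minimizing

    F = beta * ED + alpha * EW,
    ED = 0.5 * sum (y - yhat)^2,   EW = 0.5 * ||theta||^2,

where the regularization weights (alpha, beta) are re-estimated each
epoch by MacKay's evidence approximation: the effective number of
parameters is gamma = sum_i s_i^2 / (s_i^2 + alpha) over the singular
values s of sqrt(beta) * J (J the Jacobian of the network output), then
alpha = gamma / (2 EW) and beta = (n - gamma) / (2 ED).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


class BRNNRegressor:
    """Small Bayesian-regularized network; inputs/targets standardized internally."""

    def __init__(self, neurons: int = 2, epochs: int = 20, seed: int = 0,
                 inner_iter: int = 20):
        if neurons < 1:
            raise ValueError("neurons must be >= 1")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.neurons = neurons
        self.epochs = epochs
        self.seed = seed
        self.inner_iter = inner_iter

    # -- parameter packing ----------------------------------------------
    def _unpack(self, theta, m):
        k = self.neurons
        W1 = theta[: k * m].reshape(k, m)
        b1 = theta[k * m: k * m + k]
        w2 = theta[k * m + k: k * m + 2 * k]
        b2 = theta[-1]
        return W1, b1, w2, b2

    def _forward(self, theta, X):
        W1, b1, w2, b2 = self._unpack(theta, X.shape[1])
        Z = np.tanh(X @ W1.T + b1)
        return Z @ w2 + b2, Z

    def _objective(self, theta, X, y, alpha, beta):
        W1, b1, w2, b2 = self._unpack(theta, X.shape[1])
        Z = np.tanh(X @ W1.T + b1)
        yhat = Z @ w2 + b2
        r = yhat - y
        ED = 0.5 * float(r @ r)
        EW = 0.5 * float(theta @ theta)
        F = beta * ED + alpha * EW
        # backprop
        dyhat = beta * r
        g_b2 = dyhat.sum()
        g_w2 = Z.T @ dyhat
        dZ = np.outer(dyhat, w2) * (1.0 - Z**2)
        g_W1 = dZ.T @ X
        g_b1 = dZ.sum(axis=0)
        grad = np.concatenate([g_W1.ravel(), g_b1, g_w2, [g_b2]]) + alpha * theta
        return F, grad

    def _jacobian(self, theta, X):
        W1, b1, w2, b2 = self._unpack(theta, X.shape[1])
        Z = np.tanh(X @ W1.T + b1)
        dZ = (1.0 - Z**2)
        n = X.shape[0]
        blocks = []
        for k in range(self.neurons):
            blocks.append((w2[k] * dZ[:, k])[:, None] * X)      # d/dW1[k,:]
        J = np.concatenate(
            blocks + [w2 * dZ, Z, np.ones((n, 1))], axis=1
        )
        return J

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = X.shape
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._x_sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._x_mean) / self._x_sd
        self._y_mean = y.mean()
        ysd = y.std()
        self._y_sd = ysd if ysd > 0 else 1.0
        ys = (y - self._y_mean) / self._y_sd

        rng = np.random.default_rng(self.seed)
        k = self.neurons
        theta = rng.normal(0.0, 0.1, size=k * m + 2 * k + 1)
        alpha, beta = 0.01, 1.0
        for _ in range(self.epochs):
            res = minimize(
                self._objective, theta, args=(Xs, ys, alpha, beta),
                jac=True, method="L-BFGS-B",
                options={"maxiter": self.inner_iter},
            )
            theta = res.x
            _, grad = self._objective(theta, Xs, ys, alpha, beta)
            yhat, _ = self._forward(theta, Xs)
            r = yhat - ys
            ED = max(0.5 * float(r @ r), 1e-12)
            EW = max(0.5 * float(theta @ theta), 1e-12)
            J = self._jacobian(theta, Xs) * np.sqrt(beta)
            s = np.linalg.svd(J, compute_uv=False)
            gamma = float(np.sum(s**2 / (s**2 + alpha)))
            alpha = gamma / (2.0 * EW)
            beta = max((n - gamma) / (2.0 * ED), 1e-8)
        self._theta = theta
        return self

    def predict(self, X):
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        yhat, _ = self._forward(self._theta, Xs)
        return yhat * self._y_sd + self._y_mean
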