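"""Presence-only maximum-entropy model with hinge features.

The model estimates a Gibbs distribution over background covariate vectors
(here: the covariates of all effort segments, i.e. the sampled environment)
that matches the presence sample's feature means under an L1 penalty.
Features are linear plus dense forward/reverse hinges, all scaled to [0, 1]
from the background range, which yields smooth mgcv-like response shapes.
Output is the logistic transform at prevalence tau (default 0.5).

Follows the statsmodels convention: :class:`MaxentModel` is built from the
presence/background tables and ``fit`` returns :class:`MaxentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.metrics import roc_auc_score

__all__ = ["HingeFeatureSet", "MaxentModel", "MaxentResults", "auc_score", "hinge_expand"]


def hinge_expand(x, lo: float, hi: float, thresholds) -> np.ndarray:
    """Forward and reverse hinge features of one variable, clipped to [0, 1].

    forward hinge at t:  max(0, (x - t) / (hi - t))
    reverse hinge at t:  max(0, (t - x) / (t - lo))
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    x = np.asarray(x, dtype=float)[:, None]
    t = np.asarray(thresholds, dtype=float)[None, :]
    if np.any((t <= lo) | (t >= hi)):
        raise ValueError("thresholds must lie strictly inside (lo, hi)")
    fwd = np.clip((x - t) / (hi - t), 0.0, 1.0)
    rev = np.clip((t - x) / (t - lo), 0.0, 1.0)
    return np.hstack([fwd, rev])


@dataclass
class HingeFeatureSet:
    """Per-variable ranges and hinge thresholds frozen from the background."""

    variables: tuple
    ranges: dict
    thresholds: dict

    @classmethod
    def from_background(cls, background: pd.DataFrame, variables=None, n_thresholds: int = 20):
        """Thresholds at ``n_thresholds`` equally spaced background quantiles."""
        if variables is None:
            variables = tuple(background.columns)
        ranges, thr = {}, {}
        probs = np.linspace(0.0, 1.0, n_thresholds + 2)[1:-1]
        for v in variables:
            x = background[v].to_numpy(dtype=float)
            lo, hi = float(x.min()), float(x.max())
            if not lo < hi:
                raise ValueError(f"constant background variable {v!r}")
            t = np.unique(np.quantile(x, probs))
            t = t[(t > lo) & (t < hi)]
            ranges[v] = (lo, hi)
            thr[v] = t
        return cls(variables=tuple(variables), ranges=ranges, thresholds=thr)

    def design(self, table: pd.DataFrame) -> np.ndarray:
        """Feature matrix (linear-in-range + hinges), all values in [0, 1]."""
        cols = []
        for v in self.variables:
            lo, hi = self.ranges[v]
            x = table[v].to_numpy(dtype=float)
            cols.append(np.clip((x - lo) / (hi - lo), 0.0, 1.0)[:, None])
            cols.append(hinge_expand(x, lo, hi, self.thresholds[v]))
        return np.hstack(cols)


class MaxentModel:
    """Maximum-entropy presence-only model over a fixed background."""

    def __init__(
        self,
        presence: pd.DataFrame,
        background: pd.DataFrame,
        features: HingeFeatureSet | None = None,
        reg_multiplier: float = 1.5,
        prevalence: float = 0.5,
    ):
        if len(presence) < 2:
            raise ValueError("need at least 2 presence points")
        if len(background) < len(presence):
            raise ValueError("background must not be smaller than the presence set")
        self.features = features or HingeFeatureSet.from_background(
            background, variables=tuple(presence.columns)
        )
        self.F_pres = self.features.design(presence)
        self.F_bg = self.features.design(background)
        self.reg_multiplier = float(reg_multiplier)
        self.prevalence = float(prevalence)
        m = len(presence)
        sd = self.F_pres.std(axis=0)
        # per-feature penalty from the presence-sample standard error
        # (default multiplier 1.5 suppresses pure sampling noise), floored
        # so features constant on presences stay penalised
        self.penalty = self.reg_multiplier * np.maximum(sd, 0.05) / np.sqrt(m)

    def fit(self, maxiter: int = 1000) -> "MaxentResults":
        """Deterministic convex fit (L1 handled by a positive/negative split)."""
        k = self.F_pres.shape[1]
        fbar = self.F_pres.mean(axis=0)

        def objective(wpm):
            w = wpm[:k] - wpm[k:]
            s = self.F_bg @ w
            logz = special.logsumexp(s)
            q = np.exp(s - logz)
            nll = -(fbar @ w) + logz - np.log(len(s)) + self.penalty @ (wpm[:k] + wpm[k:])
            gw = -(fbar) + self.F_bg.T @ q
            return nll, np.concatenate([gw + self.penalty, -gw + self.penalty])

        x0 = np.zeros(2 * k)
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * k),
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
        )
        w = res.x[:k] - res.x[k:]
        s = self.F_bg @ w
        logz = float(special.logsumexp(s))
        q = np.exp(s - logz)
        entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
        return MaxentResults(
            model=self,
            weights=w,
            log_partition=logz,
            entropy=entropy,
            converged=bool(res.success),
        )


class MaxentResults:
    """Fitted weights, background partition constant and entropy."""

    def __init__(self, model, weights, log_partition, entropy, converged):
        self.model = model
        self.weights = np.asarray(weights, dtype=float)
        self.log_partition = float(log_partition)
        self.entropy = float(entropy)
        self.converged = bool(converged)

    @property
    def background_probabilities(self) -> np.ndarray:
        return np.exp(self.model.F_bg @ self.weights - self.log_partition)

    def raw_score(self, table: pd.DataFrame) -> np.ndarray:
        """h = w . f(x) - log Z + H (zero for a featureless model)."""
        F = self.model.features.design(table)
        return F @ self.weights - self.log_partition + self.entropy

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Logistic output: tau e^h / (1 - tau + tau e^h); in (0, 1)."""
        h = self.raw_score(table)
        tau = self.model.prevalence
        logit_tau = np.log(tau / (1.0 - tau))
        return special.expit(h + logit_tau)

    def summary(self) -> str:
        nz = int(np.sum(self.weights != 0.0))
        return (
            f"MaxEnt (hinge features), {len(self.weights)} features "
            f"({nz} active), prevalence {self.model.prevalence}\n"
            f"log-partition {self.log_partition:.4f}, background entropy "
            f"{self.entropy:.4f}, converged: {self.converged}"
        )


def auc_score(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("need both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
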