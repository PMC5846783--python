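"""Count GAMs with log link, effort offsets and fixed-df smooths.

The model for segment counts ``y_i`` (individuals per segment) is

    eta_i = beta_0 + sum_v s_v(x_iv) + log(area_i)

with ``s_v`` an unpenalised natural cubic spline with a small fixed number
of degrees of freedom (3 by default) and ``area_i`` the searched area of
the segment, so ``exp`` of the covariate part is a density in individuals
per km^2.  Three residual families are supported:

* ``negbin``  -- NB2, size theta estimated by joint ML;
* ``tweedie`` -- compound Poisson-gamma, power p profiled over a grid,
  dispersion phi by ML at the profiled optimum;
* ``zip``     -- zero-inflated Poisson whose presence probability is
  logit-linear in the density predictor (theta0, theta1 estimated by ML);
  its fitted mean is pi * lambda.

Fitting maximises the exact family log-likelihood (quasi-Newton on the
coefficients jointly with the family parameters; iteratively reweighted
least squares inside the Tweedie p-profile).  Following statsmodels
conventions, :class:`CountGAM` is the model object and ``fit`` returns a
:class:`CountGAMResults` carrying estimates, covariances and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import families
from .grids import DailyPredictions, PredictionGrid
from .splines import SplineBasis, build_spline_basis
from .survey import SurveyDataset

__all__ = ["ModelSpec", "CountGAM", "CountGAMResults", "gcv_score", "TWEEDIE_P_GRID"]

FAMILIES = ("negbin", "tweedie", "zip")
TWEEDIE_P_GRID = np.round(np.arange(1.05, 1.96, 0.05), 2)
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Family, smooth terms and offset rule of one candidate model."""

    family: str
    variables: tuple = ()
    df: int = 3
    offset: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) > 4:
            raise ValueError("at most 4 smooth terms are allowed")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicated variables in model spec")


@dataclass(frozen=True)
class _Term:
    """One fitted smooth: standardisation plus frozen spline basis."""

    variable: str
    mean: float
    scale: float
    basis: SplineBasis

    def design(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.scale
        return self.basis.transform(z)

    @property
    def train_range(self) -> tuple:
        return (
            self.basis.train_min * self.scale + self.mean,
            self.basis.train_max * self.scale + self.mean,
        )


def gcv_score(deviance: float, n: int, edf: float) -> float:
    """Generalised cross-validation score ``n * D / (n - edf)^2``."""
    if edf >= n:
        raise ValueError("effective degrees of freedom must be below n")
    return float(n) * float(deviance) / (float(n) - float(edf)) ** 2


def _mu_from_eta(eta):
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


class CountGAM:
    """Count GAM model object (build once, then :meth:`fit`)."""

    def __init__(self, y, covariates: pd.DataFrame, spec: ModelSpec, log_offset=None):
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("negative response")
        if not np.any(y > 0):
            raise ValueError("all-zero response: nothing to fit")
        if spec.family in ("negbin", "zip") and not np.allclose(y, np.round(y)):
            raise ValueError(f"{spec.family} requires integer counts")
        self.y = y
        self.spec = spec
        self.n = len(y)
        self.log_offset = (
            np.zeros(self.n) if log_offset is None else np.asarray(log_offset, float)
        )
        self.terms = []
        cols = [np.ones((self.n, 1))]
        for v in spec.variables:
            if v not in covariates.columns:
                raise ValueError(f"covariate {v!r} missing from table")
            x = covariates[v].to_numpy(dtype=float)
            m, s = float(x.mean()), float(x.std())
            if s == 0:
                raise ValueError(f"constant covariate {v!r}")
            z = (x - m) / s
            basis = build_spline_basis(z, df=spec.df, variable=v)
            term = _Term(v, m, s, basis)
            self.terms.append(term)
            cols.append(term.design(x))
        self.X = np.hstack(cols)
        self.k = self.X.shape[1]
        if np.linalg.matrix_rank(self.X) < self.k:
            raise ValueError("rank-deficient design matrix")

    @classmethod
    def from_survey(
        cls,
        dataset: SurveyDataset,
        taxon: str,
        family: str,
        variables=(),
        df: int = 3,
        offset: bool = True,
    ) -> "CountGAM":
        """Build the model from a survey dataset (counts + effort offsets)."""
        spec = ModelSpec(family=family, variables=tuple(variables), df=df, offset=offset)
        y = dataset.counts(taxon).to_numpy()
        log_off = np.log(dataset.effort_area_km2().to_numpy()) if offset else None
        return cls(y, dataset.segments, spec, log_offset=log_off)

    # -- family negative log-likelihoods (mean per observation) ----------
    def _nll_grad_negbin(self, params):
        beta, logtheta = params[: self.k], params[self.k]
        theta = np.exp(logtheta)
        eta = self.X @ beta + self.log_offset
        mu = _mu_from_eta(eta)
        y = self.y
        ll = (
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * logtheta
            + y * np.log(mu)
            - (y + theta) * np.log(theta + mu)
        )
        dldeta = y - (y + theta) * mu / (theta + mu)
        dldtheta = (
            special.digamma(y + theta)
            - special.digamma(theta)
            + logtheta
            + 1.0
            - np.log(theta + mu)
            - (y + theta) / (theta + mu)
        )
        grad = np.concatenate([self.X.T @ dldeta, [np.sum(dldtheta) * theta]])
        return -np.sum(ll) / self.n, -grad / self.n

    def _nll_grad_zip(self, params):
        # np.where evaluates both branches; silence spurious warnings from
        # the branch that is discarded
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return self._nll_grad_zip_impl(params)

    def _nll_grad_zip_impl(self, params):
        beta, t0, t1 = params[: self.k], params[self.k], params[self.k + 1]
        t1 = min(t1, 20.0)  # keep the presence-link slope finite
        eta = np.clip(self.X @ beta + self.log_offset, -_ETA_CLIP, _ETA_CLIP)
        lam = np.exp(eta)
        g = t0 + np.exp(t1) * eta
        pi = special.expit(g)
        log1mpi = -np.logaddexp(0.0, g)  # log(1 - pi), overflow-safe
        logpi = g + log1mpi
        y = self.y
        zero = y == 0
        logA = np.logaddexp(log1mpi, logpi - lam)
        ll = np.where(
            zero, logA, logpi + y * eta - lam - special.gammaln(y + 1)
        )
        # gradients
        pio = pi * (1.0 - pi)
        eml = np.exp(-lam)
        A = np.maximum(np.exp(logA), 1e-300)
        et1 = np.exp(t1)
        dldeta = np.where(
            zero,
            (pio * et1 * (eml - 1.0) - pi * eml * lam) / A,
            (1.0 - pi) * et1 + y - lam,
        )
        # dll/dg is the theta0 gradient; chain dg/dtheta1 = e^theta1 * eta
        dldt0 = np.where(zero, pio * (eml - 1.0) / A, 1.0 - pi)
        dldt1 = dldt0 * et1 * eta
        grad = np.concatenate(
            [self.X.T @ dldeta, [np.sum(dldt0)], [np.sum(dldt1)]]
        )
        return -np.sum(ll) / self.n, -grad / self.n

    # -- Tweedie profile machinery ---------------------------------------
    def _irls_tweedie(self, p, beta0=None, maxiter=60, tol=1e-10):
        """Deviance-minimising beta for fixed p (log link IRLS)."""
        y, X, off = self.y, self.X, self.log_offset
        if beta0 is None:
            mu0 = np.maximum((y + y.mean()) / 2.0, 1e-4)
            eta = np.log(mu0) - off
            beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
        else:
            beta = beta0.copy()

        def deviance(b):
            mu = _mu_from_eta(X @ b + off)
            return float(np.sum(_tweedie_unit_dev(y, mu, p)))

        dev = deviance(beta)
        converged = False
        for _ in range(maxiter):
            eta = np.clip(X @ beta + off, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta)
            z = eta - off + (y - mu) / mu
            w = mu ** (2.0 - p)
            sw = np.sqrt(w)
            bnew, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            step = 1.0
            dnew = deviance(bnew)
            while not np.isfinite(dnew) or dnew > dev + 1e-12:
                step /= 2.0
                if step < 1e-8:
                    break
                bnew = beta + step * (bnew - beta)
                dnew = deviance(bnew)
            if abs(dev - dnew) < tol * (abs(dev) + 0.1):
                beta, dev = bnew, dnew
                converged = True
                break
            beta, dev = bnew, dnew
        return beta, dev, converged

    def fit(self, maxiter: int = 5000, restarts: int = 3) -> "CountGAMResults":
        """Maximise the exact family likelihood; returns the results object."""
        if self.spec.family == "tweedie":
            return self._fit_tweedie()
        if self.spec.family == "negbin":
            fun = self._nll_grad_negbin
            x0 = np.concatenate([self._beta_start(), [0.0]])
        else:
            fun = self._nll_grad_zip
            x0 = np.concatenate([self._beta_start(), [0.0, 0.0]])
        best = None
        rng = np.random.default_rng(12345)
        start = x0
        for attempt in range(restarts):
            res = optimize.minimize(
                fun,
                start,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-8, "maxcor": 25},
            )
            # convergence: small gradient of the per-observation mean
            # log-likelihood (1e-5 accommodates near-flat ZIP optima)
            gnorm = float(np.max(np.abs(res.jac)))
            ok = np.isfinite(res.fun) and gnorm < 1e-5
            if best is None or res.fun < best[0].fun:
                best = (res, ok)
            if ok:
                break
            # first retry continues from the stall point; later ones jitter
            start = res.x if attempt == 0 else x0 + rng.normal(scale=0.3, size=len(x0))
        res, ok = best
        beta = res.x[: self.k]
        if self.spec.family == "negbin":
            fam_params = {"theta": float(np.exp(res.x[self.k]))}
        else:
            fam_params = {
                "theta0": float(res.x[self.k]),
                "theta1": float(res.x[self.k + 1]),
            }
        return CountGAMResults(
            model=self,
            beta=beta,
            family_params=fam_params,
            loglike=-res.fun * self.n,
            converged=bool(ok),
            _raw_params=res.x,
        )

    def _beta_start(self):
        """Poisson IRLS warm start (a good log-link mean structure for all
        three families); falls back to intercept-only on failure."""
        b0 = np.zeros(self.k)
        b0[0] = np.log(np.sum(self.y) / np.sum(np.exp(self.log_offset)))
        try:
            beta = b0.copy()
            y, X, off = self.y, self.X, self.log_offset
            for _ in range(25):
                eta = np.clip(X @ beta + off, -_ETA_CLIP, _ETA_CLIP)
                mu = np.exp(eta)
                z = eta - off + (y - mu) / mu
                sw = np.sqrt(mu)
                bnew, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
                if not np.all(np.isfinite(bnew)):
                    return b0
                if np.max(np.abs(bnew - beta)) < 1e-8:
                    beta = bnew
                    break
                beta = bnew
            return beta if np.all(np.isfinite(beta)) else b0
        except np.linalg.LinAlgError:
            return b0

    def _fit_tweedie(self) -> "CountGAMResults":
        y = self.y
        pos = y > 0
        best = None
        beta_warm = None
        for p in TWEEDIE_P_GRID:
            beta, dev, conv = self._irls_tweedie(p, beta0=beta_warm)
            beta_warm = beta
            mu = _mu_from_eta(self.X @ beta + self.log_offset)

            def nll_logphi(lphi, mu=mu, p=p):
                phi = np.exp(lphi)
                ll = np.sum(families.tweedie_log_zero_mass(mu[~pos], p, phi))
                tilt = (
                    y[pos] * mu[pos] ** (1.0 - p) / (1.0 - p)
                    - mu[pos] ** (2.0 - p) / (2.0 - p)
                ) / phi
                ll += np.sum(
                    families._tweedie_log_series(y[pos], p, phi) + tilt
                )
                return -ll

            opt = optimize.minimize_scalar(
                nll_logphi, bounds=(-8.0, 8.0), method="bounded",
                options={"xatol": 1e-4},
            )
            ll = -opt.fun
            phi = float(np.exp(opt.x))
            cand = (ll, -abs(p - 1.5), p, phi, beta, dev, conv, nll_logphi)
            if best is None or cand[:2] > best[:2]:
                best = cand
        ll, _, p, phi, beta, dev, conv, nll_best = best
        # refine the dispersion at the profiled optimum
        opt = optimize.minimize_scalar(
            nll_best, bounds=(np.log(phi) - 0.05, np.log(phi) + 0.05),
            method="bounded", options={"xatol": 1e-8},
        )
        ll, phi = -opt.fun, float(np.exp(opt.x))
        return CountGAMResults(
            model=self,
            beta=beta,
            family_params={"p": float(p), "phi": phi},
            loglike=float(ll),
            converged=bool(conv),
            _raw_params=beta,
        )


def _tweedie_unit_dev(y, mu, p):
    term_y = np.where(y > 0, y ** (2.0 - p) / ((1.0 - p) * (2.0 - p)), 0.0)
    return 2.0 * (term_y - y * mu ** (1.0 - p) / (1.0 - p) + mu ** (2.0 - p) / (2.0 - p))


class CountGAMResults:
    """Fitted count GAM: coefficients, family parameters, diagnostics."""

    def __init__(self, model, beta, family_params, loglike, converged, _raw_params):
        self.model = model
        self.params = np.asarray(beta, dtype=float)
        self.family_params = dict(family_params)
        self.loglike = float(loglike)
        self.converged = bool(converged)
        self._raw = np.asarray(_raw_params, dtype=float)

    # -- basic quantities -------------------------------------------------
    @property
    def family(self) -> str:
        return self.model.spec.family

    @property
    def edf(self) -> int:
        """Total coefficient count of the linear predictor."""
        return self.model.k

    @cached_property
    def linear_predictor(self) -> np.ndarray:
        return np.clip(
            self.model.X @ self.params + self.model.log_offset, -_ETA_CLIP, _ETA_CLIP
        )

    @cached_property
    def fittedvalues(self) -> np.ndarray:
        """Fitted expected counts on the training segments."""
        eta = self.linear_predictor
        if self.family == "zip":
            pi = families.zip_presence_prob(
                eta, self.family_params["theta0"], self.family_params["theta1"]
            )
            return pi * np.exp(eta)
        return np.exp(eta)

    @cached_property
    def deviance(self) -> float:
        """2 * (saturated - fitted log-likelihood) under the fitted family."""
        y = self.model.y
        if self.family == "tweedie":
            mu = np.exp(self.linear_predictor)
            return float(np.sum(_tweedie_unit_dev(y, mu, self.family_params["p"])))
        if self.family == "negbin":
            theta = self.family_params["theta"]
            mu = self.fittedvalues
            ty = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
            return float(
                2.0 * np.sum(ty - (y + theta) * np.log((y + theta) / (mu + theta)))
            )
        # zip: saturated ll has pi=1, lambda=y for y>0 and P(0)=1 for y=0
        ll_sat = np.sum(
            np.where(
                y > 0,
                y * np.log(np.where(y > 0, y, 1.0)) - y - special.gammaln(y + 1),
                0.0,
            )
        )
        return float(2.0 * (ll_sat - self.loglike))

    @property
    def gcv(self) -> float:
        return gcv_score(self.deviance, self.model.n, self.edf)

    @cached_property
    def null_deviance(self) -> float:
        """Deviance of the intercept-plus-offset-only mean structure with
        the family parameters frozen at this fit's estimates (so explained
        deviance is a like-for-like comparison)."""
        m = self.model
        tail = self._raw[m.k:]

        def nll_b0(b0):
            p = np.concatenate([[b0[0]], np.zeros(m.k - 1), tail])
            if self.family == "negbin":
                return m._nll_grad_negbin(p)[0] * m.n  # total nll
            if self.family == "zip":
                return m._nll_grad_zip(p)[0] * m.n
            mu = _mu_from_eta(b0[0] + m.log_offset)
            return np.sum(_tweedie_unit_dev(m.y, mu, self.family_params["p"]))

        from scipy.optimize import minimize_scalar

        b0_hat = np.log(np.sum(m.y) / np.sum(np.exp(m.log_offset)))
        opt = minimize_scalar(
            lambda b: float(nll_b0([b])),
            bounds=(b0_hat - 5.0, b0_hat + 5.0),
            method="bounded",
        )
        if self.family == "tweedie":
            return float(opt.fun)
        # convert the frozen-parameter nll into a deviance on this family's scale
        sat = self.deviance / 2.0 + self.loglike  # saturated log-likelihood
        return float(2.0 * (sat + opt.fun))

    @property
    def deviance_explained(self) -> float:
        nd = self.null_deviance
        return 1.0 - self.deviance / nd if nd > 0 else np.nan

    @property
    def training_ranges(self) -> dict:
        return {t.variable: t.train_range for t in self.model.terms}

    # -- covariance --------------------------------------------------------
    @cached_property
    def cov_params(self) -> np.ndarray:
        """Inverse observed information of the coefficients at the optimum
        (family parameters held at their estimates)."""
        X = self.model.X
        eta = self.linear_predictor
        mu = np.exp(eta)
        y = self.model.y
        if self.family == "negbin":
            theta = self.family_params["theta"]
            w = (y + theta) * theta * mu / (mu + theta) ** 2
            info = X.T @ (X * w[:, None])
        elif self.family == "tweedie":
            p, phi = self.family_params["p"], self.family_params["phi"]
            d2 = ((1.0 - p) * y * mu ** (1.0 - p) - (2.0 - p) * mu ** (2.0 - p)) / phi
            info = -(X.T @ (X * d2[:, None]))
        else:
            info = self._zip_obs_info()
        info = (info + info.T) / 2.0
        cov = np.linalg.pinv(info)
        # symmetrise and clip tiny negative eigenvalues from the pseudo-inverse
        cov = (cov + cov.T) / 2.0
        evals, evecs = np.linalg.eigh(cov)
        return (evecs * np.clip(evals, 0.0, None)) @ evecs.T

    def _zip_obs_info(self) -> np.ndarray:
        """Central finite differences of the analytic beta-gradient."""
        k = self.model.k
        x0 = self._raw.copy()

        def grad_beta(b):
            p = x0.copy()
            p[:k] = b
            _, g = self.model._nll_grad_zip(p)
            return g[:k] * self.model.n

        h = 1e-5 * (1.0 + np.abs(self.params))
        info = np.empty((k, k))
        for j in range(k):
            bp, bm = self.params.copy(), self.params.copy()
            bp[j] += h[j]
            bm[j] -= h[j]
            info[:, j] = (grad_beta(bp) - grad_beta(bm)) / (2.0 * h[j])
        return info

    # -- prediction --------------------------------------------------------
    def _design_for(self, cov: dict) -> np.ndarray:
        n = len(next(iter(cov.values()))) if cov else 1
        cols = [np.ones((n, 1))]
        for t in self.model.terms:
            if t.variable not in cov:
                raise ValueError(f"grid is missing covariate {t.variable!r}")
            cols.append(t.design(cov[t.variable]))
        return np.hstack(cols)

    def predict_density(self, covariates: dict) -> np.ndarray:
        """Density (individuals per km^2) at unit searched area."""
        X = self._design_for(covariates)
        eta = np.clip(X @ self.params, -_ETA_CLIP, _ETA_CLIP)
        if self.family == "zip":
            pi = families.zip_presence_prob(
                eta, self.family_params["theta0"], self.family_params["theta1"]
            )
            return pi * np.exp(eta)
        return np.exp(eta)

    def predict_daily(self, grid: PredictionGrid, with_variance: bool = True) -> DailyPredictions:
        """Daily density maps with extrapolation masking.

        A cell-day is masked whenever any model covariate falls outside the
        training range of that covariate.  Variances are first-order
        (delta-method) propagation of the coefficient covariance.
        """
        nd, nc = grid.n_days, grid.n_cells
        dens = np.empty((nd, nc))
        var = np.zeros((nd, nc))
        valid = np.ones((nd, nc), dtype=bool)
        cov_beta = self.cov_params if with_variance else None
        for t in self.model.terms:
            if t.variable not in grid.covariates:
                raise ValueError(f"grid is missing covariate {t.variable!r}")
        for i in range(nd):
            cov = {t.variable: grid.covariates[t.variable][i] for t in self.model.terms}
            for t in self.model.terms:
                lo, hi = t.train_range
                v = cov[t.variable]
                valid[i] &= (v >= lo) & (v <= hi)
            X = self._design_for(cov) if self.model.terms else np.ones((nc, 1))
            eta = np.clip(X @ self.params, -_ETA_CLIP, _ETA_CLIP)
            lam = np.exp(eta)
            if self.family == "zip":
                t0, t1 = self.family_params["theta0"], self.family_params["theta1"]
                pi = families.zip_presence_prob(eta, t0, t1)
                dens[i] = pi * lam
                dmu_deta = lam * pi * ((1.0 - pi) * np.exp(t1) + 1.0)
            else:
                dens[i] = lam
                dmu_deta = lam
            if with_variance:
                quad = np.einsum("ij,jk,ik->i", X, cov_beta, X)
                var[i] = dmu_deta**2 * np.maximum(quad, 0.0)
        return DailyPredictions(grid=grid, density=dens, valid=valid, variance=var)

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = [
            f"Count GAM ({self.family}), n = {self.model.n}, edf = {self.edf}",
            f"converged: {self.converged}   log-likelihood: {self.loglike:.3f}",
            f"deviance: {self.deviance:.3f}   GCV: {self.gcv:.6g}",
            "family parameters: "
            + ", ".join(f"{k} = {v:.4g}" for k, v in self.family_params.items()),
            f"{'term':<24}{'coef':>12}{'se':>12}",
        ]
        se = np.sqrt(np.diag(self.cov_params))
        names = ["intercept"] + [
            f"s({t.variable}).{j + 1}"
            for t in self.model.terms
            for j in range(t.basis.df)
        ]
        for name, b, s in zip(names, self.params, se):
            lines.append(f"{name:<24}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)
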