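"""Conventional inverse-variance meta-analysis: FE/RE pooling, Q, I², τ².

Fixed-effect pooling weights each study by 1/seᵢ²; the random-effects model
adds a between-study variance τ² (DerSimonian–Laird or REML) so that
wᵢ* = 1/(seᵢ² + τ²).  Intervals are Wald with the fixed 1.96 quantile and
p-values are two-sided normal tails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, stats

from .data_model import MetaDataset, MetaInputError, back_transform

__all__ = [
    "FrequentistResult",
    "HeterogeneityUndefinedError",
    "ConvergenceError",
    "fixed_effect_pool",
    "cochran_q",
    "tau2_dl",
    "tau2_reml",
    "random_effects_pool",
    "pseudo_likelihood_ratio",
]

_WALD_Z = 1.96


class HeterogeneityUndefinedError(MetaInputError):
    """Heterogeneity statistics need at least two studies."""


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class FrequentistResult:
    """Pooled estimate with Wald inference and heterogeneity statistics.

    ``Q`` and ``I2`` are NaN when only one study is available (heterogeneity
    is undefined); ``model_used`` records any K=1 degradation of RE to FE.
    """

    model: str                  # "FE" | "RE"
    mu_hat: float               # pooled log OR
    se_mu: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    tau2_method: str            # "none" | "DL" | "REML"
    Q: float
    I2: float                   # percent
    df: int
    k: int
    model_used: str = ""

    @property
    def or_scale(self):
        """(OR, (CI low, CI high)) on the odds ratio scale."""
        return back_transform(self.mu_hat, (self.ci_low, self.ci_high))

    def to_dict(self) -> dict:
        d = asdict(self)
        or_, (lo, hi) = self.or_scale
        d.update({"or": or_, "or_ci_low": lo, "or_ci_high": hi})
        return d

    def table_row(self) -> dict:
        """Flat row matching the comparison-table fields (report precision)."""
        or_, (lo, hi) = self.or_scale
        return {
            "model": self.model,
            "log_or": round(self.mu_hat, 3),
            "log_or_ci_low": round(self.ci_low, 3),
            "log_or_ci_high": round(self.ci_high, 3),
            "tau2": round(self.tau2, 4),
            "i2_percent": round(self.I2, 2) if math.isfinite(self.I2) else None,
            "or": round(or_, 3),
            "or_ci_low": round(lo, 3),
            "or_ci_high": round(hi, 3),
            "p": round(self.p, 4),
        }


def _arrays(dataset: MetaDataset):
    y = np.asarray(dataset.y, dtype=float)
    se = np.asarray(dataset.se, dtype=float)
    return y, se


def _wald(mu: float, se_mu: float, k: int, model: str, tau2: float,
          tau2_method: str, Q: float, I2: float, df: int,
          model_used: str = "") -> FrequentistResult:
    z = mu / se_mu
    p = 2.0 * stats.norm.sf(abs(z))
    return FrequentistResult(
        model=model, mu_hat=mu, se_mu=se_mu,
        ci_low=mu - _WALD_Z * se_mu, ci_high=mu + _WALD_Z * se_mu,
        z=z, p=p, tau2=tau2, tau2_method=tau2_method,
        Q=Q, I2=I2, df=df, k=k, model_used=model_used or model,
    )


def fixed_effect_pool(dataset: MetaDataset) -> FrequentistResult:
    """Fixed-effect inverse-variance pooled log odds ratio."""
    y, se = _arrays(dataset)
    w = 1.0 / se**2
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sum(w) ** -0.5)
    k = len(dataset)
    if k >= 2:
        Q, I2, df = _q_i2(y, se)
    else:
        Q, I2, df = math.nan, math.nan, 0
    return _wald(mu, se_mu, k, "FE", 0.0, "none", Q, I2, df)


def _q_i2(y, se):
    w = 1.0 / se**2
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return Q, I2, df


def cochran_q(dataset: MetaDataset) -> tuple[float, float, int]:
    """Cochran's Q with FE weights, the derived I² (percent), and df = K−1."""
    if len(dataset) < 2:
        raise HeterogeneityUndefinedError(
            f"heterogeneity needs K >= 2 studies, got {len(dataset)}"
        )
    return _q_i2(*_arrays(dataset))


def tau2_dl(dataset: MetaDataset) -> float:
    """DerSimonian–Laird moment estimator of the between-study variance.

    τ² = max(0, (Q − (K−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)) with FE weights.
    """
    Q, _, df = cochran_q(dataset)
    y, se = _arrays(dataset)
    w = 1.0 / se**2
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (Q - df) / denom)


def restricted_loglik(tau2: float, y, se) -> float:
    """Restricted log-likelihood of yᵢ ~ Normal(μ, seᵢ² + τ²) profiled over μ."""
    v = np.asarray(se, dtype=float) ** 2 + tau2
    w = 1.0 / v
    mu = np.sum(w * np.asarray(y, dtype=float)) / np.sum(w)
    return float(
        -0.5 * np.sum(np.log(v))
        - 0.5 * math.log(np.sum(w))
        - 0.5 * np.sum(w * (np.asarray(y) - mu) ** 2)
    )


def tau2_reml(dataset: MetaDataset, tol: float = 1e-10,
              max_iter: int = 200) -> float:
    """REML estimate of τ² via Fisher-scoring fixed-point iteration.

    Iterates the standard REML updating equation until |Δτ²| < tol, with the
    estimate truncated at 0; if the boundary value has higher restricted
    likelihood than the interior iterate, 0 is returned.
    """
    if len(dataset) < 2:
        raise HeterogeneityUndefinedError(
            f"heterogeneity needs K >= 2 studies, got {len(dataset)}"
        )
    y, se = _arrays(dataset)
    tau2 = max(tau2_dl(dataset), 1e-4)  # moment start
    last = tau2
    for _ in range(max_iter):
        v = se**2 + tau2
        w = 1.0 / v
        sw = np.sum(w)
        mu = np.sum(w * y) / sw
        resid2 = (y - mu) ** 2
        # REML fixed point: tau2 = sum(w^2 (r^2 + se_mu^2 - se^2)) / sum(w^2)
        num = np.sum(w**2 * (resid2 + 1.0 / sw - se**2))
        new = max(0.0, float(num / np.sum(w**2)))
        last = new
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    else:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations", last
        )
    if restricted_loglik(0.0, y, se) >= restricted_loglik(tau2, y, se):
        return 0.0
    return tau2


def random_effects_pool(dataset: MetaDataset,
                        tau2_method: str = "REML") -> FrequentistResult:
    """Random-effects pooled log odds ratio with τ² by REML (default) or DL.

    A single-study dataset degrades to the fixed-effect answer (τ² forced to
    0) with a warning, so sequential analyses can start at K = 1.
    """
    k = len(dataset)
    y, se = _arrays(dataset)
    method = tau2_method.upper()
    if method not in ("DL", "REML"):
        raise MetaInputError(f"unknown tau2_method {tau2_method!r}")
    if k == 1:
        warnings.warn(
            "random-effects pooling with a single study: tau^2 forced to 0 "
            "(fixed-effect result)", UserWarning, stacklevel=2,
        )
        tau2, Q, I2, df = 0.0, math.nan, math.nan, 0
        model_used = "FE (single study)"
    else:
        tau2 = tau2_dl(dataset) if method == "DL" else tau2_reml(dataset)
        Q, I2, df = _q_i2(y, se)
        model_used = "RE"
    w = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sum(w) ** -0.5)
    return _wald(mu, se_mu, k, "RE", tau2, method, Q, I2, df,
                 model_used=model_used)


def pseudo_likelihood_ratio(p: float) -> float:
    """The didactic frequentist 'likelihood ratio' (1 − p) / p.

    Only meaningful if H₁ were the strict complement of H₀ — which it is not;
    provided purely as a comparator to the Bayes factor, not an inferential
    quantity.  p = 0.005 gives 199.
    """
    if not 0.0 < p < 1.0:
        raise MetaInputError(f"p-value must be in (0, 1), got {p}")
    return (1.0 - p) / p
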