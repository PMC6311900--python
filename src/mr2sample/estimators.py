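"""Causal-effect estimators for two-sample summary-data MR.

Given J harmonized variants with exposure effects ``beta_x[j]`` (SE
``se_x[j]``) and outcome effects ``beta_y[j]`` (SE ``se_y[j]``), each
estimator returns the causal log odds ratio theta of the exposure on the
outcome under the instrumental-variable assumptions:

* **Wald ratio** — single variant: ``theta = beta_y / beta_x``; first-order
  SE ``se_y/|beta_x|`` or delta-method ("second-order") SE including the
  exposure uncertainty.
* **IVW** — inverse-variance-weighted combination of the per-variant
  ratios, identical to a weighted regression of ``beta_y`` on ``beta_x``
  through the origin with weights ``se_y**-2``.  The multiplicative
  random-effects model inflates the fixed-effect SE by
  ``max(1, sqrt(Q/(J-1)))`` where Q is Cochran's heterogeneity statistic.
* **MR-Egger** — the same weighted regression with a free intercept, fitted
  after orienting every variant to a positive exposure effect.  A non-zero
  intercept measures directional pleiotropy (average direct effect per
  variant); the slope is the pleiotropy-adjusted causal effect.  SEs carry
  the residual inflation factor, floored at 1.
* **Weighted median** — the weighted 50th percentile of the ordered ratio
  estimates; consistent when instruments carrying at least half of the
  weight are valid.  SE by parametric bootstrap.
* **Maximum likelihood** — joint normal model
  ``beta_x[j] ~ N(xi_j, se_x[j]^2)``, ``beta_y[j] ~ N(theta*xi_j, se_y[j]^2)``
  maximized over ``(theta, xi_1..xi_J)``; SE from the observed information.

All p-values are two-sided from the standard normal by default (the
t-distribution is available for the Egger regression via
``distribution="t"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    NonConvergenceError,
    UndefinedRatioError,
)
from .summary_io import HarmonizedDataset, HarmonizedPair

__all__ = [
    "MREstimate",
    "RatioEstimate",
    "wald_ratio",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "max_likelihood",
    "cochran_q",
    "to_odds_ratio",
    "all_estimates",
    "estimates_to_frame",
]

Z95 = 1.96  # Wald 95% multiplier, as conventionally printed


def to_odds_ratio(theta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log odds ratio with 1.96*se Wald limits."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return math.exp(theta), math.exp(theta - Z95 * se), math.exp(theta + Z95 * se)


def _two_sided_p(z: float, df: int | None = None) -> float:
    if df is None:
        return float(2.0 * stats.norm.sf(abs(z)))
    return float(2.0 * stats.t.sf(abs(z), df))


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log odds scale, with its OR view."""

    method: str
    theta: float
    se: float
    pval: float
    n_variants: int
    model: str | None = None
    q_stat: float | None = None
    converged: bool | None = None
    notes: tuple[str, ...] = ()
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        or_, lo, hi = to_odds_ratio(self.theta, self.se)
        object.__setattr__(self, "or_", or_)
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)

    @classmethod
    def from_theta(cls, method, theta, se, n_variants, model=None, q_stat=None,
                   df=None, converged=None, notes=()):
        return cls(
            method=method,
            theta=float(theta),
            se=float(se),
            pval=_two_sided_p(theta / se, df),
            n_variants=n_variants,
            model=model,
            q_stat=q_stat,
            converged=converged,
            notes=tuple(notes),
        )

    def __str__(self) -> str:  # pragma: no cover
        return (
            f"{self.method}: OR {self.or_:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), p {self.pval:.3g}"
        )


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with its variance under both SE orders."""

    snp_id: str
    ratio: float
    se_first_order: float
    se_second_order: float

    @property
    def weight(self) -> float:
        """Inverse-variance weight from the second-order SE."""
        return self.se_second_order**-2


def _ratio_se(pair: HarmonizedPair, order: str) -> float:
    first = pair.se_y / abs(pair.beta_x)
    if order == "first":
        return first
    if order == "second":
        return math.sqrt(
            pair.se_y**2 / pair.beta_x**2
            + pair.beta_y**2 * pair.se_x**2 / pair.beta_x**4
        )
    raise ConfigurationError(f"unknown se_order {order!r}")


def wald_ratio(pair: HarmonizedPair, se_order: str = "second") -> MREstimate:
    """Single-instrument causal estimate ``beta_y / beta_x``.

    ``se_order="first"`` ignores the exposure uncertainty
    (``se_y/|beta_x|``); the default delta-method SE adds the
    ``beta_y^2 se_x^2 / beta_x^4`` term.
    """
    if pair.beta_x == 0:
        raise UndefinedRatioError(f"{pair.snp_id}: exposure effect is zero")
    theta = pair.beta_y / pair.beta_x
    se = _ratio_se(pair, se_order)
    return MREstimate.from_theta(
        "wald", theta, se, 1, notes=(f"snp={pair.snp_id}", f"se_order={se_order}")
    )


def ratio_estimates(dataset: HarmonizedDataset) -> list[RatioEstimate]:
    """Per-variant ratios with first- and second-order SEs."""
    out = []
    for p in dataset:
        if p.beta_x == 0:
            raise UndefinedRatioError(f"{p.snp_id}: exposure effect is zero")
        out.append(
            RatioEstimate(
                snp_id=p.snp_id,
                ratio=p.beta_y / p.beta_x,
                se_first_order=_ratio_se(p, "first"),
                se_second_order=_ratio_se(p, "second"),
            )
        )
    return out


def _resolve_model(model: str, j: int) -> str:
    if model == "default":
        # mirrors common reference behaviour: random effects once J >= 4
        return "fixed" if j <= 3 else "random"
    if model not in {"fixed", "random"}:
        raise ConfigurationError(f"unknown model {model!r}")
    return model


def ivw(dataset: HarmonizedDataset, model: str = "default") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome on exposure effects through the origin,
    weights ``se_y**-2``:

        theta = sum(w*bx*by) / sum(w*bx^2),   SE_fixed = sum(w*bx^2)^-1/2

    The point estimate is identical under the fixed and (multiplicative)
    random-effects models; the random model scales the SE by
    ``max(1, sqrt(Q/(J-1)))``.  ``model="default"`` resolves to fixed for
    J <= 3 and random otherwise.
    """
    j = len(dataset)
    bx, by, sy = dataset.beta_x, dataset.beta_y, dataset.se_y
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all exposure effects are zero")
    resolved = _resolve_model(model, j)
    if resolved == "random" and j < 2:
        raise InsufficientInstrumentsError("random-effects IVW needs J >= 2")
    w = sy**-2.0
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2)) if j >= 2 else None
    if resolved == "random":
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return MREstimate.from_theta("ivw", theta, se, j, model=resolved, q_stat=q)


def egger(
    dataset: HarmonizedDataset, distribution: str = "normal"
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns ``(slope, intercept)`` estimates.

    Every variant is first oriented so its exposure effect is positive (the
    outcome effect flips sign in tandem), making the intercept identifiable
    as the average directional pleiotropy per variant.  The weighted
    regression ``beta_y = b0 + b1*beta_x`` uses weights ``se_y**-2``; both
    SEs are inflated by ``max(1, sqrt(RSS_w/(J-2)))``.
    """
    j = len(dataset)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs J >= 3")
    sgn = np.where(dataset.beta_x < 0, -1.0, 1.0)
    bx = dataset.beta_x * sgn
    by = dataset.beta_y * sgn
    w = dataset.se_y**-2.0
    if np.ptp(bx) == 0:
        raise DegenerateInstrumentsError(
            "no spread in exposure effects after orientation"
        )
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    # statsmodels scales the covariance by RSS_w/(J-2); re-floor that factor at 1
    inflation = max(1.0, math.sqrt(fit.scale))
    base_se = fit.bse / math.sqrt(fit.scale)
    df = j - 2 if distribution == "t" else None
    if distribution not in {"normal", "t"}:
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    slope = MREstimate.from_theta(
        "egger-slope", fit.params[1], base_se[1] * inflation, j,
        q_stat=float(fit.ssr), df=df,
    )
    intercept = MREstimate.from_theta(
        "egger-intercept", fit.params[0], base_se[0] * inflation, j, df=df
    )
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray,
                     order_keys=None) -> float:
    """Weighted 50th percentile by midpoint interpolation.

    ``order_keys`` breaks ties in the sort deterministically (snp ids).
    """
    if order_keys is None:
        order = np.argsort(values, kind="stable")
    else:
        order = np.lexsort((np.asarray(order_keys), values))
    v = values[order]
    w = weights[order] / np.sum(weights)
    midpoints = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, midpoints, v))


def weighted_median(
    dataset: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int = 42,
    se_order: str = "second",
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the weighted 50th percentile of the
    ordered per-variant ratios, weights being normalized inverse ratio
    variances (second-order by default).  The SE is the standard deviation
    of the estimate across ``n_boot`` redraws of ``(beta_x, beta_y)`` from
    their normal sampling distributions; it is reproducible for a fixed
    ``seed`` and does not affect the point estimate.
    """
    j = len(dataset)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median needs J >= 3")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    ratios = np.array([r.ratio for r in ratio_estimates(dataset)])
    ses = np.array(
        [getattr(r, f"se_{se_order}_order") for r in ratio_estimates(dataset)]
    )
    weights = ses**-2.0
    ids = np.array(dataset.snp_ids)
    theta = _weighted_median(ratios, weights, order_keys=ids)

    rng = np.random.default_rng(seed)
    bx, sx = dataset.beta_x, dataset.se_x
    by, sy = dataset.beta_y, dataset.se_y
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bad = bxs == 0
        if bad.any():  # pragma: no cover - measure-zero guard
            bxs[bad] = np.finfo(float).tiny
        r = bys / bxs
        if se_order == "first":
            v = sy**2 / bxs**2
        else:
            v = sy**2 / bxs**2 + bys**2 * sx**2 / bxs**4
        boot[b] = _weighted_median(r, 1.0 / v)
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_theta(
        "weighted-median", theta, se, j,
        notes=(f"n_boot={n_boot}", f"seed={seed}", f"se_order={se_order}"),
    )


def _profile_nll(theta: float, bx, sx, by, sy) -> float:
    # joint NLL with the latent instrument effects solved in closed form;
    # the variances are data, so no log-determinant term appears
    return float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)) / 2.0)


def max_likelihood(
    dataset: HarmonizedDataset, tol: float = 1e-8, max_iter: int = 10_000
) -> MREstimate:
    """Joint maximum-likelihood estimate of the causal effect.

    Model: ``beta_x[j] ~ N(xi_j, se_x[j]^2)``,
    ``beta_y[j] ~ N(theta*xi_j, se_y[j]^2)``, independent.  For fixed theta
    the latent effects xi_j have a closed-form optimum, leaving a
    one-dimensional profile likelihood in theta that is minimized
    numerically (initialized at the fixed-effect IVW estimate).  The SE is
    taken from the observed information of the full likelihood, profiled
    onto theta via the Schur complement.
    """
    bx, sx = dataset.beta_x, dataset.se_x
    by, sy = dataset.beta_y, dataset.se_y
    j = len(dataset)
    if np.all(bx == 0):
        raise DegenerateInstrumentsError("all exposure effects are zero")

    theta0 = ivw(dataset, model="fixed").theta if j > 1 else by[0] / bx[0]

    def nll(theta: float) -> float:
        return _profile_nll(theta, bx, sx, by, sy)

    def grad(theta: float) -> float:
        v = sy**2 + theta**2 * sx**2
        r = by - theta * bx
        return float(np.sum(-r * bx / v - r**2 * theta * sx**2 / v**2))

    # damped Newton on the 1-d profile; curvature by central difference
    theta = theta0
    converged = False
    for _ in range(max_iter):
        g = grad(theta)
        eps = 1e-6 * (1.0 + abs(theta))
        h = (grad(theta + eps) - grad(theta - eps)) / (2.0 * eps)
        if not math.isfinite(h) or h <= 0:
            h = abs(h) + 1.0  # fall back to a conservative gradient step
        step = -g / h
        f0, t = nll(theta), 1.0
        while nll(theta + t * step) > f0 and t > 1e-10:
            t *= 0.5
        theta += t * step
        if abs(t * step) <= tol * (1.0 + abs(theta)):
            converged = True
            break
    if not converged:
        raise NonConvergenceError(
            "profile likelihood did not converge", last_estimate=theta
        )

    # observed information: full Hessian in (theta, xi), Schur complement on theta
    xi = (bx / sx**2 + theta * by / sy**2) / (1.0 / sx**2 + theta**2 / sy**2)
    h_tt = float(np.sum(xi**2 / sy**2))
    h_tx = (2.0 * theta * xi - by) / sy**2
    h_xx = 1.0 / sx**2 + theta**2 / sy**2
    info = h_tt - float(np.sum(h_tx**2 / h_xx))
    if info <= 0:
        raise NonConvergenceError(
            "observed information not positive at the optimum", last_estimate=theta
        )
    se = info**-0.5
    return MREstimate.from_theta("max-likelihood", theta, se, j, converged=True)


def cochran_q(dataset: HarmonizedDataset) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q over per-variant ratios.

    ``Q = sum_j w_j (ratio_j - theta_IVW)^2`` with first-order weights
    ``w_j = beta_x[j]^2 / se_y[j]^2``; p-value from chi-square with J-1 df.
    """
    j = len(dataset)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs J >= 2")
    est = ivw(dataset, model="fixed")
    ratios = np.array([r.ratio for r in ratio_estimates(dataset)])
    w = dataset.beta_x**2 / dataset.se_y**2
    q = float(np.sum(w * (ratios - est.theta) ** 2))
    df = j - 1
    return q, df, float(stats.chi2.sf(q, df))


def all_estimates(
    dataset: HarmonizedDataset,
    methods=("ivw", "weighted-median", "egger", "max-likelihood"),
    model: str = "default",
    n_boot: int = 1000,
    seed: int = 42,
) -> list[MREstimate]:
    """Run a list of estimators on one dataset; Egger contributes two rows."""
    out: list[MREstimate] = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(dataset, model=model))
        elif m == "weighted-median":
            out.append(weighted_median(dataset, n_boot=n_boot, seed=seed))
        elif m == "egger":
            out.extend(egger(dataset))
        elif m == "max-likelihood":
            out.append(max_likelihood(dataset))
        elif m == "wald":
            if len(dataset) != 1:
                raise ConfigurationError("wald requires a single-variant dataset")
            out.append(wald_ratio(dataset[0]))
        else:
            raise ConfigurationError(f"unknown method {m!r}")
    return out


def estimates_to_frame(estimates) -> pd.DataFrame:
    """Tabulate estimates for the TSV report."""
    return pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "model": [e.model or "" for e in estimates],
            "n_variants": [e.n_variants for e in estimates],
            "theta": [e.theta for e in estimates],
            "se": [e.se for e in estimates],
            "or": [e.or_ for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "pval": [e.pval for e in estimates],
            "q_stat": [e.q_stat if e.q_stat is not None else "" for e in estimates],
        }
    )
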