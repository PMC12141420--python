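"""Poisson generalized linear mixed model of per-topic yearly article
counts, with a correlated random intercept and random slope per topic.

Model
-----
For topic k in year t with centred/scaled year covariate t~:

    y_kt ~ Poisson(lambda_kt)
    log lambda_kt = mu + gamma * t~ + b0_k + b1_k * t~
    (b0_k, b1_k) ~ N(0, Sigma),  Sigma = [[s0^2, rho*s0*s1],
                                          [rho*s0*s1, s1^2]]

A topic with positive b0_k attracts more articles than average (popular);
positive b1_k means its article count grows faster than the corpus trend
(rising).  Estimation maximises the Laplace-approximated marginal
likelihood: topics are independent given the fixed effects, so each
topic's 2-D random-effect integral is approximated at its conditional mode
(found by damped Newton), and the outer parameters
(mu, gamma, log s0, log s1, atanh rho) are optimised with L-BFGS-B.
Conditional modes double as the empirical-Bayes random-effect estimates.
The whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import gammaln

from .topic_metrics import argmax_topics


def build_counts(
    years: Sequence[int | None],
    theta: np.ndarray,
    year_range: tuple[int, int] | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-topic yearly article counts (long format: topic, year, count).

    Each article contributes to the topic where its weight is highest
    (lowest-index tie-break, as elsewhere); ``weighted=True`` instead sums
    theta across articles.  The grid is zero-filled over every year in the
    window, including years with no articles.
    """
    theta = np.asarray(theta, dtype=float)
    if len(years) != theta.shape[0]:
        raise ValueError("one year per theta row required")
    known = [y for y in years if y is not None]
    if not known:
        raise ValueError("no records with known year")
    if year_range is None:
        year_range = (min(known), max(known))
    lo, hi = year_range
    K = theta.shape[1]
    grid_years = list(range(lo, hi + 1))
    counts = np.zeros((K, len(grid_years)))
    sel = argmax_topics(theta)
    for row, y in enumerate(years):
        if y is None or not (lo <= y <= hi):
            continue
        t = y - lo
        if weighted:
            counts[:, t] += theta[row]
        else:
            counts[sel[row], t] += 1
    rows = [
        {"topic": k, "year": y, "count": counts[k, j]}
        for k in range(K)
        for j, y in enumerate(grid_years)
    ]
    df = pd.DataFrame(rows)
    if not weighted:
        df["count"] = df["count"].astype(int)
    return df


@dataclass
class PoissonGLMMResults:
    """Fitted popularity model.

    ``ranef`` holds the empirical-Bayes (conditional-mode) per-topic random
    intercepts b0 and slopes b1 on the scaled-year scale.
    """

    mu: float
    gamma: float
    sigma0: float
    sigma1: float
    rho: float
    ranef: pd.DataFrame  # index topic, columns b0, b1
    loglik: float
    converged: bool
    n_topics: int
    n_years: int
    year_mean: float
    year_scale: float
    optimizer_message: str

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * self.sigma0 * self.sigma1
        return np.array([[self.sigma0**2, c], [c, self.sigma1**2]])

    def classify(self) -> pd.Series:
        return classify_topics(self)

    def summary(self) -> str:
        lines = [
            "Poisson GLMM (log link), Laplace approximation",
            f"topics: {self.n_topics}   years: {self.n_years}   "
            f"converged: {self.converged}",
            f"fixed effects: mu = {self.mu:.4f}   gamma (per scaled year) = "
            f"{self.gamma:.4f}",
            f"random effects: sigma0 = {self.sigma0:.4f}   sigma1 = "
            f"{self.sigma1:.4f}   rho = {self.rho:.3f}",
            f"marginal log-likelihood (Laplace): {self.loglik:.3f}",
            "",
            "per-topic effects (empirical Bayes):",
        ]
        lab = self.classify()
        for k, (b0, b1) in self.ranef.iterrows():
            lines.append(f"  topic {k:>4}: b0 = {b0:+.4f}  b1 = {b1:+.4f}  [{lab[k]}]")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "mu": self.mu, "gamma": self.gamma, "sigma0": self.sigma0,
            "sigma1": self.sigma1, "rho": self.rho, "loglik": self.loglik,
            "converged": self.converged, "n_topics": self.n_topics,
            "n_years": self.n_years, "year_mean": self.year_mean,
            "year_scale": self.year_scale,
            "optimizer_message": self.optimizer_message,
        }
        with open(outdir / "fit.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh)
        out = self.ranef.copy()
        out["label"] = self.classify()
        out.to_csv(outdir / "ranef.tsv", sep="\t")


class PoissonGLMM:
    """Random-intercept + random-slope Poisson GLMM over (topic, year)
    count data.

    Parameters
    ----------
    counts : DataFrame with columns topic, year, count (long format, as
        produced by :func:`build_counts`).
    scale_year : centre and scale the year covariate to unit variance
        (default True; sign-based classification is invariant to this).
    """

    def __init__(self, counts: pd.DataFrame, scale_year: bool = True):
        required = {"topic", "year", "count"}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts must have columns {sorted(required)}")
        if (counts["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        self.topics = np.sort(counts["topic"].unique())
        years = np.sort(counts["year"].unique())
        if len(self.topics) < 2:
            raise ValueError("need at least 2 topics")
        if len(years) < 3:
            raise ValueError("need at least 3 years")
        self.years = years
        self.year_mean = float(years.mean())
        self.year_scale = float(years.std(ddof=0)) if scale_year else 1.0
        if not scale_year:
            self.year_mean = 0.0

        piv = counts.pivot_table(index="topic", columns="year", values="count",
                                 aggfunc="sum", fill_value=0.0)
        piv = piv.reindex(index=self.topics, columns=years, fill_value=0.0)
        self.y = piv.to_numpy(dtype=float)            # topics x years
        self.t = (years - self.year_mean) / self.year_scale

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "PoissonGLMM":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    # -- inner problem: conditional mode of (b0, b1) for one topic ----------

    def _inner_mode(self, y_k, eta0, Sinv):
        """Damped Newton for b maximising l_k(b) - b' Sinv b / 2."""
        t = self.t
        b = np.zeros(2)
        X = np.column_stack([np.ones_like(t), t])
        for _ in range(100):
            eta = eta0 + b[0] + b[1] * t
            lam = np.exp(eta)
            grad = X.T @ (y_k - lam) - Sinv @ b
            H = -(X.T * lam) @ X - Sinv
            step = np.linalg.solve(H, grad)
            new_b = b - step
            # damp until the penalised objective does not decrease
            f_old = self._inner_obj(y_k, eta0, b, Sinv)
            scale = 1.0
            while scale > 1e-8:
                cand = b - scale * step
                if self._inner_obj(y_k, eta0, cand, Sinv) >= f_old - 1e-12:
                    new_b = cand
                    break
                scale /= 2
            if np.max(np.abs(new_b - b)) < 1e-10:
                b = new_b
                break
            b = new_b
        eta = eta0 + b[0] + b[1] * t
        lam = np.exp(eta)
        H = -(X.T * lam) @ X - Sinv
        return b, H

    def _inner_obj(self, y_k, eta0, b, Sinv):
        eta = eta0 + b[0] + b[1] * self.t
        # overlong damped-Newton trial steps can overflow exp; the resulting
        # -inf objective is rejected by the damping loop, so silence it
        with np.errstate(over="ignore"):
            return float(y_k @ eta - np.exp(eta).sum() - 0.5 * b @ Sinv @ b)

    # -- Laplace marginal log-likelihood ------------------------------------

    def _marginal_loglik(self, params) -> tuple[float, np.ndarray]:
        mu, gamma, log_s0, log_s1, z_rho = params
        s0, s1 = np.exp(log_s0), np.exp(log_s1)
        rho = np.tanh(z_rho)
        cov = np.array([[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]])
        try:
            Sinv = np.linalg.inv(cov)
            _, logdet_S = np.linalg.slogdet(cov)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros((self.y.shape[0], 2))
        eta0 = mu + gamma * self.t
        total = 0.0
        modes = np.zeros((self.y.shape[0], 2))
        const = -gammaln(self.y + 1).sum()
        for k in range(self.y.shape[0]):
            b, H = self._inner_mode(self.y[k], eta0, Sinv)
            modes[k] = b
            h = self._inner_obj(self.y[k], eta0, b, Sinv)
            sign, logdet_negH = np.linalg.slogdet(-H)
            if sign <= 0:
                return -np.inf, modes
            # log ∫ exp(h(b)) db ≈ h(b^) + log 2π − ½ log|−H|, minus the
            # Gaussian prior normaliser log 2π + ½ log|Σ|
            total += h - 0.5 * logdet_negH - 0.5 * logdet_S
        return total + const, modes

    def fit(self, start: Sequence[float] | None = None,
            maxiter: int = 500, correlated: bool = True) -> PoissonGLMMResults:
        """Maximise the Laplace marginal likelihood; deterministic.

        ``correlated=False`` fixes the intercept-slope correlation at zero
        (independent random effects), analogous to a double-bar random-
        effect term.
        """
        y, t = self.y, self.t
        if start is None:
            ybar = max(y.mean(), 1e-3)
            start = [np.log(ybar), 0.0, np.log(0.5), np.log(0.1), 0.0]
        rho_bound = (-5, 5) if correlated else (0.0, 0.0)
        neg = lambda p: -self._marginal_loglik(p)[0]
        res = minimize(
            neg, np.asarray(start, dtype=float), method="L-BFGS-B",
            bounds=[(-20, 20), (-10, 10), (-6, 3), (-6, 3), rho_bound],
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9})
        loglik, modes = self._marginal_loglik(res.x)
        mu, gamma, log_s0, log_s1, z_rho = res.x
        ranef = pd.DataFrame(modes, index=pd.Index(self.topics, name="topic"),
                             columns=["b0", "b1"])
        return PoissonGLMMResults(
            mu=float(mu), gamma=float(gamma),
            sigma0=float(np.exp(log_s0)), sigma1=float(np.exp(log_s1)),
            rho=float(np.tanh(z_rho)), ranef=ranef, loglik=float(loglik),
            converged=bool(res.success), n_topics=len(self.topics),
            n_years=len(self.years), year_mean=self.year_mean,
            year_scale=self.year_scale, optimizer_message=str(res.message))


def fit_poisson_glmm(counts: pd.DataFrame, **kwargs) -> PoissonGLMMResults:
    """Convenience wrapper: ``PoissonGLMM(counts).fit()``."""
    return PoissonGLMM(counts, **kwargs).fit()


def classify_topics(fit: PoissonGLMMResults) -> pd.Series:
    """Quadrant labels from the signs of the per-topic random effects:
    hot (+,+), declining-popular (+,-), rising-niche (-,+), cold (-,-);
    exact zeros are 'boundary'."""
    labels = []
    for _, (b0, b1) in fit.ranef.iterrows():
        if b0 == 0 or b1 == 0:
            labels.append("boundary")
        elif b0 > 0 and b1 > 0:
            labels.append("hot")
        elif b0 > 0:
            labels.append("declining-popular")
        elif b1 > 0:
            labels.append("rising-niche")
        else:
            labels.append("cold")
    return pd.Series(labels, index=fit.ranef.index, name="label")


def simulate_counts(
    n_topics: int = 40,
    n_years: int = 30,
    mu: float = 2.0,
    gamma: float = 0.05,
    sigma0: float = 0.5,
    sigma1: float = 0.1,
    rho: float = 0.0,
    seed: int = 0,
    year_start: int = 1990,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw counts from the model itself (for recovery checks).

    Returns (long-format counts, true random effects).  gamma and the
    random effects are on the scaled-year scale used by the fitter.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(year_start, year_start + n_years)
    t = (years - years.mean()) / years.std(ddof=0)
    c = rho * sigma0 * sigma1
    cov = np.array([[sigma0**2, c], [c, sigma1**2]])
    b = rng.multivariate_normal(np.zeros(2), cov, size=n_topics)
    eta = mu + gamma * t[None, :] + b[:, [0]] + b[:, [1]] * t[None, :]
    y = rng.poisson(np.exp(eta))
    rows = [
        {"topic": k, "year": int(years[j]), "count": int(y[k, j])}
        for k in range(n_topics) for j in range(n_years)
    ]
    truth = pd.DataFrame(b, index=pd.Index(range(n_topics), name="topic"),
                         columns=["b0", "b1"])
    return pd.DataFrame(rows), truth
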