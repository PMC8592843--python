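"""Meristem / elongation-zone classification from cell length.

Along the root axis, meristematic cells stay short through repeated
divisions while cells in the elongation zone rapidly lengthen, so the
cell-length distribution within a tissue is bimodal. A two-component
Gaussian mixture is fitted to length by expectation–maximization in each
tissue × condition stratum; a cell whose posterior probability of the
short component exceeds a threshold (default 0.8, strict) is labelled a
meristem cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm


class DegenerateFitError(RuntimeError):
    """EM collapsed a component's variance; the data do not support two
    Gaussian components."""


@dataclass
class MixtureFit:
    """Parameters of a fitted two-Gaussian length mixture (µm).

    Components are relabeled after fitting so that ``mean_short <
    mean_long``; ``weight_short`` is the mixing weight of the short
    component and ``loglik`` the final observed-data log-likelihood.
    """

    mean_short: float
    mean_long: float
    sd_short: float
    sd_long: float
    weight_short: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = None

    def to_dict(self) -> dict:
        return {
            "mean_short": self.mean_short,
            "mean_long": self.mean_long,
            "sd_short": self.sd_short,
            "sd_long": self.sd_long,
            "weight_short": self.weight_short,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


_SD_FLOOR = 1e-8


def fit_mixture(
    lengths,
    init_strategy: str = "median",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a two-Gaussian mixture to cell lengths by EM.

    Initialization splits the sample at its median and takes each half's
    moments (``init_strategy="median"``); ``"quantile"`` splits at the
    quartiles instead. EM iterates until the log-likelihood improves by
    less than ``tol`` or ``max_iter`` is reached, then relabels the
    components so the short one comes first.

    Raises
    ------
    ValueError
        Fewer than 10 observations, or non-finite/non-positive lengths.
    DegenerateFitError
        A component's standard deviation collapsed below 1e-8 µm.
    """
    x = np.asarray(lengths, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("need at least 10 length observations")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("lengths must be finite and positive")

    if init_strategy == "median":
        cut = np.median(x)
    elif init_strategy == "quantile":
        cut = np.quantile(x, 0.75)
    else:
        raise ValueError(f"unknown init strategy {init_strategy!r}")
    lo, hi = x[x <= cut], x[x > cut]
    if hi.size == 0:  # all values at/below the cut (e.g. constant data)
        lo, hi = x, x
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), _SD_FLOOR * 10), max(hi.std(), _SD_FLOOR * 10)])
    w = np.array([lo.size, max(hi.size, 1)], dtype=float)
    w /= w.sum()

    loglik_trace = []
    prev = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.any(sd < _SD_FLOOR):
            raise DegenerateFitError(
                "component variance collapsed; the sample may not contain "
                "two distinct length populations (consider one component)"
            )
        # E step
        logp = np.log(w)[:, None] + norm.logpdf(x[None, :], mu[:, None], sd[:, None])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        loglik_trace.append(ll)
        resp = np.exp(logp - lse)
        if ll - prev < tol and n_iter > 1:
            converged = True
            break
        prev = ll
        # M step
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        sd = np.sqrt((resp @ x**2) / nk - mu**2)
        sd = np.where(np.isfinite(sd), sd, 0.0)
        if np.any(sd < _SD_FLOOR):
            raise DegenerateFitError(
                "component variance collapsed; the sample may not contain "
                "two distinct length populations (consider one component)"
            )

    order = np.argsort(mu)  # short component first
    mu, sd, w = mu[order], sd[order], w[order]
    return MixtureFit(
        mean_short=float(mu[0]),
        mean_long=float(mu[1]),
        sd_short=float(sd[0]),
        sd_long=float(sd[1]),
        weight_short=float(w[0]),
        loglik=float(loglik_trace[-1]),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.array(loglik_trace),
    )


def log_odds_short(fit: MixtureFit, length) -> np.ndarray:
    """Log posterior odds of the short component vs the long one.

    Finite for any finite length, which makes it the numerically safe
    quantity for thresholding (the posterior itself underflows to 0 or 1
    for extreme lengths)."""
    x = np.asarray(length, dtype=float)
    ls = np.log(fit.weight_short) + norm.logpdf(x, fit.mean_short, fit.sd_short)
    ll = np.log1p(-fit.weight_short) + norm.logpdf(x, fit.mean_long, fit.sd_long)
    out = ls - ll
    return out if out.ndim else float(out)


def posterior_short(fit: MixtureFit, length) -> np.ndarray:
    """Bayes posterior probability that a cell belongs to the short
    (meristem) component, vectorized over ``length``."""
    lo = log_odds_short(fit, length)
    p = expit(lo)
    return p if np.ndim(p) else float(p)


def classify_meristem(
    table: pd.DataFrame,
    threshold: float = 0.8,
    length_col: str = "length",
    tissue_col: str = "tissue",
    condition_col: str = "treatment",
    min_cells: int = 10,
):
    """Label every cell meristem/elongation, stratified by tissue × condition.

    A mixture is fitted per stratum and cells with posterior probability of
    the short component strictly above ``threshold`` are labelled
    ``"meristem"``; strata with fewer than ``min_cells`` cells are skipped
    with a warning (their zone is left missing).

    Returns
    -------
    (labeled, fits) : the input table with ``posterior_short`` and ``zone``
    columns added, and a dict mapping (tissue, condition) to the
    :class:`MixtureFit` of that stratum.
    """
    out = table.copy()
    out["posterior_short"] = np.nan
    out["zone"] = pd.NA
    fits = {}
    for (tissue, cond), idx in out.groupby([tissue_col, condition_col]).groups.items():
        lengths = out.loc[idx, length_col].to_numpy()
        if lengths.size < min_cells:
            warnings.warn(
                f"stratum ({tissue}, {cond}) has {lengths.size} cells; skipped",
                stacklevel=2,
            )
            continue
        fit = fit_mixture(lengths)
        fits[(tissue, cond)] = fit
        out.loc[idx, "posterior_short"] = posterior_short(fit, lengths)
        # threshold on log-odds: exact for interior thresholds and immune
        # to posterior underflow at extreme lengths (posterior is strictly
        # inside (0, 1) for any finite length)
        lo = log_odds_short(fit, lengths)
        out.loc[idx, "zone"] = np.where(
            lo > logit(threshold), "meristem", "elongation"
        )
    return out, fits


def zone_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Cells per zone in each tissue × condition stratum."""
    return (
        labeled.dropna(subset=["zone"])
        .groupby(["tissue", "treatment", "zone"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
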