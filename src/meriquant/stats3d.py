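"""Statistics for per-cell 3D geometry across BR-signalling conditions.

The workflow mirrors a standard mixed-model analysis of segmented
single-cell geometry: each geometric parameter is transformed to an
approximately normal scale, a random-intercept mixed model (REML) with
treatment and square-root distance from the quiescent centre as fixed
effects and the individual root as the random grouping is fitted per
tissue, pairwise treatment contrasts receive a single-step (Tukey-type)
max-|t| adjustment, families of models and contrasts are corrected with a
two-step adaptive Benjamini–Hochberg procedure, and the share of variance
attributable to BR signalling is reported per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "log": (np.log, np.exp),
    "sqrt": (np.sqrt, np.square),
    "cbrt": (np.cbrt, lambda x: x**3),
    "identity": (lambda x: x, lambda x: x),
}

#: parameter → normalizing transform (length/depth log, surface sqrt,
#: volume cube root, width untransformed); distance enters as sqrt.
DEFAULT_TRANSFORMS = {
    "length": "log",
    "depth": "log",
    "width": "identity",
    "surface_area": "sqrt",
    "volume": "cbrt",
}

GEOMETRY_PARAMETERS = tuple(DEFAULT_TRANSFORMS)


@dataclass
class TransformSpec:
    """Normalizing transforms per geometric parameter."""

    transforms: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    distance_transform: str = "sqrt"

    def validate(self) -> None:
        for name in (*self.transforms.values(), self.distance_transform):
            if name not in _TRANSFORMS:
                raise ValueError(f"unknown transform {name!r}")

    def forward(self, parameter: str):
        return _TRANSFORMS[self.transforms[parameter]][0]

    def inverse(self, parameter: str):
        return _TRANSFORMS[self.transforms[parameter]][1]


def transformed_col(parameter: str) -> str:
    return f"{parameter}_t"


def apply_transform(table: pd.DataFrame, spec: Optional[TransformSpec] = None) -> pd.DataFrame:
    """Add transformed parameter columns and ``sqrt_distance``.

    Raises ``ValueError`` naming the first offending row when a value is
    non-positive under log/sqrt/cbrt (geometry must be strictly positive).
    """
    spec = spec or TransformSpec()
    spec.validate()
    out = table.copy()
    for parameter, name in spec.transforms.items():
        if parameter not in out.columns:
            continue
        values = out[parameter].to_numpy(dtype=float)
        if name != "identity" and np.any(values <= 0):
            row = int(np.argmax(values <= 0))
            raise ValueError(
                f"{parameter!r} must be positive for {name} transform "
                f"(offending row index {out.index[row]})"
            )
        out[transformed_col(parameter)] = _TRANSFORMS[name][0](values)
    dist = out["distance_qc"].to_numpy(dtype=float)
    if np.any(dist < 0):
        raise ValueError("distance_qc must be non-negative")
    out["sqrt_distance"] = _TRANSFORMS[spec.distance_transform][0](dist)
    return out


def anisotropy_index(length, depth, width):
    """Shape anisotropy length² / (depth × width), unitless.

    Values above 1 indicate elongation-dominated shape; isotropic cells
    score 1.
    """
    length = np.asarray(length, dtype=float)
    depth = np.asarray(depth, dtype=float)
    width = np.asarray(width, dtype=float)
    denom = depth * width
    if np.any(denom == 0):
        raise ValueError("depth and width must be non-zero")
    out = length**2 / denom
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedFit:
    """A fitted random-intercept model for one parameter in one tissue."""

    parameter: str
    tissue: Optional[str]
    response_col: str
    fe_params: pd.Series
    cov_fe: pd.DataFrame
    random_var: float
    resid_var: float
    fixed_var: float  # variance of the fixed-effect linear predictor
    ss: Dict[str, float]  # Type II sums of squares per fixed term
    term_pvalues: Dict[str, float]
    model_pvalue: float
    n_obs: int
    n_groups: int
    df_resid: float
    treatment_levels: Tuple[str, ...]
    reference: str
    covariate_mean: float
    singular: bool


def _treatment_coef_name(level: str, reference: str) -> str:
    return f"C(treatment, Treatment('{reference}'))[T.{level}]"


def fit_mixed_model(
    table: pd.DataFrame,
    parameter: str,
    tissue: Optional[str] = None,
    spec: Optional[TransformSpec] = None,
    reference: str = "WT",
    meristem_only: bool = True,
) -> MixedFit:
    """REML fit of ``transform(parameter) ~ treatment + sqrt_distance``
    with a random intercept per root.

    The table is restricted to the requested tissue and (when a ``zone``
    column is present and ``meristem_only``) to meristem cells. A
    singular fit (random-intercept variance estimated at zero) is
    retained with a warning rather than rejected.
    """
    spec = spec or TransformSpec()
    data = table
    if tissue is not None:
        data = data[data["tissue"] == tissue]
    if meristem_only and "zone" in data.columns:
        data = data[data["zone"] == "meristem"]
    data = data.copy()
    col = transformed_col(parameter)
    if col not in data.columns or "sqrt_distance" not in data.columns:
        data = apply_transform(data, spec)
    if data.groupby("treatment")["root_id"].nunique().min() < 2:
        warnings.warn("fewer than 2 roots in some treatment", stacklevel=2)

    formula = f"{col} ~ C(treatment, Treatment('{reference}')) + sqrt_distance"

    def _sane(r) -> bool:
        cov = np.asarray(r.cov_params())
        return bool(np.all(np.isfinite(cov)) and np.abs(cov).max() < 1e8)

    # the default scipy optimizer occasionally collapses to a spurious
    # variance boundary with a broken Hessian; fall back to Powell and
    # keep the best sane REML fit
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["root_id"])
        for method in (None, "powell"):
            cand = model.fit(reml=True) if method is None else model.fit(
                reml=True, method=method
            )
            if _sane(cand) and (res is None or cand.llf > res.llf):
                res = cand
            if res is not None and method is None:
                break
        if res is None:
            res = cand
    random_var = float(np.squeeze(res.cov_re))
    # boundary (singular) fits stop with a tiny positive variance estimate
    singular = random_var < max(1e-8, 1e-2 * float(res.scale))
    if singular:
        warnings.warn(
            f"singular fit for {parameter}/{tissue}: random-intercept "
            "variance is zero",
            stacklevel=2,
        )

    fe = res.fe_params
    cov_fe = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe), : len(fe)],
        index=fe.index,
        columns=fe.index,
    )
    exog = model.exog
    linpred = exog @ fe.to_numpy()
    fixed_var = float(np.var(linpred))

    # Wald tests per fixed term and for the full fixed part
    names = list(fe.index)
    treat_idx = [i for i, n in enumerate(names) if "treatment" in n]
    dist_idx = [i for i, n in enumerate(names) if n == "sqrt_distance"]

    def wald(idx: List[int]) -> float:
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        est = L @ fe.to_numpy()
        vmat = L @ cov_fe.to_numpy() @ L.T
        stat = float(est @ np.linalg.solve(vmat, est))
        return float(stats.chi2.sf(stat, len(idx)))

    term_pvalues = {"treatment": wald(treat_idx), "sqrt_distance": wald(dist_idx)}
    model_pvalue = wald(treat_idx + dist_idx)

    # Type II sums of squares from the fixed-effects ANOVA decomposition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(smf.ols(formula, data).fit(), typ=2)
    ss = {}
    for term in aov.index:
        if "treatment" in term:
            ss["treatment"] = float(aov.loc[term, "sum_sq"])
        elif term == "sqrt_distance":
            ss["sqrt_distance"] = float(aov.loc[term, "sum_sq"])

    levels = tuple(pd.unique(data["treatment"]))
    return MixedFit(
        parameter=parameter,
        tissue=tissue,
        response_col=col,
        fe_params=fe,
        cov_fe=cov_fe,
        random_var=random_var,
        resid_var=float(res.scale),
        fixed_var=fixed_var,
        ss=ss,
        term_pvalues=term_pvalues,
        model_pvalue=model_pvalue,
        n_obs=int(len(data)),
        n_groups=int(data["root_id"].nunique()),
        df_resid=float(len(data) - exog.shape[1]),
        treatment_levels=levels,
        reference=reference,
        covariate_mean=float(data["sqrt_distance"].mean()),
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Post-hoc contrasts
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """One pairwise treatment contrast on the transformed scale."""

    tissue: Optional[str]
    parameter: str
    pair: Tuple[str, str]
    estimate: float
    se: float
    statistic: float
    raw_p: float
    adjusted_p: float
    significant: bool = False
    pct_variance_br: float = np.nan


def posthoc_pairwise(fit: MixedFit, seed: int = 0) -> List[ComparisonResult]:
    """All pairwise treatment contrasts with single-step max-|t| adjustment.

    The adjusted p-value of each contrast is the probability that the
    maximum absolute component of a multivariate t vector — with the
    correlation structure of the fitted contrasts and residual degrees of
    freedom — exceeds the observed |t| (the single-step realization of the
    Tukey procedure; exact for the studentized range in balanced one-way
    layouts and conservative otherwise). The QMC evaluation of the
    multivariate t CDF is seeded for determinism.
    """
    levels = fit.treatment_levels
    if len(levels) < 2:
        raise ValueError("post-hoc contrasts need at least 2 treatment levels")
    names = list(fit.fe_params.index)

    def coef_vector(level: str) -> np.ndarray:
        v = np.zeros(len(names))
        if level != fit.reference:
            v[names.index(_treatment_coef_name(level, fit.reference))] = 1.0
        return v

    pairs = list(combinations(levels, 2))
    L = np.array([coef_vector(a) - coef_vector(b) for a, b in pairs])
    est = L @ fit.fe_params.to_numpy()
    vmat = L @ fit.cov_fe.to_numpy() @ L.T
    se = np.sqrt(np.diag(vmat))
    tval = est / se
    df = max(fit.df_resid - (fit.n_groups - 1), 2.0)
    raw = 2.0 * stats.t.sf(np.abs(tval), df)

    corr = vmat / np.outer(se, se)
    corr = 0.5 * (corr + corr.T)
    out = []
    rng = np.random.default_rng(seed)
    for i, (a, b) in enumerate(pairs):
        if len(pairs) == 1:
            adj = raw[i]
        else:
            lim = np.full(len(pairs), abs(tval[i]))
            # the k(k−1)/2 pairwise contrasts are linearly dependent for
            # k ≥ 3 groups, so the correlation matrix is singular by design
            inside = stats.multivariate_t.cdf(
                lim,
                loc=np.zeros(len(pairs)),
                shape=corr,
                df=df,
                allow_singular=True,
                lower_limit=-lim,
                random_state=rng,
            )
            adj = 1.0 - float(inside)
        adj = float(min(1.0, max(adj, raw[i])))
        out.append(
            ComparisonResult(
                tissue=fit.tissue,
                parameter=fit.parameter,
                pair=(a, b),
                estimate=float(est[i]),
                se=float(se[i]),
                statistic=float(tval[i]),
                raw_p=float(raw[i]),
                adjusted_p=adj,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Two-step adaptive FDR
# ---------------------------------------------------------------------------

def bh_reject(pvalues, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=alpha, method="fdr_bh")[0]


@dataclass
class TwoStepFDRResult:
    stage1_flags: np.ndarray  # per model
    stage2_flags: List[np.ndarray]  # per model, per post-hoc comparison
    stage2_alpha: float
    n_stage1_significant: int
    n_models: int


def two_step_adaptive_fdr(
    model_pvalues: Sequence[float],
    posthoc_pvalues: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> TwoStepFDRResult:
    """Two-step adaptive multiplicity correction across models and contrasts.

    Stage 1 applies Benjamini–Hochberg at level ``alpha`` to the M model
    p-values; with m₁ significant models, stage 2 applies BH at the
    adapted level ``alpha·m₁/M`` to the pooled post-hoc p-values of the
    surviving models (non-surviving models are never tested at stage 2).
    This keeps the false discovery rate at ``alpha`` over the whole
    experiment. With no stage-1 survivors, stage 2 is skipped and the
    adapted level is reported as 0.
    """
    model_p = np.asarray(model_pvalues, dtype=float)
    if len(posthoc_pvalues) != model_p.size:
        raise ValueError("need one post-hoc p-value family per model")
    stage1 = bh_reject(model_p, alpha)
    m1 = int(stage1.sum())
    M = int(model_p.size)
    stage2_alpha = alpha * m1 / M if M else 0.0
    stage2 = [np.zeros(len(ps), dtype=bool) for ps in posthoc_pvalues]
    if m1 > 0:
        pooled, where = [], []
        for i, keep in enumerate(stage1):
            if keep:
                for j, p in enumerate(posthoc_pvalues[i]):
                    pooled.append(p)
                    where.append((i, j))
        if pooled:
            flags = bh_reject(pooled, stage2_alpha)
            for (i, j), f in zip(where, flags):
                stage2[i][j] = bool(f)
    else:
        stage2_alpha = 0.0
    return TwoStepFDRResult(stage1, stage2, float(stage2_alpha), m1, M)


# ---------------------------------------------------------------------------
# Variance explained by BR signalling
# ---------------------------------------------------------------------------

def pct_variance_br(fit: MixedFit) -> float:
    """Percent of total variance attributable to BR signalling.

    The fixed-effect share of the variance (variance of the fixed linear
    predictor over fixed + random-intercept + residual variance) is
    multiplied by the treatment share of the fixed Type II sums of
    squares, isolating the BR-condition part of the fixed effects from
    the distance trend. Returns a percentage in [0, 100].
    """
    total = fit.fixed_var + fit.random_var + fit.resid_var
    if total <= 0:
        raise ValueError("total variance is zero")
    ss_tot = fit.ss.get("treatment", 0.0) + fit.ss.get("sqrt_distance", 0.0)
    share = fit.ss.get("treatment", 0.0) / ss_tot if ss_tot > 0 else 0.0
    return float(100.0 * (fit.fixed_var / total) * share)


# ---------------------------------------------------------------------------
# Whole-analysis convenience
# ---------------------------------------------------------------------------

def analyze_geometry(
    table: pd.DataFrame,
    spec: Optional[TransformSpec] = None,
    parameters: Sequence[str] = GEOMETRY_PARAMETERS,
    tissues: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    reference: str = "WT",
    seed: int = 0,
):
    """Fit every parameter × tissue model and run the full correction.

    Returns a tidy DataFrame of pairwise comparisons (with adjusted
    p-values, two-step significance flags and the BR variance share) and
    the dict of :class:`MixedFit` objects keyed by (parameter, tissue).
    """
    spec = spec or TransformSpec()
    data = apply_transform(table, spec)
    if tissues is None:
        tissues = tuple(pd.unique(data["tissue"]))
    fits, model_p, posthoc = {}, [], []
    for parameter in parameters:
        for tissue in tissues:
            fit = fit_mixed_model(
                data, parameter, tissue=tissue, spec=spec, reference=reference
            )
            fits[(parameter, tissue)] = fit
            model_p.append(fit.model_pvalue)
            posthoc.append(posthoc_pairwise(fit, seed=seed))
    fdr = two_step_adaptive_fdr(
        model_p, [[c.raw_p for c in comps] for comps in posthoc], alpha=alpha
    )
    rows = []
    for i, comps in enumerate(posthoc):
        fit = fits[list(fits)[i]]
        pct = pct_variance_br(fit)
        for j, c in enumerate(comps):
            c.significant = bool(fdr.stage2_flags[i][j])
            c.pct_variance_br = pct
            rows.append(
                {
                    "parameter": c.parameter,
                    "tissue": c.tissue,
                    "pair": f"{c.pair[0]} vs {c.pair[1]}",
                    "estimate": c.estimate,
                    "se": c.se,
                    "raw_p": c.raw_p,
                    "adjusted_p": c.adjusted_p,
                    "significant": c.significant,
                    "pct_variance_br": c.pct_variance_br,
                }
            )
    return pd.DataFrame(rows), fits, fdr
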