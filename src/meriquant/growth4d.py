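"""Per-cell directional growth rates from two-time-point lineage data.

Lineage tracking links every cell at the start of a time-lapse to its
descendants at the end. When a cell divided, daughter lengths and volumes
are summed while depths and widths are averaged, so the merged geometry
describes the same material as the starting cell; rates are the merged
difference divided by the elapsed hours. Condition effects on the rates
are tested by ANCOVA with the starting distance from the QC as covariate,
beginning from an interaction model that is simplified to additive form
when the interaction is not supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

RATE_PARAMETERS = ("length", "width", "depth", "volume")

# Daughter merge rule: extensive parameters add, radial calibres average.
_SUMMED = ("length", "volume")
_AVERAGED = ("width", "depth")


def merge_and_rate(raw_pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse daughters and compute per-hour growth rates.

    Input rows carry one daughter each (columns ``cell_id, condition,
    tissue, dt, distance_qc_t0, distance_qc_t1, <param>_t0,
    <param>_t1``). Lengths and volumes of daughters are summed, depths
    and widths averaged; rates are (merged t₁ − t₀)/Δt in µm/h (µm³/h for
    volume). Rows whose lineage resolves to no daughter (missing t₁
    geometry) are rejected and reported in the returned frame's
    ``attrs["n_rejected"]``.
    """
    t1_cols = [f"{p}_t1" for p in RATE_PARAMETERS]
    ok = raw_pairs[t1_cols].notna().all(axis=1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} rows with unresolved lineage", stacklevel=2)
    rows = []
    for cell_id, g in raw_pairs[ok].groupby("cell_id", sort=False):
        first = g.iloc[0]
        rec = {
            "cell_id": cell_id,
            "condition": first["condition"],
            "tissue": first.get("tissue", ""),
            "dt": float(first["dt"]),
            "distance_qc_t0": float(first["distance_qc_t0"]),
            "distance_qc_t1": float(first["distance_qc_t1"]),
            "n_daughters": int(len(g)),
        }
        for p in RATE_PARAMETERS:
            v0 = float(first[f"{p}_t0"])
            merged = float(g[f"{p}_t1"].sum() if p in _SUMMED else g[f"{p}_t1"].mean())
            rec[f"{p}_t0"] = v0
            rec[f"{p}_t1_merged"] = merged
            rec[f"{p}_rate"] = (merged - v0) / rec["dt"]
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["n_rejected"] = n_rejected
    return out


def anisotropy_rate_4d(pairs: pd.DataFrame) -> pd.Series:
    """Per-hour change of the anisotropy index L²/(D·W) between t₀ and the
    merged t₁ geometry (display index for 4D comparisons)."""
    a0 = pairs["length_t0"] ** 2 / (pairs["depth_t0"] * pairs["width_t0"])
    a1 = pairs["length_t1_merged"] ** 2 / (
        pairs["depth_t1_merged"] * pairs["width_t1_merged"]
    )
    return (a1 - a0) / pairs["dt"]


def filter_meristem_window(
    pairs: pd.DataFrame, d0_max: float = 60.0, d1_max: float = 100.0
) -> pd.DataFrame:
    """Keep cells inside the meristem at both time points.

    Cells must start within ``d0_max`` µm of the QC and remain within
    ``d1_max`` µm at the end, ensuring the compared cells reside in the
    meristem throughout the movie. The number of removed pairs is stored
    in ``attrs["n_removed"]``.
    """
    keep = (pairs["distance_qc_t0"] <= d0_max) & (pairs["distance_qc_t1"] <= d1_max)
    out = pairs[keep].copy()
    out.attrs["n_removed"] = int((~keep).sum())
    return out


@dataclass
class AncovaResult:
    """ANCOVA of one growth-rate parameter across conditions."""

    parameter: str
    model_form: str  # "interaction" or "additive"
    interaction_pvalue: float
    coefficients: pd.Series
    contrasts: pd.DataFrame  # pair, estimate, se, raw_p, adjusted_p
    n_obs: int


def ancova_rates(
    pairs: pd.DataFrame,
    parameter: str,
    alpha_interaction: float = 0.05,
) -> AncovaResult:
    """Test condition effects on a growth rate with distance as covariate.

    Starts from ``rate ~ condition × distance`` and drops the interaction
    when its F-test p-value is ≥ 0.05 (model simplification), then
    reports pairwise condition contrasts evaluated at the covariate mean
    with Benjamini–Hochberg adjustment across the contrast family.
    """
    col = f"{parameter}_rate"
    data = pairs[["condition", "distance_qc_t0", col]].rename(columns={col: "rate"})
    conditions = list(pd.unique(data["condition"]))
    if data["distance_qc_t0"].nunique() < 2:
        raise ValueError("covariate does not vary")
    single = len(conditions) < 2

    full_formula = (
        "rate ~ distance_qc_t0"
        if single
        else "rate ~ C(condition) * distance_qc_t0"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.ols(full_formula, data).fit()
    if single:
        return AncovaResult(
            parameter, "additive", np.nan, full.params,
            pd.DataFrame(columns=["pair", "estimate", "se", "raw_p", "adjusted_p"]),
            int(full.nobs),
        )
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("collinear design")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(full, typ=2)
    inter_term = [t for t in aov.index if ":" in t][0]
    p_inter = float(aov.loc[inter_term, "PR(>F)"])
    if p_inter >= alpha_interaction:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.ols("rate ~ C(condition) + distance_qc_t0", data).fit()
        form = "additive"
    else:
        model = full
        form = "interaction"

    dbar = float(data["distance_qc_t0"].mean())
    names = list(model.params.index)

    def design_row(cond: str) -> np.ndarray:
        v = np.zeros(len(names))
        v[names.index("Intercept")] = 1.0
        main = f"C(condition)[T.{cond}]"
        if main in names:
            v[names.index(main)] = 1.0
        v[names.index("distance_qc_t0")] = dbar
        inter = f"C(condition)[T.{cond}]:distance_qc_t0"
        if inter in names:
            v[names.index(inter)] = dbar
        return v

    rows = []
    for a, b in combinations(conditions, 2):
        L = design_row(a) - design_row(b)
        tt = model.t_test(L)
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "estimate": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "raw_p": float(np.squeeze(tt.pvalue)),
            }
        )
    contrasts = pd.DataFrame(rows)
    contrasts["adjusted_p"] = multipletests(
        contrasts["raw_p"], method="fdr_bh"
    )[1]
    return AncovaResult(
        parameter, form, p_inter, model.params, contrasts, int(model.nobs)
    )


def count_divisions(
    pairs: pd.DataFrame, bins: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Count divided lineages (≥ 2 daughters), binned by starting distance.

    Default bins cover the meristem window in 20 µm steps.
    """
    if bins is None:
        bins = np.arange(0.0, 101.0, 20.0)
    divided = pairs["n_daughters"] >= 2
    cats = pd.cut(pairs["distance_qc_t0"], bins=bins)
    out = (
        pd.DataFrame({"bin": cats, "divided": divided})
        .groupby("bin", observed=False)["divided"]
        .sum()
        .rename("n_divisions")
        .reset_index()
    )
    out["n_divisions"] = out["n_divisions"].astype(int)
    return out
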