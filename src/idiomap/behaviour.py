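"""Brain-behaviour battery: normality-gated GAMs with BH-FDR.

Each behavioural measure predicts a participant's variability score while
controlling for age (linear), sex (indicator) and mean framewise
displacement (penalized smooth).  Whether the measure itself enters
linearly or as a penalized spline is decided by a Lilliefors-corrected
Kolmogorov-Smirnov normality gate on its marginal distribution: measures
that look normal are tested as linear terms, the rest as smooth terms.
P-values across the battery are adjusted with the Benjamini-Hochberg
step-up procedure; q < 0.05 is the conventional discovery threshold.

Smooth terms use cubic B-splines (basis dimension 6) with the penalty
weight chosen by AIC over a coarse log-grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MEASURES

__all__ = [
    "BehaviourError",
    "GateEntry",
    "AssociationResult",
    "PUBLISHED_TERM_KINDS",
    "normality_gate",
    "fit_association",
    "fdr_bh",
    "run_battery",
]


class BehaviourError(ValueError):
    """Invalid input to the behaviour battery."""


#: Term kinds as fixed in the reference analysis of this battery (the
#: four near-normal composites as linear terms, the rest as smooths).
PUBLISHED_TERM_KINDS = {
    "ados_css": "linear",
    "brief_gec": "linear",
    "snap_iv": "linear",
    "vabs_abc": "linear",
    "srs": "smooth",
    "rbs_r": "smooth",
    "ssp": "smooth",
    "nviq": "smooth",
}

ALPHA_GRID = 10.0 ** np.arange(-3, 4)  # penalty weights searched by AIC


@dataclass(frozen=True)
class GateEntry:
    """Normality-gate verdict for one variable."""

    kind: str       # "linear" | "smooth"
    ks_stat: float
    ks_p: float


@dataclass(frozen=True)
class AssociationResult:
    """One measure's association with a variability score."""

    measure: str
    kind: str
    statistic: float   # t for linear terms, Wald chi2/edf (approx F) else
    p: float
    r2: float          # adjusted proportion of variance explained
    coef: float        # linear coefficient (NaN for smooth terms)
    edf: float         # effective dof of the measure term
    n: int


def normality_gate(values, alpha: float = 0.05) -> GateEntry:
    """Lilliefors KS test against a normal with estimated moments.

    Pass (p >= alpha) routes the variable to a linear term; fail routes
    it to a smooth term.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise BehaviourError("need at least 8 values for the normality gate")
    if np.allclose(x.std(), 0.0):
        raise BehaviourError("constant values: normality gate undefined")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    kind = "linear" if p >= alpha else "smooth"
    return GateEntry(kind=kind, ks_stat=float(stat), ks_p=float(p))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise BehaviourError("p-values must be a non-empty 1-D array")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise BehaviourError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(measure: np.ndarray, kind: str, covariates: pd.DataFrame,
            fd_smooth: bool):
    """Assemble (exog DataFrame, smoother data, smooth names)."""
    exog = pd.DataFrame({"const": np.ones(len(measure))})
    if "age" in covariates:
        exog["age"] = covariates["age"].to_numpy(dtype=float)
    if "sex" in covariates:
        sex_m = (covariates["sex"].astype(str) == "M").astype(float)
        if sex_m.std() > 0:
            exog["sex_m"] = sex_m.to_numpy()
    smooth_cols, smooth_names = [], []
    if "mean_fd" in covariates:
        fd = covariates["mean_fd"].to_numpy(dtype=float)
        if fd_smooth:
            smooth_cols.append(fd)
            smooth_names.append("mean_fd")
        else:
            exog["mean_fd"] = fd
    if kind == "linear":
        exog["measure"] = measure
    else:
        smooth_cols.append(measure)
        smooth_names.append("measure")
    return exog, smooth_cols, smooth_names


def _fit_gam(y, exog, smooth_cols, smooth_names):
    """Penalized Gaussian GAM; penalty weight chosen by AIC on a grid."""
    from statsmodels.gam.api import BSplines, GLMGam

    for col in smooth_cols:
        if np.unique(col).size < 7:
            raise BehaviourError(
                "too few unique values for a df=6 spline; consider a "
                "linear term instead")
    bs = BSplines(np.column_stack(smooth_cols),
                  df=[6] * len(smooth_cols), degree=[3] * len(smooth_cols))
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for alpha in ALPHA_GRID:
            res = GLMGam(y, exog=exog, smoother=bs,
                         alpha=[float(alpha)] * len(smooth_cols)).fit()
            if best is None or res.aic < best[0].aic:
                best = (res, alpha)
    return best[0], bs, smooth_names


def _adjusted_r2(y, fitted, edf_total):
    n = len(y)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - rss / tss
    denom = n - edf_total - 1.0
    if denom <= 0:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1.0) / denom


def fit_association(variability, measure, kind: str,
                    covariates: pd.DataFrame,
                    measure_name: str = "measure",
                    fd_smooth: bool = True) -> AssociationResult:
    """Fit one brain-behaviour model and test the measure term.

    ``kind`` must be ``"linear"`` or ``"smooth"`` (normally taken from the
    normality gate).  Covariates enter with fixed kinds: age and sex
    linear, mean FD smooth (unless ``fd_smooth=False``, which makes the
    whole model an ordinary linear regression when the measure is linear
    too).
    """
    if kind not in ("linear", "smooth"):
        raise BehaviourError(f"unknown term kind {kind!r}")
    y = np.asarray(variability, dtype=float)
    m = np.asarray(measure, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(m)
    cov = covariates.reset_index(drop=True)
    for c in cov.columns:
        if c != "sex":
            mask &= ~pd.to_numeric(cov[c]).isna().to_numpy()
    y, m, cov = y[mask], m[mask], cov.loc[mask].reset_index(drop=True)
    n = len(y)
    if n < 20:
        raise BehaviourError(
            f"{measure_name}: only {n} complete cases (< 20)")

    exog, smooth_cols, smooth_names = _design(m, kind, cov, fd_smooth)

    if not smooth_cols:  # fully linear model: plain OLS
        import statsmodels.api as sm

        res = sm.OLS(y, exog).fit()
        coef = float(res.params["measure"])
        return AssociationResult(
            measure=measure_name, kind=kind,
            statistic=float(res.tvalues["measure"]),
            p=float(res.pvalues["measure"]),
            r2=float(res.rsquared_adj), coef=coef, edf=1.0, n=n)

    res, bs, smooth_names = _fit_gam(y, exog, smooth_cols, smooth_names)
    edf = np.asarray(res.edf, dtype=float)
    edf_total = float(edf.sum())
    r2 = _adjusted_r2(y, np.asarray(res.fittedvalues), edf_total)

    if kind == "linear":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = float(res.tvalues["measure"])
            p = float(res.pvalues["measure"])
        return AssociationResult(
            measure=measure_name, kind=kind, statistic=stat, p=p,
            r2=r2, coef=float(res.params["measure"]), edf=1.0, n=n)

    smooth_index = smooth_names.index("measure")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = res.test_significance(smooth_index)
    chi2 = float(np.squeeze(wt.statistic))
    term_edf = float(wt.df_denom)
    stat = chi2 / term_edf if term_edf > 0 else chi2
    return AssociationResult(
        measure=measure_name, kind=kind, statistic=stat,
        p=float(np.squeeze(wt.pvalue)), r2=r2, coef=float("nan"),
        edf=term_edf, n=n)


def run_battery(scores: pd.DataFrame, phenotype: pd.DataFrame,
                measures=MEASURES, scheme: str = "whole",
                gate_alpha: float = 0.05,
                force_linear: bool = False,
                term_plan: str = "ks") -> pd.DataFrame:
    """Gate, fit and FDR-correct the full behavioural battery.

    ``scores`` is the variability-score frame (indexed by id) and
    ``phenotype`` the participant table.  ``term_plan`` selects how term
    kinds are assigned: ``"ks"`` (data-driven gate, default) or
    ``"published"`` (the fixed reference classification).
    ``force_linear=True`` models every term — including mean FD — as
    linear, reproducing the all-linear sensitivity analysis.
    """
    response_col = f"variability_{scheme}"
    if response_col not in scores.columns:
        raise BehaviourError(f"scores table lacks {response_col!r}")
    pheno = phenotype.set_index("id").loc[scores.index]
    y = scores[response_col].to_numpy(dtype=float)
    covariates = pheno[["age", "sex", "mean_fd"]].reset_index(drop=True)

    rows = []
    for measure in measures:
        if measure not in pheno.columns:
            raise BehaviourError(f"phenotype table lacks measure {measure!r}")
        values = pheno[measure].to_numpy(dtype=float)
        try:
            gate = normality_gate(values, alpha=gate_alpha)
        except BehaviourError as exc:
            raise BehaviourError(f"{measure}: {exc}") from exc
        if force_linear:
            kind = "linear"
        elif term_plan == "published":
            kind = PUBLISHED_TERM_KINDS.get(measure, gate.kind)
        elif term_plan == "ks":
            kind = gate.kind
        else:
            raise BehaviourError(f"unknown term_plan {term_plan!r}")
        try:
            fit = fit_association(y, values, kind, covariates,
                                  measure_name=measure,
                                  fd_smooth=not force_linear)
        except BehaviourError as exc:
            raise BehaviourError(f"{measure}: {exc}") from exc
        rows.append({
            "measure": measure, "kind": kind,
            "ks_stat": gate.ks_stat, "ks_p": gate.ks_p,
            "statistic": fit.statistic, "p": fit.p,
            "coef": fit.coef, "edf": fit.edf, "r2": fit.r2, "n": fit.n,
        })
    table = pd.DataFrame(rows)
    table["q"] = fdr_bh(table["p"].to_numpy())
    return table
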