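"""Group inference on variability scores and ROI activation matrices.

Two layers:

* :class:`VariabilityAncova` — a statsmodels-style model object for the
  one-way ANCOVA of a variability score on diagnostic group with age,
  sex, and mean-FD covariates.  ``fit()`` returns an
  :class:`AncovaResults` carrying the group F, partial eta squared,
  covariate tests, adjusted means, and a ``summary()`` table;
  :func:`pairwise_posthoc` refits each pair with a Bonferroni-corrected p
  and a covariate-adjusted Cohen's d.
* ROI-level permutation inference — covariate-adjusted two-sample
  contrasts per ROI with family-wise error control via the permutation
  distribution of the maximum |t| (Freedman-Lane residual shuffling), and
  a one-sample sign-flip analogue for within-group mean activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncovaError",
    "VariabilityAncova",
    "AncovaResults",
    "ancova_main_effect",
    "pairwise_posthoc",
    "roi_group_contrast",
    "one_sample_roi_map",
]

DEFAULT_COVARIATES = ("age", "sex", "mean_fd")


class AncovaError(ValueError):
    """Invalid ANCOVA specification or degenerate data."""


def _prepare(data: pd.DataFrame, response: str, group: str,
             covariates) -> tuple[pd.DataFrame, list[str]]:
    df = data.copy()
    cov_terms = []
    for cov in covariates:
        if cov == "sex":
            df["sex_m"] = (df["sex"].astype(str) == "M").astype(float)
            cov_terms.append("sex_m")
        else:
            df[cov] = pd.to_numeric(df[cov])
            cov_terms.append(cov)
    if df[response].std(ddof=1) == 0:
        raise AncovaError(f"response {response!r} is constant")
    # drop covariates that are constant in this subset (e.g. an all-male
    # sample makes the sex indicator collinear with the intercept)
    kept = []
    for term in cov_terms:
        if df[term].std(ddof=1) > 0:
            kept.append(term)
    return df, kept


@dataclass
class AncovaResults:
    """Fitted one-way ANCOVA: group effect, covariates, adjusted means."""

    response: str
    group_col: str
    f_value: float
    p_value: float
    eta_p2: float
    df_effect: int
    df_resid: int
    covariate_table: pd.DataFrame
    adjusted_means: pd.Series
    coefficients: pd.Series
    anova_table: pd.DataFrame
    model_results: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"One-way ANCOVA: {self.response} ~ {self.group_col} "
            f"+ covariates",
            f"  group effect: F({self.df_effect}, {self.df_resid}) = "
            f"{self.f_value:.3f}, p = {self.p_value:.4g}, "
            f"partial eta^2 = {self.eta_p2:.3f}",
            "  adjusted means:",
        ]
        for g, m in self.adjusted_means.items():
            lines.append(f"    {g}: {m:.4f}")
        lines.append("  covariates:")
        for _, row in self.covariate_table.iterrows():
            lines.append(
                f"    {row['term']}: coef = {row['coef']:+.4f}, "
                f"F = {row['F']:.3f}, p = {row['p']:.4g}, "
                f"partial eta^2 = {row['eta_p2']:.3f}")
        return "\n".join(lines)


class VariabilityAncova:
    """One-way ANCOVA of a score on a group factor with covariates.

    Parameters
    ----------
    data : DataFrame with the response, group column and covariates
        (``sex`` may be the raw M/F column; it is coded as an indicator).
    response : response column name (e.g. ``variability_whole``).
    group : categorical factor column (>= 2 levels, each n >= 2).
    covariates : covariate names; default ``("age", "sex", "mean_fd")``.
    reference : reference level for dummy coding (default ``"TDC"`` when
        present, otherwise the first level).
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 group: str = "group",
                 covariates=DEFAULT_COVARIATES,
                 reference: str | None = None):
        levels = list(pd.unique(data[group]))
        if len(levels) < 2:
            raise AncovaError("need at least 2 groups")
        sizes = data[group].value_counts()
        small = sizes[sizes < 2]
        if not small.empty:
            raise AncovaError(
                f"every group needs n >= 2; too small: "
                f"{small.index.tolist()}")
        if reference is None:
            reference = "TDC" if "TDC" in levels else levels[0]
        self.data, self.cov_terms = _prepare(data, response, group,
                                             covariates)
        self.response = response
        self.group_col = group
        self.reference = reference
        self.levels = [reference] + [l for l in levels if l != reference]

    def fit(self) -> AncovaResults:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        terms = [f"C({self.group_col}, Treatment('{self.reference}'))"]
        terms += self.cov_terms
        formula = f"Q('{self.response}') ~ " + " + ".join(terms)
        try:
            res = smf.ols(formula, data=self.data).fit()
        except Exception as exc:  # pragma: no cover - patsy error passthrough
            raise AncovaError(f"model could not be fit: {exc}") from exc
        if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
            raise AncovaError(
                "singular design; collinear terms among "
                f"{list(res.model.exog_names)}")
        # single factor, no interactions: Type II == Type III
        table = anova_lm(res, typ=2)
        ss_res = float(table.loc["Residual", "sum_sq"])
        grp_row = table.index[0]
        f_val = float(table.loc[grp_row, "F"])
        p_val = float(table.loc[grp_row, "PR(>F)"])
        eta = float(table.loc[grp_row, "sum_sq"]
                    / (table.loc[grp_row, "sum_sq"] + ss_res))

        cov_rows = []
        for term in self.cov_terms:
            ss = float(table.loc[term, "sum_sq"])
            cov_rows.append({
                "term": term,
                "coef": float(res.params[term]),
                "F": float(table.loc[term, "F"]),
                "p": float(table.loc[term, "PR(>F)"]),
                "eta_p2": ss / (ss + ss_res),
            })
        cov_table = pd.DataFrame(
            cov_rows, columns=["term", "coef", "F", "p", "eta_p2"])

        # adjusted means: predicted response per group at sample-mean
        # covariate values
        pred_rows = []
        for level in self.levels:
            row = {self.group_col: level}
            for term in self.cov_terms:
                row[term] = float(self.data[term].mean())
            pred_rows.append(row)
        adj = pd.Series(
            np.asarray(res.predict(pd.DataFrame(pred_rows))),
            index=self.levels, name="adjusted_mean")

        return AncovaResults(
            response=self.response, group_col=self.group_col,
            f_value=f_val, p_value=p_val, eta_p2=eta,
            df_effect=int(table.loc[grp_row, "df"]),
            df_resid=int(table.loc["Residual", "df"]),
            covariate_table=cov_table, adjusted_means=adj,
            coefficients=res.params, anova_table=table, model_results=res)


def ancova_main_effect(data: pd.DataFrame, response: str,
                       group: str = "group",
                       covariates=DEFAULT_COVARIATES,
                       reference: str | None = None) -> AncovaResults:
    """Functional wrapper: build the model and fit it."""
    return VariabilityAncova(data, response, group=group,
                             covariates=covariates,
                             reference=reference).fit()


def pairwise_posthoc(data: pd.DataFrame, response: str,
                     group: str = "group",
                     covariates=DEFAULT_COVARIATES,
                     n_comparisons: int | None = None) -> pd.DataFrame:
    """Pairwise two-group ANCOVAs with Bonferroni correction.

    Each pair is refit as its own two-group ANCOVA.  Cohen's d is the
    covariate-adjusted mean difference over the pooled residual SD of the
    pairwise model; the corrected p is ``min(1, raw p * m)`` with ``m``
    the number of comparisons (default: the number of pairs).
    """
    levels = list(pd.unique(data[group]))
    pairs = list(combinations(levels, 2))
    if n_comparisons is None:
        n_comparisons = len(pairs)
    rows = []
    for a, b in pairs:
        sub = data[data[group].isin([a, b])]
        res = VariabilityAncova(sub, response, group=group,
                                covariates=covariates, reference=a).fit()
        diff = float(res.adjusted_means[b] - res.adjusted_means[a])
        mse = float(res.model_results.mse_resid)
        d = diff / np.sqrt(mse) if mse > 0 else 0.0
        p_raw = res.p_value
        if res.f_value == 0.0:
            p_raw = 1.0
        rows.append({
            "group_a": a, "group_b": b,
            "adj_mean_diff": diff,
            "F": res.f_value,
            "p_raw": p_raw,
            "p_bonf": min(1.0, p_raw * n_comparisons),
            "cohen_d": d,
        })
    return pd.DataFrame(rows)


def _residualizer(Z: np.ndarray):
    # projection onto the orthogonal complement of span(Z)
    pinv = np.linalg.pinv(Z)

    def resid(M):
        return M - Z @ (pinv @ M)

    return resid, np.linalg.matrix_rank(Z)


def roi_group_contrast(matrix: pd.DataFrame, groups: pd.Series,
                       covariates: pd.DataFrame | None = None,
                       n_permutations: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Covariate-adjusted two-sample contrast per ROI with maxT FWE.

    Fits, for each ROI, the regression of the ROI value on a group
    indicator plus covariates, and controls family-wise error with the
    permutation distribution of the maximum |t| across ROIs under
    Freedman-Lane residual shuffling: the reduced (covariate-only) model's
    residuals are permuted, re-residualized, and the group t recomputed.

    Returns a frame with ``t``, ``p_unc`` and ``p_fwe`` per ROI; the sign
    convention is second-level > first-level of the sorted group labels.
    """
    if n_permutations < 100:
        raise AncovaError("n_permutations must be >= 100")
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise AncovaError(f"exactly two groups required, got {levels}")
    Y = matrix.to_numpy(dtype=float)
    n = Y.shape[0]
    x = (np.asarray(groups) == levels[1]).astype(float)
    if covariates is not None:
        cov_df = covariates.copy()
        if "sex" in cov_df:
            cov_df["sex"] = (cov_df["sex"].astype(str) == "M").astype(float)
        C = cov_df.to_numpy(dtype=float)
        keep = C.std(axis=0) > 0
        Z = np.column_stack([np.ones(n), C[:, keep]])
    else:
        Z = np.ones((n, 1))
    resid, rank_z = _residualizer(Z)

    x_t = resid(x[:, None])[:, 0]
    if np.allclose(x_t, 0.0):
        raise AncovaError("group indicator is collinear with covariates")
    Y_t = resid(Y)
    dof = n - rank_z - 1
    if dof <= 0:
        raise AncovaError("no residual degrees of freedom")

    def t_stats(Yr):
        denom = float(x_t @ x_t)
        beta = (x_t @ Yr) / denom
        res = Yr - np.outer(x_t, beta)
        sigma2 = (res**2).sum(axis=0) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / np.sqrt(sigma2 / denom)
        return np.nan_to_num(t, posinf=1e12, neginf=-1e12)

    t_obs = t_stats(Y_t)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        Y_star = resid(Y_t[perm])  # Freedman-Lane: re-residualize on Z
        max_null[b] = np.abs(t_stats(Y_star)).max()
    exceed = (max_null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_fwe = (1 + exceed) / (n_permutations + 1)
    p_unc = 2 * stats.t.sf(np.abs(t_obs), dof)
    return pd.DataFrame(
        {"t": t_obs, "p_unc": p_unc, "p_fwe": p_fwe},
        index=matrix.columns)


def one_sample_roi_map(matrix: pd.DataFrame,
                       n_permutations: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Per-ROI one-sample t against zero with sign-flip maxT FWE."""
    Y = np.asarray(matrix, dtype=float)
    n = Y.shape[0]
    if n < 3:
        raise AncovaError("need n >= 3 rows for a one-sample map")
    if n_permutations < 100:
        raise AncovaError("n_permutations must be >= 100")

    def t_stats(M):
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        return np.nan_to_num(t, posinf=1e12, neginf=-1e12)

    t_obs = t_stats(Y)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n)
        max_null[b] = np.abs(t_stats(Y * signs[:, None])).max()
    exceed = (max_null[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_fwe = (1 + exceed) / (n_permutations + 1)
    p_unc = 2 * stats.t.sf(np.abs(t_obs), n - 1)
    cols = matrix.columns if isinstance(matrix, pd.DataFrame) else None
    return pd.DataFrame({"t": t_obs, "p_unc": p_unc, "p_fwe": p_fwe},
                        index=cols)
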