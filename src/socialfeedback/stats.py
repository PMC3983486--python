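"""Inference layer: split-plot ANOVA and correlation comparisons.

The central procedure is a split-plot (mixed) factorial ANOVA with
two-level within-subject factors (feedback target, feedback desirability,
optionally trait valence) and between-subject factors (culture, place).
Because every within factor has two levels, the analysis decomposes exactly
into orthogonal per-participant contrast variables: the participant mean
carries the between-subject effects, and each within effect (and its
interactions with between factors) lives in the corresponding difference
contrast.  Each contrast variable is submitted to an ordinary Type III
least-squares ANOVA with sum-to-zero contrasts, which tests every within
effect against its own subject-by-effect error term — the classic
univariate mixed-model F tests, valid without sphericity correction since
all within factors are dichotomous.  Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error).

Correlation machinery: Pearson r with Fisher-z confidence intervals,
Fisher's z test for comparing correlations across independent groups,
the Williams (Hotelling-type) t test for two dependent correlations
sharing one variable (df = n - 3), and the hierarchical-regression
F-change test for incremental variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "CorrResult",
    "split_plot_anova",
    "one_sample_t",
    "pearson_with_ci",
    "fisher_z_independent",
    "hotelling_williams_t",
    "hierarchical_f_change",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_num: int
    df_den: int
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class CorrResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float


def _between_formula(between: list[str], covariates: list[str]) -> str:
    terms = [f"C({b}, Sum)" for b in between]
    rhs = "*".join(terms) if terms else "1"
    for cov in covariates:
        rhs += f" + {cov}"
    return rhs


def _effect_label(row_name: str, within_part: tuple[str, ...]) -> str | None:
    """Translate an anova_lm row name plus within-contrast id into the
    conventional effect label, e.g. ('desirability',) x 'C(culture, Sum)'
    -> 'desirability:culture'."""
    if row_name == "Residual":
        return None
    pieces = list(within_part)
    if row_name != "Intercept":
        for token in row_name.split(":"):
            token = token.strip()
            if token.startswith("C(") and ", Sum)" in token:
                pieces.append(token[2:].split(",")[0].strip())
            else:
                pieces.append(token)
    if not pieces:
        return None  # grand-mean test, not a factorial effect
    return ":".join(pieces)


def split_plot_anova(
    scores: pd.DataFrame,
    dv: str,
    within: list[str],
    between: list[str],
    subject: str = "participant_id",
    covariates: list[str] | None = None,
) -> list[AnovaResult]:
    """Split-plot factorial ANOVA on a tidy per-participant cell table.

    ``scores`` holds one row per subject per within-cell with the dependent
    variable in column ``dv``.  All within factors must be two-level.
    Subjects with any missing cell are dropped listwise.  Returns the full
    effect list (all main effects and interactions of within and between
    factors) with Type III sums of squares for the unbalanced
    between-subject design.
    """
    covariates = covariates or []
    for w in within:
        if scores[w].nunique() != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")

    if within:
        wide = scores.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="mean", observed=True
        )
        n_cells = int(np.prod([2] * len(within)))
        if wide.shape[1] != n_cells:
            raise ValueError("incomplete within-cell structure")
        cell_labels = list(wide.columns)
        wide.columns = [f"_cell{i}" for i in range(len(cell_labels))]
    else:
        wide = scores.set_index(subject)[[dv]]
        cell_labels = []
    wide = wide.dropna()
    if wide.empty:
        raise ValueError("no subjects with complete data")

    meta_cols = between + covariates
    meta = scores[[subject, *meta_cols]].drop_duplicates(subject).set_index(subject)
    data = wide.join(meta, how="inner")
    for b in between:
        if data[b].nunique() < 2:
            raise ValueError(f"between factor {b!r} needs at least 2 levels")
        counts = data[b].value_counts()
        if (counts == 0).any():
            raise ValueError(f"empty cell in between factor {b!r}")

    # signed +-1 codes per within factor, in the wide column order
    level_codes = {}
    if within:
        for k, w in enumerate(within):
            levels = sorted(scores[w].unique())
            vals = [c[k] if len(within) > 1 else c for c in cell_labels]
            level_codes[w] = np.array([1.0 if v == levels[0] else -1.0 for v in vals])

    rhs = _between_formula(between, covariates)
    results: list[AnovaResult] = []
    cell_values = data[list(wide.columns)].to_numpy()

    # one contrast model per subset of within factors (the empty subset is
    # the participant mean and carries the between-subject effects)
    for r in range(len(within) + 1):
        for part in combinations(within, r):
            if within:
                weights = np.ones(len(wide.columns))
                for w in part:
                    weights = weights * level_codes[w]
                contrast = cell_values @ weights / len(wide.columns)
            else:
                contrast = cell_values[:, 0]
            df = data[meta_cols].copy()
            df["_y"] = contrast
            fit = smf.ols(f"_y ~ {rhs}", data=df).fit()
            tab = anova_lm(fit, typ=3)
            ss_err = float(tab.loc["Residual", "sum_sq"])
            df_err = int(tab.loc["Residual", "df"])
            for row_name, row in tab.iterrows():
                label = _effect_label(str(row_name), part)
                if label is None:
                    continue
                if not part and str(row_name) == "Intercept":
                    continue  # grand mean, not an effect
                ss = float(row["sum_sq"])
                F = float(row["F"])
                p = float(row["PR(>F)"])
                pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
                if not np.isfinite(F) and (np.isnan(ss) or ss <= 0):
                    # degenerate stratum, e.g. identical within cells
                    F, p, pes = 0.0, 1.0, 0.0
                results.append(
                    AnovaResult(
                        effect=label,
                        df_num=int(row["df"]),
                        df_den=df_err,
                        F=F,
                        p=p,
                        partial_eta_sq=pes,
                    )
                )
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Tidy effects table from a list of ANOVA results."""
    return pd.DataFrame([r.__dict__ for r in results])


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t test; returns (t, df, p).

    A zero-variance sample off the null yields an infinite t with p = 0.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == mu0:
            return 0.0, n - 1, 1.0
        return float(np.sign(x.mean() - mu0) * np.inf), n - 1, 0.0
    t, p = sps.ttest_1samp(x, mu0)
    return float(t), n - 1, float(p)


def pearson_with_ci(x, y, level: float = 0.95) -> CorrResult:
    """Pearson correlation with a Fisher-z confidence interval:
    tanh(atanh(r) +- z_{1-a/2} / sqrt(n - 3))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    q = sps.norm.ppf(1 - (1 - level) / 2)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return CorrResult(
        r=float(r),
        n=n,
        ci_low=float(np.tanh(z - q * se)),
        ci_high=float(np.tanh(z + q * se)),
        p=float(p),
    )


def fisher_z_independent(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher's z test for equality of two correlations from independent
    samples; returns (z, two-sided p)."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), float(2 * sps.norm.sf(abs(z)))


def hotelling_williams_t(
    r12: float, r13: float, r23: float, n: int
) -> tuple[float, int, float]:
    """Williams' t for two dependent correlations sharing variable 1.

    Tests r12 = r13 given the correlation r23 between the two non-shared
    variables; df = n - 3.  Returns (t, df, p).
    """
    if n < 5:
        raise ValueError("need n >= 5")
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], dtype=float)
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    detR = float(np.linalg.det(R))
    rbar = (r12 + r13) / 2.0
    denom = 2.0 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1 - r23) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation structure")
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    return float(t), df, float(2 * sps.t.sf(abs(t), df))


def hierarchical_f_change(
    y, base_predictors, added_predictors
) -> tuple[float, tuple[int, int], float]:
    """F test of the R-squared increment when adding predictors to an OLS
    model (both steps include an intercept).

    Returns (F_change, (df_num, df_den), p) with df_den = n - k_full - 1.
    """
    y = np.asarray(y, dtype=float)
    Xb = np.column_stack([np.asarray(c, dtype=float) for c in base_predictors])
    Xa = np.column_stack([np.asarray(c, dtype=float) for c in added_predictors])
    n = len(y)
    k_base, k_add = Xb.shape[1], Xa.shape[1]
    k_full = k_base + k_add
    Xb1 = sm.add_constant(Xb)
    Xf1 = sm.add_constant(np.column_stack([Xb, Xa]))
    if np.linalg.matrix_rank(Xf1) < k_full + 1:
        raise ValueError("rank-deficient design in the full model")
    r2_base = sm.OLS(y, Xb1).fit().rsquared
    r2_full = sm.OLS(y, Xf1).fit().rsquared
    df_den = n - k_full - 1
    f = ((r2_full - r2_base) / k_add) / ((1 - r2_full) / df_den)
    return float(f), (k_add, df_den), float(sps.f.sf(f, k_add, df_den))
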