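"""Variance comparisons, transformations, and AICc model selection.

This layer mirrors the inference workflow of the migration analysis:
Brown-Forsythe/Levene tests and Fisher variance ratios (with F-based
confidence intervals) for season and sex contrasts; log / z-score /
median-centering / arcsine response transformations; a conservative
|r| <= 0.3 collinearity screen; exhaustive fixed-effect candidate sets fitted
as mixed models with random intercepts for animal identity and year
(maximum likelihood, so log-likelihoods are comparable across fixed-effect
structures); AICc ranking with the parsimony rule (simplest model within
2 AICc of the top); and Nakagawa marginal/conditional R-squared.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LeveneResult",
    "VarianceRatio",
    "ModelCandidate",
    "SelectionResult",
    "R2Pair",
    "levene_test",
    "variance_ratio_ci",
    "transform_variables",
    "collinearity_screen",
    "aicc",
    "select_model",
    "nakagawa_r2",
    "generate_candidates",
    "GaussianMixedEngine",
    "BinomialGLMEngine",
    "fit_characteristic_models",
    "variance_comparison_report",
]


# ---------------------------------------------------------------------------
# Variance tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeveneResult:
    F: float
    df1: int
    df2: int
    p_value: float
    center: str


@dataclass(frozen=True)
class VarianceRatio:
    ratio: float
    ci_low: float
    ci_high: float
    alpha: float


def levene_test(values, groups, center: str = "median") -> LeveneResult:
    """Levene/Brown-Forsythe test of variance homogeneity.

    One-way ANOVA F statistic on absolute deviations from the group center
    (median by default, the robust Brown-Forsythe form; mean available).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    devs, ns = [], []
    for g in labels:
        v = values[groups == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        c = np.median(v) if center == "median" else np.mean(v)
        devs.append(np.abs(v - c))
        ns.append(len(v))
    n = int(sum(ns))
    k = len(labels)
    all_devs = np.concatenate(devs)
    grand = all_devs.mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in devs)
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        F = 0.0 if ss_between <= 0 else np.inf
    else:
        F = float((ss_between / df1) / (ss_within / df2))
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return LeveneResult(F=F, df1=df1, df2=df2, p_value=p, center=center)


def variance_ratio_ci(
    var1: float, n1: int, var2: float, n2: int, alpha: float = 0.05
) -> VarianceRatio:
    """Fisher ratio of two variances with a central-F confidence interval."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    if n1 <= 1 or n2 <= 1:
        raise ValueError("need n > 1 in both groups")
    ratio = var1 / var2
    df1, df2 = n1 - 1, n2 - 1
    lo = ratio / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    hi = ratio / stats.f.ppf(alpha / 2.0, df1, df2)
    return VarianceRatio(ratio=float(ratio), ci_low=float(lo), ci_high=float(hi), alpha=alpha)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def transform_variables(table: pd.DataFrame, spec: dict) -> pd.DataFrame:
    """Apply named column transforms; returns a copy.

    ``spec`` maps column -> one of:

    * ``'log'`` — natural log (errors on non-positive values, naming the row)
    * ``'log1p'`` — log(x + 1), for counts with zeros
    * ``'zscore'`` — center on the mean, divide by the SD
    * ``('center_median_by', group_col)`` — subtract the per-group median
      (the seasonal departure-timing response)
    * ``'arcsine'`` — arcsin(p) * 2 / pi, rescaling [0, 1] onto [0, 1]
    """
    out = table.copy()
    for col, tf in spec.items():
        x = out[col].to_numpy(dtype=float)
        if isinstance(tf, tuple) and tf[0] == "center_median_by":
            med = out.groupby(tf[1])[col].transform("median").to_numpy(dtype=float)
            out[col] = x - med
        elif tf == "log":
            bad = np.flatnonzero(x <= 0)
            if len(bad):
                raise ValueError(
                    f"log transform of {col!r}: non-positive value at row {bad[0]}"
                )
            out[col] = np.log(x)
        elif tf == "log1p":
            out[col] = np.log1p(x)
        elif tf == "zscore":
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zscore of constant column {col!r}")
            out[col] = (x - x.mean()) / sd
        elif tf == "arcsine":
            if np.any((x < 0) | (x > 1)):
                raise ValueError(f"arcsine transform of {col!r} needs values in [0, 1]")
            out[col] = np.arcsin(x) * 2.0 / math.pi
        else:
            raise ValueError(f"unknown transform {tf!r} for column {col!r}")
    return out


def collinearity_screen(
    table: pd.DataFrame, terms: list[str], r_max: float = 0.3
) -> tuple[list[tuple[str, str]], list[tuple[str, str, float]]]:
    """Pairwise Pearson screen; pairs with |r| > r_max are mutually exclusive.

    Returns (allowed_pairs, excluded_pairs_with_r).  Constant columns are
    flagged by pairing them with every other term (undefined correlation).
    """
    allowed, excluded = [], []
    for a, b in itertools.combinations(terms, 2):
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        if xa.std() == 0 or xb.std() == 0:
            excluded.append((a, b, float("nan")))
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        if abs(r) > r_max:
            excluded.append((a, b, r))
        else:
            allowed.append((a, b))
    return allowed, excluded


# ---------------------------------------------------------------------------
# AICc and selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCandidate:
    terms: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    delta_aicc: float = np.nan
    result: object = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class SelectionResult:
    selected: ModelCandidate
    candidates: tuple[ModelCandidate, ...]
    n_failed: int = 0
    log: str = ""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def select_model(candidates: list[ModelCandidate]) -> SelectionResult:
    """Parsimony rule: simplest model within 2 AICc of the top.

    Ties on parameter count break by lower AICc, then by lexicographic term
    order (recorded in the log).
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    best_aicc = min(c.aicc for c in candidates)
    ranked = [
        ModelCandidate(c.terms, c.k, c.loglik, c.aicc, c.aicc - best_aicc, c.result)
        for c in candidates
    ]
    within = [c for c in ranked if c.delta_aicc <= 2.0]
    within.sort(key=lambda c: (c.k, c.aicc, c.terms))
    chosen = within[0]
    log = ""
    ties = [c for c in within if c.k == chosen.k and c.aicc == chosen.aicc]
    if len(ties) > 1:
        log = f"tie on (k, AICc) among {[t.terms for t in ties]}; lexicographic order used"
    return SelectionResult(
        selected=chosen,
        candidates=tuple(sorted(ranked, key=lambda c: c.aicc)),
        log=log,
    )


@dataclass(frozen=True)
class R2Pair:
    r2_marginal: float
    r2_conditional: float


def nakagawa_r2(var_fixed: float, var_random_sum: float, var_residual: float) -> R2Pair:
    """Marginal and conditional R-squared from variance components."""
    if min(var_fixed, var_random_sum, var_residual) < 0:
        raise ValueError("variance components must be non-negative")
    denom = var_fixed + var_random_sum + var_residual
    if denom == 0:
        raise ValueError("all variance components are zero")
    return R2Pair(
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + var_random_sum) / denom,
    )


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------


def generate_candidates(
    main_terms: list[str],
    interactions: list[tuple[str, str]] | None = None,
    excluded_pairs: list[tuple[str, str]] | None = None,
    max_candidates: int = 5000,
) -> list[tuple[str, ...]]:
    """All sub-models of a global model, respecting marginality and exclusions.

    Interactions enter only alongside both main effects; term pairs flagged by
    the collinearity screen never co-occur.  The intercept-only model is the
    empty tuple.
    """
    interactions = interactions or []
    excluded = {frozenset(p) for p in (excluded_pairs or [])}
    out: list[tuple[str, ...]] = []
    for r in range(len(main_terms) + 1):
        for mains in itertools.combinations(main_terms, r):
            if any(frozenset((a, b)) <= set(mains) for a, b in excluded):
                continue
            valid_ints = [i for i in interactions if i[0] in mains and i[1] in mains]
            for ri in range(len(valid_ints) + 1):
                for ints in itertools.combinations(valid_ints, ri):
                    terms = tuple(mains) + tuple(f"{a}:{b}" for a, b in ints)
                    out.append(terms)
    if len(out) > max_candidates:
        warnings.warn(
            f"candidate set capped at {max_candidates} (generated {len(out)})",
            stacklevel=2,
        )
        out = out[:max_candidates]
    return out


# ---------------------------------------------------------------------------
# Fitting engines (external contract: term set -> loglik, k, estimates, VCs)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineFit:
    loglik: float
    k: int
    n: int
    coefficients: pd.DataFrame  # index term, columns estimate, se, p
    var_fixed: float
    var_random_sum: float
    var_residual: float
    converged: bool


def _formula(response: str, terms: tuple[str, ...]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


class GaussianMixedEngine:
    """Linear mixed models with crossed random intercepts (ML).

    Random intercepts for each grouping column (animal identity and year by
    default) are fitted as crossed variance components on a single dummy
    group; log-likelihoods come from maximum likelihood, not REML, so AICc is
    comparable across fixed-effect structures.
    """

    def __init__(self, group_cols: tuple[str, ...] = ("animal_id", "year")):
        self.group_cols = group_cols

    def fit(self, data: pd.DataFrame, response: str, terms: tuple[str, ...]) -> EngineFit:
        import statsmodels.formula.api as smf

        df = data.copy()
        df["_one"] = 1
        vc = {g: f"0 + C({g})" for g in self.group_cols}
        model = smf.mixedlm(
            _formula(response, terms), df, groups="_one", vc_formula=vc, re_formula="0"
        )
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "bfgs", "cg", "powell"):
                try:
                    cand = model.fit(reml=False, method=method, maxiter=500)
                except Exception:
                    continue
                if res is None or (cand.converged and not res.converged):
                    res = cand
                if res.converged:
                    break
        if res is None:
            raise RuntimeError("mixed model fit failed under every optimizer")
        fe = res.fe_params
        coefs = pd.DataFrame(
            {
                "estimate": fe,
                "se": res.bse_fe.reindex(fe.index),
                "p": res.pvalues.reindex(fe.index),
            }
        )
        fitted_fixed = np.asarray(model.exog @ fe.to_numpy())
        var_fixed = float(np.var(fitted_fixed))
        var_random = float(np.sum(res.vcomp) * res.scale)
        k = len(fe) + len(self.group_cols) + 1  # + VCs + residual sigma^2
        return EngineFit(
            loglik=float(res.llf),
            k=k,
            n=int(res.nobs),
            coefficients=coefs,
            var_fixed=var_fixed,
            var_random_sum=var_random,
            var_residual=float(res.scale),
            converged=bool(res.converged),
        )


class BinomialGLMEngine:
    """Fixed-effects logistic regression for binary responses.

    Stands behind the same engine contract as the Gaussian mixed engine; the
    random intercepts are omitted (see the methods note), which leaves the
    AICc ranking of fixed-effect structures and the coefficient signs intact.
    """

    def fit(self, data: pd.DataFrame, response: str, terms: tuple[str, ...]) -> EngineFit:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.glm(
            _formula(response, terms), data, family=sm.families.Binomial()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        coefs = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "p": res.pvalues}
        )
        eta = np.asarray(model.exog @ res.params.to_numpy())
        return EngineFit(
            loglik=float(res.llf),
            k=len(res.params),
            n=int(res.nobs),
            coefficients=coefs,
            var_fixed=float(np.var(eta)),
            var_random_sum=0.0,
            var_residual=math.pi**2 / 3.0,  # logit-link distribution variance
            converged=bool(res.converged),
        )


# ---------------------------------------------------------------------------
# Characteristic models and variance reports
# ---------------------------------------------------------------------------


def fit_characteristic_models(
    data: pd.DataFrame,
    response: str,
    main_terms: list[str],
    interactions: list[tuple[str, str]] | None = None,
    engine=None,
    r_max: float = 0.3,
) -> dict:
    """Candidate-set mixed-model selection for one migration characteristic.

    Numeric terms are screened for collinearity at ``r_max``; all sub-models
    of the global model respecting marginality and the screen are fitted with
    the engine (Gaussian mixed model with animal/year random intercepts by
    default), ranked by AICc, and the parsimony rule applied.  Returns the
    selection, the selected model's coefficient table and Nakagawa R².
    """
    engine = engine or GaussianMixedEngine()
    numeric = [
        t for t in main_terms
        if t in data.columns and pd.api.types.is_numeric_dtype(data[t])
    ]
    _, excluded = collinearity_screen(data, numeric, r_max=r_max) if len(numeric) > 1 else ([], [])
    excluded_pairs = [(a, b) for a, b, _ in excluded]
    term_sets = generate_candidates(main_terms, interactions, excluded_pairs)

    candidates: list[ModelCandidate] = []
    n_failed = 0
    for terms in term_sets:
        try:
            fit = engine.fit(data, response, terms)
        except Exception:
            n_failed += 1
            continue
        if not fit.converged or not np.isfinite(fit.loglik):
            n_failed += 1
            continue
        try:
            a = aicc(fit.loglik, fit.k, fit.n)
        except ValueError:
            n_failed += 1
            continue
        candidates.append(ModelCandidate(terms, fit.k, fit.loglik, a, result=fit))
    if not candidates:
        raise RuntimeError(f"no candidate converged for response {response!r}")
    selection = select_model(candidates)
    best: EngineFit = selection.selected.result
    r2 = nakagawa_r2(best.var_fixed, best.var_random_sum, best.var_residual)
    return {
        "response": response,
        "selection": selection,
        "coefficients": best.coefficients,
        "r2": r2,
        "n_failed": n_failed,
    }


#: per-characteristic transforms used before the Levene/Fisher contrasts;
#: departure timing stays on raw Julian-day deviations (median-centered per
#: season), counts use log1p, strictly positive characteristics use log.
VARIANCE_TRANSFORMS = {
    "departure": ("center_median_by", "season"),
    "distance_roamed": "log",
    "duration": "log",
    "mean_speed": "log",
    "n_stopovers": "log1p",
}

CHARACTERISTICS = list(VARIANCE_TRANSFORMS)


def variance_comparison_report(
    events: pd.DataFrame,
    characteristics: list[str] | None = None,
    transforms: dict | None = None,
) -> pd.DataFrame:
    """Season- and sex-contrast variance table for the migration characteristics.

    For each characteristic and each of the four contrasts (spring vs autumn
    within females and within males; female vs male within spring and within
    autumn): group variances, Levene (Brown-Forsythe) F/df/p and the Fisher
    variance ratio with its CI.  Contrasts with an empty cell are skipped
    with a flag row.
    """
    characteristics = characteristics or CHARACTERISTICS
    transforms = VARIANCE_TRANSFORMS if transforms is None else transforms
    spec = {c: transforms[c] for c in characteristics if c in transforms}
    work = transform_variables(events, spec)
    contrasts = [
        ("female", "season", work[work["sex"] == "F"], "spring", "autumn"),
        ("male", "season", work[work["sex"] == "M"], "spring", "autumn"),
        ("spring", "sex", work[work["season"] == "spring"], "F", "M"),
        ("autumn", "sex", work[work["season"] == "autumn"], "F", "M"),
    ]
    rows = []
    for char in characteristics:
        for name, axis, sub, g1, g2 in contrasts:
            v1 = sub.loc[sub[axis] == g1, char].to_numpy(dtype=float)
            v2 = sub.loc[sub[axis] == g2, char].to_numpy(dtype=float)
            row = {
                "characteristic": char,
                "contrast": f"{name}: {g1} vs {g2}",
                "n1": len(v1),
                "n2": len(v2),
            }
            if len(v1) < 2 or len(v2) < 2:
                row["skipped"] = True
                rows.append(row)
                continue
            var1, var2 = v1.var(ddof=1), v2.var(ddof=1)
            row.update({"var1": var1, "var2": var2, "skipped": False})
            lev = levene_test(
                np.concatenate([v1, v2]),
                np.array([g1] * len(v1) + [g2] * len(v2)),
            )
            row.update({"levene_F": lev.F, "df1": lev.df1, "df2": lev.df2,
                        "levene_p": round(lev.p_value, 3)})
            if var1 > 0 and var2 > 0:
                vr = variance_ratio_ci(var1, len(v1), var2, len(v2))
                row.update(
                    {"ratio": vr.ratio, "ci_low": vr.ci_low, "ci_high": vr.ci_high}
                )
            else:
                row["undefined_ratio"] = True
            rows.append(row)
    return pd.DataFrame(rows)
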