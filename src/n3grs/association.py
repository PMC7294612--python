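"""Covariate-adjusted association between the GRS and responder class.

Two model families, both fitted by maximum likelihood via statsmodels:

* a proportional-odds (cumulative-logit) ordinal model of the three ordered
  responder classes R < NR < AR on GRS, age, sex and BMI — one slope per
  predictor shared across the two cutpoints; and
* a binary logistic model of AR (=1) vs R (=0) after non-responders have been
  excluded upstream.

Both are oriented so that an odds ratio above 1 per GRS unit means a higher
score shifts a participant toward adverse response. The ordinal linear
predictor uses cumulative logits logit P(Y <= k) = t_k - x'b, so a positive
GRS coefficient raises the probability of the higher (AR-ward) classes.

Predicted per-class probability curves over a GRS grid carry 95% confidence
bands obtained by the delta method on the linear predictor and transformed
through the logistic link, so bands stay inside [0, 1]; the middle (NR)
category, a difference of two link transforms, uses the delta method on the
probability scale, clipped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .genotypes import GenotypeMatrix, MafComparison, compare_maf
from .panel import SnpPanel
from .response import CLASS_ORDER, ResponderLabel

__all__ = [
    "AssociationFit",
    "ProbabilityCurve",
    "SeparationError",
    "fit_ordinal",
    "fit_binary",
    "predict_curves",
    "subgroup_maf_tests",
    "proportional_odds_diagnostic",
]

_Z95 = stats.norm.ppf(0.975)
_MAX_ABS_COEF = 30.0  # |log-odds| beyond this on standardized data ≈ separation


class SeparationError(RuntimeError):
    """Raised when (quasi-)complete separation makes the MLE diverge."""


@dataclass
class AssociationFit:
    """Fitted ordinal or binary logistic association model."""

    model_kind: str  # "ordinal" | "binary"
    beta_grs: float
    or_grs: float
    se_beta: float
    wald_p: float
    covariate_coefficients: dict[str, dict[str, float]]
    cutpoints: Optional[np.ndarray]  # ordinal only; strictly increasing
    n_obs: int
    converged: bool
    class_labels: tuple[str, ...]
    n_per_class: dict[str, int]
    log_likelihood: float
    # internals needed to draw probability curves without refitting
    params: np.ndarray = field(repr=False, default=None)
    cov_params: np.ndarray = field(repr=False, default=None)
    exog_names: list[str] = field(repr=False, default_factory=list)
    covariate_means: dict[str, float] = field(repr=False, default_factory=dict)
    grs_range: tuple[float, float] = field(repr=False, default=(0.0, 0.0))
    threshold_raw: Optional[np.ndarray] = field(repr=False, default=None)

    def to_report(self) -> dict:
        """JSON-serializable model report."""
        report = {
            "model_kind": self.model_kind,
            "n_obs": self.n_obs,
            "n_per_class": self.n_per_class,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "grs": {
                "beta": self.beta_grs,
                "odds_ratio": self.or_grs,
                "se": self.se_beta,
                "wald_p": self.wald_p,
            },
            "covariates": self.covariate_coefficients,
        }
        if self.cutpoints is not None:
            report["cutpoints"] = [float(c) for c in self.cutpoints]
        return report


@dataclass
class ProbabilityCurve:
    """Per-class predicted probabilities over a GRS grid with 95% bands."""

    grs_grid: np.ndarray
    categories: tuple[str, ...]
    probabilities: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    extrapolated: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in self.categories:
            for i, g in enumerate(self.grs_grid):
                rows.append(
                    (g, cat, self.probabilities[cat][i],
                     self.ci_low[cat][i], self.ci_high[cat][i])
                )
        return pd.DataFrame(
            rows, columns=["grs", "category", "probability", "ci_low", "ci_high"]
        )


def _encode_sex(values: pd.Series, reference: Optional[str] = None) -> pd.Series:
    """Binary 0/1 indicator from a two-level category (reference level → 0)."""
    levels = sorted(values.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"sex must have at most 2 levels, got {levels}")
    ref = reference if reference is not None else levels[0]
    return (values.astype(str) != ref).astype(float)


def _design(
    grs: Sequence[float],
    covariates: Optional[pd.DataFrame],
    sex_reference: Optional[str],
) -> pd.DataFrame:
    X = pd.DataFrame({"grs": np.asarray(grs, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).copy()
        for name in cov.columns:
            col = cov[name]
            if not pd.api.types.is_numeric_dtype(col):
                col = _encode_sex(col, sex_reference)
            X[name] = np.asarray(col, dtype=float)
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    return X


def _check_variation(X: pd.DataFrame) -> None:
    if np.ptp(X["grs"].to_numpy()) == 0:
        raise ValueError("GRS is constant across participants; slope undefined")


def _check_separation(params: np.ndarray, bse: np.ndarray, kind: str) -> None:
    if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > _MAX_ABS_COEF):
        raise SeparationError(
            f"{kind} fit shows signs of complete separation "
            f"(|coef| max {np.max(np.abs(params)):.3g}); "
            "check for a predictor that perfectly splits the classes"
        )


def _covariate_table(
    names: Sequence[str], params: np.ndarray, bse: np.ndarray
) -> dict[str, dict[str, float]]:
    out = {}
    for i, name in enumerate(names):
        if name == "grs":
            continue
        z = params[i] / bse[i]
        out[name] = {
            "coef": float(params[i]),
            "se": float(bse[i]),
            "wald_p": float(2 * stats.norm.sf(abs(z))),
        }
    return out


def fit_ordinal(
    labels: Sequence[str],
    grs: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    class_order: Sequence[str] = CLASS_ORDER,
    sex_reference: Optional[str] = None,
) -> AssociationFit:
    """Proportional-odds model of ordered responder class on GRS + covariates.

    Requires all classes of ``class_order`` to be present; with fewer
    observed classes use :func:`fit_binary` instead. Reported OR is per
    1-unit GRS increase, oriented so OR > 1 means higher GRS shifts
    participants toward the last (adverse) class.
    """
    labels = pd.Series(list(labels), dtype=str)
    observed = set(labels.unique())
    expected = [c for c in class_order]
    missing = [c for c in expected if c not in observed]
    if missing:
        raise ValueError(
            f"classes {missing} absent from data; the ordinal model needs all "
            f"of {expected} — fit a binary model on the two observed classes "
            "instead"
        )
    endog = pd.Series(
        pd.Categorical(labels, categories=expected, ordered=True)
    )
    X = _design(grs, covariates, sex_reference)
    _check_variation(X)
    n_params = X.shape[1] + len(expected) - 1
    if len(endog) <= n_params:
        raise ValueError(f"n_obs={len(endog)} too small for {n_params} parameters")

    model = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", gtol=1e-10, maxiter=1000, disp=0)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(method="lbfgs", maxiter=2000, disp=0,
                            pgtol=1e-10, factr=10.0)
    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    _check_separation(params[: X.shape[1]], bse[: X.shape[1]], "ordinal")
    if not converged:
        warnings.warn("ordinal fit did not converge; fit is flagged", RuntimeWarning)

    k_exog = X.shape[1]
    cutpoints = model.transform_threshold_params(params)[1:-1]
    beta = float(params[0])
    se = float(bse[0])
    z = beta / se
    counts = labels.value_counts()
    return AssociationFit(
        model_kind="ordinal",
        beta_grs=beta,
        or_grs=float(np.exp(beta)),
        se_beta=se,
        wald_p=float(2 * stats.norm.sf(abs(z))),
        covariate_coefficients=_covariate_table(X.columns, params, bse),
        cutpoints=np.asarray(cutpoints, dtype=float),
        n_obs=int(len(endog)),
        converged=converged,
        class_labels=tuple(expected),
        n_per_class={c: int(counts.get(c, 0)) for c in expected},
        log_likelihood=float(res.llf),
        params=params,
        cov_params=np.asarray(res.cov_params(), dtype=float),
        exog_names=list(X.columns),
        covariate_means={c: float(X[c].mean()) for c in X.columns if c != "grs"},
        grs_range=(float(X["grs"].min()), float(X["grs"].max())),
        threshold_raw=params[k_exog:].copy(),
    )


def fit_binary(
    labels: Sequence[str],
    grs: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    positive_class: str = "AR",
    negative_class: str = "R",
    sex_reference: Optional[str] = None,
) -> AssociationFit:
    """Logistic regression of adverse response (AR=1) vs response (R=0).

    Non-responders must be excluded before calling; any other label raises.
    """
    labels = pd.Series(list(labels), dtype=str)
    extra = set(labels.unique()) - {positive_class, negative_class}
    if extra:
        raise ValueError(
            f"unexpected classes {sorted(extra)}: exclude them (e.g. NR) "
            "before the binary fit"
        )
    if labels.nunique() < 2:
        raise ValueError(
            f"only class {labels.unique().tolist()} present; "
            "binary fit needs both classes"
        )
    endog = (labels == positive_class).astype(float).to_numpy()
    X = _design(grs, covariates, sex_reference)
    _check_variation(X)
    exog = sm.add_constant(X, prepend=True)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(endog, exog)
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    except (np.linalg.LinAlgError, PerfectSeparationError) as err:
        raise SeparationError(
            "binary fit failed with a singular or divergent Hessian, which "
            "typically indicates (quasi-)complete separation: a predictor "
            f"perfectly splits the classes ({err})"
        ) from err
    converged = bool(res.mle_retvals.get("converged", False))
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    _check_separation(params, bse, "binary")
    if not converged:
        warnings.warn("binary fit did not converge; fit is flagged", RuntimeWarning)

    names = list(exog.columns)  # const, grs, covariates...
    i_grs = names.index("grs")
    beta = float(params[i_grs])
    se = float(bse[i_grs])
    z = beta / se
    counts = labels.value_counts()
    return AssociationFit(
        model_kind="binary",
        beta_grs=beta,
        or_grs=float(np.exp(beta)),
        se_beta=se,
        wald_p=float(2 * stats.norm.sf(abs(z))),
        covariate_coefficients=_covariate_table(names, params, bse),
        cutpoints=None,
        n_obs=int(len(endog)),
        converged=converged,
        class_labels=(negative_class, positive_class),
        n_per_class={
            negative_class: int(counts.get(negative_class, 0)),
            positive_class: int(counts.get(positive_class, 0)),
        },
        log_likelihood=float(res.llf),
        params=params,
        cov_params=np.asarray(res.cov_params(), dtype=float),
        exog_names=names,
        covariate_means={c: float(X[c].mean()) for c in X.columns if c != "grs"},
        grs_range=(float(X["grs"].min()), float(X["grs"].max())),
    )


def _threshold_jacobian(raw: np.ndarray) -> np.ndarray:
    """d cutpoints / d raw threshold params.

    Cutpoints are parameterized as t_1 = r_1, t_k = t_{k-1} + exp(r_k), so the
    Jacobian is lower triangular with 1 in the first column and exp(r_k)
    below the diagonal of column k.
    """
    k = len(raw)
    jac = np.zeros((k, k))
    for row in range(k):
        jac[row, 0] = 1.0
        for col in range(1, row + 1):
            jac[row, col] = np.exp(raw[col])
    return jac


def predict_curves(
    fit: AssociationFit,
    grs_grid: Sequence[float],
    covariate_profile: Optional[Mapping[str, float]] = None,
) -> ProbabilityCurve:
    """Per-class probability curves over a GRS grid with 95% bands.

    Continuous covariates are held at their sample means (sex at the observed
    proportion) unless a ``covariate_profile`` overrides them. Grid points
    outside the observed GRS range are still computed but the curve is
    flagged as extrapolated.
    """
    if not fit.converged:
        raise ValueError("cannot draw curves from a non-converged fit")
    grid = np.asarray(grs_grid, dtype=float)
    profile = dict(fit.covariate_means)
    if covariate_profile:
        unknown = set(covariate_profile) - set(profile)
        if unknown:
            raise KeyError(f"unknown covariates in profile: {sorted(unknown)}")
        profile.update(covariate_profile)
    extrapolated = bool(grid.min() < fit.grs_range[0] or grid.max() > fit.grs_range[1])

    if fit.model_kind == "binary":
        return _binary_curves(fit, grid, profile, extrapolated)
    return _ordinal_curves(fit, grid, profile, extrapolated)


def _binary_curves(fit, grid, profile, extrapolated) -> ProbabilityCurve:
    neg, pos = fit.class_labels
    names = fit.exog_names  # const, grs, covariates
    rows = np.empty((len(grid), len(names)))
    for j, name in enumerate(names):
        if name == "const":
            rows[:, j] = 1.0
        elif name == "grs":
            rows[:, j] = grid
        else:
            rows[:, j] = profile[name]
    eta = rows @ fit.params
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", rows, fit.cov_params, rows))
    p = expit(eta)
    lo, hi = expit(eta - _Z95 * se_eta), expit(eta + _Z95 * se_eta)
    return ProbabilityCurve(
        grs_grid=grid,
        categories=(neg, pos),
        probabilities={pos: p, neg: 1 - p},
        ci_low={pos: lo, neg: 1 - hi},
        ci_high={pos: hi, neg: 1 - lo},
        extrapolated=extrapolated,
    )


def _ordinal_curves(fit, grid, profile, extrapolated) -> ProbabilityCurve:
    cats = fit.class_labels
    names = fit.exog_names  # grs, covariates (no constant)
    p_exog = len(names)
    k_thresh = len(fit.threshold_raw)
    x = np.empty((len(grid), p_exog))
    for j, name in enumerate(names):
        x[:, j] = grid if name == "grs" else profile[name]
    beta = fit.params[:p_exog]
    cuts = fit.cutpoints
    jac_t = _threshold_jacobian(fit.threshold_raw)
    eta = x @ beta

    # cumulative logits gamma_k = t_k - eta, with delta-method SEs
    gammas, grads = [], []
    for k in range(k_thresh):
        gamma = cuts[k] - eta
        grad = np.zeros((len(grid), p_exog + k_thresh))
        grad[:, :p_exog] = -x
        grad[:, p_exog:] = jac_t[k]
        gammas.append(gamma)
        grads.append(grad)
    se_g = [
        np.sqrt(np.einsum("ij,jk,ik->i", g, fit.cov_params, g)) for g in grads
    ]

    cum = [expit(g) for g in gammas]  # P(Y <= class k)
    probs = {cats[0]: cum[0]}
    for k in range(1, k_thresh):
        probs[cats[k]] = cum[k] - cum[k - 1]
    probs[cats[-1]] = 1 - cum[-1]

    ci_low, ci_high = {}, {}
    # extreme classes: pure link transforms of one cumulative logit
    ci_low[cats[0]] = expit(gammas[0] - _Z95 * se_g[0])
    ci_high[cats[0]] = expit(gammas[0] + _Z95 * se_g[0])
    ci_low[cats[-1]] = 1 - expit(gammas[-1] + _Z95 * se_g[-1])
    ci_high[cats[-1]] = 1 - expit(gammas[-1] - _Z95 * se_g[-1])
    # middle classes: difference of two links → probability-scale delta method
    for k in range(1, k_thresh):
        dpdparam = (
            (cum[k] * (1 - cum[k]))[:, None] * grads[k]
            - (cum[k - 1] * (1 - cum[k - 1]))[:, None] * grads[k - 1]
        )
        se_p = np.sqrt(np.einsum("ij,jk,ik->i", dpdparam, fit.cov_params, dpdparam))
        ci_low[cats[k]] = np.clip(probs[cats[k]] - _Z95 * se_p, 0.0, 1.0)
        ci_high[cats[k]] = np.clip(probs[cats[k]] + _Z95 * se_p, 0.0, 1.0)

    return ProbabilityCurve(
        grs_grid=grid,
        categories=cats,
        probabilities=probs,
        ci_low=ci_low,
        ci_high=ci_high,
        extrapolated=extrapolated,
    )


def subgroup_maf_tests(
    matrix: GenotypeMatrix,
    panel: SnpPanel,
    labels: Sequence[ResponderLabel],
    pair: tuple[str, str],
    treatment: str,
) -> list[MafComparison]:
    """Per-SNP allele-count chi-squared between two responder subgroups.

    ``pair`` names the two classes to compare (e.g. ("R", "AR")) within one
    treatment's labels.
    """
    group_a = [l.participant_id for l in labels
               if l.treatment == treatment and l.label == pair[0]]
    group_b = [l.participant_id for l in labels
               if l.treatment == treatment and l.label == pair[1]]
    if not group_a or not group_b:
        empty = pair[0] if not group_a else pair[1]
        raise ValueError(
            f"subgroup {empty!r} is empty for pair {pair[0]}-vs-{pair[1]} "
            f"({treatment})"
        )
    idx = {pid: i for i, pid in enumerate(matrix.participant_ids)}
    rows_a = [idx[p] for p in group_a]
    rows_b = [idx[p] for p in group_b]
    results = []
    for snp_id in panel.snp_ids:
        col = matrix.column(snp_id)
        a = col[rows_a]
        a = a[~np.isnan(a)]
        b = col[rows_b]
        b = b[~np.isnan(b)]
        results.append(
            compare_maf(
                (int(a.sum()), 2 * len(a)), (int(b.sum()), 2 * len(b)), snp_id
            )
        )
    return results


def proportional_odds_diagnostic(
    labels: Sequence[str],
    grs: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    class_order: Sequence[str] = CLASS_ORDER,
    sex_reference: Optional[str] = None,
) -> dict:
    """Optional check of the common-slope (proportional-odds) assumption.

    Fits a separate binary logit to each cumulative split of the ordered
    classes and Wald-tests the equality of the two GRS slopes (a pragmatic
    Brant-style diagnostic). Returns the per-split slopes and the p-value of
    the equality test. Off by default in the pipeline.
    """
    labels = pd.Series(list(labels), dtype=str)
    X = sm.add_constant(_design(grs, covariates, sex_reference), prepend=True)
    order = list(class_order)
    codes = labels.map({c: i for i, c in enumerate(order)}).to_numpy()
    slopes, variances = [], []
    for k in range(len(order) - 1):
        y = (codes > k).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0)
        i = list(X.columns).index("grs")
        slopes.append(float(res.params.iloc[i]))
        variances.append(float(res.cov_params().iloc[i, i]))
    diff = slopes[0] - slopes[-1]
    se = float(np.sqrt(variances[0] + variances[-1]))  # ignores covariance: conservative screen
    z = diff / se if se > 0 else 0.0
    return {
        "slopes_per_split": slopes,
        "slope_difference": diff,
        "p_value": float(2 * stats.norm.sf(abs(z))),
    }


def write_fit_json(fit: AssociationFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_report(), indent=2))
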