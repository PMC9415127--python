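"""Weighted linear mixed meta-model for the fertiliser-N legacy effect.

The response is the per-record legacy effect ΔRE. The model is

    y = X beta + u_site + u_year + eps,
    u_site ~ N(0, sigma2_site),  u_year ~ N(0, sigma2_year),
    eps_i  ~ N(0, sigma2_resid / w_i),

with *crossed* random intercepts for experiment location and sampling year,
and replicate weights ``w_i = n_years_pooled * n_field_reps`` acting as
inverse-variance multipliers on the residual. Variance components are
profiled out: writing gamma_s = sigma2_site/sigma2_resid and gamma_y
analogously,

    V(gamma) = gamma_s Zs Zs' + gamma_y Zy Zy' + W^{-1},

beta-hat and sigma2-hat have closed forms given gamma, and (gamma_s,
gamma_y) is found by a bounded derivative-free search on [0, inf)^2 (coarse
grid, then Powell refinement; criterion change tolerance 1e-10). ML is used
whenever models with different fixed effects are compared (REML criteria
are not comparable across fixed-effect sets); final reported estimates use
REML.

Model ranking uses the small-sample corrected Akaike criterion (AICc) with
k counting all estimated parameters: fixed effects plus the two random
variances plus the residual variance. Candidate fixed-effect subsets are
enumerated exhaustively ("dredge"); models within 2 AICc of the best are
considered indistinguishable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DomainError, RankDeficientError
from .ltedata import Method
from .recovery import RecoveryRecord

__all__ = [
    "CANDIDATE_TERMS",
    "ModelSpec",
    "ModelData",
    "MixedModelFit",
    "DredgeEntry",
    "DredgeResult",
    "MeanDeltaResult",
    "MethodContrast",
    "standardise",
    "fit_mixed",
    "aicc",
    "dredge",
    "mean_delta_re",
    "method_contrast",
    "covariate_diagnostics",
]

#: the nine candidate fixed-effect terms, in canonical order
CANDIDATE_TERMS = (
    "gdd",
    "temp_seasonality",
    "aridity",
    "crop",
    "duration",
    "avg_n_rate",
    "clay",
    "method",
    "residue_retained",
)

_CONTINUOUS = {
    "gdd": "gdd",
    "temp_seasonality": "temp_seasonality",
    "aridity": "aridity",
    "duration": "duration_years",
    "avg_n_rate": "avg_n_rate",
    "clay": "clay_pct",
}


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: which fixed terms enter besides the intercept.

    The crossed random intercepts (site, year) and the replicate weights are
    structural and not selectable.
    """

    fixed_terms: tuple[str, ...] = ()
    estimation: Literal["ML", "REML"] = "REML"

    def __post_init__(self):
        unknown = set(self.fixed_terms) - set(CANDIDATE_TERMS)
        if unknown:
            raise DomainError(f"unknown fixed term(s): {sorted(unknown)}")


@dataclass
class ModelData:
    """Standardised design data: one row per RecoveryRecord.

    ``frame`` holds y (delta_re), weight, site, year and one column per
    design regressor; ``terms`` maps each candidate term to its columns;
    ``scaling`` maps each z-scored column to its original (mean, sd) so the
    transformation can be inverted exactly.
    """

    frame: pd.DataFrame
    terms: dict[str, list[str]]
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.frame["site"].nunique()

    def unscale(self, column: str, z) -> np.ndarray:
        """Invert the z-scoring of a continuous column."""
        mean, sd = self.scaling[column]
        return np.asarray(z) * sd + mean


@dataclass
class MixedModelFit:
    """Result of one mixed-model fit."""

    beta: dict[str, float]
    beta_se: dict[str, float]
    sigma2_site: float
    sigma2_year: float
    sigma2_resid: float
    gammas: tuple[float, float]
    loglik: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    estimation: str
    fixed_terms: tuple[str, ...]
    xtvix_inv: np.ndarray | None = None


def _records_frame(records: Sequence[RecoveryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.covariates
        rows.append(
            {
                "y": r.delta_re,
                "weight": r.weight,
                "site": r.site_id,
                "year": r.year,
                "gdd": c.gdd,
                "temp_seasonality": c.temp_seasonality,
                "aridity": c.aridity,
                "duration_years": float(c.duration_years),
                "avg_n_rate": c.avg_n_rate,
                "clay_pct": c.clay_pct,
                "crop": r.crop.value,
                "method": r.method.value,
                "residue_retained": float(c.residue_retained),
            }
        )
    return pd.DataFrame(rows)


def standardise(
    records: Sequence[RecoveryRecord],
    terms: Iterable[str] = CANDIDATE_TERMS,
) -> ModelData:
    """Build the standardised design for the requested candidate terms.

    Continuous co-variables are z-scored (unweighted (x - mean)/SD, sample
    SD); categorical co-variables are one-hot encoded against the
    alphabetically first observed level; the binary residue flag stays 0/1.
    A continuous co-variable with fewer than 2 distinct values is an error
    (it cannot be scaled and would be inestimable anyway).
    """
    if not records:
        raise DomainError("no records to standardise")
    terms = [t for t in CANDIDATE_TERMS if t in set(terms)]
    raw = _records_frame(records)
    frame = raw[["y", "weight", "site", "year"]].copy()
    term_cols: dict[str, list[str]] = {}
    scaling: dict[str, tuple[float, float]] = {}

    for term in terms:
        if term in _CONTINUOUS:
            col = _CONTINUOUS[term]
            x = raw[col].to_numpy(dtype=float)
            if np.unique(x).size < 2:
                raise DomainError(
                    f"continuous co-variable '{col}' has no variation; cannot standardise"
                )
            mean, sd = float(x.mean()), float(x.std(ddof=1))
            frame[col] = (x - mean) / sd
            scaling[col] = (mean, sd)
            term_cols[term] = [col]
        elif term in ("crop", "method"):
            levels = sorted(raw[term].unique())
            cols = []
            for level in levels[1:]:  # alphabetically first level = reference
                col = f"{term}_{level}"
                frame[col] = (raw[term] == level).astype(float)
                cols.append(col)
            term_cols[term] = cols
        elif term == "residue_retained":
            frame["residue_retained"] = raw["residue_retained"]
            term_cols[term] = ["residue_retained"]
    return ModelData(frame=frame, terms=term_cols, scaling=scaling)


def _indicator(labels: pd.Series) -> np.ndarray:
    levels = {v: j for j, v in enumerate(pd.unique(labels))}
    Z = np.zeros((len(labels), len(levels)))
    for i, v in enumerate(labels):
        Z[i, levels[v]] = 1.0
    return Z


def _profiled_criterion(
    gammas: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    ZsZst: np.ndarray,
    ZyZyt: np.ndarray,
    winv: np.ndarray,
    reml: bool,
):
    """-2 log (restricted) likelihood profiled over beta and sigma2."""
    n, p = X.shape
    gs, gy = float(gammas[0]), float(gammas[1])
    V = gs * ZsZst + gy * ZyZyt
    V = V + np.diag(winv) if V.ndim == 2 else np.diag(winv)
    c_and_lower = cho_factor(V, lower=True)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c_and_lower[0]))))
    vi_x = cho_solve(c_and_lower, X)
    vi_y = cho_solve(c_and_lower, y)
    xtvix = X.T @ vi_x
    try:
        beta = np.linalg.solve(xtvix, X.T @ vi_y)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError("X'V^{-1}X is singular") from exc
    resid = y - X @ beta
    q = float(resid @ cho_solve(c_and_lower, resid))
    if q <= 0:
        q = np.finfo(float).tiny
    if reml:
        dof = n - p
        sigma2 = q / dof
        sign, logdet_x = np.linalg.slogdet(xtvix)
        if sign <= 0:
            raise RankDeficientError("X'V^{-1}X is singular")
        m2l = dof * np.log(2 * np.pi * sigma2) + logdet_v + logdet_x + dof
    else:
        sigma2 = q / n
        m2l = n * np.log(2 * np.pi * sigma2) + logdet_v + n
    return m2l, beta, sigma2, xtvix


_START_GRID = (0.0, 0.05, 0.5, 5.0, 50.0)
_GAMMA_MAX = 1e6


def _build_design(data: ModelData, fixed_terms: Sequence[str]):
    frame = data.frame
    names = ["intercept"]
    cols = [np.ones(len(frame))]
    for term in [t for t in CANDIDATE_TERMS if t in set(fixed_terms)]:
        if term not in data.terms:
            raise DomainError(f"term '{term}' absent from the standardised design")
        for col in data.terms[term]:
            names.append(col)
            cols.append(frame[col].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(
            f"design matrix is rank deficient for terms {tuple(fixed_terms)}"
        )
    return X, names


def fit_mixed(
    spec: ModelSpec,
    data: ModelData,
    fix_gammas: Optional[tuple[float, float]] = None,
) -> MixedModelFit:
    """Fit the weighted crossed-random-intercepts model.

    ``fix_gammas`` pins the variance ratios (sigma2_site/sigma2_resid,
    sigma2_year/sigma2_resid) instead of optimising them; ``(0, 0)``
    collapses the model to closed-form weighted least squares. Free
    estimation requires at least 2 sites.
    """
    frame = data.frame
    w = frame["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise DomainError("weights must be > 0")
    y = frame["y"].to_numpy(dtype=float)
    X, names = _build_design(data, spec.fixed_terms)
    n, p = X.shape
    if fix_gammas is None and frame["site"].nunique() < 2:
        raise DomainError("free variance estimation needs at least 2 sites")

    Zs = _indicator(frame["site"])
    Zy = _indicator(frame["year"])
    ZsZst = Zs @ Zs.T
    ZyZyt = Zy @ Zy.T
    winv = 1.0 / w
    reml = spec.estimation == "REML"

    def crit(g):
        return _profiled_criterion(np.asarray(g, dtype=float), X, y, ZsZst, ZyZyt, winv, reml)[0]

    converged = True
    if fix_gammas is not None:
        gammas = (float(fix_gammas[0]), float(fix_gammas[1]))
    else:
        best = min(
            itertools.product(_START_GRID, _START_GRID), key=lambda g: crit(g)
        )
        res = optimize.minimize(
            crit,
            x0=np.asarray(best, dtype=float),
            method="Powell",
            bounds=[(0.0, _GAMMA_MAX), (0.0, _GAMMA_MAX)],
            options={"xtol": 1e-10, "ftol": 1e-10, "maxiter": 500},
        )
        converged = bool(res.success)
        gammas = (float(res.x[0]), float(res.x[1]))
        if crit(best) < res.fun:  # keep whichever point is actually best
            gammas = best

    m2l, beta, sigma2, xtvix = _profiled_criterion(
        np.asarray(gammas), X, y, ZsZst, ZyZyt, winv, reml
    )
    xtvix_inv = np.linalg.inv(xtvix)
    se = np.sqrt(np.maximum(np.diag(xtvix_inv) * sigma2, 0.0))
    n_params = p + 3
    loglik = -0.5 * m2l
    aicc_val = aicc(loglik, n_params, n) if n > n_params + 1 else float("inf")
    return MixedModelFit(
        beta=dict(zip(names, beta.tolist())),
        beta_se=dict(zip(names, se.tolist())),
        sigma2_site=gammas[0] * sigma2,
        sigma2_year=gammas[1] * sigma2,
        sigma2_resid=sigma2,
        gammas=gammas,
        loglik=loglik,
        n_obs=n,
        n_params=n_params,
        aicc=aicc_val,
        converged=converged,
        estimation=spec.estimation,
        fixed_terms=tuple(spec.fixed_terms),
        xtvix_inv=xtvix_inv * sigma2,
    )


def aicc(loglik: float, n_params: int, n_obs: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    k, n = n_params, n_obs
    if n <= k + 1:
        raise DomainError(f"AICc undefined: n_obs={n} <= n_params+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class DredgeEntry:
    spec: ModelSpec
    fit: Optional[MixedModelFit]
    aicc: float
    delta_aicc: float
    converged: bool


@dataclass
class DredgeResult:
    """Exhaustively ranked candidate models (ascending AICc)."""

    entries: list[DredgeEntry]
    best_set: list[DredgeEntry]  # delta_aicc <= 2 relative to the best

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "terms": ["+".join(e.spec.fixed_terms) or "(intercept)" for e in self.entries],
                "n_params": [e.fit.n_params if e.fit else np.nan for e in self.entries],
                "aicc": [e.aicc for e in self.entries],
                "delta_aicc": [e.delta_aicc for e in self.entries],
                "converged": [e.converged for e in self.entries],
            }
        )


def dredge(
    data: ModelData,
    candidate_terms: Sequence[str] = CANDIDATE_TERMS,
    estimation: Literal["ML"] = "ML",
) -> DredgeResult:
    """Fit every subset of the candidate terms and rank by AICc.

    All subset fits use ML: likelihoods from REML fits are not comparable
    between models with different fixed effects. Non-converged or singular
    subsets are kept, flagged, and ranked after every converged model. Ties
    in AICc are broken by fewer parameters, then by the lexicographic term
    set, so the ranking is deterministic and independent of input order.
    """
    candidate_terms = tuple(t for t in CANDIDATE_TERMS if t in set(candidate_terms))
    entries: list[DredgeEntry] = []
    for r in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, r):
            spec = ModelSpec(fixed_terms=subset, estimation="ML")
            try:
                f = fit_mixed(spec, data)
                entries.append(
                    DredgeEntry(spec, f, f.aicc, np.nan, f.converged)
                )
            except (RankDeficientError, np.linalg.LinAlgError):
                entries.append(DredgeEntry(spec, None, float("inf"), np.nan, False))
    entries.sort(
        key=lambda e: (
            not e.converged,
            e.aicc,
            e.fit.n_params if e.fit else np.inf,
            e.spec.fixed_terms,
        )
    )
    best_aicc = entries[0].aicc
    for e in entries:
        e.delta_aicc = e.aicc - best_aicc
    best_set = [e for e in entries if e.converged and e.delta_aicc <= 2.0]
    return DredgeResult(entries=entries, best_set=best_set)


@dataclass
class MeanDeltaResult:
    """Weighted mean ΔRE: mixed-model intercept and plain weighted mean."""

    estimate: float  # intercept of the weighted intercept-only mixed model
    se: float
    df: int
    ci_low: float
    ci_high: float
    plain_weighted_mean: float
    fit: MixedModelFit


def mean_delta_re(
    records: Sequence[RecoveryRecord],
    estimation: Literal["ML", "REML"] = "REML",
    fix_gammas: Optional[tuple[float, float]] = None,
    weighted: bool = True,
    statistic: Literal["delta_re", "re_1st", "re_lt"] = "delta_re",
) -> MeanDeltaResult:
    """Weighted average legacy effect across all records, with 95% CI.

    The primary estimate is the intercept of the weighted intercept-only
    mixed model (REML by default); the plain weighted mean is reported
    alongside. The CI is Wald-t with df = n_obs - n_sites. ``weighted=False``
    sets all weights to 1 (sensitivity analysis). ``statistic`` selects the
    response: the legacy effect by default, or either recovery fraction
    (records lacking that fraction, e.g. direct-ΔRE ones, are then dropped).
    """
    if statistic != "delta_re":
        records = [r for r in records if getattr(r, statistic) is not None]
    if not records:
        raise DomainError("no records")
    raw = _records_frame(records)
    if statistic != "delta_re":
        raw["y"] = [getattr(r, statistic) for r in records]
    if not weighted:
        raw["weight"] = 1.0
    data = ModelData(frame=raw[["y", "weight", "site", "year"]].copy(), terms={})
    fit = fit_mixed(ModelSpec(fixed_terms=(), estimation=estimation), data, fix_gammas)
    est = fit.beta["intercept"]
    se = fit.beta_se["intercept"]
    df = fit.n_obs - data.n_sites
    if df <= 0:
        raise DomainError("no residual degrees of freedom for the CI")
    tcrit = float(stats.t.ppf(0.975, df))
    w = raw["weight"].to_numpy(dtype=float)
    y = raw["y"].to_numpy(dtype=float)
    return MeanDeltaResult(
        estimate=est,
        se=se,
        df=df,
        ci_low=est - tcrit * se,
        ci_high=est + tcrit * se,
        plain_weighted_mean=float(np.sum(w * y) / np.sum(w)),
        fit=fit,
    )


@dataclass
class MethodContrast:
    """ΔRE difference between the 15N and the subplot method.

    The contrast is isotope15N minus subplot, so a positive value means the
    labelled-fertiliser method yields larger legacy-effect estimates (as
    expected when added-nitrogen interactions depress its first-season
    recovery).
    """

    contrast_all: float
    se_all: float
    p_all: float
    n_all: int
    contrast_paired: float
    se_paired: float
    p_paired: float
    n_paired: int
    outlier_dropped: Optional[str] = None  # "site:year:method" if the rule fired


def _method_model(records: Sequence[RecoveryRecord], estimation: str):
    data = standardise(records, terms=["method"])
    fit = fit_mixed(ModelSpec(fixed_terms=("method",), estimation=estimation), data)
    # reference level is alphabetically first = isotope15N, so the dummy
    # coefficient estimates subplot - isotope15N; flip the sign
    est = -fit.beta["method_subplot"]
    se = fit.beta_se["method_subplot"]
    df = fit.n_obs - data.n_sites
    p = 2.0 * float(stats.t.sf(abs(est / se), df))
    return est, se, p, fit, data


def method_contrast(
    records: Sequence[RecoveryRecord],
    estimation: Literal["ML", "REML"] = "REML",
    drop_outlier: bool = False,
) -> MethodContrast:
    """Method effect on ΔRE, on all records and on the paired subset.

    The paired subset keeps only site-years where both methods were applied,
    giving the most direct comparison. ``drop_outlier=True`` additionally
    removes, from the paired subset, the single record with the largest
    absolute studentised residual if it exceeds 3 (off by default; when it
    fires the dropped record is identified in the result).
    """
    usable = [r for r in records if r.method in (Method.isotope15N, Method.subplot)]
    methods = {r.method for r in usable}
    if methods != {Method.isotope15N, Method.subplot}:
        raise DomainError("method_contrast needs records from both methods")
    est_a, se_a, p_a, _, _ = _method_model(usable, estimation)

    by_sy: dict[tuple[str, int], set[Method]] = {}
    for r in usable:
        by_sy.setdefault((r.site_id, r.year), set()).add(r.method)
    paired_keys = {k for k, m in by_sy.items() if len(m) == 2}
    paired = [r for r in usable if (r.site_id, r.year) in paired_keys]
    if not paired:
        raise DomainError("no site-year offers both methods")

    dropped = None
    est_p, se_p, p_p, fit_p, data_p = _method_model(paired, estimation)
    if drop_outlier:
        resid = _studentised_residuals(fit_p, data_p)
        i = int(np.argmax(np.abs(resid)))
        if abs(resid[i]) > 3.0:
            r = paired[i]
            dropped = f"{r.site_id}:{r.year}:{r.method.value}"
            paired = paired[:i] + paired[i + 1 :]
            est_p, se_p, p_p, fit_p, data_p = _method_model(paired, estimation)

    return MethodContrast(
        contrast_all=est_a,
        se_all=se_a,
        p_all=p_a,
        n_all=len(usable),
        contrast_paired=est_p,
        se_paired=se_p,
        p_paired=p_p,
        n_paired=len(paired),
        outlier_dropped=dropped,
    )


def _studentised_residuals(fit: MixedModelFit, data: ModelData) -> np.ndarray:
    frame = data.frame
    X, names = _build_design(data, fit.fixed_terms)
    beta = np.array([fit.beta[n] for n in names])
    resid = frame["y"].to_numpy(dtype=float) - X @ beta
    w = frame["weight"].to_numpy(dtype=float)
    marg_sd = np.sqrt(fit.sigma2_site + fit.sigma2_year + fit.sigma2_resid / w)
    return resid / marg_sd


@dataclass
class CovariateDiagnostics:
    correlations: pd.DataFrame  # Pearson r among continuous co-variables
    collinear_pairs: list[tuple[str, str, float]]  # |r| > 0.8
    response_shape: dict[str, dict[str, float]]  # skewness/kurtosis summaries


def covariate_diagnostics(
    records: Sequence[RecoveryRecord], threshold: float = 0.8
) -> CovariateDiagnostics:
    """Collinearity screen plus distribution-shape summary.

    Pearson correlations among the continuous co-variables, flagging pairs
    with |r| above the threshold, and skewness/excess-kurtosis of the three
    recovery statistics as a numerical stand-in for density-plot normality
    checks.
    """
    raw = _records_frame(records)
    cols = list(_CONTINUOUS.values())
    corr = raw[cols].corr(method="pearson")
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(cols)
        for b in cols[i + 1 :]
        if abs(corr.loc[a, b]) > threshold
    ]
    shape = {}
    series = {
        "delta_re": np.array([r.delta_re for r in records], dtype=float),
        "re_1st": np.array([r.re_1st for r in records if r.re_1st is not None]),
        "re_lt": np.array([r.re_lt for r in records if r.re_lt is not None]),
    }
    for name, x in series.items():
        if x.size >= 3:
            shape[name] = {
                "skewness": float(stats.skew(x, bias=False)),
                "excess_kurtosis": float(stats.kurtosis(x, bias=False)),
            }
    return CovariateDiagnostics(
        correlations=corr, collinear_pairs=flagged, response_shape=shape
    )
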