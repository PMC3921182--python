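"""Repeated-measures mixed models of ln(rf) and AICc multimodel inference.

The response is the monthly selection ratio ln(rf) of one bird for one
unit, measured repeatedly across months.  The model is a linear mixed
model with a random intercept per bird and serially correlated
within-bird residuals:

    y_it = x_it' beta + u_i + e_it,   u_i ~ N(0, sigma_u^2),
    corr(e_it, e_it') = rho^{|t - t'|}   (AR(1), integer month lags)

or compound symmetry (rho = 0 in the residual, so the bird intercept
alone carries the within-bird correlation).  Fits are maximum likelihood
via a profiled GLS likelihood and a deterministic quasi-Newton search, so
identical data always reproduce identical estimates.

Multimodel inference over the meteorological covariates follows the
information-theoretic recipe: all subsets of {thermal_height,
thermal_velocity, wind_speed} on top of a fixed base model, ranked by
AICc, with Akaike weights, shrinkage (full-set) model-averaged
coefficients, unconditional standard errors, and per-parameter
importance (the summed weight of models containing the parameter).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MET_TERMS = ("thermal_height", "thermal_velocity", "wind_speed")


# ---------------------------------------------------------------------------
# design matrices (treatment coding, first level reference)
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Metadata needed to rebuild design rows for predictions."""

    terms: list[str]
    levels: dict[str, list] = field(default_factory=dict)  # categorical term -> levels
    means: dict[str, float] = field(default_factory=dict)  # continuous term -> mean
    columns: list[str] = field(default_factory=list)
    term_columns: dict[str, list[int]] = field(default_factory=dict)

    @property
    def categorical_terms(self) -> list[str]:
        return [t for t in self.terms if ":" not in t and t in self.levels]

    def row(self, assignment: dict) -> np.ndarray:
        """One design row; unspecified continuous terms sit at their mean."""
        blocks = [np.array([1.0])]
        for term in self.terms:
            blocks.append(self._term_values(term, assignment))
        return np.concatenate(blocks)

    def _term_values(self, term: str, assignment: dict) -> np.ndarray:
        if ":" in term:
            a, b = term.split(":")
            return np.outer(self._term_values(a, assignment),
                            self._term_values(b, assignment)).ravel()
        if term in self.levels:
            lv = self.levels[term]
            val = assignment[term]
            return np.array([1.0 if val == l else 0.0 for l in lv[1:]])
        return np.array([float(assignment.get(term, self.means[term]))])


def build_design(
    data: pd.DataFrame,
    terms: list[str],
    categorical: set[str] | None = None,
) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix with intercept, dummy-coded factors, interactions 'a:b'.

    A term is treated as categorical when its dtype is non-numeric, when
    listed in ``categorical``, or when named ``month`` (months enter the
    models as seasons, not as a linear trend).
    """
    categorical = set() if categorical is None else set(categorical)
    categorical.add("month")
    info = DesignInfo(terms=list(terms))

    base_terms = sorted({p for t in terms for p in t.split(":")})
    for t in base_terms:
        if t not in data.columns:
            raise ValueError(f"model term {t!r} not in data")
        if t in categorical or not pd.api.types.is_numeric_dtype(data[t]):
            lv = sorted(pd.unique(data[t]).tolist())
            if len(lv) < 2:
                raise ValueError(f"factor {t!r} has a single level (aliased)")
            info.levels[t] = lv
        else:
            info.means[t] = float(data[t].mean())

    def term_block(term: str) -> tuple[np.ndarray, list[str]]:
        if ":" in term:
            a, b = term.split(":")
            block_a, names_a = term_block(a)
            block_b, names_b = term_block(b)
            cols, names = [], []
            for i, na in enumerate(names_a):
                for j, nb in enumerate(names_b):
                    cols.append(block_a[:, i] * block_b[:, j])
                    names.append(f"{na}:{nb}")
            return np.column_stack(cols), names
        if term in info.levels:
            lv = info.levels[term]
            block = np.column_stack(
                [(data[term] == l).to_numpy(float) for l in lv[1:]]
            )
            return block, [f"{term}[{l}]" for l in lv[1:]]
        return data[[term]].to_numpy(float), [term]

    blocks = [np.ones((len(data), 1))]
    info.columns = ["intercept"]
    info.term_columns = {}
    for term in terms:
        block, names = term_block(term)
        start = sum(b.shape[1] for b in blocks)
        info.term_columns[term] = list(range(start, start + block.shape[1]))
        blocks.append(block)
        info.columns.extend(names)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient for terms {terms}")
    return X, info


def independent_terms(
    data: pd.DataFrame,
    terms: list[str],
    categorical: set[str] | None = None,
) -> list[str]:
    """Greedily keep terms that leave the design matrix full rank.

    Small panels routinely alias attribute factors (e.g. every breeder is
    an adult); terms are admitted in the given order and a term that
    would make the design rank deficient is dropped.
    """
    kept: list[str] = []
    for term in terms:
        try:
            build_design(data, kept + [term], categorical)
        except ValueError:
            continue
        kept.append(term)
    return kept


# ---------------------------------------------------------------------------
# mixed-model fit
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Fixed terms, covariance structure and grouping of one candidate model."""

    fixed_terms: list[str]
    covariance: str = "ar1"  # "ar1" | "compound_symmetry"
    grouping: str = "bird_id"
    time: str = "month"
    response: str = "ln_rf"
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.covariance not in ("ar1", "compound_symmetry"):
            raise ValueError(f"unknown covariance structure {self.covariance!r}")


@dataclass
class FitResult:
    """Likelihood fit (ML or REML) of one mixed model."""

    loglik: float
    k: int
    n: int
    beta: pd.Series
    cov_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    rho: float
    spec: ModelSpec
    design: DesignInfo
    method: str = "ml"
    df_den: dict[str, float] | None = None  # between-within df per term
    converged: bool = True

    @property
    def coefficients(self) -> dict[str, tuple[float, float]]:
        se = np.sqrt(np.diag(self.cov_beta))
        return {name: (float(b), float(s))
                for name, b, s in zip(self.beta.index, self.beta.to_numpy(), se)}

    def wald_tests(self) -> pd.DataFrame:
        """Per-term Wald F tests.

        Denominator degrees of freedom follow the between-within scheme:
        factors constant within a bird are tested against the bird-level
        df, time-varying terms against the within-bird residual df.
        """
        rows = []
        b = self.beta.to_numpy()
        for term, cols in self.design.term_columns.items():
            L = np.zeros((len(cols), len(b)))
            for i, c in enumerate(cols):
                L[i, c] = 1.0
            lb = L @ b
            middle = L @ self.cov_beta @ L.T
            fstat = float(lb @ np.linalg.solve(middle, lb) / len(cols))
            df_den = (self.df_den or {}).get(term, self.n - self.k)
            p = float(stats.f.sf(fstat, len(cols), df_den))
            rows.append({"term": term, "F": fstat, "df_num": len(cols),
                         "df_den": df_den, "p": p})
        return pd.DataFrame(rows)


def _block_chol(pattern: np.ndarray, sigma_u2: float, sigma_e2: float,
                rho: float) -> np.ndarray:
    """Cholesky factor of one bird's marginal covariance block."""
    lags = np.abs(pattern[:, None] - pattern[None, :])
    V = sigma_u2 + sigma_e2 * rho**lags
    # jitter keeps the factorization stable at variance boundaries
    return np.linalg.cholesky(V + 1e-10 * np.eye(len(pattern)))


def _profiled_negloglik(theta, blocks, covariance, reml=False):
    """-2 log-likelihood profiled over beta; theta on unconstrained scale.

    With ``reml`` the restricted likelihood adds the log|X'V^-1 X| term
    and counts n - p observations, removing the downward bias of the
    variance components that plain ML carries in small bird samples.
    """
    if covariance == "ar1":
        sigma_u2, sigma_e2, rho = np.exp(theta[0]), np.exp(theta[1]), np.tanh(theta[2])
    else:
        sigma_u2, sigma_e2, rho = np.exp(theta[0]), np.exp(theta[1]), 0.0
    xtx = 0.0
    xty = 0.0
    yty = 0.0
    logdet = 0.0
    cache: dict[bytes, np.ndarray] = {}
    for X, y, pattern in blocks:
        key = pattern.tobytes()
        if key not in cache:
            cache[key] = _block_chol(pattern, sigma_u2, sigma_e2, rho)
        L = cache[key]
        logdet += 2 * np.log(np.diag(L)).sum()
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        xtx = xtx + Xw.T @ Xw
        xty = xty + Xw.T @ yw
        yty = yty + yw @ yw
    beta = np.linalg.solve(xtx, xty)
    rss = yty - beta @ xty
    n = sum(len(y) for _, y, _ in blocks)
    nll2 = logdet + rss + n * np.log(2 * np.pi)
    if reml:
        p = xtx.shape[0]
        sign, xtx_logdet = np.linalg.slogdet(xtx)
        nll2 += xtx_logdet - p * np.log(2 * np.pi)
    return nll2, beta, xtx


def fit_mixed_ar1(data: pd.DataFrame, spec: ModelSpec,
                  method: str = "ml") -> FitResult:
    """Likelihood fit of the random-intercept + AR(1) (or CS) mixed model.

    ``method`` is ``"ml"`` (for AICc model ranking, which requires full
    ML) or ``"reml"`` (for hypothesis tests on fixed effects, where ML
    variance components would be biased low).  Deterministic: the
    optimizer starts from method-of-moments variance components and the
    lag-1 residual autocorrelation, with Nelder-Mead refinement of the
    2-3 variance parameters (beta is profiled out by GLS at every step).
    """
    if method not in ("ml", "reml"):
        raise ValueError(f"unknown estimation method {method!r}")
    reml = method == "reml"
    data = data.dropna(subset=[spec.response]).copy()
    groups = data[spec.grouping]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 birds")
    X, design = build_design(data, spec.fixed_terms, spec.categorical)
    y = data[spec.response].to_numpy(float)
    time = data[spec.time].to_numpy(float)

    blocks = []
    for _, idx in data.groupby(spec.grouping, sort=True).indices.items():
        order = idx[np.argsort(time[idx], kind="stable")]
        blocks.append((X[order], y[order], time[order]))

    # method-of-moments start from OLS residuals
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = max(resid.var(), 1e-8)
    bird_means = np.array([r[1].mean() - (r[0] @ beta0).mean() for r in blocks])
    su2 = float(np.clip(bird_means.var(), 0.05 * s2, 0.95 * s2))
    se2 = max(s2 - su2, 0.05 * s2)
    lag1 = []
    for Xb, yb, tb in blocks:
        rb = yb - Xb @ beta0
        if len(rb) > 2 and rb.std() > 1e-12 * (1 + np.abs(yb).max()):
            lag1.append(np.corrcoef(rb[:-1], rb[1:])[0, 1])
    rho0 = float(np.clip(np.nanmean(lag1) if lag1 else 0.0, -0.8, 0.8))

    if spec.covariance == "ar1":
        theta0 = np.array([np.log(su2), np.log(se2), np.arctanh(rho0)])
    else:
        theta0 = np.array([np.log(su2), np.log(se2)])

    res = optimize.minimize(
        lambda th: _profiled_negloglik(th, blocks, spec.covariance, reml)[0],
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    nll2, beta, xtx = _profiled_negloglik(res.x, blocks, spec.covariance, reml)
    if spec.covariance == "ar1":
        sigma_u2, sigma_e2, rho = (np.exp(res.x[0]), np.exp(res.x[1]),
                                   float(np.tanh(res.x[2])))
        n_var = 3
    else:
        sigma_u2, sigma_e2, rho = np.exp(res.x[0]), np.exp(res.x[1]), 0.0
        n_var = 2

    cov_beta = np.linalg.inv(xtx)

    # between-within denominator df: a term whose columns are constant
    # within every bird is tested at the bird level
    n_birds = len(blocks)
    group_codes = data.groupby(spec.grouping, sort=True).ngroup().to_numpy()
    is_between = {}
    for term, cols in design.term_columns.items():
        block = X[:, cols]
        between = all(
            np.ptp(block[group_codes == g], axis=0).max(initial=0.0) == 0
            for g in range(n_birds)
        )
        is_between[term] = between
    p_between = 1 + sum(len(design.term_columns[t])
                        for t, b in is_between.items() if b)
    p_within = X.shape[1] - p_between
    df_between = max(n_birds - p_between, 1)
    df_within = max(len(y) - n_birds - p_within, 1)
    df_den = {t: float(df_between if b else df_within)
              for t, b in is_between.items()}

    return FitResult(
        loglik=float(-0.5 * nll2),
        k=X.shape[1] + n_var,
        n=len(y),
        beta=pd.Series(beta, index=design.columns),
        cov_beta=cov_beta,
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        rho=rho,
        spec=spec,
        design=design,
        method=method,
        df_den=df_den,
        converged=bool(res.success),
    )


def compare_covariance(data: pd.DataFrame, spec: ModelSpec) -> dict:
    """AICc comparison of AR(1) vs compound-symmetry residual structure.

    Returns the winning structure and both criterion values; an exact tie
    goes to the simpler compound-symmetry structure.
    """
    fits = {}
    crit = {}
    for structure in ("ar1", "compound_symmetry"):
        s = ModelSpec(spec.fixed_terms, covariance=structure, grouping=spec.grouping,
                      time=spec.time, response=spec.response,
                      categorical=spec.categorical)
        fits[structure] = fit_mixed_ar1(data, s)
        crit[structure] = aicc(fits[structure].loglik, fits[structure].k,
                               fits[structure].n)
    winner = ("compound_symmetry"
              if crit["compound_symmetry"] <= crit["ar1"] else "ar1")
    return {"winner": winner, "aicc": crit, "fits": fits}


def marginal_means(fit: FitResult, factor: str) -> pd.DataFrame:
    """Least-squares (marginal) means of a categorical factor.

    Predictions are averaged over a balanced grid of the other
    categorical terms with continuous terms at their data means, so
    unbalanced sampling does not tilt the level means.  SEs come from the
    fixed-effect covariance.
    """
    design = fit.design
    if factor not in design.levels:
        raise ValueError(f"{factor!r} is not a categorical term of this model")
    others = [t for t in design.categorical_terms if t != factor]
    grids = list(itertools.product(*[design.levels[t] for t in others])) or [()]
    rows = []
    b = fit.beta.to_numpy()
    for level in design.levels[factor]:
        L = np.zeros(len(b))
        for combo in grids:
            assignment = dict(zip(others, combo))
            assignment[factor] = level
            L += design.row(assignment)
        L /= len(grids)
        est = float(L @ b)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        rows.append({"level": level, "mean": est, "se": se,
                     "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# information-theoretic machinery
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized evidence weights from a list of AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


@dataclass
class ModelAverageResult:
    """Model-averaged coefficient of one parameter."""

    parameter: str
    estimate: float
    unconditional_se: float
    ci_low: float
    ci_high: float
    importance: float


def model_average(
    fits: list[FitResult], weights: np.ndarray, parameter: str
) -> ModelAverageResult:
    """Shrinkage (full-set) model averaging of one coefficient.

    Models without the parameter contribute estimate 0 with variance 0,
    so rarely supported parameters shrink toward no effect; the
    unconditional SE adds the between-model spread to the within-model
    variance.  ``importance`` is the summed weight of models containing
    the parameter.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(fits):
        raise ValueError("weights not aligned to fits")
    betas, variances, contains = [], [], []
    for fit in fits:
        coef = fit.coefficients
        if parameter in coef:
            b, se = coef[parameter]
            betas.append(b)
            variances.append(se**2)
            contains.append(True)
        else:
            betas.append(0.0)
            variances.append(0.0)
            contains.append(False)
    betas = np.asarray(betas)
    variances = np.asarray(variances)
    est = float(np.sum(weights * betas))
    se = float(np.sqrt(np.sum(weights * (variances + (betas - est) ** 2))))
    importance = float(np.sum(weights[np.asarray(contains)]))
    return ModelAverageResult(
        parameter=parameter,
        estimate=est,
        unconditional_se=se,
        ci_low=est - 1.96 * se,
        ci_high=est + 1.96 * se,
        importance=importance,
    )


def effect_multiplier(beta: float, delta_x: float = 1.0, ndigits: int | None = 2):
    """Multiplicative change in the selection ratio rf per ``delta_x``.

    A model-averaged coefficient beta on, e.g., thermal height in km means
    each additional ``delta_x`` km multiplies rf by exp(beta * delta_x).
    """
    value = float(np.exp(beta * delta_x))
    return round(value, ndigits) if ndigits is not None else value


def screen_effects(test_table: pd.DataFrame, alpha: float = 0.01,
                   p_col: str = "p") -> pd.DataFrame:
    """Flag effects with p strictly below alpha (guards against Type I error
    inflation across the many per-habitat tests)."""
    p = test_table[p_col]
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = test_table.copy()
    out["significant"] = p < alpha
    return out


def met_candidate_set(base_terms: list[str],
                      met_terms=MET_TERMS) -> list[list[str]]:
    """All-subsets candidate set over the meteorological parameters.

    Bird-characteristic and season terms stay in every model; the 2^3
    subsets of met parameters distinguish the candidates.
    """
    out = []
    for r in range(len(met_terms) + 1):
        for combo in itertools.combinations(met_terms, r):
            out.append(list(base_terms) + list(combo))
    return out


def ecoregion_model_average(
    data: pd.DataFrame,
    base_terms: list[str],
    met_terms=MET_TERMS,
    covariance: str = "ar1",
    response: str = "ln_rf",
) -> dict:
    """Fit the candidate set for one ecoregion and model-average met effects.

    Returns the per-model ranking table, Akaike weights, and a
    ModelAverageResult per meteorological parameter.
    """
    fits = []
    for terms in met_candidate_set(base_terms, met_terms):
        spec = ModelSpec(terms, covariance=covariance, response=response)
        fits.append(fit_mixed_ar1(data, spec))
    crit = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    weights = akaike_weights(crit)
    ranking = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.fixed_terms) for f in fits],
            "k": [f.k for f in fits],
            "loglik": [f.loglik for f in fits],
            "aicc": crit,
            "delta_aicc": crit - crit.min(),
            "weight": weights,
        }
    ).sort_values("aicc").reset_index(drop=True)
    averages = {p: model_average(fits, weights, p) for p in met_terms}
    return {"fits": fits, "weights": weights, "ranking": ranking,
            "averages": averages}
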