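"""Phylogenetic generalized least squares (pGLS) with Pagel's lambda.

Model: y = X beta + eps, eps ~ MVN(0, sigma2 * V(lam)), where V(lam) is the
phylogenetic covariance with off-diagonals scaled by lambda. For fixed lambda
the ML estimates are the GLS ones:

    beta  = (X' V^-1 X)^-1 X' V^-1 y
    sigma2 = e' V^-1 e / n              (ML divisor n)
    loglik = -1/2 [ n ln(2 pi sigma2) + ln|V| + n ]

lambda itself is estimated by maximizing this profile log-likelihood over a
bounded interval (default [1e-4, 0.9999]); the bounded search keeps the fit
away from exactly singular shared-history structures while still registering
estimates at the bounds as "effectively 0" or "effectively 1". ML (not REML)
variance is used throughout so that likelihoods remain comparable across
fixed-effect structures during information-criterion model selection.

Hypothesis layer: likelihood-ratio tests of lambda-hat against lambda = 0 and
lambda = 1 (chi-square, 1 df), and a sequential (Type I) ANOVA in which each
predictor is assessed after those listed before it, on data whitened by the
full model's fitted covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize_scalar

from .errors import NumericalError, TraitDataError
from .phylo import PhyloCovariance, lambda_transform

#: Default lambda search interval; estimates printed as 0.0001 / 0.9999 sit
#: at these bounds.
DEFAULT_LAMBDA_BOUNDS = (1e-4, 0.9999)

_RESPONSES = ("ltm", "lsl", "lsv")
_PREDICTORS = ("lbm", "pol", "ltm", "lsl")


@dataclass(frozen=True)
class ModelSpec:
    """A response and an *ordered* predictor list (order fixes Type-I SS).

    An empty predictor tuple is the intercept-only null model.
    """

    response: str
    predictors: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if self.response in self.predictors:
            raise TraitDataError(f"response {self.response!r} cannot be a predictor")
        if len(set(self.predictors)) != len(self.predictors):
            raise TraitDataError("duplicated predictor")

    @property
    def label(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.response} ~ {rhs}"

    @classmethod
    def from_formula(cls, text: str) -> "ModelSpec":
        """Parse ``"resp ~ pred1 + pred2"`` or ``"resp ~ 1"``."""
        parts = text.split("~")
        if len(parts) != 2 or not parts[0].strip():
            raise TraitDataError(f"malformed formula {text!r}; expected 'y ~ x1 + x2'")
        response = parts[0].strip()
        rhs = [t.strip() for t in parts[1].split("+") if t.strip()]
        if not rhs:
            raise TraitDataError(f"malformed formula {text!r}: empty right-hand side")
        predictors = tuple(t for t in rhs if t != "1")
        return cls(response=response, predictors=predictors)


@dataclass(frozen=True)
class AnovaTerm:
    """One line of a sequential (Type I) ANOVA: SS, F(1, df_resid), p."""

    term: str
    ss: float
    F: float
    p: float
    df_resid: int


@dataclass(frozen=True)
class LambdaLRT:
    """Likelihood-ratio tests of the fitted lambda against 0 and 1."""

    lambda_hat: float
    statistic_vs_0: float
    statistic_vs_1: float
    p_vs_0: float
    p_vs_1: float


@dataclass(frozen=True)
class PGLSFit:
    """A fitted pGLS model.

    ``beta`` is ordered as the design columns (intercept first). ``se``,
    ``t`` and ``p_coef`` use the unbiased variance (divisor n - k) as is
    conventional for Wald-type coefficient tests; ``sigma2`` and ``loglik``
    are the ML quantities used for model comparison.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_coef: np.ndarray
    sigma2: float
    lambda_hat: float
    loglik: float
    n: int
    k_coef: int
    response: Optional[str] = None
    anova: tuple[AnovaTerm, ...] = ()
    lrt: Optional[LambdaLRT] = None

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "terms": list(self.terms),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "t": [float(v) for v in self.t],
            "p_coef": [float(v) for v in self.p_coef],
            "sigma2": self.sigma2,
            "lambda": self.lambda_hat,
            "loglik": self.loglik,
            "n": self.n,
            "k_coef": self.k_coef,
            "anova": [
                {"term": a.term, "ss": a.ss, "F": a.F, "p": a.p, "df_resid": a.df_resid}
                for a in self.anova
            ],
        }
        if self.lrt is not None:
            d["lambda_lrt"] = {
                "statistic_vs_0": self.lrt.statistic_vs_0,
                "statistic_vs_1": self.lrt.statistic_vs_1,
                "p_vs_0": self.lrt.p_vs_0,
                "p_vs_1": self.lrt.p_vs_1,
            }
        return d


def _as_matrix(V) -> np.ndarray:
    return V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, dtype=float)


def design_matrix(table, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Response vector, design matrix (intercept first) and column names."""
    y = table.analysis_matrix([spec.response])[:, 0]
    cols = table.analysis_matrix(spec.predictors) if spec.predictors else np.empty((len(table), 0))
    X = np.column_stack([np.ones(len(table)), cols])
    return y, X, ("intercept", *spec.predictors)


def gls_profile_fit(y, X, V) -> tuple[np.ndarray, float, float]:
    """GLS/ML estimates (beta, sigma2, loglik) at a fixed covariance V.

    Raises :class:`NumericalError` when V is not positive definite or the
    design is singular, carrying condition diagnostics.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    V = _as_matrix(V)
    n, k = X.shape
    if n <= k:
        raise NumericalError(f"need n > k_coef, got n={n}, k={k}")
    try:
        c, low = cho_factor(V)
    except LinAlgError as exc:
        raise NumericalError(
            f"covariance not positive definite (cond={np.linalg.cond(V):.3g})"
        ) from exc
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except LinAlgError as exc:
        raise NumericalError(
            f"singular design (cond(X'V^-1X)={np.linalg.cond(XtViX):.3g})"
        ) from exc
    e = y - X @ beta
    sigma2 = float(e @ cho_solve((c, low), e) / n)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    # degenerate (noiseless) fit: residual variance at rounding level
    tol = max(1e-12 * float(y @ Vi_y / n), 1e-300)
    if sigma2 < tol:
        warnings.warn("residual variance is (numerically) zero; loglik set to +inf")
        return beta, sigma2, float("inf")
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdetV + n)
    return beta, sigma2, float(loglik)


def profile_loglik(lam: float, y, X, V_base: PhyloCovariance) -> float:
    """Profile log-likelihood of lambda (beta and sigma2 maximized out)."""
    return gls_profile_fit(y, X, lambda_transform(V_base, lam))[2]


def _fit_at_lambda(y, X, V_base, lam, terms, response) -> PGLSFit:
    V = lambda_transform(V_base, lam)
    beta, sigma2, loglik = gls_profile_fit(y, X, V)
    n, k = np.asarray(X).shape
    # Wald-type coefficient tests with the unbiased variance estimate.
    c, lowf = cho_factor(_as_matrix(V))
    XtViX = np.asarray(X).T @ cho_solve((c, lowf), np.asarray(X))
    e = y - np.asarray(X) @ beta
    s2_unbiased = float(e @ cho_solve((c, lowf), e) / max(n - k, 1))
    cov_beta = s2_unbiased * np.linalg.inv(XtViX)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=max(n - k, 1))
    return PGLSFit(
        terms=tuple(terms), beta=beta, se=se, t=t, p_coef=p, sigma2=sigma2,
        lambda_hat=float(lam), loglik=loglik, n=n, k_coef=k, response=response,
    )


def optimize_lambda(
    y,
    X,
    V_base: PhyloCovariance,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
    n_coarse: int = 25,
    terms: Optional[Sequence[str]] = None,
    response: Optional[str] = None,
) -> PGLSFit:
    """Maximize the profile likelihood over lambda in ``bounds``.

    The profile can be multimodal on small trees, so a coarse grid scan
    locates the basin and a bounded scalar optimization refines the argmax
    within the bracketing grid interval; the better of grid and refined
    points is kept.
    """
    lo, hi = bounds
    if not 0.0 <= lo < hi <= 1.0:
        raise NumericalError(f"invalid lambda bounds {bounds}")
    grid = np.linspace(lo, hi, n_coarse)
    vals = np.array([profile_loglik(l, y, X, V_base) for l in grid])
    if not np.isfinite(vals).any():
        raise NumericalError(
            "profile log-likelihood not finite anywhere on the coarse grid: "
            + ", ".join(f"{l:.3f}:{v:.3g}" for l, v in zip(grid, vals))
        )
    i = int(np.nanargmax(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, n_coarse - 1)]
    best_lam, best_val = float(grid[i]), float(vals[i])
    if bhi > blo:
        res = minimize_scalar(
            lambda l: -profile_loglik(l, y, X, V_base),
            bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success and -res.fun >= best_val:
            best_lam, best_val = float(res.x), float(-res.fun)
    if terms is None:
        terms = tuple(f"x{j}" for j in range(np.asarray(X).shape[1]))
    return _fit_at_lambda(y, X, V_base, best_lam, terms, response)


def lrt_lambda(fit: PGLSFit, y, X, V_base: PhyloCovariance) -> LambdaLRT:
    """LRTs of lambda-hat against lambda = 0 and lambda = 1 (chi2, 1 df).

    Statistics are clipped at 0: when lambda-hat sits at a search bound the
    bounded estimate can be infinitesimally inside the fixed value it is
    tested against.
    """
    ll_hat = fit.loglik
    ll0 = gls_profile_fit(y, X, lambda_transform(V_base, 0.0))[2]
    ll1 = gls_profile_fit(y, X, lambda_transform(V_base, 1.0))[2]
    s0 = max(0.0, 2.0 * (ll_hat - ll0))
    s1 = max(0.0, 2.0 * (ll_hat - ll1))
    return LambdaLRT(
        lambda_hat=fit.lambda_hat,
        statistic_vs_0=s0, statistic_vs_1=s1,
        p_vs_0=float(stats.chi2.sf(s0, df=1)), p_vs_1=float(stats.chi2.sf(s1, df=1)),
    )


def sequential_anova(y, X, V, terms: Sequence[str]) -> tuple[AnovaTerm, ...]:
    """Sequential (Type I) ANOVA on data whitened by a fixed covariance V.

    ``X`` has the intercept first and predictors in entry order; ``terms``
    names the predictor columns (len = k - 1). Each term's F compares the
    reduction in residual SS when it enters (1 df) against the full model's
    residual mean square with n - k df.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if len(terms) != k - 1:
        raise NumericalError("terms must name the non-intercept design columns")
    df_resid = n - k
    if df_resid < 1:
        raise NumericalError(f"no residual degrees of freedom (n={n}, k={k})")
    L = np.linalg.cholesky(_as_matrix(V))
    z = solve_triangular(L, y, lower=True)
    Z = solve_triangular(L, X, lower=True)

    def rss(j: int) -> float:
        resid = z - Z[:, :j] @ np.linalg.lstsq(Z[:, :j], z, rcond=None)[0]
        return float(resid @ resid)

    rss_seq = [rss(j) for j in range(1, k + 1)]  # intercept-only .. full
    ms_resid = rss_seq[-1] / df_resid
    out = []
    for j, term in enumerate(terms):
        ss = rss_seq[j] - rss_seq[j + 1]
        F = ss / ms_resid if ms_resid > 0 else float("inf")
        out.append(
            AnovaTerm(term=term, ss=ss, F=F,
                      p=float(stats.f.sf(F, 1, df_resid)), df_resid=df_resid)
        )
    return tuple(out)


def fit_model(
    spec: ModelSpec,
    table,
    V_base: PhyloCovariance,
    lam: Optional[float] = None,
    bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> PGLSFit:
    """Fit one model spec on a trait table aligned to ``V_base.tip_order``.

    With ``lam=None`` lambda is estimated by ML and likelihood-ratio tests
    against 0 and 1 are attached; with a fixed ``lam`` the GLS fit is done at
    that value. A sequential Type-I ANOVA (conditioning on the full model's
    fitted lambda) is attached when the model has predictors.
    """
    aligned = table.reordered(V_base.tip_order)
    y, X, terms = design_matrix(aligned, spec)
    if lam is None:
        fit = optimize_lambda(y, X, V_base, bounds=bounds, terms=terms,
                              response=spec.response)
        lrt = lrt_lambda(fit, y, X, V_base)
    else:
        fit = _fit_at_lambda(y, X, V_base, lam, terms, spec.response)
        lrt = None
    anova = ()
    if spec.predictors and np.isfinite(fit.loglik):
        V_hat = lambda_transform(V_base, fit.lambda_hat)
        anova = sequential_anova(y, X, V_hat, spec.predictors)
    return PGLSFit(
        terms=fit.terms, beta=fit.beta, se=fit.se, t=fit.t, p_coef=fit.p_coef,
        sigma2=fit.sigma2, lambda_hat=fit.lambda_hat, loglik=fit.loglik,
        n=fit.n, k_coef=fit.k_coef, response=spec.response, anova=anova, lrt=lrt,
    )
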