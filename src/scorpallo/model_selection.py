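"""AICc multimodel inference over the study's candidate model sets.

Three candidate sets (18 models in total) target the three responses:

* testes mass   (ltm): 1; lbm; pol; lbm+pol                      (4 models)
* sperm length  (lsl): 1; lbm; pol; ltm; lbm+pol; lbm+ltm        (6 models)
* spermatophore volume (lsv): 1; lbm; pol; ltm; lsl; lbm+ltm;
  lbm+pol; lbm+lsl                                               (8 models)

Additive models list body mass (lbm) first so that the sequential Type-I
ANOVA controls for body size before assessing sperm-competition predictors.
Interaction models are excluded from the candidate space.

Each model is fitted by pGLS with its own ML lambda; models are ranked by
AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1) and summarized with Akaike weights.
Models within 2 AICc of the best are flagged as selected.

How many parameters k counts is configurable: regression coefficients only
(default — matches the convention in which an interaction model y ~ a*b is a
"four parameter" model), coefficients + the residual variance, or
coefficients + variance + the estimated lambda.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import NumericalError, TraitDataError
from .pgls import DEFAULT_LAMBDA_BOUNDS, LambdaLRT, ModelSpec, PGLSFit, fit_model

#: ΔAICc below which a model is retained as substantially supported.
DELTA_SELECT = 2.0

K_COUNTING_MODES = (
    "coefficients",
    "coefficients+variance",
    "coefficients+variance+lambda",
)

_EXTRA_K = {"coefficients": 0, "coefficients+variance": 1, "coefficients+variance+lambda": 2}


@dataclass(frozen=True)
class CandidateSet:
    """The ordered candidate models for one response variable."""

    response: str
    models: tuple[ModelSpec, ...]

    def __post_init__(self):
        nulls = [m for m in self.models if not m.predictors]
        if len(nulls) != 1:
            raise TraitDataError("a candidate set must contain the null model exactly once")
        if any(m.response != self.response for m in self.models):
            raise TraitDataError("all models in a set share the response")


def build_candidate_sets() -> dict[str, CandidateSet]:
    """The 18-model candidate space, keyed by response (ltm, lsl, lsv)."""

    def cs(response: str, *preds: tuple[str, ...]) -> CandidateSet:
        return CandidateSet(
            response=response,
            models=tuple(ModelSpec(response, p) for p in preds),
        )

    return {
        "ltm": cs("ltm", (), ("lbm",), ("pol",), ("lbm", "pol")),
        "lsl": cs("lsl", (), ("lbm",), ("pol",), ("ltm",), ("lbm", "pol"), ("lbm", "ltm")),
        "lsv": cs(
            "lsv", (), ("lbm",), ("pol",), ("ltm",), ("lsl",),
            ("lbm", "ltm"), ("lbm", "pol"), ("lbm", "lsl"),
        ),
    }


def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1); needs n > k + 1."""
    if n - k - 1 <= 0:
        raise NumericalError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return aic(loglik, k) + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values: Iterable[float]) -> np.ndarray:
    """Normalized exp(-delta/2) across a candidate set.

    The minimum is subtracted before exponentiation for numerical stability;
    non-finite AICc values receive weight 0.
    """
    a = np.asarray(list(aicc_values), dtype=float)
    if a.size == 0 or not np.isfinite(a).any():
        raise NumericalError("akaike_weights() needs at least one finite AICc")
    delta = a - np.nanmin(a[np.isfinite(a)])
    w = np.where(np.isfinite(delta), np.exp(-np.where(np.isfinite(delta), delta, 0) / 2.0), 0.0)
    return w / w.sum()


@dataclass(frozen=True)
class SelectionRow:
    """One candidate model with its fit and AICc bookkeeping."""

    spec: ModelSpec
    fit: PGLSFit
    k: int
    aicc: float
    delta: float
    weight: float
    selected: bool

    @property
    def lrt(self) -> Optional[LambdaLRT]:
        return self.fit.lrt


@dataclass(frozen=True)
class SelectionTable:
    """Ranked candidate models for one response, in candidate-set order."""

    response: str
    rows: tuple[SelectionRow, ...]
    k_counting: str

    def best(self) -> SelectionRow:
        return min(self.rows, key=lambda r: r.aicc)

    @property
    def selected(self) -> tuple[SelectionRow, ...]:
        return tuple(r for r in self.rows if r.selected)

    def to_dataframe(self) -> pd.DataFrame:
        """Mirror of the study's selection-table layout, one line per term."""
        recs = []
        for row in self.rows:
            fit = row.fit
            anova = {a.term: a for a in fit.anova}
            lines = fit.terms if fit.k_coef > 1 else ("intercept",)
            for i, term in enumerate(lines):
                first = i == 0
                a = anova.get(term)
                recs.append(
                    {
                        "response": self.response,
                        "model": row.spec.label,
                        "predictor": term,
                        "slope": fit.coef(term),
                        "F": a.F if a else math.nan,
                        "p": a.p if a else fit.p_coef[0],
                        "AICc": row.aicc if first else math.nan,
                        "dAICc": row.delta if first else math.nan,
                        "wt": row.weight if first else math.nan,
                        "lambda": fit.lambda_hat if first else math.nan,
                        "p_lambda_vs_0": fit.lrt.p_vs_0 if first and fit.lrt else math.nan,
                        "p_lambda_vs_1": fit.lrt.p_vs_1 if first and fit.lrt else math.nan,
                        "selected": row.selected if first else None,
                    }
                )
        return pd.DataFrame.from_records(recs)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self) -> str:
        payload = {
            "response": self.response,
            "k_counting": self.k_counting,
            "rows": [
                {
                    "model": r.spec.label,
                    "k": r.k,
                    "aicc": r.aicc,
                    "delta": r.delta,
                    "weight": r.weight,
                    "selected": r.selected,
                    "fit": r.fit.to_dict(),
                }
                for r in self.rows
            ],
        }
        return json.dumps(payload, indent=2)


def model_k(fit: PGLSFit, k_counting: str = "coefficients") -> int:
    """Parameter count entering AICc under the chosen counting convention."""
    if k_counting not in _EXTRA_K:
        raise TraitDataError(f"k_counting must be one of {K_COUNTING_MODES}")
    return fit.k_coef + _EXTRA_K[k_counting]


def select(deltas: Iterable[float]) -> list[bool]:
    """Selection rule: delta AICc strictly below :data:`DELTA_SELECT`."""
    return [d < DELTA_SELECT for d in deltas]


def evaluate_candidates(
    cset: CandidateSet,
    table,
    V_base,
    k_counting: str = "coefficients",
    lambda_bounds: tuple[float, float] = DEFAULT_LAMBDA_BOUNDS,
) -> SelectionTable:
    """Fit every model in a candidate set and rank it by AICc."""
    fits = [fit_model(m, table, V_base, bounds=lambda_bounds) for m in cset.models]
    ks = [model_k(f, k_counting) for f in fits]
    aiccs = [aicc(f.loglik, k, f.n) for f, k in zip(fits, ks)]
    finite_min = min(a for a in aiccs if math.isfinite(a))
    deltas = [a - finite_min for a in aiccs]
    weights = akaike_weights(aiccs)
    flags = select(deltas)
    rows = tuple(
        SelectionRow(spec=m, fit=f, k=k, aicc=a, delta=d, weight=float(w), selected=s)
        for m, f, k, a, d, w, s in zip(cset.models, fits, ks, aiccs, deltas, weights, flags)
    )
    return SelectionTable(response=cset.response, rows=rows, k_counting=k_counting)
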