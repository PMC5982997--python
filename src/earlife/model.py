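"""The multilevel aggregated binomial regression model.

For participant-stratum row i with k_i occurrences out of n_i eligible
clips:

    k_i ~ Binomial(n_i, p_i)
    logit(p_i) = alpha + a_PARTICIPANT[i] + sum_j beta_j * x_ij
    alpha ~ Normal(0, 2)
    beta_j ~ Normal(0, 2)
    a_PARTICIPANT ~ Normal(0, sigma)
    sigma ~ HalfCauchy(0, 1)

Predictors are the weekend dummy (from the stratum), the sex dummy
(female = 1), and the standardized trait composite.  The binomial
coefficient is included in the likelihood so that pointwise terms are
comparable across models of the same rows (required for WAIC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit
from scipy.special import logit as _logit

from .errors import ConfigurationError, DataError, SchemaError

VALID_PREDICTORS = ("weekend", "sex", "alhb")

_LOG_2_PI = np.log(2.0 * np.pi)


def logit(p):
    """Log-odds of p; domain (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("logit requires p in (0, 1)")
    out = _logit(p)
    return float(out) if out.ndim == 0 else out


def inverse_logit(x):
    """Logistic function, mapping log-odds to (0, 1)."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelSpec:
    """One regression: an outcome behavior plus an ordered predictor set."""

    behavior: str
    predictors: tuple[str, ...] = ()
    prior_alpha_sd: float = 2.0
    prior_beta_sd: float = 2.0
    prior_sigma_scale: float = 1.0

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise ConfigurationError("duplicate predictor names")
        for p in self.predictors:
            if p not in VALID_PREDICTORS:
                raise ConfigurationError(f"unknown predictor {p!r}")
        if min(self.prior_alpha_sd, self.prior_beta_sd, self.prior_sigma_scale) <= 0:
            raise ConfigurationError("prior scales must be positive")

    @property
    def name(self) -> str:
        return "+".join(self.predictors) if self.predictors else "intercept_only"


@dataclass
class ParameterState:
    """One point in parameter space (log-odds scale)."""

    alpha: float
    beta: np.ndarray  # aligned with ModelSpec.predictors
    offsets: np.ndarray  # one per participant in the design
    sigma: float

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.offsets = np.asarray(self.offsets, dtype=float)


@dataclass
class Design:
    """Model-ready arrays built from count rows + participant covariates."""

    k: np.ndarray
    n: np.ndarray
    X: np.ndarray  # rows x predictors
    pidx: np.ndarray  # row -> participant slot
    participant_ids: np.ndarray
    predictors: tuple[str, ...]
    row_index: pd.DataFrame  # participant_id / behavior / stratum per row
    n_dropped: int = 0

    @property
    def n_rows(self) -> int:
        return self.k.shape[0]

    @property
    def n_participants(self) -> int:
        return self.participant_ids.shape[0]

    @property
    def log_binom_coef(self) -> np.ndarray:
        return (
            gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)
        )


def build_design(
    rows: pd.DataFrame,
    participants: pd.DataFrame,
    predictors: tuple[str, ...],
    standardize_alhb: bool = True,
) -> Design:
    """Assemble the design for one behavior's rows.

    The weekend dummy comes from the stratum label; sex and the trait
    composite are merged from the participant table.  The trait
    composite is z-scored over the participants present in the rows, so
    the intercept refers to a participant at the mean trait value.
    Rows with n = 0 carry no information and are dropped (counted).
    """
    for p in predictors:
        if p not in VALID_PREDICTORS:
            raise ConfigurationError(f"unknown predictor {p!r}")
    if rows["behavior"].nunique() > 1:
        raise DataError("design rows must belong to a single behavior")
    rows = rows.sort_values(["participant_id", "stratum"]).reset_index(drop=True)
    nonzero = rows["n"].to_numpy() > 0
    n_dropped = int((~nonzero).sum())
    rows = rows[nonzero].reset_index(drop=True)
    if len(rows) == 0:
        raise DataError("no rows with positive denominators")
    part = participants.set_index("participant_id")
    pids = np.sort(rows["participant_id"].unique())
    slot = {p: i for i, p in enumerate(pids)}
    pidx = rows["participant_id"].map(slot).to_numpy()
    cols = []
    for p in predictors:
        if p == "weekend":
            cols.append((rows["stratum"] == "weekend").to_numpy(dtype=float))
        else:
            col = "alhb" if p == "alhb" else "sex"
            if col not in part.columns:
                raise SchemaError(f"participant table lacks column {col!r}")
            x = part[col].reindex(rows["participant_id"]).to_numpy(dtype=float)
            if np.any(~np.isfinite(x)):
                raise SchemaError(f"non-finite {col!r} for some participants")
            if p == "alhb" and standardize_alhb:
                per = part[col].reindex(pids).to_numpy(dtype=float)
                mu, sd = per.mean(), per.std(ddof=0)
                if sd > 0:
                    x = (x - mu) / sd
                else:
                    x = x - mu
            cols.append(x)
    X = np.column_stack(cols) if cols else np.zeros((len(rows), 0))
    return Design(
        k=rows["k"].to_numpy(dtype=float),
        n=rows["n"].to_numpy(dtype=float),
        X=X,
        pidx=pidx,
        participant_ids=pids,
        predictors=tuple(predictors),
        row_index=rows[["participant_id", "behavior", "stratum"]].copy(),
        n_dropped=n_dropped,
    )


def binomial_loglik(k, n, eta, include_coef: bool = True):
    """Stable log Binomial(k | n, inverse_logit(eta)), elementwise.

    Uses log_expit so that eta of either sign and large magnitude stays
    finite whenever the corresponding count is zero.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    with np.errstate(invalid="ignore"):
        ll = k * log_expit(eta) + (n - k) * log_expit(-eta)
        # 0 * -inf at the boundaries is a structural zero
        ll = np.where((k == 0) & np.isneginf(eta), (n - k) * log_expit(-eta), ll)
        ll = np.where((k == n) & np.isposinf(eta), k * log_expit(eta), ll)
    if include_coef:
        ll = ll + gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return ll


def linear_predictor(state: ParameterState, design: Design) -> np.ndarray:
    if state.beta.shape[0] != design.X.shape[1]:
        raise ConfigurationError("beta length does not match design predictors")
    if state.offsets.shape[0] != design.n_participants:
        raise ConfigurationError("one offset per participant is required")
    return state.alpha + design.X @ state.beta + state.offsets[design.pidx]


def log_likelihood(state: ParameterState, design: Design):
    """(total, pointwise) aggregated-binomial log-likelihood."""
    pointwise = binomial_loglik(design.k, design.n, linear_predictor(state, design))
    return float(pointwise.sum()), pointwise


def _normal_logpdf(x, sd):
    return -0.5 * (np.asarray(x) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2_PI


def half_cauchy_logpdf(x, scale=1.0):
    x = np.asarray(x, dtype=float)
    return np.where(
        x < 0, -np.inf, np.log(2.0 / (np.pi * scale * (1.0 + (x / scale) ** 2)))
    )


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    if state.sigma <= 0:
        return -np.inf
    lp = float(_normal_logpdf(state.alpha, spec.prior_alpha_sd))
    lp += float(_normal_logpdf(state.beta, spec.prior_beta_sd).sum())
    lp += float(_normal_logpdf(state.offsets, state.sigma).sum())
    lp += float(half_cauchy_logpdf(state.sigma, spec.prior_sigma_scale))
    return lp


def log_posterior(state: ParameterState, design: Design, spec: ModelSpec) -> float:
    """Unnormalized log posterior; -inf (not an exception) for sigma <= 0."""
    lp = log_prior(state, spec)
    if not np.isfinite(lp):
        return -np.inf
    total, _ = log_likelihood(state, design)
    return lp + total
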