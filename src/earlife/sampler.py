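"""Adaptive MCMC for the multilevel aggregated binomial model.

The sampler is Metropolis-within-Gibbs over the centered
parameterization, with three extra moves that target the posterior's
known ridges:

* an ancillary rescaling of (sigma, offsets) holding offsets/sigma
  fixed (the non-centered direction), which decorrelates sigma from the
  offsets;
* a translation of (alpha, offsets) along alpha + mean(offset), the
  direction the likelihood cannot identify;
* the analogous translation of (beta_j, offsets) along any
  participant-level covariate (sex, trait), whose slope is likewise
  identified only through the offset prior.

All chains run vectorized in one NumPy stream; proposal scales adapt by
Robbins-Monro during warmup (target acceptance 0.44) and are frozen
afterwards.  Convergence is checked with split R-hat and bulk ESS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .errors import ConvergenceWarning, DataError
from .model import (
    Design,
    ModelSpec,
    build_design,
    half_cauchy_logpdf,
)

_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class SamplerConfig:
    """Chains/iterations and convergence thresholds."""

    chains: int = 4
    draws: int = 2000
    warmup: int = 1000
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0


#: Reduced settings for quick exploratory fits and CI-speed profiles;
#: the ESS bar is scaled down with the draw budget.
FAST_CONFIG = SamplerConfig(
    chains=2, draws=600, warmup=600, rhat_threshold=1.05, ess_threshold=100.0
)


@dataclass
class PosteriorSample:
    """Posterior draws plus everything WAIC and diagnostics need."""

    alpha: np.ndarray  # (chains, draws)
    beta: np.ndarray  # (chains, draws, n_predictors)
    offsets: np.ndarray  # (chains, draws, n_participants)
    sigma: np.ndarray  # (chains, draws)
    pointwise_loglik: np.ndarray  # (chains, draws, n_rows)
    predictors: tuple[str, ...]
    participant_ids: np.ndarray
    row_index: pd.DataFrame
    diagnostics: dict
    converged: bool
    seed: object
    config: SamplerConfig
    n_dropped_rows: int = 0

    @property
    def n_draws_total(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter, chains flattened."""
        if name == "alpha":
            return self.alpha.reshape(-1)
        if name == "sigma":
            return self.sigma.reshape(-1)
        if name.startswith("beta_"):
            j = self.predictors.index(name[5:])
            return self.beta[:, :, j].reshape(-1)
        if name.startswith("offset_"):
            pid = type(self.participant_ids[0])(name[7:])
            j = int(np.flatnonzero(self.participant_ids == pid)[0])
            return self.offsets[:, :, j].reshape(-1)
        raise KeyError(name)

    def parameter_names(self, include_offsets: bool = False) -> list[str]:
        names = ["alpha"] + [f"beta_{p}" for p in self.predictors] + ["sigma"]
        if include_offsets:
            names += [f"offset_{p}" for p in self.participant_ids]
        return names


def _row_loglik(k, n, eta):
    # binomial log-likelihood without the constant coefficient
    return k * log_expit(eta) + (n - k) * log_expit(-eta)


def _normal_delta(x_new, x_old, sd):
    return -0.5 * ((x_new / sd) ** 2 - (x_old / sd) ** 2)


def fit(
    spec: ModelSpec,
    rows: pd.DataFrame,
    participants: pd.DataFrame,
    config: SamplerConfig | None = None,
    seed=None,
) -> PosteriorSample:
    """Draw from the posterior of one model.

    Reproducible given ``seed``; attaches a ConvergenceWarning (and sets
    ``converged=False``) when split R-hat or bulk ESS for the global
    parameters miss their thresholds, rather than failing silently.
    """
    config = config or SamplerConfig()
    design = build_design(rows, participants, spec.predictors)
    return _fit_design(spec, design, config, seed)


def _fit_design(
    spec: ModelSpec, design: Design, config: SamplerConfig, seed
) -> PosteriorSample:
    rng = np.random.default_rng(seed)
    C, D, W = config.chains, config.draws, config.warmup
    k, n, X, pidx = design.k, design.n, design.X, design.pidx
    if n.sum() <= 0:
        raise DataError("all denominators are zero")
    R, P, Np = design.n_rows, X.shape[1], design.n_participants
    bounds = np.flatnonzero(np.r_[1, np.diff(pidx)])
    coef = design.log_binom_coef
    pa, pb, ps = spec.prior_alpha_sd, spec.prior_beta_sd, spec.prior_sigma_scale

    # covariates constant within participant admit a translation move
    part_level = []
    for j in range(P):
        xp = np.zeros(Np)
        spread = 0.0
        for s, i in enumerate(bounds):
            stop = bounds[s + 1] if s + 1 < Np else R
            vals = X[i:stop, j]
            xp[s] = vals[0]
            spread = max(spread, float(vals.max() - vals.min()))
        if spread == 0.0:
            part_level.append((j, xp))

    phat = np.clip((k.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)
    alpha = np.log(phat / (1 - phat)) + 0.2 * rng.standard_normal(C)
    beta = 0.1 * rng.standard_normal((C, P))
    off = 0.1 * rng.standard_normal((C, Np))
    sigma = np.exp(np.log(0.5) + 0.3 * rng.standard_normal(C))

    eta = alpha[:, None] + beta @ X.T + off[:, pidx]
    rowll = _row_loglik(k, n, eta)
    tot = rowll.sum(axis=1)

    ls_alpha = np.full(C, np.log(0.1))
    ls_beta = np.full((C, P), np.log(0.1))
    ls_off = np.full(C, np.log(0.3))
    ls_sig = np.full(C, np.log(0.5))
    ls_nc = np.full(C, np.log(0.3))
    ls_sh = np.full(C, np.log(0.2))
    ls_shb = np.full((C, P), np.log(0.2))

    out_alpha = np.empty((C, D))
    out_beta = np.empty((C, D, P))
    out_off = np.empty((C, D, Np))
    out_sigma = np.empty((C, D))
    out_pw = np.empty((C, D, R))

    def adapt(ls, acc, t):
        gamma = 2.0 * (t + 10.0) ** -0.6
        return ls + gamma * (acc - _TARGET_ACCEPT)

    for t in range(W + D):
        warm = t < W
        # --- alpha random walk ---
        da = np.exp(ls_alpha) * rng.standard_normal(C)
        eta_p = eta + da[:, None]
        rl = _row_loglik(k, n, eta_p)
        delta = rl.sum(1) - tot + _normal_delta(alpha + da, alpha, pa)
        acc = np.log(rng.random(C)) < delta
        alpha = np.where(acc, alpha + da, alpha)
        eta = np.where(acc[:, None], eta_p, eta)
        rowll = np.where(acc[:, None], rl, rowll)
        tot = np.where(acc, rl.sum(1), tot)
        if warm:
            ls_alpha = adapt(ls_alpha, acc.astype(float), t)
        # --- beta random walks ---
        for j in range(P):
            db = np.exp(ls_beta[:, j]) * rng.standard_normal(C)
            eta_p = eta + db[:, None] * X[:, j]
            rl = _row_loglik(k, n, eta_p)
            delta = rl.sum(1) - tot + _normal_delta(beta[:, j] + db, beta[:, j], pb)
            acc = np.log(rng.random(C)) < delta
            beta[:, j] = np.where(acc, beta[:, j] + db, beta[:, j])
            eta = np.where(acc[:, None], eta_p, eta)
            rowll = np.where(acc[:, None], rl, rowll)
            tot = np.where(acc, rl.sum(1), tot)
            if warm:
                ls_beta[:, j] = adapt(ls_beta[:, j], acc.astype(float), t)
        # --- participant offsets, elementwise ---
        d = np.exp(ls_off)[:, None] * rng.standard_normal((C, Np))
        part_cur = np.add.reduceat(rowll, bounds, axis=1)
        eta_p = eta + d[:, pidx]
        rl = _row_loglik(k, n, eta_p)
        part_prop = np.add.reduceat(rl, bounds, axis=1)
        delta = (
            part_prop
            - part_cur
            + _normal_delta(off + d, off, sigma[:, None])
        )
        acc = np.log(rng.random((C, Np))) < delta
        off = off + d * acc
        eta = eta + (d * acc)[:, pidx]
        rowll = _row_loglik(k, n, eta)
        tot = rowll.sum(1)
        if warm:
            ls_off = adapt(ls_off, acc.mean(axis=1), t)
        # --- sigma | offsets (no likelihood term) ---
        dls = np.exp(ls_sig) * rng.standard_normal(C)
        sig_p = sigma * np.exp(dls)
        ssq = (off**2).sum(axis=1)
        delta = (
            -Np * (np.log(sig_p) - np.log(sigma))
            - 0.5 * ssq * (1.0 / sig_p**2 - 1.0 / sigma**2)
            + half_cauchy_logpdf(sig_p, ps)
            - half_cauchy_logpdf(sigma, ps)
            + dls
        )
        acc = np.log(rng.random(C)) < delta
        sigma = np.where(acc, sig_p, sigma)
        if warm:
            ls_sig = adapt(ls_sig, acc.astype(float), t)
        # --- non-centered rescale of (sigma, offsets) ---
        dls = np.exp(ls_nc) * rng.standard_normal(C)
        sig_p = sigma * np.exp(dls)
        scale = (sig_p / sigma)[:, None]
        off_p = off * scale
        eta_p = eta + (off_p - off)[:, pidx]
        rl = _row_loglik(k, n, eta_p)
        delta = (
            rl.sum(1)
            - tot
            + half_cauchy_logpdf(sig_p, ps)
            - half_cauchy_logpdf(sigma, ps)
            + dls
        )
        acc = np.log(rng.random(C)) < delta
        sigma = np.where(acc, sig_p, sigma)
        off = np.where(acc[:, None], off_p, off)
        eta = np.where(acc[:, None], eta_p, eta)
        rowll = np.where(acc[:, None], rl, rowll)
        tot = rowll.sum(1)
        if warm:
            ls_nc = adapt(ls_nc, acc.astype(float), t)
        # --- translation along alpha + mean(offset) ---
        dsh = np.exp(ls_sh) * rng.standard_normal(C)
        delta = _normal_delta(alpha + dsh, alpha, pa) + _normal_delta(
            off - dsh[:, None], off, sigma[:, None]
        ).sum(axis=1)
        acc = np.log(rng.random(C)) < delta
        alpha = np.where(acc, alpha + dsh, alpha)
        off = off - (dsh * acc)[:, None]
        if warm:
            ls_sh = adapt(ls_sh, acc.astype(float), t)
        # --- translation along participant-level covariates ---
        for j, xp in part_level:
            dsh = np.exp(ls_shb[:, j]) * rng.standard_normal(C)
            off_p = off - dsh[:, None] * xp[None, :]
            delta = _normal_delta(beta[:, j] + dsh, beta[:, j], pb) + (
                _normal_delta(off_p, off, sigma[:, None])
            ).sum(axis=1)
            acc = np.log(rng.random(C)) < delta
            beta[:, j] = np.where(acc, beta[:, j] + dsh, beta[:, j])
            off = np.where(acc[:, None], off_p, off)
            if warm:
                ls_shb[:, j] = adapt(ls_shb[:, j], acc.astype(float), t)

        if not warm:
            s = t - W
            out_alpha[:, s] = alpha
            out_beta[:, s] = beta
            out_off[:, s] = off
            out_sigma[:, s] = sigma
            out_pw[:, s] = rowll + coef

    diagnostics, converged = _diagnose(
        out_alpha, out_beta, out_sigma, out_off, design.predictors, config
    )
    if not converged:
        warnings.warn(
            f"model {spec.name!r} on {spec.behavior!r}: "
            f"R-hat/ESS thresholds missed {diagnostics['failed']}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return PosteriorSample(
        alpha=out_alpha,
        beta=out_beta,
        offsets=out_off,
        sigma=out_sigma,
        pointwise_loglik=out_pw,
        predictors=design.predictors,
        participant_ids=design.participant_ids,
        row_index=design.row_index,
        diagnostics=diagnostics,
        converged=converged,
        seed=seed,
        config=config,
        n_dropped_rows=design.n_dropped,
    )


def _diagnose(alpha, beta, sigma, offsets, predictors, config):
    import arviz as az

    posterior = {"alpha": alpha, "sigma": sigma, "offsets": offsets}
    for j, p in enumerate(predictors):
        posterior[f"beta_{p}"] = beta[:, :, j]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(posterior)
        rhat = az.rhat(ds)
        ess = az.ess(ds, method="bulk")
    diagnostics = {"rhat": {}, "ess_bulk": {}, "failed": []}
    global_names = ["alpha", "sigma"] + [f"beta_{p}" for p in predictors]
    converged = True
    for name in global_names + ["offsets"]:
        r = float(np.nanmax(np.atleast_1d(rhat[name].values)))
        e = float(np.nanmin(np.atleast_1d(ess[name].values)))
        diagnostics["rhat"][name] = r
        diagnostics["ess_bulk"][name] = e
        if name in global_names:
            if r > config.rhat_threshold or e < config.ess_threshold:
                diagnostics["failed"].append(name)
                converged = False
    return diagnostics, converged


def summarize(
    sample: PosteriorSample,
    prob: float = 0.95,
    include_offsets: bool = False,
) -> pd.DataFrame:
    """Posterior mean, SD, and central percentile interval per parameter."""
    lo_q, hi_q = 50 * (1 - prob), 50 * (1 + prob)
    records = []
    for name in sample.parameter_names(include_offsets=include_offsets):
        draws = sample.stacked(name)
        lo, hi = np.percentile(draws, [lo_q, hi_q])
        records.append(
            {
                "parameter": name,
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(records).set_index("parameter")
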