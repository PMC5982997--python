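"""WAIC, Akaike weights, and the sequential model-selection workflow.

WAIC follows the deviance convention WAIC = -2 (lppd - p_WAIC) with the
variance-based penalty: lppd_i = log mean_s exp(ll_is) and
p_WAIC,i = Var_s(ll_is) (population variance over draws, the ArviZ
convention), summed over observation rows.  The pointwise
unit is the aggregated participant-stratum row, i.e. the unit the
likelihood is actually written over, so all models compared for a
behavior score identical rows.

Model building mirrors the study workflow: weekend and sex are screened
one at a time against the intercept-only null, adopted when their 95%
credible interval excludes zero *and* their pairwise Akaike weight
exceeds the null's; the trait model (plus adopted nuisance covariates)
is then compared against the nuisance-only reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .behaviors import BehaviorSpec
from .errors import DataError
from .model import ModelSpec
from .sampler import PosteriorSample, SamplerConfig, fit, summarize


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-observation -2*(lppd_i - p_i)
    se: float


def waic(pointwise_loglik) -> WaicResult:
    """WAIC from a draws x observations pointwise log-likelihood matrix.

    Accepts (draws, obs) or (chains, draws, obs).  The standard error is
    computed from the spread of the pointwise contributions and reported
    for context only; selection uses the weights.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 1:
        raise DataError("need >= 2 draws and >= 1 observation")
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll).all(axis=0))[0])
        raise DataError(f"non-finite log-likelihood in observation row {bad}")
    S = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0)  # population variance, as in ArviZ
    pointwise = -2.0 * (lppd_i - p_i)
    total = float(pointwise.sum())
    se = float(np.sqrt(ll.shape[1] * pointwise.var(ddof=1))) if ll.shape[1] > 1 else 0.0
    return WaicResult(
        waic=total,
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        pointwise=pointwise,
        se=se,
    )


def akaike_weights(waics) -> np.ndarray:
    """Normalized exp(-0.5 * delta-WAIC) across a model set."""
    w = np.asarray(waics, dtype=float)
    if w.size < 1:
        raise DataError("need at least one model")
    rel = np.exp(-0.5 * (w - w.min()))
    return rel / rel.sum()


def compare_models(samples: dict[str, PosteriorSample]) -> pd.DataFrame:
    """WAIC table with delta-WAIC and Akaike weights for a model set.

    All models must have been fitted to the identical observation rows.
    """
    names = list(samples)
    ref_index = None
    for name, s in samples.items():
        idx = s.row_index.reset_index(drop=True)
        if ref_index is None:
            ref_index = idx
        elif not idx.equals(ref_index):
            raise DataError(
                f"model {name!r} was fitted to different rows than the others"
            )
    results = {name: waic(s.pointwise_loglik) for name, s in samples.items()}
    waics = np.array([results[name].waic for name in names])
    weights = akaike_weights(waics)
    table = pd.DataFrame(
        {
            "model": names,
            "waic": waics,
            "lppd": [results[n].lppd for n in names],
            "p_waic": [results[n].p_waic for n in names],
            "se": [results[n].se for n in names],
            "d_waic": waics - waics.min(),
            "weight": weights,
        }
    ).set_index("model")
    return table.sort_values("waic")


@dataclass
class SelectionReport:
    """Outcome of the two-step selection for one behavior."""

    behavior: str
    degenerate: bool = False
    adopted: tuple[str, ...] = ()
    step1: dict = field(default_factory=dict)
    focal_predictors: tuple[str, ...] = ()
    reference_predictors: tuple[str, ...] = ()
    focal_weight: float = float("nan")
    slope_mean: float = float("nan")
    slope_sd: float = float("nan")
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    ci_excludes_zero: bool = False
    weight_exceeds_null: bool = False
    alhb_favored: bool = False
    waic_table: pd.DataFrame | None = None
    n_rows: int = 0
    converged: bool = True
    samples: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("samples")
        d["waic_table"] = (
            self.waic_table.reset_index().to_dict("records")
            if self.waic_table is not None
            else None
        )
        return d


def _pairwise_weight(sample_a: PosteriorSample, sample_b: PosteriorSample) -> float:
    """Akaike weight of model A in the two-model set {A, B}."""
    w = akaike_weights(
        [waic(sample_a.pointwise_loglik).waic, waic(sample_b.pointwise_loglik).waic]
    )
    return float(w[0])


def _beta_summary(sample: PosteriorSample, predictor: str, prob=0.95):
    s = summarize(sample, prob=prob)
    row = s.loc[f"beta_{predictor}"]
    return (
        float(row["mean"]),
        float(row["sd"]),
        (float(row["ci_low"]), float(row["ci_high"])),
    )


def build_and_select(
    behavior: BehaviorSpec,
    rows: pd.DataFrame,
    participants: pd.DataFrame,
    config: SamplerConfig | None = None,
    seed=None,
    keep_samples: bool = False,
) -> SelectionReport:
    """Run the nuisance-screening + trait-model workflow for one behavior.

    Step 1 fits weekend-only and sex-only models against the
    intercept-only null (skipped entirely for weekday-only behaviors,
    which are compared against the intercept-only model).  Step 2 fits
    the trait model with the adopted nuisance covariates and reports its
    pairwise Akaike weight against the nuisance-only reference, the
    slope posterior, and the two interpretation flags.
    """
    config = config or SamplerConfig()
    brows = rows[rows["behavior"] == behavior.name]
    if len(brows) == 0:
        raise DataError(f"no rows for behavior {behavior.name!r}")
    report = SelectionReport(behavior=behavior.name)
    if brows["k"].sum() == 0 or brows["n"].sum() == 0:
        report.degenerate = True
        return report
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(8))

    def _fit(predictors):
        try:
            return fit(
                ModelSpec(behavior.name, tuple(predictors)),
                brows,
                participants,
                config,
                seed=next(seeds),
            )
        except Exception as exc:
            raise DataError(f"fit failed for behavior {behavior.name!r}: {exc}")

    null = _fit(())
    samples = {"intercept_only": null}
    adopted: list[str] = []
    if not behavior.weekday_only:
        for cov in ("weekend", "sex"):
            if cov == "weekend" and set(brows["stratum"]) == {"pooled"}:
                continue  # pooled rows carry no weekend contrast
            s = _fit((cov,))
            samples[cov] = s
            mean, sd, ci = _beta_summary(s, cov)
            wt = _pairwise_weight(s, null)
            adopt = (ci[0] > 0 or ci[1] < 0) and wt > 0.5
            report.step1[cov] = {
                "beta_mean": mean,
                "beta_sd": sd,
                "ci": ci,
                "weight_vs_null": wt,
                "adopted": adopt,
            }
            if adopt:
                adopted.append(cov)
    report.adopted = tuple(adopted)
    reference = samples[adopted[0]] if len(adopted) == 1 else None
    ref_predictors = tuple(adopted)
    if reference is None:
        if adopted:
            reference = _fit(ref_predictors)
            samples["+".join(ref_predictors)] = reference
        else:
            reference = null
    focal_predictors = ref_predictors + ("alhb",)
    focal = _fit(focal_predictors)
    samples["+".join(focal_predictors)] = focal
    mean, sd, ci = _beta_summary(focal, "alhb")
    weight = _pairwise_weight(focal, reference)
    report.focal_predictors = focal_predictors
    report.reference_predictors = ref_predictors if ref_predictors else ("intercept",)
    report.focal_weight = weight
    report.slope_mean, report.slope_sd, report.slope_ci = mean, sd, ci
    report.ci_excludes_zero = ci[0] > 0 or ci[1] < 0
    report.weight_exceeds_null = weight > 0.5
    report.alhb_favored = report.ci_excludes_zero and report.weight_exceeds_null
    report.waic_table = compare_models(
        {name: s for name, s in samples.items()}
    )
    report.n_rows = int((brows["n"] > 0).sum())
    report.converged = all(s.converged for s in samples.values())
    if keep_samples:
        report.samples = samples
    return report
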