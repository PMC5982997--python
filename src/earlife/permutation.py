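"""Permutation-based multiplicity check for trait effects.

For a behavior whose trait model was favored on the real data, the
trait scores are randomly reassigned among participants — all other
variables stay put — and the model is refitted, by default 100 times.
The real-data slope and Akaike weight are then compared against the
permutation distributions: if permuted (null) datasets regularly
produce slopes and weights as extreme as the observed ones, the
observed association is not distinguishable from a selection artifact.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .behaviors import BehaviorSpec
from .comparison import _beta_summary, _pairwise_weight
from .errors import DataError
from .model import ModelSpec
from .sampler import SamplerConfig, fit

logger = logging.getLogger(__name__)


def permute_trait_scores(
    participants: pd.DataFrame, rng, identity: bool = False
) -> pd.DataFrame:
    """Reassign the trait column among participants (multiset preserved)."""
    permuted = participants.copy()
    values = permuted["alhb"].to_numpy().copy()
    if not identity:
        rng.shuffle(values)
    permuted["alhb"] = values
    return permuted


def permute_and_refit(
    behavior: BehaviorSpec,
    rows: pd.DataFrame,
    participants: pd.DataFrame,
    n_runs: int = 100,
    master_seed=None,
    config: SamplerConfig | None = None,
    predictors: tuple[str, ...] = ("weekend", "alhb"),
    reference_predictors: tuple[str, ...] = ("weekend",),
    force_identity: bool = False,
) -> pd.DataFrame:
    """Refit the trait model under ``n_runs`` trait-label permutations.

    Permutations are drawn uniformly over all labelings (the identity is
    allowed).  Each run reuses the real denominators and covariates;
    only the trait column moves.  The reference model contains no trait
    term, so it is fitted once and shared.  Runs whose fit fails are
    flagged (``ok=False``) and excluded from summaries.
    """
    if n_runs < 1:
        raise DataError("n_runs must be >= 1")
    config = config or SamplerConfig()
    brows = rows[rows["behavior"] == behavior.name]
    if len(brows) == 0:
        raise DataError(f"no rows for behavior {behavior.name!r}")
    if set(reference_predictors) - set(predictors) or "alhb" not in predictors:
        raise DataError("focal predictors must add 'alhb' to the reference set")
    ss = np.random.SeedSequence(master_seed)
    ref_seed, *run_seeds = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_runs + 1)
    ]
    reference = fit(
        ModelSpec(behavior.name, tuple(reference_predictors)),
        brows,
        participants,
        config,
        seed=ref_seed,
    )
    records = []
    n_failed = 0
    for run_id, run_seed in enumerate(run_seeds):
        rng = np.random.default_rng(run_seed)
        permuted = permute_trait_scores(participants, rng, identity=force_identity)
        rec = {"run_id": run_id, "seed": run_seed, "ok": True}
        try:
            sample = fit(
                ModelSpec(behavior.name, tuple(predictors)),
                brows,
                permuted,
                config,
                seed=run_seed,
            )
            mean, sd, ci = _beta_summary(sample, "alhb")
            rec.update(
                slope_mean=mean,
                slope_sd=sd,
                ci_low=ci[0],
                ci_high=ci[1],
                weight=_pairwise_weight(sample, reference),
                converged=sample.converged,
            )
        except Exception as exc:  # flagged, not fatal
            n_failed += 1
            rec.update(
                ok=False,
                slope_mean=np.nan,
                slope_sd=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                weight=np.nan,
                converged=False,
            )
            logger.warning("permutation run %d failed: %s", run_id, exc)
        records.append(rec)
    if n_failed:
        logger.warning("%d of %d permutation runs failed", n_failed, n_runs)
    return pd.DataFrame(records)


def summarize_permutation(
    runs: pd.DataFrame,
    real_slope: float,
    real_weight: float,
    weight_one_threshold: float = 0.995,
) -> dict:
    """Exceedance report for a permutation batch.

    Counts runs whose |slope| reaches the real |slope| and whose weight
    reaches the real weight, and tallies the runs attaining a weight of
    ~1.00 (>= ``weight_one_threshold``) in each slope direction, with
    the median slope of each group.
    """
    ok = runs[runs["ok"] == True]  # noqa: E712
    if len(ok) == 0:
        raise DataError("no successful permutation runs")
    slopes = ok["slope_mean"].to_numpy()
    weights = ok["weight"].to_numpy()
    pos_one = ok[(weights >= weight_one_threshold) & (slopes > 0)]
    neg_one = ok[(weights >= weight_one_threshold) & (slopes < 0)]
    return {
        "n_runs": int(len(runs)),
        "n_ok": int(len(ok)),
        "n_failed": int(len(runs) - len(ok)),
        "prop_abs_slope_ge_real": float(
            np.mean(np.abs(slopes) >= abs(real_slope))
        ),
        "prop_weight_ge_real": float(np.mean(weights >= real_weight)),
        "n_pos_weight_one": int(len(pos_one)),
        "n_neg_weight_one": int(len(neg_one)),
        "median_pos_weight_one_slope": (
            float(pos_one["slope_mean"].median()) if len(pos_one) else float("nan")
        ),
        "median_neg_weight_one_slope": (
            float(neg_one["slope_mean"].median()) if len(neg_one) else float("nan")
        ),
        "real_slope": float(real_slope),
        "real_weight": float(real_weight),
    }
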