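"""Inter-rater agreement and the reliability gate.

Coding reliability is assessed on a jointly coded clip set: every rater
labels every clip for each behavior, agreement is summarized with
Cohen's kappa (mean pairwise kappa when there are more than two
raters), and behaviors with kappa below 0.41 — the conventional lower
bound of "moderate" agreement — are excluded from analysis.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .behaviors import BehaviorSpec
from .errors import ConfigurationError, ValidationError


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    proportion and p_e the chance agreement implied by each rater's
    marginal label frequencies.  When both raters are constant and
    identical (p_e = p_o = 1) the agreement is perfect and 1.0 is
    returned rather than 0/0.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("ratings must be equal-length non-empty vectors")
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    pa = np.array([np.mean(a == lab) for lab in labels])
    pb = np.array([np.mean(b == lab) for lab in labels])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def multi_rater_kappa(matrix: pd.DataFrame) -> float:
    """Mean pairwise Cohen's kappa over all rater pairs.

    ``matrix`` is clips x raters, every cell filled.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 raters")
    if matrix.isna().any().any():
        raise ValidationError("coding matrix has missing cells")
    kappas = [
        cohens_kappa(matrix[r1], matrix[r2])
        for r1, r2 in combinations(matrix.columns, 2)
    ]
    return float(np.mean(kappas))


def fleiss_kappa(matrix: pd.DataFrame) -> float:
    """Fleiss' kappa, offered as a sensitivity alternative."""
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 raters")
    n_raters = matrix.shape[1]
    labels = sorted(set(matrix.to_numpy().ravel()))
    counts = np.stack(
        [(matrix.to_numpy() == lab).sum(axis=1) for lab in labels], axis=1
    )
    p_j = counts.sum(axis=0) / counts.sum()
    p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        return 1.0
    return float((p_bar - p_e) / (1.0 - p_e))


def apply_reliability_gate(
    behaviors: list[BehaviorSpec], threshold: float = 0.41
) -> tuple[list[BehaviorSpec], list[BehaviorSpec]]:
    """Split behaviors into (retained, excluded) by the kappa cut-off.

    A behavior is retained iff kappa >= threshold (the cut-off is the
    value *below* which behaviors are excluded, so exactly 0.41 stays).
    Ordering is preserved.
    """
    retained, excluded = [], []
    for spec in behaviors:
        if spec.kappa is None or not np.isfinite(spec.kappa):
            raise ConfigurationError(f"behavior {spec.name!r} has no kappa value")
        (retained if spec.kappa >= threshold else excluded).append(spec)
    return retained, excluded


def read_ratings(path) -> dict[str, pd.DataFrame]:
    """Read long-format ratings (clip_id, rater_id, behavior, label).

    Returns one clips x raters matrix per behavior.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("clip_id", "rater_id", "behavior", "label"):
        if col not in df.columns:
            raise ValidationError(f"ratings file lacks column {col!r}")
    return {
        behavior: sub.pivot(index="clip_id", columns="rater_id", values="label")
        for behavior, sub in df.groupby("behavior")
    }
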