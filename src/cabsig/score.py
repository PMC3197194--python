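"""Classical mean-expression signature score and its comparison with the
correlation-ratio classifier.

The mean score of a sample is the arithmetic mean of its signature-gene
log2 expression values.  The activation threshold is derived from a healthy
reference cohort as mean + 1.96 * SD of the reference scores (the upper 95%
normal limit); a score at or above the threshold calls the sample "high".

``compare_methods`` puts both classifiers side by side: a Spearman rank
correlation between the decision variable d and the mean score, the 2x2
agreement table, and the fraction of discordant calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isnan

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix, GeneSignature

__all__ = [
    "mean_score",
    "cohort_scores",
    "hc_threshold",
    "spearman",
    "ScoreComparison",
    "compare_methods",
]

EXACT_SPEARMAN_MAX_N = 9


def mean_score(profile: np.ndarray) -> float:
    """Arithmetic mean of a signature expression profile."""
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise DegenerateInputError("profile contains non-finite values")
    return float(profile.mean())


def cohort_scores(matrix: ExpressionMatrix, signature: GeneSignature) -> pd.Series:
    """Per-sample mean signature score for a whole cohort."""
    sub = matrix.subset(genes=signature)
    return pd.Series(sub.values.mean(axis=0), index=sub.sample_ids, name="mean_score")


def hc_threshold(hc_scores: np.ndarray) -> float:
    """Healthy-reference activation threshold: mean + 1.96 * sample SD."""
    hc_scores = np.asarray(hc_scores, dtype=float)
    if hc_scores.size < 2:
        raise DegenerateInputError("threshold needs >= 2 reference scores")
    return float(hc_scores.mean() + 1.96 * hc_scores.std(ddof=1))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p.

    Exact permutation p (enumeration of all n! pairings) for n <= 9, the
    large-sample t approximation above.  Ties take average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    rho = float(stats.spearmanr(x, y).statistic)
    if isnan(rho):
        raise DegenerateInputError("Spearman undefined (constant input)")
    if n > EXACT_SPEARMAN_MAX_N:
        return rho, float(stats.spearmanr(x, y).pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    sx = np.sqrt(rx_c @ rx_c)
    count = 0
    total = 0
    tol = 1e-12
    target = abs(rho) - tol
    for perm in permutations(ry):
        ry_c = np.asarray(perm) - ry.mean()
        sy = np.sqrt(ry_c @ ry_c)
        r = (rx_c @ ry_c) / (sx * sy)
        total += 1
        if abs(r) >= target:
            count += 1
    return rho, count / total


@dataclass
class ScoreComparison:
    """Head-to-head comparison of the mean score and the correlation ratio."""

    table: pd.DataFrame  # sample_id, mean_score, d, call_meanscore, call_cabs
    threshold: float
    agreement_fraction: float
    discordance_fraction: float
    spearman_rho: float
    spearman_p: float
    agreement_counts: pd.DataFrame  # 2x2, rows=call_cabs, cols=call_meanscore

    def to_summary_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "agreement_fraction": self.agreement_fraction,
            "discordance_fraction": self.discordance_fraction,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "agreement_table": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.agreement_counts.iterrows()
            },
            "note": "p-values descriptive; mean-score threshold = HC mean + 1.96 SD",
        }


def compare_methods(
    decisions: pd.DataFrame,
    scores: pd.Series,
    threshold: float,
) -> ScoreComparison:
    """Compare the two classifiers on a common sample set.

    Parameters
    ----------
    decisions
        Decision table with columns ``sample_id``, ``d``, ``call``.
    scores
        Per-sample mean scores indexed by sample ID (same sample set).
    threshold
        Mean-score activation cutoff; ``score >= threshold`` calls high.
    """
    dec = decisions.set_index("sample_id")
    only_dec = sorted(set(dec.index) - set(scores.index))
    only_sco = sorted(set(scores.index) - set(dec.index))
    if only_dec or only_sco:
        raise ValueError(
            f"sample sets differ: only in decisions {only_dec[:5]}, "
            f"only in scores {only_sco[:5]}"
        )
    scores = scores.loc[dec.index]
    call_ms = np.where(scores.to_numpy() >= threshold, "high", "low")
    table = pd.DataFrame(
        {
            "sample_id": dec.index,
            "mean_score": scores.to_numpy(),
            "d": dec["d"].to_numpy(),
            "call_meanscore": call_ms,
            "call_cabs": dec["call"].to_numpy(),
        }
    ).reset_index(drop=True)
    agree = (table["call_meanscore"] == table["call_cabs"]).mean()
    rho, p = spearman(table["d"].to_numpy(), table["mean_score"].to_numpy())
    counts = (
        table.groupby(["call_cabs", "call_meanscore"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=["high", "low"], columns=["high", "low"], fill_value=0)
    )
    return ScoreComparison(
        table=table,
        threshold=float(threshold),
        agreement_fraction=float(agree),
        discordance_fraction=float(1.0 - agree),
        spearman_rho=rho,
        spearman_p=p,
        agreement_counts=counts,
    )
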