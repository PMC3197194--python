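"""Paired longitudinal monitoring of the decision variable.

Patients classified before treatment are re-evaluated after treatment; the
change in the decision variable d within each baseline stratum (high / low)
is tested with a two-sided Wilcoxon signed-rank test.  Zero differences are
dropped before ranking (Wilcoxon's original procedure).  The null
distribution is exact — full enumeration of the 2^n sign assignments, with
midranks, for n <= 12 nonzero differences — and a tie-corrected normal
approximation above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CabsigError, NoInformationError

__all__ = [
    "pair_samples",
    "wilcoxon_signed_rank",
    "monitor_stratum",
    "monitor",
    "PairedMonitoringResult",
]

EXACT_WILCOXON_MAX_N = 12
TIMEPOINTS = ("before", "after")

PAIR_COLUMNS = ["pair_id", "sample_before", "sample_after", "d_before", "d_after", "stratum"]


@dataclass
class PairedMonitoringResult:
    """Signed-rank outcome for one baseline stratum."""

    stratum_label: str
    pairs: pd.DataFrame  # pair_id, d_before, d_after
    n: int
    w_statistic: float
    p_value: float
    direction: str  # "increase" | "decrease" | "none"

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum_label,
            "n_pairs": self.n,
            "w_statistic": self.w_statistic,
            "p_value": self.p_value,
            "direction": self.direction,
        }


def _lookup_timepoint(metadata: pd.DataFrame, sample_id: str) -> tuple[str, str]:
    if sample_id not in metadata.index:
        raise CabsigError(f"sample {sample_id!r} missing from metadata")
    row = metadata.loc[sample_id]
    pair_id, timepoint = str(row.get("pair_id")), str(row.get("timepoint"))
    if timepoint not in TIMEPOINTS:
        raise CabsigError(
            f"sample {sample_id!r}: unknown timepoint label {timepoint!r} "
            f"(expected one of {TIMEPOINTS})"
        )
    return pair_id, timepoint


def pair_samples(
    records_before: pd.DataFrame,
    records_after: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Link before/after decision records into patient pairs.

    Returns the pair table (stratum = the *baseline* call) and the list of
    orphan pair_ids (one timepoint missing), which are excluded but never
    silently dropped.
    """
    sides: dict[str, dict[str, pd.Series]] = {t: {} for t in TIMEPOINTS}
    for expected, records in zip(TIMEPOINTS, (records_before, records_after)):
        for _, rec in records.iterrows():
            pair_id, timepoint = _lookup_timepoint(metadata, rec["sample_id"])
            if timepoint != expected:
                raise CabsigError(
                    f"sample {rec['sample_id']!r} labeled {timepoint!r} but supplied "
                    f"in the {expected!r} table"
                )
            if pair_id in sides[expected]:
                raise CabsigError(
                    f"duplicate pair_id {pair_id!r} within timepoint {expected!r}"
                )
            sides[expected][pair_id] = rec
    complete = [p for p in sides["before"] if p in sides["after"]]
    orphans = sorted(
        (set(sides["before"]) | set(sides["after"])) - set(complete)
    )
    rows = []
    for pid in complete:
        b, a = sides["before"][pid], sides["after"][pid]
        rows.append(
            (pid, b["sample_id"], a["sample_id"], float(b["d"]), float(a["d"]), b["call"])
        )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS), orphans


def wilcoxon_signed_rank(differences: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(W, p)`` where W is the sum of the ranks of the positive
    differences.  Exact enumeration (midranks, 2^n sign assignments) for
    n <= 12 after zero-dropping; normal approximation with tie correction
    otherwise.  All-zero input raises :class:`NoInformationError`.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise NoInformationError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        return w, _exact_p(ranks, w)
    return w, _approx_p(ranks, w, n)


def _exact_p(ranks: np.ndarray, w: float) -> float:
    # midranks are multiples of 1/2: double everything and convolve counts
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_p(ranks: np.ndarray, w: float, n: int) -> float:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise NoInformationError("zero variance under the null (all ranks tied away)")
    z = (w - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def monitor_stratum(pairs: pd.DataFrame, stratum: str) -> PairedMonitoringResult:
    """Signed-rank test of d_after - d_before within one baseline stratum.

    An all-zero stratum is reported as direction ``"none"`` with p = 1
    rather than erroring (the low-level test still raises, so pipelines can
    distinguish).
    """
    sub = pairs[pairs["stratum"] == stratum]
    if sub.empty:
        raise CabsigError(f"no pairs in stratum {stratum!r}")
    diffs = sub["d_after"].to_numpy() - sub["d_before"].to_numpy()
    med = float(np.median(diffs))
    direction = "increase" if med > 0 else ("decrease" if med < 0 else "none")
    try:
        w, p = wilcoxon_signed_rank(diffs)
    except NoInformationError:
        w, p, direction = 0.0, 1.0, "none"
    return PairedMonitoringResult(
        stratum_label=stratum,
        pairs=sub[["pair_id", "d_before", "d_after"]].reset_index(drop=True),
        n=len(sub),
        w_statistic=w,
        p_value=p,
        direction=direction,
    )


def monitor(
    records_before: pd.DataFrame,
    records_after: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[dict[str, PairedMonitoringResult], list[str]]:
    """Pair samples and run the signed-rank test in every baseline stratum."""
    pairs, orphans = pair_samples(records_before, records_after, metadata)
    results = {
        stratum: monitor_stratum(pairs, stratum)
        for stratum in sorted(pairs["stratum"].unique())
    }
    return results, orphans
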