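"""Within-group co-expression structure of a gene signature.

For a sample group, every unordered pair of signature genes gets a Pearson
correlation computed across the group's samples.  Each gene's *correlation
index* is the median of its correlations with the remaining genes, and the
group's ``r_median`` is the median of those indexes — a single number
summarizing how coherently the signature is co-activated in that group.
Activated groups show high r_median (the motivating interferon signature:
~0.63 in activated patients vs ~0.33 in quiescent ones).

Two groups are compared with a two-sided Mann-Whitney U test on either the
off-diagonal pairwise correlations (default) or the per-gene indexes.  The
pairwise values share samples and are therefore dependent; the p-value is
descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix, GeneSignature, SampleGroup

__all__ = ["CorrelationProfile", "correlation_profile", "compare_correlation_levels"]


@dataclass
class CorrelationProfile:
    """Pairwise correlation matrix, per-gene indexes and r_median of one group."""

    group_label: str
    gene_ids: tuple[str, ...]
    pairwise: np.ndarray  # M x M, symmetric, unit diagonal
    index: np.ndarray  # per-gene correlation index
    r_median: float
    pairwise_median: float  # median of the off-diagonal pairwise values
    n_samples: int

    @property
    def offdiagonal(self) -> np.ndarray:
        """The M(M-1)/2 upper-triangle pairwise correlations."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.pairwise[iu]


def correlation_profile(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    group: SampleGroup | None = None,
) -> CorrelationProfile:
    """Compute the correlation profile of one sample group.

    ``group=None`` uses every sample in the matrix.  Requires >= 3 samples
    for a non-degenerate Pearson (2 samples give only +/-1; a warning is
    emitted) and no zero-variance gene within the group.
    """
    if group is None:
        group = SampleGroup("all", tuple(matrix.sample_ids))
    sub = matrix.subset(genes=signature, samples=group.sample_ids)
    X = sub.values  # M x n
    M, n = X.shape
    if n < 2:
        raise DegenerateInputError(
            f"group {group.label!r}: correlation needs >= 2 samples, got {n}"
        )
    if n < 3:
        warnings.warn(
            f"group {group.label!r} has {n} samples; pairwise Pearson is degenerate (+/-1)",
            stacklevel=2,
        )
    variances = X.var(axis=1)
    if np.any(variances == 0.0):
        bad = sub.gene_ids[int(np.argmax(variances == 0.0))]
        raise DegenerateInputError(
            f"group {group.label!r}: gene {bad!r} has zero variance"
        )
    pairwise = np.corrcoef(X)
    pairwise = np.clip((pairwise + pairwise.T) / 2.0, -1.0, 1.0)  # exact symmetry
    np.fill_diagonal(pairwise, 1.0)
    index = np.empty(M)
    for j in range(M):
        index[j] = np.median(np.delete(pairwise[j], j))
    iu = np.triu_indices(M, k=1)
    return CorrelationProfile(
        group_label=group.label,
        gene_ids=tuple(sub.gene_ids),
        pairwise=pairwise,
        index=index,
        r_median=float(np.median(index)),
        pairwise_median=float(np.median(pairwise[iu])),
        n_samples=n,
    )


def compare_correlation_levels(
    a: CorrelationProfile,
    b: CorrelationProfile,
    unit: str = "pairwise",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing correlation levels of two groups.

    ``unit='pairwise'`` compares the M(M-1)/2 off-diagonal correlations,
    ``unit='index'`` the M per-gene indexes.  Both profiles must cover the
    same signature.  Returns ``(U, p)``.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("profiles cover different signatures")
    if unit == "pairwise":
        x, y = a.offdiagonal, b.offdiagonal
    elif unit == "index":
        x, y = a.index, b.index
    else:
        raise ValueError(f"unit must be 'pairwise' or 'index', got {unit!r}")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
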