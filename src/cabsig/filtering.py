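"""Two-stage gene filtering before heterogeneity analysis.

Stage 1 removes genes whose median log2 expression across all samples falls
strictly below an intensity threshold (default 6.0, i.e. twice a typical
array background).  Stage 2 removes low-variability genes: per-gene MAD
(median absolute deviation, unscaled) strictly below the median of the MADs
of the stage-1 survivors.  "Strictly below" in both stages: a gene exactly
at the cutoff survives.

The MAD here is the raw ``median(|x - median(x)|)`` without the 1.4826
normal-consistency factor — the cutoff is the median of the MADs themselves,
so any constant factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .matrix import ExpressionMatrix

__all__ = ["FilterReport", "intensity_filter", "mad_filter", "run_filters"]

DEFAULT_INTENSITY_THRESHOLD = 6.0


@dataclass
class FilterReport:
    """Counts and removed-ID lists for the two filtering stages."""

    n_input: int
    n_after_intensity: int
    n_after_mad: int
    intensity_threshold: float
    mad_cutoff: float
    removed_by_intensity: list[str] = field(default_factory=list)
    removed_by_mad: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_intensity": self.n_after_intensity,
            "n_after_mad": self.n_after_mad,
            "intensity_threshold": self.intensity_threshold,
            "mad_cutoff": self.mad_cutoff,
            "removed_by_intensity": self.removed_by_intensity,
            "removed_by_mad": self.removed_by_mad,
        }


def intensity_filter(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes whose per-gene median expression is >= ``threshold``."""
    if matrix.n_genes == 0:
        raise DegenerateInputError("empty matrix")
    medians = np.median(matrix.values, axis=1)
    keep = medians >= threshold
    if not keep.any():
        raise DegenerateInputError(
            f"intensity filter at threshold {threshold} removed every gene"
        )
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return matrix.subset(genes=kept_ids), removed


def gene_mads(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene raw MAD across samples."""
    v = matrix.values
    return np.median(np.abs(v - np.median(v, axis=1, keepdims=True)), axis=1)


def mad_filter(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str], float]:
    """Remove genes whose MAD is strictly below the median of all gene MADs.

    At least half the genes always survive (ties at the cutoff are kept).
    """
    if matrix.n_genes < 2:
        raise DegenerateInputError("MAD filter needs >= 2 genes")
    mads = gene_mads(matrix)
    cutoff = float(np.median(mads))
    keep = mads >= cutoff
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return matrix.subset(genes=kept_ids), removed, cutoff


def run_filters(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_INTENSITY_THRESHOLD
) -> tuple[ExpressionMatrix, FilterReport]:
    """Intensity filter then MAD filter, with a populated report."""
    after_int, removed_int = intensity_filter(matrix, threshold)
    after_mad, removed_mad, cutoff = mad_filter(after_int)
    report = FilterReport(
        n_input=matrix.n_genes,
        n_after_intensity=after_int.n_genes,
        n_after_mad=after_mad.n_genes,
        intensity_threshold=float(threshold),
        mad_cutoff=cutoff,
        removed_by_intensity=removed_int,
        removed_by_mad=removed_mad,
    )
    return after_mad, report
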