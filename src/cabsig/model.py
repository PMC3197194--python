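"""Correlation-ratio classification of signature activation (CABS).

The classifier assigns each sample to a "high" (activated) or "low"
(quiescent) signature state in three steps:

1. *Prototype construction.*  A training cohort is split into two groups —
   either supplied, or bootstrapped by agglomerative clustering of the
   samples on their signature-gene profiles — and each group is summarized
   by its per-gene median expression vector, the prototype ``G_i = (G_i1,
   ..., G_iM)``.  The cluster with the larger mean signature expression is
   the "high" group.

2. *Decision variable.*  For a sample's signature profile ``x``, Pearson
   correlations with both prototypes give ``COR_high`` and ``COR_low``; the
   decision variable is their ratio ``d = COR_high / COR_low``.

3. *Call.*  The sample is called "high" when ``COR_high >= COR_low``.
   When ``COR_low > 0`` this is exactly ``d >= 1``; when ``COR_low <= 0``
   the ratio is sign-unsafe and the correlation comparison governs.

Prototypes are fit once and may be reused on other cohorts (the intended
use: fit on one disease cohort, classify controls and other diseases).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import DegenerateInputError, UnknownIDError
from .matrix import ExpressionMatrix, GeneSignature, SampleGroup

__all__ = [
    "PrototypePair",
    "DecisionRecord",
    "bootstrap_groups",
    "build_prototypes",
    "decision_variable",
    "classify_cohort",
    "fit_and_classify",
    "records_to_frame",
    "SignatureClassificationModel",
    "SignatureClassificationResults",
]

DECISION_COLUMNS = ["sample_id", "cor_high", "cor_low", "d", "call"]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        raise DegenerateInputError("Pearson correlation undefined for constant vector")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


@dataclass(frozen=True)
class PrototypePair:
    """Per-gene median expression vectors of the high and low training groups."""

    signature: GeneSignature
    high: np.ndarray
    low: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        M = self.signature.size
        for name in ("high", "low"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (M,):
                raise ValueError(f"{name} prototype must have length {M}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} prototype contains non-finite values")
            if np.ptp(v) == 0.0:
                raise DegenerateInputError(
                    f"{name} prototype is constant; correlation undefined"
                )

    def save(self, path: str | Path) -> None:
        doc = {
            "signature": list(self.signature.gene_ids),
            "signature_name": self.signature.name,
            "high": self.high.tolist(),
            "low": self.low.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PrototypePair":
        doc = json.loads(Path(path).read_text())
        sig = GeneSignature(doc.get("signature_name", "signature"), tuple(doc["signature"]))
        return cls(
            signature=sig,
            high=np.asarray(doc["high"], dtype=float),
            low=np.asarray(doc["low"], dtype=float),
            provenance=doc.get("provenance", {}),
        )


@dataclass(frozen=True)
class DecisionRecord:
    """Per-sample classification outcome."""

    sample_id: str
    cor_high: float
    cor_low: float
    d: float
    call: str  # "high" | "low"


def records_to_frame(records: Sequence[DecisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.cor_high, r.cor_low, r.d, r.call) for r in records],
        columns=DECISION_COLUMNS,
    )


def bootstrap_groups(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    k: int = 2,
    linkage_method: str = "ward",
    metric: str = "correlation",
) -> tuple[SampleGroup, SampleGroup]:
    """Split samples into high/low groups by clustering signature profiles.

    Agglomerative clustering of the samples on the M signature genes, cut
    into ``k=2`` clusters; the cluster with the larger mean signature
    expression is labeled ``high``.  The default — Ward linkage on
    per-sample standardized profiles (``metric='correlation'``) — clusters
    in the same correlation geometry the classifier scores in (for z-scored
    profiles, squared Euclidean distance is proportional to 1 - Pearson)
    while keeping Ward's balanced merges; ``linkage_method='average'``
    gives the classic 1 - Pearson / average-linkage alternative, and
    ``metric='euclidean'`` clusters raw (level-sensitive) profiles.
    """
    if k != 2:
        raise ValueError("only k=2 (high/low) is supported")
    sub = matrix.subset(genes=signature)
    X = sub.values.T  # samples x genes
    if X.shape[0] < 2:
        raise DegenerateInputError("clustering needs >= 2 samples")
    if np.any(np.ptp(X, axis=1) == 0.0) and metric == "correlation":
        flat = [s for s, p in zip(sub.sample_ids, np.ptp(X, axis=1)) if p == 0.0]
        raise DegenerateInputError(
            f"zero-variance signature profile(s) {flat[:3]} break correlation distance"
        )
    if np.ptp(X) == 0.0 or np.all(np.ptp(X, axis=0) == 0.0):
        raise DegenerateInputError("all samples identical; clustering is degenerate")
    if metric == "correlation" and linkage_method == "ward":
        # Ward needs raw observations in Euclidean space; z-scoring each
        # profile maps 1 - Pearson onto squared Euclidean distance
        Z_obs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        Z = linkage(Z_obs, method="ward")
    else:
        Z = linkage(X, method=linkage_method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    ids = np.asarray(sub.sample_ids)
    means = {c: X[labels == c].mean() for c in np.unique(labels)}
    high_cluster = max(means, key=lambda c: (means[c], -c))
    high_ids = tuple(ids[labels == high_cluster])
    low_ids = tuple(ids[labels != high_cluster])
    for label, members in (("high", high_ids), ("low", low_ids)):
        if len(members) < 2:
            warnings.warn(
                f"bootstrap cluster {label!r} has {len(members)} sample(s); "
                "its prototype is a single profile",
                stacklevel=2,
            )
    return SampleGroup("high", high_ids), SampleGroup("low", low_ids)


def build_prototypes(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    groups: tuple[SampleGroup, SampleGroup],
) -> PrototypePair:
    """Per-gene group medians, in signature order (CABS step 1)."""
    by_label = {g.label: g for g in groups}
    if set(by_label) != {"high", "low"}:
        raise ValueError("groups must be labeled 'high' and 'low'")
    if set(by_label["high"].sample_ids) & set(by_label["low"].sample_ids):
        raise ValueError("high and low groups overlap")
    sub = matrix.subset(genes=signature)
    vectors = {}
    for label, grp in by_label.items():
        vals = sub.subset(samples=grp.sample_ids).values
        vectors[label] = np.median(vals, axis=1)
    return PrototypePair(
        signature=signature,
        high=vectors["high"],
        low=vectors["low"],
        provenance={
            "n_high": len(by_label["high"]),
            "n_low": len(by_label["low"]),
            "high_samples": list(by_label["high"].sample_ids),
            "low_samples": list(by_label["low"].sample_ids),
        },
    )


def decision_variable(
    profile: np.ndarray, prototypes: PrototypePair, sample_id: str = "sample"
) -> DecisionRecord:
    """CABS steps 2-3 for one signature profile.

    ``d`` is reported as a signed infinity when ``COR_low`` is exactly 0;
    the call itself never depends on the ratio.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (prototypes.signature.size,):
        raise ValueError(
            f"profile length {profile.shape} != signature size {prototypes.signature.size}"
        )
    if not np.all(np.isfinite(profile)):
        raise DegenerateInputError(f"sample {sample_id!r}: non-finite profile")
    if np.ptp(profile) == 0.0:
        raise DegenerateInputError(
            f"sample {sample_id!r}: constant profile, correlation undefined"
        )
    cor_high = _pearson(profile, prototypes.high)
    cor_low = _pearson(profile, prototypes.low)
    if cor_low != 0.0:
        d = cor_high / cor_low
    else:
        d = float(np.copysign(np.inf, cor_high)) if cor_high != 0.0 else float("nan")
    call = "high" if cor_high >= cor_low else "low"
    return DecisionRecord(sample_id, cor_high, cor_low, float(d), call)


def classify_cohort(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    prototypes: PrototypePair,
) -> tuple[list[DecisionRecord], dict]:
    """Classify every sample of a cohort against fixed prototypes.

    Prototypes are *not* refit.  A sample on which the decision variable is
    undefined aborts with an error naming it (never silently skipped).
    """
    missing = [g for g in signature.gene_ids if g not in set(matrix.gene_ids)]
    if missing:
        raise UnknownIDError(
            f"{len(missing)} signature gene(s) absent from matrix: {missing[:5]}"
        )
    sub = matrix.subset(genes=signature)
    records = [
        decision_variable(sub.values[:, j], prototypes, sample_id=s)
        for j, s in enumerate(sub.sample_ids)
    ]
    n_high = sum(r.call == "high" for r in records)
    summary = {
        "n_samples": len(records),
        "n_high": n_high,
        "n_low": len(records) - n_high,
        "fraction_high": n_high / len(records) if records else float("nan"),
    }
    return records, summary


def fit_and_classify(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    linkage_method: str = "ward",
    metric: str = "correlation",
) -> tuple[PrototypePair, list[DecisionRecord]]:
    """One-cohort convenience workflow: bootstrap, build prototypes, classify."""
    groups = bootstrap_groups(
        matrix, signature, linkage_method=linkage_method, metric=metric
    )
    prototypes = build_prototypes(matrix, signature, groups)
    records, _ = classify_cohort(matrix, signature, prototypes)
    return prototypes, records


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class SignatureClassificationModel:
    """Correlation-ratio signature classifier bound to a training cohort.

    Parameters
    ----------
    matrix
        Training cohort expression matrix (log2, genes x samples).
    signature
        The gene signature scored by the classifier.
    linkage_method, metric
        Agglomerative-clustering settings for the bootstrap labeling.

    Examples
    --------
    >>> model = SignatureClassificationModel(matrix, signature)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> new_calls = res.predict(other_cohort)
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        signature: GeneSignature,
        linkage_method: str = "ward",
        metric: str = "correlation",
    ) -> None:
        self.matrix = matrix
        self.signature = signature
        self.linkage_method = linkage_method
        self.metric = metric

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        signature_genes: Sequence[str],
        name: str = "signature",
        **kwargs,
    ) -> "SignatureClassificationModel":
        """Build from a genes x samples DataFrame and a gene-ID list."""
        return cls(
            ExpressionMatrix(data),
            GeneSignature.from_ids(signature_genes, name=name),
            **kwargs,
        )

    def fit(
        self, groups: tuple[SampleGroup, SampleGroup] | None = None
    ) -> "SignatureClassificationResults":
        """Fit prototypes (bootstrapping the groups unless supplied) and
        classify the training cohort."""
        if groups is None:
            groups = bootstrap_groups(
                self.matrix,
                self.signature,
                linkage_method=self.linkage_method,
                metric=self.metric,
            )
        prototypes = build_prototypes(self.matrix, self.signature, groups)
        records, summary = classify_cohort(self.matrix, self.signature, prototypes)
        return SignatureClassificationResults(self, prototypes, groups, records, summary)


class SignatureClassificationResults:
    """Fitted prototypes plus the training-cohort classification."""

    def __init__(
        self,
        model: SignatureClassificationModel,
        prototypes: PrototypePair,
        groups: tuple[SampleGroup, SampleGroup],
        records: list[DecisionRecord],
        summary_stats: dict,
    ) -> None:
        self.model = model
        self.prototypes = prototypes
        self.groups = groups
        self.records = records
        self.summary_stats = summary_stats

    @property
    def decisions(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def predict(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Classify a new cohort against the fitted prototypes (no refit)."""
        records, _ = classify_cohort(matrix, self.model.signature, self.prototypes)
        return records_to_frame(records)

    def summary(self) -> str:
        s = self.summary_stats
        prov = self.prototypes.provenance
        sig = self.model.signature
        lines = [
            "Signature classification (correlation-ratio / CABS)",
            "=" * 53,
            f"Signature:        {sig.name} ({sig.size} genes)",
            f"Training samples: {s['n_samples']}"
            f"  (bootstrap groups: {prov.get('n_high', '?')} high / {prov.get('n_low', '?')} low)",
            f"Clustering:       {self.model.linkage_method} linkage, {self.model.metric} distance",
            "-" * 53,
            f"Called high:      {s['n_high']} ({100 * s['fraction_high']:.1f}%)",
            f"Called low:       {s['n_low']}",
            "-" * 53,
            "Rule: call = high iff Pearson(profile, P_high) >= Pearson(profile, P_low);",
            "      d = COR_high / COR_low reported per sample.",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        s = self.summary_stats
        return (
            f"<SignatureClassificationResults: {s['n_high']} high / "
            f"{s['n_low']} low of {s['n_samples']}>"
        )
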