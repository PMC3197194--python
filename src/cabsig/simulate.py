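"""Synthetic cohort generator with a latent-factor signature block.

Each sample group shares one latent activation factor: for sample ``s`` in
group ``g`` with factor draw ``f_s ~ N(0, 1)``, signature gene ``j`` gets

    x_js = b_j + shift_g * w_j + (lambda_g + jitter_j) * f_s + eps_js

where ``b_j ~ N(baseline_mean, baseline_sd^2)`` is the gene's baseline
level, ``w_j`` a gene-specific induction weight (uniform, normalized to
mean 1) scaling the group's activation shift, ``lambda_g`` the factor
loading and ``eps_js ~ N(0, noise_sd^2)`` i.i.d. noise.  With jitter 0 the
within-group correlation of every signature gene pair is exactly

    rho = lambda^2 / (lambda^2 + noise_sd^2),

inverted by :func:`loading_for_rho`.  Background genes are independent
noise around their own baselines.  Gene-level draws (baselines, weights,
jitter) are made once per cohort, so groups and paired timepoints are
comparable gene by gene.  Two *different* cohorts share gene identities
only when generated with the same ``gene_seed`` — required whenever
prototypes fitted on one cohort are applied to another.

The gene-specific baselines and induction weights are what make prototype
classification meaningful: real signature genes sit at different expression
levels and are induced to different degrees, and the classifier reads that
shape.  A flat baseline with a uniform shift would give near-constant,
near-collinear prototypes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "GroupDesign",
    "CohortDesign",
    "loading_for_rho",
    "generate_cohort",
    "paired_cohort",
]


@dataclass(frozen=True)
class GroupDesign:
    """One sample group: size, target pairwise correlation, activation shift."""

    label: str
    n_samples: int
    rho: float
    mean_shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.n_samples < 1:
            raise ValueError("group size must be >= 1")
        if not math.isfinite(self.mean_shift):
            raise ValueError("mean_shift must be finite")


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    Defaults mirror the motivating study's signature: 35 signature genes on
    a log2 scale around 8 with unit noise; activated groups use rho ~ 0.63
    and a +2 shift, quiescent ones rho ~ 0.33 and no shift.
    """

    groups: list[GroupDesign]
    m_signature: int = 35
    n_background: int = 200
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    loading_jitter: float = 0.1
    activation_spread: float = 1.0  # weights w_j ~ U(1 - s, 1 + s), normalized
    seed: int = 0
    gene_seed: int | None = None  # share gene identities across cohorts

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group")
        if self.m_signature < 2:
            raise ValueError("m_signature must be >= 2")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.loading_jitter < 0 or self.baseline_sd < 0:
            raise ValueError("loading_jitter and baseline_sd must be >= 0")
        if not 0.0 <= self.activation_spread <= 1.0:
            raise ValueError("activation_spread must be in [0, 1]")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")

    @classmethod
    def two_group(
        cls,
        n_high: int = 50,
        n_low: int = 50,
        rho_high: float = 0.63,
        rho_low: float = 0.33,
        shift_high: float = 2.0,
        seed: int = 0,
        **kwargs,
    ) -> "CohortDesign":
        """Activated-vs-quiescent design at the study's reference values."""
        return cls(
            groups=[
                GroupDesign("activated", n_high, rho_high, shift_high),
                GroupDesign("quiescent", n_low, rho_low, 0.0),
            ],
            seed=seed,
            **kwargs,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortDesign":
        doc = json.loads(Path(path).read_text())
        groups = [GroupDesign(**g) for g in doc.pop("groups")]
        return cls(groups=groups, **doc)


def loading_for_rho(rho: float, noise_sd: float = 1.0) -> float:
    """Factor loading giving pairwise correlation ``rho`` at noise ``noise_sd``.

    Inverts rho = lambda^2 / (lambda^2 + sigma^2):
    lambda = sigma * sqrt(rho / (1 - rho)).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    return noise_sd * math.sqrt(rho / (1.0 - rho))


@dataclass(frozen=True)
class _GeneEffects:
    """Per-gene draws shared by all groups (and both paired timepoints)."""

    baselines_sig: np.ndarray
    baselines_bg: np.ndarray
    weights: np.ndarray
    jitter: np.ndarray


def _init_streams(
    design: CohortDesign, seed: int | None
) -> tuple[np.random.Generator, _GeneEffects]:
    """Sample-level RNG plus gene effects from their own (shareable) streams."""
    base = design.seed if seed is None else seed
    gene_seed = base if design.gene_seed is None else design.gene_seed
    return np.random.default_rng([base, 1]), _draw_gene_effects(design, gene_seed)


def _draw_gene_effects(design: CohortDesign, gene_seed: int) -> _GeneEffects:
    # one substream per component, so two designs sharing gene_seed get
    # identical signature-gene effects whatever their group structure or
    # background size — required for cross-cohort prototype reuse
    def stream(k: int) -> np.random.Generator:
        return np.random.default_rng([gene_seed, 10 + k])

    b_sig = stream(0).normal(design.baseline_mean, design.baseline_sd, design.m_signature)
    b_bg = stream(1).normal(design.baseline_mean, design.baseline_sd, design.n_background)
    s = design.activation_spread
    w = stream(2).uniform(1.0 - s, 1.0 + s, design.m_signature)
    if w.mean() > 0:
        w = w / w.mean()  # keep the cohort-level mean shift exact
    jitter = stream(3).normal(0.0, design.loading_jitter, design.m_signature) \
        if design.loading_jitter > 0 else np.zeros(design.m_signature)
    return _GeneEffects(b_sig, b_bg, w, jitter)


def _group_block(
    design: CohortDesign,
    group: GroupDesign,
    eff: _GeneEffects,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = loading_for_rho(group.rho, design.noise_sd)
    f = rng.normal(size=group.n_samples)
    loadings = lam + eff.jitter
    sig = (
        eff.baselines_sig[:, None]
        + group.mean_shift * eff.weights[:, None]
        + loadings[:, None] * f[None, :]
        + rng.normal(0.0, design.noise_sd, (design.m_signature, group.n_samples))
    )
    bg = eff.baselines_bg[:, None] + rng.normal(
        0.0, design.noise_sd, (design.n_background, group.n_samples)
    )
    return np.vstack([sig, bg])


def _gene_ids(design: CohortDesign) -> list[str]:
    sig = [f"SIG{j + 1:03d}" for j in range(design.m_signature)]
    bg = [f"BG{j + 1:04d}" for j in range(design.n_background)]
    return sig + bg


def signature_ids(design: CohortDesign) -> list[str]:
    """Gene IDs of the signature block."""
    return [f"SIG{j + 1:03d}" for j in range(design.m_signature)]


def generate_cohort(
    design: CohortDesign, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one cohort; returns the matrix and true-group metadata.

    Fully reproducible: same design + seed, same matrix.  ``seed`` overrides
    ``design.seed`` when given.
    """
    rng, eff = _init_streams(design, seed)
    blocks, sample_ids, labels = [], [], []
    for group in design.groups:
        blocks.append(_group_block(design, group, eff, rng))
        sample_ids += [f"{group.label}_{i + 1:03d}" for i in range(group.n_samples)]
        labels += [group.label] * group.n_samples
    data = pd.DataFrame(
        np.hstack(blocks), index=_gene_ids(design), columns=sample_ids
    )
    meta = pd.DataFrame({"group": labels}, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(data, meta.copy()), meta.reset_index()


def paired_cohort(
    design: CohortDesign,
    after_groups: list[GroupDesign],
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Generate linked before/after matrices for paired monitoring.

    ``after_groups`` must match the design's group labels and sizes; rho and
    mean_shift may change (the treatment effect).  Gene-level draws are
    shared between timepoints; factors and noise are redrawn, i.e. the
    patient's activation state is resampled under the new parameters.
    Sample IDs carry the timepoint; pair_ids are bijective between the two
    matrices.
    """
    by_label = {g.label: g for g in after_groups}
    if set(by_label) != {g.label for g in design.groups}:
        raise ValueError("after_groups labels must match the design's groups")
    for g in design.groups:
        if by_label[g.label].n_samples != g.n_samples:
            raise ValueError(f"group {g.label!r}: paired sizes must match")
    rng, eff = _init_streams(design, seed)
    gene_ids = _gene_ids(design)
    mats, metas = [], []
    for timepoint, groups in (("before", design.groups), ("after", [by_label[g.label] for g in design.groups])):
        blocks, ids, pair_ids, labels = [], [], [], []
        for group in groups:
            blocks.append(_group_block(design, group, eff, rng))
            for i in range(group.n_samples):
                pid = f"{group.label}_P{i + 1:03d}"
                pair_ids.append(pid)
                ids.append(f"{pid}_{timepoint}")
                labels.append(group.label)
        data = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=ids)
        metas.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "group": labels,
                    "pair_id": pair_ids,
                    "timepoint": timepoint,
                }
            )
        )
        mats.append(data)
    meta = pd.concat(metas, ignore_index=True)
    meta_idx = meta.set_index("sample_id")
    before = ExpressionMatrix(mats[0], meta_idx.loc[mats[0].columns].copy())
    after = ExpressionMatrix(mats[1], meta_idx.loc[mats[1].columns].copy())
    return before, after, meta
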