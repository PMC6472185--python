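"""Background correction, housekeeper stability and lane scaling.

The normalization path for an nCounter cartridge runs in three stages:

1. **Background thresholding** — per lane, counts below
   ``geomean(negative controls) + 2 * SD(negative controls)`` are floored to
   that threshold.  Flooring (not subtraction) keeps every value strictly
   positive, which the log-ratio statistics downstream require.
2. **Housekeeper selection** — candidate housekeeping genes are ranked by
   the geNorm stability statistic M (mean, over all other candidates, of
   the standard deviation across lanes of the pairwise log2 expression
   ratio) and the least stable gene is removed iteratively until ``n_keep``
   (>= 3) genes survive.
3. **Lane scaling** — the scaling factor of lane *l* is
   ``SF_l = A / g_l`` where ``g_l`` is the geometric mean of the selected
   housekeepers in lane *l* and ``A`` the arithmetic mean of the ``g_l``
   across lanes.  Multiplying every count by its lane's factor equalizes
   housekeeper geometric means across lanes while preserving their mean.

The M statistic is invariant to multiplying a whole lane by a positive
constant, which is exactly what makes it usable *before* lane effects are
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientControlsError, ValidationError
from .matrix import ExpressionMatrix, GENE_CLASSES, geometric_mean
from .rcc import Cartridge

DEFAULT_N_KEEP = 3


@dataclass(frozen=True)
class NormalizationResult:
    """Everything the normalization path computed, per lane and per gene."""

    background_thresholds: pd.Series  # per sample
    selected_housekeepers: tuple[str, ...]
    stability_m: dict[str, float]  # final M of the surviving housekeepers
    lane_geomeans: pd.Series  # g_l, on background-corrected counts
    scaling_factors: pd.Series  # SF_l = mean(g)/g_l
    matrix: ExpressionMatrix  # stage "normalized", gene probes only
    control_matrix: ExpressionMatrix  # stage "normalized", control probes

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "background_threshold": self.background_thresholds,
                "lane_geomean": self.lane_geomeans,
                "scaling_factor": self.scaling_factors,
            }
        ).rename_axis("sample_id")


def background_threshold(negative_counts) -> float:
    """Per-lane background level: geomean(negatives) + 2 * SD(negatives).

    Zero counts are replaced by 1 inside the geometric mean only; the
    standard deviation (sample SD, ddof=1) is taken on the raw counts.
    The result is therefore always >= 1.
    """
    counts = np.asarray(list(negative_counts), dtype=float)
    if counts.size < 2:
        raise InsufficientControlsError(
            f"need >= 2 negative controls, got {counts.size}"
        )
    if (counts < 0).any():
        raise DomainError("negative control counts must be non-negative")
    floored = np.where(counts == 0, 1.0, counts)
    return float(geometric_mean(floored) + 2.0 * counts.std(ddof=1))


def apply_background(
    matrix: ExpressionMatrix, thresholds: pd.Series
) -> ExpressionMatrix:
    """Floor each sample's counts at that sample's background threshold."""
    missing = [s for s in matrix.sample_ids if s not in thresholds.index]
    if missing:
        raise ValidationError(f"no background threshold for samples: {missing}")
    clipped = matrix.values.clip(lower=thresholds[matrix.sample_ids], axis=1)
    return ExpressionMatrix(
        values=clipped, code_class=matrix.code_class, stage="background_corrected"
    )


def genorm_stability(hk_matrix: pd.DataFrame) -> dict[str, float]:
    """geNorm M for every row of a (genes × samples) positive-valued table.

    ``M_j = mean over k != j of SD_samples(log2(x_j / x_k))`` with the
    sample standard deviation (ddof=1).  Lower M means more stable.

    The pairwise SDs are computed from the covariance matrix of the log2
    values: ``Var(L_j - L_k) = Var(L_j) + Var(L_k) - 2 Cov(L_j, L_k)``,
    which is O(g^2) in memory instead of O(g^2 s).
    """
    values = hk_matrix.to_numpy(dtype=float)
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise DomainError("stability needs >= 2 genes and >= 2 samples")
    if (values <= 0).any():
        raise DomainError("stability is defined on strictly positive values")
    log2 = np.log2(values)
    cov = np.cov(log2, ddof=1)  # genes x genes
    var = np.diag(cov)
    pair_var = var[:, None] + var[None, :] - 2.0 * cov
    pair_sd = np.sqrt(np.clip(pair_var, 0.0, None))
    np.fill_diagonal(pair_sd, 0.0)
    m = pair_sd.sum(axis=1) / (values.shape[0] - 1)
    return dict(zip(hk_matrix.index, m.astype(float)))


def select_housekeepers(
    hk_matrix: pd.DataFrame, n_keep: int = DEFAULT_N_KEEP
) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop the least stable candidate until ``n_keep`` remain.

    Each round recomputes M on the survivors and removes the gene with the
    highest M; among exact ties the lexicographically last name goes first,
    so the procedure is fully deterministic.  Survivors are returned in the
    input row order together with their final M values.
    """
    if n_keep < 3:
        raise ValidationError(f"n_keep must be >= 3, got {n_keep}")
    if hk_matrix.shape[0] < n_keep:
        raise ValidationError(
            f"only {hk_matrix.shape[0]} housekeeper candidates for n_keep={n_keep}"
        )
    current = hk_matrix
    m_map = genorm_stability(current)
    while current.shape[0] > n_keep:
        worst = max(m_map, key=lambda g: (m_map[g], g))
        current = current.drop(index=worst)
        m_map = genorm_stability(current)
    survivors = [g for g in hk_matrix.index if g in m_map]
    return survivors, m_map


def scaling_factors(hk_matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-lane geomeans g_l of the selected housekeepers and SF_l = mean(g)/g_l."""
    values = hk_matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise DomainError("scaling factors require strictly positive counts")
    g = pd.Series(geometric_mean(values, axis=0), index=hk_matrix.columns)
    sf = g.mean() / g
    return g, sf


def normalize_cartridge(
    cartridge: Cartridge, n_keep: int = DEFAULT_N_KEEP
) -> NormalizationResult:
    """Run the full background → housekeeper selection → scaling path.

    Endogenous and housekeeping probes make up the output matrix; control
    probes are excluded from it but their scaled values are retained in
    ``control_matrix``.
    """
    flat = ExpressionMatrix.from_cartridge(cartridge)
    thresholds = {}
    for s in cartridge.samples:
        negatives = [c.count for c in s.codes_of_class("Negative")]
        if len(negatives) < 2:
            raise InsufficientControlsError(
                f"sample '{s.sample_id}': need >= 2 negative controls, got {len(negatives)}"
            )
        thresholds[s.sample_id] = background_threshold(negatives)
    thresholds = pd.Series(thresholds, name="background_threshold")

    corrected = apply_background(flat, thresholds)
    hk = corrected.of_class("Housekeeping")
    if hk.shape[0] < max(n_keep, 3):
        raise ValidationError(
            f"cartridge has {hk.shape[0]} housekeeping probes; need >= {max(n_keep, 3)}"
        )
    if hk.shape[1] < 2:
        # one lane: pairwise stability across samples is undefined, and the
        # single geomean equals its own mean, so every candidate is kept and
        # the scaling factor is exactly 1
        selected = list(hk.values.index)
        m_map = {g: float("nan") for g in selected}
    else:
        selected, m_map = select_housekeepers(hk.values, n_keep=n_keep)
    g, sf = scaling_factors(hk.values.loc[selected])

    scaled = corrected.values.mul(sf[corrected.sample_ids], axis=1)
    full = ExpressionMatrix(
        values=scaled, code_class=corrected.code_class, stage="normalized"
    )
    return NormalizationResult(
        background_thresholds=thresholds,
        selected_housekeepers=tuple(selected),
        stability_m={gname: float(m_map[gname]) for gname in selected},
        lane_geomeans=g,
        scaling_factors=sf,
        matrix=full.of_class(*GENE_CLASSES),
        control_matrix=full.of_class("Positive", "Negative"),
    )
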