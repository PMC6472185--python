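"""Variability-based gene filtering.

The same stability statistic used for housekeeper selection ranks genes in
the opposite direction here: the *k* genes with the highest geNorm M —
those whose expression ratios against the rest of the panel vary most
across samples — are kept for visualization.  Unlike housekeeper
selection, the ranking is a single pass (no iterative removal): the filter
is a selection of the most variable genes, not an elimination tournament.

The filter is parameterized either as an absolute gene count ``k`` or as a
percentage of the panel, which resolves to ``ceil(p% × genes)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError
from .matrix import ExpressionMatrix
from .normalize import genorm_stability


@dataclass(frozen=True)
class FilterSpec:
    """``count`` mode keeps exactly k genes; ``percentage`` keeps ceil(k% of panel)."""

    mode: str  # "count" | "percentage"
    k: float

    def __post_init__(self):
        if self.mode not in ("count", "percentage"):
            raise ValidationError(f"unknown filter mode {self.mode!r}")
        if self.mode == "count" and (self.k < 1 or self.k != int(self.k)):
            raise ValidationError(f"count-mode k must be a positive integer, got {self.k}")
        if self.mode == "percentage" and not (0 < self.k <= 100):
            raise ValidationError(f"percentage must be in (0, 100], got {self.k}")

    def resolve(self, n_genes: int) -> int:
        if self.mode == "count":
            k = int(self.k)
            if k > n_genes:
                raise ValidationError(
                    f"k={k} exceeds the {n_genes} genes available (maximum k is {n_genes})"
                )
            return k
        return max(1, math.ceil(self.k / 100.0 * n_genes))


def instability_ranking(
    matrix: ExpressionMatrix,
) -> tuple[list[str], dict[str, float]]:
    """Genes sorted by M descending (most variable first), plus the M map.

    Ties are broken lexicographically ascending so the ranking is
    deterministic.  Requires strictly positive values, i.e. a
    background-corrected or normalized matrix.
    """
    m_map = genorm_stability(matrix.values)
    ranked = sorted(m_map, key=lambda g: (-m_map[g], g))
    return ranked, m_map


def apply_filter(matrix: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Keep the top-k most variable genes; sample axis untouched.

    The k-gene selection is always a prefix of the (k+1)-gene selection
    because the ranking is computed once for the whole matrix.
    """
    k = spec.resolve(matrix.shape[0])
    ranked, _ = instability_ranking(matrix)
    keep = set(ranked[:k])
    genes = [g for g in matrix.gene_ids if g in keep]  # preserve input order
    return matrix.subset_genes(genes)
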