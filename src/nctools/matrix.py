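"""The genes × samples expression matrix container used by every stage."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rcc import Cartridge

STAGES = ("flat", "background_corrected", "normalized", "zscored")

#: code classes that make it into analysis matrices (controls are kept in
#: the normalization record instead)
GENE_CLASSES = ("Endogenous", "Housekeeping")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples table with per-gene code-class annotation.

    ``values`` is indexed by gene name with one column per sample;
    ``code_class`` is aligned to the gene index.  ``stage`` records how far
    through the pipeline the values are: raw instrument counts (``flat``),
    background-floored (``background_corrected``), lane-scaled
    (``normalized``) or per-gene standardized (``zscored``).
    """

    values: pd.DataFrame
    code_class: pd.Series
    stage: str = "flat"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not self.values.index.equals(self.code_class.index):
            raise ValidationError("code_class index must match gene index")
        if self.stage != "zscored" and (self.values.to_numpy() < 0).any():
            raise ValidationError(f"stage {self.stage!r} must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return replace(
            self, values=self.values.loc[list(genes)], code_class=self.code_class.loc[list(genes)]
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(samples)])

    def of_class(self, *classes: str) -> "ExpressionMatrix":
        mask = self.code_class.isin(classes)
        return replace(self, values=self.values.loc[mask], code_class=self.code_class.loc[mask])

    def with_stage(self, stage: str) -> "ExpressionMatrix":
        return replace(self, stage=stage)

    def to_tsv(self, path: str | Path) -> None:
        """Write genes as rows: gene, code_class, then one column per sample."""
        out = self.values.copy()
        out.insert(0, "code_class", self.code_class)
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, stage: str = "normalized") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        code_class = df.pop("code_class")
        return cls(values=df.astype(float), code_class=code_class, stage=stage)

    @classmethod
    def from_cartridge(
        cls, cartridge: Cartridge, classes: Sequence[str] | None = None
    ) -> "ExpressionMatrix":
        """Flat-count matrix from a cartridge; probes in first-lane order."""
        first = cartridge.samples[0]
        keep = set(classes) if classes is not None else None
        order = [
            (c.code_class, c.gene_name)
            for c in first.codes
            if keep is None or c.code_class in keep
        ]
        data = {}
        for s in cartridge.samples:
            counts = {(c.code_class, c.gene_name): c.count for c in s.codes}
            data[s.sample_id] = [counts[key] for key in order]
        values = pd.DataFrame(
            data, index=pd.Index([g for _, g in order], name="gene"), dtype=float
        )
        code_class = pd.Series([cc for cc, _ in order], index=values.index, name="code_class")
        return cls(values=values, code_class=code_class, stage="flat")


def geometric_mean(x: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Geometric mean of positive values (no zero handling — caller's job)."""
    return np.exp(np.mean(np.log(np.asarray(x, dtype=float)), axis=axis))
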