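"""Synthetic nCounter cartridges with known ground truth.

The generator emulates a 770-probe immune-profiling-style panel run on a
12-lane cartridge.  Counts follow a multiplicative log-normal model,

    count[g, l] = round(base_g * e_l * 2**eps),   eps ~ Normal(0, sd_class),

with a per-lane effect ``e_l`` (the technical artifact that lane scaling
is supposed to remove), per-class log2 noise (housekeepers tight,
endogenous genes loose), positive controls proportional to their ladder
concentration times the lane effect (so linearity r² ≈ 1 by
construction), and negative controls drawn from a truncated normal
background.  Rounding is round-half-to-even throughout so cartridges are
bit-reproducible across platforms.

Ground truth (lane effects, the designated stable housekeepers, planted
cluster/regulator structure) is returned alongside the cartridge so tests
can check recovery, not just execution.

This generator does not attempt real panel gene names or real biological
covariance; see the methods note for what that implies for the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rcc import Cartridge, CodeCount, RCCSample, write_rcc

#: standard six-point positive ladder, fM
POSITIVE_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


@dataclass(frozen=True)
class PlantedClusters:
    """Two anti-correlated gene blocks for dendrogram-recovery tests.

    Block 1 is shifted up by ``amplitude`` (log2) in the first half of the
    lanes and down in the second half; block 2 the opposite.
    """

    block_size: int = 10
    amplitude: float = 2.0


@dataclass(frozen=True)
class PlantedRegulators:
    """Regulator → targets map; each target tracks its regulator's log2
    profile plus Normal(0, noise_sd) noise."""

    links: dict[str, tuple[str, ...]]
    noise_sd: float = 0.1


@dataclass(frozen=True)
class SimulationSpec:
    n_lanes: int = 12
    n_endogenous: int = 730
    n_housekeeping: int = 40
    n_pos: int = 6
    n_neg: int = 8
    lane_effects: tuple[float, ...] | None = None  # None -> drawn 2**N(0, 0.25)
    hk_noise_sd: float | tuple[float, ...] = 0.1  # log2 SD, scalar or per gene
    endo_noise_sd: float = 0.5  # log2 SD
    background_mean: float = 10.0
    background_sd: float = 3.0
    pos_counts_per_fm: float = 200.0
    binding_density_range: tuple[float, float] = (0.3, 1.5)
    planted_clusters: PlantedClusters | None = None
    planted_regulators: PlantedRegulators | None = None
    patients: tuple[tuple[str | None, int | None], ...] | None = None  # per lane
    cartridge_id: str = "SIMCART"
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_lanes <= 12):
            raise ValidationError(f"n_lanes must be in [1, 12], got {self.n_lanes}")
        if self.n_pos < 3 or self.n_pos > len(POSITIVE_LADDER):
            raise ValidationError(f"n_pos must be in [3, {len(POSITIVE_LADDER)}]")
        if self.n_neg < 2:
            raise ValidationError("need >= 2 negative controls")
        if self.n_housekeeping < 3:
            raise ValidationError("need >= 3 housekeeping probes")
        if self.lane_effects is not None:
            if len(self.lane_effects) != self.n_lanes:
                raise ValidationError("lane_effects length must equal n_lanes")
            if any(e <= 0 for e in self.lane_effects):
                raise ValidationError("lane effects must be positive")
        if not np.isscalar(self.hk_noise_sd) and len(self.hk_noise_sd) != self.n_housekeeping:
            raise ValidationError("per-gene hk_noise_sd length must equal n_housekeeping")
        if self.patients is not None and len(self.patients) != self.n_lanes:
            raise ValidationError("patients length must equal n_lanes")


@dataclass(frozen=True)
class GroundTruth:
    lane_effects: tuple[float, ...]
    stable_housekeepers: tuple[str, ...]  # lowest-noise housekeepers
    hk_noise_sd: tuple[float, ...]
    base_expression: pd.Series  # per gene
    cluster_blocks: tuple[tuple[str, ...], tuple[str, ...]] | None
    regulator_links: dict[str, tuple[str, ...]] | None


def _gene_names(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    endo = [f"GENE{i + 1:04d}" for i in range(spec.n_endogenous)]
    hk = [f"HK{i + 1:03d}" for i in range(spec.n_housekeeping)]
    return endo, hk


def _control_names(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    letters = "ABCDEFGH"
    pos = [
        f"POS_{letters[i]}({POSITIVE_LADDER[i]:g})" for i in range(spec.n_pos)
    ]
    neg = [f"NEG_{letters[i]}(0)" for i in range(spec.n_neg)]
    return pos, neg


def simulate_cartridge(spec: SimulationSpec) -> tuple[Cartridge, GroundTruth]:
    """Draw one cartridge and its ground-truth record; seed-deterministic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    endo_names, hk_names = _gene_names(spec)
    pos_names, neg_names = _control_names(spec)

    lane_effects = (
        np.asarray(spec.lane_effects, dtype=float)
        if spec.lane_effects is not None
        else 2.0 ** rng.normal(0.0, 0.25, spec.n_lanes)
    )
    base_endo = 2.0 ** rng.uniform(4.0, 11.0, spec.n_endogenous)
    base_hk = 2.0 ** rng.uniform(6.0, 10.0, spec.n_housekeeping)
    hk_sd = (
        np.full(spec.n_housekeeping, float(spec.hk_noise_sd))
        if np.isscalar(spec.hk_noise_sd)
        else np.asarray(spec.hk_noise_sd, dtype=float)
    )

    # log2 expression per gene x lane, before lane effects
    log_endo = np.log2(base_endo)[:, None] + rng.normal(
        0.0, spec.endo_noise_sd, (spec.n_endogenous, spec.n_lanes)
    )
    log_hk = np.log2(base_hk)[:, None] + rng.normal(
        0.0, 1.0, (spec.n_housekeeping, spec.n_lanes)
    ) * hk_sd[:, None]

    blocks = None
    if spec.planted_clusters is not None:
        pc = spec.planted_clusters
        if 2 * pc.block_size > spec.n_endogenous:
            raise ValidationError("planted cluster blocks exceed endogenous panel")
        half = spec.n_lanes // 2
        pattern = np.where(np.arange(spec.n_lanes) < half, pc.amplitude, -pc.amplitude)
        log_endo[: pc.block_size] += pattern
        log_endo[pc.block_size : 2 * pc.block_size] -= pattern
        blocks = (
            tuple(endo_names[: pc.block_size]),
            tuple(endo_names[pc.block_size : 2 * pc.block_size]),
        )

    links = None
    if spec.planted_regulators is not None:
        pr = spec.planted_regulators
        index = {g: i for i, g in enumerate(endo_names)}
        for reg, targets in pr.links.items():
            for tgt in targets:
                if reg not in index or tgt not in index:
                    raise ValidationError(f"planted link {reg}->{tgt} outside endogenous panel")
                reg_profile = log_endo[index[reg]]
                log_endo[index[tgt]] = (
                    np.log2(base_endo[index[tgt]])
                    + (reg_profile - reg_profile.mean())
                    + rng.normal(0.0, pr.noise_sd, spec.n_lanes)
                )
        links = {r: tuple(t) for r, t in pr.links.items()}

    endo_counts = np.round(2.0 ** log_endo * lane_effects[None, :]).astype(int)
    hk_counts = np.round(2.0 ** log_hk * lane_effects[None, :]).astype(int)
    pos_counts = np.round(
        np.asarray(POSITIVE_LADDER[: spec.n_pos])[:, None]
        * spec.pos_counts_per_fm
        * lane_effects[None, :]
    ).astype(int)
    neg_counts = np.round(
        np.clip(
            rng.normal(spec.background_mean, spec.background_sd, (spec.n_neg, spec.n_lanes)),
            0.0,
            None,
        )
    ).astype(int)
    densities = rng.uniform(*spec.binding_density_range, spec.n_lanes)

    samples = []
    for lane in range(spec.n_lanes):
        codes = (
            [CodeCount("Positive", pos_names[i], "SYN_POS", int(pos_counts[i, lane]))
             for i in range(spec.n_pos)]
            + [CodeCount("Negative", neg_names[i], "SYN_NEG", int(neg_counts[i, lane]))
               for i in range(spec.n_neg)]
            + [CodeCount("Housekeeping", hk_names[i], f"SYN_HK{i + 1:03d}",
                         int(hk_counts[i, lane])) for i in range(spec.n_housekeeping)]
            + [CodeCount("Endogenous", endo_names[i], f"SYN_{i + 1:04d}",
                         int(endo_counts[i, lane])) for i in range(spec.n_endogenous)]
        )
        patient_id, order = (
            spec.patients[lane] if spec.patients is not None else (None, None)
        )
        samples.append(
            RCCSample.create(
                sample_id=f"{spec.cartridge_id}_L{lane + 1:02d}",
                lane_id=lane + 1,
                codes=codes,
                binding_density=round(float(densities[lane]), 4),
                patient_id=patient_id,
                sample_order=order,
                cartridge_id=spec.cartridge_id,
            )
        )

    min_sd = hk_sd.min()
    truth = GroundTruth(
        lane_effects=tuple(float(e) for e in lane_effects),
        stable_housekeepers=tuple(
            hk_names[i] for i in range(spec.n_housekeeping) if hk_sd[i] <= min_sd + 1e-12
        ),
        hk_noise_sd=tuple(float(s) for s in hk_sd),
        base_expression=pd.Series(
            np.concatenate([base_endo, base_hk]), index=endo_names + hk_names
        ),
        cluster_blocks=blocks,
        regulator_links=links,
    )
    return Cartridge(samples=tuple(samples), cartridge_id=spec.cartridge_id), truth


def simulate_regulatory_matrix(
    n_genes: int = 20,
    n_samples: int = 30,
    n_links: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Expression matrix with planted regulator → target pairs.

    The first ``2 * n_links`` genes form disjoint (regulator, target)
    pairs: the target equals the regulator plus Normal(0, noise_sd) noise
    (noise_sd = 0.1 is 10% of the unit-variance signal).  All remaining
    genes are independent standard normals.  Values are shifted to be
    positive so the matrix is usable wherever log-ratios are taken.
    """
    if 2 * n_links > n_genes:
        raise ValidationError("need at least 2 genes per planted link")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    x = rng.normal(0.0, 1.0, (n_genes, n_samples))
    links = []
    for i in range(n_links):
        reg, tgt = 2 * i, 2 * i + 1
        x[tgt] = x[reg] + rng.normal(0.0, noise_sd, n_samples)
        links.append((genes[reg], genes[tgt]))
    values = pd.DataFrame(x + 8.0, index=pd.Index(genes, name="gene"), columns=[
        f"S{j + 1:02d}" for j in range(n_samples)
    ])
    return values, links


def write_fixture_set(spec: SimulationSpec, directory: str | Path) -> list[Path]:
    """One RCC file per lane plus a ground_truth.tsv sidecar."""
    cartridge, truth = simulate_cartridge(spec)
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample in cartridge.samples:
        path = out / f"{sample.sample_id}.RCC"
        write_rcc(sample, path)
        paths.append(path)
    pd.DataFrame(
        {
            "sample_id": cartridge.sample_ids,
            "lane_effect": truth.lane_effects,
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "housekeeper": [f"HK{i + 1:03d}" for i in range(len(truth.hk_noise_sd))],
            "log2_noise_sd": truth.hk_noise_sd,
        }
    ).to_csv(out / "ground_truth_housekeepers.tsv", sep="\t", index=False)
    return paths
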