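"""Per-lane quality-control flags: binding density, linearity, limit of detection.

Three flags are computed per lane:

* **Binding density** — the imaged spot density (spots/µm²) reported by the
  instrument; lanes outside the configured interval (default the vendor's
  published [0.1, 2.25] operating range, closed at both ends) are flagged
  as over- or under-loaded.
* **Positive-control linearity** — the squared Pearson correlation (r²)
  between ``log2(count + 1)`` and ``log2(concentration)`` over the
  synthetic positive-control ladder (standard six-point set
  POS_A..POS_F = 128, 32, 8, 2, 0.5, 0.125 fM).
* **Limit of detection** — the low-concentration positive control
  (default POS_E, 0.5 fM) must rise above the lane's negative-control
  background threshold (``geomean + 2·SD``; see :mod:`nctools.normalize`).

QC is advisory: a failed flag produces messages, never an exception, and
never alters counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InsufficientControlsError, ValidationError
from .normalize import background_threshold
from .rcc import RCCSample, parse_control_concentration

#: Standard positive-control spike-in ladder (fM).
DEFAULT_POSITIVE_LADDER = {
    "POS_A": 128.0,
    "POS_B": 32.0,
    "POS_C": 8.0,
    "POS_D": 2.0,
    "POS_E": 0.5,
    "POS_F": 0.125,
}

DEFAULT_LOD_PROBE = "POS_E"


@dataclass(frozen=True)
class QCConfig:
    binding_density_low: float = 0.1
    binding_density_high: float = 2.25
    linearity_min_r2: float = 0.95
    lod_probe: str = DEFAULT_LOD_PROBE
    positive_ladder: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITIVE_LADDER)
    )


@dataclass(frozen=True)
class Flag:
    passed: bool
    value: float | None = None
    message: str | None = None


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    binding_density: Flag
    linearity: Flag  # value holds r²
    lod: Flag  # value holds the probe count; threshold in extras
    lod_threshold: float | None
    messages: tuple[str, ...]


def _positive_control_counts(sample: RCCSample) -> dict[str, int]:
    """Counts of positive-control probes keyed by their base name (POS_A...)."""
    out: dict[str, int] = {}
    for c in sample.codes_of_class("Positive"):
        base = c.gene_name.split("(")[0]
        out[base] = c.count
    return out


def binding_density_flag(
    sample: RCCSample, low: float = 0.1, high: float = 2.25
) -> Flag:
    """Pass iff ``low <= binding_density <= high`` (closed interval)."""
    bd = sample.binding_density
    if bd is None:
        return Flag(False, None, f"{sample.sample_id}: binding density missing from lane attributes")
    if low <= bd <= high:
        return Flag(True, bd)
    return Flag(
        False, bd,
        f"{sample.sample_id}: binding density {bd:g} outside [{low:g}, {high:g}]",
    )


def positive_control_linearity(
    sample: RCCSample, known_concentrations: dict[str, float] | None = None
) -> float:
    """r² between log2(count + 1) and log2(concentration) over the ladder.

    Concentrations parsed from the probe names (``POS_A(128)``) take
    precedence; otherwise the supplied / default ladder is used.  Requires
    at least three usable positive controls.  Zero variance in the counts
    makes the correlation undefined; that degenerate case returns 0.0 with
    a warning.
    """
    ladder = known_concentrations if known_concentrations is not None else DEFAULT_POSITIVE_LADDER
    counts, concs = [], []
    for c in sample.codes_of_class("Positive"):
        base = c.gene_name.split("(")[0]
        conc = parse_control_concentration(c.gene_name)
        if conc is None:
            conc = ladder.get(base)
        if conc is None or conc <= 0:
            continue
        counts.append(c.count)
        concs.append(conc)
    if len(counts) < 3:
        raise InsufficientControlsError(
            f"{sample.sample_id}: need >= 3 positive controls with known "
            f"concentrations, got {len(counts)}"
        )
    x = np.log2(np.asarray(concs, dtype=float))
    y = np.log2(np.asarray(counts, dtype=float) + 1.0)
    if np.allclose(y.std(), 0.0) or np.allclose(x.std(), 0.0):
        warnings.warn(
            f"{sample.sample_id}: zero variance in positive-control counts; r² set to 0",
            stacklevel=2,
        )
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def limit_of_detection_flag(
    sample: RCCSample, probe_name: str = DEFAULT_LOD_PROBE
) -> tuple[Flag, float]:
    """Pass iff the named positive control exceeds the lane's background.

    Returns the flag plus the background threshold it was compared against.
    """
    counts = _positive_control_counts(sample)
    if probe_name not in counts:
        raise ValidationError(
            f"{sample.sample_id}: positive control '{probe_name}' not present"
        )
    negatives = [c.count for c in sample.codes_of_class("Negative")]
    threshold = background_threshold(negatives)
    observed = counts[probe_name]
    if observed >= threshold:
        return Flag(True, float(observed)), threshold
    return (
        Flag(
            False,
            float(observed),
            f"{sample.sample_id}: {probe_name} count {observed} below "
            f"background threshold {threshold:.3f}",
        ),
        threshold,
    )


def qc_report(sample: RCCSample, config: QCConfig | None = None) -> QCReport:
    """All three flags for one lane.  Failures warn; they never raise."""
    cfg = config or QCConfig()
    bd = binding_density_flag(sample, cfg.binding_density_low, cfg.binding_density_high)
    r2 = positive_control_linearity(sample, cfg.positive_ladder)
    lin_ok = r2 >= cfg.linearity_min_r2
    lin = Flag(
        lin_ok, r2,
        None if lin_ok else
        f"{sample.sample_id}: positive-control linearity r²={r2:.4f} "
        f"below {cfg.linearity_min_r2:g}",
    )
    lod, threshold = limit_of_detection_flag(sample, cfg.lod_probe)
    messages = tuple(f.message for f in (bd, lin, lod) if f.message)
    return QCReport(
        sample_id=sample.sample_id,
        binding_density=bd,
        linearity=lin,
        lod=lod,
        lod_threshold=threshold,
        messages=messages,
    )


def qc_table(reports: Iterable[QCReport]):
    """QC reports as a flat table, one row per sample (for TSV export)."""
    import pandas as pd

    rows = [
        {
            "sample_id": r.sample_id,
            "binding_density": r.binding_density.value,
            "bd_flag": "PASS" if r.binding_density.passed else "FAIL",
            "linearity_r2": r.linearity.value,
            "lin_flag": "PASS" if r.linearity.passed else "FAIL",
            "lod_flag": "PASS" if r.lod.passed else "FAIL",
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def write_qc_table(reports: Sequence[QCReport], path: str | Path) -> None:
    qc_table(reports).to_csv(path, sep="\t", index=False)
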