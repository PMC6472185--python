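"""Reading, writing and assembling NanoString nCounter RCC files.

An RCC file is the per-lane text export of an nCounter run.  It is a
sectioned CSV: each section is delimited by ``<Name>`` / ``</Name>`` tag
lines.  Attribute sections (``Header``, ``Sample_Attributes``,
``Lane_Attributes``) contain ``key,value`` rows; ``Code_Summary`` is a
four-column CSV (``CodeClass,Name,Accession,Count``) with one row per
probe.  Unknown sections are preserved verbatim so that a parse/write
cycle is lossless.

Sample chronology (the position of a sample in a patient's time series)
is not part of the instrument format; it is carried in the
``Sample_Attributes`` section under the ``PatientID`` / ``SampleOrder``
keys when this package writes a file, and can otherwise be attached from
an external metadata table (:func:`read_metadata` / :func:`apply_metadata`).
When no explicit order is available, ``collection_date`` (the ``Date``
attribute) and finally file order are used as fallbacks.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .exceptions import (
    DuplicateCodeError,
    PanelMismatchError,
    RCCFormatError,
    RCCParseError,
    ValidationError,
)

MANDATORY_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")
CODE_SUMMARY_HEADER = "CodeClass,Name,Accession,Count"

#: Probe names like POS_A(128) / NEG_B(0); the parenthesised number is the
#: spiked-in concentration in fM.
CONTROL_NAME_RE = re.compile(r"^(POS|NEG)_([A-H])\((\d*\.?\d+)\)$")


class CodeCount(NamedTuple):
    """One probe's count in one lane."""

    code_class: str
    gene_name: str
    accession: str
    count: int


@dataclass(frozen=True)
class RCCSample:
    """One lane's parsed RCC content.

    The attribute dictionaries hold the file's key/value rows verbatim,
    which makes ``parse_rcc(write_rcc(x)) == x`` hold field for field.
    Convenience accessors (``sample_id``, ``lane_id``, ``binding_density``,
    ``patient_id``, ``sample_order``, ``collection_date``) read from them.
    """

    header: dict[str, str] = field(default_factory=dict)
    sample_attributes: dict[str, str] = field(default_factory=dict)
    lane_attributes: dict[str, str] = field(default_factory=dict)
    codes: tuple[CodeCount, ...] = ()
    extra_sections: dict[str, str] = field(default_factory=dict)

    # -- derived accessors -------------------------------------------------
    @property
    def sample_id(self) -> str:
        return self.sample_attributes.get("ID", "")

    @property
    def lane_id(self) -> int | None:
        raw = self.lane_attributes.get("ID")
        return int(raw) if raw not in (None, "") else None

    @property
    def binding_density(self) -> float | None:
        raw = self.lane_attributes.get("BindingDensity")
        return float(raw) if raw not in (None, "") else None

    @property
    def patient_id(self) -> str | None:
        return self.sample_attributes.get("PatientID") or None

    @property
    def sample_order(self) -> int | None:
        raw = self.sample_attributes.get("SampleOrder")
        return int(raw) if raw not in (None, "") else None

    @property
    def collection_date(self) -> _dt.date | None:
        raw = self.sample_attributes.get("Date")
        if not raw:
            return None
        for fmt in ("%Y%m%d", "%Y-%m-%d"):
            try:
                return _dt.datetime.strptime(raw, fmt).date()
            except ValueError:
                continue
        return None

    # -- construction ------------------------------------------------------
    @classmethod
    def create(
        cls,
        sample_id: str,
        lane_id: int,
        codes: Iterable[CodeCount],
        binding_density: float | None = None,
        patient_id: str | None = None,
        sample_order: int | None = None,
        collection_date: _dt.date | str | None = None,
        cartridge_id: str = "",
    ) -> "RCCSample":
        """Build a sample from plain values, filling canonical attribute keys."""
        sample_attrs = {"ID": sample_id, "Owner": "", "Comments": ""}
        if collection_date is not None:
            if isinstance(collection_date, str):
                collection_date = _dt.date.fromisoformat(collection_date)
            sample_attrs["Date"] = collection_date.strftime("%Y%m%d")
        if patient_id is not None:
            sample_attrs["PatientID"] = patient_id
        if sample_order is not None:
            sample_attrs["SampleOrder"] = str(sample_order)
        lane_attrs = {"ID": str(lane_id)}
        if binding_density is not None:
            lane_attrs["BindingDensity"] = repr(float(binding_density))
        if cartridge_id:
            lane_attrs["CartridgeID"] = cartridge_id
        return cls(
            header={"FileVersion": "3.0", "SoftwareVersion": "nctools"},
            sample_attributes=sample_attrs,
            lane_attributes=lane_attrs,
            codes=tuple(codes),
        )

    def with_metadata(
        self,
        patient_id: str | None = None,
        sample_order: int | None = None,
        collection_date: _dt.date | str | None = None,
    ) -> "RCCSample":
        """Return a copy with patient/chronology metadata attached."""
        attrs = dict(self.sample_attributes)
        if patient_id is not None:
            attrs["PatientID"] = patient_id
        if sample_order is not None:
            attrs["SampleOrder"] = str(int(sample_order))
        if collection_date is not None:
            if isinstance(collection_date, str):
                collection_date = _dt.date.fromisoformat(collection_date)
            attrs["Date"] = collection_date.strftime("%Y%m%d")
        return replace(self, sample_attributes=attrs)

    # -- probe views -------------------------------------------------------
    def codes_of_class(self, code_class: str) -> list[CodeCount]:
        return [c for c in self.codes if c.code_class == code_class]

    def panel_key(self) -> frozenset[tuple[str, str]]:
        return frozenset((c.code_class, c.gene_name) for c in self.codes)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on invariant violations."""
        lane = self.lane_id
        if lane is None or not (1 <= lane <= 12):
            raise ValidationError(f"lane_id must be in [1, 12], got {lane!r}")
        seen: set[tuple[str, str]] = set()
        for c in self.codes:
            if not c.gene_name:
                raise ValidationError("empty gene name in code summary")
            if c.count < 0:
                raise ValidationError(f"negative count for {c.gene_name}")
            key = (c.code_class, c.gene_name)
            if key in seen:
                raise ValidationError(f"duplicate probe {key} in sample {self.sample_id}")
            seen.add(key)


@dataclass(frozen=True)
class Cartridge:
    """Up to 12 lanes sharing one probe panel."""

    samples: tuple[RCCSample, ...]
    cartridge_id: str = ""

    def __post_init__(self):
        if not self.samples:
            raise ValidationError("a cartridge needs at least one sample")
        if len(self.samples) > 12:
            raise ValidationError("a cartridge holds at most 12 samples")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_meta(self) -> pd.DataFrame:
        """Per-sample metadata table (sample_id, patient_id, sample_order, ...)."""
        rows = [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "sample_order": s.sample_order,
                "collection_date": s.collection_date,
                "lane_id": s.lane_id,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)


def parse_control_concentration(name: str) -> float | None:
    """Concentration in fM parsed from a control probe name, or None."""
    m = CONTROL_NAME_RE.match(name)
    return float(m.group(3)) if m else None


# ---------------------------------------------------------------------------
# parsing


def _split_sections(text: str) -> tuple[dict[str, tuple[list[str], int]], list[str]]:
    """Map section name -> (body lines, first body line number); keep order."""
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")
    sections: dict[str, tuple[list[str], int]] = {}
    order: list[str] = []
    current: str | None = None
    body: list[str] = []
    start = 0
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        m_open = re.match(r"^<([A-Za-z0-9_]+)>$", stripped)
        m_close = re.match(r"^</([A-Za-z0-9_]+)>$", stripped)
        if m_open and current is None:
            current = m_open.group(1)
            body = []
            start = i + 1
        elif m_close and current == m_close.group(1):
            sections[current] = (body, start)
            order.append(current)
            current = None
        elif current is not None:
            body.append(line)
    if current is not None:
        raise RCCFormatError(f"section '{current}' is not closed")
    return sections, order


def _parse_attr_block(body: list[str]) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for line in body:
        if not line.strip():
            continue
        key, _, value = line.partition(",")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_rcc(source: str | Path) -> RCCSample:
    """Parse one RCC file (path or its text content) into an :class:`RCCSample`.

    Raises :class:`RCCFormatError` for a missing section,
    :class:`RCCParseError` (with line number) for a malformed count row, and
    :class:`DuplicateCodeError` for a repeated (code_class, gene_name) pair.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and source.endswith((".RCC", ".rcc")):
        text = Path(source).read_text()
    else:
        text = source

    sections, order = _split_sections(text)
    for name in MANDATORY_SECTIONS:
        if name not in sections:
            raise RCCFormatError(f"missing mandatory section '{name}'")

    header = _parse_attr_block(sections["Header"][0])
    sample_attrs = _parse_attr_block(sections["Sample_Attributes"][0])
    lane_attrs = _parse_attr_block(sections["Lane_Attributes"][0])

    body, start = sections["Code_Summary"]
    codes: list[CodeCount] = []
    seen: set[tuple[str, str]] = set()
    for offset, line in enumerate(body):
        lineno = start + offset
        stripped = line.strip()
        if not stripped:
            continue
        if stripped == CODE_SUMMARY_HEADER:
            continue
        parts = stripped.split(",")
        if len(parts) != 4:
            raise RCCParseError(
                f"expected 4 comma-separated fields, got {len(parts)}", lineno
            )
        code_class, name, accession, raw_count = (p.strip() for p in parts)
        try:
            count = int(raw_count)
        except ValueError:
            raise RCCParseError(f"non-integer count {raw_count!r}", lineno) from None
        if count < 0:
            raise RCCParseError(f"negative count {count}", lineno)
        key = (code_class, name)
        if key in seen:
            raise DuplicateCodeError(f"duplicate probe {key}")
        seen.add(key)
        codes.append(CodeCount(code_class, name, accession, count))

    extra = {
        name: "\n".join(sections[name][0])
        for name in order
        if name not in MANDATORY_SECTIONS
    }
    return RCCSample(
        header=header,
        sample_attributes=sample_attrs,
        lane_attributes=lane_attrs,
        codes=tuple(codes),
        extra_sections=extra,
    )


# ---------------------------------------------------------------------------
# writing


def _write_attr_block(name: str, attrs: dict[str, str]) -> list[str]:
    lines = [f"<{name}>"]
    lines += [f"{k},{v}" for k, v in attrs.items()]
    lines.append(f"</{name}>")
    return lines


def write_rcc(sample: RCCSample, path: str | Path | None = None) -> str:
    """Serialize a sample to RCC text (and optionally write it to *path*)."""
    sample.validate()
    lines: list[str] = []
    lines += _write_attr_block("Header", sample.header)
    lines += _write_attr_block("Sample_Attributes", sample.sample_attributes)
    lines += _write_attr_block("Lane_Attributes", sample.lane_attributes)
    lines.append("<Code_Summary>")
    lines.append(CODE_SUMMARY_HEADER)
    for c in sample.codes:
        lines.append(f"{c.code_class},{c.gene_name},{c.accession},{c.count}")
    lines.append("</Code_Summary>")
    for name, body in sample.extra_sections.items():
        lines.append(f"<{name}>")
        if body:
            lines.append(body)
        lines.append(f"</{name}>")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# experiment assembly


def assemble_experiment(
    samples: Sequence[RCCSample], cartridge_id: str = ""
) -> Cartridge:
    """Combine per-lane samples into a :class:`Cartridge`.

    Verifies that every sample carries the identical probe panel; samples are
    ordered by (patient_id, sample_order) when all samples carry both, else
    input order is preserved.
    """
    if not samples:
        raise ValidationError("cannot assemble an experiment from zero samples")
    reference = samples[0].panel_key()
    for s in samples[1:]:
        if s.panel_key() != reference:
            diff = reference.symmetric_difference(s.panel_key())
            names = sorted({g for _, g in diff})
            raise PanelMismatchError(
                f"probe panel mismatch between '{samples[0].sample_id}' and "
                f"'{s.sample_id}': {', '.join(names)}",
                difference=diff,
            )
    ordered = list(samples)
    if all(s.patient_id is not None and s.sample_order is not None for s in samples):
        ordered.sort(key=lambda s: (s.patient_id, s.sample_order))
    if not cartridge_id:
        ids = {s.lane_attributes.get("CartridgeID", "") for s in samples}
        cartridge_id = ids.pop() if len(ids) == 1 else ""
    return Cartridge(samples=tuple(ordered), cartridge_id=cartridge_id)


# ---------------------------------------------------------------------------
# external metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read an experiment metadata TSV.

    Expected columns: ``sample_file`` (or ``sample_id``), and any of
    ``patient_id``, ``sample_order``, ``collection_date``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_file" not in df.columns and "sample_id" not in df.columns:
        raise ValidationError("metadata table needs a sample_file or sample_id column")
    return df


def apply_metadata(
    samples: Sequence[RCCSample],
    metadata: pd.DataFrame,
    file_names: Sequence[str] | None = None,
) -> list[RCCSample]:
    """Attach patient/chronology metadata from a table to parsed samples.

    Matching is by ``sample_file`` (when *file_names* is given) or by
    ``sample_id``.
    """
    key_col = "sample_file" if "sample_file" in metadata.columns else "sample_id"
    lookup = metadata.set_index(key_col)
    out: list[RCCSample] = []
    for i, s in enumerate(samples):
        key = file_names[i] if file_names is not None and key_col == "sample_file" else s.sample_id
        if key in lookup.index:
            row = lookup.loc[key]
            s = s.with_metadata(
                patient_id=row.get("patient_id"),
                sample_order=int(row["sample_order"]) if pd.notna(row.get("sample_order")) else None,
                collection_date=row.get("collection_date") if pd.notna(row.get("collection_date")) else None,
            )
        out.append(s)
    return out
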