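"""NanoString RCC lane-file I/O and count-matrix assembly.

The nCounter Digital Analyzer writes one plain-text RCC file per lane, a
sectioned format (``<Header>``, ``<Sample_Attributes>``, ``<Lane_Attributes>``,
``<Code_Summary>``) whose ``Code_Summary`` body is CSV with columns
``CodeClass,Name,Accession,Count``.  This module parses and emits that
dialect, assembles per-lane counts into a probes x samples matrix, and reads
the sample-annotation table carrying subtype and clinical covariates.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

#: standard nCounter positive-control concentration ladder (fM)
POSITIVE_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

SUBTYPES = ("URB", "DRB", "control")
N_STAGES = ("N0", "N1", "N2")
C_STAGES = ("C0", "C1", "C2")

ANNOTATION_COLUMNS = [
    "sample_id", "subtype", "sex", "laterality",
    "age_months", "n_stage", "c_stage", "rb1_germline",
]


class RCCParseError(ValueError):
    """Raised when an RCC file violates the dialect."""


class ValidationError(ValueError):
    """Raised for inconsistent in-memory objects or annotation rows."""


@dataclass(frozen=True)
class Probe:
    code_class: str
    name: str
    accession: str = ""
    expected_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValidationError(f"unknown code class {self.code_class!r}")
        if (self.expected_concentration is not None) != (self.code_class == "Positive"):
            raise ValidationError(
                f"probe {self.name!r}: expected_concentration present iff Positive"
            )


@dataclass
class CodeSet:
    probes: list[Probe]
    panel_name: str = "panel"

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate probe names in codeset: {dupes}")

    @property
    def probe_names(self) -> list[str]:
        return [p.name for p in self.probes]

    def names_of_class(self, code_class: str) -> list[str]:
        return [p.name for p in self.probes if p.code_class == code_class]

    def validate_for_analysis(self) -> None:
        for cc in CODE_CLASSES:
            if not self.names_of_class(cc):
                raise ValidationError(f"codeset has no {cc} probe")


@dataclass
class LaneRecord:
    sample_id: str
    lane_attributes: dict[str, str]
    counts: dict[str, int]
    header: dict[str, str] = field(default_factory=dict)
    sample_attributes: dict[str, str] = field(default_factory=dict)
    codeset: CodeSet | None = None


@dataclass
class CountMatrix:
    """Probes x samples count table with probe class labels.

    ``values`` is float so normalized matrices reuse the type; a raw matrix
    is validated to be integer-valued and non-negative.
    """

    codeset: CodeSet
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.codeset.probes), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.codeset.probes)} probes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValidationError("count matrix has negative entries")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")

    # -- indexing helpers -------------------------------------------------
    def rows_of_class(self, code_class: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.codeset.probes) if p.code_class == code_class],
            dtype=int,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.codeset, list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.codeset.probe_names, columns=self.sample_ids
        )
        df.insert(0, "CodeClass", [p.code_class for p in self.codeset.probes])
        df.index.name = "Name"
        return df

    def assert_raw(self) -> None:
        if not np.allclose(self.values, np.round(self.values)):
            raise ValidationError("raw count matrix must be integer-valued")

    def copy_with(self, values: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.codeset, list(self.sample_ids), values)


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    subtype: str
    sex: str
    laterality: str
    age_months: float
    n_stage: str
    c_stage: str
    rb1_germline: bool

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown subtype {self.subtype!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.laterality not in ("unilateral", "bilateral"):
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        if not (self.age_months >= 0) or math.isnan(self.age_months):
            raise ValidationError(f"negative age {self.age_months}")
        if self.n_stage not in N_STAGES:
            raise ValidationError(f"unknown N stage {self.n_stage!r}")
        if self.c_stage not in C_STAGES:
            raise ValidationError(f"unknown C stage {self.c_stage!r}")


# ---------------------------------------------------------------------------
# RCC parsing / emission
# ---------------------------------------------------------------------------

_SECTIONS = ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")


def _split_sections(lines: list[str], path: str) -> dict[str, tuple[int, list[str]]]:
    sections: dict[str, tuple[int, list[str]]] = {}
    current: str | None = None
    body: list[str] = []
    start = 0
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("<") and stripped.endswith(">"):
            tag = stripped[1:-1]
            if tag.startswith("/"):
                if current != tag[1:]:
                    raise RCCParseError(
                        f"{path}:{lineno}: closing tag </{tag[1:]}> does not match "
                        f"open section {current!r}"
                    )
                sections[current] = (start, body)
                current, body = None, []
            else:
                if current is not None:
                    raise RCCParseError(
                        f"{path}:{lineno}: nested section <{tag}> inside {current!r}"
                    )
                current = tag
                start = lineno
                body = []
        elif current is not None:
            body.append(line.rstrip("\n"))
    if current is not None:
        raise RCCParseError(f"{path}: unterminated section <{current}>")
    return sections


def _parse_kv(body: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in body:
        if not line.strip():
            continue
        key, _, value = line.partition(",")
        out[key] = value
    return out


def read_rcc(file: str | Path) -> LaneRecord:
    """Parse one RCC lane file into a :class:`LaneRecord`.

    Raises :class:`RCCParseError` (naming the offending line) on a missing
    section, a negative or non-integer count, or a duplicate probe name.
    """
    path = Path(file)
    lines = path.read_text().splitlines(keepends=True)
    sections = _split_sections(lines, str(path))
    for required in ("Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise RCCParseError(f"{path}: missing <{required}> section")

    header = _parse_kv(sections.get("Header", (0, []))[1])
    sample_attrs = _parse_kv(sections.get("Sample_Attributes", (0, []))[1])
    lane_attrs = _parse_kv(sections["Lane_Attributes"][1])

    start, body = sections["Code_Summary"]
    rows = list(csv.reader(body))
    if not rows or [c.strip() for c in rows[0]] != ["CodeClass", "Name", "Accession", "Count"]:
        raise RCCParseError(f"{path}:{start + 1}: Code_Summary header row malformed")

    probes: list[Probe] = []
    counts: dict[str, int] = {}
    for offset, row in enumerate(rows[1:], start=2):
        lineno = start + offset
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise RCCParseError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
        code_class, name, accession, count_str = (c.strip() for c in row)
        if name in counts:
            raise RCCParseError(f"{path}:{lineno}: duplicate probe name {name!r}")
        try:
            count = int(count_str)
        except ValueError:
            raise RCCParseError(
                f"{path}:{lineno}: non-integer count {count_str!r}"
            ) from None
        if count < 0:
            raise RCCParseError(f"{path}:{lineno}: negative count {count}")
        conc = None
        if code_class == "Positive":
            conc = _ladder_concentration(name)
        try:
            probes.append(Probe(code_class, name, accession, conc))
        except ValidationError as exc:
            raise RCCParseError(f"{path}:{lineno}: {exc}") from None
        counts[name] = count

    sample_id = sample_attrs.get("ID") or lane_attrs.get("ID") or path.stem
    return LaneRecord(
        sample_id=sample_id,
        lane_attributes=lane_attrs,
        counts=counts,
        header=header,
        sample_attributes=sample_attrs,
        codeset=CodeSet(probes, panel_name=header.get("GeneRLF", "panel")),
    )


def _ladder_concentration(name: str) -> float:
    # Positive probe names follow the POS_A(128) convention; fall back to the
    # ladder position when the concentration is not embedded in the name.
    if "(" in name and name.endswith(")"):
        try:
            return float(name[name.index("(") + 1:-1])
        except ValueError:
            pass
    letter = name.split("_")[-1][:1].upper()
    idx = ord(letter) - ord("A") if letter.isalpha() else 0
    return POSITIVE_LADDER_FM[idx % len(POSITIVE_LADDER_FM)]


def write_rcc(lane: LaneRecord, codeset: CodeSet, file: str | Path) -> None:
    """Emit an RCC file; probe order follows the codeset."""
    missing = [p.name for p in codeset.probes if p.name not in lane.counts]
    if missing:
        raise ValidationError(
            f"lane {lane.sample_id!r}: counts missing for probes {missing[:5]}"
        )
    buf = io.StringIO()
    header = dict(lane.header) or {"FileVersion": "1.7", "SoftwareVersion": "4.0"}
    sample_attrs = dict(lane.sample_attributes)
    sample_attrs.setdefault("ID", lane.sample_id)
    lane_attrs = dict(lane.lane_attributes)

    def kv_section(tag: str, mapping: dict[str, str]) -> None:
        buf.write(f"<{tag}>\n")
        for k, v in mapping.items():
            buf.write(f"{k},{v}\n")
        buf.write(f"</{tag}>\n")

    kv_section("Header", header)
    kv_section("Sample_Attributes", sample_attrs)
    kv_section("Lane_Attributes", lane_attrs)
    buf.write("<Code_Summary>\n")
    buf.write("CodeClass,Name,Accession,Count\n")
    for probe in codeset.probes:
        buf.write(
            f"{probe.code_class},{probe.name},{probe.accession},"
            f"{int(lane.counts[probe.name])}\n"
        )
    buf.write("</Code_Summary>\n")
    Path(file).write_text(buf.getvalue())


def assemble_matrix(lanes: Sequence[LaneRecord], codeset: CodeSet) -> CountMatrix:
    """Stack lane counts into a probes x samples matrix (column order = lane order)."""
    if not lanes:
        raise ValidationError("no lanes to assemble")
    sample_ids = [lane.sample_id for lane in lanes]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"duplicate sample ids across lanes: {dupes}")
    names = codeset.probe_names
    values = np.empty((len(names), len(lanes)), dtype=float)
    for j, lane in enumerate(lanes):
        if set(lane.counts) != set(names):
            raise ValidationError(
                f"lane {lane.sample_id!r}: probe set does not match codeset"
            )
        values[:, j] = [lane.counts[n] for n in names]
    return CountMatrix(codeset, sample_ids, values)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(file: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(file, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        rb1 = str(row["rb1_germline"]).strip().lower()
        if rb1 not in ("yes", "no", "true", "false", "0", "1"):
            raise ValidationError(f"unknown rb1_germline token {row['rb1_germline']!r}")
        try:
            age = float(row["age_months"])
        except ValueError:
            raise ValidationError(f"non-numeric age {row['age_months']!r}") from None
        records.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                subtype=str(row["subtype"]),
                sex=str(row["sex"]),
                laterality=str(row["laterality"]),
                age_months=age,
                n_stage=str(row["n_stage"]),
                c_stage=str(row["c_stage"]),
                rb1_germline=rb1 in ("yes", "true", "1"),
            )
        )
    return records


def write_annotations(records: Iterable[SampleAnnotation], file: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "subtype": r.subtype,
            "sex": r.sex,
            "laterality": r.laterality,
            "age_months": r.age_months,
            "n_stage": r.n_stage,
            "c_stage": r.c_stage,
            "rb1_germline": "yes" if r.rb1_germline else "no",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(file, index=False)


def read_matrix_csv(file: str | Path, housekeeping_override: Sequence[str] | None = None) -> CountMatrix:
    """Read a probes x samples count matrix from CSV.

    Expected layout: first column probe name, second column code class, then
    one column per sample.  ``housekeeping_override`` relabels the named
    probes as Housekeeping for matrices exported without code classes.
    """
    df = pd.read_csv(file, index_col=0)
    if "CodeClass" not in df.columns:
        raise ValidationError("matrix CSV must carry a CodeClass column")
    classes = df.pop("CodeClass")
    probes = []
    for name, cc in classes.items():
        if housekeeping_override and name in housekeeping_override:
            cc = "Housekeeping"
        conc = _ladder_concentration(str(name)) if cc == "Positive" else None
        probes.append(Probe(str(cc), str(name), "", conc))
    return CountMatrix(CodeSet(probes), [str(c) for c in df.columns], df.to_numpy(float))


def write_matrix_csv(matrix: CountMatrix, file: str | Path) -> None:
    matrix.to_frame().to_csv(file)
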