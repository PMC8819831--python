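"""Core domain records: annotations, extended precursors, dataset splits.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  GFF3 input (1-based
inclusive) is converted at the boundary.  A cut between positions ``c - 1``
and ``c`` of the extended sequence is stored as the integer ``c`` and the
cut-class label is carried by the nucleotide at index ``c``:

* ``DR5`` -- first nucleotide of the 5' mature product (Drosha, 5' arm),
* ``DC5`` -- first nucleotide after the 5' mature product (Dicer, 5' arm),
* ``DC3`` -- first nucleotide of the 3' mature product (Dicer, 3' arm),
* ``DR3`` -- first nucleotide after the 3' mature product (Drosha, 3' arm).

Sequences are stored as RNA (``A/C/G/U`` plus ``N``); DNA input is
transcribed on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

CUT_CLASSES = ("DR5", "DC5", "DC3", "DR3")

#: canonical column order of the dataset TSV
TSV_COLUMNS = (
    "record_id",
    "species",
    "extended_seq",
    "precursor_start",
    "precursor_end",
    "mat5p_start",
    "mat5p_end",
    "mat3p_start",
    "mat3p_end",
    "dr5",
    "dc5",
    "dc3",
    "dr3",
    "dot_bracket",
    "structure_array",
)

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA/RNA string to the RNA alphabet."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicAnnotation:
    """One GFF3 feature: a precursor hairpin or a mature microRNA product."""

    record_id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    kind: str  # "precursor" or "mature"
    parent_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.record_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.record_id}: bad strand {self.strand!r}")
        if self.kind not in ("precursor", "mature"):
            raise ValueError(f"{self.record_id}: bad kind {self.kind!r}")
        if self.kind == "mature" and not self.parent_id:
            raise ValueError(f"{self.record_id}: mature record lacks parent_id")


@dataclass
class ExtendedPrecursor:
    """An extended precursor: hairpin plus flanking genomic context.

    ``cuts`` maps cut-class name to the cut index (see module docstring).
    ``dot_bracket``/``structure_array`` cover the *extended* sequence and may
    be absent.  ``annotated_mature_seqs`` optionally carries the mature
    sequences as given by the source annotation, used for consistency
    filtering.
    """

    record_id: str
    species: str
    extended_seq: str
    precursor_span: tuple[int, int]
    mature5p_span: Optional[tuple[int, int]] = None
    mature3p_span: Optional[tuple[int, int]] = None
    cuts: dict[str, int] = field(default_factory=dict)
    flank_left_len: int = 0
    flank_right_len: int = 0
    dot_bracket: Optional[str] = None
    structure_array: Optional[str] = None
    annotated_mature_seqs: dict[str, str] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.extended_seq)
        for span in (self.precursor_span, self.mature5p_span, self.mature3p_span):
            if span is not None and not (0 <= span[0] <= span[1] <= n):
                raise ValueError(f"{self.record_id}: span {span} outside sequence of length {n}")
        if self.mature5p_span and self.mature3p_span:
            if self.mature5p_span[1] > self.mature3p_span[0]:
                raise ValueError(f"{self.record_id}: 5p mature does not precede 3p mature")
        order = [self.cuts[c] for c in CUT_CLASSES if c in self.cuts]
        if order != sorted(order):
            raise ValueError(f"{self.record_id}: cut sites out of order: {self.cuts}")

    @property
    def precursor_seq(self) -> str:
        a, b = self.precursor_span
        return self.extended_seq[a:b]

    def mature_seq(self, arm: str) -> Optional[str]:
        span = self.mature5p_span if arm == "5p" else self.mature3p_span
        if span is None:
            return None
        return self.extended_seq[span[0] : span[1]]

    def shifted(self, offset: int, new_seq: str, **overrides) -> "ExtendedPrecursor":
        """Return a copy with all coordinates shifted by ``offset`` into ``new_seq``."""

        def sh(span):
            return None if span is None else (span[0] + offset, span[1] + offset)

        kwargs = dict(
            extended_seq=new_seq,
            precursor_span=sh(self.precursor_span),
            mature5p_span=sh(self.mature5p_span),
            mature3p_span=sh(self.mature3p_span),
            cuts={k: v + offset for k, v in self.cuts.items()},
        )
        kwargs.update(overrides)
        return replace(self, **kwargs)


@dataclass
class DatasetSplit:
    train: list[ExtendedPrecursor]
    validation: list[ExtendedPrecursor]
    test: list[ExtendedPrecursor]
    identity_threshold: float = 0.8

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


def _span_cols(span, prefix):
    if span is None:
        return {f"{prefix}_start": "", f"{prefix}_end": ""}
    return {f"{prefix}_start": span[0], f"{prefix}_end": span[1]}


def records_to_frame(records: list[ExtendedPrecursor]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "species": r.species,
            "extended_seq": r.extended_seq,
            "precursor_start": r.precursor_span[0],
            "precursor_end": r.precursor_span[1],
            **_span_cols(r.mature5p_span, "mat5p"),
            **_span_cols(r.mature3p_span, "mat3p"),
            **{c.lower(): r.cuts.get(c, "") for c in CUT_CLASSES},
            "dot_bracket": r.dot_bracket or "",
            "structure_array": r.structure_array or "",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TSV_COLUMNS))


def write_tsv(records: list[ExtendedPrecursor], path) -> None:
    """Write records in the canonical TSV format (header, tab-separated)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _opt_int(v) -> Optional[int]:
    if v == "" or v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    return int(v)


def read_tsv(path) -> list[ExtendedPrecursor]:
    """Read the canonical TSV format back into records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing dataset columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        cuts = {}
        for c in CUT_CLASSES:
            v = _opt_int(getattr(row, c.lower()))
            if v is not None:
                cuts[c] = v
        m5 = (_opt_int(row.mat5p_start), _opt_int(row.mat5p_end))
        m3 = (_opt_int(row.mat3p_start), _opt_int(row.mat3p_end))
        rec = ExtendedPrecursor(
            record_id=row.record_id,
            species=row.species,
            extended_seq=to_rna(row.extended_seq),
            precursor_span=(int(row.precursor_start), int(row.precursor_end)),
            mature5p_span=None if m5[0] is None else m5,
            mature3p_span=None if m3[0] is None else m3,
            cuts=cuts,
            dot_bracket=row.dot_bracket or None,
            structure_array=row.structure_array or None,
        )
        rec.flank_left_len = rec.precursor_span[0]
        rec.flank_right_len = len(rec.extended_seq) - rec.precursor_span[1]
        out.append(rec)
    return out
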