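"""Tokenization of (sequence, structure) inputs and per-position labels.

Each position is encoded as a single joint token over nucleotide x structure
character, drawn from a fixed per-mode vocabulary (one embedding table keeps
masking simple; how to fuse the two channels is an open design choice and
this is ours):

* ``seq_only``      -- 5 nucleotides (A, C, G, U, N), structure ignored;
* ``seq_dotbracket``-- 5 x {(, ), .} = 15 symbols;
* ``seq_bprna``     -- 5 x {L, R, H, B, I, M, E} = 35 symbols.

Token 0 is reserved for padding and is masked throughout the network.
Labels are the five classes DR5, DC5, DC3, DR3, O (no cut), with the cut
classes placed per the cut-index convention of :mod:`mircleave.records`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .records import CUT_CLASSES, ExtendedPrecursor
from .structure import StructureAnnotation

INPUT_MODES = ("seq_only", "seq_dotbracket", "seq_bprna")
NUCLEOTIDES = "ACGUN"
STRUCTURE_ALPHABETS = {
    "seq_only": ".",
    "seq_dotbracket": "().",
    "seq_bprna": "LRHBIME",
}
LABEL_CLASSES = CUT_CLASSES + ("O",)
O_INDEX = LABEL_CLASSES.index("O")
PAD = 0


def vocab_size(mode: str) -> int:
    return 1 + len(NUCLEOTIDES) * len(STRUCTURE_ALPHABETS[mode])


def token_id(mode: str, nt: str, struct_char: str) -> int:
    salpha = STRUCTURE_ALPHABETS[mode]
    nt = nt if nt in NUCLEOTIDES else "N"
    try:
        s_idx = salpha.index(struct_char)
    except ValueError:
        raise ValueError(f"structure character {struct_char!r} invalid for mode {mode}")
    return 1 + NUCLEOTIDES.index(nt) * len(salpha) + s_idx


@dataclass
class LabeledExample:
    """Tokenized model input with optional per-position labels."""

    tokens: np.ndarray
    labels: Optional[np.ndarray]
    record_id: str

    def __len__(self) -> int:
        return len(self.tokens)


def _structure_string(structure, mode: str, n: int) -> str:
    if mode == "seq_only":
        return "." * n
    if structure is None:
        raise ValueError(f"mode {mode} requires a structure annotation")
    if isinstance(structure, StructureAnnotation):
        s = structure.dot_bracket if mode == "seq_dotbracket" else structure.structure_array
    else:
        s = str(structure)
    if len(s) != n:
        raise ValueError(f"structure length {len(s)} != sequence length {n}")
    return s


def encode(
    rec: ExtendedPrecursor,
    structure: Union[StructureAnnotation, str, None] = None,
    mode: str = "seq_bprna",
    with_labels: bool = True,
) -> LabeledExample:
    """Tokenize a record (and its structure, for the structural modes).

    Labels are emitted when the record carries cut annotations and
    ``with_labels`` is set; positions without a cut class are labeled ``O``.
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}")
    seq = rec.extended_seq
    struct = _structure_string(structure, mode, len(seq))
    tokens = np.array(
        [token_id(mode, nt, sc) for nt, sc in zip(seq, struct)], dtype=np.int32
    )
    labels = None
    if with_labels and rec.cuts:
        labels = np.full(len(seq), O_INDEX, dtype=np.int32)
        for cls, pos in rec.cuts.items():
            labels[pos] = LABEL_CLASSES.index(cls)
    return LabeledExample(tokens=tokens, labels=labels, record_id=rec.record_id)


def encode_dataset(records, structures=None, mode="seq_bprna", with_labels=True):
    """Encode a list of records; ``structures`` may be None (seq_only) or parallel."""
    if structures is None:
        structures = [None] * len(records)
    return [
        encode(r, s, mode=mode, with_labels=with_labels)
        for r, s in zip(records, structures)
    ]


def structure_for(rec: ExtendedPrecursor, mode: str):
    """The structure input a record carries, as needed by ``mode`` (or None)."""
    if mode == "seq_only":
        return None
    if mode == "seq_dotbracket":
        if rec.dot_bracket is None:
            raise ValueError(f"{rec.record_id}: no dot-bracket stored")
        return rec.dot_bracket
    if rec.structure_array is None:
        raise ValueError(f"{rec.record_id}: no structure array stored")
    return rec.structure_array
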