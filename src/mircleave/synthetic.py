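"""Synthetic extended-precursor generator with known cut sites.

Each record is assembled as

    5' flank | mature5p | upper stem | loop | upper stem' | mature3p | 3' flank

where the 3' arm is a noisy reverse complement of the 5' arm (per-position
mismatches at ``mismatch_rate``; bulge insertions at ``bulge_rate``,
restricted to the upper stem so mature products keep their drawn length)
and the mature duplex carries 2-nt 3' overhangs at both ends, mirroring
Drosha/Dicer cleavage geometry: the 3' product starts two base pairs
loop-ward of the 5' product's end, and the precursor ends with two
unpaired overhang nucleotides.  Cut sites are therefore known exactly by
construction, and sequence motifs can be planted at configured offsets
around them so that the labeling task is learnable by construction.

Motifs on the 5' arm are planted before the 3' arm is generated, preserving
complementarity; motifs on the 3' arm are substituted directly afterwards
and may break local pairs (the constructed dot-bracket marks non-complementary
positions unpaired), as mismatches do in real duplexes.  Flanks are i.i.d.
uniform nucleotides -- no genomic composition is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .records import DatasetSplit, ExtendedPrecursor, write_tsv
from .structure import build_structure_array

_NTS = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_CAN_PAIR = {"AU", "UA", "CG", "GC", "GU", "UG"}

#: default planted motifs: class -> [(offset, nucleotide, planting probability)]
DEFAULT_MOTIFS: dict[str, list[tuple[int, str, float]]] = {
    "DR5": [(0, "U", 1.0)],
    "DC5": [(-2, "A", 1.0)],
    "DC3": [(-1, "G", 1.0), (0, "U", 1.0)],
}


@dataclass(frozen=True)
class SynthConfig:
    n_records: int = 100
    stem_extra_range: tuple[int, int] = (3, 8)  # upper stem beyond the duplex
    loop_len_range: tuple[int, int] = (4, 10)
    mature_len_range: tuple[int, int] = (20, 24)
    flank_len_range: tuple[int, int] = (30, 50)
    mismatch_rate: float = 0.05
    bulge_rate: float = 0.05
    motifs: dict[str, list[tuple[int, str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MOTIFS.items()}
    )
    overhang: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stem_extra_range",
            "loop_len_range",
            "mature_len_range",
            "flank_len_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible {name}: ({lo}, {hi})")
        if self.loop_len_range[0] < 3:
            raise ValueError("loop length must be >= 3 to close a hairpin")
        for cls, specs in self.motifs.items():
            for _, _, prob in specs:
                if not 0.0 <= prob <= 1.0:
                    raise ValueError(f"{cls}: planting probability outside [0, 1]")


def _rand_nt(rng, k: int) -> list[str]:
    return list(_NTS[rng.integers(0, 4, size=k)])


def generate_record(
    cfg: SynthConfig, rng: np.random.Generator, record_id: str = "synth"
) -> ExtendedPrecursor:
    """Draw one synthetic extended precursor (see module docstring)."""
    lo, hi = cfg.mature_len_range
    m_len = int(rng.integers(lo, hi + 1))
    s_len = int(rng.integers(cfg.stem_extra_range[0], cfg.stem_extra_range[1] + 1))
    loop_len = int(rng.integers(cfg.loop_len_range[0], cfg.loop_len_range[1] + 1))
    f5_len = int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1))
    f3_len = int(rng.integers(cfg.flank_len_range[0], cfg.flank_len_range[1] + 1))

    core = _rand_nt(rng, m_len + s_len)  # 5' arm: mature5p + upper stem

    # 5'-arm motifs planted on the core, before the 3' arm copies it
    for cls, anchor in (("DR5", 0), ("DC5", m_len)):
        for off, nt, prob in cfg.motifs.get(cls, []):
            idx = anchor + off
            if 0 <= idx < len(core) and rng.random() < prob:
                core[idx] = nt

    # 3' arm: noisy reverse complement, partner index tracked per position
    arm3: list[str] = []
    partners: list[Optional[int]] = []
    pos_of_core: dict[int, int] = {}
    for i in range(len(core) - 1, -1, -1):
        if i >= m_len and rng.random() < cfg.bulge_rate:
            arm3.append(_rand_nt(rng, 1)[0])
            partners.append(None)
        ch = _COMPLEMENT[core[i]]
        if rng.random() < cfg.mismatch_rate:
            ch = str(rng.choice([c for c in "ACGU" if c != ch]))
        pos_of_core[i] = len(arm3)
        arm3.append(ch)
        partners.append(i)
    arm3.extend(_rand_nt(rng, cfg.overhang))
    partners.extend([None] * cfg.overhang)

    flank5 = _rand_nt(rng, f5_len)
    flank3 = _rand_nt(rng, f3_len)
    loop = _rand_nt(rng, loop_len)
    seq = flank5 + core + loop + arm3 + flank3

    arm3_start = f5_len + len(core) + loop_len
    dr5 = f5_len
    dc5 = dr5 + m_len
    dc3 = arm3_start + pos_of_core[m_len - 1] + cfg.overhang
    dr3 = arm3_start + len(arm3)

    cuts = {"DR5": dr5, "DC5": dc5, "DC3": dc3, "DR3": dr3}
    # 3'-arm motifs substituted directly (may create local mismatches)
    for cls in ("DC3", "DR3"):
        for off, nt, prob in cfg.motifs.get(cls, []):
            q = cuts[cls] + off
            if 0 <= q < len(seq) and rng.random() < prob:
                seq[q] = nt

    # constructed dot-bracket: intended pairs kept while still complementary
    db = ["."] * len(seq)
    for a3_idx, ci in enumerate(partners):
        if ci is None:
            continue
        i_abs = f5_len + ci
        j_abs = arm3_start + a3_idx
        if seq[i_abs] + seq[j_abs] in _CAN_PAIR:
            db[i_abs], db[j_abs] = "(", ")"

    extended = "".join(seq)
    dot_bracket = "".join(db)
    ann = build_structure_array(extended, dot_bracket)
    return ExtendedPrecursor(
        record_id=record_id,
        species="synthetic",
        extended_seq=extended,
        precursor_span=(dr5, dr3),
        mature5p_span=(dr5, dc5),
        mature3p_span=(dc3, dr3),
        cuts=cuts,
        flank_left_len=f5_len,
        flank_right_len=f3_len,
        dot_bracket=dot_bracket,
        structure_array=ann.structure_array,
    )


def generate_records(cfg: SynthConfig, rng=None) -> list[ExtendedPrecursor]:
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    width = len(str(max(cfg.n_records - 1, 1)))
    return [
        generate_record(cfg, rng, record_id=f"synth-{i:0{width}d}")
        for i in range(cfg.n_records)
    ]


def generate_dataset(cfg: SynthConfig, out_dir=None) -> DatasetSplit:
    """Generate ``cfg.n_records`` records and split them 80:10:10.

    Records are independent draws, so no identity clustering is needed; the
    (seeded) shuffle alone decides the split.  When ``out_dir`` is given,
    ``train.tsv``/``validation.tsv``/``test.tsv`` plus a combined FASTA are
    written there.
    """
    rng = np.random.default_rng(cfg.seed)
    recs = generate_records(cfg, rng)
    order = rng.permutation(cfg.n_records)
    n_train = int(0.8 * cfg.n_records)
    n_val = int(0.1 * cfg.n_records)
    split = DatasetSplit(
        train=[recs[i] for i in order[:n_train]],
        validation=[recs[i] for i in order[n_train : n_train + n_val]],
        test=[recs[i] for i in order[n_train + n_val :]],
        identity_threshold=1.0,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, part in zip(("train", "validation", "test"), split):
            write_tsv(part, out / f"{name}.tsv")
        with open(out / "records.fasta", "w") as fh:
            for r in recs:
                fh.write(f">{r.record_id}\n{r.extended_seq}\n")
    return split
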