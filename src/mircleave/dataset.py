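"""Building, filtering, splitting and augmenting the extended-precursor dataset.

The pipeline turns genome FASTA + microRNA GFF3 annotations into
:class:`~mircleave.records.ExtendedPrecursor` records: each precursor is
extracted with up to 300 nt of flanking genomic sequence per side (truncated
at chromosome edges and at neighboring precursors on the same strand), cut
sites are derived from the mature-product annotations after locating each
product's arm on the precursor-only fold, inconsistent or ambiguous records
are dropped with machine-readable reasons, and the survivors are split into
train/validation/test sets with a greedy identity-clustering step that keeps
near-duplicate sequences (>= 80% global-alignment identity) out of the
held-out sets.  Flank lengths are finally resampled to 30-50 nt to augment
the training data.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import pairwise_identity
from .records import (
    CUT_CLASSES,
    DatasetSplit,
    ExtendedPrecursor,
    GenomicAnnotation,
    reverse_complement,
    to_rna,
)
from .structure import hairpin_loops

MAX_FLANK = 300


class AmbiguousArm(Exception):
    """A mature product overlaps the hairpin loop; its arm cannot be assigned."""


# ---------------------------------------------------------------------------
# GFF3 / FASTA input


def read_genome_fasta(path) -> dict[str, str]:
    """Read a (multi-record, possibly wrapped) genome FASTA into a dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_mirbase_gff3(path) -> list[GenomicAnnotation]:
    """Parse a miRBase-dialect GFF3 into annotation records.

    ``miRNA_primary_transcript`` features become precursors keyed by ``ID``;
    ``miRNA`` features become mature products linked via ``Derives_from``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GenomicAnnotation] = []
    for feat in db.all_features():
        if feat.featuretype == "miRNA_primary_transcript":
            kind, parent = "precursor", ""
        elif feat.featuretype == "miRNA":
            kind = "mature"
            parent = feat.attributes.get("Derives_from", [""])[0]
        else:
            continue
        out.append(
            GenomicAnnotation(
                record_id=feat.attributes.get("ID", [feat.id])[0],
                name=feat.attributes.get("Name", [feat.id])[0],
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                kind=kind,
                parent_id=parent,
            )
        )
    return out


# ---------------------------------------------------------------------------
# extraction


def extract_extended_precursor(
    genome_seq: str,
    ann: GenomicAnnotation,
    neighbors: Sequence[GenomicAnnotation] = (),
    max_flank: int = MAX_FLANK,
    species: str = "",
) -> ExtendedPrecursor:
    """Extract a precursor with up to ``max_flank`` nt of genomic flank per side.

    Flanks are truncated at the chromosome edge and at the nearest
    neighboring *precursor* annotation on the same chromosome and strand
    (mature products and cross-strand features are ignored).  Minus-strand
    records are reverse-complemented so the result reads 5'->3'.
    """
    if ann.kind != "precursor":
        raise ValueError(f"{ann.record_id}: extraction requires a precursor annotation")
    if ann.start < 1 or ann.end > len(genome_seq):
        raise IndexError(
            f"{ann.record_id}: [{ann.start},{ann.end}] outside chromosome of "
            f"length {len(genome_seq)}"
        )

    left_gap = ann.start - 1
    right_gap = len(genome_seq) - ann.end
    for nb in neighbors:
        if nb.kind != "precursor" or nb.chrom != ann.chrom or nb.strand != ann.strand:
            continue
        if nb.record_id == ann.record_id:
            continue
        if nb.end < ann.start:
            left_gap = min(left_gap, ann.start - nb.end - 1)
        elif nb.start > ann.end:
            right_gap = min(right_gap, nb.start - ann.end - 1)
    left = min(max_flank, max(left_gap, 0))
    right = min(max_flank, max(right_gap, 0))

    g0 = ann.start - 1 - left
    g1 = ann.end + right
    seq = to_rna(genome_seq[g0:g1])
    if ann.strand == "-":
        seq = reverse_complement(seq)
        left, right = right, left
    prec_len = ann.end - ann.start + 1
    return ExtendedPrecursor(
        record_id=ann.record_id,
        species=species,
        extended_seq=seq,
        precursor_span=(left, left + prec_len),
        flank_left_len=left,
        flank_right_len=right,
    )


def place_mature_products(
    rec: ExtendedPrecursor,
    matures: Sequence[GenomicAnnotation],
    precursor_ann: GenomicAnnotation,
) -> ExtendedPrecursor:
    """Map mature-product genomic annotations into extended-sequence spans.

    Products are ordered along the transcript; which is the 5p and which the
    3p product is decided later by :func:`assign_cut_sites` from the fold.
    Here they are stored positionally (upstream span -> ``mature5p_span``).
    """
    spans = []
    for m in matures:
        if m.strand == "+":
            s = rec.precursor_span[0] + (m.start - precursor_ann.start)
            e = s + (m.end - m.start + 1)
        else:
            s = rec.precursor_span[0] + (precursor_ann.end - m.end)
            e = s + (m.end - m.start + 1)
        if not (0 <= s < e <= len(rec.extended_seq)):
            raise IndexError(f"{m.record_id}: mature span outside extended sequence")
        spans.append(((s, e), m))
    spans.sort(key=lambda t: t[0])
    rec.mature5p_span = spans[0][0] if spans else None
    rec.mature3p_span = spans[1][0] if len(spans) > 1 else None
    return rec


def assign_cut_sites(
    rec: ExtendedPrecursor, precursor_dotbracket: str
) -> ExtendedPrecursor:
    """Derive the four cut indices from the mature spans and the precursor fold.

    The precursor-only fold locates the hairpin loop; each mature product is
    assigned to the 5' or 3' arm by falling entirely on one side of that
    loop.  A product overlapping the loop raises :class:`AmbiguousArm`
    (callers flag the record for removal); zero or multiple hairpins set the
    ``structure_ambiguous`` flag.  Cut indices follow the package convention
    (label on the nucleotide 3' of the cut).
    """
    p0, p1 = rec.precursor_span
    loops = hairpin_loops(precursor_dotbracket)
    if len(loops) != 1:
        rec.flags.add("structure_ambiguous")
        return rec
    loop0, loop1 = (loops[0][0] + p0, loops[0][1] + p0)  # extended coords

    cuts: dict[str, int] = {}
    for span in (rec.mature5p_span, rec.mature3p_span):
        if span is None:
            continue
        s, e = span
        if e <= loop0:  # entirely 5' of the loop
            if "DR5" in cuts:
                rec.flags.add("structure_ambiguous")
                return rec
            cuts["DR5"], cuts["DC5"] = s, e
        elif s >= loop1:  # entirely 3' of the loop
            if "DC3" in cuts:
                rec.flags.add("structure_ambiguous")
                return rec
            cuts["DC3"], cuts["DR3"] = s, e
        else:
            raise AmbiguousArm(
                f"{rec.record_id}: mature span {span} overlaps hairpin loop "
                f"[{loop0},{loop1})"
            )
    rec.cuts = cuts
    # a lone product stored positionally as "5p" may turn out to lie on the 3' arm
    if rec.mature5p_span and rec.mature3p_span is None and "DC3" in cuts:
        rec.mature3p_span, rec.mature5p_span = rec.mature5p_span, None
    return rec


# ---------------------------------------------------------------------------
# filtering


def filter_records(
    recs: Iterable[ExtendedPrecursor], require_both_mature: bool = True
) -> tuple[list[ExtendedPrecursor], list[tuple[ExtendedPrecursor, str]]]:
    """Drop unusable records, returning ``(kept, [(record, reason), ...])``.

    Reasons: ``missing_mature`` (fewer than two mature products while
    ``require_both_mature``), ``loop_overlap`` (flagged ambiguous arm),
    ``structure_ambiguous`` (precursor fold without a unique hairpin), and
    ``inconsistent_annotation`` (annotated mature sequence differs from the
    genome extract).
    """
    kept, dropped = [], []
    for r in recs:
        if "loop_overlap" in r.flags:
            dropped.append((r, "loop_overlap"))
            continue
        if "structure_ambiguous" in r.flags:
            dropped.append((r, "structure_ambiguous"))
            continue
        if require_both_mature and (r.mature5p_span is None or r.mature3p_span is None):
            dropped.append((r, "missing_mature"))
            continue
        mismatch = False
        for arm, annotated in r.annotated_mature_seqs.items():
            extracted = r.mature_seq(arm)
            if extracted is not None and to_rna(annotated) != extracted:
                mismatch = True
        if mismatch:
            dropped.append((r, "inconsistent_annotation"))
            continue
        kept.append(r)
    return kept, dropped


# ---------------------------------------------------------------------------
# identity clustering and splitting


def _greedy_clusters(
    recs: list[ExtendedPrecursor], threshold: float
) -> list[list[int]]:
    """CD-HIT-style greedy clustering, longest sequence first.

    Each sequence joins the first existing cluster whose *representative*
    (the longest member) it matches at >= threshold identity.
    """
    order = sorted(range(len(recs)), key=lambda i: (-len(recs[i].extended_seq), i))
    clusters: list[list[int]] = []
    for i in order:
        seq = recs[i].extended_seq
        for cl in clusters:
            if pairwise_identity(seq, recs[cl[0]].extended_seq) >= threshold:
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def split_dataset(
    recs: list[ExtendedPrecursor],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    threshold: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Cluster at ``threshold`` identity and assign whole clusters to splits.

    Clusters are shuffled with ``seed`` and dealt to train/validation/test
    to approximate ``ratios`` over record counts.  Because greedy clustering
    only bounds identity to representatives, a final enforcement pass moves
    any validation/test record with >= threshold identity to some training
    record into the training set, so the split invariant holds exactly.
    """
    if len(recs) < 3:
        raise ValueError("split_dataset needs at least 3 records")
    clusters = _greedy_clusters(recs, threshold)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(clusters))

    if len(clusters) == 1:
        warnings.warn("all records fall in one identity cluster; train gets everything")
        return DatasetSplit([recs[i] for i in clusters[0]], [], [], threshold)

    n_total = len(recs)
    targets = [r * n_total for r in ratios]
    buckets: list[list[int]] = [[], [], []]
    for ci in perm:
        cl = clusters[ci]
        deficits = [targets[k] - len(buckets[k]) for k in range(3)]
        k = int(np.argmax(deficits))
        buckets[k].extend(cl)

    train, val, test = ([recs[i] for i in b] for b in buckets)

    def leaks(r):
        return any(
            pairwise_identity(r.extended_seq, t.extended_seq) >= threshold for t in train
        )

    moved = [r for r in val + test if leaks(r)]
    if moved:
        val = [r for r in val if r not in moved]
        test = [r for r in test if r not in moved]
        train = train + moved
    return DatasetSplit(train, val, test, threshold)


# ---------------------------------------------------------------------------
# flank augmentation


def sample_flanks(
    rec: ExtendedPrecursor,
    min_flank: int = 30,
    max_flank: int = 50,
    n_samples: int = 1,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[ExtendedPrecursor]:
    """Resample flank lengths uniformly in ``[min_flank, max_flank]``.

    Each of the ``n_samples`` output records independently draws a left and
    right flank length and trims the extended sequence accordingly,
    re-offsetting spans and cuts.  Flanks shorter than ``min_flank`` are
    clamped to what is available, with a warning.  A stored dot-bracket is
    sliced along when every trimmed position is unpaired, otherwise the
    structure annotation is cleared for re-annotation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p0, p1 = rec.precursor_span
    avail_l, avail_r = p0, len(rec.extended_seq) - p1
    if avail_l < min_flank or avail_r < min_flank:
        warnings.warn(
            f"{rec.record_id}: available flanks ({avail_l}, {avail_r}) shorter "
            f"than min_flank={min_flank}; clamping"
        )
    out = []
    for k in range(n_samples):
        left = min(int(rng.integers(min_flank, max_flank + 1)), avail_l)
        right = min(int(rng.integers(min_flank, max_flank + 1)), avail_r)
        lo, hi = p0 - left, p1 + right
        new_seq = rec.extended_seq[lo:hi]
        db = sa = None
        if rec.dot_bracket is not None:
            trimmed = rec.dot_bracket[:lo] + rec.dot_bracket[hi:]
            if set(trimmed) <= {"."}:
                db = rec.dot_bracket[lo:hi]
                if rec.structure_array is not None:
                    sa = rec.structure_array[lo:hi]
        sampled = rec.shifted(
            -lo,
            new_seq,
            record_id=f"{rec.record_id}|f{k}" if n_samples > 1 else rec.record_id,
            flank_left_len=left,
            flank_right_len=right,
            dot_bracket=db,
            structure_array=sa,
        )
        out.append(sampled)
    return out


def augment(
    recs: list[ExtendedPrecursor],
    min_flank: int = 30,
    max_flank: int = 50,
    n_samples: int = 10,
    seed: int = 0,
) -> list[ExtendedPrecursor]:
    """Flank-resample every record ``n_samples`` times (1 base + n-1 extra)."""
    rng = np.random.default_rng(seed)
    out: list[ExtendedPrecursor] = []
    for rec in recs:
        out.extend(sample_flanks(rec, min_flank, max_flank, n_samples, rng=rng))
    return out
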