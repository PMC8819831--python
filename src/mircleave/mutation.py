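"""In-silico saturation mutagenesis around annotated cut sites.

Every character in a window around each annotated cut site is substituted
with every other character of the scan alphabet (nucleotides A/C/G/U in a
-5..+5 window, or structure-array characters L/R/H/B/I/M in a -10..+10
window), the model is re-run, and the decision value of the scanned cut
class *at the annotated cut position* is recorded.  Structure mutations
substitute single structure-array characters without re-folding or
repairing pair consistency (the model consumes characters, not structures),
and never touch the nucleotide sequence.  ``E`` (exterior) is not part of
the structure mutation alphabet.

The heatmap entry for character ``n`` at offset ``p`` is the mean change in
decision value between the mutated and unmutated sets,

    H[n, p] = [ sum_i 1{s_ip != n} (D_inp - D_i,s_ip,p)
                + 1{s_ip == n} sum_{m in M_ip} (D_inp - D_imp) ]
              / [ sum_i 1{s_ip != n} + |M_ip| 1{s_ip == n} ],

where ``s_ip`` is the original character of example ``i`` at offset ``p``,
``M_ip`` the set of valid mutations (all alphabet characters except
``s_ip``), and ``D_inp`` the decision value with character ``n`` at offset
``p``.  Mutations toward the original character thus contribute with
opposite sign, making the H rows of a column sum (weighted) to zero.

Significance is assessed with paired-difference t-tests per (character,
position) cell, Bonferroni-corrected over all tested cells; cells whose
character occurs at that position in fewer than 5% of training records are
not tested.  The t-test pairs one difference per (example, mutation),
including all valid mutations when the original already equals ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import NUCLEOTIDES, STRUCTURE_ALPHABETS, encode, structure_for, token_id
from .network import CutSiteModel, call_cuts
from .records import ExtendedPrecursor

NT_ALPHABET = "ACGU"
STRUCT_ALPHABET = "LRHBIM"  # E excluded from the mutation alphabet


@dataclass(frozen=True)
class MutationScanConfig:
    target: str = "nucleotide"  # "nucleotide" or "structure"
    window: Optional[tuple[int, int]] = None  # inclusive offsets, default per target
    min_occurrence: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.target not in ("nucleotide", "structure"):
            raise ValueError(f"unknown scan target {self.target!r}")
        if self.window is not None and self.window[0] != -self.window[1]:
            raise ValueError("scan window must be symmetric around 0")

    @property
    def offsets(self) -> range:
        lo, hi = self.window or ((-5, 5) if self.target == "nucleotide" else (-10, 10))
        return range(lo, hi + 1)

    @property
    def alphabet(self) -> str:
        return NT_ALPHABET if self.target == "nucleotide" else STRUCT_ALPHABET


@dataclass
class RecordScan:
    """Decision values for one record: ``D[(n, p)]`` plus original characters.

    ``unmutated`` is the decision value of the intact record at the
    annotated cut (``D_{i, s_ip, p}`` for every offset ``p``).
    """

    record_id: str
    originals: dict[int, str]
    D: dict[tuple[str, int], float]
    unmutated: float = np.nan


@dataclass
class MutationHeatmap:
    """Mean decision-value changes over the scan window, with significance."""

    H: pd.DataFrame  # alphabet x offsets, NaN where unsupported
    support: pd.DataFrame  # indicator-count denominators
    significant: Optional[pd.DataFrame] = None
    pvalues: Optional[pd.DataFrame] = None


def _mean_scores(models, token_arrays):
    if isinstance(models, CutSiteModel):
        models = [models]
    per = [m.predict_scores(token_arrays) for m in models]
    return [np.mean([p[i] for p in per], axis=0) for i in range(len(token_arrays))]


def scan_decision_values(
    model: Union[CutSiteModel, Sequence[CutSiteModel]],
    rec: ExtendedPrecursor,
    cls: str,
    cfg: MutationScanConfig,
) -> Optional[RecordScan]:
    """All-variant decision values of class ``cls`` at its annotated cut.

    Returns ``None`` (with a warning) when the record lacks the cut class.
    Offsets falling outside the sequence are truncated.  The unmutated
    decision value is reused for the original character at each offset, so
    each record costs ``|window| * (|alphabet| - 1) + 1`` forward passes.
    """
    import warnings

    if cls not in rec.cuts:
        warnings.warn(f"{rec.record_id}: cut class {cls} not annotated; skipped")
        return None
    mode = (
        "seq_bprna"
        if cfg.target == "structure"
        else (model[0] if not isinstance(model, CutSiteModel) else model).cfg.input_mode
    )
    structure = structure_for(rec, mode)
    base = encode(rec, structure, mode=mode, with_labels=False)
    cut = rec.cuts[cls]
    n = len(rec.extended_seq)
    offsets = [p for p in cfg.offsets if 0 <= cut + p < n]

    originals = {}
    variants = []  # (n_char, p, token array)
    for p in offsets:
        q = cut + p
        s_char = rec.extended_seq[q] if cfg.target == "nucleotide" else structure[q]
        originals[p] = s_char
        for ch in cfg.alphabet:
            if ch == s_char:
                continue
            toks = base.tokens.copy()
            if cfg.target == "nucleotide":
                toks[q] = token_id(mode, ch, structure[q] if structure else ".")
            else:
                toks[q] = token_id(mode, rec.extended_seq[q], ch)
            variants.append((ch, p, toks))

    scores = _mean_scores(model, [base.tokens] + [v[2] for v in variants])
    from .encoding import LABEL_CLASSES

    col = LABEL_CLASSES.index(cls)
    base_val = float(scores[0][cut, col])
    D: dict[tuple[str, int], float] = {}
    for p in offsets:
        if originals[p] in cfg.alphabet:
            D[(originals[p], p)] = base_val
    for (ch, p, _), sc in zip(variants, scores[1:]):
        D[(ch, p)] = float(sc[cut, col])
    return RecordScan(rec.record_id, originals, D, unmutated=base_val)


def _cell_pairs(scans: Sequence[RecordScan], cfg: MutationScanConfig):
    """Per-cell paired differences (mutated - unmutated) per the H formula."""
    pairs: dict[tuple[str, int], list[float]] = {
        (ch, p): [] for ch in cfg.alphabet for p in cfg.offsets
    }
    for scan in scans:
        base = scan.unmutated
        for p, s_char in scan.originals.items():
            # originals outside the alphabet (N; exterior E in structure
            # scans) still contribute mutated-vs-unmutated differences
            for ch in cfg.alphabet:
                if (ch, p) not in scan.D:
                    continue
                if ch != s_char:
                    pairs[(ch, p)].append(scan.D[(ch, p)] - base)
                else:
                    # mutations toward the original: one pair per valid mutation
                    for m in cfg.alphabet:
                        if m != s_char and (m, p) in scan.D:
                            pairs[(ch, p)].append(base - scan.D[(m, p)])
    return pairs


def heatmap(scans: Sequence[RecordScan], cfg: MutationScanConfig) -> MutationHeatmap:
    """Aggregate per-record scans into the H matrix (see module docstring)."""
    pairs = _cell_pairs(scans, cfg)
    offsets = list(cfg.offsets)
    H = pd.DataFrame(np.nan, index=list(cfg.alphabet), columns=offsets)
    support = pd.DataFrame(0, index=list(cfg.alphabet), columns=offsets)
    for (ch, p), diffs in pairs.items():
        support.loc[ch, p] = len(diffs)
        if diffs:
            H.loc[ch, p] = float(np.mean(diffs))
    return MutationHeatmap(H=H, support=support)


def significance(
    scans: Sequence[RecordScan],
    cfg: MutationScanConfig,
    train_occurrence: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bonferroni-corrected paired t-tests per heatmap cell.

    ``train_occurrence`` holds the training-set frequency of each character
    at each offset (rows = characters, columns = offsets); cells below
    ``cfg.min_occurrence`` are excluded from testing, as are cells with
    fewer than two paired observations.  Returns (significant, pvalues);
    untested cells are False / NaN.
    """
    pairs = _cell_pairs(scans, cfg)
    offsets = list(cfg.offsets)
    pvals = pd.DataFrame(np.nan, index=list(cfg.alphabet), columns=offsets)
    tested = []
    for (ch, p), diffs in pairs.items():
        occ = 0.0
        if ch in train_occurrence.index and p in train_occurrence.columns:
            occ = float(train_occurrence.loc[ch, p])
        if occ < cfg.min_occurrence or len(diffs) < 2:
            continue
        arr = np.asarray(diffs, dtype=np.float64)
        if np.allclose(arr, arr[0]):
            # zero variance: identical shifts; exactly zero -> not significant
            pvals.loc[ch, p] = 1.0 if np.allclose(arr, 0.0) else 0.0
        else:
            pvals.loc[ch, p] = float(stats.ttest_1samp(arr, 0.0).pvalue)
        tested.append((ch, p))
    n_tested = len(tested)
    significant = pd.DataFrame(False, index=list(cfg.alphabet), columns=offsets)
    for ch, p in tested:
        significant.loc[ch, p] = bool(pvals.loc[ch, p] * n_tested < cfg.alpha)
    return significant, pvals


def position_frequency_matrix(
    records: Sequence[ExtendedPrecursor],
    cls: str,
    window: Optional[tuple[int, int]] = None,
    target: str = "nucleotide",
) -> pd.DataFrame:
    """Character counts per offset around the annotated cut (for logos).

    Rows are the characters observed, columns the window offsets; a record
    contributes to every column whose position lies inside its sequence, so
    each column sums to its number of contributing records.  Normalize
    columns to obtain the frequency matrix used for occurrence filtering.
    """
    cfg = MutationScanConfig(target=target, window=window)
    offsets = list(cfg.offsets)
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        if cls not in rec.cuts:
            continue
        cut = rec.cuts[cls]
        source = (
            rec.extended_seq if target == "nucleotide" else structure_for(rec, "seq_bprna")
        )
        for j, p in enumerate(offsets):
            q = cut + p
            if not 0 <= q < len(source):
                continue
            ch = source[q]
            if ch not in counts:
                counts[ch] = np.zeros(len(offsets), dtype=np.int64)
            counts[ch][j] += 1
    pfm = pd.DataFrame(counts).T
    pfm.columns = offsets
    return pfm.sort_index()


def occurrence_frequencies(pfm: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a PFM into per-position character frequencies."""
    return pfm / pfm.sum(axis=0)


def write_pfm(pfm: pd.DataFrame, path) -> None:
    """Write a PFM in a plain position-weight-matrix text layout."""
    pfm.to_csv(path, sep="\t", index_label="char", lineterminator="\n")
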