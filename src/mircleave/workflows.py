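"""High-level pipelines wiring the package's modules together.

These functions are the package's operational surface (there is no shell
CLI): building a labeled dataset from GFF3 + genome FASTA, annotating
secondary structure, training replicate models, predicting and writing the
prediction table, evaluating, and running mutation scans.  Each function is
pure with respect to its declared inputs/outputs, and all randomness flows
from explicit seeds.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .encoding import encode_dataset, structure_for
from .metrics import EvalReport, evaluate_predictions
from .mutation import (
    MutationHeatmap,
    MutationScanConfig,
    heatmap,
    occurrence_frequencies,
    position_frequency_matrix,
    scan_decision_values,
    significance,
)
from .network import (
    CutSiteModel,
    ModelConfig,
    PredictionResult,
    ensemble_predict,
    train_replicate,
)
from .records import CUT_CLASSES, ExtendedPrecursor
from .structure import annotate, fold


def build_dataset_from_files(
    gff_path,
    fasta_path,
    species: str = "",
    max_flank: int = ds.MAX_FLANK,
    require_both_mature: bool = True,
    engine="auto",
):
    """GFF3 + genome FASTA -> filtered extended-precursor records.

    Returns ``(kept, dropped_with_reasons)``.  Precursors are extracted with
    flanks truncated at neighbors, mature products are placed, the
    precursor-only fold assigns each product's arm and thence the cut sites,
    and unusable records are dropped with reasons.
    """
    genome = ds.read_genome_fasta(fasta_path)
    anns = ds.read_mirbase_gff3(gff_path)
    precursors = [a for a in anns if a.kind == "precursor"]
    matures = defaultdict(list)
    for a in anns:
        if a.kind == "mature":
            matures[a.parent_id].append(a)

    records = []
    for prec in precursors:
        if prec.chrom not in genome:
            continue
        rec = ds.extract_extended_precursor(
            genome[prec.chrom], prec, precursors, max_flank=max_flank, species=species
        )
        ds.place_mature_products(rec, matures.get(prec.record_id, []), prec)
        try:
            ds.assign_cut_sites(rec, fold(rec.precursor_seq, engine=engine))
        except ds.AmbiguousArm:
            rec.flags.add("loop_overlap")
        records.append(rec)
    return ds.filter_records(records, require_both_mature=require_both_mature)


def annotate_records(
    records: Sequence[ExtendedPrecursor], engine="auto"
) -> list[ExtendedPrecursor]:
    """Fold each full extended sequence and attach dot-bracket + structure array."""
    for rec in records:
        ann = annotate(rec.extended_seq, rec.dot_bracket, engine=engine)
        rec.dot_bracket = ann.dot_bracket
        rec.structure_array = ann.structure_array
    return list(records)


def train_replicates(
    train: Sequence[ExtendedPrecursor],
    val: Sequence[ExtendedPrecursor],
    cfg: ModelConfig,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[list[CutSiteModel], list[dict]]:
    """Train ``n_replicates`` models differing only in their seed."""
    mode = cfg.input_mode
    train_ex = encode_dataset(train, [structure_for(r, mode) for r in train], mode=mode)
    val_ex = encode_dataset(val, [structure_for(r, mode) for r in val], mode=mode)
    models, histories = [], []
    for k in range(n_replicates):
        rep_cfg = ModelConfig(**{**cfg.__dict__, "seed": seed + 7919 * k})
        model = CutSiteModel(rep_cfg)
        model, hist = train_replicate(model, train_ex, val_ex, rep_cfg)
        models.append(model)
        histories.append(hist)
    return models, histories


def predict_records(
    models,
    records: Sequence[ExtendedPrecursor],
    mode: Optional[str] = None,
) -> list[PredictionResult]:
    """Single-model or ensemble predictions for a list of records."""
    if isinstance(models, CutSiteModel):
        models = [models]
    mode = mode or models[0].cfg.input_mode
    examples = encode_dataset(
        records, [structure_for(r, mode) for r in records], mode=mode, with_labels=False
    )
    if len(models) == 1:
        scores = models[0].predict_scores([ex.tokens for ex in examples])
        from .network import call_cuts

        return [
            PredictionResult(s, call_cuts(s), ex.record_id)
            for ex, s in zip(examples, scores)
        ]
    return [ensemble_predict(models, ex) for ex in examples]


def predictions_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Prediction table: per record, position and peak score per cut class."""
    from .encoding import LABEL_CLASSES

    rows = []
    for r in results:
        row = {"record_id": r.record_id}
        for cls in CUT_CLASSES:
            pos = r.called_cuts[cls]
            row[f"{cls.lower()}_pos"] = pos
            row[f"{cls.lower()}_score"] = float(
                r.decision_values[pos, LABEL_CLASSES.index(cls)]
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_predictions_tsv(results: Sequence[PredictionResult], path) -> None:
    predictions_to_frame(results).to_csv(path, sep="\t", index=False, lineterminator="\n")


def evaluate_records(
    results: Sequence[PredictionResult],
    truths: Sequence[ExtendedPrecursor],
    d_max: int = 10,
) -> EvalReport:
    preds = {r.record_id: r.called_cuts for r in results}
    true = {t.record_id: t.cuts for t in truths}
    return evaluate_predictions(preds, true, d_max=d_max)


def mutation_scan(
    models,
    records: Sequence[ExtendedPrecursor],
    cls: str,
    cfg: Optional[MutationScanConfig] = None,
    train_records: Optional[Sequence[ExtendedPrecursor]] = None,
) -> MutationHeatmap:
    """Full mutation scan of one cut class over a record set.

    When ``train_records`` is given, the training-set occurrence filter and
    Bonferroni-corrected paired t-tests populate the significance mask.
    """
    cfg = cfg or MutationScanConfig()
    scans = []
    for rec in records:
        scan = scan_decision_values(models, rec, cls, cfg)
        if scan is not None:
            scans.append(scan)
    hm = heatmap(scans, cfg)
    if train_records is not None:
        pfm = position_frequency_matrix(
            train_records, cls, cfg.window, target=cfg.target
        )
        occ = occurrence_frequencies(pfm)
        hm.significant, hm.pvalues = significance(scans, cfg, occ)
    return hm
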