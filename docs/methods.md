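# Methods

## Task and conventions

The package labels each position of an extended microRNA precursor
sequence (precursor hairpin plus flanking genomic context) with one of
five classes: the four cleavage sites DR5, DC5, DC3, DR3 produced by
Drosha and Dicer, or O (no cut). All coordinates are 0-based half-open; a
cut falling between positions c−1 and c is stored as the integer c and the
class label is carried by the nucleotide at index c. Consequently DR5 and
DC3 are the first nucleotides of the 5' and 3' mature products and DC5 and
DR3 the first nucleotides after them, and slicing the extended sequence at
`[DR5, DC5)` / `[DC3, DR3)` recovers the mature sequences exactly. All
sequences are stored as RNA; DNA input is transcribed on read, and N bases
are kept (they map to a dedicated token) rather than dropped.

## Dataset construction

Precursors are read from miRBase-dialect GFF3 with their genome FASTA.
Each is extracted with up to 300 nt of flank per side, truncated at
chromosome edges and at neighboring *precursor* annotations on the same
chromosome and strand (cross-strand neighbors are ignored, since a
transcript does not collide with features on the opposite strand).
Minus-strand loci are reverse-complemented so records read 5'→3'.

The arm of each mature product is decided from a fold of the precursor
alone: a product lying entirely 5' of the unique hairpin loop is the 5p
product, entirely 3' of it the 3p product. Records are dropped, with
machine-readable reasons, when a product overlaps the loop
(`loop_overlap`), the fold lacks a unique hairpin (`structure_ambiguous`),
both mature products are required but absent (`missing_mature`), or the
annotated mature sequence disagrees with the genome extract
(`inconsistent_annotation`).

**Identity-aware splitting.** Sequences are clustered greedily
(longest-first, CD-HIT style): each sequence joins the first cluster whose
representative it matches at ≥ 0.8 identity. Identity is
matches/columns of an optimal Needleman–Wunsch global alignment with
match 1, mismatch 0, linear gap −1; among co-optimal alignments the one
with most matches is used, which makes the value well defined because
columns = (|a|+|b|+M−S)/2 is a function of score S and matches M alone.
Whole clusters are dealt to train/validation/test at 80:10:10 (by record
count, seeded shuffle); splitting whole clusters rather than individual
sequences is the leakage-safe reading of an under-specified step. Greedy
clustering only bounds identity to representatives, so a final enforcement
pass moves any held-out record with ≥ threshold identity to a training
record into the training set; the no-leakage invariant therefore holds by
construction and is verified by brute force in the tests.

**Flank augmentation.** Each record's flanks are resampled uniformly from
30–50 nt (10 samples per record for the ×10 augmented sets). Records with
less than 30 nt of available flank are clamped to what exists, with a
warning, rather than discarded. Resampling re-offsets all spans and cut
indices; a stored structure is sliced along only when every trimmed
position is unpaired, otherwise it is cleared for re-annotation.

## Structure annotation

Secondary structure enters the model either as the dot-bracket string or
as the *enhanced structure array*: paired positions become L (5' partner)
or R (3' partner), and each maximal unpaired run is classified by
enclosure — H inside a branchless closing pair, B on one strand between
stacked helices (the other strand contiguous), I when both strands of an
internal loop are gapped, M inside a pair enclosing ≥ 2 branch helices,
and E outside every pair. E is an addition to the L/R/H/B/I/M alphabet:
extended sequences carry long single-stranded flanks that the loop
alphabet cannot express, and collapsing them into another class would
distort the largest region of the input. Pseudoknots are rejected by the
parser (the MFE engines used emit none).

Folding goes through an adapter: ViennaRNA's python bindings are used when
importable (engine temperature and parameters are the engine's defaults),
precomputed dot-brackets are accepted everywhere, and a built-in
deterministic maximum-weighted-pairing dynamic program (GC=3, AU=2, GU=1,
minimum hairpin 3, isolated pairs removed as with RNAfold's `--noLP`)
serves as fallback. The fallback has no loop-entropy model and is adequate
for strongly paired hairpins, not a thermodynamic substitute; tests and
the synthetic pipeline never require ViennaRNA. The full extended sequence
is folded as one molecule for model input; the precursor-only fold is used
solely for arm assignment.

## Model

Input tokens are joint (nucleotide, structure character) symbols from a
fixed per-mode vocabulary — 5 nucleotides × {·}, {(,),.} or
{L,R,H,B,I,M,E} — plus a reserved padding token that is masked everywhere,
so batch padding never influences decision values. A single embedding
table over joint symbols was chosen over two parallel embeddings: one
table, simpler masking.

The network is embedding → dropout → Bi-LSTM → (optional second Bi-LSTM)
→ time-distributed dense(5) with softmax, trained with per-position
categorical cross-entropy and Adam (epsilon = 10^epsilon_exp), gradient
norm clipped at 5. Training is plain unweighted cross-entropy despite the
extreme O-class imbalance: calling is per-class argmax, so O-vs-rest
calibration does not move the calls. Early stopping watches validation
loss (patience 5, max 50 epochs by default — the original schedule is
unspecified); the best-validation weights are restored. The
implementation is pure numpy with hand-derived backpropagation, verified
against finite differences in the tests; with a fixed seed and BLAS it is
bit-reproducible.

Shipped presets (per input mode) are the tuned full-scale combinations:

| mode  | embed | dropout | LSTM1 | LSTM2 | lr      | epsilon  |
|-------|-------|---------|-------|-------|---------|----------|
| seq   | 96    | 0.315   | 320   | 192   | 3.2e-3  | 10^−7.56 |
| db    | 32    | 0.213   | 64    | 256   | 1.91e-3 | 10^−6.79 |
| bprna | 32    | 0.417   | 128   | 320   | 3.57e-3 | 10^−6.87 |

The tuning search bounds (dropout 0–0.5, embedding 32–160, LSTM 64–320 /
0–320, learning rate 1e-5–0.1, epsilon 1e-10–1e-4) are documented as
config bounds only; no hyperparameter search ships with the package.

**Decoding.** Each cut class is called at the leftmost argmax of its
decision-value column; O is never called. Leftmost tie-breaking is
deterministic and order-independent. `normalized_binary_predict` divides
one class column by its maximum and thresholds at 0.5 (strictly greater),
the mode used for comparisons against window-classifier baselines.

**Ensembles** average member decision-value matrices before calling (mean
rather than vote — the combination rule is our choice, documented, not
asserted as the original authors'). `select_ensemble` adds replicates in
decreasing single-model validation PMF order and keeps the size (capped at
12) minimizing validation PSE.

## Mutation scanning

Around each annotated cut, every window position (−5..+5 for nucleotides,
−10..+10 for structure characters) is substituted with every other
alphabet character, and the decision value of the scanned class at the
annotated cut is recorded; windows truncated by sequence edges contribute
their in-bounds offsets, and values are cached so the unmutated record is
evaluated once. Structure mutations replace single characters without
re-folding or repairing pair consistency (an L may lose its R): the model
consumes characters, not structures, and this mirrors direct character
substitution. E is excluded from the structure mutation alphabet, which
contains only the six loop/pair classes.

The heatmap cell H[n,p] is the indicator-weighted mean difference between
mutated and unmutated decision values (mutations toward the original
character contribute with opposite sign); the implementation is tested to
1e−10 against a literal double-loop evaluation of the formula.
Significance uses a paired t-test per cell with one pair per (example,
mutation) — the pairing when the original equals the scanned character is
ambiguous in the source description; pairing per mutation is our
documented choice — Bonferroni-corrected over all tested cells, where a
cell is tested only if its character occurs at that position in ≥ 5% of
training records and has ≥ 2 pairs. Zero-variance cells get p = 1 when
the shift is exactly zero, p = 0 otherwise (the t statistic diverges).
Position frequency matrices over the same windows support logo rendering
and provide the occurrence filter.

## Synthetic hairpins

The generator emits the stated world the tests assume: mature products of
20–24 nt, an upper stem of 3–8 bp beyond the duplex, terminal loops of
4–10 nt, flanks of 30–50 nt, 2-nt 3' overhangs at both duplex ends
(Dicer's cut on the 3' arm sits two base pairs loop-ward of the 5'
product's end; the precursor ends with two unpaired nucleotides), a 5%
per-position mismatch rate and 5% bulge rate on the 3' arm (bulges are
confined to the upper stem so mature lengths stay exact). Default motif
planting, probability 1.0: U at DR5+0, A at DC5−2, G at DC3−1, U at
DC3+0 — chosen to mirror the cut-site signals the full-scale analysis
reports, so the mutation scanner should rediscover them on synthetic data
(a qualitative check only).

In a perfect duplex the DC5−2 position base-pairs with DC3−1, so the A and
G motifs cannot coexist through complementarity: 5'-arm motifs are planted
on the 5' strand before the 3' arm is generated (preserving pairing), and
3'-arm motifs are substituted directly afterwards, possibly breaking local
pairs — rendered unpaired in the constructed dot-bracket, as real
mismatches are. The "zero noise → exact reverse complement" contract is
therefore stated with motif planting disabled. The constructed
dot-bracket (not a folding engine) ships with each record.

What the generator does *not* model: genomic flank composition (flanks are
i.i.d. uniform), realistic pri-miRNA thermodynamics, mirtrons, multi-loop
precursors, and annotation noise. A green learnability test therefore
establishes that the pipeline can recover planted, fully determined
signals at small scale — not that real-data benchmark numbers are
reproduced; those require the full annotation corpus and large trained
replicates, which are out of desk-scale reach by design.

## Numerical choices and degenerate inputs

- Identity ties: score first, then matches (section above); identical
  sequences short-circuit to 1.0. N never matches in alignments.
- Softmax rows are computed with max-subtraction; rows sum to 1 within
  1e−6 (tested).
- Training aborts with a diagnostic on non-finite loss.
- `split_dataset` with a single cluster places everything in train with a
  warning; fewer than 3 records is an error.
- Empty sequences, unbalanced dot-brackets (with position), mismatched
  sequence/structure lengths, and unknown modes/engines raise early with
  explicit messages.
- Float32 is the training default; float64 is used in gradient tests.

## Interface shape

The package is a library: the importable API plus `examples/` scripts are
the operational surface, with `mircleave.workflows` providing the
high-level pipelines (build, annotate, synthesize, train, predict,
evaluate, scan). There is no shell CLI; model directories (config JSON +
npz weights + ensemble manifest) are the persistence format.
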