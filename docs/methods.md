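# Methods

This note records the models, parameter choices and numerical conventions
behind `vdjwell`, and what the synthetic-data tests do and do not establish
about real data.

## Library model and read cleaning

The package assumes a plate-multiplexed 5'-RACE-style amplicon:

```
[well barcode] [TSO] [ ... variable domain ... ] [constant-region primer]
```

sequenced as overlapping paired-end reads. Cleaning runs in a fixed order —
pair merging, barcode demultiplexing, primer-based chain assignment with
excision, TSO removal, `N` exclusion, 3' quality trimming below q10, and a
385 bp minimum length — with exact per-stage read accounting
(`reads_in == reads_out + reads_discarded` at every stage).

Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `min_overlap` | 20 nt | shortest acceptable pair overlap; exhaustive scan, most-matching overlap wins |
| `max_mismatch_rate` | 0.1 | mismatch tolerance inside the overlap; higher-quality base and its quality are kept, ties keep the forward read |
| barcode mismatches | 0 | barcodes carry sample identity; an error here would cross-assign wells, so no tolerance |
| primer / TSO mismatches | 2 | these only gate chain identity / trim the 5' end; modest tolerance recovers reads with sequencing errors |
| `q_min` | 10 | 3' bases strictly below this Phred score are trimmed |
| `min_len` | 385 bp | minimum retained merged length |

Ties are always resolved by discarding, never guessing: a read equidistant
from two barcodes or matching two chain classes equally well is dropped,
because downstream scoring assumes clean well/chain assignment.

## Denoising

ASVs are called by a greedy abundance collapse: after exact dereplication
(abundance-sorted, ties lexicographic), a sequence is absorbed into an
already-retained ASV when it is within `max_hamming = 2` substitutions
(equal lengths only — the error model is substitution-only, so Hamming
distance is well-posed) and its count is at most `abundance_ratio = 0.1`
times the parent's current count. Read counts are conserved exactly, and
support fractions per well+chain sum to 1 before filtering. The denoiser
sits behind a small interface so a model-based denoiser can be substituted;
the collapse itself is checked in tests against an independent brute-force
single-linkage absorption oracle on small inputs.

A known limitation: absorption of singleton error reads requires the parent
to hold at least `1 / abundance_ratio = 10` reads. At well depths below
roughly 100 reads per chain the true sequence can fall under that floor and
fragment into singleton ASVs. The default simulator depth (200 reads/well,
i.e. ~70–100 reads per chain) stays above it; very shallow real wells would
need a smaller `abundance_ratio` or deeper sequencing.

## Annotation and binning

Variable domains are translated in the best forward frame (longest stop-free
stretch; a frame must offer at least 90 stop-free residues to count as a
candidate domain). Region segmentation into FR1–FR4/CDR1–CDR3 is delegated
to a pluggable backend, because IMGT numbering is an external convention:

* `table` — exact lookup of known domain amino-acid sequences and their
  region boundaries (in tests, fed from the simulator's ground truth);
* `motif` — a heuristic locating the conserved Cys23/Cys104 pair and the
  J-region `[WF]GxG` anchor, assuming the canonical region lengths used
  throughout this package (FR1 25, CDR1 8, FR2 17, CDR2 7, FR3 38, FR4 11
  aa, CDR3 5–25 aa).

IMGT positions are simplified to a sequential 1..N numbering without
insertion codes; the exported nucleotide span covers positions 1–127 for
light-type chains (VL/α/γ) and 1–128 for heavy-type (VH/β/δ), clipped —
never padded — when the annotation starts late or ends early. The TCR
mapping onto the light/heavy span lengths is an explicit assumption; only
the BCR spans are externally defined.

Chains with any zero-length region are removed. ASVs with identical
(chain class, region amino acids) collapse into one bin (counts summed,
representative = most abundant member, ties to the lexicographically
smaller sequence), and bins below 10% read support within their well+chain
are dropped. The threshold is inclusive (`>= 0.10`), reading "10% minimum"
as the smallest retained value; it is applied per chain per well.

## Scoring

The star rating combines within-well support and cross-replicate
concordance (see README for the formulas). Numerical conventions:

* The printed combination `max(λ, ln(Match))` contradicts λ being a
  *ceiling* and the stated 0–5 range (a literal max would force every total
  ≥ 3). The default mode therefore clamps `ln(Match)` into `[0, λ]`;
  `literal_max_mode` preserves the printed formula for auditing.
* `Match` can be ≤ 0 (e.g. one supporting sample in a large group); its
  log-component is floored at 0 rather than raising.
* "Reads per primer well" is the total read count assigned to that chain's
  primer class within the well.
* ν weights TRs only in the support term; the penalty term's
  `(BR + TR) / Total` is unweighted, as printed.
* Subclone-less sample IDs count as one empty-string subclone, so two such
  samples of the same parent are TRs of each other.
* Aberrant-chain identity is compared on amino-acid bins, since
  edge-trimmed nucleotide variants are already collapsed upstream.
* Percentiles are the fraction of same-chain-class scores strictly below,
  over the whole run (singleton population ⇒ 0).
* Aberrant flagging requires strictly more than 50% of the run's distinct
  samples; exactly half is retained. Heavy chains are never flagged.
* High-confidence pair selection takes, per sample and chain type, the
  maximum-scoring chain strictly above 4 (ties: higher ASV score, then
  lexicographically smaller nucleotide span); verified-by-cloning entries
  qualify regardless of score. Identical (VL aa, VH aa) pairs arising from
  replicates of the same clone collapse into one pair *before* the
  uniqueness rule — otherwise every replicated clone would annihilate its
  own evidence; a chain shared between two *different* pairs still drops
  both.

## Pairing classifier

Positives are high-confidence pairs; negatives are a seeded derangement of
heavy chains over the same light chains. The derangement is built from
disjoint transpositions (one 3-cycle absorbs an odd leftover) so the
positive+scrambled graph decomposes into small connected components; that
makes leakage-free grouped cross-validation possible, since grouping is by
connected components of shared chain sequences and a single-cycle
derangement would collapse everything into one group.

Features are chain-derived only (region lengths, chain-class indicators,
length differences, and a germline-similarity stub scoring identity against
a configurable sequence pool) — never the replicate-based star score, so
the classifier is an independent line of evidence. The model is a
gradient-boosted tree classifier with library-default hyperparameters and a
recorded seed; no tuning loop. Metrics come from pooled held-out
predictions of a stratified, grouped k-fold split.

## Synthetic data: what it emulates, and what it does not

The simulator emulates: the amplicon architecture above; per-cycle quality
flat at q37 decaying linearly to q8 over the last 30 cycles (so the q10
trim rule is exercised); uniform substitution errors; plate/well/sample-ID
replicate structure; oligoclonal mixtures with exact fractions; and a
run-wide aberrant light chain spiked into a chosen fraction of samples at
30% of the well mixture. Clone sequences are random codon strings with
conserved Cys/`[WF]GxG` anchors at canonical positions — not real
germlines — because annotation is table-driven and biological realism is
unnecessary for correctness tests. Light and heavy CDR3 lengths of a clone
are correlated (heavy = light + 6), a planted covariate that gives true
pairings a signal scrambled pairings usually lack.

It does **not** emulate: indels (the substitution-only model keeps the
Hamming-based collapse well-posed; an indel mode would require an
edit-distance denoiser), PCR chimeras, UMIs (the protocol has none),
abundance skew within a chain, real germline diversity, or batch effects.
Consequently, passing tests demonstrate the correctness of the
consolidation logic and the scoring arithmetic under the stated error
model — not annotation accuracy on real antibody sequences (that depends on
the external numbering tool a production deployment would plug in) and not
the field performance of the pairing classifier (whose printed features
here are simulator-aligned stubs).

## Problem sizes in tests and the acceptance script

The score-ceiling search uses a 101-point ASV grid × ~400 log-spaced match
values; filter probes scan tight integer ranges around each boundary. The
end-to-end study is two plates, 8 parents × 3 subclones (24 wells), 200
reads/well, 0.2% substitution errors — small enough to run in seconds while
still exercising demultiplexing across plates, replicate grouping and
aberrant-chain flagging at 60% prevalence. The pairing evaluation uses 80
candidates for the separable check and 480 for the label-shuffled null,
where the larger sample keeps the null AUC's sampling noise well inside
0.5 ± 0.1 under grouped 5-fold cross-validation.
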