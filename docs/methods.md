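# Methods

## Windowing

Genomes are DNA (`A/C/G/T/N`, `U` and lowercase normalized on input);
windows are emitted in RNA. Regular windows start at multiples of the
step; a final window anchored at `L − window_length` guarantees the tail
is covered, and a genome no longer than one window yields `[0, L)`.
Defaults: window 500 nt, step 300. The 200 nt overlap exceeds the
longest pre-miRNA we expect to recover, so every hairpin lies wholly
within at least one window; the step is configurable. Both strands are
scanned by default (miRNAs arise on either); minus-strand windows are
reverse-complemented before transcription, and every coordinate reported
anywhere in the package is 0-based, half-open, on the plus strand.
Windows with more than 10% `N` are skipped (configurable); isolated `N`s
are tolerated by the folder as unpairable residues.

Note that the window start grid is generally not symmetric under
reverse-complementing the genome (the anchored tail breaks it unless
`(L − window_length)` is a multiple of the step), so strand symmetry of
the window multiset holds exactly only on symmetric grids; the test
suite checks it there.

## Folding

The bundled engine is a deliberately simple, non-physical pair-count
model: a structure's energy is `−Σ e(i,j)` over its pairs with
e(GC) = 3, e(AU) = 2, e(GU) = 1 kcal/mol, minimum hairpin loop 3 nt, no
pseudoknots. The weights order pair stabilities realistically and make
every quantity exactly computable:

* **MFE** by a Nussinov-style maximization DP; traceback is
  deterministic (position *i* pairs with the largest admissible partner
  achieving the optimum), so identical inputs give identical
  dot-brackets.
* **Ensemble** quantities by a McCaskill-style inside/outside DP at
  T = 310.15 K (RT = 0.0019872·T): `Z = Σ_S exp(−E(S)/RT)`,
  `EFE = −RT ln Z`, pair probabilities from the outside pass,
  `MFE frequency = exp((EFE − MFE)/RT)`, and
  `diversity = Σ_{i<j} 2 p_ij (1 − p_ij)`. Tables are scaled per
  nucleotide by `exp(MFE/(n·RT))` so strongly pairing long sequences
  stay inside float range; deep underflow of negligibly weighted
  pairless sub-regions is tolerated.
* An **exhaustive enumerator** of all nested structures (guard: 30 nt)
  serves as an independent oracle; the DPs agree with it exactly for the
  MFE and to ~1e−13 for ensemble quantities over hundreds of random
  sequences.

Inner loops are numba-compiled; a 500-nt window folds in ~40 ms, so a
50 kb two-strand run takes well under a minute. The backend contract
also admits the ViennaRNA bindings (`vienna`), adapted into the same
types; a missing engine raises a capability error at configuration time,
never a silent fallback. The toy model's absolute energies are not
physical: only contrasts between sequences folded under the same model
are meaningful.

## Extraction, filtering, trimming, deduplication

A hairpin loop is a pair enclosing only unpaired bases. Its stem-loop
spans out to the outermost pair reachable through single-branch regions
(stacks, bulges, internal loops), stopping below a multiloop or the
exterior — each multiloop branch therefore becomes its own hairpin. The
excised sub-structure is re-indexed and keeps the restriction of the
window structure; trimmed/excised hairpins are **not** re-folded by
default (cheaper and deterministic; a re-fold can be layered on by
calling the backend on the excised sequence).

Filters keep hairpins with length ≥ 60 **and** pairs ≥ 16, both
boundaries inclusive — the natural reading of eliminating those below
the minimums.

Trimming aims at sequences whose length resembles real pre-miRNAs while
keeping the normalized free energy favourable: shorter sequences have
higher MFE/L, so the cut closest to the terminal loop that still
reaches the minimum length is preferred. Rule 1 discards hairpins
shorter than the minimum outright. Rule 2 walks the pair chain outward
from the loop; at each internal loop/bulge the candidate span keeps the
inner closing pair and extends one unpaired nucleotide into the
loop/bulge on each side where one exists; the first span ≥ the minimum
wins. With a reference set supplied, the per-genome minimum can be taken
as the 10th percentile of known-miRNA lengths (`trim_min_from_reference`);
the global default is 60.

Deduplication is a single pass per (genome, strand) stream in window
order: each sequence is compared with the most recently kept one; on
substring containment (either direction) the shorter is discarded, on
equality the later. This removes the echoes produced by overlapping
windows without an all-pairs comparison; it intentionally does not
collapse identical hairpins that are far apart.

## Labeling

The matcher is a Smith-Waterman local aligner with linear gaps
(match +2, mismatch −3, gap −5) and deterministic traceback (first best
cell in row-major order; diagonal preferred, then up, then left).
Identity is matches over aligned columns (gaps included); coverage is
the aligned reference span over the reference length. A hairpin is
positive when any reference reaches identity ≥ 0.9 and coverage ≥ 0.9.
These parameters are this package's documented defaults for a
self-contained, deterministic matcher; a precomputed tab-separated match
table (outfmt-6-compatible subset) can be supplied instead, so an
external aligner's output can drive labeling unchanged. Labeling is
monotone in both thresholds.

## Features

The 77 slots and their order are frozen in
`src/mirhairpin/feature_manifest.json`. Choices where descriptions admit
more than one reading:

* `dQ` follows the printed formula `(1/L) Σ_{i<j} p_ij log₂ p_ij`
  with no leading minus, hence always ≤ 0 (the positive
  Shannon-entropy variant is common elsewhere; comparisons across
  toolkits should check the sign convention).
* `EFE` is the raw ensemble free energy in kcal/mol; the per-length
  normalization lives only in `mfe_efe_difference = |MFE − EFE|/L`.
* `MFEI_1` uses %G+C on the 0–100 scale (the literature convention).
* `avg_bp_stem` is paired *nucleotides* per stem, i.e. 2·bp/stem.
* `terminal_loop_length` is the unpaired count of the hairpin (main)
  loop.
* A stem is a maximal perfectly stacked helix of ≥ 1 bp, so every pair
  belongs to a stem; `bp_proportion` normalizes pair-class counts by
  sequence length, `bp_proportion_stem` by total stem pairs.
* Triplet bins collapse `(`/`)` to one "paired" state (2³ patterns × 4
  nucleotides = 32); bin index is `8·nt + pattern`, nucleotides in
  A,C,G,U order, pattern the binary number with paired = 1
  (`triplets_0` = A with "...").
* Division guards return 0 with a warning: `gc_ratio` with no C,
  `MFEI_1` at 0% GC, `MFEI_2` with no stems, `MFEI_4` with no pairs.

Sequences containing `N` make composition groups sum below 1 (only
A/C/G/U are counted); this only affects windows admitted under the
N-fraction threshold.

## Characterization

Normalization is the standard z-score (mean subtracted, divided by the
standard deviation); constant columns become zeros with a warning.
t-SNE runs on all positives plus a seed-subsampled set of unlabeled rows
(default 10× the positives, capped at 5000), perplexity
`min(30, (rows−1)/3)`, fixed `random_state` — treated as a library-backed
black box and tested only at the contract level (determinism, preserved
separation of well-separated clusters). Ranking fits a
`RandomForestClassifier` (default 10 trees, fixed seed) per dataset on
positive vs unlabeled, ranks features by decreasing impurity importance
(ties broken by canonical order, so each dataset's ranks are a
permutation of 0..76) and averages ranks across datasets; rank 0 is
best.

## Synthetic genomes

`generate_genome` draws i.i.d. uniform background and overwrites it with
fold-backs (random arm + loop + exact reverse-complement arm; default
arm 30 nt, loop 4 nt, arm GC fraction 0.5) at jittered, ≥ 500 nt-spaced
positions on random strands; a fraction (default half) is copied into
the returned reference set. Every implant is folded in isolation at
generation time and re-drawn (deterministically, from the same seed
stream) until it passes the default filters, so recovery failures
indicate pipeline defects rather than unlucky draws. The background
models none of a real genome's structure (no repeats, isochores or
composition bias), and the toy energy model pairs random RNA far more
aggressively than a nearest-neighbour model would — so passing the
recovery checks demonstrates the bookkeeping (coordinates, strands,
filters, labeling) is correct, not that real-genome hairpin counts or
feature distributions are reproduced. Real-genome runs at published
scale (multi-gigabase folding, registry-scale matching) are outside
desk scope, and the original extraction's step/overlap and alignment
thresholds are not public, so absolute extracted-hairpin counts are not
comparable anyway.

## Problem sizes

The default verification sizes — 200 enumeration-checked sequences of
≤ 20 nt, a 50 kb genome with 10 implants, 1000 random hairpins for the
conservation sweep — run end to end in well under a minute after JIT
warm-up and are this package's chosen desk-scale study conditions.

## Known limitations

* The toy energy model is non-physical by design; use the ViennaRNA
  backend for realistic thermodynamics.
* Trimming does not re-fold; the restricted structure can be slightly
  suboptimal for the excised sequence.
* The aligner is O(mn) per pair with no k-mer prefilter; labeling very
  large hairpin sets against large registries would benefit from an
  external aligner via the match-table hook.
* Multibranch loops are split into independent hairpins; no merging of
  overlapping candidates across windows beyond containment dedup.
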