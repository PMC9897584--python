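# Methods

## Problem and model

The package transfers protein-function annotations between proteomes
separated by roughly 700 My of evolution, where homologous pairs
typically share 10–30 % sequence identity. At that distance a single
remote-homology search is not decisive: many model-organism family
members map onto few non-model sequences, and no alignment statistic
separates them. The method therefore has two stages: (1) symmetric
remote-homology mapping with best-bidirectional filtering, which is
fully automatic, and (2) family-specific plausibility filters that
encode what a functional member of the family must look like. Stage 2
narrows candidates; the final call is an expert judgment, which the
package surfaces as report flags rather than deciding silently.

## Stage 1: hit processing

Hit tables are consumed as ranked by the search tool; "top hit" means
the rank-1 hit surviving the filter, never a re-sort by any single
statistic (an optional re-ranking by probability/E-value/score/id is
available for tabular inputs that carry no rank). Defaults: E-value
≤ 1e-3, probability ≥ 20 (printed 0–100 scale), 250 hits kept. These
are the standard settings of the search protocol the pipeline consumes
and are exposed as flags.

The consensus tally counts (query, target) incidences — a query with
several alignment blocks to one target counts once — at a selection
threshold of 100 % probability. Because result files print probability
with one decimal, "100 %" is implemented as printed probability
≥ 99.95. Targets supported by at least one query from every required
organism are selected, ordered by total support then id.

Best-bidirectional pairs require exact mutuality of the two top-hit
maps. For BLAST tabular inputs (used for the cross-species map in the
PPI stage) the best hit is max bitscore, ties broken by min E-value,
then lexicographic target id; ties are real in BLAST output, so the
tie-break is part of the contract.

Set-logic operations (filtering, inversion to non-redundant target
groups, union/overlap reports, mutual-best intersection) are checked
against brute-force enumeration in the test suite; the overlap report
gives both directions of every pairwise set difference because
"missed by list A relative to list B" is otherwise ambiguous.

## Stage 2a: GPCR pocket conservation

Ballesteros–Weinstein (BW) labels are arithmetic around per-helix
anchors: within helix h, reference position p is labelled
h.(50 + p − anchor_h). Anchors, helix spans, the 30 cavity-facing
pocket positions and the retinal-rule positions ship as an editable
YAML configuration with a provenance note — they are inputs to the
method, not constants; the packaged file encodes the rod-opsin
reference frame (K296 = 7.43, E113 = 3.28). Candidate positions
inherit labels through a pairwise alignment; positions aligned to
reference gaps stay unlabelled and read as gaps in the profile.

Pocket identity counts exclude positions gapped on either side from
the denominator by default; a strict mode counts them as mismatches.
Both are provided because published identity counts rarely state the
convention.

The retinal rule: a functional opsin needs the Schiff-base lysine;
the counter-ion residue is classified acidic (D/E), tyrosine, serine
or other. Tyrosine and serine substitutions shift the absorbance
maximum but retain function (the vertebrate E is generally replaced by
Y in invertebrate opsins), so they classify, not fail; loss of the
lysine fails the candidate. The minimal 4-residue signalling pocket is
configuration left empty by default — its residue identities are not
published — and the conservation count only runs when the user
supplies both the positions and a reference profile.

## Stage 2b: domain architecture

The PROSITE PA-syntax engine supports literals, `x`, allowed `[...]`
and forbidden `{...}` sets, fixed and variable repeats, and `<`/`>`
anchors. Two match modes: *all* reports every (start, end) span that
matches (multiple ends per start for variable-length patterns); *scan*
is a leftmost, non-overlapping, greedy scan with at most one (longest)
hit per start. The scanner is validated against exhaustive expansion
of the pattern to concrete strings for all patterns expanding to
≤ 10⁵ strings. PROSITE weight-matrix profiles are out of scope;
domains detectable only by profiles can be supplied as precomputed hit
tables.

Domain placement assumes the type I receptor convention (N-terminus
extracellular) by default, overridable per protein; flipping the
orientation exactly swaps the extracellular and cytoplasmic lists.
Zero TM helices leaves domains unplaced with a warning; more than one
is an error in single-TM mode. Classification is a pure function of
the placed domain-class sets: TIR with zero LRRs → `TIR_only`; LRRs
with no TIR → `LRR_only` (rejected as a TLR); ≥ 1 extracellular LRR +
cytoplasmic TIR → `canonical_TLR`, or `TLR_with_extra_domains` when
extra ectodomain classes (cadherin, calcium-binding EGF,
thrombospondin modules; a configurable list) are present. The LRR
threshold for "multiple LRRs" is set at ≥ 1 hit because the count
depends entirely on pattern granularity; the raw count is reported so
users can apply stricter cutoffs.

## Stage 2c: PPI evidence

The interaction predictor is deliberately external: anything
satisfying `score(seq_a, seq_b) -> [0, 1]`, deterministic for fixed
inputs, can drive the screen (a pre-trained deep model in practice; a
mock in tests). Scores are not assumed symmetric; pairs are passed in
role order. The edge threshold defaults to 0.5 on the scorer's
probability scale — the source protocol does not print a cutoff — and
is configurable.

Triangle evidence enumerates α–β–γ triples with all three
role-respecting edges, deterministically sorted, and is validated
against cubic enumeration. Cross-species overlay translates each edge
through the BBH map and looks it up in the second network.

The perturbation test scores the original pair, then per trial samples
k (default 25) positions without replacement — from the mapped
binding-site set in the site arm, from the whole sequence in the
random arm — substitutes each with a uniform draw over the 19
non-identical standard residues, and re-scores; means and SDs are
reported over n_trials (default 50) per arm. The substitution
distribution is a design choice (the protocol does not specify one);
sampling from a larger site set, rather than a fixed 25, is likewise
assumed, with a fixed-site mode available by passing exactly k
positions. One base seed spawns independent per-trial streams, so
results are bit-reproducible. When k = 0, or when the scorer is
constant, all trial scores are identical and the arm reports that
common value exactly rather than a floating-point mean, keeping the
zero-drop contract exact. If the site set is smaller than 25, k is
clipped with a warning; an explicit k larger than the available
positions is an error.

Interface extraction uses the any-atom rule: a residue of chain set A
is an interface residue iff any of its atoms lies within the cutoff
(default 5 Å, Euclidean) of any atom of chain set B; implemented with
a k-d tree and validated against the O(n²) scan and under rigid-body
transforms.

## Synthetic data

The generators define the study conditions and are deterministic
functions of their config (same config → same bytes).

* **Homolog corpus** (defaults: 200 model queries, 60 families,
  sequence length 200): one target per family, model members derived
  by point substitution at rate 0.75 per residue — ~25 % residual
  identity, the middle of the twilight zone. Substitutions are uniform
  over the 19 alternatives; no indels or paralog structure. HHR files
  plant the true target as the rank-1 hit (probability 95–100, half
  printing as 100.0 so the consensus path is exercised; E-value
  ≤ 1e-10) over weaker decoy hits, one of which fails the E-value
  cutoff by construction. Decoy queries receive only sub-threshold
  hits.
* **Domain corpus**: 900-residue sequences with a planted TM helix at
  600–622 and concrete pattern instances written extracellular or
  cytoplasmic per category. Background sequences exclude tryptophan
  and every toy motif contains a literal W, so planted motifs cannot
  arise by chance — the fixtures test plumbing and placement, not
  motif statistics.
* **Interface complexes**: 300-residue chain A with 30 planted
  interface positions placed within 4 Å of chain B in the toy
  coordinates (all other residues ≥ 10 Å away), and a mock logistic
  scorer that depends only on how many planted interface residues
  remain unmutated.

What passing on these fixtures shows: the plumbing, set logic,
numbering transfer, pattern semantics and perturbation machinery are
exact. What it does not show: performance on real proteomes, where hit
rankings are noisy, alignments contain indels, domain patterns have
non-trivial false-positive rates, and the PPI scorer is imperfect —
none of which the generators simulate.

## Problem sizes and numerical choices

The acceptance script uses a 200-query/60-family corpus, 1000 random
pattern-scan cases (expansion capped at 2000 concrete strings per
pattern), 50 random tripartite networks (≤ 30 nodes), 30 random
50-atom interface toys, 500 rounds of set-logic comparison, and 20
perturbation pairs at k = 25, 50 trials — sizes chosen so the whole
script completes in seconds on one CPU while every code path is
exercised. Coordinates are 1-based with inclusive ends everywhere.
Probabilities are stored on the printed 0–100 scale, matching the
result files. FASTA ids keep both the full token and the shortened
numeric form (`pdam_00017423-RA` → `17423`); B/Z/U/J/O fold to X with
a warning; obsolete ids are reported, never silently dropped.

## Known limitations

Running the remote-homology search, TM prediction, PROSITE profile
scans, homology modelling, docking, and the PPI predictor itself are
all out of scope: the package consumes their outputs. The published
headline counts of full-scale runs (hundreds of unique targets from
~1000-query receptomes) depend on those external search results and on
supplementary hit tables, so they are not reproducible at desk scale;
the packaged consensus tally is the one full-scale printed input the
pipeline re-analyses directly. Only single-result HHR layout is
parsed; batch e-mail formats vary and are not assumed.
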