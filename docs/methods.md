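# Methods

This note documents the models, parameters and design choices behind
`corallox`, and what the synthetic-data tests do and do not establish.

## Sequence model and coordinates

All coordinates are 1-based inclusive, matching the convention used when
catalytic residues are quoted as e.g. "His 757". Nucleotide candidates are
translated with the standard genetic code (table 1): annotated CDS features
are translated directly (terminal stop stripped, ambiguity codons → X);
unannotated transcripts get a six-frame longest-ORF search (start-to-stop,
default minimum 100 aa). When several ORFs tie on length the earliest start
in frame order +1, +2, +3, −1, −2, −3 wins. The 100-aa floor keeps the
search well below the shortest analysable partial cores (~150 aa) while
discarding incidental short ORFs; it is configurable. Behaviour on
transcripts with several long ORFs is deliberately simple (longest wins)
and documented rather than heuristic.

## Motifs

The motif table is literal-string matching with per-motif Hamming budgets:
WLLAK exact (it is the hard filter), YRDD / HAAVN / C-terminal motif with
one mismatch allowed. Two C-terminal spellings (PNGTAI, PNSIAI) circulate
for the soft-coral fusion proteins; both are shipped as accepted patterns
and reports surface which one matched rather than adjudicating. The
presence filter additionally requires the final residue to be Ile, Thr or
Ser (the set observed across coral and mammalian LOXs, including the known
Ser exception).

Core trimming selects the rightmost exact WLLAK hit (else the rightmost
inexact hit): the catalytic-domain copy of the motif sits in the final
third of a ~1066-aa fusion, so upstream occurrences are treated as decoys.
Trimming is idempotent by construction. Core lengths outside [280, 400] aa
are warned about, not filtered — the expected window (~318–330 aa) is
approximate.

## Alignment and residue mapping

Pairwise alignment is affine-gap Needleman–Wunsch via Biopython's
`PairwiseAligner` with BLOSUM62, gap open 10, gap extend 0.5 (a gap of
length k costs 10 + 0.5·(k−1)). These are Clustal W-era protein defaults;
all three are configurable. Two scoring modes exist: strict global
(terminal gaps penalised) for identity matrices, and semiglobal (terminal
gaps free) for mapping partial queries onto a longer reference. Traceback
determinism comes from always taking the aligner's first optimal
alignment; scores are verified against an independent exhaustive
enumeration oracle in the tests, so the choice among co-optimal tracebacks
never affects a reported score.

Percent identity uses identical residue-pair columns over all alignment
columns. The COX screen instead asks for identity ≥ 30 % *and* an overlap
of ≥ 200 aligned residue pairs: with the gap-seeking optimal alignment,
identity computed over aligned pairs alone sits near 30 % even for
unrelated sequences of this composition (the optimiser cherry-picks
matches), whereas the all-columns null is ~15–18 % against ~70 % for true
COX homologs — only the all-columns definition separates homology from
noise at the twilight-zone cut. Both quantities are exposed on
`AlignmentResult`.

`map_position` returns the query residue in the column carrying a given
reference residue; a query gap inside the aligned extent is "unaligned",
and columns outside the query's first/last residue are "truncated".
Mapping is strictly monotone over mapped positions (property-tested).

Residue rules are evaluated pairwise against the reference, not on a
multiple alignment: every check the workflow performs is a per-sequence
question, and pairwise-to-reference keeps the mapping reproducible. AOS
tetrad rules are checked against the AOS domain slice (residues 1–373 of
the fusion reference) with its own semiglobal alignment; LOX rules against
the full-length reference.

The Coffa determinant's coordinate in fusion-reference numbering is not
published, so no biological default ships; it is a required configuration
value. The synthetic reference layout declares it at position 773 (an
arbitrary LOX-domain site clear of the other planted features).

## Classification thresholds

* `fusion_min` = 950 aa: full coral fusions run ~1037–1081 aa (soft-coral
  ones 1066–1067 aa) while a stand-alone LOX domain is ~700 aa; 950
  separates the regimes with margin on both sides. A genuinely truncated
  fusion below the cutoff (the 810-aa case) is reported as LOX — length
  plus tetrad mappability is the rule, and the note field carries the
  evidence. AOS-LOX and HPL-LOX fusions are not sequence-distinguishable
  and share the `AOS_LOX_fusion` label with a note.
* AOS tetrad mappability ≥ 3 of 4 (substitutions count as mappable;
  unaligned/truncated do not).
* Full-length: no truncated LOX rule check and alignment coverage ≥ 90 %
  of the relevant reference region (whole fusion for fusion calls, the
  LOX domain for LOX calls). Completeness is reported as `None` for
  COX-like / non-dioxygenase verdicts, where no LOX alignment defines it.
* COX screen: identity ≥ 30 % over ≥ 200 aligned pairs (classic
  twilight-zone convention), against a user-supplied COX reference.
* Identity clustering is single-linkage on the thresholded identity graph
  — a formalisation of reading "groups" off a tree; the tree itself is
  also produced.

Stereospecificity is always reported as "Coffa-predicted" and every report
row carries a caveat that verdicts are sequence-based predictions:
positional specificity (8- vs 11- vs 5-LOX) is *not* claimed, because
sequence analysis cannot establish it.

## Trees

Neighbor joining on d = 100 − identity with the standard Q criterion;
ties broken deterministically by lowest label-index pair; negative branch
lengths clamped to zero (never triggered by additive input). On additive
matrices NJ recovers topology and branch lengths exactly; the tests verify
this against a least-squares topology-fitting oracle over all fifteen
5-taxon topologies and against scikit-bio's independent NJ. The linear
distance transform is deliberate — the workflow's trees are identity
summaries, not evolutionary-model estimates — and maximum-likelihood
inference is out of scope. Clade-level statements are the only claims the
trees support.

## Peak assignment

Candidates must pass every gate both sides carry (|Δrt| ≤ 0.2 min,
|Δm/z| ≤ 0.05); among them the match with more shared fields wins, then
the smallest tolerance-normalised mean distance. The tolerances preserve
the printed separations: HETE isomers sit 0.2 min apart and m/z anchors
are printed to one decimal. Two ambiguity rules follow from the anchor
table: same-m/z candidates whose rt also falls inside tolerance (the HETE
isomers) are listed as alternatives, and an m/z-only winner that shares
its m/z with another reference (PGD2 vs PGE2) is always flagged. The
conversion rate is defined as the product-area fraction of total radio
area — "fraction of substrate consumed" would be indistinguishable on a
single chromatogram and is the documented alternative reading. Aldehydes
have no printed anchors and are excluded from the default table. The EDTA
incubation condition is carried as metadata only; no inhibition model is
applied.

## Synthetic data

The generator's defaults define the study conditions:

* Reference layout: 1066 aa; WLLAK at 737 (core 330 aa), iron ligands
  757/762/943/947, terminal Ile1066, PNGTAI ending at 1066, YRDD at 900,
  HAAVN at 960, AOS tetrad 66/67/349/353, Coffa site 773.
* Class mix 30 % fusion / 25 % full LOX / 25 % partial / 10 % COX-like /
  10 % decoy; background divergence 10 % per non-planted site (pure
  substitutions); Coffa residue drawn 60 % Gly, 30 % Ala, 10 % the
  observed indeterminate variants (Ile/Phe/Val).
* Partial cores span the WLLAK anchor to the C-terminus with up to 10
  upstream residues (330–340 aa) — the retained-partial regime; shorter
  C-terminal fragments would by construction lack the anchor and belong
  to the filtered-out class, so they are not emitted under a LOX label.
* COX-like sequences are 30 %-diverged copies of a synthetic COX
  reference (a random 600-aa protein; a stand-in, labelled synthetic,
  for a real COX record the user would normally supply); decoys are
  uniform random proteins of 300–900 aa.
* Background composition is uniform over the 20 amino acids. Planted
  features dominate every detection step, so compositional realism is
  not modelled.
* Peak tables jitter rt/m/z with centred Gaussian noise; metabolites
  without an anchored rt elute in a quiet mid-chromatogram window
  (10–15 min), between the prostaglandins and the HETEs.

What passing tests show: the decision cascade, mapping and assignment
logic are exactly correct on data satisfying their assumptions, at the
noise levels stated. What they do not show: robustness to indels and
alignment ambiguity in deeply diverged real sequences, to chimeric or
frameshifted assemblies, to motif spelling drift beyond one mismatch, or
to chromatographic drift beyond the stated jitter. Mutation specs that
alter signature components (e.g. the terminal residue) change the correct
verdict itself; truth labels in that regime follow the planted class, not
the re-derived verdict, and such specs are meant for targeted tests only.

## Problem sizes and determinism

The default verification runs use 300–500 enumeration-checked alignment
pairs (length ≤ 8, where exhaustive enumeration is tractable), 200
additive trees of 4–8 taxa, a 200-sequence panel, and 1000 Monte-Carlo
peak draws — sizes at which every check is exact or tightly estimated
while the whole suite stays fast. All generators are seeded
(`numpy.random.SeedSequence` derived); identical configs give
byte-identical outputs, and pipeline reports are byte-stable across
repeated runs (timestamps only ever appear in logs).
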