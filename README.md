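# corallox

Curation of coral dioxygenase sequences and eicosanoid LC-MS peaks.

Corals synthesise eicosanoids — oxygenated C20 fatty-acid signals — through
lipoxygenases (LOX) and through natural fusion proteins in which an
N-terminal catalase-related allene oxide synthase is fused to a C-terminal
8R-lipoxygenase (AOS-LOX). Deciding which transcripts or predicted proteins
in a coral sequence collection are genuine LOXs, which are AOS-LOX fusions,
and which are neither is done in practice with a small set of hard sequence
criteria rather than statistical models. `corallox` implements that curation
workflow as a tested, reusable library for sequence analysts working on
cnidarian (or other invertebrate) oxylipin biology, together with the
matching LC-MS peak-identification step used to confirm the enzymes'
products.

## What it computes

**Motif filter.** A candidate protein counts as LOX-like when it carries the
conserved catalytic-domain motifs — the WLLAK anchor (exact), YRDD and HAAVN
(≤ 1 mismatch) — a C-terminal motif (PNGTAI, with the PNSIAI spelling
variant also accepted) within the final 15 residues, and a terminal residue
in {Ile, Thr, Ser}. Partial sequences are trimmed from the WLLAK anchor to
the C-terminus (the ~330-aa core) before identity analyses.

**Reference-anchored residue rules.** Catalytic positions are numbered on a
full-length AOS-LOX fusion reference and mapped onto each query through a
global affine-gap alignment (BLOSUM62, gap open 10, extend 0.5; Biopython's
`PairwiseAligner`). The shipped rule table covers the LOX iron ligands
His757, His762, His943, Asn947 and the terminal Ile1066, and the AOS
catalytic tetrad Thr66, His67, Arg349, Tyr353 (AOS domain = residues 1–373
of the fusion). The single Gly/Ala "Coffa" determinant predicts R- versus
S-stereospecificity (Gly → R, Ala → S, anything else indeterminate); its
coordinate must be supplied by the caller, since it depends on the chosen
reference numbering.

**Classification cascade.** Signature-positive sequences ≥ 950 aa whose AOS
tetrad is mappable are AOS-LOX fusions; other signature-positive sequences
are LOX (full-length when the alignment covers ≥ 90 % of the relevant
reference region and no rule site is truncated, else partial). Sequences
without the signature are screened against a cyclooxygenase reference
(COX-like at ≥ 30 % identity over ≥ 200 aligned residues) and otherwise set
aside. "Predicted active" requires every iron ligand and the terminal
residue to match.

**Identity matrices and trees.** All-pairs percent identity (identical
columns / alignment columns) and neighbor joining on d = 100 − identity,
with Newick output (scikit-bio tree containers).

**Peak assignment and conversion.** Chromatographic peaks are identified
against printed eicosanoid anchors — arachidonic acid (19.9 min), 8-HETE
(17.2 min, m/z 319.2), 15-/11-/5-HETE (16.8/17.0/17.4 min, m/z 319.2),
α-ketol (335.2), cyclopentenone (317.2), PGF2α (6.9 min, 353.2), PGE2
(8.5 min, 351.2), PGD2 (351.2, no anchored rt) — with tolerances 0.2 min
and 0.05 m/z. Conversion rate = 100 × (radio peak area outside the
substrate window) / (total radio area).

A seeded synthetic-data generator (`corallox.synth`) emits reference
layouts, labelled sequence panels and jittered peak tables with planted
ground truth, so the whole pipeline is testable offline.

## Worked example

```python
import corallox as cx

cfg = cx.SynthConfig(seed=5, n_sequences=30)
records, truths = cx.generate_panel(cfg)
refs = cx.ReferenceSet(cx.make_pseudo_reference(cfg), cx.make_cox_reference(cfg))
rules = cx.default_rule_table(cfg.layout.coffa_pos)

verdict = cx.classify_sequence(cx.to_protein(records[0])[0], refs, rules)
print(verdict.architecture, verdict.completeness,
      verdict.stereospecificity, verdict.predicted_active)
# AOS_LOX_fusion full_length R True

radio = [cx.Peak(17.2, 53.0, "radio"), cx.Peak(19.9, 47.0, "radio")]
print(cx.conversion_rate(radio))   # 53.0
```

The first line is the cascade's verdict for a planted full-length fusion:
fusion architecture, complete coverage of the reference, R-stereospecific
(Gly at the determinant) and predicted catalytically competent. The second
is the conversion rate of a radiochromatogram in which a single product
peak at 17.2 min holds 53 % of the total labelled area. The scripts in
`examples/` walk through each capability (classification, core trimming +
trees, peak assignment, conversion rates, residue rules) and print what the
numbers mean; `corallox --help` exposes the same pipeline as `annotate`,
`tree`, `peaks` and `synth` subcommands.

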