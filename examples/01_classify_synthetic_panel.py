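"""Classify a synthetic coral dioxygenase panel against planted truth.

Generates 30 sequences with known labels (AOS-LOX fusions, stand-alone
LOX domains, WLLAK-to-C-terminus partial cores, COX-like decoys, and
unrelated proteins), runs the motif + catalytic-residue cascade, and
compares the verdicts with the generator's truth records.
"""

import corallox as cx

cfg = cx.SynthConfig(seed=5, n_sequences=30)
records, truths = cx.generate_panel(cfg)
refs = cx.ReferenceSet(cx.make_pseudo_reference(cfg), cx.make_cox_reference(cfg))
rules = cx.default_rule_table(cfg.layout.coffa_pos)

n_correct = 0
print(f"{'sequence':28s} {'verdict':16s} {'complete':12s} {'stereo':6s} active")
for rec, truth in zip(records, truths):
    c = cx.classify_sequence(cx.to_protein(rec)[0], refs, rules)
    ok = c.architecture == truth.architecture
    n_correct += ok
    print(
        f"{c.seq_id:28s} {c.architecture:16s} {str(c.completeness):12s} "
        f"{c.stereospecificity:6s} {c.predicted_active}"
    )

print(f"\narchitecture recovery: {n_correct}/{len(records)}")
print(
    "Every verdict is a sequence-based prediction: the architecture comes from\n"
    "motif evidence + length + AOS-tetrad mappability, stereo from the Coffa\n"
    "Gly/Ala determinant, and 'active' from iron-ligand/terminal conservation."
)
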