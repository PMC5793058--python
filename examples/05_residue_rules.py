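"""Map catalytic residues through an alignment and predict competence.

Plants a His757->Lys substitution and a C-terminal truncation into
copies of the reference and shows how the residue checks, the activity
prediction, and the Coffa stereochemistry call respond.
"""

import corallox as cx

cfg = cx.SynthConfig()
ref = cx.make_pseudo_reference(cfg)
rules = cx.default_rule_table(cfg.layout.coffa_pos)

mutant = ref.residues[:756] + "K" + ref.residues[757:]
truncated = ref.residues[:930]

for label, seq in [("reference", ref.residues), ("H757K", mutant), ("truncated@930", truncated)]:
    checks = cx.check_rules(seq, ref, rules)
    active, failures = cx.predict_activity(checks)
    coffa = next(c for c in checks if c.rule.role == "coffa")
    print(f"{label:14s} active={active!s:5s} stereo={cx.coffa_call(coffa):13s} "
          f"failures={failures or '-'}")

print(
    "\nIron ligands His757/His762/His943/Asn947 plus the terminal Ile are\n"
    "required for the activity prediction; positions beyond a truncation\n"
    "are reported as 'truncated' rather than guessed."
)
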