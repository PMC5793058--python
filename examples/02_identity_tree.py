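"""Build an identity matrix and neighbor-joining tree over trimmed cores.

Partial lipoxygenase sequences are trimmed from the conserved WLLAK
anchor to the C-terminus (the ~330-aa catalytic core), aligned all
against all, and summarised as a percent-identity matrix and an NJ tree
on d = 100 - identity.
"""

import corallox as cx

cfg = cx.SynthConfig(
    seed=9,
    n_sequences=8,
    class_mix={"AOS_LOX_fusion": 0.5, "LOX_partial": 0.5},
)
records, _ = cx.generate_panel(cfg)

cores = []
for rec in records:
    cand = cx.to_protein(rec)[0]
    core = cx.trim_core(cand)
    cores.append(cx.ProteinCandidate(rec.id, core.residues, "as_is"))
    print(f"{rec.id:28s} core {core.span[0]:4d}..{core.span[1]} ({core.length} aa)")

m = cx.identity_matrix(cores)
lo, hi = m.off_diagonal_range()
print(f"\npairwise identity range over cores: {lo:.1f}-{hi:.1f}%")

tree = cx.nj_tree(m)
print("\nNJ tree (Newick):")
print(cx.write_newick(tree))
print(
    "\nBranch lengths are in identity-distance units (100 - %identity).\n"
    "All cores here derive from one reference layout at a uniform background\n"
    "divergence, so the tree is near-star-like; real panels with distinct\n"
    "lineages produce the clade structure the identity blocks imply."
)
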