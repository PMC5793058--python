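seq_id	architecture	completeness	coffa_predicted_stereo	predicted_active	failed_rules	notes	status	caveat
syn0001_AOS_LOX_fusion	AOS_LOX_fusion	full_length	S	True		anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0002_AOS_LOX_fusion	AOS_LOX_fusion	full_length	S	True		anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0003_AOS_LOX_fusion	AOS_LOX_fusion	full_length	indeterminate	True	coffa@773:I	anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label|substitution coffa@773: expected {A,G}, observed I	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0004_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True		anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0005_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True		anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0006_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True		anchor WLLAK at 737-741 (0 mm)|C-terminal motif 'PNGTAI' at 1061-1066 (0 mm)|terminal residue I in allowed set|fusion architecture; AOS-LOX and HPL-LOX are not sequence-distinguishable and share this label	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0007_LOX_full	LOX	full_length	S	True		anchor WLLAK at 364-368 (0 mm)|C-terminal motif 'PNGTAI' at 688-693 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0008_LOX_full	LOX	full_length	indeterminate	True	coffa@773:V	anchor WLLAK at 364-368 (0 mm)|C-terminal motif 'PNGTAI' at 688-693 (0 mm)|terminal residue I in allowed set|substitution coffa@773: expected {A,G}, observed V	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0009_LOX_full	LOX	full_length	S	True		anchor WLLAK at 364-368 (0 mm)|C-terminal motif 'PNGTAI' at 688-693 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0010_LOX_full	LOX	full_length	S	True		anchor WLLAK at 364-368 (0 mm)|C-terminal motif 'PNGTAI' at 688-693 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0011_LOX_full	LOX	full_length	R	True		anchor WLLAK at 364-368 (0 mm)|C-terminal motif 'PNGTAI' at 688-693 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0012_LOX_partial	LOX	partial	S	True		anchor WLLAK at 6-10 (0 mm)|C-terminal motif 'PNGTAI' at 330-335 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0013_LOX_partial	LOX	partial	R	True		anchor WLLAK at 1-5 (0 mm)|C-terminal motif 'PNGTAI' at 325-330 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0014_LOX_partial	LOX	partial	S	True		anchor WLLAK at 8-12 (0 mm)|C-terminal motif 'PNGTAI' at 332-337 (0 mm)|terminal residue I in allowed set	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0015_LOX_partial	LOX	partial	indeterminate	True	coffa@773:V	anchor WLLAK at 3-7 (0 mm)|C-terminal motif 'PNGTAI' at 327-332 (0 mm)|terminal residue I in allowed set|substitution coffa@773: expected {A,G}, observed V	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0016_LOX_partial	LOX	partial	indeterminate	True	coffa@773:F	anchor WLLAK at 7-11 (0 mm)|C-terminal motif 'PNGTAI' at 331-336 (0 mm)|terminal residue I in allowed set|substitution coffa@773: expected {A,G}, observed F	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0017_COX_like	COX_like	NA	indeterminate	False		COX screen identity 72.3% over aligned pairs	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0018_COX_like	COX_like	NA	indeterminate	False		COX screen identity 70.2% over aligned pairs	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0019_decoy	non_dioxygenase	NA	indeterminate	False		no LOX motif signature; no COX similarity	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
syn0020_decoy	non_dioxygenase	NA	indeterminate	False		no LOX motif signature; no COX similarity	ok	sequence-based prediction only; catalytic activity and positional specificity require expression and product analysis
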