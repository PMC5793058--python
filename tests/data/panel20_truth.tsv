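seq_id	architecture	completeness	stereospecificity	predicted_active	substitutions
syn0001_AOS_LOX_fusion	AOS_LOX_fusion	full_length	S	True	
syn0002_AOS_LOX_fusion	AOS_LOX_fusion	full_length	S	True	
syn0003_AOS_LOX_fusion	AOS_LOX_fusion	full_length	indeterminate	True	
syn0004_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True	
syn0005_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True	
syn0006_AOS_LOX_fusion	AOS_LOX_fusion	full_length	R	True	
syn0007_LOX_full	LOX	full_length	S	True	
syn0008_LOX_full	LOX	full_length	indeterminate	True	
syn0009_LOX_full	LOX	full_length	S	True	
syn0010_LOX_full	LOX	full_length	S	True	
syn0011_LOX_full	LOX	full_length	R	True	
syn0012_LOX_partial	LOX	partial	S	True	
syn0013_LOX_partial	LOX	partial	R	True	
syn0014_LOX_partial	LOX	partial	S	True	
syn0015_LOX_partial	LOX	partial	indeterminate	True	
syn0016_LOX_partial	LOX	partial	indeterminate	True	
syn0017_COX_like	COX_like		indeterminate	False	
syn0018_COX_like	COX_like		indeterminate	False	
syn0019_decoy	non_dioxygenase		indeterminate	False	
syn0020_decoy	non_dioxygenase		indeterminate	False	
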