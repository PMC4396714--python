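synonymy	%also%known%as%	symmetric
synonymy	(	symmetric
synonymy	aka	symmetric
synonymy	so called	symmetric
synonymy	also called	symmetric
synonymy	%also% referred% to%	symmetric
synonymy	%referred% to%	symmetric
hierarchy	%such%as%	np1_parent
hierarchy	%or other%	np2_parent
hierarchy	%and other%	np2_parent
hierarchy	%including%	np1_parent
hierarchy	%associated with	np2_parent
hierarchy	is	np2_parent
hierarchy	are	np2_parent
hierarchy	%type of%	np2_parent
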