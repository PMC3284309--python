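>FxFG yeast nucleoporin Nsp1p fragment (residues 375-479)
SKPAFSFGAKPDENKASATSKPAFSFGAKPEEKKDDNSSKPAFSFGAKSN
EDKQDGTAKPAFSFGAKPAEKNNNETSKPAFSFGAKSDEKKDGDASKPAF
SFGAK
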