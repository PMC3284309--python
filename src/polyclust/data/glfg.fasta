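>GLFG yeast nucleoporin Nup116p fragment (residues 346-457)
GSRRASVGSGALFGAKPASGGLFGQSAGSKAFGMNTNPTGTTGGLFGQTN
QQQSGGGLFGQQQNSNAGGLFGQNNQSQNQSGLFGQQNSSNAFGQPQQQG
GLFGSKPAGGLFGQQQGASY
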