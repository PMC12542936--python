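"""Physical constants (SI)."""

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m
KB = 1.380649e-23        # Boltzmann constant, J/K
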