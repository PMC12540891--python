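"""Physical constants and CO2 reference properties.

All internal computation is SI (Pa, K, m3, mol); MPa, bar and g/L appear
only at I/O boundaries.
"""

R = 8.314462618  # gas constant, J/(mol K)
K_B = 1.380649e-23  # Boltzmann constant, J/K
N_A = 6.02214076e23  # Avogadro constant, 1/mol

MW_CO2 = 44.01  # g/mol

# CO2 critical point; the acentric factor is a standard literature value
# (not printed in the solubility source data).
CO2_TC = 304.1  # K
CO2_PC = 7.38e6  # Pa
CO2_OMEGA = 0.225

MPA = 1.0e6  # Pa per MPa
BAR = 1.0e5  # Pa per bar
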