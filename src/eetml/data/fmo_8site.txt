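# Eight-site Frenkel exciton Hamiltonian of the FMO monomer (cm^-1).
# Site energies and couplings after Schmidt am Busch et al.,
# J. Phys. Chem. Lett. 2, 93 (2011), as tabulated in the 8-site FMO
# literature; energies offset to absolute wavenumbers.  Pigment 8 is the
# donor near the chlorosome baseplate, pigment 3 the acceptor coupling to
# the reaction center.
12505.0   -97.9     5.5    -5.8     6.7   -12.1   -10.3    37.5
  -97.9 12425.0    30.1     7.3     2.0    11.5     4.8     7.9
    5.5    30.1 12195.0   -58.8    -1.5    -9.6     4.7     1.5
   -5.8     7.3   -58.8 12375.0   -64.9   -17.4   -64.4    -1.7
    6.7     2.0    -1.5   -64.9 12600.0    89.5    -6.4     4.5
  -12.1    11.5    -9.6   -17.4    89.5 12515.0    31.7    -9.7
  -10.3     4.8     4.7   -64.4    -6.4    31.7 12465.0     3.5
   37.5     7.9     1.5    -1.7     4.5    -9.7     3.5 12700.0
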