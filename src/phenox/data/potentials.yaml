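# Default electron tower of half-reactions relevant to anaerobic phenazine
# oxidation, at pH 7 vs. the standard hydrogen electrode (volts).
# Values are standard literature midpoint potentials; users may override
# any entry by loading their own table.
temperature_K: 298.15
reference_pH: 7.0
half_reactions:
  - name: PCA
    E0_prime: -0.116
    n_electrons: 2
    n_protons: 2
    oxidized_label: PCA_ox
    reduced_label: PCA_red
  - name: pyocyanin
    E0_prime: -0.040
    n_electrons: 2
    n_protons: 2
    oxidized_label: PYO_ox
    reduced_label: PYO_red
  - name: menaquinone
    E0_prime: -0.074
    n_electrons: 2
    n_protons: 2
    oxidized_label: MK
    reduced_label: MKH2
  - name: demethylmenaquinone
    E0_prime: 0.036
    n_electrons: 2
    n_protons: 2
    oxidized_label: DMK
    reduced_label: DMKH2
  - name: ubiquinone
    E0_prime: 0.100
    n_electrons: 2
    n_protons: 2
    oxidized_label: UQ
    reduced_label: UQH2
  - name: fumarate
    E0_prime: 0.033
    n_electrons: 2
    n_protons: 2
    oxidized_label: fumarate
    reduced_label: succinate
  - name: TMAO
    E0_prime: 0.130
    n_electrons: 2
    n_protons: 2
    oxidized_label: TMAO
    reduced_label: TMA
  - name: DMSO
    E0_prime: 0.160
    n_electrons: 2
    n_protons: 2
    oxidized_label: DMSO
    reduced_label: DMS
  - name: nitrate
    E0_prime: 0.433
    n_electrons: 2
    n_protons: 2
    oxidized_label: NO3-
    reduced_label: NO2-
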