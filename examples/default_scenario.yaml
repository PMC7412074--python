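# Default simulation scenario: a phalanx clonal population at the scale of
# the motivating survey (~240 genets, ~700 grid-sampled units, 8 loci).
# Every key mirrors a SimulationConfig field; omitted keys keep defaults.
seed: 0
arena: [50.0, 50.0]
allele_counts: [8, 5, 4, 7, 16, 11, 14, 8]
n_genets: 240
pareto_exponent: 1.1      # clone-size tail (true ramets per genet)
max_clone_size: 400
architecture: phalanx
sigma: 0.7                # ramet dispersal around the genet seed (m)
exclusion: 1.8            # minimum genet seed spacing (m)
mutation_rate: 0.0        # somatic mutations per allele copy
selfing_rate: 0.0
dirichlet_alpha: 1.0
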