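# One simulated deme with a recent hard selective sweep at the focal site.
# All analysis thresholds are at their canonical defaults (5 % frequency
# filter, 7-SNP cluster cut, 2-SNP network edge filter, 1 % core-group
# minimum, 200 kb EHH cap); override any of them here.

sim_n_pop = 100        # diploids -> 200 haplotypes
sim_n_sites = 300      # site lattice at 200 bp spacing (~60 kb span)
sim_generations = 60
sim_s = 0.2            # selection coefficient of the focal allele
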