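"""AMOVA, pairwise F_ST, S_nn and PCoA on a synthetic study.

Hierarchical variance partition over taxa / populations / samples, with
permutation significance, plus the nearest-neighbour statistic and the
principal-coordinate view of population distances.
"""

import numpy as np

from pinepop.differentiation import amova, pairwise_difference_matrix, pcoa, snn
from pinepop.divergence import concatenated_snp_matrix, jc_population_distance
from pinepop.synthetic import StudyScenario, generate_study

study, _ = generate_study(StudyScenario(n_loci=15, n_mtdna=0), seed=21)
samples = study.samples.sample_ids
mat = concatenated_snp_matrix(
    [study.alignments[l] for l in study.nuclear_ids], samples)
D = pairwise_difference_matrix(mat)
pops = np.array([study.samples[s].population for s in samples])
taxa = np.array([study.samples[s].taxon for s in samples])

res = amova(D, pops, taxa, permutations=300, seed=22)
print("AMOVA variance partition (% of total):")
for k, v in res.percentages.items():
    print(f"  {k:28s} {v:6.1f}%")
print(f"  Phi_ST = {res.phi['phi_st']:.3f} (p = {res.p_values['phi_st']:.3f})")

sr = snn(D, taxa, permutations=300, seed=23)
print(f"S_nn over taxa = {sr.snn:.3f} (p = {sr.p_value:.3f}); 1 means every "
      "sample's nearest neighbours are conspecific, ~1/3 means no signal.")

jc = jc_population_distance(
    [study.alignments[l] for l in study.nuclear_ids], study.populations())
pc = pcoa(jc.to_numpy())
print(f"PCoA of JC net population distances: axis 1 = "
      f"{pc.pct_variance[0]:.0f}%, axis 2 = {pc.pct_variance[1]:.0f}% of "
      "the positive-eigenvalue variance.")
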