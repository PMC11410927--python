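"""Windowed diversity statistics (pi, Watterson's theta, Tajima's D) on a neutral window.

Simulates a neutral coalescent window and prints the three estimators. Under
neutrality both pi and theta_W estimate the scaled mutation rate theta, and
Tajima's D (their standardised difference) should sit near zero; a strongly
negative D would indicate an excess of rare alleles, as after a sweep.
"""

from vectorpop.diversity import nucleotide_diversity, tajimas_d, watterson_theta
from vectorpop.simulate import NeutralWindowSpec, simulate_coalescent_window

theta = 10.0
hm = simulate_coalescent_window(NeutralWindowSpec(n_haplotypes=20, theta=theta, seed=7))
print(f"simulated window: {hm.n_sites} segregating sites, {hm.n_haplotypes} haplotypes")
print(f"pi        = {nucleotide_diversity(hm):.3f}   (estimates theta = {theta})")
print(f"theta_W   = {watterson_theta(hm):.3f}   (estimates theta = {theta})")
print(f"Tajima D  = {tajimas_d(hm):+.3f}   (near 0 under neutrality)")
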