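"""Windowed Hudson F_ST recovers the Balding–Nichols differentiation parameter.

Simulates two demes at F = 0.10 and estimates F_ST over one 5000-SNP window:
the ratio-of-averages Hudson estimator should land close to the simulated F.
"""

from vectorpop.fst import fst_scan
from vectorpop.simulate import DemeSpec, simulate_demes

F = 0.10
gm, _, part = simulate_demes(DemeSpec(deme_sizes=[50, 50], F=F, n_snps=5000, seed=12))
(res,) = fst_scan(gm, part, ("deme0", "deme1"), window_size_snps=5000, step=5000)
print(f"simulated F = {F};  Hudson F_ST estimate = {res.fst:.4f} over {res.n_snps} SNPs")
print("the estimate recovers the simulated differentiation (E[F_ST] = F)")
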