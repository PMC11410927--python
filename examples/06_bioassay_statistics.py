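"""WHO tube-bioassay statistics: Abbott correction, Wilson CIs, classification, GLM.

Summarises simulated bioassay counts (one site engineered more resistant) and
fits the binomial GLM comparing sites and insecticides, printing per-term Wald
chi-square tests.
"""

from vectorpop.bioassay import fit_binomial_glm, proportion_summary, summarize_bioassay
from vectorpop.simulate import BioassaySimSpec, simulate_bioassay

spec = BioassaySimSpec(
    sites=["Kimpese", "Mikalayi"],
    insecticides=["deltamethrin 0.05%", "permethrin 0.75%"],
    intercept=1.8,
    site_effects={"Kimpese": -1.5},  # lower mortality = stronger resistance
    n_exposed=100,
)
records = simulate_bioassay(spec, seed=4)
for s in summarize_bioassay(records):
    print(f"{s.site:<9} {s.insecticide:<20} mortality {s.percent_mortality:5.1f}% "
          f"[{s.ci_low:.1f}, {s.ci_high:.1f}]  -> {s.status}")

fit = fit_binomial_glm(records, design="site + insecticide")
for term in fit.wald_chi2:
    print(f"GLM term {term:<12} Wald chi2 = {fit.wald_chi2[term]:7.2f}, "
          f"df = {fit.df[term]}, p = {fit.p_values[term]:.3g}")

pct, (lo, hi) = proportion_summary(730, 866)
print(f"field-collection proportion example: {pct}% blood-fed (95% CI {lo}-{hi})")
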