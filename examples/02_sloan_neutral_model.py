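"""Fit Sloan's neutral community model and the Preston log-normal SAD.

Simulates a neutral metacommunity (Dirichlet-multinomial with Nm = 1000
at 2000 reads per sample, i.e. a true migration rate m = 0.5), fits the
neutral model to occurrence frequency vs mean relative abundance, and
fits the log-normal species-abundance distribution with a geometric
comparator for AIC model selection.
"""

from phyloassembly import (
    fit_geometric_sad,
    fit_lognormal_sad,
    fit_ncm,
    simulate_scenario,
)

scen = simulate_scenario("neutral", seed=8, n_taxa=500, n_samples=40, reads=2000)
fit = fit_ncm(scen.table)

print(f"migration rate m = {fit.m:.3f} (true value 0.5)")
print(f"generalized R^2  = {fit.r2:.3f}  (> 0.2 reads as a neutral signal)")
print(f"community size N = {fit.N:.0f} reads, detection threshold d = {fit.d:.2e}")
print("OTUs vs the 95% neutral band:", fit.partition_counts.to_dict())

pooled = scen.table.data.sum(axis=1).to_numpy()
ln = fit_lognormal_sad(pooled)
geo = fit_geometric_sad(pooled)
print(f"\nPreston log-normal fit: S0 = {ln.S0:.1f} species at the modal octave, "
      f"a = {ln.a:.3f} (width 1/a = {1 / ln.a:.2f} octaves)")
print(f"AIC log-normal {ln.aic:.1f} vs geometric {geo.aic:.1f} "
      f"-> {'log-normal' if ln.aic < geo.aic else 'geometric'} preferred")
print(
    "\nA near-0.5 m, high R^2 and a log-normal SAD win are exactly what a\n"
    "neutrally assembled community should produce."
)
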