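"""Fit cooperative and non-cooperative binding isotherms.

Generates a noisy anisotropy titration of a specific DNA probe (three
binding motifs, cooperative: K_D = 68 nM, Hill n = 3) and a non-specific
probe (single-site, K_D = 165 nM), fits both with the Hill model, and
prints the recovered constants.
"""

import insulator_bridge as ib

# specific probe: cooperative binding, large anisotropy amplitude
specific = ib.gen_isotherm(kd=68.0, n=3.0, r_free=100.0, delta_r=32.0,
                           sigma=1.5, seed=42, label="DNA with binding motifs")
# non-specific probe: single-site, smaller amplitude
nonspecific = ib.gen_isotherm(kd=165.0, n=1.0, r_free=100.0, delta_r=12.0,
                              sigma=1.5, seed=43, label="scrambled DNA")

for iso in (specific, nonspecific):
    fit = ib.fit_isotherm(iso, model="hill")
    print(f"{iso.label}:")
    print(f"  K_D = {fit.kd:6.1f} +/- {fit.kd_se:.1f} nM"
          f"   Hill n = {fit.hill_n:.2f} +/- {fit.n_se:.2f}"
          f"   delta_r = {fit.delta_r:.1f} units")

print()
print("A Hill coefficient well above 1 indicates cooperative, multimeric")
print("binding to the motif-bearing probe; on the scrambled probe the")
print("coefficient is consistent with 1 (within its standard error), i.e.")
print("independent, non-cooperative association.  Single noisy titrations")
print("scatter around the generating values (K_D 68/165 nM, n 3/1).")
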