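"""Anchor-to-target Hi-C aggregation with a feature-free control.

Simulates a distance-decaying contact map over a 2 Mb chromosome with a
3x contact enrichment between anchor-factor bins and co-bound target
bins at 15-60 kb separations, then recovers that enrichment with the
aggregation-profile analysis.
"""

import numpy as np

import insulator_bridge as ib
from insulator_bridge import hic

cfg = ib.HicSimConfig(seed=3, enrichment=3.0)
contacts, peaks = ib.gen_contact_map(cfg)
print(f"contact map: {len(contacts)} non-empty bin pairs, "
      f"{sum(len(p) for p in peaks.values())} peaks")

targets = hic.factor_bound_sites(contacts, [peaks["CP190"], peaks["Chromator"]],
                                 mode="all")
controls = hic.feature_free_sites(contacts, list(peaks.values()), stride=4)
profile = hic.build_aggregation(peaks["BEAF32"], targets, contacts,
                                control_targets=controls)

i0 = int(np.where(profile.offsets == 0)[0][0])
ratio = profile.signal[i0] / profile.control[i0]
print(f"{profile.n_pairs} anchor/target pairs at 15-60 kb "
      f"({profile.n_pairs_control} control pairs)")
print(f"central signal = {profile.signal[i0]:.3f}, "
      f"control = {profile.control[i0]:.3f}, ratio = {ratio:.2f}")
print(f"Wilcoxon two-sided p = {profile.p_value:.2e}")
print()
print("The profile is flat except at offset 0 (the target bin itself):")
for off, s, c in zip(profile.offsets, profile.signal, profile.control):
    bar = "#" * int(round(40 * s / profile.signal[i0]))
    print(f"  {off:+6d} bp  {s:6.3f}  {bar}")
print()
print("A central ratio near the simulated 3x with a small p-value means the")
print("co-bound target bins interact with the anchors above the background")
print("expected from their genomic distance alone.")
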