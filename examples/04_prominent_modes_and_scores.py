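"""Windowed analysis: prominent modes, hotspots, and residue scores.

A 20-window series emulates the fluctuating per-window networks of a long
trajectory; one dominant, persistent edge is planted so the expected answer
is known.  Prominent modes must be both strong (above the Tukey fence of
the strength distribution) and persistent (averaged content in the top
quartile); their heavily weighted residues are the mechanical hotspots.
"""

import rigiditygraph as rg
from rigiditygraph import spectral
from rigiditygraph.scores import residue_score_table

ref = rg.make_reference_enm(n_residues=30, seed=11)
series = rg.make_window_series(ref, n_windows=20, perturbation=0.3, seed=2)
print(f"planted edge between residues "
      f"{tuple(r + 1 for r in series.planted_residues)} "
      f"at k = {series.planted_k:.1f} kcal/mol/A^2")

stats = spectral.mean_mode_content(series.window_graphs(), "K")
prom = spectral.select_prominent_modes(stats, content_quantile=0.75)
print(f"\nprominent modes (of {stats.spectrum.n}):")
for a in prom.modes:
    print(f"  mode {a + 1}: strength {stats.strengths[a]:7.1f}, "
          f"content {stats.mean_contents[a]:.3f}, "
          f"hotspots {[r + 1 for r in prom.hotspots[a]]}")

tab = residue_score_table(series.models)
hot = tab[tab.hotspot].sort_values("kappa_B", ascending=False)
print("\nhotspot residues and their rigidity scores:")
print(hot[["residue", "resname", "kappa_B", "kappa_S"]]
      .to_string(index=False))
print()
print("kappa_B / kappa_S are strength x persistence of the mode each")
print("residue's backbone / side chain carries; the planted pair tops the")
print("table because its coupling is both strong and present in every")
print("window.")
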