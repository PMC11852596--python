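"""Population length statistics of a simulated collagen-monomer study.

Runs the full pipeline on 10 synthetic images, pools the per-molecule
lengths, and reports the distribution mode ("length pattern"), the fraction
inside the 280-320 nm window around the monomer's 300 nm theoretical
contour, and the recovery error against ground truth.
"""

from colmorph import (FilamentSpec, ImageSpec, analyze_dataset,
                      collagen_analysis_params, generate_dataset)
from colmorph.morphometry import plot_distribution

dataset = generate_dataset(FilamentSpec(), ImageSpec(), n_images=10, seed=42)
result = analyze_dataset(dataset, params=collagen_analysis_params())

d = result.distribution
print(f"flag-free molecules:   {d.n_molecules} ({result.n_flagged} excluded by QC)")
print(f"length mode (KDE):     {d.mode:.1f} nm   <- the 'length pattern'")
print(f"mean +/- sd:           {d.mean:.1f} +/- {d.sd:.1f} nm")
print(f"fraction in 280-320:   {d.window_fraction:.2f}")
print(f"recovery vs truth:     bias {result.recovery.bias:+.2f} nm, "
      f"RMSE {result.recovery.rmse:.2f} nm, "
      f"match rate {result.recovery.match_rate:.2f}")
print()
print("A mode near 300 nm with a high in-window fraction means the pipeline")
print("recovers the generative contour length of the simulated monomers.")

plot_distribution(d, "length_distribution.png")
print("histogram saved to length_distribution.png")
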