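"""Generate a small licensing ChIP experiment and quantify origin signal.

Builds a toy genome with a known origin map, samples MNase ChIP and input
fragments, runs the depletion-workflow normalization chain (CPM ->
non-origin background -> input subtraction) and prints per-origin MCM
signal in 1 kb windows. With background normalization the genome-wide
non-origin level is exactly 1, so origin signals read as fold enrichment
summed over the window's 25 bp bins.
"""

import numpy as np

from mcmkit.chipquant import quantify_origin_signal, top_fraction_origins
from mcmkit.coverage import (
    fragments_to_coverage,
    normalize_background,
    normalize_cpm,
    subtract_input,
)
from mcmkit.genome import toy_genome
from mcmkit.simulate import (
    generate_origin_map,
    sample_chip_fragments,
    sample_input_and_spikein,
)

genome = toy_genome(n_chromosomes=2, spikein_length=0)
origins = generate_origin_map(genome, origins_per_chromosome=8, seed=42)

chip = sample_chip_fragments(origins, genome, n_fragments=200_000,
                             digestion_level=0.8, background_fraction=0.3, seed=1)
inp = sample_input_and_spikein(genome, n_input=200_000, n_spikein=0, seed=2)

chip_track = normalize_background(
    normalize_cpm(fragments_to_coverage(chip, 25, genome)), origins
)
input_track = normalize_background(
    normalize_cpm(fragments_to_coverage(inp, 25, genome)), origins
)
net = subtract_input(chip_track, input_track)

signals = quantify_origin_signal(net, origins, window=1_000)
merged = origins[["name", "occupancy"]].merge(signals, on="name")
print(merged.to_string(index=False, float_format=lambda x: f"{x:8.1f}"))

r = np.corrcoef(merged["occupancy"], merged["signal"])[0, 1]
print(f"\ncorrelation(signal, true occupancy) = {r:.3f}")
top, k = top_fraction_origins(signals, fraction=0.5)
print(f"origins holding 50% of total MCM signal: {k} of {len(origins)}")
print("-> normalized window signal tracks the ground-truth number of "
      "loaded MCM double hexamers per origin.")
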