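"""How many neurons can combinatorial 7-colour labelling tell apart?

Simulates cells that each receive Poisson(2) copies of every fluorescent
protein, normalizes the expression profiles into colour vectors, and asks
two questions at a hue-distance threshold Th(d) = 0.2: what fraction of
cell *pairs* are discriminable, and what fraction of cells in a cohort are
*uniquely* labelled (no neighbour within Th(d) — the birthday problem).
"""

from qdyefinder import (
    LabelModel,
    percent_discriminable,
    percent_unique,
    simulate_cells,
)

TH_D = 0.2

for n_channels in (3, 7):
    model = LabelModel(n_channels=n_channels, mean_copies=2.0)
    cells = simulate_cells(model, 10_000, rng=1)
    pct, _, _ = percent_discriminable(cells, TH_D)
    print(f"{n_channels} channels: {pct:.1f}% of pairs discriminable")

model7 = LabelModel(n_channels=7, mean_copies=2.0)
for n_cells in (100, 200):
    mean, sd = percent_unique(model7, n_cells, TH_D, n_sims=200, rng=2)
    print(f"7 channels, {n_cells} cells: {mean:.1f}% +/- {sd:.1f}% uniquely labelled")

# With 3 colours only ~93% of pairs separate; with 7 colours virtually all
# do (>99.9%).  Uniqueness is harder: even at 7 colours, crowding a cohort
# from 100 to 200 cells costs ~7 points of uniqueness.
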