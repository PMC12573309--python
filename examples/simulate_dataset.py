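"""Generate a synthetic paired longitudinal dataset and inspect its shape.

A single dynamic latent variable per component drives both views; visits are
then removed at random so the two views end up on different, irregular
per-individual time grids.  Here we use a reduced feature count so the script
runs in seconds; drop the n/p/q overrides for the full-size defaults.
"""

from tosccamm import SimulationConfig, generate

config = SimulationConfig(n=60, p=300, q=60, seed=7)
dataset = generate(config)

x, y = dataset.data.x_view, dataset.data.y_view
print(f"X view: {x.n_rows} visit rows x {x.n_features} features")
print(f"Y view: {y.n_rows} visit rows x {y.n_features} features")
print(f"individuals: {len(dataset.data.individuals)}, full grid t = 1..{config.n_times}")
print(f"removed visits: X {60 * 10 - x.n_rows} (20%), Y {60 * 10 - y.n_rows} (30%)")

ex = dataset.data.individuals[0]
tx, _ = x.block(ex)
ty, _ = y.block(ex)
print(f"individual {ex}: X visits at t={[int(t) for t in tx]}, "
      f"Y visits at t={[int(t) for t in ty]}")
print("(the two views need not share a time grid; the model bridges them)")
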