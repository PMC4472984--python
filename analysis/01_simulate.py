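"""Generate the synthetic Cq tables used by the downstream analysis steps.

Two tables of the published 19-gene × 2-cultivar × 2-tissue × 2-treatment ×
2-timepoint × 3-replicate design are written: a noiseless one (programmed
truth passes through exactly) and one with 0.25-cycle Gaussian Cq noise
(realistic biological replicate scatter).
"""

from pathlib import Path

from drqpcr.synthetic_data import paper_scenario, simulate_cq

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for noise, name in ((0.0, "simulated_cq_zero_noise.csv"), (0.25, "simulated_cq.csv")):
    spec = paper_scenario(noise_sd=noise, seed=2015)
    table = simulate_cq(spec)
    table.write_csv(OUT / name)
    print(f"wrote {OUT / name}: {len(table)} rows, noise_sd={noise}")

spec = paper_scenario(noise_sd=0.25, seed=2015)
spec.to_yaml(OUT / "scenario.yaml")
print(f"wrote {OUT / 'scenario.yaml'} ({len(spec.genes)} genes, "
      f"{len(spec.placeholder_cells)} placeholder truth cells)")
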