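"""Simulate a small circle treatment study with a known causal locus.

Each individual is a white disc growing over 6 time points; treatment slows
growth, and under treatment the growth rate also depends on 7 Bernoulli QTL
and the minor-allele count at one causal SNP. The script writes the PNG +
manifest layout, the genotype table and the ground-truth CSV, then prints
what the treatment did to final sizes.
"""

import numpy as np

from lspheno import CircleConfig, generate_circle_dataset, generate_genotypes, write_synthetic_run

config = CircleConfig(n_per_condition=20, image_size=64, seed=7)
genotypes = generate_genotypes(20, n_snps=100, causal_index=42, seed=11)
dataset, truth = generate_circle_dataset(config, genotypes)
info = write_synthetic_run(dataset, truth, "example_output/circles")

df = truth.per_individual
print(f"wrote {len(dataset.samples)} individuals x {config.n_timepoints} timepoints -> {info['manifest']}")
for cond in ("control", "treated"):
    rates = df[df.condition == cond]["rate"]
    print(f"  {cond:8s} growth rate: mean {rates.mean():.2f} px/timepoint (sd {rates.std():.2f})")
carriers = df[(df.condition == "treated") & (df.causal_count > 0)]["rate"].mean()
noncarr = df[(df.condition == "treated") & (df.causal_count == 0)]["rate"].mean()
print(f"  causal-allele carriers grow {carriers - noncarr:+.2f} px/timepoint faster under treatment")
print("The treated mean is lower by construction; the carrier gap is the genetic signal")
print("the full pipeline should recover from the images alone.")
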