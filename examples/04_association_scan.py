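"""End-to-end causal-locus recovery on the synthetic circle study.

Runs the full benchmark: simulate genotypes + images, train both networks,
compute cross-sectional geodesic traits (treated vs control final time point
per genotype), and scan the SNP panel by per-marker regression with a
Bonferroni p < 0.01 threshold. Prints the report and writes a Manhattan plot.
"""

import json

from lspheno import CircleConfig, run_synthetic_benchmark
from lspheno.decoder import DecoderConfig
from lspheno.embedding import EmbeddingConfig

# a compact 32x32 scenario with a strong causal allele (half-scale circle
# geometry; the causal effect dominates the polygenic background)
report = run_synthetic_benchmark(
    "example_output/benchmark",
    seed=1,
    circle=CircleConfig(
        n_per_condition=60, image_size=32,
        d0_mean=5.0, d0_sd=0.75,
        rate_mean_control=3.5, rate_mean_treated=2.0, rate_sd=0.5,
        qtl_effect=0.05, causal_effect=1.0,
    ),
    n_snps=500,
)
print(json.dumps(report, indent=2))
print("causal_recovered: the planted SNP passed Bonferroni; false_positives: spurious hits.")
print("R: correlation of the longitudinal trait with relative white-pixel growth.")
print("Manhattan plot -> example_output/benchmark/manhattan.png")
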