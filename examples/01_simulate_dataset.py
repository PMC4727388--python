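"""Simulate a temperature-shift gonadal expression dataset.

Eggs incubate at the female-producing temperature (FPT) until Day 0;
a subset then shifts to the male-producing temperature (MPT).  The
generator plants four gene classes (development-dependent,
sex-dependent, immediate temperature-responsive, and combined) on top
of log-normal replicate noise, and returns the ground truth alongside
the FPKM-like matrix.
"""

from tsdnet import SimulationConfig, generate_expression_dataset

config = SimulationConfig(
    n_genes=500,
    frac_development=0.05,
    frac_sex=0.05,
    frac_temperature=0.05,
    frac_candidate_both=0.05,
    effect_size_log2=2.0,   # planted 4-fold changes
    noise_sd=0.25,          # log2-scale replicate noise
    seed=1,
)
matrix, truth = generate_expression_dataset(config)

print(f"matrix: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} samples")
print("samples per (condition, day):")
print(matrix.samples.groupby(["condition", "day"]).size().to_string())
classes = {}
for cls in ("null", "development_dependent", "sex_dependent",
            "temperature_responsive", "candidate_both"):
    classes[cls] = len(truth.genes_of_class(cls))
print("planted classes:", classes)
# Day 0 exists only in the FPT arm (it is the shared pre-shift baseline),
# Days 0-12 are triplicate and testable, Days 18-36 descriptive singletons.
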