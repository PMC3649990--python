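"""Generate a synthetic prognosis cohort and inspect its planted structure.

The generator emulates a breast-cancer cohort: latent subtype drives the
ER/PR/HER2 markers and expression centroids, a per-sample instability latent
drives copy-number aberration burden, and survival follows a
proportional-hazards model over clinical, genomic-instability and planted
gene-module effects.
"""

from survbench import GeneratorConfig, generate_cohort, genomic_instability_index

config = GeneratorConfig(n_samples=300, n_genes=600, seed=7)
cohort = generate_cohort(config)

print(f"samples: {len(cohort.samples)}  "
      f"(train {len(cohort.train_samples)} / validation {len(cohort.validation_samples)})")
print(f"genes: {cohort.expression.shape[0]}  segments: {len(cohort.segments)} rows")
print(f"censored fraction: {1 - cohort.outcome.event.mean():.3f} "
      f"(target {config.censoring_rate})")

gii = genomic_instability_index(cohort.cn_genes)
her2 = cohort.clinical["HER2"] == 1
print(f"mean GII, HER2+: {gii[her2].mean():.3f}   HER2-: {gii[~her2].mean():.3f}")
print("-> HER2-positive tumors carry the heaviest copy-number aberration burden,")
print("   the association the instability latent is designed to plant.")

counts = cohort.clinical.groupby(cohort.truth["subtype"])["ER"].agg(["size", "mean"])
print("\nsubtype sizes and ER-positive fraction:")
print(counts.rename(columns={"size": "n", "mean": "ER+ frac"}).to_string())
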