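"""Weighted co-expression module detection on a synthetic cohort.

Generates a cohort with three planted modules, picks a soft-thresholding
power by the scale-free criterion, builds the topological overlap matrix and
cuts the average-linkage tree into modules, then compares with the planted
truth via the adjusted Rand index (1 = perfect recovery).
"""

from sklearn.metrics import adjusted_rand_score

from pancanstrat import (
    GeneratorConfig,
    NetworkConfig,
    compute_tom,
    detect_modules,
    generate_cohort,
    pick_soft_power,
    restrict_matched_cohort,
    site_mean_normal,
    summarize_modules,
    tissue_correct,
)

tumour, normal, sheet, truth = generate_cohort(GeneratorConfig(seed=1))
pair = restrict_matched_cohort(tumour, normal, sheet, min_samples=20)
corrected = tissue_correct(pair.tumour, pair.sheet, site_mean_normal(pair.normal, pair.sheet))

cfg = NetworkConfig()
power = pick_soft_power(corrected.data, cfg)
print(f"soft power: {power.power} (scale-free target met: {power.target_met})")

tom = compute_tom(corrected.data, power.power, cfg.sign)
assignment = detect_modules(tom, cfg)
sizes = assignment.labels.value_counts()
print("\ndetected module sizes (unassigned = background genes):")
print(sizes.to_string())

ari = adjusted_rand_score(truth.module_of[assignment.gene_ids], assignment.labels)
print(f"\nadjusted Rand index vs planted modules: {ari:.3f}")
# ~1.0 means the three planted gene sets were recovered almost exactly.

profile = summarize_modules(corrected.data, assignment)
print("\nmodule expression (mean ln tumour/normal over member genes), first 4 tumours:")
print(profile.iloc[:, :4].round(3))
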