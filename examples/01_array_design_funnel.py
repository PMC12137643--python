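"""Array-design filter funnel on a simulated resequencing panel.

Simulates a founder panel, degrades the calls with realistic artifacts,
then runs the staged SNP-selection cascade (sequencing QC, shared-variant
filter, genotype-performance categories, legacy-array integration) and
prints the funnel with percentage lines.
"""

import numpy as np

from orchardpop.array_design import (
    FunnelReport,
    classify_performance,
    integrate_legacy,
    qc_filter,
    select_final,
    shared_variant_filter,
)
from orchardpop.simulate import (
    ArtifactModel,
    SimulationConfig,
    degrade_calls,
    simulate_founders,
)

cfg = SimulationConfig(n_founders=120, n_variants=4000,
                       chrom_lengths={"Chr1": 20_000_000}, seed=42)
clean = simulate_founders(cfg)
# heterogeneous artifacts: ~10% of variants are badly missing (fail the
# 0.4 missing-rate QC), a further slice is marginally missing (fail the
# 97.5% call-rate screen), the rest genotype cleanly
rng = np.random.default_rng(42)
u = rng.random(cfg.n_variants)
missing = np.where(u < 0.10, 0.5, np.where(u < 0.25, 0.05, 0.002))
variants, geno, _ = degrade_calls(
    clean, None, ArtifactModel(missing_rate=missing, mean_depth=8.0), seed=42
)

qc = qc_filter(variants, geno)
shared = shared_variant_filter(variants, geno)
stage2 = qc & shared
cats = classify_performance(geno.subset_variants(stage2))
final = np.flatnonzero(stage2)[select_final(cats)]

final_pos = {(variants.chrom[j], int(variants.pos[j])) for j in final}
legacy = {("Chr1", int(p)) for p in
          np.random.default_rng(0).integers(0, 20_000_000, 300)}
merge = integrate_legacy(final_pos, legacy)

report = FunnelReport.from_counts(
    [("raw", variants.n_variants), ("qc_pass", int(qc.sum())),
     ("shared>=2", int(stage2.sum())), ("category_pass", len(final))],
    final_count=merge.n_merged,
)
print(report.to_frame().to_string(index=False))
print(f"legacy integrated: {merge.n_legacy}, overlap removed: {merge.n_overlap}")
print(f"final merged array: {merge.n_merged} SNPs "
      f"({report.percent_line(len(final))} designed de novo)")
# Each stage line shows surviving variants and how many the stage removed;
# the percentage is relative to the final merged SNP count.
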