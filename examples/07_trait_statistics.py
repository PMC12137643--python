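"""Descriptive trait statistics for an orchard diversity panel.

Simulates correlated sugar/acid traits and flowering dates, then computes
the Spearman correlation matrix with its significance mask, a
cluster-vs-rest comparison with the normality gate, component ratios, and
the flowering-day distribution.
"""

import numpy as np
import pandas as pd

from orchardpop.datatypes import PhenotypeTable
from orchardpop.phenostats import (
    cluster_vs_rest,
    flowering_distribution,
    spearman_matrix,
    trait_summary,
)

rng = np.random.default_rng(23)
n = 200
acc = [f"acc{i}" for i in range(n)]
malate = rng.gamma(4, 1.0, n)
citrate = rng.gamma(4, 0.8, n)
ta = 0.2 * malate + 0.1 * citrate + rng.normal(0, 0.1, n)
ph = 4.5 - 0.5 * ta + rng.normal(0, 0.05, n)
rows = []
for trait, vals in [
    ("malate", malate), ("citrate", citrate), ("TA", ta), ("pH", ph),
    ("sucrose", rng.normal(70, 8, n)), ("glucose", rng.normal(11, 2, n)),
    ("fructose", rng.normal(9, 2, n)), ("sorbitol", rng.normal(3.2, 0.6, n)),
    ("flowering_date", np.round(rng.normal(97, 5, n))),
]:
    for a, v in zip(acc, vals):
        rows.append(dict(accession=a, trait=trait, year=2016, value=v))
pheno = PhenotypeTable(pd.DataFrame(rows))

corr = spearman_matrix(pheno, ["TA", "pH", "malate", "citrate"])
print("Spearman rho (X = not significant at 0.05):")
disp = corr.rho.round(2).astype(str)
disp[corr.not_significant] = "X"
print(disp.to_string())

low_acid = [a for a, v in zip(acc, ta) if v < np.quantile(ta, 0.1)]
res = cluster_vs_rest(pheno, "malate", low_acid)
print(f"\nlow-acidity cluster vs rest (malate): {res.test}-test "
      f"p = {res.p:.2e} (n = {res.n_cluster} vs {res.n_rest})")

summ = trait_summary(pheno)
print(f"sugar ratio (suc:glu:fru:sorbitol) = {summ.sugar_ratio}")
lo, hi = summ.malate_citrate_range
print(f"malate/citrate ratio range: {lo:.2f} to {hi:.2f}")

flow = flowering_distribution(pheno)
print(f"peak flowering day {flow.peak_day} "
      f"({100 * flow.peak_share:.2f}% of trees), span {flow.span_days} days")
# TA tracks malate/citrate positively and pH negatively, mirroring how
# titratable acidity behaves in fruit panels.
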