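"""IBD-segment calling and shared-region discovery within a family.

Gene-drops a sibship, calls identity-by-descent segments from the phased
haplotypes, checks them against the recorded descent truth, and derives
the family's top-decile shared IBD regions.
"""

import pandas as pd

from orchardpop.datatypes import PedigreeTable
from orchardpop.ibd import call_ibd_segments, ibd_pileup, shared_regions
from orchardpop.simulate import SimulationConfig, gene_drop, simulate_founders

cfg = SimulationConfig(n_founders=6, n_variants=2500,
                       chrom_lengths={"Chr1": 25_000_000}, seed=5)
founders = simulate_founders(cfg)
rows = [dict(individual=f, sire=None, dam=None, relation_type="cross")
        for f in founders.samples]
sibs = [f"sib{i}" for i in range(10)]
for s in sibs:
    rows.append(dict(individual=s, sire="F000", dam="F001",
                     relation_type="cross"))
geno, truth = gene_drop(founders, PedigreeTable(pd.DataFrame(rows)), cfg)

vmap = cfg.variant_map()
called = call_ibd_segments(
    geno.subset_samples([geno.samples.index(s) for s in sibs]),
    vmap["chrom"].to_numpy(), vmap["pos"].to_numpy(),
    min_bp=1_000_000, min_markers=25,
)
print(f"called {len(called)} IBD segments among {len(sibs)} full sibs")
truth_pair = truth.ibd_segments("sib0", "sib1", min_bp=1_000_000,
                                merge_gap_markers=1)
print(f"sib0-sib1: truth has {len(truth_pair)} segments >= 1 Mb; "
      f"called {len([s for s in called if s.pair == ('sib0', 'sib1')])}")

pileup = ibd_pileup(called, sibs, bin_bp=100_000,
                    chrom_lengths=cfg.chrom_lengths)
regions = shared_regions(pileup, top_fraction=0.10)
print("top-10% shared IBD regions of the sibship:")
for r in regions:
    print(f"  {r.chrom}:{r.start / 1e6:.1f}-{r.end / 1e6:.1f} Mb, "
          f"covered by {r.frequency} of {pileup.n_pairs} pairs")
# The most frequently shared bins mark the stretches of the parental
# genomes that most sib pairs co-inherited.
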