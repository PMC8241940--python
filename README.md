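# sagscreen

Decision layer for single-cell genomics campaigns on uncultured microbes:
contamination screening of single amplified genomes (SAGs), paralog-corrected
quality metrics with MIMAG/MISAG tiering, marker-gene-coverage community
abundance, identity-threshold grouping of SAGs into co-assembly candidates
(CAGs), and sorting/MDA/PCR funnel accounting.

## Who this is for

Groups running single-cell dispensing or FACS campaigns on environmental
samples (wastewater, sediment, host-associated communities) who need to turn
upstream outputs — assemblies, marker-gene classifications, CheckM tables,
ANI/16S identity matrices, real-time MDA plate data — into defensible
decisions: which contigs to strip before database submission, which SAGs to
co-assemble, which genomes clear which quality tier, and how efficient the
sorting funnel actually was. Everything upstream (assembly, gene calling,
marker extraction, read mapping, ANI computation) stays in its usual tools;
`sagscreen` consumes their tabular outputs.

## The methods in brief

**Hierarchical contig classification (HCC) and screening.** Each contig is
classified by its highest-ranking phylogenetic marker (rRNA gene > universal
single-copy protein > any protein), taking the lowest common ancestor (LCA)
of that class's hits. The assembly's dominant taxon is the lineage with the
largest summed contig length at the evaluation rank (phylum by default). Any
contig whose own classification *clearly contradicts* the dominant lineage
with mean supporting identity > 40% is flagged as potential contamination
and removed. This catches contaminant fragments that marker-set tools miss
because they carry no conserved marker at all.

**Paralog-corrected contamination.** CheckM's contamination *C* counts
duplicated markers; its strain heterogeneity *SH* is the fraction of
duplicates that are near-identical and therefore unlikely to be
cross-species. The corrected value is

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>corr</sub> = *C* − (*SH*/100)·*C*

Predicted genome size extrapolates assembly size by the genuinely recovered
fraction: *size* / ((*completeness* − *C*<sub>corr</sub>)/100). Tiers follow
MIMAG/MISAG with contamination judged on *C*<sub>corr</sub>: medium needs
completeness ≥ 50 and *C*<sub>corr</sub> < 10; high additionally needs
completeness > 90, *C*<sub>corr</sub> < 5 and complete rRNAs.

**Marker-coverage abundance.** A taxon's abundance is the summed coverage of
all its universal single-copy marker genes, each marker contributing its
contig's mean coverage — invariant under contig fragmentation, unlike the
legacy per-contig scheme (also implemented, for comparison), which inflates
poorly assembling genomes.

**CAG grouping.** SAGs are merged into co-assembly groups by transitive
closure of pairs with 16S identity ≥ 100% and/or ANI > 98.4% (both
thresholds are configuration).

**Funnel statistics.** Per-well MDA positivity is called against the plate's
negative controls (Cq margin + endpoint-RFU sigma rule); stage rates are
reported as MDA/sorted and PCR, Sanger/MDA-positive.

## Worked example

The package ships a desk-scale fixture: the per-genome quality table of a
winery-wastewater Patescibacteria/CPR sorting campaign (27 SAGs + 4 CAGs)
and its 880-cell sorting funnel.

```python
from sagscreen.fixtures import table1_records, funnel_wells, cag_pairwise
from sagscreen.qc import summarize_qc
from sagscreen.funnel import funnel_stats
from sagscreen.cluster import group_sags

s = summarize_qc(table1_records(kinds=("SAG",)))
print(s.mean_completeness, s.mean_corrected_contamination, s.tier_counts)
# 42.8 0.8 {'high': 0, 'medium': 10, 'low': 17}

r = funnel_stats(funnel_wells())
print(r.pct_mda_of_sorted, r.pct_pcr_of_mda, r.pct_sanger_of_mda)
# 81.5 58.6 50.1

ids, id16s, ani = cag_pairwise()
g = group_sags(ids, id16s, ani)
print(g.n_entities, sorted(len(c) for c in g.cag_components))
# 15 [2, 3, 3, 8]
```

Reading: the 27 SAGs average 42.8% completeness and 0.8% corrected
contamination, 10 reach the medium tier and 17 stay low; of 880 sorted
cells 81.5% amplified, 58.6% of those gave a 16S PCR product and 50.1%
an interpretable Sanger read; and threshold grouping collapses the 27
SAGs into 4 CAGs plus 11 singletons — 15 distinct genomes.

The same stages run from TSV inputs on the command line:

```bash
sag-screen simulate community --seed 1 --out demo/   # synthetic inputs
sag-screen simulate sort --seed 1 --out demo/
sag-screen run --in demo/ --out demo_out/
```

## Layout

| module | contents |
| --- | --- |
| `sagscreen.taxonomy` | lineage paths, LCA, contradiction test |
| `sagscreen.screen` | HCC, dominant taxon, contaminant flagging/filtering |
| `sagscreen.qc` | corrected contamination, predicted size, tiers, N50 |
| `sagscreen.abundance` | marker-based and contig-based profiles |
| `sagscreen.cluster` | CAG grouping, reference filter, concordance, novelty, unique regions |
| `sagscreen.funnel` | MDA calling, funnel statistics, sorted-taxon proportions |
| `sagscreen.simulate` | seeded generators with ground truth |
| `sagscreen.io` / `sagscreen.pipeline` / `sagscreen.cli` | TSV schemas, config, `sag-screen` |

See `docs/methods.md` for the full model description, parameter defaults and
known limitations.
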