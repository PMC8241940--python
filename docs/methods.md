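# Methods

This note documents the models and procedures `sagscreen` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic generators do and do not emulate.

## Taxonomy model

Lineages are name-based, semicolon-delimited paths (`Bacteria;
Patescibacteria;Saccharibacteria`) with positional ranks — domain,
(optional superphylum), phylum, class, order, family, genus, species.
Paths may be truncated at any depth but never skip intermediate ranks,
which makes the lowest common ancestor (LCA) the longest common prefix and
keeps it well-defined without a reference tree. No external taxonomy
(SILVA/NCBI/GTDB) is loaded or reconciled; names are compared verbatim, so
inputs must come from a consistent classification source.

Two lineages **contradict** when both are resolved to the contradiction
rank and their prefixes through that rank differ. Truncated paths are
indeterminate, never contradicting — a contig classified only as
"Bacteria" is no evidence against any bacterial host. The contradiction
rank defaults to phylum; the sources on which this screening style is
based do not pin the rank down, and phylum is the most conservative choice
that still separates the clades a single-cell campaign confuses in
practice (free DNA from unrelated community members). It is configurable
(`RankConfig.contradiction_rank`).

## Contig screening (HCC)

Marker precedence is rRNA gene > universal single-copy protein marker >
other protein, on the reasoning that reliability of a taxonomic call
decreases in that order. The contig's classification uses *only* the
highest-precedence class present: its LCA and the arithmetic mean of its
percent identities (all hits of that class, concordant or not — the
simplest faithful reading of an "average supporting identity").

The dominant taxon of an assembly is **length-weighted**: at the
contradiction rank, the lineage maximising summed supporter contig length
wins (ties broken lexicographically), then the result is deepened to the
supporters' LCA. Length weighting was an open choice (count or coverage
weighting would also be defensible); it is robust to fragmentation, which
is the dominant artefact in MDA assemblies, and coverage in MDA data is
too biased to weight by. Contigs not resolved to the contradiction rank
cannot vote; if no contig is resolved that far, the overall LCA of
classified contigs is used as a degenerate fallback.

A contig is flagged as potential contamination iff it contradicts the
dominant lineage **and** its mean identity strictly exceeds the threshold
(default 40, on whatever identity scale the upstream aligner reported —
the rule is unit-agnostic). Strictness at the boundary is deliberate and
locked by tests. Flagged contigs are removed; the screen report carries
removed fractions by count and by length.

## Genome quality

* `paralog_corrected_contamination(C, SH) = C·(1 − SH/100)` — duplicates
  that are near-identical (CheckM strain heterogeneity) are discounted as
  within-strain paralogy or amplification artefacts, not cross-species
  contamination.
* `predicted_genome_size(size, completeness, C_corr) =
  size / ((completeness − C_corr)/100)`. Subtracting corrected
  contamination first removes foreign/duplicated sequence from the
  numerator's provenance before extrapolating; with clean genomes this is
  plain size/completeness. This variant — rather than dividing by
  completeness alone — is what reproduces the packaged reference table for
  every row including the contaminated co-assemblies, and is the package's
  reading of "relating size to completeness".
* MIMAG/MISAG tier: high requires completeness > 90, corrected
  contamination < 5 **and** an explicit `rna_complete` flag (rRNA/tRNA
  detection is upstream; the default `False` honestly caps tiers at
  medium rather than silently granting "high"); medium requires
  completeness ≥ 50 and corrected contamination < 10; else low. Tiering on
  the *corrected* value is required to reproduce published tier columns
  where raw CheckM contamination exceeds 10 but the tier is still medium.
* Summary means are rounded to one decimal, half away from zero (a mean
  of 0.7518 prints 0.8).
* `n50` is the standard largest-L-covering-half definition.

The packaged reference table carries one row whose printed corrected
contamination (0.9) cannot arise from its printed CheckM contamination (0)
under the formula; the fixture keeps the row verbatim, QC consumes the
printed value via the `corrected_contamination` override field, and the
formula-consistency test excludes that row explicitly.

## Abundance estimators

The marker-based estimator sums, per taxon, the mean contig coverage of
every universal marker gene (single-copy proteins and rRNAs, weighted
equally — the sources do not distinguish them, and equal weighting keeps
the estimator a pure coverage sum). Per-gene coverage is approximated by
the encoding contig's mean coverage. The estimator is exactly invariant
under any contig split/merge that preserves per-marker contig coverage.
The legacy contig-based estimator (one coverage contribution per
classified contig) is provided to demonstrate and quantify its
fragmentation bias: fragmented genomes gain weight under it.

Markers/contigs not resolved to the reporting rank (default phylum) go to
an explicit unclassified bucket; by default it is excluded from the
simplex and reported as a fraction of the grand total
(`include_unclassified=True` puts it inside the simplex under the root
path).

## CAG grouping and genome comparisons

Grouping joins SAGs whose 16S identity is ≥ 100% and/or whose ANI is
strictly > 98.4%, then takes connected components — transitive closure is
intentional, since co-assembly is transitive in practice. Two ANI merge
conventions circulate for this kind of data (a strain-level ~98.4% and a
species-level 95%); the default is the stricter 98.4 with `tani` exposed
in the configuration, and the grouping result records which criterion
fired on each edge so the choice is auditable. Raising either threshold
can only refine the partition (tested property).

Reference genomes are admitted for comparison when N50 > 35 kb,
completeness > 70% and corrected contamination < 5% (all strict).
Classification concordance reports, per genome, the deepest rank at which
all available methods (e.g. 16S, genome taxonomy, MLSA) agree and whether
they agree completely at their common depth; genomes assessed by fewer
than three methods are counted separately. The novelty rank is a plain
threshold ladder against the nearest admitted reference (ANI ≥ 95 same
species; else AAI ≥ 65 novel species; ≥ 45 novel genus; else novel
family) — explicitly *not* a GTDB/PhyloRank placement, just a coarse,
deterministic label with configurable cutoffs.

`unique_region_summary` merges 0-based half-open alignment intervals and
reports the complement (regions a genome holds that its partner lacks),
with a minimum-region filter defaulting to 200 bp — alignment tails
shorter than that are noise at typical blastn settings. With the filter at
0, unshared + merged aligned bp equals the genome length exactly.

`naive_fragment_identity` chops one sequence into 1020 bp fragments,
places each on the partner at its best shared-16-mer anchor offset, scores
ungapped identity, and averages both directions. It exists so synthetic
end-to-end tests can start from FASTA; it is not OrthoANI-equivalent
(no reciprocal-best filtering, no gapped alignment) and drifts low on
diverged pairs — do not use it on real genomes.

## Funnel model

MDA positivity is called against ≥ 3 negative-control wells: Cq present,
at least `margin_cycles` (default 5) earlier than the earliest control
(controls that never amplify count as +∞), and endpoint RFU at least
`rfu_sigma` (default 3) control standard deviations (sample SD) above the
control mean. Real instruments do not publish their calling rule; this
control-anchored form is the package's own, chosen so that only its
monotone contract (more fluorescence / earlier Cq never flips a positive
to negative) is load-bearing, and both knobs are configuration.

Funnel percentages follow the reporting convention of the field's funnel
sentences: MDA over sorted cells; PCR **and** Sanger over MDA-positive
wells (that denominator is what makes stage triples like 81.5/58.6/50.1
mutually consistent). Negative controls are excluded from all
denominators; monotonicity violations in the input are an error, not
silently repaired.

## Synthetic generators

`simulate_community` builds genomes fragmented into lognormal contig
lengths (mean 20 kb, log-sd 0.5 — typical of MDA single-cell SPAdes
assemblies), places 40 single-copy markers + 1 rRNA per genome on contigs
with probability proportional to length, and sets per-contig coverage to
`depth_scale × abundance` times optional lognormal noise (multiplicative,
a qualitative stand-in for MDA amplification bias). It does **not**
simulate reads, chimeras, GC bias, or the branching-process statistics of
MDA, so passing recovery tests show estimator correctness under the
stated coverage model, not robustness to every real-world artefact.

`inject_contamination` appends contaminant contigs (default 5 kb, low
coverage) carrying protein hits to a contradicting source taxon with
identities from a configured range; the planted rate is the fraction of
the final table. Constructed outside the ambiguity ranges (identities
clearly above/below the 40% threshold), screening recovers the plant with
100% recall and precision — the corresponding tests validate the decision
logic, not the difficulty of borderline real contaminants.

`simulate_sort_run` mirrors a five half-384-well-plate campaign: 880
cells, 16 negative controls per plate, conditional stage probabilities
(0.815, 0.586, 0.854), Gaussian Cq/RFU emissions for positives and
baseline RFU for negatives/controls. `simulate_sag_replicates` plants a
strain partition in ANI/16S matrices drawn from disjoint within/between
ranges and refuses ambiguous (overlapping) constructions.

All generators are deterministic under a single integer seed
(bit-identical tables), which the tests assert.

## Numerical and interface conventions

Percentages are 0–100 everywhere in tables; fractions live only in
abundance profiles. Coordinates are 0-based half-open. TSV is the single
tabular dialect (header row, UTF-8, '.' decimal, empty = absent). Ties in
dominant-taxon selection break lexicographically; CAG labels are assigned
by each component's smallest member id, so outputs are order-invariant
and reproducible.

## Problem sizes used in tests

The test and acceptance suites run entirely on desk-scale inputs chosen
to keep the statistics meaningful: the 31-row quality table; 880-well
funnels over 50 seeds for rate-recovery (binomial 95% CIs at n = 880);
20-replicate, ≥ 200-contig communities for contamination-rate recovery
(±3 points) and abundance recovery under Poisson coverage noise
(±2 points); 50-node random taxonomies for exhaustive LCA oracle
equivalence. These sizes give the property checks their stated power
while keeping the whole suite in seconds.

## Known limitations

* Name-based taxonomy: synonym or rank-label drift between upstream
  classifiers will read as disagreement.
* The 40% contamination-identity threshold is applied to whatever identity
  column the upstream search produced; mixing nucleotide and amino-acid
  identities across marker classes is the caller's responsibility.
* Dominant-taxon selection assumes the genuine host dominates by length;
  a SAG that is mostly contaminant will be screened against the wrong
  lineage (as would any majority rule).
* Tier "high" is reachable only via the explicit `rna_complete` flag.
* The novelty ladder is a heuristic label, not a placement.
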