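# Methods

## Data model

The pipeline consumes plain-text inputs: per-sample, per-engine PSM tables
(TSV: spectrum key, sample, engine, peptide, score, semicolon-joined
protein accessions, decoy flag), a protein annotation table (accession →
UniRef50 cluster, NCBI tax id, category-tagged UniProtKB keywords, EC
numbers, KO ids, description), a taxonomy in the NCBI-taxdump dialect
(`\t|\t` field separators, scientific names only), an optional ADM1 step
config and an optional virus→host override table. Native engine formats
(mzIdentML, dat) are out of scope; the tables are the interface.

## FDR filtering

Filtering is stratified by (sample, engine): each engine's search is
validated on its own before merging. Within a stratum, records are ranked
by descending score and the threshold `t*` is the lowest score whose
prefix satisfies `#decoys / #targets ≤ α` (default α = 0.01). The estimator
is the simple decoy-to-target ratio D/T rather than 2D/(T+D); the choice is
isolated in `fdr_threshold` and swappable. Ties in score are kept or
dropped together — the threshold applies to the score value, not the rank —
so equal-scoring records can never straddle the cutoff. Single-peptide
identifications are retained (one-peptide rule). A stratum with no targets,
or no feasible threshold, returns empty with a warning rather than failing
the run. Merging engine results unions records; identical (spectrum,
peptide, accessions) identifications collapse into one record carrying all
contributing engine tags and the best score, while engine disagreement on a
spectrum's peptide is preserved — downstream counting deduplicates at the
spectrum level, so a spectrum never contributes twice to one metaprotein.

## Metaproteins

Every accession maps to exactly one group: its UniRef50 cluster, or a
`SINGLETON:<accession>` group when unclustered, so nothing is silently
dropped. A spectrum adds one count to each distinct group reachable through
its accessions but at most one to any single group. No fractional splitting
is applied to shared spectra; totals can therefore exceed the number of
distinct spectra when a spectrum spans groups, and the family rollup is
exactly conservative only in the absence of such sharing. The group's
taxonomy is the LCA over the distinct taxa of its annotated members
(members without a usable taxon are ignored; none at all puts the group at
the root). Function sets are unions over members; the representative
description is the lexicographically smallest, making output independent
of input order.

## Profiles, clustering, statistics

Normalization divides each sample column by its total spectral count.
Family rollup uses the LCA's ancestor at family rank with an explicit
`unassigned` bucket (never a fake taxon id); process rollup duplicates a
metaprotein's counts into each of its Biological Process keywords, since a
protein can serve several processes and no splitting rule is defensible.
Chord matrices keep the top-k (default 20) families and processes by total
spectra, ties broken lexicographically, with remaining processes summed
into `Other_Functions` so process totals are conserved for the retained
families.

Sample clustering is UPGMA on cityblock (L1) distances over the normalized
all-metaprotein profiles. The linkage is implemented in-package rather than
delegated because the contract fixes a deterministic tie-break — among
equal-distance candidate pairs, the one with the lexicographically smallest
member labels merges first — which library implementations leave
unspecified; scipy's average linkage serves as an independent cross-check
on tie-free inputs in the tests, and scipy computes the distances. Merge
heights are cophenetic distances; Newick export treats the tree as
ultrametric (leaf depth = height/2).

Two-group comparisons use the two-sided Student's t-test with pooled
variance (Welch is deliberately not the default; the equal-variance test is
the documented convention here), significance at p < 0.05, with the
convention p = 1 for two zero-variance groups with equal means. No
multiple-testing correction is applied.

## Phage, CRISPR, antimicrobial

Classification order: LCA under the Viruses superkingdom → `viral_taxonomic`;
LCA at root with a description matching the viral vocabulary
(word-boundary, case-insensitive) → `viral_by_function`; cellular LCA with
"phage"/"prophage" in the description → `prophage`; else not viral. The
default vocabulary (phage, prophage, capsid, tail, baseplate, portal,
terminase, virion, tape measure, holin) is replaceable; a bare "polymerase"
term is excluded by default because at root level it would sweep in
cellular polymerases — users studying phage polymerases should add it
explicitly. CRISPR detection matches "CRISPR", Cas-protein names
(cas1–cas13, csn, cmr) or the "Antiviral defense" keyword; antimicrobial
detection matches the keyword "Antimicrobial" or linocin / lysozyme /
maritimacin / bacteriocin.

Host assignment precedence: override table (keyed by group id, virus LCA
name or description) → a prophage's own LCA family → genus-token heuristic
(first word of the virus name looked up among genus nodes, mapped to its
family). Unassigned is a first-class outcome — in real data most phages
cannot be placed — and the per-family table conserves viral spectra through
an `unassigned` row. Family denominators come from the microbial family
rollup; CRISPR and antimicrobial proteins count as microbial.

The phage-per-cell estimator is `ratio × (d_cell/d_phage)³` with defaults
1.0 µm and 100 nm (volume ratio 1000): equal protein density and spherical
shapes make spectral abundance a proxy for total protein volume. The input
is a viral-to-host *ratio*; a share of all spectra f is first converted via
f/(1−f). At community fraction 0.4% both readings round to 4 phages per
cell; the ratio form is used because per-family figures are reported as
phage-to-family normalized counts.

## ADM1 mapping

Steps are configured in a flat TSV (step id, stage, substrate, EC list, KO
list, taxon restriction); a default mapping ships with the package covering
hydrolysis, substrate uptake, acidogenesis/fermentation, acetogenesis,
methanogenesis and one-carbon metabolism. The shipped EC/KO sets are a
curated starting point, deliberately editable rather than hard-coded — any
serious application should review them against its own annotation source.
One-carbon metabolism is modeled as its own stage rather than folded into
methanogenesis, keeping the bacterial CODH/ACS signal separate from the
archaeal pathway. A metaprotein matches a step when its EC or KO sets
intersect the step's and its LCA superkingdom satisfies the restriction
(`bacteria_only` for fermentation, `archaea_only` for methanogenesis);
unresolved superkingdoms fail every restriction, so restriction can only
remove counts. Methanogenesis typing uses the acetoclastic (acetate-substrate)
share of the stage's spectra: below θ = 0.1 the sample is called strictly
hydrogenotrophic, otherwise mixotrophic. The study motivating this
dichotomy gives no numeric cutoff; θ is exposed in the config and reported,
and the synthetic communities are separable for any θ in roughly
(0.02, 0.4). The archaeal-versus-bacterial split of ACDS spectra is
reported per sample because bacterial dominance supports a syntrophic
acetate-oxidation reading of a hydrogenotrophic profile.

## Synthetic data generator

The generator emulates a multi-plant digester study: by default 7 families
(five bacterial including cellulolytic and thermophilic clostridia, two
methanogen families) with field-realistic relative weights; 2–4 annotated
metaproteins per family wired to the default ADM1 map; per-family phage
loads of 2.3% (Clostridiaceae) and 2.8% (Enterobacteriaceae); a CRISPR
share of 0.6% and an antimicrobial share of 0.3% per family; 35% of each
family's metaprotein weight annotated only at order level, emulating the
large unassigned fraction of real data; and 77% of each family's phage
weight placed at the taxonomy root, recognisable only by description, as
observed for real phage proteins. Phage loads are defined relative to the
family-assigned (measurable) spectra, so the expected measured ratio equals
the configured load.

Study structure: plants × 2 time points × 2 technical replicates
(duplicate extractions) × 3 engines, default 20,000 spectra per
measurement. Replicate noise is Dirichlet-multinomial acting on *family*
totals — within-family composition is fixed and phages track their hosts —
with concentrations 40 (between plants), 400 (between time points) and
1000 (between technical replicates; replicates are near-identical, per the
motivating study). Concentration `None` disables a level, giving the pure
multinomial regime in which family fractions are recoverable within
`4·sqrt(p(1−p)/N)`. Plants alternate methanogenesis types; the strictly
hydrogenotrophic modifier multiplies acetoclastic metaprotein weights by
0.02 and bacterial-ACDS weights by 3. Engine detection is Bernoulli (p =
0.9) per engine per spectrum; target scores are N(25, 5²) and decoy scores
a left-shifted N(15, 5²) so the FDR threshold is non-trivial; an optional
entrapment fraction adds target-flagged records with decoy-distributed
scores for measuring realized FDR. Everything is driven by one
`numpy.random.default_rng(seed)`, so fixed seeds give identical outputs.

What the generator does *not* emulate: real peptide sequences and their
physicochemical detectability biases, shared peptides between UniRef50
clusters (each synthetic metaprotein has private accessions), protein-level
inference ambiguity, chimeric spectra, and database incompleteness.
Passing recovery tests therefore demonstrates the correctness of the
counting, rollup and classification machinery under the stated sampling
model — not robustness to those real-data pathologies.

## Problem sizes and numerics

The shipped tests simulate 2 plants at 20,000 spectra per measurement
(8 samples, 3 engines) for recovery checks, 1,000 repetitions for t-test
calibration, and 120 random trees (≤ 50 nodes) plus exhaustive prefix-scan
oracles for the LCA and FDR equivalences. Normalized columns are held to
|1 − Σ| ≤ 1e−9; clustering heights are exact arithmetic on scipy distances;
all tie-breaks (description choice, chord selection, UPGMA merges) are
lexicographic so reruns are byte-identical.

## Known limitations

Shared-spectrum counting can inflate totals (documented above); the
UniRef50 grouping is taken from the annotation table, never re-derived from
sequence; merged/deleted tax ids are not remapped; the viral vocabulary and
host-genus heuristic are string-based and language-dependent; krona/chord
outputs are data exports, not rendered figures; and the ADM1 mapping is a
static enzyme lookup — no digestion kinetics are modeled.
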