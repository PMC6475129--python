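# Methods

## The model

The pipeline treats a size-fractionated gene catalog as a set of similarity
clusters, each cluster a bag of predicted-protein sequences tagged with
(sample, site, depth, size fraction). Three nested cluster sets encode
increasingly strong evidence that a gene belongs to a genuinely ultrasmall
organism rather than to contaminating material:

* **PU** — the cluster has at least one member from the ultrasmall
  (<0.22 µm) fraction. Clusters without any such member are discarded.
* **UO** ⊆ PU — every member is ultrasmall; a gene also seen in a larger
  fraction is most parsimoniously a regular-sized organism's.
* **WUO** ⊆ UO — ultrasmall members occur at ≥ 2 distinct sites.
  "Site" means the station identifier; the same station sampled at two
  depths is one site, since depth is carried separately in the matrix rows.

Cluster membership is decided at cluster level; the downstream *sequence*
sets default to the ultrasmall-fraction members of selected clusters
(for PU the all-members variant is exposed too, as the two counts differ
there and either convention is defensible).

Orthogonally, each surviving sequence is placed on a divergence axis using
its best reference-database hit (best = maximal bitscore, ties broken by
E-value, then identity, then subject id — a total order, so rerunning the
pipeline can never reorder results): at mutual alignment coverage > 80%,
%ID < 90 puts it in **light dark matter** and %ID < 70 also in **dark
matter** (dark ⊆ light dark). No hit at all, a best hit with coverage
≤ 80% (insufficient evidence of similarity — a strict mode excludes these
instead, behind a flag), or a best hit annotated to an override group
(CPR, DPANN, domain-only bacteria/archaea, candidate taxa, unclassified)
assigns both tiers. All identity boundaries are strict inequalities exactly
as published; 70.0 %ID therefore falls in light dark matter only.

Viral removal applies two independent screens: (a) the best reference hit is
annotated as viral (no identity/coverage threshold is published for this
screen, so annotation alone decides); (b) *any* metavirome hit reaches
≥ 80 %ID and ≥ 80% mutual coverage (inclusive). Mutual coverage of a hit is
`min(query_span/qlen, subject_span/slen)` with spans from the 1-based
inclusive alignment coordinates; reversed subject coordinates are accepted
and spanned with `|send − sstart| + 1`.

## Completeness scoring

KO assignment requires %ID > 25, E-value < 1e-5 and mutual coverage > 70%
— all strict, and deliberately different from the inclusive ≥ 30% / ≥ 80%
thresholds of the similarity network, because the two rules are published
with different inequality senses. A sequence may support several KOs
(paralogy); presence sets union them, which presence/absence scoring is
robust to.

A pathway is an ordered list of modules; a module definition is boolean
logic over KO ids in a small grammar: whitespace = AND, comma = OR (binding
tighter than whitespace, KEGG-style), parentheses group, `-K…` marks an
optional enzyme (excluded from the presence expression, reported when
observed), `*K…` marks a key enzyme. The richer constructs of real KEGG
definitions (complex `+` signs, `--` gaps) are deliberately reduced to
AND/OR, which is how the completeness proxy uses them: a module is present
iff its expression is satisfiable from the observed KO set.

Completeness of a pathway at a (site, depth, dataset) key is the percentage
of its modules present. A cell is flagged — read "this pathway credibly
occurs here" — when completeness reaches the flag threshold **and** all key
enzymes of the pathway are present. The published text prints the threshold
as ≥ 60% in one place and > 60% in another; this implementation adopts the
inclusive ≥ 60% and makes it configurable, so the boundary case (exactly
60%) flags by default. Ribosomal complexes (55 bacterial / 67 archaeal
proteins, 31 shared; one single-KO module per protein) are scored with the
same machinery as positive controls, each against its own full protein
list, shared proteins counting for both; they never flag.

The matrix rows — (site, depth) keys plus a final "pool" row unioning all
sites — are ordered by agglomerative Ward clustering
(`scipy.cluster.hierarchy.linkage`, Euclidean distance) on each row's
concatenated completeness vector across all dataset stringencies, mirroring
the full column span of the published heat map; the pool row is excluded
from clustering and appended last. The dendrogram exports as Newick with
branch lengths taken as differences of merge heights.

## Statistics

Enrichment of each taxonomic group in each filtered dataset against the PU
baseline uses the two-sided Fisher exact test with the point-probability
rule: p is the total conditional hypergeometric mass of tables (same
margins) whose point probability does not exceed the observed one, ties
admitted within 1e-7 relative tolerance. Tables with total n ≤ 1000 are
evaluated by exact integer enumeration (`math.comb` numerators over a
common denominator — no floating-point tie ambiguity at all); larger tables
use `scipy.stats.fisher_exact`, which implements the same rule. The sample
odds ratio is (ad)/(bc), +∞ on division by zero. Bonferroni correction
multiplies by the full test count (9 groups × 6 datasets = 54 by default)
and verdicts require the corrected p < 0.05, with direction from the odds
ratio.

Composition is counted on dataset membership *before* viral removal
(otherwise the viruses group would be identically zero under screen (a) and
could never be reported as depleted); completeness is computed after
removal. Counts are sequences, not clusters.

Spearman correlation delegates to `scipy.stats.spearmanr` (mid-ranks for
ties); a constant vector returns NaN rather than raising, since an
undefined correlation is a data condition, not a programming error. Only
the coefficient is part of the core contract; the t-approximation p-value
is available behind a flag. Sequencing-effort covariates normalise each
indicator to its cross-site maximum, so the best-sampled site scores 1.0.

## The synthetic generator

`synthetic_data.generate` fabricates hit tables directly rather than
simulating sequences and running an aligner: the pipeline's contracts
consume tabular alignments, so this exercises every tested code path while
isolating the artifact from aligner versions. Defaults define the study
conditions used throughout the tests: 5 sites, 600 clusters (~1,700–2,000
sequences), six pathways, noise-free.

* Cluster classes and mixture: 60% `novel_ultrasmall` (ultrasmall-only;
  reference identity ~ Uniform(45, 68)%, 25% with no reference hit; half
  widespread over 2–3 sites), 20% `known_regular` (ultrasmall-only,
  identity ~ Uniform(92, 99)%), 10% `viral` (60% by virus-annotated best
  hit, 40% by metavirome match), 10% `shared_fraction` (members in both
  fractions, identity ~ Uniform(70, 95)%). The identity windows are chosen
  to sit clearly inside the published decision regions (dark matter < 70,
  known ≥ 90, viral ≥ 80) so that noise-free recovery is exact rather than
  probabilistic; an `identity_noise` parameter redraws a fraction of
  identities from Uniform(30, 99) to blur the classes, with truth labels
  always derived from realised values so the bundle stays self-consistent.
* Alignment records pin qstart = 1 and mirror the span on the subject, so
  realised mutual coverage is within 1/(2·qlen) of its target — again kept
  clear of the 0.7/0.8 boundaries by the coverage windows. E-values are a
  deterministic monotone function of bitscore and lengths (Karlin–Altschul
  shaped); only their ordering and the 1e-5 crossing matter.
* Planted repertoires: per (site, pathway) target completeness fractions
  are realised as a *prefix* of the pathway's module list (a fraction that
  is not an exact multiple of 1/n_modules is a configuration error naming
  the pathway). Each present module contributes a deterministic satisfying
  KO set (first alternative of every OR); qualifying KEGG hits are attached
  to widespread dark-matter carrier sequences at that site. Because
  carriers sit in the most stringent dataset (WUO dark matter), the planted
  completeness is identical across all seven dataset stringencies at a
  site, and the pool row equals the per-site maximum (prefix union). This
  makes exact recovery checkable; it also means the default bundle does not
  exercise *strict* stringency decreases, which is why stringency ordering
  is asserted as ≥ rather than >.
* `self_check` re-derives every label from the emitted bundle with a
  plain loop-based reimplementation of the rules and reports mismatches —
  a generator bug cannot silently become the pipeline's "truth".
* The enrichment scenario is simulated at count level
  (`simulate_enrichment_counts`): the PU baseline and each dataset are
  independent multinomial draws over the group proportions (default
  500/group in expectation), with optional per-(group, dataset) proportion
  multipliers for planted enrichment. Under the null (no shift) the raw
  Fisher tests reject at ≈ 0.047 at α = 0.05 over 54,000 draws — the mild
  conservatism expected of a discrete exact test.

What the generator does *not* emulate: real sequence content (no FASTA),
phylogenetic correlation between sites, compositional coupling between the
taxonomic groups and the planted KO repertoires, and nested sampling of the
dataset counts (dataset and baseline draws are independent). Passing tests
therefore demonstrate that the *rules* are implemented exactly and that the
statistics are calibrated under the stated sampling model — not that the
thresholds themselves are optimal for real data.

## Numerical and design choices

* Problem sizes in the test and acceptance runs (600-cluster default
  bundle, 100 fuzzed bundles of 20–100 clusters, 1,000 calibration
  replicates, exhaustive Fisher enumeration to margins of 30) were chosen
  as the smallest sizes at which every property is exercised with
  comfortable statistical resolution.
* Ties in `best_hit` cannot occur silently: the comparison key ends in the
  subject identifier, a total order.
* The dark-matter `reason` vocabulary includes `low_coverage` for the
  sub-coverage branch, which the tier rules treat as "both tiers" by
  default (strict mode: neither).
* Degenerate inputs: an empty site yields empty KO sets and 0%
  completeness; a single-row matrix returns identity order and a trivial
  dendrogram; empty hit lists are absence signals, not errors; a 2×2 table
  with an all-zero margin has p = 1 (only one table is possible).
* `write_hits` serialises floats with `repr`, the shortest exact decimal,
  so parse → serialise → parse is the identity on all three readers.

## Known limitations

* The nr-based viral screen uses annotation of the best hit only; no
  identity/coverage gate is published for it, so a divergent hit to a viral
  protein removes the sequence.
* KO assignment and dark-matter classification are computed independently
  (a KO homolog may simultaneously be "known similar"); the published
  methods read this way and no cross-screen is applied.
* Gene families are built from all hits passing thresholds, not best hits
  only; on bipartite (environment × reference) hit tables the components
  are star-shaped around reference proteins.
* The Spearman stage reports coefficients only; no inferential claims are
  attached to effort correlations.
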