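# Methods

## Consensus annotation model

Each protein may receive evidence from three independent streams, labelled
by their provenance in dbCAN-style output: `HMMER` (profile HMM), `eCAMI`
(k-mer classifier) and `DIAMOND` (similarity search). A CAZyme call is
accepted iff at least two streams agree on the same family after
subfamily collapse; the reported family is taken from the highest-priority
agreeing stream (HMMER, then eCAMI, then DIAMOND). Rationale for the
collapse: streams report at different granularity (GH13 vs GH13_10) and all
downstream analyses are at family level. When a stream reports several
candidate families for one protein, any intersection with another stream
counts as agreement, and the priority stream's best e-value hit supplies
the label. With three single-label streams two disjoint agreeing pairs
cannot occur (pigeonhole), so the rule is unambiguous.

Acceptance filters, applied after a global e-value cutoff of 10⁻³:

| filter | coverage | identity | extra requirement |
|---|---|---|---|
| EC-linked CAZyme | ≥ 0.40 | ≥ 0.30 | — |
| sulfatase (S1 subfamily) | ≥ 0.50 | ≥ 0.30 | PF00884 ∈ domains |

Both bounds are inclusive (≥). Coverage and identity are stored as
fractions of the database target; percentage thresholds are converted once
at config load. MAG retention uses completeness ≥ 50% (inclusive) and
contamination < 10% (strict), following MIMAG "medium quality" phrasing
("less than 10%").

## Substrate catalog

`data/substrate_catalog.tsv` maps CAZy families, EC numbers, S1 sulfatase
subfamilies and mannitol-pathway gene symbols to nine substrate panels
(alginate, laminarin, FCSP, carrageenan, agarose, derived galactans,
starch, sulfatases, mannitol) and a molecular-weight class. HMW marks
endo-acting / polymer-cleaving entries (e.g. guluronate-specific alginate
lyase, glucan endo-1,3-β-D-glucosidase, κ/ι/λ-carrageenases, β-agarases,
α-fucosidases); LMW marks exo-acting oligomer consumers (β-glucosidases,
galactosidases, oligo-alginate lyase). `dedicated = 1` means the key is
unambiguous for a single substrate; ambiguous families (GH16 spans
laminarinases and agarases, GH30 laminarinases and fucosidases, GH13 the
broad amylase cluster) stay multi-substrate here and are resolved only
with gene-cluster context. The catalog is a reconstructed curation scoped
to the substrates above — it makes no completeness claim against the live
CAZy/SulfAtlas databases — and ships as an editable TSV so curation
changes are diffable data, not code.

The "galactan" panel aggregates the β-/α-galactosidase LMW activities
downstream of FCSP, carrageenan and agarose degradation. Starch capability
accepts either HMW amylases or LMW α-glucosidases. Mannitol capability
requires a complete route: M2DH **and** fructokinase (cytoplasmic route),
or a mannitol-PTS component **and** M1PDH (phosphorylative route); both may
coexist.

## CGC detection and substrate inference

Signature genes are CAZymes (by accepted consensus call), transporters
(TC), transcription factors (TF) and signal-transduction proteins (STP) —
the role vocabulary of CGC-finder-style output. A cluster is a maximal run
of signature genes on one contig in which consecutive signature genes are
separated by ≤ `cgc_max_gap` (default 2) non-signature genes, containing
≥ 1 CAZyme and ≥ 1 non-CAZyme signature gene. Strand is ignored:
polysaccharide-utilization loci are frequently mixed-strand. The detector
is proven equivalent (by exhaustive enumeration in the tests) to a
brute-force maximal-valid-window oracle over all role strings up to length
9 plus a seeded sample of longer strings.

A cluster is *degradative* iff ≥ `cgc_min_degradative` (default 2) of its
members carry GH, PL or CE calls; CBM/GT/AA members never count — binding
modules bind, they do not cleave. Substrate inference over a degradative
cluster's families: every dedicated family contributes its substrate
("dedicated" evidence); an ambiguous family's candidate substrate is kept
only when a *different* member family supports the same substrate
("colocalization" evidence, the complementary-activity pairing). Clusters
resolving to no substrate are tallied as unclassified; clusters composed
entirely of CBM/GT CAZymes are reported but never substrate-assigned.
Multi-substrate clusters are allowed (counted once per substrate, flagged
by the evidence column) rather than silently discarded.

## Community statistics

- **Density**: 1000 · n_CAZymes / n_genes per MAG by default; per-Mbp
  available via `density_unit`. The per-gene unit is robust to genome
  incompleteness. Class comparisons use the Wilcoxon rank-sum test
  (`scipy.stats.mannwhitneyu`, `method="auto"`): exact null distribution at
  small untied sample sizes, tie-corrected normal approximation otherwise.
- **Composition**: Bray–Curtis dissimilarity over per-MAG family vectors,
  scaled by 1000/n_genes by default (a "density composition"); raw counts
  via `feature="counts"`. Pairs of all-zero vectors are undefined and
  reported as NaN, never silently 0. BC is not a metric; no triangle
  property is asserted anywhere.
- **Sections**: per-taxon per-section mean ± SD of relative abundance over
  samples, with a tie-corrected Kruskal–Wallis H and chi-square p per
  taxon. Raw p-values are primary (no multiple-testing correction is
  applied to the decision), with a Benjamini–Hochberg column emitted
  alongside for transparency.
- **Co-abundance**: Pearson r over samples (closed, compositional data —
  correlations are computed on the closed values exactly as is common for
  co-abundance heatmaps; no CLR transform by default, and the
  compositional caveat stands). Two-sided p from t = r√((n−2)/(1−r²));
  |r| = 1 pairs get p = 0; constant MAGs are excluded with a warning.
  Groups: edges are pairs with p ≤ 0.05 and r ≥ 0.3; MAGs are clustered by
  average linkage on 1 − r, the tree is cut at height 0.7, and groups are
  connected components of the edge graph within cut clusters, size ≥ 2.
  All four knobs are config fields. Output order is deterministic
  (descending summed abundance); labels are A1…/B1… where A marks
  IV-enriched groups (mean member log₁₀ fold change < −0.1), B otherwise.
  Fold changes use log₁₀((mean_V + ε)/(mean_IV + ε)) with ε = 0.01
  percentage points, below any displayed abundance, to avoid infinities.
- **Expression**: within-category relative fractions (categories: CAZymes,
  sulfatases, CGC-member CAZymes — the last a subset of the first) per
  section and class; no gene-length normalization, since shares within a
  category are insensitive to a common per-gene scale, and the
  within-category choice is the default with raw counts also emitted.
  Highly expressed clusters: per sample, substrate-assigned clusters are
  sorted by expression share and the minimal prefix reaching the upper
  quantile (default 0.25) of total CGC expression is selected; a cluster
  qualifies if selected in any sample of the section.

## Synthetic communities

The generator emulates the data structure of a macroalgae-fed herbivore
hindgut MAG study so that every pipeline stage can be checked against
planted truth:

- **Community**: 68 MAGs by default — 31 Bacteroidia, 23 Clostridia,
  5 Bacilli, 4 Gammaproteobacteria, 2 Verrucomicrobiae, and one each of
  three further classes including a sulfur-cycling class with no
  carbohydrate capability. Completeness is drawn uniformly in
  [75.0, 99.5]% and contamination in [0, 6.4]% (the retained-quality
  range; configurable to exercise QC rejection).
- **Guilds**: Bacteroidia carry the full brown+red-algae panel including
  sulfatases; Clostridia are brown-algae-biased (no carrageenan/agarose);
  Bacilli and Gammaproteobacteria are narrow; the sulfur-cycling class is
  empty. Planted families are always guild-restricted (an ambiguous family
  is only planted where *all* its substrates lie in the guild), so the
  planted capability matrix equals the guild table exactly.
- **Scale**: 400 genes per MAG by default, in 100-gene contigs with
  ~1 kb gene spacing — large enough that CAZymes are a realistic minority
  and small enough that the full community generates in about a second.
  Density statistics are scale-free (per-1000-gene rates are planted per
  class, Bacteroidia highest), so conclusions do not depend on this size.
- **CGCs**: Poisson(`cgc_rate` = 2) clusters per guild MAG, each with ≥ 2
  families dedicated to one planted substrate plus a transporter
  (optionally a regulator and one intervening gene). Features are placed
  with ≥ 3 buffer genes so planted clusters never merge.
- **Annotation noise**: per stream, a hit is emitted with probability
  `annotator_agreement` and its label corrupted to a uniformly random
  other family with probability `label_noise` (streams independent) — the
  simplest mechanism that exercises the ≥ 2-agreement rule, with a
  closed-form outcome distribution the tests verify against. Defaults are
  noise-free; tests exercise 10–20% noise explicitly.
- **Abundance**: per sample, MAG weights = class-level base mean × fixed
  per-MAG lognormal variation × a shared per-block lognormal factor
  (sd 0.8 by default) × the block's section multiplier × lognormal
  residual noise (sd 0.15), closed to 100%. Six default blocks emulate
  IV-enriched (A) and stable/V-enriched (B) co-abundant groups.
- **Transcripts**: negative-binomial counts (dispersion 2) for annotated
  genes with class-by-section expression multipliers that make the
  hindgut chamber (V) Bacteroidia/Clostridia-dominated.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence-level artefacts (chimeric contigs,
fragmented genes, binning contamination leaking genes across MAGs),
correlated annotator errors (real streams fail on the same divergent
proteins, not independently), incomplete database coverage of novel
families, compositional coupling between capability and abundance, and
background transporter/regulator genes outside planted clusters (so on
synthetic data every detected cluster is planted; on real data the
detector will also report spurious neighbourhoods at a rate set by the
local density of signature genes).

## Numerical and design choices

- All randomness lives in the generator (one `numpy` Generator per plan
  seed); analysis stages are deterministic and seed-free, and re-running
  the pipeline on identical inputs yields byte-identical TSVs (fixed float
  formats, stable sort keys everywhere; tie-breaks are lexicographic on
  ids).
- Coordinates are 1-based inclusive everywhere (GFF3 convention).
- The rank-sum statistic reported is W (rank sum of the first class);
  exact p at small untied n, tie-corrected normal otherwise.
- Degenerate inputs are explicit: < 3 samples for correlation is an
  error, constant MAGs are dropped with a warning, all-zero Bray–Curtis
  pairs are NaN, a section/category with zero transcript counts yields
  missing fractions, a class with < 2 MAGs cannot be rank-sum tested.
- Known limitations: the substrate catalog is scoped curation, not a
  database mirror; co-abundance correlations on closed data conflate
  shared response with closure effects (the B1 group in the worked
  example absorbs weakly coupled MAGs for exactly this reason at n = 8
  samples); group delineation thresholds (r ≥ 0.3, cut 0.7) are
  pragmatic defaults, declared and configurable, not estimated from data.
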