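# Methods

This note documents the models and procedures implemented in `beebias`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic-data tests show.

## Literature counting

**Record model.** A source record carries a native identifier (UT for
Web of Science, EID for Scopus), an optional DOI, title, abstract, year,
document type, language and free-text country field. DOIs are normalised by
lower-casing, trimming, and stripping a leading `doi:` prefix; an empty
result is treated as absent.

**Within-source deduplication** keeps the first record per native id, then
the first record per normalised DOI among the survivors. Null DOIs never
collide. The operation is idempotent and order-preserving.

**Cross-source linkage** is precision-first and two-step: an exact merge on
normalised DOIs, then — for the DOI-unmatched remainder, grouped by
identical publication year — greedy one-to-one linking of pairs whose
token-overlap title similarity (|shared tokens| / |smaller token set|)
reaches the threshold (default 0.9, configurable). Ties are broken by
higher similarity, then input order, making linkage deterministic. The
output partition (intersection / WoS-only / Scopus-only) always satisfies
the accounting identity |union| = |I| + |W| + |S|.

**Alias library.** Each genus contributes its canonical name, binomial
abbreviations generated from species names ("Apis mellifera" →
"a. mellifera"), and configured common-name expansions (honey bee/honeybee
→ *Apis*, bumble bee/bumblebee → *Bombus*, carpenter bee → *Xylocopa*,
mason bee → *Osmia*, leafcutter/leaf-cutting bee → *Megachile*, mining bee
→ *Andrena*). Multi-valued alias cells are split on `;`, `,`, `/`, `|`
(common export dialects). Every alias is stored Porter-stemmed. A
non-abbreviation alias claimed by two genera is a hard error; colliding
abbreviations (e.g. the same epithet under two genera sharing an initial)
are dropped with a warning rather than guessed — matching stays
conservative.

**Index and counting.** Titles and abstracts are lower-cased, stripped of
punctuation and Porter-stemmed (implemented in `beebias.porter` as the
classic 1980 algorithm, e.g. "pollinating" → "pollin"); the inverted index
maps each stemmed token to per-document position lists. Multi-token aliases
must match as *consecutive* stemmed tokens — positional phrase matching
prevents "honey … bee" false positives, a detail the alias-matching idea
leaves open. A document contributes at most one count to each genus it
mentions, (genus, year) cells accumulate those contributions, and each
unordered genus pair in a document increments a co-occurrence count.
Documents without a year are retained under a sentinel year (−1) and
excluded from year-indexed models, avoiding silent loss.
`mode="high_confidence"` excludes binomial-abbreviation aliases, the
matching class that manual validation of such pipelines identifies as
error-prone. Topic filtering is a pluggable document predicate (default
pass-through); transformer NER and embedding-based filtering are out of
scope, and geographic assignment uses an exact whole-phrase gazetteer
(case-insensitive, word-boundary-delimited) instead.

**Validation harness.** Automated totals are compared with manual reference
counts via Spearman ρ (average ranks on ties), Pearson r, MAE, RMSE and the
OLS slope of manual on automated; an optional labelled precision sample is
summarised with a Wilson score interval. Requires ≥ 3 shared genera.

## Network centrality

Networks are non-negative visitation matrices, plants on rows. Cleaning
removes empty rows/columns (transposing first when pollinators arrive on
rows) and rejects negative entries or matrices that empty out. Pollinator
labels parse to genus (first token, capitalised, synonym-mapped); columns
sharing a parsed genus are **summed before** metric computation, treating
the genus as one node — the merge rule genus-level analysis implies but
label-parsing alone does not fix.

Species strength is `s_j = Σ_i a_ij / r_i`; the strengths of a cleaned
matrix always sum to the number of plant rows. Specialisation is
`d_j = Σ_i p'_ij ln(p'_ij / q_i)` with `p'_ij = a_ij / A_j` and
`q_i = r_i / m`; terms with `a_ij = 0` contribute zero. The standardised
`d'_j = (d_j − d_min) / (d_max − d_min)` uses extremes attainable given the
column total and margins: `d_max = ln(1/min_i q_i)` (the KL divergence is
convex over the allocation simplex, so its maximum sits at the vertex with
the rarest partner, which every integer total can realise), and `d_min` by
incremental greedy allocation of the column total one visit at a time to
the row with the smallest marginal increase — exact for a separable convex
objective, and verified against exhaustive enumeration over all integer
allocations on small matrices. Non-integer (pre-normalised) weights fall
back to the continuous bounds (`d_min = 0`). When the bounds coincide (the
margins admit a single divergence value, e.g. one visit in an identity
matrix), `d'` is defined as 1 if that common value is positive and 0
otherwise, which keeps the "maximally specialised given the margins"
reading. For binary networks the metrics are computed on the 0/1 entries
directly.

Within each network, metrics are z-scored with the sample standard
deviation; an all-equal vector maps to zeros rather than infinities, which
keeps degenerate networks usable. Networks with fewer than 3 matched
pollinator genera are dropped entirely (with a drop log). The per-genus
summary averages z-scores within regions and then across regions
(region-balanced, so heavily sampled regions cannot dominate); genera with
no region labels use an interaction-weighted pooled mean. Sensitivity
analyses recompute the centrality–effort Spearman after excluding each
region in turn (regions whose removal leaves < 3 genera are flagged, not
computed) and under a percentile bootstrap over networks (default B = 1000,
seeded; degenerate resamples skipped and counted). Both strength and `d'`
are z-scored and reported per network; only z-strength feeds the genus
centrality summary.

## Trait space

Traits (intertegular distance and tongue length, mm) are z-scored over
species; principal components are extracted from the *genus-mean* matrix so
species-rich genera cannot dominate the genus-level axes; each species
inherits its genus' PC scores and the least-squares residuals of the
z-scored traits on those scores (default 2 PCs, configurable to 1) become
the analysis coordinates. Residuals are orthogonal to the genus-PC
regressors by construction.

Densities are Gaussian product-kernel KDEs with a per-axis Silverman
rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)`, evaluated on a
regular grid spanning the data range plus 3 bandwidths per side (default
200×200; 60–120 cells per axis in tests and the pipeline for speed — the
grid integral stays within 1% of unity either way). An isopleth region at
level ℓ is the smallest highest-density set of cells holding ≥ ℓ of the
grid mass (default ℓ = 0.95; the level is a choice, not a given). Coverage
of the all-species region by a group is the cell-count fraction of the
reference region intersected — an explicit operationalisation of "covers X%
of overall trait space". Overlap mass is `Σ min(f_A, f_B)·ΔA` (symmetric);
a group's unique mass is its density mass outside the other group's
isopleth region. Permutation nulls redraw same-size species subsets without
replacement (default 999 draws, seeded) and use the add-one estimator
`p = (1 + #extreme)/(n_perm + 1)`; the tail is explicit — lower for
coverage and overlap (the scientific question is whether groups span *less*
space than chance), upper for centroid distance.

## Bias statistics

**Popularity expectations.** Expected counts are proportional to a
public-interest score: `expected_g = T·pop_g / Σ pop` with `T` the observed
total, so expected and observed totals agree exactly. Deviations are
reported as residuals and as percent of expected rounded half-away-from-zero
to integers, the convention that matches how such tables are printed.
`deviation_table` accepts externally supplied expected counts so published
observed/expected pairs can be re-analysed directly.

**Policy groups.** Genera are classified in the effort × centrality plane:
high effort above an effort threshold (default: median of
log10(articles + 1)), high centrality above a centrality threshold
(default: median of mean z-strength). Thresholds are free parameters
reported with every classification; the four groups always partition the
classified set, and a managed share per group is computed when flags are
supplied.

**Scaling.** OLS of log10(articles + 1) on log10(richness) with HC3
standard errors (`(XᵀX)⁻¹ Xᵀ diag(e²/(1−h)²) X (XᵀX)⁻¹`) and Wald 95% CIs.
Points with Cook's D > 4/n or leverage > 2p/n are flagged; refits exclude
flagged points, the named dominant genera (*Apis*, *Bombus* by default) and
the top ⌈1%⌉ of genera by richness and by article count.

**Family comparisons.** Welch's heteroscedastic one-way ANOVA with
Satterthwaite-type denominator df, followed by Games–Howell pairwise
contrasts (unequal-variance SEs, Welch–Satterthwaite df, studentised-range
reference) with Benjamini–Hochberg adjustment across the k(k−1)/2 pairs.
Groups need ≥ 2 values and positive variance; families below that are
excluded upstream. The BH step-up is monotone and never below the raw p; it
is *not* idempotent on its own output (a property sometimes assumed of it),
which the tests deliberately do not assert.

**Share trends.** Yearly category shares are modelled with two-column
binomial GLMs (logit link) of share on calendar year; complete separation
is flagged rather than estimated. Multi-level compositions use one-vs-rest
fits with BH-adjusted p-values. Era changes compare mean shares over an
early and a recent window (default five years each) in percentage points.

**Count models.** Genus-year counts are fitted with fixed-effects NB2
negative-binomial regression (log link), coefficients and dispersion
estimated jointly by maximum likelihood via statsmodels, with the log of
the yearly total as an exposure offset so coefficients describe shares of
attention rather than absolute counts. Effects are reported as incidence
rate ratios `exp(β)` with Wald 95% intervals; dispersion is reported as
`θ = 1/α` and an essentially-zero α is flagged as the Poisson limit.
Random-effects (country/genus) structures are out of scope by design; the
design matrix accepts the same covariates (managed, managed × scaled year,
sociality, nesting contrasts, scaled log1p richness, z-strength).

## Synthetic study design

The generators are pure functions of their specs (seed included). The
corpus generator plants alias mentions (full name, abbreviation or common
name per configured rates — defaults 0.15 each) in distractor text from a
closed synthetic vocabulary that cannot collide with any alias after
stemming; mention rates decay with the genus' position in the cast
(0.5/rank^0.7), mimicking the concentration of real effort; 30% of
documents are exported to both pseudo-sources and 15% lack DOIs, so both
linkage steps are exercised. The network generator allocates a fixed
interaction total (600 by default) per network by multinomial sampling with
cell probabilities ∝ plant weight × genus attractiveness over four
pseudo-regions. Trait clouds are bivariate normals around (5, 5) mm with sd
0.5 mm; group offsets are expressed in sd units so overlap is controlled on
the analysed scale, genus labels are assigned independently of group with
small genus-mean shifts (so residualisation has work to do without erasing
group structure), and the rare non-positive draw is resampled. The count
generator uses a managed premium of IRR 2.86, a managed × year interaction,
a richness elasticity of IRR 1.5 per sd of log1p richness, dispersion
θ = 2, and yearly exposure totals growing geometrically from 252 (1975) to
3,574 (2023) — magnitudes mirroring the published study so the synthetic
audit is a scaled, qualitative emulation rather than a reproduction of
licensed data.

What passing tests show — and what they do not: exact planted-count
recovery demonstrates that deduplication, linkage, indexing and phrase
matching are lossless *under unambiguous text*; real abstracts contain
homonyms, spelling variants and non-English fragments the generator does
not emulate, so real-world precision/recall must come from the validation
harness on labelled samples, not from these tests. Likewise the synthetic
networks have no sampling heterogeneity beyond region labels, and the trait
clouds are Gaussian; the statistics are verified as *procedures*, not as
field estimates.

## Numerical choices and problem sizes

Seeds are explicit everywhere randomness occurs; the pipeline derives
per-stage seeds from a master seed by hashing. NB fits retry with BFGS on
Newton non-convergence and raise rather than return a silent failure.
Percent deviations round half away from zero. The acceptance checks run at
deliberately modest sizes chosen as the smallest that make the statistical
assertions sharp: 1,000 random matrices for strength conservation; the
`d'` bounds verified exhaustively over *all* 2×2 integer matrices with
total ≤ 12 and all 2×3/3×2 with total ≤ 8 plus 2,000 sampled shapes up to
4×4 with total ≤ 12; 50 fixtures per statistical kernel against independent
oracles (pingouin, statsmodels, literal formulas); 200 replicates at
n = 2,000 for NB recovery (mean bias < 0.05, Wald coverage within
[0.92, 0.98]); 500 replicates for permutation-p uniformity (KS < 0.1); and
20 replicates for the planted-attractiveness ranking. Published field-level
estimates (e.g. ρ = 0.140, scaling 0.673, IRR 4.37/2.86, the hypervolume
percentages) depend on licensed corpora and compiled datasets and are not
reproduction targets; the synthetic study emulates them qualitatively.

## Known limitations

Visitation is not pollination: strength and `d'` describe structural
position in recorded networks, inherit abundance and sampling effects, and
say nothing about per-visit effectiveness. Genus-level attributes (managed,
sociality, nesting) are binary lineage properties that collapse
within-genus variation. The fixed-effects NB model ignores the panel
correlation a random-effects structure would absorb, so its intervals are
calibrated for the synthetic design, not for country-genus panels.
Abbreviation matching trades recall for precision and is excluded entirely
in high-confidence mode. The KDE machinery is 2-D by construction; more
trait axes would need a different density estimator.
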