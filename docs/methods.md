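# Methods

## The weighted-sum target score

Each candidate protein is scored from a single evidence platform by

    TS = w_e * (effect / effect_ref) + w_c * (C / c_ref) + w_h * (H / h_ref)

with defaults `w_e = 0.33`, `w_c = 0.34`, `w_h = 0.33` (the published weighting,
kept verbatim rather than rounded to thirds) and reference constants
`effect_ref = 2.37` (CSF Abeta42 fold change) for fold-change platforms,
`effect_ref = 3.7` (APOE-e4 odds ratio) for genetics, `c_ref = 4092` and
`h_ref = 11294` (citations of the founding APP pathogenesis paper and
APP-plus-disease publication count, both fixed historical snapshots). All four
references and both count inputs are unitless counts or ratios; fold changes are
signed magnitudes `|F| >= 1` (sign = direction of change in cases, ignored by the
score), odds ratios are per-risk-allele.

Model assumptions worth making explicit:

* The three components are exchangeable up to their weights — a citation-rich target
  with a weak effect can outrank an effect-rich target with no literature.
  The score is linear; no saturation is applied, so scores above 1 are possible for
  evidence stronger than the references. The internal control (APP by convention) is
  the one exception: when designated, its score is pinned to exactly 1 by fiat and
  the row is flagged. Its computed component terms are retained for inspection; the
  term-sum identity `total = effect + citation + publication` therefore holds for
  every row except a pinned control.
* `C` and `H` are point-in-time literature counts. They are inputs, not quantities
  the package derives; the pathogenesis-annotation table carries them.
* Evidence aggregation within a platform takes the strongest signal: the maximum
  odds ratio across a target's associations, the largest fold magnitude across its
  proteomic observations.

### Metabolomic imputation

A protein reached only through metabolomics has no direct fold change. It inherits
one from its linked metabolites: with `n` altered linked metabolites of magnitudes
`|F_i|` out of `N` total linked metabolites,

    imputed |F| = (sum_i |F_i| + (N - n)) / N

i.e. the mean magnitude over all `N` links with unaltered metabolites counted at 1
(no change). `N` deliberately counts *all* link-table partners of the protein, not
only altered ones — the imputation dilutes the signal of a promiscuous protein whose
other partners did not move. With `N = n = 1` the formula degenerates to the direct
fold change, so the metabolomic equation reduces exactly to the proteomic one
(property-tested).

### Platform resolution and ranking

Targets implicated by several scoreable platforms report a single score. The default
rule is `max` (the most favorable platform, recorded in the output); `priority`
(proteomics > genetics > metabolomics) is available for users who prefer direct
measurements over imputed or allele-level effects. The source data report one
platform per ranked target without stating a rule, so this is surfaced as
configuration rather than hidden. Epigenetic evidence has no score equation; it
contributes platform membership only and a target with only epigenetic evidence is
reported as unscoreable.

Ranking is total descending with ties broken by accession ascending; ranks are dense
from 1. Duplicate accessions are an error, not a silent merge.

## Candidate assembly

The unified target list is keyed by UniProt accession; gene symbols are display
metadata. GWAS and epigenetic rows report genes, and the gene-to-accession mapping
is an explicit input table, because the locus-to-protein choice (which gene a SNP
tags) is a curation decision the pipeline should not make silently. Metabolomics
contributes proteins linked to >= 2 *distinct* altered metabolites (duplicated link
rows collapse; the threshold is configurable as `min_links`).

## Drug compatibility

Modes of action are partitioned in a shipped, user-replaceable YAML into
*inhibiting* (inhibitor, antagonist, antibody, blocker, suppressor), *activating*
(agonist, activator, inducer, stimulator) and *neutral* (substrate, modulator,
binder, cofactor, unknown) classes. A gain-of-function target is compatible with
inhibiting modes and incompatible with activating ones; a loss-of-function target
the reverse. Compatibility is `unknown` exactly when no direction can be judged:
the target's role is unknown, or the mode carries no direction (the neutral class —
"substrate" is a known word but says nothing about therapeutic direction). Only
approved and clinical-trial drugs are joined; targets without pathogenesis
annotation are excluded from the candidate table but stay in the ranked list.
Targets on a known-target list (default ACHE, APP) are labelled `validation`
rather than `novel`: recovering them is the strategy's positive control. A drug
with several modes on one target yields one row per mode, each judged separately.

## Enrichment

Over-representation is the exact hypergeometric upper tail
`P(X >= k)` for a `K`-gene pathway, `n`-gene query and `N_u`-gene universe
(computed with `scipy.stats.hypergeom`; tests verify it against exhaustive urn
enumeration for universes up to 12). Multiplicity is handled by Benjamini-Hochberg
step-up (via `statsmodels`, checked against hand-computed vectors), applied across
the pathways with non-zero overlap. The universe defaults to the union of the GMT's
member genes; an explicit universe file overrides it and restricts every set. Only
over-representation is tested — depletion is out of scope, matching the behavior of
the usual web tools this replaces.

## Synthetic data generator

The generator emulates the *structure* of the curated inputs, with distributions
chosen to reproduce the qualitative landscape of the real analysis:

* Background odds ratios: lognormal, median 1.15, sigma 0.15 — typical GWAS effects.
* Background fold magnitudes: `1 + Exponential(mean 0.6)`.
* Citation/publication counts: discrete power law (zipf, exponent 2) — most targets
  have a thin literature, a few are heavily studied.
* Bipartite links: guaranteed `>= 2` altered metabolites for each designated
  metabolomic target, plus Poisson-degree background links, deduplicated.
* Every background effect draw is resampled to stay at or below its reference
  constant (2.37 / 3.7 for effects, 4092 / 11294 for counts). This encodes the
  anchoring assumption that the internal control represents the strongest known
  evidence: background scores concentrate near 0.24 and cannot reach 1. It is also
  what makes planted-signal recovery well-posed — without the truncation the upper
  order statistics of 500 background draws overlap a 3x-boosted planted signal and
  "planted targets rank on top" would not be a construction, only a tendency.
* Planted targets receive all components multiplied by `plant_boost` (default 3)
  and are assigned the proteomics or metabolomics platform, alternating. Genetics
  is not used for planting: the background odds-ratio distribution sits roughly
  three-fold below its reference, so a 3x boost there lands *at* the anchor rather
  than above the proteomic background ceiling, and recovery would be a coin flip
  rather than a property. Planted metabolomic targets get dedicated altered
  metabolites carrying the boosted folds (not shared with background proteins), so
  the boost cannot leak into background imputations.
* The drug catalog guarantees each planted target one approved-or-clinical drug
  whose mode is compatible with its (planted) GOF/LOF role.
* One PPI hub with 10 guaranteed neighbors and one pathway seeded with 5 of the
  hub's neighbor genes emulate the hub-and-enrichment motif of the real analysis.

Ground truth (planted accessions, per-target true components including realized
`N`/`n`, eligible drug pairs on planted targets, the hub and the seeded pathway) is
derived from the *emitted* tables after construction, so it is consistent with them
by definition.

What the generator does **not** emulate: linkage structure among SNPs, correlated
fold changes, real metabolite chemistry, drug pharmacology, or literature-count
biases that correlate with effect sizes. Passing recovery tests therefore shows the
pipeline's bookkeeping and ranking are correct under the stated statistical
conditions — not that the score separates real targets from noise in curated data.

Default scale: 500 targets (platform mix 42% genetics / 19% proteomics /
36% metabolomics / 3% epigenetics, 8 two-platform targets), 86 altered metabolites
plus as many unaltered link partners, 120 catalog drugs, 5 planted targets at 3x.
These defaults mirror the proportions of the real curated corpus at a size where a
full pipeline run takes well under a second.

## Numerical choices

* Score totals use compensated summation (`math.fsum`); with components exactly at
  the references the three weighted terms sum to exactly 1.0 in IEEE double
  precision.
* Fold-change normalization: input ratios with magnitude in (0, 1) are converted to
  `-1/|r|` (a decrease), on by default with a logged count; with normalization off
  such rows are rejected. A fold change of 0 is always rejected.
* Determinism: all generator draws come from one `numpy` PCG64 stream in a fixed
  order; network exports sort nodes and edges lexicographically; every output table
  has a fixed column order. Same seed, same bytes.
* Deduplication keeps the first occurrence (evidence rows on their platform key,
  drug rows on drug/target/mode).
* Stage normalization: lowercase synonym lookup, any unmapped `phase ...` string
  counts as clinical-trial, anything else falls back to experimental with a warning.

## Known limitations

* The headline counts of the original analysis (524 proteins, 1179 links, 18
  targets / 75 drugs, the printed enrichment p-value) depend on 2016 snapshots of
  curated databases that are not shipped; the pipeline logs the corresponding counts
  of whatever inputs it is given instead of asserting them.
* `C` and `H` must be supplied; the package does not query literature databases.
* Multi-platform resolution and the String confidence cutoff are configuration, not
  claims about what the original analysis used.
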