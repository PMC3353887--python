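# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Homology projection

Ortholog tables carry (yeast ORF, human gene, source, optional
confidence) rows; identifiers are upper-cased and no alias resolution is
attempted. The default merge is the **union** of sources with provenance
retained — union maximises recall, which matches a screening use case;
intersection is available for high-precision work. A human gene
orthologous to both a sensitive and a non-sensitive yeast gene is a
modulator homolog (any-ortholog rule); this is the only reading under
which modulator and non-modulator homologs form a disjoint partition of
the genes with screened orthologs. Yeast ORFs absent from the phenotype
table are dropped with a logged count rather than treated as
non-sensitive: absence of evidence is not a negative phenotype.

## LCC permutation test

The statistic is the size of the largest connected component of the
subgraph induced by the query set; ties between equal-size components
are broken by the lexicographically smallest member so results are
deterministic. Two nulls are provided:

* **uniform** (default): node sets of size |query ∩ nodes| drawn
  uniformly without replacement. Used by all headline numbers.
* **degree_matched**: sampling within geometric degree bins with
  boundaries 1, 2, 3–4, 5–8, 9–16, … (degree 0 is its own bin). Hub
  genes inflate connectivity, so a degree-aware null is the standard
  robustness companion; exact binning is a convention, and results from
  both nulls should be reported together.

The p-value uses the add-one estimator (n_geq + 1)/(n_perm + 1), which
is never zero; when n_geq = 0 the result carries an explicit
upper-bound flag. Published claims of the form p < 1e-16 from analytic
or extrapolated nulls are treated as bounds — the package guarantees
correct bound semantics rather than reproducing extrapolation.

Because the LCC is integer-valued, the null distribution of p is
discrete. "Uniformity" of null p-values therefore means calibration at
achievable levels — P(p ≤ t) = t for each achievable tail value t — and
that is what the test suite asserts, alongside exact agreement with
exhaustive subset enumeration on small graphs.

Enrichment of subnetworks uses the upper-tail hypergeometric
probability with Benjamini–Hochberg adjustment reported alongside raw
p-values; terms with no query member are not reported.

## Candidate selection

Rules run in a fixed order with a per-gene audit trail; the core set
(homologs of all-agent-sensitive yeast genes) is included before any
exclusion applies, because a universally sensitive deletion phenotype is
stronger evidence than a category label. "Several protein–protein
interactions" is a rank criterion (network degree), not a hard cutoff —
no defensible threshold exists. "One-to-one" means the gene is the
unique human homolog of at least one of its yeast orthologs, computed
from the merged table's multiplicity index. The expression gate is
strict (> 100 intensity units); a gene absent from the expression table
counts as not expressed and is logged, not errored. The telomere add-on
is configuration, not inference: shelterin has no yeast counterpart, so
its inclusion is a biological decision recorded as such. The weighting
among preference criteria is a package choice (lexicographic rank key)
and is configurable.

## Toxicity calling

Relative survival is (colonies/seeded)/PE with PE the mean dose-0
plating efficiency per line × agent, capped at 1.0. Zero-colony
replicates become 0.5 colonies (continuity correction) so log2 values
stay finite; each correction is counted on the curve.

The noise region is built per agent × dose from log2(control line mean /
non-targeting mean); the non-targeting line contributes its self-ratio
0, so the interval always contains 0. The effect size of a test line is
its log2 ratio's *excess* beyond the nearest region boundary — the
thresholds 0.26 (= log2 1.20, a 20% change) and 0.32 (= log2 1.25, 25%)
are measured from the region edge, not from the control mean, so a call
always clears the entire observed control spread. The alternative
reading of "20% more sensitive" as an absolute survival difference is
inconsistent with the printed log2 constants and is not implemented.

The significance test is a two-sided Welch t-test on log2 replicate
survivals. Log2 space matches the thresholds and makes multiplicative
noise homoscedastic; Welch avoids assuming equal variance between
clones. Calls are per dose with the maximum-|excess| qualifying dose
reported ("at at least one dose-point" semantics). No multiple-testing
correction is applied across lines or doses: each line × agent is one
declared comparison at α = 0.05, and the conjunctive effect-size gate
makes the realised false-call rate far below α (measured in the
recovery tests). The t-test is only evaluated at doses whose excess
clears the low gate, since a dose failing the gate cannot qualify.

Summary percentages are whole percents with halves rounded away from
zero (25/34 → 74, 19/34 → 56, 14/34 → 41, 11/34 → 32). The
screen-vs-comparison contingency test is Fisher's exact, computed by
exact integer enumeration of tables with the observed margins using the
standard minimum-likelihood two-sided rule; a zero margin returns p = 1
with a degenerate flag.

## Autophagy scoring

A cell is autophagic iff it shows strictly more than 5 puncta (the
threshold is configurable). Condition-vs-reference comparisons use the
same exact Fisher test on autophagic/non-autophagic counts (chi-square
offered for large n); stars follow p < 0.05 / p < 0.01. Fold induction
uses the untreated condition of the same cell line as reference and is
undefined (not 0 or ∞) when the reference fraction is 0.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions: 2,000 yeast genes × 2,000 human
genes (a desk-scale genome), 30% ortholog coverage, 15% one-to-many
rate, 80% per-source retention of the latent truth (so the two sources
partially overlap), 30% sensitivity per agent with a 12-gene all-agent
core, a Barabási–Albert interactome of mean degree ~6 with a 30-gene
planted module wired at edge probability 0.25, log-normal expression
(median ≈ 148 intensity units against the 100 threshold), abstract
equitoxic doses 0–3 with per-agent decay 1.1 log2 units/dose (top dose
≈ 10% control survival), 3 replicates at 10% multiplicative CV, one
non-targeting and four non-silenced control lines, injected effect
magnitude 0.5 log2, and a 75% planted modulator rate among tested
candidate lines. Replicate CV is not published for the original assays;
0.10 is an assay-realistic default exposed as a parameter, and the
recovery analyses also run at 0.05.

Noise is multiplicative log-normal so log2 ratios have additive
homoscedastic noise, matching the caller's thresholds. Survival is
truncated at 1.0 after noise; exact zeros are never generated, though
integer colony rounding can produce zero counts at extreme kill, which
the caller's continuity correction absorbs. The per-line effect applies
only at dose > 0: dose 0 is the plating-efficiency anchor and must
normalise to 1.

One global seed drives a splittable per-generator stream
(`default_rng([seed, stream_index])` with stable append-only indices),
so identical configuration and seed give byte-identical outputs and new
generators never perturb existing ones.

What the generator does **not** emulate: real ortholog-database
disagreement structure (coverage is missing-at-random), interactome
study bias and false-positive edges, day effects or plate-position
effects in colony assays, off-target shRNA effects beyond the
non-silenced control mechanism, and dose–response curvature (kill is
exponential in dose). Passing tests therefore demonstrate correctness
of the analysis pipeline under its stated assumptions, not performance
on real screens. In particular, with default settings the planted
30-gene module is diluted inside the full ~540-gene modulator query, so
the whole-set permutation p is null-like; the planted signal is
assessed by querying the module itself. Published absolute counts
(1,368 / 646 / 284) depend on 2008-era database versions and are not
reproduction targets; the package reproduces the *arithmetic* on the
printed counts and the procedure's statistical behaviour.

## Problem sizes

Simulated analyses run at desk scale, chosen so the full suite and the
acceptance script complete in seconds to minutes on one CPU: 2,000-gene
universes, 1,000-permutation tests (500 in the pipeline acceptance
run), 4 × 100-line recovery screens, 200-seed calibration studies, and
exhaustive sweeps capped at N ≤ 40 (Fisher) / N ≤ 40 (hypergeometric
parameters) / 12 nodes (LCC enumeration).
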