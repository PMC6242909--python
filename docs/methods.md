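# Methods

## Scope and data model

`satmut` treats a saturation-mutagenesis analysis as three layers:

1. a **proteome** — accessioned sequences over the 20 standard amino acids,
   with B/U/X/Z tolerated on input but excluded from enumeration and every
   statistic (the 19-substitution scheme is defined only for standard
   residues);
2. **residue annotations** — 1-based, inclusive intervals carrying one class
   label from one of six categories (functional, ptm, secondary_structure,
   domain, ppi, topology). Class vocabularies are controlled but
   extensible via configuration. "Background" is always computed, never
   stored: a residue is background for a category iff no record of that
   category covers it;
3. **scores** — a map from (accession, position, wt, mut) to a value in
   [0, 1]. The scorer itself is a pluggable seam (a deterministic callable
   or a precomputed table); the package never re-implements any particular
   predictor.

Enumeration is lazy and totally ordered (protein input order, ascending
position, alphabetical mutant), so proteome-scale scans never materialise
key lists and repeated runs are byte-identical. The closed form
`19 × (standard residues)` is validated against exhaustive enumeration in
the tests.

## Statistics

**Threshold bands.** The score distribution is summarised by the fractions
below/above ordered thresholds, default (0.3, 0.6, 0.9): below 0.3 is read
as (nearly) neutral, above 0.6 as likely deleterious, above 0.9 as extreme.
The full four-band partition ([0,t1), [t1,t2], (t2,t3], (t3,1]) always sums
to 1.

**Class conditioning.** A variant belongs to an annotation class iff its
wild-type position is covered by that (category, class); a variant at a
multiply-annotated residue counts once in every covering class, and the
category-level aggregate is the union (no double counting within itself).

**Rank-sum comparisons.** All class-vs-class and blind-test comparisons are
two-tailed Wilcoxon rank-sum tests on the rank sum `W` of the first sample,
using the normal approximation `z = (W − μ_W)/σ_W` with midranks and
tie-corrected variance and no continuity correction. Tie correction is
included because bounded or synthetic score sets can tie; with continuous
scores it is a no-op and the statistic coincides with the textbook
(and scipy `ranksums`) value. For pooled sample sizes at or below a
configurable cutoff (default 12) the p-value is computed instead by exact
enumeration of all rank assignments, `p = min(1, 2·min(P(W≤w), P(W≥w)))`.
Two-tailed p-values below 1e-300 are reported via an explicit underflow
flag (`"< 1e-300"`), never as 0 and never silently. Raw p-values are the
primary read-out; a Benjamini–Hochberg column is available as a clearly
optional extra.

**Positional profiles.** Each variant maps to the relative position
`(position − 1)/(L − 1)` (N-terminus 0, C-terminus 1; length-1 proteins
excluded) and is binned into `n_bins` half-open bins `[i/n, (i+1)/n)` with
the last bin closed; 100 bins by default, i.e. percent of sequence length.
These conventions are package choices; any monotone alternative ("position/L"
etc.) changes bin membership only at edges.

**Codon degeneracy.** Variants are grouped by *mutant* amino acid; each
group's grand mean score (over all variants, not per-protein means first) is
paired with the amino acid's sense-codon count in the standard nuclear code
(Leu/Ser/Arg 6; Ala/Gly/Pro/Thr/Val 4; Ile 3; Met/Trp 1; the rest 2; total
61), and a Pearson correlation over the 20 pairs is reported.

**Substitution matrices.** For a class, `mean[i, j]` is the arithmetic mean
score of variants with wild-type `i` and mutant `j` at covered positions;
rows are wild-type, columns mutant, both alphabetical, and the orientation
is written into every output header. A cell is masked when its count is
**at most** `min_count` (default 100, i.e. a strict "more than 100
occurrences" filter, applied per cell per class); the diagonal is
structurally empty and always masked. Secondary-structure differential
profiles aggregate by mutant amino acid (class mean minus the mean over
SS-unassigned residues); a wild-type-marginal variant is available as an
extra, non-canonical view. Correlations against per-amino-acid biophysical
scales use the shared Pearson routine; the packaged example scale is
synthetic (invented values for interface demonstration) and carries that
warning in its header.

**Case studies.** A protein landscape is the L×20 matrix of scores with the
wild-type cell of each row reserved (NaN in memory, `WT` in TSV, distinct
colour in plots); building one requires a complete scan for that protein and
missing cells are an error. The blind-test procedures are (a) the
minimum-score check over a single-label variant list, with both strict (>)
and inclusive (≥) threshold conventions exposed; (b) two-class rank-sum
discrimination with per-label distribution summaries; (c) cross-predictor
agreement as Pearson r over the intersection of variant keys.

## Synthetic generator

The generator emulates the *product* of a curated proteome study so that
every pipeline stage has ground truth. Sequences are i.i.d. draws from a
configurable composition (uniform by default). Each category places
non-overlapping intervals within itself (SS elements, topology segments or
PTM sites of one track never stack), while different categories overlap
freely — a domain may contain helices and sites, as in real annotation.
Target coverage densities and interval-length ranges per category default
to: functional 5% (1–3 residues), ptm 5% (single residues),
secondary_structure 30% (4–12), domain 35% (40–120), ppi 6% (5–15),
topology 45% (20–60). Densities are approached by rejection sampling and an
interval that cannot fit a protein at all is an error.

Scores follow a **logit-additive effect model**:

    score = logistic(β₀ + Σ_active β_class + γ[wt, mut] + ε),  ε ~ N(0, σ²)

where the sum runs over the *distinct* (category, class) labels covering the
position (set semantics — duplicate coverage by the same class adds the
shift once). Defaults: β₀ = −0.8 (a mildly tolerant baseline); class shifts
(logits) functional classes +1.5, disulfide bonds +2.0,
glycosylation/lipidation +0.8, other PTMs +0.3, SS classes +0.5, domains
+0.4, interaction patches +0.7, transmembrane +0.6, intramembrane +1.2,
plain topological compartments 0.0; γ ≡ 0; σ = 0.5. The ordering of these
knobs follows the known biology (oxidised cysteines and intramembrane
stretches least tolerant, domains mildest, soluble compartments at
baseline); their magnitudes are arbitrary effect-size choices, not estimates
of any real predictor. The +0.3 for the "Other" PTM class and 0.0 for
non-membrane topology classes fill gaps where no default was prescribed,
keeping "Other" weakest among PTMs and the compartments as the tolerant
reference.

Reproducibility: a single seed is split into independent streams keyed
`[seed, 0, protein]` (sequence/length), `[seed, 1, crc32(category),
protein]` (annotation placement) and `[seed, 2, protein]` (score noise), so
adding a category or protein never perturbs other draws, and equal seeds
give byte-identical output files.

`truth_report` emits, per class, the planted logit shift and the expected
score mean `E[logistic(β₀ + β + σε)]` via 80-node Gauss–Hermite quadrature
(exactly `logistic(β₀ + β)` at σ = 0; the quadrature matches a 10⁶-draw
Monte-Carlo estimate to < 10⁻³ in the tests).

### What recovery means here

`evaluate_recovery` checks two things on a simulated study: (a) for every
category, the empirical means of its classes plus the category background
rank exactly as the planted expected means (pairs with equal planted shifts
carry no order and are skipped); (b) every class with a nonzero shift shows
the matching class-vs-background rank-sum direction. Recovery is defined
*within* categories deliberately: a class of category C never receives C's
own coverage as contamination, while classes of other categories do, so
expected means across categories differ by category-dependent offsets and
the cross-category ranking of single-class expectations is not identified.
Within a category, the other tracks contaminate every class equally in
expectation, which matches the per-track class-vs-background construction
the statistics module reports.

The default densities give each sparse-category class roughly 200+ covered
positions at the default study scale (50 proteins × 300 residues), putting
the narrowest planted mean gaps (0.1 logit ≈ 0.02 score near the baseline)
at ≥ 3 standard errors — small enough classes would make ordering recovery a
coin flip at this scale.

### What the generator does not emulate

Realistic protein length and composition statistics (beyond the knobs);
inter-protein homology and domain families; correlated noise along the
sequence (ε is i.i.d. per variant, whereas real predictors smooth along
positions); position-within-interval structure (e.g. N-terminal
methionine effects, interval-edge attenuation); any particular predictor's
score distribution. Passing tests therefore demonstrate that the
*statistics* are implemented correctly and can recover planted effects —
not that any real predictor has those effects.

## Problem sizes for tests and the acceptance script

The suite validates oracle equivalence on 100 random ~2,000-variant
instances, rank-sum calibration on all pooled sizes ≤ 12 plus 200 null
replicates (6 proteins × 100 residues each), and planted-effect recovery on
60 (test suite) / 100 (acceptance script) default-scale studies; the
SP17-scale enumeration identity is checked on a generated 8,939,795-residue
proteome via the closed form after validating it exhaustively on small
proteomes. These sizes are the package's chosen trade-off between
statistical resolution and a few minutes of runtime on one CPU.

## Known limitations

* The annotation reader accepts only the documented TSV; UniProt flat files
  or GFF3 must be converted upstream.
* `score_scan` calls the scorer per variant in Python — fine for case
  studies; proteome-scale scoring should go through precomputed tables
  (`attach_scores`) or the vectorised generator.
* Exact rank-sum enumeration is combinatorial; the default cutoff (12)
  keeps it instant, and far larger cutoffs are impractical.
* Landscape TSVs store one row per position; very long proteins produce
  wide-but-tall files that are better consumed programmatically.
* The discrimination and min-score procedures assume binary label
  vocabularies; multi-class blind sets must be dichotomised first.
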