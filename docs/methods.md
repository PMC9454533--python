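# Methods

## Scope and model of the data

`fluidvar` analyses *annotated post-calling* somatic variants from matched
plasma/urine liquid-biopsy pairs. Everything upstream — read mapping, UMI
consensus, base calling, effect annotation, population allele frequencies,
evidence-code assignment, splice-disruption prediction — is treated as
input. A variant enters the pipeline as a record with coordinates and
alleles, site quality, VAF (percent), depth, gene symbol, consequence
class, signed intron offset, population allele frequency, ACMG/AMP evidence
codes, a clinical evidence level (A–D or none), and boolean flags for
gain/loss-of-function association, external splice prediction and
established pathogenicity.

### Variant identity and normalization

Concordance between fluids requires a representation-invariant identity.
The key is `(chrom, pos, ref, alt)` after canonical minimal trimming:
shared trailing bases are removed first, then shared leading bases with the
position advanced, always keeping at least one base per allele. When a
reference context is available the same loop additionally shifts indels
left through repeat tracts, yielding the unique leftmost minimal
representation; without context, anchored indel representations are already
stable under the trim rules. Chromosome names are compared after stripping
an optional `chr` prefix. Multi-allelic records are split before
normalization, one variant per ALT allele.

Coordinate conventions: VCF positions are 1-based; the exclusion-window BED
is 0-based half-open. The conversion lives in exactly one place
(`window_contains`): window `(start, end)` covers 1-based positions
`start < pos ≤ end`.

### VAF and quality sources

VAF resolution order: the configured INFO tag (default `VAFPCT`, percent),
then the first sample's `AD/DP` ratio; a record with neither is rejected.
Call quality defaults to the `QUAL` column; an alternate INFO tag can be
named in the tag configuration, since "call quality" is not a standardized
quantity across callers. Missing population allele frequency is treated as
0 — absence from the population databases is itself evidence of rarity —
and missing evidence codes classify as VUS.

## Filter cascade

Three sequential stages; all thresholds inclusive on the keep side.

| stage | keeps a variant iff | defaults |
|---|---|---|
| confidence | quality ≥ `min_call_quality` ∧ VAF ≥ `min_vaf_pct` ∧ position outside the excluded windows | 50, 3 % |
| common | pop. AF ≤ `max_pop_af` ∨ established pathogenic | 1 % |
| deleterious | \|intron offset\| ≤ `max_intron_offset` ∧ (class ∈ {P, LP, VUS} ∨ GoF ∨ LoF ∨ damaging consequence ∨ splice-region within `splice_loss_offset` ∨ splice predictor flag) | 20 b, 2 b |

Damaging consequence classes: frameshift, in-frame indel, start loss,
stop change, missense, copy-number loss. Each removal is attributed to the
*first* failing criterion in documented order (quality, VAF, window;
common; deep-intronic, not-deleterious) so attrition reports are stable.
The same classifier that produces the reported class distributions supplies
the class used inside the deleterious filter; one engine serves both roles.

## Classification

The five-class impact call implements the 2015 ACMG/AMP combining rules
verbatim over the code alphabet PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4,
BP1–7. Pathogenic: PVS1 with (≥1 PS | ≥2 PM | 1 PM+1 PP | ≥2 PP), or ≥2 PS,
or 1 PS with (≥3 PM | 2 PM+≥2 PP | 1 PM+≥4 PP). Likely pathogenic: PVS1+1
PM, 1 PS+1–2 PM, 1 PS+≥2 PP, ≥3 PM, 2 PM+≥2 PP, or 1 PM+≥4 PP. Benign: BA1
or ≥2 BS; likely benign: 1 BS+1 BP or ≥2 BP. If rules on both sides fire,
or none fires, the call is VUS — deterministic and guideline-consistent.
In-silico predictor aggregation appears only as PP3/BP4-style codes in the
input; no evidence codes are computed here.

Tiers: (likely) benign → IV; otherwise evidence level A/B → I, C/D → II,
else III. This makes tier IV ⇔ benign-side class, and the tier-III fraction
mirrors the VUS fraction.

VAF bins are left-closed half-open over the post-filter domain:
[3,5), [5,10), [10,20), [20,50), [50,100]. The half-open choice makes the
bins a partition; the last bin is closed at 100.

## Concordance and aggregation

Shared-variant membership uses key equality only; VAF, quality and
annotations never enter identity. Recovery from fluid A to fluid B is
`100·|A∩B|/|A|`, undefined for an empty source and then *dropped* (not
zero-filled) before cohort medians. Pathogenic-only recovery conditions on
the class in the *source* fluid: a plasma-pathogenic key counts as
recovered if present in urine regardless of the urine call's class.
Medians use the even-count-average convention; percentages print to one
decimal. The gene table sorts by total count descending, ties by symbol;
the pathogenic presence matrix orders rows by the number of positive
sample×fluid columns, ties by label. Counting is over unique normalized
keys per sample (multi-transcript duplicates collapse).

Invariants enforced on every run: per-fluid total = exclusive + shared;
grand total = both exclusives + 2×shared; each distribution table sums to
its fluid's total; stage outputs chain exactly into the next stage's
inputs.

## Statistics

* **Spearman rho**: Pearson correlation of mid-ranks (average ranks on
  ties), p from the t approximation with n−2 df; constant vectors are
  rejected.
* **Wilcoxon signed-rank** (two-sided): zero differences dropped, mid-ranks
  on tied magnitudes; exact null distribution when n ≤ 25 without ties,
  otherwise the normal approximation with tie and continuity correction.
  The convention matters at the third decimal of p, so results carry a
  method descriptor, and the reference concentration table's p is asserted
  inside a band (0.10–0.14) rather than at a point.
* **Chi-square independence**: Pearson statistic, margins-based expected
  counts, df = (r−1)(c−1), no continuity correction (the reference table is
  2×5 with all expected counts well above 1). Zero margins are errors; the
  pipeline drops all-zero category columns before testing, since they carry
  no information about the association.

All three delegate the numerics to scipy behind this package's interface;
tests cross-check them against independent oracles (mid-rank Pearson from
scratch, exhaustive 2^n sign enumeration, the 2×2 closed form).

## Synthetic cohort generator

The generator emulates the reference study's *statistical structure*, not
its sequences. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 15 | matched pairs |
| `plasma_median_count` / `urine_median_count` | 66 / 110 | per-sample post-filter count medians (log-normal, σ 0.45/0.50, chosen so a 15-sample cohort spans roughly 40–300) |
| `shared_fraction` | 431/1222 ≈ 0.353 | probability a plasma survivor's key also appears in the matched urine sample |
| `vaf_bin_masses` | (0.367, 0.318, 0.190, 0.104, 0.022) | reference pooled bin counts, normalized; draws are uniform within the bin |
| `class_proportions` | (0.044, 0.090, 0.851, 0.011, 0.003) | reference pooled class counts, normalized |
| `removal_rates` | 0.20/0.40/0.05/0.25/0.05/0.05 | expected planted removals per survivor, by reason (low quality, low VAF, windowed, common, deep-intronic, non-deleterious); Poisson counts |
| `hotspot_presence` | (1.0, 0.8) | recurrent pathogenic variants present in both fluids of a patient with these probabilities — the "found in every sample" structure |
| concentrations | log-normal, medians 172/196 ng/mL, σ 0.8/1.3, Gaussian-copula ρ −0.2, urine non-detect probability 2/15 | matched cfDNA concentrations with weak negative rank correlation and below-detection zeros |

Evidence codes are drawn from class-conditional recipes that provably yield
the intended class under the combining rules; benign-class survivors are
given a missense consequence so they still pass the deleterious filter (the
mechanism by which real benign calls survive it). Each planted removal
violates *exactly* its intended criterion and satisfies every other clause,
so cascade recall and precision against the plant are exact, not
statistical. Every emitted record carries a truth row (fate, stage, reason,
class, shared status, hotspot flag).

Randomness: one explicit seed; per-patient substreams derive from
`(seed, patient index)`, so a patient's data is invariant to cohort size,
and identical configurations produce byte-identical files.

What the generator does **not** model — and hence what passing tests do not
show about real data: read-level error, UMI consensus artifacts,
coverage-dependent VAF noise, correlated per-gene mutation hotspots beyond
the weight vector, annotation disagreement between callers, and any
germline contamination structure. Tests on synthetic cohorts validate the
*pipeline's correctness* (set algebra, rule application, reporting
invariants, parameter recovery), not biological effect sizes.

## Numerical and degenerate-input choices

Thresholds are inclusive on the keep side throughout. Empty filter input
yields empty output with zeroed reports. An empty recovery source is
undefined, never 0. A cohort must contain ≥ 1 pair; paired tests need ≥ 3
nonzero differences; constant vectors and zero chi-square margins are
errors rather than NaNs. Reported percentages are rounded only at the
reporting layer (one decimal, or integer where the reference tables print
integers); JSON artifacts store unrounded values.

## Problem sizes

Default analyses run on 15-patient cohorts (~6 000 emitted records
including plants); parameter-recovery checks use up to 100 patients and
10⁴ VAF draws. The full test suite and the acceptance script each complete
in well under a minute on one CPU.

## Known limitations

Per-variant agreement with a commercial annotation/classification engine is
not attainable from evidence codes alone; fidelity is at the distribution
level. The Wilcoxon p is convention-dependent (documented band). The
generator's gene panel and loci are synthetic; gene symbols are real, their
coordinates are not. Left-alignment beyond trim rules requires a caller-
supplied reference context.
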