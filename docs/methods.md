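# Methods

`codonscreen` implements the computational side of a codon-usage-based
genetic modifier screen: synonymous recoding of a coding sequence to tune
its translation, the ordinal severity statistic and two-stage
classification rules of a Drosophila deficiency (Df) screen, and the
downstream interval-overlap and gene-group enrichment analysis. A
synthetic-data generator with planted ground truth makes every stage
testable without external downloads.

## Codon recoding and CAI

A coding sequence is recoded codon-by-codon within synonymous families of
the standard genetic code. Three schemes are provided:

- `extremal_common` — every codon becomes its family's most frequent
  synonym in the supplied genome-wide usage table (maximally "optimised");
- `extremal_rare` — every codon becomes the least frequent synonym
  ("deoptimised");
- `fractional_rare` — `round(f·R)` of the `R` recodable positions (codons
  whose family has more than one member) are replaced by the rare synonym.
  "Dispersed" placement is deterministic: the chosen ranks are
  `floor(i·R/k)` for `i = 0..k−1`, which for `f = 0.5` substitutes every
  second recodable codon starting from the first and never places two
  substitutions at adjacent recodable ranks unless `k > ⌈R/2⌉` forces it.
  A seeded-random placement is available as an explicit opt-in.

The amino-acid sequence is preserved by construction; a terminal stop codon
is never recoded.

The Codon Adaptation Index is the geometric mean of relative adaptiveness
values `w_c = f_c / max(f_c' : c' synonymous with c)` over all sense codons
of the sequence, computed in log space. Conventions, chosen to match the
common web-server implementation of CAI:

- all sense codons contribute, so single-codon families (ATG, TGG) enter
  with `w = 1`;
- stop codons are excluded;
- zero counts in a usage table are smoothed to 0.5 before normalisation so
  every `w > 0` and the geometric mean is defined;
- ties at a family extreme break to the lexicographically smallest codon,
  making recodings deterministic.

An `extremal_common` recoding therefore has CAI exactly 1.0 (sum of zero
logs), and for any sequence `s` and table,
`CAI(extremal_rare(s)) ≤ CAI(s) ≤ CAI(extremal_common(s))`.

The packaged usage table (`data/dmel_codon_usage_synthetic.tsv`) is a
constructed per-1000 table reproducing the qualitative codon preferences of
the D. melanogaster genome (C/G-ending optimal codons); it is a labelled
synthetic stand-in, and reproducing a specific transgene design requires
supplying the usage table the design actually used.

## Screen scoring and two-stage classification

Each cross is graded into three ordinal categories weighted 1 (mild), 3
(moderate), 5 (severe); the severity score is the weighted mean
`(1·n_mild + 3·n_moderate + 5·n_severe) / total`, bounded in [1, 5]. The
fold-change score of a deficiency for one transgene is
`severity(Df cross) / severity(transgene-only control)`; lethality enters
as the eclosion ratio `eclosed(Df) / eclosed(control)` (with an optional
normalisation factor for unequal cross sizes).

Per-transgene calls use stage thresholds (defaults: primary enhancer
fc ≥ 1.35 / suppressor fc ≤ 0.65; secondary enhancer fc ≥ 1.95 /
suppressor fc ≤ 0.50; eclosion fold 5, boundaries inclusive exactly as
stated). The eclosion rule's orientation is a genuinely open design point:
the two stages of the source protocol state opposite pairings. This
implementation pairs *reduced* eclosion with enhancement in both stages —
lethality is the extreme of an enhanced Ras phenotype — and exposes the
reversed orientation behind the `lethality_enhances` switch. If the fold
change and eclosion rules fire in opposite directions for one transgene the
call is `ambiguous`, and the deficiency is routed to `needs_review` and
excluded from category tallies (the protocol never addresses this case). A
Df cross with zero scorable flies gets a NaN fold change and is classified
on the eclosion rule alone, so total lethality registers as enhancement
under the default orientation.

Df categories combine the two transgene calls: both enhanced → enhancer;
both suppressed → suppressor; exactly one modified → differential with the
detail (`rare_only_enhanced`, …) recorded; opposite directions →
differential with both directions preserved (the phenotype is by
construction signalling-strength-dependent); neither → not a modifier.
Only primary-stage modifier/differential Dfs are evaluated at the secondary
stage, and a call is *confirmed* when the secondary-stage category (under
the stricter thresholds) matches the primary one. `run_screen` is
deterministic and order-independent: records are grouped by
(stage, df_id, transgene), exact duplicates collapse, distinct replicate
rows for one key are summed, and Dfs are processed in sorted order.

## Synthetic screens

`simulate_cross` draws `eclosed ~ Binomial(n, eclosion_p)` then category
counts `~ Multinomial(eclosed, probs)` — scored flies are the eclosed
experimental-genotype flies. Default study conditions:

| parameter | default | rationale |
|---|---|---|
| progeny per cross | 30 (common) / 60 (rare) | the screen scale being emulated |
| baseline probs, common | (0.2, 0.4, 0.4) → severity 3.4 | strong-signalling control |
| baseline probs, rare | (0.7, 0.25, 0.05) → severity 1.7 | weak control; ~2× milder than common |
| eclosion probability | 0.8 | typical viable-cross eclosion |
| effect mix | 74% null, 16% enh, 7% sup, 1.5% + 1.5% differential | mirrors the observed screen composition |
| planted severity shift | 2.0 score units | one full category step |
| lethality factor | 1.0 | effects act through severity by default |

Planted effects move category probability mass stepwise along
mild → moderate → severe (or the reverse) until the mean severity has moved
by `severity_shift` score units, saturating at all-severe/all-mild; each
unit of mass moved one step changes the mean by the category spacing 2.0.
This stick-shift parameterisation was chosen over an ordinal-logit model
for transparency: the induced mean shift is exact and auditable.
Randomness flows through named sub-streams (effects / crosses / genome /
cds) derived from the single mandatory seed, so enlarging one part of a
simulation does not perturb the others; everything is bitwise reproducible
per seed.

Two consequences of these conditions are worth knowing. First, severity
saturates at 5, so the common transgene's fold change cannot exceed
5/3.4 ≈ 1.47; common-side enhancement can pass the 1.95 secondary
threshold only through the lethality rule. Second, severity cannot fall
below 1, so the rare transgene's fold change cannot fall below
1/severity(control) ≈ 0.59 — close to the 0.65 primary threshold — which
makes suppressor calls on the weak transgene an all-or-none event per
screen, decided largely by the shared control draw. Both are properties of
fold-change screens with bounded ordinal scores, not of this
implementation, and they are left visible rather than tuned away.

What the generator does *not* emulate: balancer genetics and Mendelian
segregation (eclosion is a single binomial), between-replicate batch
effects, scorer drift, or any coupling between eye severity and viability
beyond the planted lethality factor. Passing recovery tests on these
simulations therefore demonstrates that the classification rules are
implemented and calibrated as specified — not that the rules are optimal
for real screen data.

## Interval overlap and enrichment

Coordinates are BED-convention throughout: 0-based, half-open; a gene is
covered by a deficiency when the intervals share ≥ 1 base on the same
chromosome (adjacent half-open intervals do not overlap); a minimum
gene-overlap fraction is available as an option. Enrichment of a covered
gene set against curated gene groups uses the one-sided Fisher exact test
— the hypergeometric upper tail P(X ≥ k), computed exactly in log space,
no normal approximation — with group members intersected with the universe
first. The universe defaults to all genes in the supplied annotation, and
Benjamini–Hochberg correction is applied across the groups of one scan, so
separate category scans (e.g. differential vs general modifiers) are
corrected separately; put all groups in one call for a global correction.
Results sort by adjusted p with deterministic group-id tie-break.

## Numerical and validation choices

- Family frequencies must sum to 1 within 1e-9; CAI uses `fsum` in log
  space; all floats serialise at 6 significant digits for stable diffs.
- Fisher p-values are validated in tests against exhaustive
  rational-arithmetic enumeration for all margins N ≤ 30 (within 1e-12);
  interval mapping against a per-base brute-force oracle; BH against the
  textbook step-up recursion.
- Calibration tests run 200 simulated null screens of 100 Dfs at the 30/60
  progeny scale (a few seconds of compute) and assert that secondary
  confirmation never exceeds the primary differential rate — structurally
  guaranteed, since confirmed calls are a subset of primary calls — and
  that a planted one-category shift on the 60-progeny transgene is
  recovered as a differential call with sensitivity > 0.9.
- Problem sizes in tests and the acceptance script (100-Df calibration
  screens, one 470-Df full-scale screen, N ≤ 30 Fisher grids) were chosen
  as the smallest sizes at which the statistical assertions are stable.

## Known limitations

- The severity statistic treats the 1/3/5 weighting as given; no ordinal
  regression or uncertainty on the fold change is attempted, matching the
  protocol being implemented.
- Eclosion ratios assume comparably sized crosses unless a normalisation
  factor is supplied.
- Gapped alignment, codon-pair bias, tRNA adaptation, and mRNA-structure
  metrics are out of scope; nucleotide identity is ungapped and requires
  equal lengths.
- The packaged codon-usage table is synthetic (see above); analyses of real
  designs should supply a real table.
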