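# Methods

## Scope and data model

`lipidkit` operates downstream of peak picking, alignment and MS² annotation:
its input is a species × samples table of peak areas (or concentrations),
per-sample metadata (group, tissue, protein content, extraction volume) and
an internal-standard map. The central in-memory objects are a
`ConcentrationMatrix` (species × samples, µg lipid/µg protein), per-class
`ClassTotals`, and chain-abundance matrices keyed by `C:D` fatty-acyl
signatures.

## Nomenclature

Shorthand names are parsed as *class token + chain tokens*. `_` separates
chains of unknown sn-position, `/` of known position; `O-` marks an ether
(alkyl) chain and maps PC/PE/PI onto the distinct ether subclasses PC-O /
PE-O / PI-O, which carry their own rows in class statistics (ether pools
respond differently from their diacyl counterparts and are reported
separately). The plasmalogen prefix `P-` is normalised to `O-` with one
extra double bond on the ether chain (the standard shorthand equivalence).
Sphingolipid hydroxylation is carried in `;O`/`;O2` suffixes; the legacy
`d18:1`/`t18:1` dialect is accepted and normalised. Names with fewer chain
tokens than the class requires (e.g. `SM 34:1`) are kept at sum-composition
level: they participate in class totals but are excluded from
building-block analysis, since a total C:D cannot be attributed to
individual chains. Unknown class tokens fail loudly by default — silently
dropping species would corrupt class totals — with an explicit
skip-with-warning mode for exploratory use.

The class registry (19 profile classes + PSY) is an editable YAML config;
the bundled registry covers every class row of the reference profile.

## Semi-quantification

Concentration is estimated per species as

    conc(i, s) = area(i, s) / area(IS_class(i), s) × spike(class(i))
                 × extract_volume(s) / protein(s)

The ratio form cancels per-sample global response factors, so results are
invariant to injection-volume or source drift, and linear in the analyte
area. Classes without a labelled analogue in the standard mix borrow the
closest chemistry (HexCer/SHexCer → ceramide standard; PC-O → PC, PE-O → PE,
PI-O → PI; LPI → LPC; CL → PG). This borrowing can over- or under-estimate
those classes by a class-specific response factor; a per-class multiplier is
exposed in the IS map to model it. The effective in-extract spike is a
config value (default: the 100 µg/mL mix stock with an explicit
`dilution_factor`, and a 125 ng/mL psychosine-d5 spike); because every
result downstream of quantification is a ratio or a group contrast, the
dilution factor rescales concentrations uniformly without affecting calls.

A zero internal-standard area is treated as an acquisition failure for that
sample (error, not imputation). Missing-value handling is opt-in:
`half-min` per-species imputation or a presence-rate filter; the default is
pass-through.

Psychosine is quantified by the same ratio against its own deuterated
standard and reported in ng/µg protein.

## Class profiles

Species are summed within class per sample; the grand total is the sum over
classes (equivalently over species — conservation is enforced by tests).
Two-group comparison uses a two-sided t-test per item; the class-profile
default is Welch's test on raw-scale concentrations (means are reported on
the raw scale), with Student's pooled test and log-scale testing as options.
Stars follow the conventional bands (\* <0.05, \*\* <0.01, \*\*\* <0.001) and
are a pure, monotone function of p. No multiple-testing correction is
applied by default, matching per-class raw-p reporting conventions;
Benjamini–Hochberg can be applied on the returned p-values. Items with zero
variance in both groups and equal means report p = NaN rather than aborting
a table-wide scan. "Error bars" are reported as both SD and SEM columns.

## Multivariate analysis

The default chain is: median normalisation of sample columns (each column
divided by its median, rescaled by the median of medians to preserve the
overall scale) → Pareto scaling of species rows (centre, divide by √sd;
autoscaling optional; constant rows map to zero) → PCA with samples as
observations. Explained variances equal the eigenvalues of the sample
covariance (verified against an independent eigendecomposition); a
deterministic sign convention (largest-|loading| entry positive) makes runs
reproducible. Group confidence ellipses use the χ²(2) quantile on the
group's 2-D score covariance — with n as small as 4–6 these ellipses are
descriptive, not exact small-sample confidence regions.

The heatmap stage selects the top-k (default 50) species by ascending
p-value, breaking ties by |log₂ fold change| then name so selection is
deterministic, autoscales rows for display and clusters both axes with
Euclidean distance and complete linkage (correlation distance available).

## Reaction-activation scoring

For a catalogued transformation r → p, the per-sample weight is
`w = total(p)/total(r)` over class totals (or chain abundances). Weights
are ratios, hence invariant to per-sample rescaling. Group comparison runs
on log₂ weights, making activation and suppression exactly symmetric:
swapping group labels flips every call with identical p-values.

The default test on log weights is Student's pooled t: both groups share a
noise model by design, and at n = 4–6 per group the pooled test holds the
nominal type-I rate while Welch's variant is measurably conservative
(~0.044 at nominal 0.05 in simulation); Welch remains available. The
reported Z-score is the signed probit of the two-sided p,
`Z = sign(Δ)·Φ⁻¹(1−p/2)` — a deterministic, monotone-in-p summary that
places all edges on a common normal scale. Calls use p < 0.05 by default
with a stricter 0.02 "highlight" tier exposed for reporting.

The class-level catalog ships with ten well-established phospholipid
transformations (PA→PG/PI via CDS, PI/PC→PA via PLD, PC/PE/PA→PS via
PSS1/PSS2, PC→PG via PLD1/4/6, CL→PG via MIGA/PLD6, PC→LPC via PLA) and is
extensible via CSV. Chain-level catalogs are generated from the chains
actually observed: elongation (c,d)→(c+2,d), desaturation (c,d)→(c,d+1)
and β-oxidation (c,d)→(c−2,d), the latter restricted to substrates with
≥20 carbons so the ubiquitous C16/C18 pool does not saturate the network.
Enzyme/gene annotation comes from a lookup keyed by (edge type, substrate
chain) — SCD1 for 16:0/18:0 desaturation, FADS2 (D6D) for 18:1/18:2,
FADS1 (D5D) for 20:3/22:2, ELOVL1/3/6 for the C16→C18 and 22:0→24:0
elongations — with generic fallbacks.

Chain abundance is concentration-weighted with multiplicity (a di-18:1
species contributes its concentration twice to 18:1); multiplicity-off mode
exists. Ether chains count with their C:D signature; sphingoid bases
(hydroxylated chains) are excluded by default so the analysis reflects
fatty-acyl chains, with an inclusion flag.

## Psychosine correlation

Psychosine is correlated with each class total across the pooled cohort
(both groups; per-group mode available) — Pearson on log-transformed
concentrations by default, since concentrations are positive and
multiplicative, with Spearman as the rank-based option. Classes are
labelled positive/negative at a configurable α. With pooled groups the
correlation is dominated by the group contrast; that is the intended
reading (classes that move with vs against psychosine accumulation), not a
within-group association.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, and
its defaults are the study conditions the rest of the suite is judged
under:

* **Design**: two groups (default 5 control / 4 case; 6/5 for psychosine
  runs), one tissue template per cohort (B, C, SC, SN).
* **Class structure**: control-group class totals default to the bundled
  reference profile of mouse nervous-tissue class concentrations; the
  case/control effect ratio per class defaults to the matching reference
  ratio (the `null_design` variant sets every ratio to 1).
* **Species**: ~13 species per class (a cohort of ~220 species across 18–19
  classes), with chains drawn from a pool concentrated on C16/C18 with 0–1
  double bonds and a PUFA/very-long-chain tail — the composition that
  dominates nervous tissue. Within a class, species means are a fixed
  Dirichlet(2) split of the class baseline, so class totals are controlled
  while species vary. Sphingolipids carry an 18:1;O2 base; ether classes an
  O- first chain. Every generated name round-trips through the parser.
* **Noise**: i.i.d. multiplicative log-normal per cell with CV 20% by
  default (typical combined technical+biological variability for
  lipidomics), mean-one parameterisation so expected totals equal the
  design targets exactly and the zero-CV limit is deterministic.
* **Psychosine**: control level per tissue (0.08–0.20 ng/µg) with
  case/control ratios 5 / 8 / 22 / 27 for B / C / SC / SN respectively —
  the SC/SN ratios mirror the reported ~22×/~27× accumulation; CNS levels
  are not published and were fixed once at plausibly lower values.
* **Feature tables** are constructed by inverting the semi-quantification
  formula (with per-sample log-normal response factors that the ratio
  cancels), so `semiquantify` recovers the planted concentrations to
  floating-point accuracy.

**Planted effects.** A class-level effect scales the product class in the
case group. A chain-level effect cannot be realised by scaling arbitrary
species — a species multiplier drags all co-occurring partner chains along —
so it is realised through *homo-acyl carrier species* (all chains equal to
the planted chain; one species per two-chain glycerophospholipid class is
converted to the homo-acyl form if absent), rescaled so the planted chain's
total expected abundance changes by exactly the requested fold while every
other chain's expectation is untouched. Ground truth records planted edges,
carriers and realised multipliers.

**Ground-truth semantics for false calls.** Scaling a pool moves *every*
edge that touches it: planting PA→PG ×3 triples the PG totals, so CL→PG and
PC→PG weights triple too, and calling them is correct behaviour, not error.
Recovery harnesses therefore count false calls only over edges that touch
neither side of the perturbed pool.

**What the generator does not model** — and hence what passing tests do not
show about real data: correlated species noise within a class (co-regulation
and shared-IS noise), missing values and detection-limit censoring,
class-specific response-factor bias, retention-time or batch drift, and
per-class species counts matching any particular study. Calibration and
recovery results transfer to real cohorts only to the extent that log-normal
independent noise approximates them.

## Numerical choices and degenerate inputs

Simulation sizes used by the acceptance script and test suite: 1,000 null
replicates for type-I calibration, 200 replicates per planted-edge recovery
harness, 50 cohorts for psychosine-ratio recovery — chosen so binomial
uncertainty on the measured rates is small relative to the bounds checked.
Zero/NaN handling: weights are NaN where either pool is non-positive (the
sample is excluded for that edge); edges with a class missing entirely are
skipped with a warning (strict mode raises); constant rows scale to zero;
both-groups-zero-variance items report NaN p-values. Heatmap tie-breaks and
the PCA sign convention are fixed for byte-identical reruns. All randomness
in a pipeline run flows from one seed.

## Known limitations

* Semi-quantification is level-2/3 (class-matched single-point response):
  absolute concentrations inherit the standard's response factor; ether and
  glycosphingolipid classes are most affected.
* Reaction calls are association statements about pool ratios, not flux
  estimates; an activated call is consistent with, but not proof of,
  increased enzyme activity.
* Double-bond positions are not represented at shorthand level, so n-3/n-6
  series and sn-positional specificity are out of reach.
* With 4–6 samples per group, per-species tests are underpowered and
  confidence ellipses are descriptive; class- and chain-level aggregation
  is the intended resolution.
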