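# Methods

## The molecule model

A `DuplexFragment` is a double-stranded interval `[start, end)` of the
reference (0-based half-open internally; SAM output is 1-based per the
standard). Each end is independently blunt, a 5′ overhang or a 3′ overhang
(default probabilities ⅓ each); overhang lengths are geometric with mean
8 bp by default. The core duplex may additionally carry nicks (backbone
breaks) and gaps (missing stretches on one strand), with Poisson counts in
the core length (defaults 10⁻³ and 3×10⁻⁴ per bp; mean gap length 5 bp).
Sonicated-DNA overhang lengths and the very existence of gaps are not
well characterised experimentally, so all of these are configuration, not
assertions; the geometric mean-8 default is chosen so that 20 bp clipping
leaves a visible residual, the regime the clipping experiment probes.

### Single-strand regions and damage

SS regions, with the strand that is exposed as template:

| structure | exposed (damaged) strand | span |
|---|---|---|
| left 5′ / right 3′ overhang | plus | overhang span |
| left 3′ / right 5′ overhang | minus | overhang span |
| gap on strand *s* | opposite of *s* | gap interval |
| nick on strand *s* | opposite of *s* | `nick_window` (default 2 bp) downstream (3′ of the nick on *s*) |

Damage is per eligible base within an SS region: 8-oxoG and Iz on exposed
G (defaults 0.02 each), deaminated C on exposed C (default 0.01). One
uniform draw per base partitions the lesion kinds, so a base carries at
most one lesion. Realistic artifact regimes sit at ≤ ~0.05 per base; the
full [0, 1] range is accepted so certainty cases remain expressible.
Double-stranded DNA can optionally receive strand-discordant damage
(`p_ds_damage`, default 0): a random substitution on one strand only.

The nick model deserves a note, because it is the one place the mechanism
is not settled chemistry: we treat a nick as transiently exposing a short
breathing window downstream, with lesions accumulating on the intact
strand — the stretch that nick translation will use as template during end
repair. This makes nick-borne damage concordant after repair (hence
dangerous), and makes an enzyme's activity *at nicks* matter for error
removal, which is exactly the observed S1-vs-mung-bean difference the
model needs to express. Setting `nick_window = 0` switches nick-borne
damage off entirely.

### End repair

End repair blunts every molecule: 5′ overhangs and gaps are filled in
using the existing strand as template, nicks are sealed after nick
translation, 3′ overhangs are chewed back (their lesions discarded, the
fragment shortened). A lesion that served as template becomes a
**concordant substitution** via the manifestation map (8-oxoG→T, Iz→C,
deamC→T, on the damaged strand). Truth tables record planted substitutions
in the damaged-strand frame by default (`frame_rule = "damaged_strand"`);
`"reference"` projects onto the plus strand at planting time instead. The
analysis-side frame choice (below) is independent of this bookkeeping.

### Nuclease digestion

Digestion happens after damage and before end repair. Enzyme "units" map
to event probabilities by the saturating form `p_max·(1 − e^(−units/u₀))`
(u₀ = 5 units) — monotone, bounded, and deliberately *not* a kinetic
model. Archetypes:

| model | overhangs | gaps | nicks | notes |
|---|---|---|---|---|
| `s1` | 1.0 | 1.0 | 0.9 | terminal-base preference G:3 |
| `mbn` | 1.0 | 1.0 | 0.2 | preference G:2, C:2 |
| `recjf` | 5′ only | — | — | 5′→3′ SS exonuclease |
| `none` | — | — | — | mock |

Overhang excision discards the overhang and its lesions; gap cleavage
removes the gap span and splits the molecule (lineage kept via
`molecule_id` suffixes); nick cleavage splits at the nick and excises its
breathing window. Products shorter than `min_length` (50 bp) are dropped.
RecJf's weaker error removal is *emergent* — it simply has no interior
activity, so gap- and nick-borne lesions survive it. The `end_bias`
weights re-choose the cut terminus among the next `end_bias_window` (3)
bases in proportion to the 5′-terminal base they would leave, reproducing
the first-cycle G enrichment seen after S1 treatment; it is seeded per cut
location so common-random-number comparisons stay coupled.

Digestion decisions use per-fragment seeded streams drawn in a fixed
structural order, so for a fixed seed the set of excised features only
grows with units — surviving-lesion counts are monotone non-increasing in
dose by construction, and paired treatment comparisons share randomness.

### Library sampling and sequencing

Each repaired molecule yields two strand families: F1R2 reads sequence the
genome-plus strand (read 1 forward at the left end), F2R1 the minus
strand. Per family the duplicate count is zero-truncated geometric, mean 3
(the distribution is not experimentally constrained; this one is simple
and heavy-tailed enough to exercise family-size logic). PCR errors are
applied per molecule copy to the template (consistent across the mate
overlap); sequencing errors are independent per read base (defaults 10⁻⁴
and 10⁻³ respectively). Reads are 2×100 bp, qualities constant Q30 —
quality-aware consensus is out of scope. Dilution: `ligated_amount × 
molecules_per_unit` distinct molecules are sampled without replacement;
fewer molecules at fixed coordinates space means fewer coordinate
collisions, which is the entire dilution story. Output: paired FASTQ,
truth SAM with exact coordinates (no aligner), and truth tables for
variants and molecules. Identical config + seed reproduces all outputs
byte for byte.

## Consensus calling

SP-Gs group read pairs by exact `(chrom, frag_start, frag_end)`; a dsDCS
is emitted when both orientation families have ≥ `min_family_size`
members (default 1 — the method's stated requirement is presence of both
read directions, nothing more). Within a family the per-position rule is:
call the plurality base among covering non-N read bases if its agreement
fraction reaches the threshold, else N; the default threshold is 1.0 for
families of ≤ 2 pairs and 0.8 for larger ones — unanimity for the small
families where a single errored read could otherwise dominate. Fractions
exactly at the threshold pass; a tie for the top base yields N. Mates of
one pair disagreeing in their overlap yield N for that pair. Duplex
combination: both family consensuses non-N and equal → that base;
non-N and different → N flagged `strand_conflict`; otherwise N flagged
`insufficient`. Indels are excluded (read bases under insertions are
dropped; deleted positions stay uncovered).

dsDCS records keep their SP-G coordinates rather than being re-mapped
with an external aligner: coordinates are exact for simulated data and
this keeps the tool self-contained; `--export-fastq` emits dsDCS reads
for anyone who wants to re-map externally.

## Spectrum counting and frames

Counting walks each dsDCS against the reference; N positions count
nowhere, so numerators and denominators shrink together (clipping and
known-variant BED masking are implemented as N-masking for exactly this
reason). Two strand frames are provided:

* **reference** — plus-strand ref → plus-strand observed;
* **fragment** (default) — each position is classified in the orientation
  of the inward-sequencing read from the *nearer* fragment end: left half
  as-is, right half complemented (odd-length middles count left). This is
  the frame in which end-repair artifacts are guaranteed asymmetric: the
  damaged strand at a fragment end is the one whose 5′ terminus the
  inward read starts from, so 8-oxoG reads G>T from either end. Which
  frame a given published strand-resolved spectrum used is genuinely
  ambiguous; both are implemented, and 6-type pooling is identical in
  either frame.

Frequencies are `count/denominator × 10⁶`, 6-type classes pool the two
complementary 12-type classes over summed denominators, zero-denominator
classes are reported missing (NaN), never 0. Group comparison: two-sided
equal-variance Student's *t* (Welch by flag) or Dunnett's many-to-one
test via the equicorrelated multivariate-*t* distribution
(`scipy.stats.dunnett`, fixed internal quadrature seed so results are
reproducible); log₂ fold changes add a frequency floor ε = 0.001 per 10⁶
to both means so they stay finite; a zero mean difference is reported as
p = 1 even for degenerate zero-variance groups.

## Coverage, composition and misassignment

Coverage counts non-N dsDCS bases per genome position. mean/SD/CV are
computed over per-position depth with population SD (ddof 0); the
50 000-section histogram is presentational, with a `per_bin_stats` flag
for anyone who wants statistics over binned means instead (whether a
published CV was per-position or per-bin is usually unstated; we state
ours). `covered_rate` divides by the full genome length. Per-cycle
composition is computed on reads *as sequenced* (R1 = forward,
R2 = reverse), N excluded per cycle, rows renormalised.

An SP-G is *misassigned* when its members descend from ≥ 2 distinct
source molecules (truth mode, via molecule ids carried in read names).
The analytic companion is a Poisson-occupancy ("birthday") estimate: with
k molecules over N distinguishable coordinates and λ = k/N, the expected
fraction of occupied coordinates holding ≥ 2 molecules is
`(1 − e^(−λ) − λe^(−λ)) / (1 − e^(−λ))` ≈ k/2N for small λ. N is derived
from the shear model as `n_starts / Σ p_len²` (collision-equivalent count
of the discretised normal length distribution).

## Study designs and problem sizes

The canned studies in `ssduplex.studies` fix the simulation conditions:

* **mechanism/clipping and nuclease studies**: 10⁴ fragments, 10⁵ bp
  genome at GC 0.52, package-default damage and structure rates; the
  nuclease study runs untreated / S1 at saturating dose / RecJf on the
  same fragment pool and also reports the coverage deltas between
  digested and undigested libraries.
* **duplex suppression**: sequencing errors 10⁻², PCR 10⁻³, family mean
  3, no SS damage; fragments 160 ± 15 bp so 100 bp mates tile the whole
  molecule and every position has duplex coverage.
* **misassignment**: 4 kb genome, 120 ± 15 bp fragments, 100 molecules
  per relative amount unit over amounts {20, 39, 78, 156} — a coordinate
  space small enough that collision counts are in the tens-to-hundreds
  and the closed form can be checked tightly at the upper amounts.

These sizes are the package's chosen desk-scale designs; statistical
checks in the test suite use standard-error or binomial/Poisson bounds
appropriate to them.

## What the simulator does and does not emulate

It emulates: fragment coordinate collisions and dilution, per-strand read
families with PCR/sequencing noise, SS-structure-confined damage, end
repair's conversion of SS lesions to concordant errors, dose-dependent
nuclease action with cut-site base preference, and read truncation on
short fragments. It does not emulate: alignment error or mapping-quality
structure (truth coordinates are exact), base-quality variation, adapter
chemistry, indels, GC-dependent amplification bias, enzyme kinetics, or
any sequence-context dependence of damage. Passing tests therefore
demonstrate the *logic* of duplex consensus, its SS blind spot and the
nuclease remedy — not performance on real aligned data, where mapping
artifacts and context effects add failure modes this model does not
contain.

## Known limitations

* The fragment-frame convention (nearer-end read orientation) is one
  reasonable formalisation of "the base each read base was mapped to";
  per-read counting on overlapping mates could differ at mid-fragment
  positions.
* Nick-breathing damage and its concordance through nick translation is a
  mechanistic assumption (see above), exposed via `nick_window`.
* `strand_conflict` vs `insufficient` flags are not serialised through
  SAM round trips (both read back as N/insufficient).
* Coordinate-keyed consensus treats colliding molecules as one family;
  the misassignment report quantifies, but does not correct, this.
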