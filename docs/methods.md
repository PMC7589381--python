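# Methods

This note documents the models, conventions and numerical choices
behind `polyko`, and what the synthetic-data generators do and do not
emulate.

## Coordinate and naming conventions

Protospacer positions are counted **1..20 from the PAM**, position 1
being PAM-proximal; in 5'→3' string coordinates position *p* is index
20 − *p*. The Cas9 cut is modelled as blunt, 3 bp PAM-proximal of the
PAM (between protospacer positions 3 and 4) — the standard SpCas9
convention. Genomic intervals are 0-based half-open on the forward
strand. Wild-type alleles carry the `h` suffix (`Ah`); edited alleles
are numbered in order of first observation, which makes the coding a
pure function of the ordered input and therefore stable across re-runs.

## Paralog discovery

`find_paralogs` aligns the query against both strands of every contig
with semi-global (query-in-infix) edit-distance alignment (edlib),
records the best hit, masks it and repeats until the best remaining hit
falls below the identity floor. This is fully sensitive at the floor —
heuristic k-mer seeding was rejected because an ~8%-diverged copy can
lack any exact 11-mer and be missed. Identity is matches over total
alignment columns with gap columns counted as mismatches; this
denominator is stated explicitly because published identity tables are
not reproduced here. Coverage is the aligned query fraction, below 1
only when a contig end truncates a hit. Families are formed by
single-linkage clustering at a within-family identity threshold
(default 0.85). The tree is neighbor joining (scikit-bio) on
distance = 1 − identity with negative branch lengths clamped to zero —
a deliberate, fast substitute for maximum-likelihood phylogenetics;
assigning clade labels is left to the user.

## Guide design

All 20-mers 5' of an NGG on either strand are candidates. For each
non-reference paralog the homologous 23-nt window is located through
the global alignment of the two CDSs; a gap-disrupted or
non-contiguous window, or one without a valid NGG, marks the paralog
non-targetable. The filter keeps candidates with

* GC strictly greater than 40% (strict by design — 40.0% fails);
* every paralog targetable, with identical PAM in all paralogs
  (a broken PAM defeats targeting, and PAM mismatches are never
  counted toward the tolerated budget);
* at most one mismatch per paralog, and only at positions ≥ 10 from
  the PAM (boundary inclusive): seed-region mismatches abolish
  cleavage, PAM-distal single mismatches are tolerated.

The off-target screen scans every contig (coding or not) for 23-mers
with ≤ `max_mm` protospacer mismatches (default 2, configurable to 0)
and a mandatory GG; hits inside the family's own loci are excluded. A
candidate passes only with zero remaining hits — a desk-scale,
deterministic equivalent of "no BLAST hit" criteria, which are
otherwise tool-dependent. Ranking is fewest total mismatches, then
highest GC, then 5'-most position; fully deterministic.

## Allele calling and chimerism

Reads are globally aligned to the wild-type reference with affine gaps
(match +2, mismatch −4, open −10, extend −0.5). Indels are
left-normalised (leftmost placement, as in VCF) so that allele identity
is well defined inside homopolymers and equivalent alignment
representations collapse to one event list. Events are reported
relative to the cut. Substitutions never become events: up to 2 of them
outside a ±30-nt cut window are treated as sequencing noise, more
reject the read, as does overall identity below 0.8 ("foreign
amplicon"). Frame consequence is net indel length mod 3, computed only
for coding loci. A locus with more than two distinct alleles across
clones flags the plant as chimeric; a saturation warning is raised when
fewer than two clones per observed allele were sequenced, since thin
clone coverage undercounts allele diversity.

## Trace decomposition

A mixed trace is modelled as a nonnegative combination of the control
trace shifted by each candidate indel size (±1..±10 by default) in a
window downstream of the cut (default bases 10–60). Insertions treat
the inserted bases as unknown: window positions that would fall inside
them are dropped from the fit. Weights are solved by nonnegative least
squares over the flattened four-channel signal sampled at peak centres;
frequencies are the weights rescaled to sum to 1 (raw weights are also
kept), R² is 1 − SS_res/SS_tot, and fits with R² < 0.9 are flagged
low-confidence. This is the simplest faithful variant of
decomposition-based indel tracking; no p-value machinery is attempted.

## Inheritance

Loci are unlinked; selfing transmits each gamete allele uniformly from
the parental pair. A chimeric founder transmits from an explicit
germline subset — the package's way of expressing that somatic-only
mutations are absent from the germ line and vanish from the pedigree.
While a transgene (hence Cas9) is present, each transmitted wild-type
allele can convert to a fresh de novo allele with a per-generation,
per-locus probability. The T-DNA is a single unlinked insertion with a
copy count 0/1/2; a hemizygous parent yields 3:1
transgenic:non-transgenic selfed offspring, (4ⁿ−1):1 for n unlinked
insertions. Segregation is tested by Pearson χ² with df = 1 and no
continuity correction, α = 0.05; allele tracking classifies offspring
alleles as inherited or de novo (anomalous if the offspring lacks the
transgene) and parental mutant alleles transmitted to no offspring as
lost.

## Phenotype statistics

One-way fixed-effects ANOVA on line is the only factor; nested
technical replicates, if present, should be averaged per plant before
testing. Tukey's HSD (statsmodels, studentized-range quantiles) gives
adjusted pairwise p-values; the compact letter display uses the
insert-and-absorb algorithm (start with one all-groups column, split on
each significant pair, absorb subset columns), which guarantees both
directions: groups sharing a letter are never significantly different
and every non-significant pair shares a letter. Letters follow
descending group means. Transformation efficiency is
100 × independent transgenics / explants, reported to one decimal.

## Synthetic data: what it emulates, and what it does not

Defaults are fixed to the conditions of a realistic tetraploid
knockout campaign: families of 2–8 copies at 89–99% identity (pairwise
divergence is made exact by mutating disjoint position sets, so copy i
vs j differ at exactly d_i + d_j sites; d bounds are derived so that
even gap-containing co-optimal alignments measure inside the target
range); chimeric T1 loci with 3–8 distinct single-indel alleles drawn
from a spectrum of +1 insertions (p = 0.3) and 1–10-bp deletions
(geometric, p = 0.7 total) — observed editing outcomes constrain the
support but not the distribution, which is therefore configurable;
idealised chromatograms with one unit Gaussian peak per base (spacing
10 positions/base, peak σ = spacing/4) plus seeded Gaussian channel
noise; phenotype effects multiplicative on control means with CV 0.05
and 5 replicates per line (the two triple-mutant lines reduce phytic
acid to 0.647× and 0.728× of control — 35.3% and 27.2% reductions —
and triple inorganic P; control means, e.g. 25 mg/g phytic acid, are
round placeholder values on realistic scales).

Not emulated: real chromatogram artefacts (mobility shifts, dye blobs,
decaying peak heights), base-quality models, sequencing errors beyond
Gaussian trace noise and isolated substitutions, linkage and
recombination (all loci unlinked), expression variation, and any
wet-lab chemistry. Passing tests therefore demonstrate the correctness
of the algorithms under clean, known-truth conditions — not robustness
to every failure mode of real Sanger data.

Every generator takes an explicit seed and owns a private
`numpy.random.Generator`; identical seeds give byte-identical outputs.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
exercise the statistics meaningfully: 600-nt loci, ≤ 100-kb genomes for
oracle comparisons, 1000 round-trip allele calls, 100 decomposition
seeds at noise 0.05, 500 simulated segregation families of n = 100, 200
null calibration runs for the letter display, and demo pedigrees of 60
offspring per selfed parent over three generations.

## Known limitations

* Guide conservation scoring assumes the family alignment is reliable;
  paralogs more diverged than ~15% may map windows ambiguously.
* Trace decomposition estimates net indel-size frequencies only; two
  different alleles with the same net size are not distinguished
  (allele-level resolution is the clone-sequencing path's job).
* The chimeric-transmission model draws gametes uniformly from the
  germline subset; real chimeras may have biased sectors.
* ANOVA assumes homoscedastic normal replicates; no mixed-effects or
  robust alternatives are provided.
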