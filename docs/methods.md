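# Methods

## The aggregation model

The scoring system treats each external MHC class II binding predictor as a
black box that, for one allele, returns a ranked list of peptide windows
over the antigen. Nothing about the predictors is modelled beyond two
assumptions: (i) the reported metric orders peptides so that smaller means
stronger predicted binding, and (ii) only the relative order matters —
metric scales are never compared across algorithms or alleles. This is why
the whole pipeline is scale-free: multiplying all metrics of a list by a
positive constant changes neither ranks nor any downstream quantity (a
property-tested invariant).

Per (algorithm, allele) list, the top `top_k` peptides are selected
(default 20). Residue scores are then

- `S_i = Σ w(rank)` over all selected peptides covering residue `i`,
- `N_i = |{alleles with ≥ 1 selected peptide covering i}|`,
- `F_i = S_i × N_i`,

with `pct_i = 100 · F_i / max_j F_j` and colour strata assigned on `pct`.
Selection happens first, accumulation second; a peptide outside its list's
top `top_k` contributes nothing anywhere.

### Rank weights

The defining property of the weight function is that the rank-1 peptide of
a list contributes weight 1. How the weight decays below rank 1 is a free
choice; three schemes are implemented:

| scheme     | w(r)                  | default |
|------------|-----------------------|---------|
| linear     | (K + 1 − r)/K         | yes     |
| reciprocal | 1/r                   |         |
| uniform    | 1                     |         |

Linear is the default because it keeps every selected peptide contributing
(unlike reciprocal, which effectively discards the tail) while still
ordering contributions by predicted binding (unlike uniform). All three
agree at rank 1.

### The allele count N

`N` counts *alleles*, not predictions: a residue covered by the same allele
in both algorithms counts once (`n_mode="allele_union"`, the default).
Counting (algorithm, allele) pairs instead is config-selectable
(`n_mode="allele_algorithm_pairs"`) for sensitivity analyses.

### Colour strata

Strata are half-open on the lower bound, `[lower, next_lower)`, with the
top stratum closed at 100: dark_red [75, 100], red [50, 75), orange
[40, 50), yellow [30, 40), green [20, 30), blue [10, 20), light_blue
[0, 10). The blue/light_blue boundary is set at 10 so that the seven strata
tile [0, 100] exactly; a pct value on any boundary belongs to the higher
stratum. Percent values are clipped to [0, 100] after normalisation to
absorb one-ulp floating-point overshoot at the maximum.

## Hotspots and candidate extraction

A hotspot is a maximal run of residues with `pct ≥ min_pct` (default 75,
i.e. the dark-red stratum) of length ≥ `min_len` (default 9, the shortest
class I core — there is no principled run-length rule, so the smallest
biologically meaningful unit is used). Candidate vaccine peptides are
chosen per hotspot as the window of length 15–17 overlapping the hotspot
that maximises *mean* F; the mean (rather than the sum) makes 15-, 16- and
17-mers compete fairly, and ties prefer the shorter then the earlier
window, which makes extraction deterministic. Windows never extend past the
protein; identical selections from adjacent hotspots are merged.

Candidate labels follow the `pN` convention: `p` plus the absolute 1-based
position of the peptide's first residue on the full-length protein.
Sub-sequences carry an `anchor` so labels survive slicing. Labels are
emitted lowercase and parsed case-insensitively.

## Nested class I epitopes and cross-species identity

Nested class I detection is purely positional: exact substring search of
8–11-mers (or a user-supplied candidate list) inside a class II peptide,
reported with the offset and the absolute `pN` label. Class I binding
prediction is deliberately out of scope.

Cross-species comparison is an ungapped sliding-window alignment of the
candidate against the supplied ortholog, maximising the identity count
(ties: leftmost window). Two percentages are reported, because "similarity"
is ambiguous in common usage: exact-match identity and the fraction of
positions with a positive BLOSUM62 score. The displayed integer identity is
floored (15/16 = 93.75 % displays as 93), a conservative choice; the raw
floats are retained. With BLOSUM62 every identity scores positive, so
identity ≤ similarity always.

## Clonotype analysis

Clonotypes are keyed `"<CDR3α or NA>_<CDR3β or NA>"`, matching droplet VDJ
exports where one chain may fail to assemble; at least one chain must be
present and counts are positive. Frequencies are
`100 × count / total_cells`; displayed frequencies are rounded half-up to
one decimal with a trailing `.0` stripped, which reproduces the printed
style of published figures exactly (4.478 → "4.5", 2.985 → "3",
1.990 → "2", 0.995 → "1"). The "top clonotypes" summary reports its
combined share under both plausible denominators — percent of cells and
percent of distinct clonotypes — because the field's shorthand does not
distinguish them; the count threshold (default ≥ 4 cells) is read as a cell
count, not a percent, and is config-overridable.

Per-peptide clonotype ranking takes an injectable scorer
`(record, peptide) → score`. The shipped default is a deterministic toy:
the Jaccard similarity of 3-mer sets between the CDR3β chain and the
peptide, with the α chain contributing a second Jaccard at weight 0.25
(renormalised) when present, and 0 for a missing β chain. It is a stand-in
for a trained TCR–peptide binding predictor and carries no biological
signal beyond sequence overlap; its purpose is to exercise the ranking,
tie-breaking (score desc, count desc, key asc) and report machinery
deterministically. Externally computed predictions can replace it via a
`key → score` TSV.

The caliper tumour-volume helper implements the standard ellipsoid
approximation `V = max_diameter × min_diameter² × 0.4` (mm³), with
validation that 0 ≤ min ≤ max.

## Synthetic data: what it emulates and what it does not

The generator exists to exercise the aggregation machinery end to end from
a single seed; it makes no attempt at MHC biology (no anchor residues, no
hydrophobicity, no VDJ recombination model).

**Proteins** are uniform-random over the 20 canonical residues.

**Predictions**: every sliding window of length 15 gets
`metric = noise − bonus × overlap_fraction`, where the noise is Gaussian
(sd 1.5), drawn independently per (algorithm, allele), and the bonus is 3.0
at full overlap with a planted region — the two algorithms share the bonus
but not the noise, giving correlated-but-distinct rankings. The defaults
(50-aa protein, one planted region at residues 18–32, three alleles × two
algorithms) were chosen so that the planted signal is recoverable by design:
the full-overlap bonus is two noise standard deviations, so windows on the
plant dominate every list's top ranks, while the bonus difference between
adjacent windows (0.2) is well inside the noise, so the selected top-20
lists tile the whole planted segment instead of stacking on its centre. A
much larger bonus/noise ratio (or a much longer protein) concentrates
coverage at the region centre and the dark-red run then recovers only the
middle of the plant — a useful reminder that the aggregation localises
*peak* consensus, not region boundaries.

**Clonotypes**: CDR3-like strings follow the `C…F` motif (length 10–17,
purely cosmetic). Clone sizes are drawn from a geometric distribution with
success probability `1 − skew` (skew 0 ⇒ all singletons), capped and then
renormalised by deterministic round-robin increments/decrements so each
group's counts sum *exactly* to its cell total. Groups after the first copy
a `shared_fraction` of their keys from the first group; the defaults — a
vaccinated group of 201 cells over 80 clonotypes (skew 0.4) and a control
group of 57 cells over 35 clonotypes (skew 0.3), with no sharing — mirror
the sequencing scale and near-complete between-group uniqueness reported
for vaccine-elicited CD4 repertoires.

Passing tests on this generator demonstrate that the bookkeeping
(selection, accumulation, normalisation, segmentation, set arithmetic,
exact totals, determinism) is correct; they say nothing about how real
predictors correlate, how real repertoires are distributed, or whether real
hotspots translate into immunogenic peptides.

## Numerical and degenerate-input choices

- Rank assignment breaks metric ties by ascending start, then peptide
  lexicographically — a total order, so loading is deterministic.
- An empty selection yields an all-zero track (with a warning), all-zero
  pct and a uniform light_blue stratum, never a division by zero.
- Score-track arrays are float64/int64; S/N/F equality against the
  brute-force oracle is asserted exactly (to 1e-12) in tests, which holds
  because both sides sum the same finite weights.
- Under-full prediction groups (fewer than `top_k` rows) are kept whole
  with a warning rather than rejected.
- The pipeline writes only text artifacts and embeds no timestamps, so
  reruns with one seed are byte-identical; the manifest echoes the full
  config, the seed and the package version.

## Problem sizes

The test suite and the demo run at desk scale by choice: 50-aa synthetic
antigens (36 windows × 6 predictor lists), 200 randomised oracle instances
of ≤ 60 aa, and clonotype groups of ≤ 201 cells. These sizes exercise every
code path; nothing in the implementation is specific to them, and the
complexity is linear in windows × lists for scoring and in clonotypes for
the repertoire analysis.

## Known limitations

- The scorer aggregates predictor *ranks* only; it cannot recover
  information a predictor's raw affinities would add.
- Cross-species comparison is ungapped; an indel between orthologs breaks
  the window alignment (gapped alignment is deliberately out of scope).
- The toy TCR scorer is not a binding predictor; rankings under it are
  meaningful only as a pipeline exercise unless external scores are
  supplied.
- Hotspot boundaries depend on the percent-of-max cut, hence on the single
  highest-scoring residue of the protein; proteins with one dominant site
  will suppress secondary sites below the dark-red threshold.
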