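# epitopemap

Tools for designing Th1-directed multi-peptide cancer vaccines from MHC
class II binding predictions, and for analysing the CD4 T-cell receptor
(TCR) repertoires such vaccines elicit.

The package is aimed at tumour-immunology groups who run several MHC class
II binding predictors (NetMHCIIpan-style, Rankpep-style) over a candidate
tumour antigen across a panel of alleles and need a principled way to merge
the resulting ranked peptide lists into per-residue "immunogenicity
hotspots", pick 15–17-mer vaccine candidate peptides from them, check those
candidates for nested class I (CD8) epitopes and for cross-species sequence
conservation, and finally examine single-cell VDJ clonotype tables from
vaccinated versus control animals.

## The combined scoring system

For each (algorithm, allele) prediction list, the top *K* peptides by
predicted binding rank are selected (*K* = 20 by default; the binding metric
is rank-like, smaller = stronger). Every residue *i* of the antigen then
accumulates:

- **S_i** — the sum, over all selected peptides covering residue *i*, of a
  rank weight *w(r)*. The rank-1 peptide of a list contributes *w* = 1; by
  default weights fall off linearly to 1/*K* at rank *K* (reciprocal and
  uniform schemes are available).
- **N_i** — the number of distinct MHC class II alleles (union over
  algorithms) with at least one selected peptide covering residue *i*: the
  allele promiscuity of the site.
- **F_i = S_i × N_i** — the final score, rewarding residues that are both
  densely covered by high-ranking peptides and promiscuous across alleles.

F is normalised to percent of the protein-wide maximum and binned into
colour strata (dark red ≥ 75 %, red 50–75 %, orange 40–50 %, yellow
30–40 %, green 20–30 %, blue 10–20 %, light blue < 10 %) for an HTML
heatmap. Maximal dark-red runs (≥ 9 residues by default) are hotspots;
per hotspot, the 15–17-mer window maximising mean F becomes a candidate
vaccine peptide, labelled `pN` by the absolute 1-based position of its
first residue.

Candidates can then be screened for exactly nested 8–11-mer class I
epitopes (reported with absolute `pN` labels) and aligned ungapped against
an orthologous protein to report percent identity and BLOSUM62-positive
similarity.

The clonotype module computes per-clonotype frequencies (cell count over
total sequenced cells), between-group overlap (shared/unique keys, Jaccard
index), top clonotypes above a count threshold, and per-peptide rankings of
clonotypes under an injectable TCR–peptide scorer (a deterministic toy
k-mer-similarity scorer ships with the package; externally computed scores
can be loaded from TSV).

A fully seeded synthetic-data module generates every input the pipeline
consumes — random antigens, two-algorithm multi-allele prediction tables
with a planted high-binding region, and skewed, group-structured clonotype
tables — so the whole analysis can be exercised and tested without any
external predictor.

## Worked example

Run the full pipeline on the synthetic demo dataset (a 50-aa antigen with a
high-binding region planted at residues 18–32; two algorithms × three
alleles; one vaccinated and one control clonotype group):

```sh
epitopemap run-all --synthetic --seed 0 --out demo --peptide KDIVALMVRRAYDIA
```

`demo/hotspots.bed` (0-based half-open coordinates) shows the recovered
hotspot, matching the planted region almost exactly:

```
synthetic_protein	18	31	hotspot_1	100.0	+
```

`demo/candidates.tsv` shows the candidate vaccine peptide extracted from it:

```
label	start	end	length	sequence	mean_F
p18	18	32	15	RYPLAYDCDFSAYCD	116.88
```

`demo/residue_scores.tsv` holds the per-residue track behind the
`demo/heatmap.html` rendering; inside the hotspot all three alleles
contribute (N = 3) and F is within the dark-red stratum:

```
position	residue	S	N	F	pct	stratum
21	L	40.6	3	121.8	91.3386	dark_red
22	A	40.7	3	122.1	91.5636	dark_red
```

The clonotype report writes per-group frequency tables
(`demo/frequencies_vaccine.tsv`: 201 cells, with the top clones displayed
as e.g. `3`, `2.5`, `2` percent), the group overlap
(`demo/overlap_vaccine_vs_control.tsv`: `jaccard=0.000000` — the synthetic
repertoires are disjoint, as expected for vaccine-induced clones), and a
top-4 clonotype ranking per supplied peptide.

Library use mirrors the CLI; the nested class I search of the published
TOP2A class II peptide p232 is one call:

```python
>>> from epitopemap import ProteinRecord, find_nested_class1
>>> host = ProteinRecord(id="p232", sequence="KDIVALMVRRAYDIA", anchor=232)
>>> find_nested_class1(host, candidates=["VALMVRRAY"])
[NestedEpitope(sequence='VALMVRRAY', offset=3, absolute_label='p235')]
```

## Input dialects

- **Prediction TSV**: tab-separated, header
  `algorithm allele start peptide metric [rank]`; `start` is absolute
  1-based on the protein; `metric` is rank-like (smaller = stronger —
  affinity-style outputs must be converted on ingest); `#` lines are
  comments. If `rank` is absent, ranks are assigned per (algorithm, allele)
  by ascending metric, ties by ascending start, then peptide.
- **Clonotype CSV**: header `alpha_cdr3,beta_cdr3,count`; an empty cell or
  `NA` marks a missing chain; duplicate keys are merged by summing counts.
- Proteins as FASTA; hotspots as BED (0-based half-open); candidates as
  FASTA/TSV.

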