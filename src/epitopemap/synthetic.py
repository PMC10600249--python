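"""Seeded synthetic inputs for the whole pipeline.

Stands in for the external binding predictors and the study's sequencing
data: (a) random proteins; (b) per-(algorithm, allele) sliding-window
prediction tables in which windows overlapping "planted" regions receive a
binding bonus on top of independent per-predictor noise, so the two
algorithms produce correlated-but-distinct rankings with a recoverable
high-binding region; (c) group-structured clonotype tables with a skewed
(truncated-geometric) clone-size distribution, exact group cell totals and a
controllable fraction of clonotype keys shared between groups.

The generator is intentionally simple — noise plus an overlap bonus — and
exists to exercise the aggregation machinery, not to approximate MHC
biology. Everything is a pure function of the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clonotypes import ClonotypeRecord, ClonotypeTable
from .scoring import PredictionRow, PredictionTable, assign_ranks
from .sequence_io import CANONICAL_AA, ProteinRecord

_AA = "".join(sorted(CANONICAL_AA))

# rng stream tags so each generator draws from an independent child stream
_STREAM_PROTEIN = 1
_STREAM_PREDICTIONS = 2
_STREAM_CLONOTYPES = 3


@dataclass(frozen=True)
class ClonotypeGroupSpec:
    """One synthetic sample group of the clonotype generator."""

    group: str
    total_cells: int
    n_clonotypes: int
    skew: float = 0.4  # 0 = all singletons; towards 1 = heavier clone sizes
    shared_fraction: float = 0.0  # fraction of keys copied from the first group

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if self.total_cells < self.n_clonotypes:
            raise ValueError(
                f"group {self.group!r}: total_cells {self.total_cells} < "
                f"n_clonotypes {self.n_clonotypes} (infeasible)"
            )
        if not 0 <= self.skew < 1:
            raise ValueError("skew must be in [0, 1)")
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic dataset; defaults define the demo conditions.

    The default protein is a compact 50-aa demo antigen with one planted
    high-binding region of width 15, scanned with 15-mer windows for 3 class
    II alleles by 2 algorithms. Per-predictor noise is Gaussian (sd 1.5) and
    the full-overlap bonus is 3.0 — two noise standard deviations, so the
    plant dominates each predictor's ranking, while the bonus difference
    between adjacent windows (0.2) stays within the noise, so the selected
    top lists tile the whole planted segment rather than only its centre.
    The default clonotype groups mirror a vaccinated sample of 201 CD4+ T
    cells and an adjuvant-control sample of 57 cells, with disjoint
    repertoires.
    """

    seed: int = 0
    protein_length: int = 50
    alleles: tuple[str, ...] = ("H2-IAq", "H2-IEq", "HLA-DRB1*01:01")
    algorithms: tuple[str, ...] = ("alg1", "alg2")
    planted_regions: tuple[tuple[int, int], ...] = ((18, 32),)
    window: int = 15
    noise_sd: float = 1.5
    plant_bonus: float = 3.0
    clonotype_groups: tuple[ClonotypeGroupSpec, ...] = (
        ClonotypeGroupSpec("vaccine", total_cells=201, n_clonotypes=80, skew=0.4),
        ClonotypeGroupSpec("control", total_cells=57, n_clonotypes=35, skew=0.3),
    )

    def __post_init__(self) -> None:
        if self.protein_length < self.window:
            raise ValueError("protein_length must be >= window")
        for start, end in self.planted_regions:
            if not 1 <= start <= end <= self.protein_length:
                raise ValueError(f"planted region ({start}, {end}) outside protein bounds")


def _rng(spec: SyntheticSpec, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream, *extra])


def generate_protein(spec: SyntheticSpec, protein_id: str = "synthetic_protein") -> ProteinRecord:
    """Uniform-random protein over the 20 canonical residues; anchor 1."""
    rng = _rng(spec, _STREAM_PROTEIN)
    seq = "".join(rng.choice(list(_AA), size=spec.protein_length))
    return ProteinRecord(id=protein_id, sequence=seq, anchor=1)


def _overlap_fraction(start: int, window: int, regions) -> float:
    """Largest fraction of the window covered by any planted region."""
    end = start + window - 1
    best = 0.0
    for rs, re in regions:
        ov = min(end, re) - max(start, rs) + 1
        if ov > 0:
            best = max(best, ov / window)
    return best


def mock_predictions(spec: SyntheticSpec, protein: ProteinRecord) -> PredictionTable:
    """Sliding-window prediction table covering all (algorithm, allele) pairs.

    metric = Gaussian noise (independent per algorithm and allele) minus
    ``plant_bonus`` × overlap fraction with the planted regions; smaller is
    better. Ranks are assigned per (algorithm, allele) by ascending metric.
    """
    n_windows = len(protein.sequence) - spec.window + 1
    starts = [protein.anchor + off for off in range(n_windows)]
    rows: list[PredictionRow] = []
    for ai, alg in enumerate(spec.algorithms):
        for gi, allele in enumerate(spec.alleles):
            rng = _rng(spec, _STREAM_PREDICTIONS, ai, gi)
            noise = rng.normal(0.0, spec.noise_sd, size=n_windows)
            for w, start in enumerate(starts):
                bonus = spec.plant_bonus * _overlap_fraction(start, spec.window,
                                                             spec.planted_regions)
                peptide = protein.slice_absolute(start, start + spec.window - 1)
                rows.append(PredictionRow(alg, allele, start, peptide,
                                          float(noise[w] - bonus)))
    return PredictionTable(protein_id=protein.id, rows=assign_ranks(rows))


def _cdr3(rng: np.random.Generator) -> str:
    """Random CDR3-like string: C…F motif, total length 10–17 (cosmetic)."""
    middle = rng.integers(8, 16)  # inclusive-exclusive -> 8..15 inner residues
    return "C" + "".join(rng.choice(list(_AA), size=int(middle))) + "F"


def _clone_sizes(rng: np.random.Generator, n: int, total: int, skew: float) -> list[int]:
    """n clone sizes from a truncated geometric, renormalised to sum to total."""
    if skew == 0.0:
        sizes = np.ones(n, dtype=int)
    else:
        sizes = rng.geometric(p=1.0 - skew, size=n)
    sizes = np.minimum(sizes, total - n + 1)  # leave >=1 cell for every clone
    diff = total - int(sizes.sum())
    order = np.argsort(-sizes, kind="stable")
    i = 0
    while diff != 0:
        idx = order[i % n]
        if diff > 0:
            sizes[idx] += 1
            diff -= 1
        elif sizes[idx] > 1:
            sizes[idx] -= 1
            diff += 1
        i += 1
    return [int(s) for s in sizes]


def mock_clonotype_tables(spec: SyntheticSpec) -> list[ClonotypeTable]:
    """Group-structured clonotype tables with exact totals and key sharing.

    Each group draws unique CDR3α/β pairs (α missing for ~20% of clonotypes,
    as in droplet VDJ data where one chain often fails to assemble); groups
    after the first copy ``shared_fraction`` of their keys from the first
    group. Clone sizes sum exactly to the group's total_cells.
    """
    tables: list[ClonotypeTable] = []
    first_chains: list[tuple[str | None, str]] = []
    for grp_idx, grp in enumerate(spec.clonotype_groups):
        rng = _rng(spec, _STREAM_CLONOTYPES, grp_idx)
        n = grp.n_clonotypes
        chains: list[tuple[str | None, str]] = []
        if grp_idx > 0 and grp.shared_fraction > 0 and first_chains:
            n_shared = min(int(round(grp.shared_fraction * n)), len(first_chains))
            chains.extend(first_chains[:n_shared])
        seen = {c for c in chains}
        while len(chains) < n:
            alpha = None if rng.random() < 0.2 else _cdr3(rng)
            beta = _cdr3(rng)
            pair = (alpha, beta)
            if pair in seen:
                continue
            seen.add(pair)
            chains.append(pair)
        sizes = _clone_sizes(rng, n, grp.total_cells, grp.skew)
        records = [ClonotypeRecord(a, b, s) for (a, b), s in zip(chains, sizes)]
        table = ClonotypeTable(group=grp.group, records=records)
        assert table.total_cells == grp.total_cells
        tables.append(table)
        if grp_idx == 0:
            first_chains = chains
    return tables


def write_predictions_tsv(table: PredictionTable, path) -> None:
    """Emit the prediction TSV dialect the scoring loader consumes."""
    with open(path, "w") as fh:
        fh.write("# synthetic binding predictions (smaller metric = stronger binder)\n")
        fh.write("algorithm\tallele\tstart\tpeptide\tmetric\trank\n")
        for r in sorted(table.rows, key=lambda r: (r.algorithm, r.allele, r.rank)):
            fh.write(f"{r.algorithm}\t{r.allele}\t{r.start}\t{r.peptide}\t"
                     f"{r.metric:.6f}\t{r.rank}\n")


def write_clonotypes_csv(table: ClonotypeTable, path) -> None:
    """Emit the clonotype CSV dialect the clonotype loader consumes."""
    with open(path, "w") as fh:
        fh.write("alpha_cdr3,beta_cdr3,count\n")
        for r in sorted(table.records, key=lambda r: (-r.count, r.key)):
            fh.write(f"{r.alpha_cdr3 or ''},{r.beta_cdr3 or ''},{r.count}\n")
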