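import numpy as np
import pytest

from epitopemap.scoring import (PredictionRow, PredictionTable, ScoringConfig,
                                assign_ranks)
from epitopemap.sequence_io import CANONICAL_AA, ProteinRecord

AA = "".join(sorted(CANONICAL_AA))


def random_protein(rng: np.random.Generator, length: int, anchor: int = 1,
                   protein_id: str = "prot") -> ProteinRecord:
    seq = "".join(rng.choice(list(AA), size=length))
    return ProteinRecord(id=protein_id, sequence=seq, anchor=anchor)


def random_prediction_table(rng: np.random.Generator, protein: ProteinRecord,
                            n_alleles: int = 3, n_algorithms: int = 2,
                            max_rows_per_group: int = 8,
                            peptide_len: int = 9) -> PredictionTable:
    """Random per-group peptide windows with random metrics; ranks assigned."""
    rows = []
    n_starts = len(protein.sequence) - peptide_len + 1
    for alg in [f"alg{i}" for i in range(1, n_algorithms + 1)]:
        for allele in [f"allele{chr(65 + j)}" for j in range(n_alleles)]:
            n_rows = int(rng.integers(1, max_rows_per_group + 1))
            starts = rng.choice(n_starts, size=min(n_rows, n_starts), replace=False)
            for off in starts:
                start = protein.anchor + int(off)
                pep = protein.slice_absolute(start, start + peptide_len - 1)
                rows.append(PredictionRow(alg, allele, start, pep,
                                          float(rng.normal())))
    return PredictionTable(protein_id=protein.id, rows=assign_ranks(rows))


def brute_force_snf(selected: PredictionTable, protein: ProteinRecord,
                    config: ScoringConfig):
    """Independent per-residue oracle: loop every residue over every row.

    Recomputes the rank weight from its closed form rather than calling the
    implementation's weight function.
    """
    n = len(protein.sequence)
    S = [0.0] * n
    N = [0] * n
    for i in range(n):
        pos = protein.anchor + i
        alleles = set()
        pairs = set()
        for row in selected.rows:
            if row.start <= pos <= row.start + len(row.peptide) - 1:
                if config.weight_scheme == "linear":
                    w = (config.top_k + 1 - row.rank) / config.top_k
                elif config.weight_scheme == "reciprocal":
                    w = 1.0 / row.rank
                else:
                    w = 1.0
                S[i] += w
                alleles.add(row.allele)
                pairs.add((row.algorithm, row.allele))
        N[i] = len(alleles) if config.n_mode == "allele_union" else len(pairs)
    F = [s * c for s, c in zip(S, N)]
    return S, N, F


@pytest.fixture
def small_protein() -> ProteinRecord:
    return ProteinRecord(id="toy", sequence="ACDEFGHIKL", anchor=1)
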