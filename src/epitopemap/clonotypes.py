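"""CD4 TCR clonotype frequency, overlap and per-peptide ranking analysis.

A clonotype is identified by its paired CDR3 amino-acid sequences, keyed as
``"<alpha or NA>_<beta or NA>"`` (matching 10x VDJ-style exports where one
chain may be unrecovered). Frequencies are cell counts over the total
sequenced T cells of the sample; overlap between groups (e.g. vaccinated vs
adjuvant control) is a set comparison on clonotype keys; per-peptide rankings
order clonotypes by a TCR-peptide binding score supplied by an injectable
scorer, so externally computed predictions (e.g. an ERGO run) can replace the
built-in toy k-mer similarity scorer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import pandas as pd

MISSING_CHAIN = "NA"


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype: CDR3α/CDR3β pair (either may be missing) and cell count."""

    alpha_cdr3: str | None
    beta_cdr3: str | None
    count: int

    def __post_init__(self) -> None:
        if not self.alpha_cdr3 and not self.beta_cdr3:
            raise ValueError("clonotype with both CDR3 chains missing")
        if self.count < 1:
            raise ValueError(f"clonotype {self.key}: nonpositive count {self.count}")

    @property
    def key(self) -> str:
        return f"{self.alpha_cdr3 or MISSING_CHAIN}_{self.beta_cdr3 or MISSING_CHAIN}"


@dataclass
class ClonotypeTable:
    """All clonotypes of one sample group, with the group's total cell count."""

    group: str
    records: list[ClonotypeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError(f"group {self.group!r}: duplicate clonotype keys")

    @property
    def total_cells(self) -> int:
        return sum(r.count for r in self.records)

    def keys(self) -> set[str]:
        return {r.key for r in self.records}


@dataclass(frozen=True)
class RankedClonotype:
    key: str
    score: float
    count: int
    freq_pct: float


@dataclass
class PeptideBindingRanking:
    """Clonotypes ranked by predicted binding to one peptide, best first."""

    peptide: str
    ranked: list[RankedClonotype]


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset
    unique_to_a: frozenset
    unique_to_b: frozenset
    jaccard: float


def _norm_chain(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.upper() == MISSING_CHAIN or s.lower() == "nan":
        return None
    return s.upper()


def load_clonotypes(path, group: str) -> ClonotypeTable:
    """Load a clonotype CSV: columns ``alpha_cdr3,beta_cdr3,count``.

    An empty cell or ``NA`` marks a missing chain. Rows with identical keys
    are merged by summing counts (with a warning).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"alpha_cdr3", "beta_cdr3", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns: {sorted(missing)}")
    merged: dict[str, ClonotypeRecord] = {}
    for row_num, rec in enumerate(df.itertuples(index=False), start=1):
        alpha = _norm_chain(rec.alpha_cdr3)
        beta = _norm_chain(rec.beta_cdr3)
        try:
            count = int(rec.count)
        except ValueError as exc:
            raise ValueError(f"row {row_num}: bad count {rec.count!r}") from exc
        try:
            record = ClonotypeRecord(alpha, beta, count)
        except ValueError as exc:
            raise ValueError(f"row {row_num}: {exc}") from exc
        if record.key in merged:
            warnings.warn(f"duplicate clonotype key {record.key}; merging counts")
            old = merged[record.key]
            record = ClonotypeRecord(alpha, beta, old.count + count)
        merged[record.key] = record
    return ClonotypeTable(group=group, records=list(merged.values()))


def format_frequency(freq_pct: float) -> str:
    """Percent frequency rounded half-up to one decimal, trailing ``.0`` stripped.

    Reproduces displayed values such as 9/201 -> "4.5" and 6/201 -> "3".
    """
    d = Decimal(repr(freq_pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    s = str(d)
    return s[:-2] if s.endswith(".0") else s


def clonotype_frequencies(table: ClonotypeTable) -> dict[str, tuple[float, str]]:
    """Per clonotype: (freq_pct, display string); freq_pct = 100 × count / total."""
    total = table.total_cells
    if total == 0:
        raise ValueError(f"group {table.group!r}: empty clonotype table")
    out: dict[str, tuple[float, str]] = {}
    for rec in table.records:
        freq = 100.0 * rec.count / total
        out[rec.key] = (freq, format_frequency(freq))
    return out


def top_clonotypes(table: ClonotypeTable, min_count: int = 4,
                   n: int | None = 5) -> tuple[list[ClonotypeRecord], float, float]:
    """Most frequent clonotypes reaching ``min_count`` cells, at most ``n``.

    Returns the subset plus its combined share, expressed both as percent of
    total cells and as percent of distinct clonotypes (the denominator the
    field reports is ambiguous, so both are given).
    """
    if not table.records:
        raise ValueError(f"group {table.group!r}: empty clonotype table")
    eligible = [r for r in table.records if r.count >= min_count]
    eligible.sort(key=lambda r: (-r.count, r.key))
    subset = eligible if n is None else eligible[:n]
    if not subset:
        return [], 0.0, 0.0
    cell_share = 100.0 * sum(r.count for r in subset) / table.total_cells
    clone_share = 100.0 * len(subset) / len(table.records)
    return subset, cell_share, clone_share


def group_overlap(a: ClonotypeTable, b: ClonotypeTable) -> OverlapResult:
    """Set partition of clonotype keys between two groups plus Jaccard index."""
    ka, kb = a.keys(), b.keys()
    union = ka | kb
    shared = ka & kb
    return OverlapResult(
        shared=frozenset(shared),
        unique_to_a=frozenset(ka - kb),
        unique_to_b=frozenset(kb - ka),
        jaccard=len(shared) / len(union) if union else 0.0,
    )


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def toy_tcr_peptide_score(record: ClonotypeRecord, peptide: str, k: int = 3) -> float:
    """Deterministic stand-in TCR-peptide binding score in [0, 1].

    The Jaccard similarity of the k-mer sets of the CDR3β chain and the
    peptide; when the α chain is present its Jaccard contributes with weight
    0.25 (renormalised). A missing β chain scores 0. This is a toy surrogate
    for a trained TCR-peptide binding predictor, useful only to exercise the
    ranking machinery deterministically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(peptide) < k:
        raise ValueError(f"peptide shorter than k={k}")
    if not record.beta_cdr3:
        return 0.0
    pep = _kmers(peptide.upper(), k)

    def jacc(chain: str) -> float:
        km = _kmers(chain, k)
        union = km | pep
        return len(km & pep) / len(union) if union else 0.0

    beta = jacc(record.beta_cdr3)
    if record.alpha_cdr3:
        return (beta + 0.25 * jacc(record.alpha_cdr3)) / 1.25
    return beta


Scorer = Callable[[ClonotypeRecord, str], float]


def rank_clonotypes_for_peptide(table: ClonotypeTable, peptide: str,
                                scorer: Scorer = toy_tcr_peptide_score,
                                top: int = 4) -> PeptideBindingRanking:
    """Rank all clonotypes by scorer(record, peptide), keep the top ``top``.

    Sort: score descending, ties by cell count descending then key ascending.
    """
    if not table.records:
        raise ValueError(f"group {table.group!r}: empty clonotype table")
    freqs = clonotype_frequencies(table)
    scored = []
    for rec in table.records:
        s = float(scorer(rec, peptide))
        if not math.isfinite(s):
            raise ValueError(f"scorer returned non-finite value for {rec.key}")
        scored.append(RankedClonotype(rec.key, s, rec.count, freqs[rec.key][0]))
    scored.sort(key=lambda r: (-r.score, -r.count, r.key))
    return PeptideBindingRanking(peptide=peptide, ranked=scored[:top])


def load_scores_tsv(path) -> Scorer:
    """Scorer backed by a precomputed score TSV (columns ``key``, ``score``).

    Lets externally computed TCR-peptide predictions replace the toy scorer;
    clonotypes absent from the file score 0.
    """
    df = pd.read_csv(path, sep="\t")
    table = dict(zip(df["key"], df["score"].astype(float)))

    def scorer(record: ClonotypeRecord, peptide: str) -> float:
        return table.get(record.key, 0.0)

    return scorer


def tumor_volume(max_diameter: float, min_diameter: float) -> float:
    """Caliper tumor volume in mm³: maximum diameter × (minimum diameter)² × 0.4."""
    if min_diameter < 0 or max_diameter < 0:
        raise ValueError("diameters must be nonnegative")
    if min_diameter > max_diameter:
        raise ValueError("minimum diameter exceeds maximum diameter")
    return max_diameter * min_diameter**2 * 0.4
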