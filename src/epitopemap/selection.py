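"""Hotspot segmentation, vaccine candidate extraction, nested class I epitopes
and cross-species identity of candidate peptides.

A hotspot is a maximal run of consecutive residues whose percent-of-maximum
score stays at or above a threshold (default 75, the dark-red stratum) for at
least ``min_len`` residues. Candidate vaccine peptides are the 15–17-mer
windows overlapping each hotspot that maximise the mean final score F.
Class I (CD8) 8–11-mer epitopes nested inside a class II candidate are
located by exact substring search and labelled by absolute position. The
cross-species check reports, for a candidate against an orthologous protein,
the best ungapped window's percent identity and BLOSUM62-positive similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .scoring import ResidueScoreTrack
from .sequence_io import ProteinRecord


@dataclass(frozen=True)
class Hotspot:
    """Maximal high-scoring run, absolute 1-based inclusive coordinates."""

    start: int
    end: int
    peak_pct: float
    mean_F: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CandidatePeptide:
    """A selected 15–17-mer vaccine candidate anchored on the parent protein."""

    label: str
    start: int
    end: int
    sequence: str
    mean_F: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def anchor(self) -> int:
        # lets a CandidatePeptide serve as a nested-search host
        return self.start


@dataclass(frozen=True)
class NestedEpitope:
    """A class I k-mer found inside a class II host peptide."""

    sequence: str
    offset: int  # 0-based within the host peptide
    absolute_label: str  # pN, N = host anchor + offset

    @property
    def absolute_position(self) -> int:
        return int(self.absolute_label[1:])


@dataclass(frozen=True)
class CrossSpeciesMatch:
    """Best ungapped placement of a query peptide on a subject protein."""

    query_peptide: str
    subject_id: str
    subject_start: int  # absolute 1-based on the subject
    identity_pct: float
    similarity_pct: float

    @property
    def display_identity(self) -> int:
        """Integer percent identity as displayed (floored)."""
        return math.floor(self.identity_pct)


def find_hotspots(track: ResidueScoreTrack, min_pct: float = 75.0,
                  min_len: int = 9) -> list[Hotspot]:
    """Maximal runs of residues with pct >= ``min_pct`` and length >= ``min_len``."""
    if track.pct is None:
        raise ValueError("track pct not computed")
    hot = track.pct >= min_pct
    hotspots: list[Hotspot] = []
    i = 0
    n = track.length
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                seg_F = track.F[i : j + 1]
                seg_pct = track.pct[i : j + 1]
                hotspots.append(
                    Hotspot(
                        start=track.anchor + i,
                        end=track.anchor + j,
                        peak_pct=float(seg_pct.max()),
                        mean_F=float(seg_F.mean()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return hotspots


def extract_candidates(track: ResidueScoreTrack, protein: ProteinRecord,
                       hotspots: list[Hotspot], min_len: int = 15,
                       max_len: int = 17) -> list[CandidatePeptide]:
    """Per hotspot, the window of length in [min_len, max_len] overlapping it
    that maximises mean F; ties prefer shorter, then earlier windows.

    Windows are constrained to the protein bounds; duplicate (start, end)
    selections across hotspots are merged.
    """
    if len(protein.sequence) < min_len:
        raise ValueError(
            f"protein {protein.id!r} shorter ({len(protein.sequence)}) than "
            f"minimum candidate length {min_len}"
        )
    chosen: dict[tuple[int, int], CandidatePeptide] = {}
    for spot in hotspots:
        best = None  # (-mean_F, length, start)
        for length in range(min_len, max_len + 1):
            lo_start = max(protein.anchor, spot.start - length + 1)
            hi_start = min(spot.end, protein.end - length + 1)
            for start in range(lo_start, hi_start + 1):
                off = start - track.anchor
                mean_f = float(track.F[off : off + length].mean())
                key = (-mean_f, length, start)
                if best is None or key < best:
                    best = key
        if best is None:
            continue
        neg_mean_f, length, start = best
        end = start + length - 1
        if (start, end) not in chosen:
            chosen[(start, end)] = CandidatePeptide(
                label=f"p{start}",
                start=start,
                end=end,
                sequence=protein.slice_absolute(start, end),
                mean_F=-neg_mean_f,
            )
    return sorted(chosen.values(), key=lambda c: (c.start, c.end))


def find_nested_class1(host, k_range: tuple[int, int] = (8, 11),
                       candidates: list[str] | None = None) -> list[NestedEpitope]:
    """Locate class I k-mers nested in a class II host peptide.

    ``host`` is anything with ``sequence`` and ``anchor`` attributes (a
    :class:`CandidatePeptide` or an anchored :class:`ProteinRecord`). With an
    explicit ``candidates`` list, every exact substring occurrence is
    reported; otherwise all k-mers with k in ``k_range`` are enumerated
    (positions only — no class I binding prediction is attempted).
    """
    seq = host.sequence
    anchor = host.anchor
    found: list[NestedEpitope] = []
    if candidates is not None:
        for cand in candidates:
            start = 0
            while True:
                off = seq.find(cand, start)
                if off < 0:
                    break
                found.append(NestedEpitope(cand, off, f"p{anchor + off}"))
                start = off + 1
    else:
        kmin, kmax = k_range
        for k in range(kmin, kmax + 1):
            for off in range(len(seq) - k + 1):
                found.append(NestedEpitope(seq[off : off + k], off, f"p{anchor + off}"))
    found.sort(key=lambda e: (e.offset, len(e.sequence), e.sequence))
    return found


def cross_species_match(query: str, subject: ProteinRecord,
                        matrix: str = "BLOSUM62") -> CrossSpeciesMatch:
    """Best ungapped placement of ``query`` over all subject windows.

    Maximises the identity count (ties: smaller subject start). Identity is
    the exact-match fraction; similarity the fraction of positions with a
    positive substitution-matrix score. With BLOSUM62 every identity is also
    a positive-scoring pair, so identity_pct <= similarity_pct.
    """
    query = query.upper()
    sub = subject.sequence
    q = len(query)
    if q > len(sub):
        raise ValueError("query longer than subject")
    mat = substitution_matrices.load(matrix)
    best = None  # (-matches, window_start_offset)
    for off in range(len(sub) - q + 1):
        window = sub[off : off + q]
        matches = sum(a == b for a, b in zip(query, window))
        key = (-matches, off)
        if best is None or key < best:
            best = key
    neg_matches, off = best
    window = sub[off : off + q]
    similar = sum(1 for a, b in zip(query, window) if mat[a, b] > 0)
    return CrossSpeciesMatch(
        query_peptide=query,
        subject_id=subject.id,
        subject_start=subject.anchor + off,
        identity_pct=100.0 * (-neg_matches) / q,
        similarity_pct=100.0 * similar / q,
    )


def write_hotspots_bed(hotspots: list[Hotspot], protein_id: str, path) -> None:
    """Write hotspots as BED: 0-based half-open (1-based inclusive [s, e] ->
    [s-1, e))."""
    with open(path, "w") as fh:
        for i, spot in enumerate(hotspots, start=1):
            fh.write(
                f"{protein_id}\t{spot.start - 1}\t{spot.end}\t"
                f"hotspot_{i}\t{spot.peak_pct:.1f}\t+\n"
            )


def write_candidates_tsv(candidates: list[CandidatePeptide], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart\tend\tlength\tsequence\tmean_F\n")
        for c in candidates:
            fh.write(f"{c.label}\t{c.start}\t{c.end}\t{c.length}\t{c.sequence}\t{c.mean_F:.6g}\n")


def write_candidates_fasta(candidates: list[CandidatePeptide], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.label}\n{c.sequence}\n")
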