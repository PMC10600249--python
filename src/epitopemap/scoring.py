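"""Combined per-residue MHC class II epitope scoring.

The scoring system aggregates peptide binding predictions from several
algorithms (e.g. NetMHCIIpan-style and Rankpep-style tools, run externally)
over a panel of MHC class II alleles into per-residue immunogenicity scores:

* per (algorithm, allele) list, the ``top_k`` peptides by predicted binding
  rank are selected (smaller metric = stronger predicted binding);
* each residue accumulates a weighted coverage score ``S`` summed over all
  selected peptides covering it, where the rank-1 peptide of a list
  contributes weight 1 and lower ranks contribute less (configurable scheme);
* ``N`` counts the distinct alleles with at least one selected peptide
  covering the residue (high-affinity allele promiscuity);
* the final score is ``F = S * N``, normalised to percent of the protein-wide
  maximum and binned into named colour strata for heatmap display.

Dark-red runs of the resulting track are the immunogenic "hotspots" from
which vaccine candidate peptides are drawn (see :mod:`epitopemap.selection`).
"""

from __future__ import annotations

import html as _html
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import ProteinRecord

WEIGHT_SCHEMES = ("linear", "reciprocal", "uniform")
N_MODES = ("allele_union", "allele_algorithm_pairs")

#: Default percent-of-maximum colour strata: (lower bound, name), decreasing.
#: Intervals are half-open [lower, next_lower) with the top stratum closed at 100.
DEFAULT_STRATA = (
    (75.0, "dark_red"),
    (50.0, "red"),
    (40.0, "orange"),
    (30.0, "yellow"),
    (20.0, "green"),
    (10.0, "blue"),
    (0.0, "light_blue"),
)

#: CSS colours used by the HTML heatmap, one per default stratum.
STRATUM_COLORS = {
    "dark_red": "#8b0000",
    "red": "#e03030",
    "orange": "#f28c28",
    "yellow": "#f2d328",
    "green": "#3cb043",
    "blue": "#2b6cb0",
    "light_blue": "#add8e6",
}


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable parameters of the combined scoring system."""

    top_k: int = 20
    weight_scheme: str = "linear"
    n_mode: str = "allele_union"
    strata_bounds: tuple = DEFAULT_STRATA

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be a positive integer")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight_scheme {self.weight_scheme!r}")
        if self.n_mode not in N_MODES:
            raise ValueError(f"unknown n_mode {self.n_mode!r}")
        lowers = [b for b, _ in self.strata_bounds]
        if list(lowers) != sorted(lowers, reverse=True) or len(set(lowers)) != len(lowers):
            raise ValueError("strata lower bounds must be strictly decreasing")
        if lowers[-1] != 0 or lowers[0] > 100:
            raise ValueError("strata must cover [0, 100]")


@dataclass(frozen=True)
class PredictionRow:
    """One predicted binder: a peptide window scored for one (algorithm, allele).

    ``metric`` is rank-like: smaller means stronger predicted binding.
    ``rank`` is 1-based within its (algorithm, allele) list, 1 = best.
    """

    algorithm: str
    allele: str
    start: int  # absolute 1-based peptide start on the protein
    peptide: str
    metric: float
    rank: int | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.peptide) - 1


@dataclass
class PredictionTable:
    """All prediction rows for one protein, across algorithms and alleles."""

    protein_id: str
    rows: list[PredictionRow] = field(default_factory=list)

    @property
    def alleles(self) -> set[str]:
        return {r.allele for r in self.rows}

    @property
    def algorithms(self) -> set[str]:
        return {r.algorithm for r in self.rows}

    def groups(self) -> dict[tuple[str, str], list[PredictionRow]]:
        """Rows keyed by (algorithm, allele)."""
        out: dict[tuple[str, str], list[PredictionRow]] = {}
        for r in self.rows:
            out.setdefault((r.algorithm, r.allele), []).append(r)
        return out


@dataclass
class ResidueScoreTrack:
    """Per-residue score accumulators over one protein.

    Arrays are indexed by 0-based offset within the protein; the absolute
    1-based position of offset ``i`` is ``anchor + i``.
    """

    protein_id: str
    length: int
    anchor: int = 1
    S: np.ndarray = None
    N: np.ndarray = None
    F: np.ndarray = None
    pct: np.ndarray = None
    strata: list[str] = None

    def __post_init__(self) -> None:
        if self.S is None:
            self.S = np.zeros(self.length)
        if self.N is None:
            self.N = np.zeros(self.length, dtype=int)
        if self.F is None:
            self.F = np.zeros(self.length)


def _validate_row(row_num: int, algorithm: str, allele: str, start: int,
                  peptide: str, protein: ProteinRecord) -> None:
    if start < protein.anchor or start + len(peptide) - 1 > protein.end:
        raise ValueError(
            f"row {row_num}: peptide [{start}, {start + len(peptide) - 1}] "
            f"outside protein [{protein.anchor}, {protein.end}]"
        )
    actual = protein.slice_absolute(start, start + len(peptide) - 1)
    if actual != peptide:
        raise ValueError(
            f"row {row_num}: peptide {peptide!r} does not match protein "
            f"{protein.id!r} at position {start} (found {actual!r})"
        )


def assign_ranks(rows: list[PredictionRow]) -> list[PredictionRow]:
    """Assign 1-based ranks within each (algorithm, allele) list.

    Sort key: ascending metric, then ascending start, then peptide
    (lexicographic) — a deterministic total order.
    """
    out: list[PredictionRow] = []
    groups: dict[tuple[str, str], list[PredictionRow]] = {}
    for r in rows:
        groups.setdefault((r.algorithm, r.allele), []).append(r)
    for grp in groups.values():
        grp_sorted = sorted(grp, key=lambda r: (r.metric, r.start, r.peptide))
        for i, r in enumerate(grp_sorted, start=1):
            out.append(PredictionRow(r.algorithm, r.allele, r.start, r.peptide, r.metric, i))
    return out


def load_predictions(path, protein: ProteinRecord) -> PredictionTable:
    """Load a prediction TSV and validate it against ``protein``.

    Expected tab-separated columns: ``algorithm allele start peptide metric``
    with optional ``rank``; ``#`` lines are comments; ``start`` is absolute
    1-based. If ``rank`` is absent, ranks are assigned per (algorithm, allele)
    by ascending metric with ties broken by ascending start.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"algorithm": str, "allele": str})
    required = {"algorithm", "allele", "start", "peptide", "metric"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")

    seen: set[tuple] = set()
    rows: list[PredictionRow] = []
    has_rank = "rank" in df.columns
    for row_num, rec in enumerate(df.itertuples(index=False), start=1):
        start = int(rec.start)
        peptide = str(rec.peptide).upper()
        _validate_row(row_num, rec.algorithm, rec.allele, start, peptide, protein)
        key = (rec.algorithm, rec.allele, start, peptide)
        if key in seen:
            raise ValueError(f"row {row_num}: duplicate prediction {key}")
        seen.add(key)
        rank = int(rec.rank) if has_rank else None
        rows.append(PredictionRow(rec.algorithm, rec.allele, start, peptide,
                                  float(rec.metric), rank))

    if not has_rank:
        rows = assign_ranks(rows)
    else:
        for (alg, allele), grp in PredictionTable(protein.id, rows).groups().items():
            ranks = [r.rank for r in grp]
            if len(set(ranks)) != len(ranks) or any(r < 1 for r in ranks):
                raise ValueError(
                    f"group ({alg}, {allele}): ranks must be distinct positive integers"
                )
    return PredictionTable(protein_id=protein.id, rows=rows)


def select_top_k(table: PredictionTable, config: ScoringConfig) -> PredictionTable:
    """Keep, per (algorithm, allele), the rows ranked in the top ``top_k``."""
    kept: list[PredictionRow] = []
    for (alg, allele), grp in table.groups().items():
        if any(r.rank is None for r in grp):
            raise ValueError(f"group ({alg}, {allele}): ranks not assigned")
        if len(grp) < config.top_k:
            warnings.warn(
                f"group ({alg}, {allele}) has only {len(grp)} rows "
                f"(top_k={config.top_k}); keeping all"
            )
        kept.extend(r for r in grp if r.rank <= config.top_k)
    kept.sort(key=lambda r: (r.algorithm, r.allele, r.rank))
    return PredictionTable(protein_id=table.protein_id, rows=kept)


def weight_of_rank(rank: int, config: ScoringConfig) -> float:
    """Per-residue weight contributed by a peptide of the given rank.

    The rank-1 peptide of a list always contributes 1. ``linear`` decreases
    to 1/top_k at rank top_k; ``reciprocal`` is 1/rank; ``uniform`` is 1.
    """
    if not 1 <= rank <= config.top_k:
        raise ValueError(f"rank {rank} outside [1, {config.top_k}]")
    if config.weight_scheme == "linear":
        return (config.top_k + 1 - rank) / config.top_k
    if config.weight_scheme == "reciprocal":
        return 1.0 / rank
    return 1.0


def accumulate_residue_scores(selected: PredictionTable, protein: ProteinRecord,
                              config: ScoringConfig) -> ResidueScoreTrack:
    """Accumulate S, N and F = S × N per residue from the selected peptides.

    ``S`` sums, over every selected row covering the residue, the weight of
    the row's rank; ``N`` counts the distinct alleles (default: union over
    algorithms) with at least one selected row covering the residue. The
    ``pct`` and strata fields are filled by :func:`percent_of_max` and
    :func:`assign_strata`.
    """
    n = len(protein.sequence)
    track = ResidueScoreTrack(protein_id=protein.id, length=n, anchor=protein.anchor)
    if not selected.rows:
        warnings.warn("no selected predictions; score track is all zeros")
        return track

    covering: list[set] = [set() for _ in range(n)]
    for row in selected.rows:
        w = weight_of_rank(row.rank, config)
        lo = row.start - protein.anchor
        hi = lo + len(row.peptide)  # exclusive
        track.S[lo:hi] += w
        tag = row.allele if config.n_mode == "allele_union" else (row.algorithm, row.allele)
        for i in range(lo, hi):
            covering[i].add(tag)
    track.N = np.array([len(c) for c in covering], dtype=int)
    track.F = track.S * track.N
    return track


def percent_of_max(track: ResidueScoreTrack) -> ResidueScoreTrack:
    """Fill ``pct`` = 100 × F / max(F); all zeros when no residue is covered."""
    fmax = float(track.F.max(initial=0.0))
    if fmax == 0:
        track.pct = np.zeros(track.length)
    else:
        # clip: F/Fmax can exceed 1 by an ulp in floating point
        track.pct = np.clip(100.0 * track.F / fmax, 0.0, 100.0)
    return track


def assign_stratum(pct: float, config: ScoringConfig = ScoringConfig()) -> str:
    """Name of the colour stratum containing ``pct`` (percent of maximum)."""
    if not 0 <= pct <= 100:
        raise ValueError(f"pct {pct} outside [0, 100]")
    for lower, name in config.strata_bounds:
        if pct >= lower:
            return name
    raise AssertionError("strata do not cover [0, 100]")  # pragma: no cover


def assign_strata(track: ResidueScoreTrack,
                  config: ScoringConfig = ScoringConfig()) -> ResidueScoreTrack:
    """Fill the per-residue stratum names from ``pct``."""
    if track.pct is None:
        raise ValueError("pct not computed; call percent_of_max first")
    track.strata = [assign_stratum(float(p), config) for p in track.pct]
    return track


def score_protein(table: PredictionTable, protein: ProteinRecord,
                  config: ScoringConfig = ScoringConfig()) -> ResidueScoreTrack:
    """Convenience: top-k selection, accumulation, normalisation, strata."""
    selected = select_top_k(table, config)
    track = accumulate_residue_scores(selected, protein, config)
    percent_of_max(track)
    assign_strata(track, config)
    return track


def track_to_frame(track: ResidueScoreTrack, protein: ProteinRecord) -> pd.DataFrame:
    """Per-residue table: position, residue, S, N, F, pct, stratum."""
    if track.strata is None:
        raise ValueError("track not fully populated")
    return pd.DataFrame(
        {
            "position": np.arange(track.length) + track.anchor,
            "residue": list(protein.sequence),
            "S": track.S,
            "N": track.N,
            "F": track.F,
            "pct": track.pct,
            "stratum": track.strata,
        }
    )


def render_heatmap(track: ResidueScoreTrack, protein: ProteinRecord, out,
                   format: str = "tsv",
                   config: ScoringConfig = ScoringConfig()) -> None:
    """Write the score track as a per-residue TSV or a coloured HTML heatmap."""
    if format == "tsv":
        track_to_frame(track, protein).to_csv(out, sep="\t", index=False,
                                              float_format="%.6g")
        return
    if format != "html":
        raise ValueError(f"unknown heatmap format {format!r}")

    colors = dict(STRATUM_COLORS)
    for _, name in config.strata_bounds:
        colors.setdefault(name, "#999999")
    spans = []
    per_line = 60
    for i, (ch, stratum) in enumerate(zip(protein.sequence, track.strata)):
        pos = track.anchor + i
        spans.append(
            f'<span class="aa {stratum}" title="p{pos} {_html.escape(ch)} '
            f'pct={track.pct[i]:.1f}">{_html.escape(ch)}</span>'
        )
        if (i + 1) % per_line == 0:
            spans.append(f' <span class="pos">{pos}</span><br/>\n')
    bounds = list(config.strata_bounds)
    legend = []
    for idx, (lower, name) in enumerate(bounds):
        upper = 100.0 if idx == 0 else bounds[idx - 1][0]
        closing = "]" if idx == 0 else ")"
        legend.append(
            f'<li><span class="aa {name}">&nbsp;&nbsp;</span> '
            f"{name}: [{lower:g}, {upper:g}{closing}% of maximum score</li>"
        )
    css = "\n".join(
        f".{name} {{ background: {color}; color: white; }}"
        if name != "light_blue"
        else f".{name} {{ background: {color}; }}"
        for name, color in colors.items()
    )
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>Per-residue immunogenicity heatmap: {_html.escape(track.protein_id)}</title>
<style>
body {{ font-family: sans-serif; }}
.seq {{ font-family: monospace; font-size: 14px; line-height: 1.6; }}
.aa {{ padding: 1px 0; }}
.pos {{ color: #888; font-size: 11px; }}
{css}
</style></head>
<body>
<h1>{_html.escape(track.protein_id)}</h1>
<p>Per-residue combined MHC class II score F = S &times; N, shown as percent
of the protein-wide maximum.</p>
<div class="seq">{''.join(spans)}</div>
<h2>Legend</h2>
<ul>{''.join(legend)}</ul>
</body></html>
"""
    with open(out, "w") as fh:
        fh.write(doc)
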