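"""End-to-end orchestration: config, logging, staged pipeline runs.

Two entry points chain the library stages and write their artifacts to an
output directory:

* :func:`run_epitope_pipeline` — predictions (loaded or synthesised) →
  per-residue score track → heatmap → hotspots → candidate peptides →
  optional nested class I search and cross-species check → manifest.
* :func:`run_clonotype_report` — clonotype tables → per-group frequency
  tables → pairwise overlap reports → per-peptide binding rankings →
  manifest.

All randomness flows from the single config seed; rerunning with the same
config yields byte-identical text outputs. A stage failure raises
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from itertools import combinations
from pathlib import Path

import yaml

from . import selection
from .clonotypes import (ClonotypeTable, clonotype_frequencies, group_overlap,
                         load_clonotypes, rank_clonotypes_for_peptide,
                         top_clonotypes, toy_tcr_peptide_score)
from .scoring import ScoringConfig, load_predictions, render_heatmap, score_protein
from .sequence_io import ProteinRecord, read_fasta
from .synthetic import (SyntheticSpec, generate_protein, mock_clonotype_tables,
                        mock_predictions, write_clonotypes_csv,
                        write_predictions_tsv)

logger = logging.getLogger("epitopemap")


class PipelineError(RuntimeError):
    """A stage failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat run configuration; file keys and CLI flags share these names.

    Exactly one of ``predictions_tsv`` / ``synthetic`` must be supplied for
    the epitope pipeline. With ``synthetic`` the protein and predictions are
    generated from ``seed``.
    """

    out_dir: str = "epitopemap_out"
    seed: int = 0
    log_level: str = "INFO"
    protein_fasta: str | None = None
    protein_anchor: int = 1
    predictions_tsv: str | None = None
    synthetic: bool = False
    ortholog_fasta: str | None = None
    class1_candidates: tuple[str, ...] = ()
    clonotype_csvs: tuple[tuple[str, str], ...] = ()  # (group, path) pairs
    peptides: tuple[str, ...] = ()
    top_k: int = 20
    weight_scheme: str = "linear"
    n_mode: str = "allele_union"
    hotspot_min_pct: float = 75.0
    hotspot_min_len: int = 9
    candidate_min_len: int = 15
    candidate_max_len: int = 17
    clonotype_min_count: int = 4
    clonotype_top_n: int = 5
    rank_top: int = 4
    synthetic_overrides: dict = field(default_factory=dict)

    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(top_k=self.top_k, weight_scheme=self.weight_scheme,
                             n_mode=self.n_mode)

    def synthetic_spec(self) -> SyntheticSpec:
        return SyntheticSpec(seed=self.seed, **self.synthetic_overrides)


def load_config(path) -> PipelineConfig:
    """Read a flat key: value YAML config file into a PipelineConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError("config", f"{path}: expected a flat key-value mapping")
    return merge_config(PipelineConfig(), raw)


def merge_config(base: PipelineConfig, overrides: dict) -> PipelineConfig:
    """New config with ``overrides`` applied over ``base`` (CLI beats file)."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    cleaned = {}
    for key, value in overrides.items():
        if value is None:
            continue
        if key == "clonotype_csvs":
            value = tuple((str(g), str(p)) for g, p in
                          (item if isinstance(item, (list, tuple)) else item.split("=", 1)
                           for item in value))
        elif key in ("class1_candidates", "peptides"):
            value = tuple(str(v) for v in value)
        cleaned[key] = value
    return dataclasses.replace(base, **cleaned)


def _setup_logging(config: PipelineConfig) -> None:
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


def _manifest(config: PipelineConfig, outputs: list[str], out_dir: Path,
              name: str = "manifest.json") -> None:
    try:
        version = metadata.version("epitopemap")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    doc = {
        "epitopemap_version": version,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "outputs": sorted(outputs),
    }
    with open(out_dir / name, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")


def _load_protein(config: PipelineConfig) -> ProteinRecord:
    records = read_fasta(config.protein_fasta, anchor=config.protein_anchor)
    if len(records) > 1:
        logger.warning("protein FASTA has %d records; using the first", len(records))
    return records[0]


def run_epitope_pipeline(config: PipelineConfig) -> dict:
    """Run scoring → hotspots → candidates (+ optional nested/cross-species).

    Returns a dict of in-memory results keyed by stage; writes all artifacts
    under ``config.out_dir``.
    """
    _setup_logging(config)
    stage = "config"
    try:
        if bool(config.predictions_tsv) == bool(config.synthetic):
            raise PipelineError(
                "config", "exactly one of predictions_tsv / synthetic must be given")
        if config.predictions_tsv and not config.protein_fasta:
            raise PipelineError("config", "predictions_tsv requires protein_fasta")
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs: list[str] = []
        scoring_cfg = config.scoring_config()

        stage = "inputs"
        logger.info("[inputs] preparing protein and predictions")
        if config.synthetic:
            spec = config.synthetic_spec()
            protein = generate_protein(spec)
            table = mock_predictions(spec, protein)
            pred_path = out_dir / "predictions.tsv"
            write_predictions_tsv(table, pred_path)
            outputs.append(pred_path.name)
        else:
            protein = _load_protein(config)
            table = load_predictions(config.predictions_tsv, protein)

        stage = "scoring"
        logger.info("[scoring] accumulating per-residue scores")
        track = score_protein(table, protein, scoring_cfg)
        track_path = out_dir / "residue_scores.tsv"
        render_heatmap(track, protein, track_path, format="tsv", config=scoring_cfg)
        heatmap_path = out_dir / "heatmap.html"
        render_heatmap(track, protein, heatmap_path, format="html", config=scoring_cfg)
        outputs += [track_path.name, heatmap_path.name]

        stage = "hotspots"
        logger.info("[hotspots] segmenting high-scoring runs")
        hotspots = selection.find_hotspots(track, config.hotspot_min_pct,
                                           config.hotspot_min_len)
        bed_path = out_dir / "hotspots.bed"
        selection.write_hotspots_bed(hotspots, protein.id, bed_path)
        outputs.append(bed_path.name)

        stage = "candidates"
        logger.info("[candidates] extracting %d-%d-mer vaccine candidates",
                    config.candidate_min_len, config.candidate_max_len)
        candidates = selection.extract_candidates(
            track, protein, hotspots, config.candidate_min_len, config.candidate_max_len)
        selection.write_candidates_fasta(candidates, out_dir / "candidates.fasta")
        selection.write_candidates_tsv(candidates, out_dir / "candidates.tsv")
        outputs += ["candidates.fasta", "candidates.tsv"]

        nested = {}
        if config.class1_candidates:
            stage = "nested"
            logger.info("[nested] searching class I k-mers inside candidates")
            with open(out_dir / "nested_epitopes.tsv", "w") as fh:
                fh.write("host_label\tclass1_sequence\toffset\tabsolute_label\n")
                for cand in candidates:
                    hits = selection.find_nested_class1(
                        cand, candidates=list(config.class1_candidates))
                    nested[cand.label] = hits
                    for hit in hits:
                        fh.write(f"{cand.label}\t{hit.sequence}\t{hit.offset}\t"
                                 f"{hit.absolute_label}\n")
            outputs.append("nested_epitopes.tsv")

        xspecies = {}
        if config.ortholog_fasta:
            stage = "xspecies"
            logger.info("[xspecies] cross-species identity check")
            subject = read_fasta(config.ortholog_fasta)[0]
            with open(out_dir / "cross_species.tsv", "w") as fh:
                fh.write("label\tsubject_id\tsubject_start\tidentity_pct\t"
                         "similarity_pct\tdisplay_identity\n")
                for cand in candidates:
                    m = selection.cross_species_match(cand.sequence, subject)
                    xspecies[cand.label] = m
                    fh.write(f"{cand.label}\t{m.subject_id}\t{m.subject_start}\t"
                             f"{m.identity_pct:.4f}\t{m.similarity_pct:.4f}\t"
                             f"{m.display_identity}\n")
            outputs.append("cross_species.tsv")

        stage = "manifest"
        _manifest(config, outputs + ["manifest.json"], out_dir)
        logger.info("[manifest] wrote %d artifacts to %s", len(outputs) + 1, out_dir)
        return {"protein": protein, "track": track, "hotspots": hotspots,
                "candidates": candidates, "nested": nested, "xspecies": xspecies}
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("[%s] failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc


def run_clonotype_report(config: PipelineConfig,
                         tables: list[ClonotypeTable] | None = None) -> dict:
    """Frequency tables per group, pairwise overlaps, per-peptide rankings.

    ``tables`` may be supplied directly (e.g. synthetic); otherwise they are
    loaded from ``config.clonotype_csvs``.
    """
    _setup_logging(config)
    stage = "config"
    try:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs: list[str] = []

        stage = "load"
        if tables is None:
            if config.synthetic:
                tables = mock_clonotype_tables(config.synthetic_spec())
                for t in tables:
                    path = out_dir / f"clonotypes_{t.group}.csv"
                    write_clonotypes_csv(t, path)
                    outputs.append(path.name)
            elif config.clonotype_csvs:
                tables = [load_clonotypes(path, group)
                          for group, path in config.clonotype_csvs]
            else:
                raise PipelineError("config", "no clonotype tables supplied")
        logger.info("[load] %d clonotype group(s)", len(tables))

        stage = "frequencies"
        freq_results = {}
        for t in tables:
            freqs = clonotype_frequencies(t)
            subset, cell_share, clone_share = top_clonotypes(
                t, config.clonotype_min_count, config.clonotype_top_n)
            freq_results[t.group] = (freqs, subset, cell_share, clone_share)
            path = out_dir / f"frequencies_{t.group}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# group={t.group} total_cells={t.total_cells}\n")
                fh.write(f"# top clonotypes (count>={config.clonotype_min_count}, "
                         f"n<={config.clonotype_top_n}): {len(subset)} clonotypes, "
                         f"{cell_share:.1f}% of cells, "
                         f"{clone_share:.1f}% of clonotypes\n")
                fh.write("key\tcount\tfreq_pct\tfreq_display\n")
                for rec in sorted(t.records, key=lambda r: (-r.count, r.key)):
                    f_pct, disp = freqs[rec.key]
                    fh.write(f"{rec.key}\t{rec.count}\t{f_pct:.6f}\t{disp}\n")
            outputs.append(path.name)

        stage = "overlap"
        overlaps = {}
        for a, b in combinations(tables, 2):
            ov = group_overlap(a, b)
            overlaps[(a.group, b.group)] = ov
            path = out_dir / f"overlap_{a.group}_vs_{b.group}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# jaccard={ov.jaccard:.6f} shared={len(ov.shared)} "
                         f"unique_{a.group}={len(ov.unique_to_a)} "
                         f"unique_{b.group}={len(ov.unique_to_b)}\n")
                fh.write("key\tstatus\n")
                for key in sorted(ov.shared):
                    fh.write(f"{key}\tshared\n")
                for key in sorted(ov.unique_to_a):
                    fh.write(f"{key}\tunique_{a.group}\n")
                for key in sorted(ov.unique_to_b):
                    fh.write(f"{key}\tunique_{b.group}\n")
            outputs.append(path.name)

        stage = "ranking"
        rankings = {}
        if config.peptides:
            target = tables[0]
            for idx, pep in enumerate(config.peptides, start=1):
                ranking = rank_clonotypes_for_peptide(
                    target, pep, toy_tcr_peptide_score, config.rank_top)
                rankings[pep] = ranking
                path = out_dir / f"ranking_peptide_{idx}.tsv"
                with open(path, "w") as fh:
                    fh.write(f"# peptide={pep} group={target.group}\n")
                    fh.write("key\tscore\tcount\tfreq_pct\tfreq_display\n")
                    for r in ranking.ranked:
                        fh.write(f"{r.key}\t{r.score:.6f}\t{r.count}\t"
                                 f"{r.freq_pct:.6f}\t"
                                 f"{clonotype_frequencies(target)[r.key][1]}\n")
                outputs.append(path.name)

        stage = "manifest"
        _manifest(config, outputs + ["clonotype_manifest.json"], out_dir,
                  name="clonotype_manifest.json")
        logger.info("[manifest] wrote %d artifacts to %s", len(outputs) + 1, out_dir)
        return {"tables": tables, "frequencies": freq_results,
                "overlaps": overlaps, "rankings": rankings}
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("[%s] failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc


def run_all(config: PipelineConfig) -> dict:
    """Epitope pipeline followed by the clonotype report (shared out_dir/seed)."""
    results = run_epitope_pipeline(config)
    if config.synthetic or config.clonotype_csvs:
        results["clonotypes"] = run_clonotype_report(config)
    return results
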