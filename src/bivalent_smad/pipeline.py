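"""End-to-end orchestration: tracks -> peaks -> gene states -> expression ->
enrichment -> candidate genes.

The default thresholds are the analysis' published cutoffs: Smad2/3 and
H3K4me3 peaks at signal ratio >= 8, H3K27me3 at >= 5, marks scored within
+/- 1 kb of the TSS, Smad2/3 targets from 10 kb upstream to the end of the
first intron, probes kept above intensity 70, up/down categories at
2-fold / 0.5-fold. A candidate gene is, by default, a Smad2/3 target whose
promoter resolves from bivalent (K4+K27+) to K4-only under TGF-beta; the
optional expression criteria additionally require TGF-beta-up at 24 h and
RANKL-down at any (or all) of 24/48/72 h.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_io import (Annotation, ReadSet, read_annotation, read_samples,
                        write_bed, write_bedgraph)
from .peak_calling import (bin_reads, call_peaks, ratio_track,
                           tss_metaprofile, write_metaprofile_tsv)
from .chromatin_state import (GeneStateTable, RESOLVED_BIVALENT,
                              classify_transitions, mark_status,
                              smad_target_genes, write_gene_set_tsv)
from .expression_analysis import (ExpressionMatrix, FoldChangeTable,
                                  filter_expressed, fold_change,
                                  normalize_mean100, ranked_list)
from .enrichment_stats import (ZeroMarginError, contingency, gsea_es,
                               gsea_permutation_p, write_running_sum_tsv)

log = logging.getLogger("bivalent_smad")


class ConfigurationError(ValueError):
    pass


REQUIRED_SAMPLES = (
    ("Smad2/3", "TGFb_plus"),
    ("H3K4me3", "TGFb_minus"),
    ("H3K4me3", "TGFb_plus"),
    ("H3K27me3", "TGFb_minus"),
    ("H3K27me3", "TGFb_plus"),
)


@dataclass
class PipelineConfig:
    """All knobs of the analysis; defaults are the published cutoffs."""

    # input paths (optional when running from in-memory objects)
    annotation: str | None = None
    sample_sheet: str | None = None
    tgfb_expression: str | None = None
    rankl_expression: str | None = None
    outdir: str | None = None

    # peak calling
    bin_size: int = 100
    pseudocount: float = 1.0
    merge_gap: int = 200
    min_width: int = 100
    smad_ratio: float = 8.0
    k4_ratio: float = 8.0
    k27_ratio: float = 5.0
    use_input_control: bool = False

    # gene assignment
    upstream: int = 10_000
    tss_flank: int = 1_000
    window_end: str = "intron_end"

    # expression
    expr_floor: float = 70.0
    up_fold: float = 2.0
    down_fold: float = 0.5
    epsilon: float = 1.0
    rank_tgfb_at: float = 24.0
    rank_rankl_at: float = 72.0

    # candidate criteria
    use_tgfb_up: bool = False
    use_rankl_down: bool = False
    rankl_down_mode: str = "any"  # or "all"
    rankl_down_times: tuple[float, ...] = (24.0, 48.0, 72.0)

    # enrichment
    gsea_weight: float = 1.0
    gsea_nperm: int = 1000

    # misc
    metaprofile_flank: int = 2_000
    write_tracks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_size", "merge_gap", "min_width", "smad_ratio",
                     "k4_ratio", "k27_ratio", "upstream", "tss_flank",
                     "expr_floor", "up_fold", "down_fold", "epsilon",
                     "gsea_nperm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.rankl_down_mode not in ("any", "all"):
            raise ConfigurationError(
                f"rankl_down_mode must be 'any' or 'all', "
                f"got {self.rankl_down_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rankl_down_times" in raw:
            raw["rankl_down_times"] = tuple(
                float(t) for t in raw["rankl_down_times"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["rankl_down_times"] = list(self.rankl_down_times)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def sha256(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis rerun elsewhere hashes identically)."""
        raw = asdict(self)
        for key in ("annotation", "sample_sheet", "tgfb_expression",
                    "rankl_expression", "outdir"):
            raw.pop(key)
        raw["rankl_down_times"] = list(self.rankl_down_times)
        blob = json.dumps(raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CandidateReport:
    """Final candidate genes with per-gene evidence and stage counts."""

    candidates: tuple[str, ...]
    evidence: pd.DataFrame
    stage_counts: dict
    enrichment: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "candidates": list(self.candidates),
            "stage_counts": self.stage_counts,
            "enrichment": self.enrichment,
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(outdir / "candidates.tsv", "w") as fh:
            fh.write("gene_id\n")
            for gid in self.candidates:
                fh.write(f"{gid}\n")
        ev = self.evidence.copy()
        ev.index.name = "gene_id"
        ev.sort_index().to_csv(outdir / "evidence.tsv", sep="\t",
                               float_format="%.6g")


def select_candidates(states: GeneStateTable, smad_targets: set[str],
                      tgfb_folds: FoldChangeTable | None = None,
                      rankl_folds: FoldChangeTable | None = None,
                      *, use_tgfb_up: bool = False,
                      use_rankl_down: bool = False,
                      rankl_down_mode: str = "any",
                      rankl_down_times: tuple[float, ...] = (24.0, 48.0, 72.0),
                      tgfb_at: float = 24.0,
                      up_fold: float = 2.0, down_fold: float = 0.5,
                      config: PipelineConfig | None = None,
                      stage_counts: dict | None = None,
                      enrichment: dict | None = None) -> CandidateReport:
    """Intersect the evidence axes into the candidate gene set.

    Default criteria: Smad2/3 target AND bivalent->K4-only transition.
    Optional: TGF-beta ratio > ``up_fold`` at ``tgfb_at``; RANKL ratio <
    ``down_fold`` at any/all of ``rankl_down_times`` (gene-level ratios via
    the highest-mean-intensity probe; genes without a kept probe fail an
    active expression criterion).
    """
    universe = list(states.table.index)
    if not universe:
        raise ConfigurationError("empty gene universe")
    ev = pd.DataFrame(index=pd.Index(sorted(universe), name="gene_id"))
    ev["is_smad_target"] = [g in smad_targets for g in ev.index]
    ev["transition"] = states.table["transition"].reindex(ev.index)
    ev["resolved_bivalent"] = ev["transition"] == RESOLVED_BIVALENT
    selected = ev["is_smad_target"] & ev["resolved_bivalent"]

    if tgfb_folds is not None:
        ratios = tgfb_folds.gene_ratios(tgfb_at).reindex(ev.index)
        ev[f"tgfb_ratio_{tgfb_at:g}h"] = ratios
        ev["tgfb_up"] = ratios > up_fold
        if use_tgfb_up:
            selected &= ev["tgfb_up"].fillna(False)
    elif use_tgfb_up:
        raise ConfigurationError("use_tgfb_up requires TGFb fold changes")

    if rankl_folds is not None:
        down_cols = []
        for t in rankl_down_times:
            r = rankl_folds.gene_ratios(t).reindex(ev.index)
            ev[f"rankl_ratio_{t:g}h"] = r
            down_cols.append(r < down_fold)
        down = pd.concat(down_cols, axis=1)
        ev["rankl_down"] = (down.any(axis=1) if rankl_down_mode == "any"
                            else down.all(axis=1))
        if use_rankl_down:
            selected &= ev["rankl_down"]
    elif use_rankl_down:
        raise ConfigurationError("use_rankl_down requires RANKL fold changes")

    ev["candidate"] = selected
    candidates = tuple(sorted(ev.index[selected]))
    counts = dict(stage_counts or {})
    counts["n_candidates"] = len(candidates)
    provenance = {
        "tool": "bivalent-smad",
        "version": __version__,
        "seed": config.seed if config else None,
        "config_sha256": config.sha256() if config else None,
    }
    return CandidateReport(candidates=candidates, evidence=ev,
                           stage_counts=counts,
                           enrichment=dict(enrichment or {}),
                           provenance=provenance)


def _call_sample_peaks(readset: ReadSet, annotation: Annotation,
                       config: PipelineConfig,
                       control: ReadSet | None = None):
    track = bin_reads(readset, annotation.chrom_sizes, config.bin_size)
    ctrack = (bin_reads(control, annotation.chrom_sizes, config.bin_size)
              if control is not None else None)
    ratios = ratio_track(track, ctrack, pseudocount=config.pseudocount)
    threshold = {"Smad2/3": config.smad_ratio,
                 "H3K4me3": config.k4_ratio,
                 "H3K27me3": config.k27_ratio}[readset.antibody]
    peaks = call_peaks(ratios, threshold, merge_gap=config.merge_gap,
                       min_width=config.min_width,
                       chrom_sizes=annotation.chrom_sizes)
    return track, peaks


def run_from_objects(annotation: Annotation,
                     readsets: dict[tuple[str, str], ReadSet],
                     tgfb_matrix: ExpressionMatrix | None,
                     rankl_matrix: ExpressionMatrix | None,
                     config: PipelineConfig | None = None
                     ) -> CandidateReport:
    """Run the full analysis on in-memory inputs; see module docstring."""
    config = config or PipelineConfig()
    missing = [key for key in REQUIRED_SAMPLES if key not in readsets]
    if missing:
        raise ConfigurationError(
            "missing required samples (antibody, condition): "
            + ", ".join(map(str, missing)))

    controls = {cond: readsets.get(("input", cond))
                for cond in ("TGFb_plus", "TGFb_minus")}

    tracks, peaks = {}, {}
    for key in REQUIRED_SAMPLES:
        control = controls[key[1]] if config.use_input_control else None
        if config.use_input_control and control is None:
            raise ConfigurationError(
                f"use_input_control set but no input sample for {key[1]}")
        tracks[key], peaks[key] = _call_sample_peaks(
            readsets[key], annotation, config, control)
        log.info("peaks[%s/%s]: %d", key[0], key[1], len(peaks[key]))

    targets = smad_target_genes(peaks[("Smad2/3", "TGFb_plus")], annotation,
                                upstream=config.upstream,
                                window_end=config.window_end)
    log.info("Smad2/3 target genes: %d / %d", len(targets), len(annotation))

    marks = {
        key: mark_status(peaks[key], annotation, flank=config.tss_flank)
        for key in REQUIRED_SAMPLES if key[0] != "Smad2/3"
    }
    states = classify_transitions(
        marks[("H3K4me3", "TGFb_minus")], marks[("H3K27me3", "TGFb_minus")],
        marks[("H3K4me3", "TGFb_plus")], marks[("H3K27me3", "TGFb_plus")],
    )
    resolved = states.genes_with(RESOLVED_BIVALENT)
    log.info("bivalent->K4-only genes: %d", len(resolved))

    stage_counts = {
        "n_genes": len(annotation),
        "n_sbr_peaks": len(peaks[("Smad2/3", "TGFb_plus")]),
        "n_smad_targets": len(targets),
        "n_k4_plus_minus_tgfb": sum(marks[("H3K4me3", "TGFb_minus")].values()),
        "n_k4_plus_plus_tgfb": sum(marks[("H3K4me3", "TGFb_plus")].values()),
        "n_k27_plus_minus_tgfb": sum(
            marks[("H3K27me3", "TGFb_minus")].values()),
        "n_k27_plus_plus_tgfb": sum(marks[("H3K27me3", "TGFb_plus")].values()),
        "n_resolved_bivalent": len(resolved),
    }

    enrichment: dict = {}
    universe = set(annotation.genes)
    try:
        enrichment["targets_vs_resolved_bivalent"] = contingency(
            targets, resolved, universe).to_dict()
    except (ZeroMarginError, ValueError) as exc:
        enrichment["targets_vs_resolved_bivalent"] = {"error": str(exc)}

    folds: dict[str, FoldChangeTable | None] = {"TGFb": None, "RANKL": None}
    ranked: dict[str, pd.DataFrame] = {}
    for stim, matrix, rank_at in (
            ("TGFb", tgfb_matrix, config.rank_tgfb_at),
            ("RANKL", rankl_matrix, config.rank_rankl_at)):
        if matrix is None:
            continue
        normed = matrix if matrix.normalized else normalize_mean100(matrix)
        kept = filter_expressed(normed, floor=config.expr_floor)
        log.info("%s expression: kept %d probes (%d genes)", stim,
                 kept.n_probes, kept.n_genes)
        stage_counts[f"n_probes_kept_{stim.lower()}"] = kept.n_probes
        stage_counts[f"n_genes_kept_{stim.lower()}"] = kept.n_genes
        table = fold_change(kept.matrix, epsilon=config.epsilon,
                            up_fold=config.up_fold,
                            down_fold=config.down_fold)
        folds[stim] = table
        ranked[stim] = ranked_list(table, at=rank_at, level="gene")

        cats = table.gene_categories(rank_at)
        expr_universe = set(cats.index)
        set_in_universe = targets & expr_universe
        for direction, label in (("up", "up"), ("down", "down")):
            category = set(cats.index[cats == label])
            try:
                enrichment[f"targets_vs_{stim.lower()}_{direction}"] = \
                    contingency(set_in_universe, category,
                                expr_universe).to_dict()
            except (ZeroMarginError, ValueError) as exc:
                enrichment[f"targets_vs_{stim.lower()}_{direction}"] = {
                    "error": str(exc)}
        if set_in_universe and set_in_universe != expr_universe:
            gres = gsea_permutation_p(
                ranked[stim], set_in_universe, n_perm=config.gsea_nperm,
                seed=config.seed, weight=config.gsea_weight)
            enrichment[f"gsea_targets_{stim.lower()}"] = gres.to_dict()
            log.info("GSEA %s: ES=%.3f p=%.4g", stim, gres.es, gres.p_perm)

    report = select_candidates(
        states, targets, folds["TGFb"], folds["RANKL"],
        use_tgfb_up=config.use_tgfb_up,
        use_rankl_down=config.use_rankl_down,
        rankl_down_mode=config.rankl_down_mode,
        rankl_down_times=config.rankl_down_times,
        tgfb_at=config.rank_tgfb_at,
        up_fold=config.up_fold, down_fold=config.down_fold,
        config=config, stage_counts=stage_counts, enrichment=enrichment)
    log.info("candidate genes: %d", len(report.candidates))

    if config.outdir:
        _write_outputs(Path(config.outdir), config, annotation, tracks,
                       peaks, targets, states, folds, ranked, report)
    return report


def _write_outputs(outdir, config, annotation, tracks, peaks, targets,
                   states, folds, ranked, report) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "metaprofiles").mkdir(exist_ok=True)
    if config.write_tracks:
        (outdir / "tracks").mkdir(exist_ok=True)
    target_genes = [annotation.genes[g] for g in sorted(targets)]
    for key, pk in peaks.items():
        stem = f"{key[0].replace('/', '_')}_{key[1]}"
        write_bed(pk, outdir / "peaks" / f"{stem}.bed")
        if config.write_tracks:
            write_bedgraph(tracks[key],
                           outdir / "tracks" / f"{stem}.bedGraph")
        profile_genes = target_genes or annotation.sorted_genes()
        try:
            profile = tss_metaprofile(tracks[key], profile_genes,
                                      flank=config.metaprofile_flank)
            write_metaprofile_tsv(
                profile, outdir / "metaprofiles" / f"{stem}.tsv")
        except ValueError:
            pass
    write_gene_set_tsv(targets, outdir / "smad_targets.tsv")
    states.to_tsv(outdir / "gene_states.tsv")
    for stim, table in folds.items():
        if table is not None:
            table.to_tsv(outdir / f"fold_changes_{stim.lower()}.tsv")
            ranked[stim].to_csv(outdir / f"ranked_{stim.lower()}.tsv",
                                sep="\t", index=False, float_format="%.6g")
    report.write(outdir)


def run_full(config: PipelineConfig) -> CandidateReport:
    """File-driven entry point: read everything named in the config,
    run the analysis, write reports into ``config.outdir``."""
    if not config.annotation or not config.sample_sheet:
        raise ConfigurationError(
            "config must name an annotation and a sample sheet")
    annotation = read_annotation(config.annotation)
    readsets = read_samples(config.sample_sheet)
    tgfb = (ExpressionMatrix.from_tsv(config.tgfb_expression)
            if config.tgfb_expression else None)
    rankl = (ExpressionMatrix.from_tsv(config.rankl_expression)
             if config.rankl_expression else None)
    return run_from_objects(annotation, readsets, tgfb, rankl, config)
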