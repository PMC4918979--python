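"""Synthetic toy genome, planted ChIP enrichment, and expression matrices.

The generator plants a known truth -- which genes are Smad2/3 targets,
their promoter chromatin state before and after TGF-beta, and their
TGF-beta / RANKL expression responses -- and then realises it as BED read
sets (Poisson background plus planted enrichment) and probe x timepoint
intensity matrices, so the whole downstream pipeline can be exercised and
scored against the planted truth without any external data.

Truth classes (one per gene):

==================  ======  ==============  =============  =====  =========
class               Smad    state(TGFb-)    state(TGFb+)   TGFb   RANKL 72h
==================  ======  ==============  =============  =====  =========
nedd9_like          yes     K4+K27+         K4+K27-        3.0x   0.3x
target_stable_biv   yes     K4+K27+         K4+K27+        1.0x   1.0x
target_active       yes     K4+K27-         K4+K27-        2.5x   0.4x
nontarget_resolving no      K4+K27+         K4+K27-        1.0x   1.0x
nontarget_active    no      K4+K27-         K4+K27-        1.0x   2.6x
nontarget_silent    no      K4-K27+         K4-K27+        1.0x   1.0x
background          no      K4-K27-         K4-K27-        1.0x   1.0x
==================  ======  ==============  =============  =====  =========

"nedd9_like" is the canonical planted positive: a Smad2/3 target whose
bivalent promoter resolves to K4-only under TGF-beta, whose expression is
TGF-beta-up (> 2-fold) and RANKL-down (< 0.5-fold by 72 h).

Every random draw comes from an RNG stream derived from the master seed by
stable hashing of a (module, sample) label, so adding samples never
perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_io import (Annotation, GeneModel, GenomicInterval, ReadSet,
                        ValidationError, write_annotation, write_reads_bed)

RANKL_TIMEPOINTS = (0.0, 3.0, 12.0, 24.0, 48.0, 72.0)
TGFB_TIMEPOINTS = (0.0, 24.0)

# fraction of sequenced reads that map; matches the reported library summary
MAPPED_FRACTION = 0.717


class CapacityError(ValidationError):
    """Genes cannot be placed without overlap at the requested density."""


@dataclass(frozen=True)
class TruthClass:
    is_smad_target: bool
    state_before: tuple[bool, bool]  # (K4, K27)
    state_after: tuple[bool, bool]
    tgfb_effect: float
    rankl_profile: tuple[float, ...]  # aligned to RANKL_TIMEPOINTS


CLASS_SPECS: dict[str, TruthClass] = {
    "nedd9_like": TruthClass(True, (True, True), (True, False), 3.0,
                             (1.0, 0.9, 0.7, 0.45, 0.35, 0.3)),
    "target_stable_bivalent": TruthClass(True, (True, True), (True, True),
                                         1.0, (1.0,) * 6),
    "target_active": TruthClass(True, (True, False), (True, False), 2.5,
                                (1.0, 0.95, 0.8, 0.6, 0.45, 0.4)),
    "nontarget_resolving": TruthClass(False, (True, True), (True, False),
                                      1.0, (1.0,) * 6),
    "nontarget_active": TruthClass(False, (True, False), (True, False), 1.0,
                                   (1.0, 1.1, 1.4, 1.9, 2.3, 2.6)),
    "nontarget_silent": TruthClass(False, (False, True), (False, True), 1.0,
                                   (1.0,) * 6),
    "background": TruthClass(False, (False, False), (False, False), 1.0,
                             (1.0,) * 6),
}

DEFAULT_CLASS_FRACTIONS = {
    "nedd9_like": 0.10,
    "target_stable_bivalent": 0.15,
    "target_active": 0.15,
    "nontarget_resolving": 0.05,
    "nontarget_active": 0.20,
    "nontarget_silent": 0.15,
    "background": 0.20,
}


@dataclass
class SimConfig:
    """Generator parameters; the defaults define the simulated study.

    ``background_density`` is in reads per bp; ``enrichment_fold`` is the
    in-peak density relative to background. ``min_intergenic_gap`` keeps
    neighbouring target windows (10 kb upstream) from overlapping planted
    promoter peaks at default geometry.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_200_000
    n_genes: int = 100
    background_density: float = 0.05
    enrichment_fold: float = 10.0
    read_length: int = 50
    peak_width: int = 1_000
    n_probes_per_gene: int = 2
    expr_noise_sigma: float = 0.25
    low_expression_fraction: float = 0.15
    min_intergenic_gap: int = 11_000
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))

    def __post_init__(self) -> None:
        for name, val in (("n_chroms", self.n_chroms),
                          ("chrom_len", self.chrom_len),
                          ("n_genes", self.n_genes),
                          ("read_length", self.read_length),
                          ("peak_width", self.peak_width),
                          ("n_probes_per_gene", self.n_probes_per_gene)):
            if val < 0 or (name != "n_genes" and val == 0):
                raise ValidationError(f"{name} must be positive")
        if self.background_density <= 0 or self.enrichment_fold < 1:
            raise ValidationError(
                "background_density must be > 0 and enrichment_fold >= 1")
        unknown = set(self.class_fractions) - set(CLASS_SPECS)
        if unknown:
            raise ValidationError(f"unknown truth classes: {sorted(unknown)}")
        if sum(self.class_fractions.values()) > 1 + 1e-9:
            raise ValidationError("class fractions must sum to <= 1")


@dataclass
class GeneTruth:
    gene_id: str
    truth_class: str
    is_smad_target: bool
    state_before: tuple[bool, bool]
    state_after: tuple[bool, bool]
    tgfb_effect: float
    rankl_profile: dict[float, float]
    planted_peaks: list[tuple[str, str, GenomicInterval, float]]


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth]

    @property
    def smad_targets(self) -> set[str]:
        return {g for g, t in self.genes.items() if t.is_smad_target}

    def genes_of_class(self, name: str) -> set[str]:
        return {g for g, t in self.genes.items() if t.truth_class == name}

    @property
    def nedd9_like(self) -> set[str]:
        return self.genes_of_class("nedd9_like")

    def planted_intervals(self, antibody: str, condition: str
                          ) -> list[GenomicInterval]:
        out = []
        for gid in sorted(self.genes):
            for ab, cond, iv, _fold in self.genes[gid].planted_peaks:
                if ab == antibody and cond == condition:
                    out.append(iv)
        return out

    def to_json(self, path) -> None:
        payload = {}
        for gid in sorted(self.genes):
            t = self.genes[gid]
            payload[gid] = {
                "truth_class": t.truth_class,
                "is_smad_target": t.is_smad_target,
                "state_before": list(t.state_before),
                "state_after": list(t.state_after),
                "tgfb_effect": t.tgfb_effect,
                "rankl_profile": {format(k, "g"): v
                                  for k, v in t.rankl_profile.items()},
                "planted_peaks": [
                    [ab, cond, iv.chrom, iv.start, iv.end, fold]
                    for ab, cond, iv, fold in t.planted_peaks
                ],
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        genes = {}
        for gid, rec in payload.items():
            genes[gid] = GeneTruth(
                gene_id=gid,
                truth_class=rec["truth_class"],
                is_smad_target=rec["is_smad_target"],
                state_before=tuple(rec["state_before"]),
                state_after=tuple(rec["state_after"]),
                tgfb_effect=rec["tgfb_effect"],
                rankl_profile={float(k): v
                               for k, v in rec["rankl_profile"].items()},
                planted_peaks=[
                    (ab, cond, GenomicInterval(chrom, s, e), fold)
                    for ab, cond, chrom, s, e, fold in rec["planted_peaks"]
                ],
            )
        return cls(genes)


def derive_seed(master: int, *labels: str) -> int:
    """Stable sub-seed from the master seed and a stream label."""
    key = f"{master}|" + "|".join(labels)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# annotation + truth


def _make_exons(rng: np.random.Generator, chrom: str, start: int,
                length: int, strand: str) -> tuple[GenomicInterval, ...]:
    min_exon, min_intron = 100, 200
    max_k = min(5, 1 + (length - min_exon) // (min_exon + min_intron))
    k = int(rng.integers(2, max(3, max_k + 1)))
    k = min(k, max_k)
    slack = length - k * min_exon - (k - 1) * min_intron
    w = rng.random(2 * k - 1)
    extra = np.floor(slack * w / w.sum()).astype(int)
    lens = []
    for i in range(2 * k - 1):
        base = min_exon if i % 2 == 0 else min_intron
        lens.append(base + int(extra[i]))
    # pad the last exon so pieces sum exactly to the gene length
    lens[-1] += length - sum(lens)
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        if i % 2 == 0:
            exons.append(GenomicInterval(chrom, pos, pos + ln, strand))
        pos += ln
    return tuple(exons)


def simulate_annotation(config: SimConfig
                        ) -> tuple[Annotation, TruthTable]:
    """Toy genome: non-overlapping genes with 2-5 exons on both strands,
    each assigned a truth class with planted peaks at its promoter."""
    rng = np.random.default_rng(derive_seed(config.seed, "annotation"))
    chrom_sizes = {f"chr{i + 1}": config.chrom_len
                   for i in range(config.n_chroms)}
    chroms = sorted(chrom_sizes)

    per_chrom = [config.n_genes // config.n_chroms +
                 (1 if i < config.n_genes % config.n_chroms else 0)
                 for i in range(config.n_chroms)]

    genes: dict[str, GeneModel] = {}
    idx = 0
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        lens = rng.integers(1500, 4001, size=n_c)
        gap = config.min_intergenic_gap
        needed = int(lens.sum()) + (n_c + 1) * gap
        if needed > config.chrom_len:
            raise CapacityError(
                f"cannot place {n_c} genes on {chrom}: need {needed} bp "
                f"with min gap {gap}, have {config.chrom_len}"
            )
        leftover = config.chrom_len - needed
        w = rng.random(n_c + 1)
        extras = np.floor(leftover * w / w.sum()).astype(int)
        pos = 0
        for j in range(n_c):
            pos += gap + int(extras[j])
            start = pos
            length = int(lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene_{idx:04d}"
            exons = _make_exons(rng, chrom, start, length, strand)
            genes[gid] = GeneModel(
                gid, GenomicInterval(chrom, start, start + length, strand),
                exons)
            pos = start + length
            idx += 1
    annotation = Annotation(genes, chrom_sizes)

    # assign truth classes
    gene_ids = sorted(genes)
    n = len(gene_ids)
    class_names = sorted(config.class_fractions)
    counts = {c: int(np.floor(config.class_fractions[c] * n))
              for c in class_names}
    assigned = sum(counts.values())
    counts["background"] = counts.get("background", 0) + (n - assigned)
    labels: list[str] = []
    for c in class_names:
        labels.extend([c] * counts[c])
    labels.extend(["background"] * (n - len(labels)))
    labels = list(np.array(labels, dtype=object)[rng.permutation(n)])

    truth_genes: dict[str, GeneTruth] = {}
    for gid, cls_name in zip(gene_ids, labels):
        cls_spec = CLASS_SPECS[cls_name]
        g = genes[gid]
        chrom_len = chrom_sizes[g.chrom]
        half = config.peak_width // 2
        promoter = GenomicInterval(
            g.chrom,
            max(0, g.tss - half),
            min(chrom_len, g.tss + config.peak_width - half),
        )
        # Smad2/3 binding is planted mostly upstream of the TSS so the
        # whole peak sits inside the target window even when the first
        # exon + intron are short (the window ends at the first intron,
        # which can lie < 500 bp into the gene body).
        offset = int(0.9 * config.peak_width)
        if g.strand == "+":
            s_start = max(0, g.tss - offset)
            smad_iv = GenomicInterval(
                g.chrom, s_start,
                min(chrom_len, s_start + config.peak_width))
        else:
            s_end = min(chrom_len, g.tss + offset + 1)
            smad_iv = GenomicInterval(
                g.chrom, max(0, s_end - config.peak_width), s_end)
        planted: list[tuple[str, str, GenomicInterval, float]] = []
        if cls_spec.is_smad_target:
            planted.append(("Smad2/3", "TGFb_plus", smad_iv,
                            config.enrichment_fold))
        for cond, (k4, k27) in (("TGFb_minus", cls_spec.state_before),
                                ("TGFb_plus", cls_spec.state_after)):
            if k4:
                planted.append(("H3K4me3", cond, promoter,
                                config.enrichment_fold))
            if k27:
                planted.append(("H3K27me3", cond, promoter,
                                config.enrichment_fold))
        truth_genes[gid] = GeneTruth(
            gene_id=gid,
            truth_class=cls_name,
            is_smad_target=cls_spec.is_smad_target,
            state_before=cls_spec.state_before,
            state_after=cls_spec.state_after,
            tgfb_effect=cls_spec.tgfb_effect,
            rankl_profile=dict(zip(RANKL_TIMEPOINTS, cls_spec.rankl_profile)),
            planted_peaks=planted,
        )
    return annotation, TruthTable(truth_genes)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(annotation: Annotation, truth: TruthTable,
                   antibody: str, condition: str,
                   config: SimConfig) -> ReadSet:
    """Poisson background plus planted enrichment for one library.

    Background reads fall uniformly at density ``background_density``; each
    planted peak of matching antibody/condition adds reads at
    ``(fold - 1) x background`` density inside its interval. The sequenced
    total is back-calculated so the mapped fraction is ~71.7%.
    """
    rng = np.random.default_rng(
        derive_seed(config.seed, "reads", antibody, condition))
    rl = config.read_length
    reads: list[GenomicInterval] = []
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        n_bg = rng.poisson(config.background_density * size)
        starts = rng.integers(0, max(1, size - rl), size=n_bg)
        reads.extend(
            GenomicInterval(chrom, int(s), int(s) + rl) for s in starts)

    matched = 0
    for gid in sorted(truth.genes):
        for ab, cond, iv, fold in truth.genes[gid].planted_peaks:
            if ab != antibody or cond != condition:
                continue
            matched += 1
            lam = (fold - 1.0) * config.background_density * iv.length
            n_extra = rng.poisson(lam)
            size = annotation.chrom_sizes[iv.chrom]
            mids = rng.integers(iv.start, iv.end, size=n_extra)
            for m in mids:
                s = int(np.clip(int(m) - rl // 2, 0, max(0, size - rl)))
                reads.append(GenomicInterval(iv.chrom, s, s + rl))
    if matched == 0 and antibody != "input":
        warnings.warn(
            f"no planted enrichment for ({antibody}, {condition}); "
            "returning background-only reads", stacklevel=2)

    mapped = len(reads)
    total = int(round(mapped / MAPPED_FRACTION)) if mapped else 0
    sample_id = f"{antibody.replace('/', '_')}_{condition}"
    return ReadSet(sample_id=sample_id, antibody=antibody,
                   condition=condition, reads=tuple(reads),
                   total_sequenced=max(total, mapped))


# ---------------------------------------------------------------------------
# expression


def simulate_expression(annotation: Annotation, truth: TruthTable,
                        config: SimConfig, stimulus: str):
    """Probe x timepoint AD-like intensities for one stimulus.

    Baselines are lognormal (a configurable fraction planted below the
    detection floor); TGFb has columns {0, 24 h} with the planted
    multiplicative effect at 24 h, RANKL the six-timepoint planted profile;
    multiplicative lognormal noise throughout.
    """
    from .expression_analysis import ExpressionMatrix

    if stimulus not in ("TGFb", "RANKL"):
        raise ValidationError(f"unknown stimulus {stimulus!r}")
    rng = np.random.default_rng(
        derive_seed(config.seed, "expression", stimulus))
    gene_ids = sorted(annotation.genes)
    probes, gene_of = [], []
    for gid in gene_ids:
        for j in range(config.n_probes_per_gene):
            probes.append(f"{gid}.p{j + 1}_at")
            gene_of.append(gid)
    n_probes = len(probes)

    low = rng.random(n_probes) < config.low_expression_fraction
    baseline = np.where(
        low,
        rng.lognormal(np.log(25.0), 0.5, n_probes),
        rng.lognormal(np.log(300.0), 0.7, n_probes),
    )

    times = TGFB_TIMEPOINTS if stimulus == "TGFb" else RANKL_TIMEPOINTS
    effect = np.ones((n_probes, len(times)))
    for i, gid in enumerate(gene_of):
        t = truth.genes[gid]
        if stimulus == "TGFb":
            effect[i, 1] = t.tgfb_effect
        else:
            effect[i] = [t.rankl_profile[tp] for tp in times]

    sigma = config.expr_noise_sigma
    if sigma > 0:
        noise = rng.lognormal(0.0, sigma, size=effect.shape)
    else:
        noise = 1.0
    values = baseline[:, None] * effect * noise
    df = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                      columns=[float(t) for t in times])
    mapping = pd.Series(gene_of, index=df.index, name="gene_id")
    return ExpressionMatrix(values=df, probe_to_gene=mapping,
                            normalized=False)


# ---------------------------------------------------------------------------
# whole datasets


CHIP_SAMPLES = (
    ("Smad2/3", "TGFb_plus"),
    ("H3K4me3", "TGFb_minus"),
    ("H3K4me3", "TGFb_plus"),
    ("H3K27me3", "TGFb_minus"),
    ("H3K27me3", "TGFb_plus"),
)


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: Annotation
    truth: TruthTable
    readsets: dict[tuple[str, str], ReadSet]
    tgfb: "object"
    rankl: "object"


def simulate_dataset(config: SimConfig,
                     outdir: str | Path | None = None) -> SimulatedDataset:
    """Generate annotation, all ChIP libraries and both expression
    matrices; optionally write them as a self-contained file bundle."""
    annotation, truth = simulate_annotation(config)
    readsets = {
        key: simulate_reads(annotation, truth, key[0], key[1], config)
        for key in CHIP_SAMPLES
    }
    tgfb = simulate_expression(annotation, truth, config, "TGFb")
    rankl = simulate_expression(annotation, truth, config, "RANKL")
    ds = SimulatedDataset(config, annotation, truth, readsets, tgfb, rankl)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation(annotation, outdir / "annotation.gff3")
        sheet = []
        for key in CHIP_SAMPLES:
            rs = readsets[key]
            bed = outdir / f"{rs.sample_id}.bed"
            write_reads_bed(rs, bed)
            sheet.append({
                "sample_id": rs.sample_id,
                "path": bed.name,
                "antibody": rs.antibody,
                "condition": rs.condition,
                "total_sequenced": rs.total_sequenced,
            })
        with open(outdir / "samples.yaml", "w") as fh:
            yaml.safe_dump(sheet, fh, sort_keys=False)
        tgfb.to_tsv(outdir / "expression_tgfb.tsv")
        rankl.to_tsv(outdir / "expression_rankl.tsv")
        truth.to_json(outdir / "truth.json")
    return ds
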