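"""Peak-to-gene assignment and chromatin-state transition classification.

Membership is always tested on the peak *summit*. A gene is a Smad2/3
target if a summit falls in the strand-oriented window from 10 kb upstream
of the TSS to the end of the first intron (gene end for intronless genes);
a gene is K4(+)/K27(+) under a condition if a summit of the corresponding
mark lies within +/- 1 kb of the TSS, bounds inclusive. Each gene's
chromatin state per condition is one of {K4+K27+, K4+K27-, K4-K27+,
K4-K27-}; the transition label pairs the TGFb_minus and TGFb_plus states,
and "K4+K27+->K4+K27-" is the bivalent-to-active resolution the candidate
filter keys on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import Annotation, GeneModel, GenomicInterval, ValidationError
from .peak_calling import Peak

DEFAULT_UPSTREAM = 10_000
DEFAULT_TSS_FLANK = 1_000

STATES = ("K4+K27+", "K4+K27-", "K4-K27+", "K4-K27-")
RESOLVED_BIVALENT = "K4+K27+->K4+K27-"


def state_label(k4: bool, k27: bool) -> str:
    return f"K4{'+' if k4 else '-'}K27{'+' if k27 else '-'}"


def target_window(gene: GeneModel, chrom_size: int,
                  upstream: int = DEFAULT_UPSTREAM,
                  window_end: str = "intron_end") -> GenomicInterval:
    """Strand-oriented target window, inclusive at both ends.

    '+' strand: [tss - upstream, end of first intron]; '-' strand mirrors
    (upstream = higher coordinates). ``window_end`` may be ``intron_end``
    (default) or ``intron_start``; intronless genes use the gene end.
    Clipped to [0, chrom_size).
    """
    if window_end not in ("intron_end", "intron_start"):
        raise ValidationError(f"unknown window_end mode {window_end!r}")
    intron = gene.first_intron
    if gene.strand == "+":
        lo = gene.tss - upstream
        if intron is None:
            hi = gene.interval.end - 1
        elif window_end == "intron_end":
            hi = intron.end - 1
        else:
            hi = intron.start
    else:
        hi = gene.tss + upstream
        if intron is None:
            lo = gene.interval.start
        elif window_end == "intron_end":
            lo = intron.start
        else:
            hi_pos = intron.end - 1
            lo = hi_pos
    lo = max(lo, 0)
    hi = min(hi, chrom_size - 1)
    # inclusive [lo, hi] -> half-open [lo, hi + 1)
    return GenomicInterval(gene.chrom, lo, hi + 1, gene.strand)


def smad_target_genes(peaks: Sequence[Peak], annotation: Annotation,
                      upstream: int = DEFAULT_UPSTREAM,
                      window_end: str = "intron_end") -> set[str]:
    """Genes with a peak summit inside their target window."""
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes.values():
        w = target_window(g, annotation.chrom_sizes[g.chrom],
                          upstream=upstream, window_end=window_end)
        trees.setdefault(g.chrom, IntervalTree()).addi(w.start, w.end,
                                                       g.gene_id)
    out: set[str] = set()
    for p in peaks:
        tree = trees.get(p.region.chrom)
        if tree is None:
            continue
        for hit in tree[p.summit]:
            out.add(hit.data)
    return out


def mark_status(peaks: Sequence[Peak], annotation: Annotation,
                flank: int = DEFAULT_TSS_FLANK) -> dict[str, bool]:
    """Per-gene flag: some peak summit within [tss - flank, tss + flank]."""
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes.values():
        lo = max(g.tss - flank, 0)
        hi = min(g.tss + flank, annotation.chrom_sizes[g.chrom] - 1)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g.gene_id)
    flagged: set[str] = set()
    for p in peaks:
        tree = trees.get(p.region.chrom)
        if tree is None:
            continue
        for hit in tree[p.summit]:
            flagged.add(hit.data)
    return {gid: gid in flagged for gid in annotation.genes}


@dataclass
class GeneStateTable:
    """Per-gene K4/K27 calls per condition plus the derived transition.

    ``table`` is indexed by gene_id with boolean columns ``k4_minus``,
    ``k27_minus``, ``k4_plus``, ``k27_plus`` and a string ``transition``.
    """

    table: pd.DataFrame

    def transition_counts(self) -> pd.Series:
        return self.table["transition"].value_counts().sort_index()

    def genes_with(self, transition: str) -> set[str]:
        mask = self.table["transition"] == transition
        return set(self.table.index[mask])

    def contingency_matrix(self) -> pd.DataFrame:
        """4x4 before x after state counts (margins = per-condition counts)."""
        before = self.table.apply(
            lambda r: state_label(r.k4_minus, r.k27_minus), axis=1)
        after = self.table.apply(
            lambda r: state_label(r.k4_plus, r.k27_plus), axis=1)
        mat = pd.crosstab(before, after)
        return mat.reindex(index=STATES, columns=STATES, fill_value=0)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.sort_index().to_csv(path, sep="\t")


def classify_transitions(k4_before: Mapping[str, bool],
                         k27_before: Mapping[str, bool],
                         k4_after: Mapping[str, bool],
                         k27_after: Mapping[str, bool]) -> GeneStateTable:
    """Label each gene with its (before, after) chromatin-state pair."""
    maps = {"k4_before": k4_before, "k27_before": k27_before,
            "k4_after": k4_after, "k27_after": k27_after}
    universe = set(k4_before)
    missing: dict[str, list[str]] = {}
    for name, m in maps.items():
        diff = sorted(universe.symmetric_difference(m))
        if diff:
            missing[name] = diff[:10]
    if missing:
        raise ValidationError(
            f"gene universe mismatch across state maps: {missing}"
        )
    rows = []
    for gid in sorted(universe):
        k4m, k27m = bool(k4_before[gid]), bool(k27_before[gid])
        k4p, k27p = bool(k4_after[gid]), bool(k27_after[gid])
        rows.append({
            "gene_id": gid,
            "k4_minus": k4m, "k27_minus": k27m,
            "k4_plus": k4p, "k27_plus": k27p,
            "transition": f"{state_label(k4m, k27m)}->{state_label(k4p, k27p)}",
        })
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneStateTable(table)


def write_gene_set_tsv(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for gid in sorted(genes):
            fh.write(f"{gid}\n")
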