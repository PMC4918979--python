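"""Microarray-style expression matrices: normalisation, filtering,
time-course fold changes and ranked gene lists.

Values emulate Affymetrix "average difference" (AD) intensities. Each array
(column) is scaled so its mean is exactly 100; probes are kept when some
timepoint exceeds the intensity floor (default 70, strict); fold changes are
taken against the 0 h column with a denominator floor epsilon to survive
near-zero baselines. "Up" means ratio > 2 and "down" ratio < 0.5, both
strict, per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import ValidationError

DEFAULT_FLOOR = 70.0
DEFAULT_EPSILON = 1.0
DEFAULT_UP_FOLD = 2.0
DEFAULT_DOWN_FOLD = 0.5


@dataclass
class ExpressionMatrix:
    """Probe x timepoint intensity matrix with a probe-to-gene map.

    ``values``: DataFrame indexed by probe_id, columns are hours (float,
    strictly increasing, starting at 0). ``probe_to_gene``: Series mapping
    every probe to exactly one gene_id.
    """

    values: pd.DataFrame
    probe_to_gene: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.columns = [float(c) for c in self.values.columns]
        cols = list(self.values.columns)
        if not cols or cols[0] != 0.0 or any(
                b <= a for a, b in zip(cols, cols[1:])):
            raise ValidationError(
                f"timepoints must be strictly increasing from 0, got {cols}"
            )
        if (self.values.values < 0).any():
            raise ValidationError("negative intensity values")
        missing = self.values.index.difference(self.probe_to_gene.index)
        if len(missing):
            raise ValidationError(
                f"probes without a gene mapping: {list(missing[:5])}"
            )
        self.probe_to_gene = self.probe_to_gene.loc[self.values.index]

    @property
    def timepoints(self) -> list[float]:
        return list(self.values.columns)

    @property
    def genes(self) -> set[str]:
        return set(self.probe_to_gene)

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False
                 ) -> "ExpressionMatrix":
        """Read a TSV: probe_id, gene_id, then one column per hour."""
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "probe_id" or df.columns[1] != "gene_id":
            raise ValidationError(
                f"{path}: first two columns must be probe_id, gene_id"
            )
        df = df.set_index("probe_id")
        mapping = df["gene_id"]
        values = df.drop(columns="gene_id")
        return cls(values=values, probe_to_gene=mapping,
                   normalized=normalized)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [format(c, "g") for c in out.columns]
        out.insert(0, "gene_id", self.probe_to_gene)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def normalize_mean100(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each array (column) so its mean AD value is exactly 100."""
    means = matrix.values.mean(axis=0)
    if (means <= 0).any():
        bad = [c for c, m in means.items() if m <= 0]
        raise ValidationError(f"all-zero array column(s): {bad}")
    values = matrix.values / means * 100.0
    return ExpressionMatrix(values=values,
                            probe_to_gene=matrix.probe_to_gene,
                            normalized=True)


@dataclass
class FilterResult:
    matrix: ExpressionMatrix
    n_probes: int
    n_genes: int
    kept_genes: set[str]


def filter_expressed(matrix: ExpressionMatrix,
                     floor: float = DEFAULT_FLOOR) -> FilterResult:
    """Keep probes whose maximum over timepoints strictly exceeds ``floor``.

    Kept genes are the image of kept probes under the probe-to-gene map.
    """
    if not matrix.normalized:
        raise ValidationError("filter_expressed requires a normalized matrix")
    keep = matrix.values.max(axis=1) > floor
    values = matrix.values.loc[keep]
    mapping = matrix.probe_to_gene.loc[keep]
    kept = ExpressionMatrix(values=values, probe_to_gene=mapping,
                            normalized=True)
    return FilterResult(matrix=kept, n_probes=int(keep.sum()),
                        n_genes=len(set(mapping)), kept_genes=set(mapping))


@dataclass
class FoldChangeTable:
    """Per-probe expression ratios against 0 h plus up/down categories."""

    ratios: pd.DataFrame
    probe_to_gene: pd.Series
    mean_intensity: pd.Series
    up_fold: float = DEFAULT_UP_FOLD
    down_fold: float = DEFAULT_DOWN_FOLD

    @property
    def timepoints(self) -> list[float]:
        return list(self.ratios.columns)

    def _check_timepoint(self, at: float) -> float:
        at = float(at)
        if at not in self.ratios.columns:
            raise ValidationError(
                f"timepoint {at} not in {list(self.ratios.columns)}"
            )
        return at

    def categories(self, at: float) -> pd.Series:
        """'up' (> up_fold), 'down' (< down_fold) or 'unchanged', strict."""
        at = self._check_timepoint(at)
        r = self.ratios[at]
        return pd.Series(
            np.where(r > self.up_fold, "up",
                     np.where(r < self.down_fold, "down", "unchanged")),
            index=r.index, name=f"category_{at:g}h",
        )

    def _collapse_probes(self) -> pd.Series:
        """Representative probe per gene: highest mean intensity, ties by id."""
        df = pd.DataFrame({
            "gene": self.probe_to_gene,
            "mean": self.mean_intensity,
        })
        df = df.reset_index().rename(columns={df.index.name or "index":
                                              "probe"})
        df.columns = ["probe", "gene", "mean"]
        df = df.sort_values(["gene", "mean", "probe"],
                            ascending=[True, False, True])
        return df.groupby("gene", sort=True)["probe"].first()

    def gene_ratios(self, at: float) -> pd.Series:
        """Gene-level ratio via the highest-mean-intensity probe."""
        at = self._check_timepoint(at)
        rep = self._collapse_probes()
        out = self.ratios[at].loc[rep.values]
        out.index = rep.index
        return out

    def gene_categories(self, at: float) -> pd.Series:
        at = self._check_timepoint(at)
        rep = self._collapse_probes()
        cats = self.categories(at).loc[rep.values]
        cats.index = rep.index
        return cats

    def to_tsv(self, path) -> None:
        out = self.ratios.copy()
        out.columns = [f"ratio_{c:g}h" for c in out.columns]
        out.insert(0, "gene_id", self.probe_to_gene)
        out.index.name = "probe_id"
        out.sort_index().to_csv(path, sep="\t", float_format="%.6g")


def fold_change(matrix: ExpressionMatrix,
                epsilon: float = DEFAULT_EPSILON,
                up_fold: float = DEFAULT_UP_FOLD,
                down_fold: float = DEFAULT_DOWN_FOLD) -> FoldChangeTable:
    """ratio(t) = max(value(t), eps) / max(value(0), eps) per probe."""
    if not matrix.normalized:
        raise ValidationError("fold_change requires a normalized matrix")
    v = matrix.values.clip(lower=epsilon)
    ratios = v.div(v[0.0], axis=0)
    return FoldChangeTable(
        ratios=ratios,
        probe_to_gene=matrix.probe_to_gene,
        mean_intensity=matrix.values.mean(axis=1),
        up_fold=up_fold, down_fold=down_fold,
    )


def ranked_list(table: FoldChangeTable, at: float,
                level: str = "probe") -> pd.DataFrame:
    """Identifiers sorted by descending ratio at ``at``; ties by identifier.

    ``level='gene'`` collapses to one probe per gene (highest mean
    intensity) before ranking. Returns a DataFrame with columns
    ``id`` and ``score``.
    """
    if level == "probe":
        scores = table.ratios[table._check_timepoint(at)]
    elif level == "gene":
        scores = table.gene_ratios(at)
    else:
        raise ValidationError(f"unknown level {level!r}")
    df = pd.DataFrame({"id": scores.index.astype(str),
                       "score": scores.values})
    df = df.sort_values(["score", "id"],
                        ascending=[False, True]).reset_index(drop=True)
    return df
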