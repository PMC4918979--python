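"""Gene-set enrichment statistics.

Two statistics drive the analysis: (1) 2x2 fold enrichment of a gene set
within a category, with a Pearson chi-square test (df = 1, no continuity
correction by default), and (2) the GSEA running enrichment score over a
ranked list, with a gene-set (label) permutation p-value. The label
permutation is the only scheme available to a one-array-per-timepoint
design; sample-label permutation would need replicates.

Cells of the 2x2 table: a = in-set & in-category, b = in-set & not,
c = category only, d = neither. Fold enrichment is the set's frequency
inside the category over its frequency in the universe:
``(a/(a+c)) / ((a+b)/N)`` -- symmetric under set/category exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000


class ZeroMarginError(ValueError):
    """Chi-square undefined because a table margin is zero.

    Carries ``fold_enrichment`` (may itself be NaN when undefined).
    """

    def __init__(self, msg: str, fold_enrichment: float):
        super().__init__(msg)
        self.fold_enrichment = fold_enrichment


@dataclass(frozen=True)
class ContingencyResult:
    a: int
    b: int
    c: int
    d: int
    fold_enrichment: float
    chi2: float
    p: float
    low_expected: bool
    yates: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {
            "cells": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "fold_enrichment": self.fold_enrichment,
            "chi2": self.chi2,
            "p": self.p,
            "low_expected": self.low_expected,
            "yates": self.yates,
        }


def contingency(set_members: Iterable[str], category_members: Iterable[str],
                universe: Iterable[str], yates: bool = False
                ) -> ContingencyResult:
    """2x2 fold enrichment and Pearson chi-square of set vs category."""
    uni = set(universe)
    s = set(set_members)
    cat = set(category_members)
    if not s <= uni or not cat <= uni:
        raise ValueError("set and category must be subsets of the universe")
    a = len(s & cat)
    b = len(s - cat)
    c = len(cat - s)
    d = len(uni) - a - b - c
    n = a + b + c + d

    if a + c > 0 and a + b > 0 and n > 0:
        fold = (a / (a + c)) / ((a + b) / n)
    else:
        fold = float("nan")

    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        raise ZeroMarginError(
            f"chi-square undefined: zero margin in table "
            f"a={a} b={b} c={c} d={d}", fold)
    det = a * d - b * c
    if yates:
        det = max(abs(det) - n / 2, 0)
    chi2 = n * det * det / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    expected = [
        margins[0] * margins[2] / n, margins[0] * margins[3] / n,
        margins[1] * margins[2] / n, margins[1] * margins[3] / n,
    ]
    return ContingencyResult(a=a, b=b, c=c, d=d, fold_enrichment=fold,
                             chi2=float(chi2), p=p,
                             low_expected=min(expected) < 5, yates=yates)


# ---------------------------------------------------------------------------
# GSEA


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray
    leading_edge: tuple[str, ...]
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "es": self.es,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "leading_edge_size": len(self.leading_edge),
        }


def _as_ranked(ranked) -> tuple[list[str], np.ndarray]:
    if isinstance(ranked, pd.DataFrame):
        ids = [str(x) for x in ranked.iloc[:, 0]]
        scores = np.asarray(ranked.iloc[:, 1], dtype=float)
    else:
        ids = [str(i) for i, _ in ranked]
        scores = np.asarray([s for _, s in ranked], dtype=float)
    if len(set(ids)) != len(ids):
        raise ValueError("ranked list contains duplicate identifiers")
    return ids, scores


def _validate_set(ids: Sequence[str], gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    hit = np.fromiter((i in members for i in ids), dtype=bool, count=len(ids))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == len(ids):
        raise ValueError("gene set covers the whole ranked list")
    return hit


def gsea_es(ranked, gene_set: Iterable[str],
            weight: float = DEFAULT_WEIGHT) -> GseaResult:
    """Running enrichment score over a ranked list.

    At a hit the sum rises by ``|score|**weight`` over the summed hit
    weights; at a miss it falls by ``1/(N - Nh)``. The enrichment score is
    the signed maximal absolute deviation; the leading edge holds the hits
    at or before (positive ES) / at or after (negative ES) the extremum.
    """
    ids, scores = _as_ranked(ranked)
    hit = _validate_set(ids, gene_set)
    n = len(ids)
    k = int(hit.sum())
    w = np.abs(scores) ** weight
    w_hits = np.where(hit, w, 0.0)
    total = w_hits.sum()
    if total == 0:  # all hit scores zero: fall back to unweighted steps
        w_hits = hit.astype(float)
        total = float(k)
    inc = np.where(hit, w_hits / total, -1.0 / (n - k))
    run = np.cumsum(inc)
    # signed extremum; the positive one is preferred on |.| ties
    if float(run.max() + run.min()) >= -1e-12:
        i = int(np.argmax(run))
    else:
        i = int(np.argmin(run))
    es = float(np.clip(run[i], -1.0, 1.0))
    if es >= 0:
        leading = tuple(ids[j] for j in range(i + 1) if hit[j])
    else:
        leading = tuple(ids[j] for j in range(i, n) if hit[j])
    return GseaResult(es=es, running_sum=run, leading_edge=leading)


def _perm_es(weights: np.ndarray, n: int, k: int,
             hits_sorted: np.ndarray) -> np.ndarray:
    """Signed extremum ES for each row of sorted hit positions.

    Along a run between hits the running sum falls linearly, so extrema can
    only occur immediately after a hit (maxima) or immediately before one
    (minima); evaluating those 2k candidates reproduces the full scan.
    """
    b, kk = hits_sorted.shape
    assert kk == k
    whit = weights[hits_sorted]
    total = whit.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        whit = whit.copy()
        whit[zero] = 1.0
        total = whit.sum(axis=1, keepdims=True)
    cum = np.cumsum(whit, axis=1) / total
    miss_before = (hits_sorted - np.arange(k)) / (n - k)
    after = cum - miss_before
    before = after - whit / total
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    # same tie rule as the streaming scan: positive extremum preferred
    return np.clip(np.where(hi + lo >= -1e-12, hi, lo), -1.0, 1.0)


def gsea_permutation_p(ranked, gene_set: Iterable[str],
                       n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                       weight: float = DEFAULT_WEIGHT) -> GseaResult:
    """Gene-set (label) permutation p-value for the enrichment score.

    ``p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1)`` with random same-size
    gene sets drawn over the ranked universe; deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = gsea_es(ranked, gene_set, weight=weight)
    ids, scores = _as_ranked(ranked)
    hit = _validate_set(ids, gene_set)
    n, k = len(ids), int(hit.sum())
    w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)
    u = rng.random((n_perm, n))
    hits = np.argpartition(u, k - 1, axis=1)[:, :k]
    hits.sort(axis=1)
    es_star = _perm_es(w, n, k, hits)
    exceed = int((np.abs(es_star) >= abs(obs.es)).sum())
    p = (1 + exceed) / (n_perm + 1)
    return GseaResult(es=obs.es, running_sum=obs.running_sum,
                      leading_edge=obs.leading_edge,
                      p_perm=p, n_perm=n_perm, seed=seed)


def write_running_sum_tsv(result: GseaResult, ranked, path) -> None:
    ids, scores = _as_ranked(ranked)
    with open(path, "w") as fh:
        fh.write("rank\tid\tscore\trunning_sum\n")
        for i, (gid, sc, rs) in enumerate(zip(ids, scores,
                                              result.running_sum), 1):
            fh.write(f"{i}\t{gid}\t{sc:.6g}\t{rs:.6g}\n")
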