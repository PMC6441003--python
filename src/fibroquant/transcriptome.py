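"""Fold-change/overlap transcriptome comparison on gene-level count tables.

The quantification pipeline has a fixed, enforced order:

    raw counts → RPM normalization → pseudocount → log / fold-change calls

RPM scaling uses 1e6 / raw column total; the pseudocount (default 0.05) is
added after RPM so the floor is comparable across libraries. Fold-change
calling is threshold-based (no distributional test): a gene is "up" when
treated/baseline ≥ threshold and "down" when baseline/treated ≥ threshold,
both boundaries inclusive. Set overlaps report every Venn segment plus a
shared percentage whose denominator is the union of the compared sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "GeneSetOverlap",
    "PCAResult",
    "add_pseudocount",
    "normalize_rpm",
    "call_fold_changes",
    "overlap_sets",
    "sample_correlation",
    "pca_samples",
]

DEFAULT_PSEUDOCOUNT = 0.05


@dataclass(frozen=True)
class ExpressionTable:
    """Gene-keyed abundance table with a one-way normalization state flag.

    ``values`` is a genes × samples DataFrame; ``sample_conditions`` maps each
    sample (column) name to its condition. ``normalization`` is "raw" or "rpm";
    ``pseudocounted`` records whether the floor constant has been added.
    """

    values: pd.DataFrame
    sample_conditions: dict[str, str]
    normalization: str = "raw"
    pseudocounted: bool = False

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        missing = set(self.values.columns) - set(self.sample_conditions)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("negative abundance values")

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.sample_conditions[s] == condition]
        if not out:
            raise ValueError(f"condition {condition!r} not present in table")
        return out

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.sample_conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        """Read the ``gene_id`` + ``<condition>_<rep>`` TSV dialect."""
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
        return cls(values=df, sample_conditions=conditions)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def normalize_rpm(table: ExpressionTable) -> ExpressionTable:
    """Scale every sample to reads-per-million using raw column totals."""
    if table.normalization != "raw":
        raise ValueError("table is already normalized")
    if table.pseudocounted:
        raise ValueError("RPM totals must be computed on raw counts, before pseudocount")
    totals = table.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero column total for sample(s): {list(zero.index)}")
    return replace(table, values=table.values * (1e6 / totals), normalization="rpm")


def add_pseudocount(table: ExpressionTable, c: float = DEFAULT_PSEUDOCOUNT) -> ExpressionTable:
    """Add a small floor constant to every value (guarded against reapplication)."""
    if table.pseudocounted:
        raise ValueError("pseudocount already applied")
    if c < 0:
        raise ValueError("pseudocount must be >= 0")
    return replace(table, values=table.values + c, pseudocounted=True)


def _condition_means(table: ExpressionTable, condition: str) -> pd.Series:
    return table.values[table.samples_for(condition)].mean(axis=1)


def call_fold_changes(
    table: ExpressionTable,
    baseline: str,
    treated: str,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene fold-change calls of ``treated`` against ``baseline``.

    Requires an RPM-normalized, pseudocounted table. Gene values are the
    arithmetic means over each condition's replicates. Returns a DataFrame
    indexed by gene with columns ``baseline_value``, ``treated_value``,
    ``log2fc`` and ``direction`` (up / down / unchanged); the fold threshold
    is inclusive in both directions.
    """
    if table.normalization != "rpm" or not table.pseudocounted:
        raise ValueError("fold-change calling requires an RPM-normalized, pseudocounted table")
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    base = _condition_means(table, baseline)
    trt = _condition_means(table, treated)
    fold = trt / base
    log2fc = np.log2(fold)
    direction = pd.Series("unchanged", index=table.values.index)
    direction[fold >= threshold] = "up"
    direction[1.0 / fold >= threshold] = "down"
    return pd.DataFrame(
        {
            "baseline_value": base,
            "treated_value": trt,
            "log2fc": log2fc,
            "direction": direction,
        }
    )


@dataclass(frozen=True)
class GeneSetOverlap:
    """Venn bookkeeping for 2–3 named identifier sets."""

    names: tuple[str, ...]
    sizes: dict[str, int]
    segment_counts: dict[frozenset, int]  # exclusive Venn segments
    intersection_all: int
    union: int
    shared_percent: float  # 100 · |∩ all| / |∪ all|

    def pairwise_intersection(self, a: str, b: str) -> int:
        """|A ∩ B| (not exclusive of a third set)."""
        return sum(
            n for seg, n in self.segment_counts.items() if a in seg and b in seg
        )


def overlap_sets(sets: dict[str, "set[str] | list[str]"]) -> GeneSetOverlap:
    """All Venn segment counts, union and shared percentage for 2 or 3 sets."""
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_sets takes 2 or 3 named sets")
    clean: dict[str, set] = {}
    for name, ids in sets.items():
        ids = list(ids)
        if len(ids) != len(set(ids)):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate identifiers in set {name!r}: {dupes[:5]}")
        clean[name] = set(ids)

    names = tuple(clean)
    union = set().union(*clean.values())
    inter_all = set.intersection(*clean.values())
    segments: dict[frozenset, int] = {}
    for element_membership in ({n for n in names if x in clean[n]} for x in union):
        key = frozenset(element_membership)
        segments[key] = segments.get(key, 0) + 1
    shared = 100.0 * len(inter_all) / len(union) if union else 0.0
    return GeneSetOverlap(
        names=names,
        sizes={n: len(s) for n, s in clean.items()},
        segment_counts=segments,
        intersection_all=len(inter_all),
        union=len(union),
        shared_percent=shared,
    )


def sample_correlation(table: ExpressionTable, sample_a: str, sample_b: str) -> float:
    """Pearson correlation of two samples on log2-transformed values.

    Requires a pseudocounted table so the log transform is finite.
    """
    if not table.pseudocounted:
        raise ValueError("log-scale correlation requires a pseudocounted table")
    for s in (sample_a, sample_b):
        if s not in table.values.columns:
            raise ValueError(f"sample {s!r} not in table")
    x = np.log2(table.values[sample_a].to_numpy())
    y = np.log2(table.values[sample_b].to_numpy())
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance sample: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples × components
    explained_pct: np.ndarray


def pca_samples(table: ExpressionTable) -> PCAResult:
    """PCA with samples as observations on gene-wise centred log2 values.

    The matrix is centred per gene (not scaled). Component signs follow a
    deterministic convention: the largest-magnitude gene loading of each
    component is positive.
    """
    if not table.pseudocounted:
        raise ValueError("PCA operates on log2 values; pseudocount the table first")
    samples = list(table.values.columns)
    if len(samples) < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = np.log2(table.values.to_numpy()).T  # samples × genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: flip components whose extreme loading is negative
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s**2
    explained = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    cols = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=samples, columns=cols),
        explained_pct=explained,
    )
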