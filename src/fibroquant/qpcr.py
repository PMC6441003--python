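"""Small-number statistics shared across the pipeline.

Relative qPCR quantification (multi-reference ΔΔCt), ChIP-qPCR percent-input
normalization, Welch's unequal-variance t-test and population doubling time.

The ΔΔCt convention used throughout: a gene whose abundance doubles amplifies
one cycle *earlier*, i.e. Ct drops by 1 per log2 unit of expression, and the
fold change between conditions is ``2**(-ΔΔCt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "DdctResult",
    "ChipMeasurement",
    "ddct_fold_change",
    "percent_input",
    "welch_t",
    "doubling_time",
]


@dataclass(frozen=True)
class CtRecord:
    """Replicate cycle-threshold measurements for one gene in one condition."""

    gene: str
    condition: str
    cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cts) < 1:
            raise ValueError(f"{self.gene}/{self.condition}: no Ct replicates")
        if any(ct <= 0 for ct in self.cts):
            raise ValueError(f"{self.gene}/{self.condition}: Ct values must be > 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.cts))

    @property
    def var_of_mean(self) -> float:
        """Variance of the replicate mean (sample variance / n); 0 for n=1."""
        n = len(self.cts)
        if n < 2:
            return 0.0
        return float(np.var(self.cts, ddof=1) / n)


@dataclass(frozen=True)
class DdctResult:
    gene: str
    fold_change: float
    sem: float
    ddct: float


@dataclass(frozen=True)
class ChipMeasurement:
    """One ChIP-qPCR locus: IP and input Cts plus the input chromatin fraction.

    ``input_fraction`` is the fraction of chromatin used as input relative to
    the amount used in the immunoprecipitation; it has no default because the
    dilution factor is experiment-specific.
    """

    locus: str
    ct_ip: float
    ct_input: float
    input_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ValueError(
                f"{self.locus}: input_fraction must be in (0, 1], got {self.input_fraction}"
            )


def _index_records(records: Iterable[CtRecord]) -> dict[tuple[str, str], CtRecord]:
    out: dict[tuple[str, str], CtRecord] = {}
    for rec in records:
        key = (rec.gene, rec.condition)
        if key in out:
            raise ValueError(f"duplicate Ct record for {key}")
        out[key] = rec
    return out


def ddct_fold_change(
    records: Iterable[CtRecord],
    target: str,
    references: Sequence[str],
    baseline: str,
    treated: str,
) -> DdctResult:
    """ΔΔCt fold change of ``target`` normalized to a panel of reference genes.

    The reference Ct for a condition is the arithmetic mean of the reference
    genes' replicate-mean Cts, which corresponds to the geometric mean of their
    linear abundances. Then ``ΔCt = Ct_target − Ct_ref`` per condition,
    ``ΔΔCt = ΔCt_treated − ΔCt_baseline`` and ``fold = 2**(−ΔΔCt)``.

    The SEM is propagated first-order: the replicate-mean variances of the
    target and each reference in both conditions combine through the linear
    form of ΔΔCt and are mapped to the linear scale via ``ln2 · fold``.
    """
    if not references:
        raise ValueError("at least one reference gene is required")
    by_key = _index_records(records)
    for gene in [target, *references]:
        for cond in (baseline, treated):
            if (gene, cond) not in by_key:
                raise ValueError(f"missing Ct record for gene {gene!r} in condition {cond!r}")

    k = len(references)
    var_ddct = 0.0
    dct = {}
    for cond in (baseline, treated):
        tgt = by_key[(target, cond)]
        refs = [by_key[(g, cond)] for g in references]
        ref_ct = float(np.mean([r.mean for r in refs]))
        dct[cond] = tgt.mean - ref_ct
        var_ddct += tgt.var_of_mean + sum(r.var_of_mean for r in refs) / k**2

    ddct = dct[treated] - dct[baseline]
    fold = 2.0 ** (-ddct)
    sem = math.log(2.0) * fold * math.sqrt(var_ddct)
    return DdctResult(gene=target, fold_change=fold, sem=sem, ddct=ddct)


def percent_input(m: ChipMeasurement) -> float:
    """ChIP enrichment as percent of input chromatin recovered.

    The input Ct is first adjusted for the input dilution
    (``Ct_input − log2(1/input_fraction)``), then
    ``percent = 100 · 2**(adjusted_input − Ct_ip)``.
    """
    adjusted_input = m.ct_input - math.log2(1.0 / m.input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - m.ct_ip)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom and
    a two-sided p-value. Degenerate zero-variance-in-both-groups inputs use the
    conventions p = 1 for equal means and p = 0 for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("welch_t requires at least 2 observations per sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    df_fallback = float(na + nb - 2)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, df_fallback, 1.0
        t = math.inf if a.mean() > b.mean() else -math.inf
        return t, df_fallback, 0.0
    sa, sb = va / na, vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def doubling_time(n0: float, n1: float, elapsed: float) -> float:
    """Population doubling time in the units of ``elapsed``.

    ``PDT = elapsed · ln2 / ln(n1/n0)``; requires growth (n1 > n0).
    """
    if n0 <= 0 or n1 <= 0:
        raise ValueError("cell counts must be positive")
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")
    if n1 <= n0:
        raise ValueError("population did not grow (n1 <= n0); doubling time undefined")
    return elapsed * math.log(2.0) / math.log(n1 / n0)
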