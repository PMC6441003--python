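"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators, each a pure function of (spec, seed):

* nucleus fields — two-channel images (DNA counterstain + paint probe) of
  elliptical, non-overlapping nuclei with a controllable radial probe bias;
* count tables — negative-binomial gene × sample counts with planted log2
  fold changes;
* promoter sets — i.i.d. background sequence with a motif instance planted in
  a known fraction of promoters;
* Ct tables — qPCR replicates with known true expression changes.

The radial probe model: probe spot centres inside a nucleus are sampled with
probability proportional to ``((d_max − d)/d_max)**β`` for peripheral bias
(β > 0) or ``(d/d_max)**|β|`` for interior bias (β < 0), where d is the
pixel's distance from the nucleus boundary; β = 0 is uniform. Each centre is
rendered as a Gaussian point-spread blob (default σ = 2 px) so blob tails
cross shell boundaries, which is exactly the hard case for the quantifier.
The fraction of spot centres falling in each equal-area shell of the truth
mask is recorded per nucleus as ``truth_shell_fractions``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fish import NucleusRecord, erode_equal_area_shells
from .motifs import BASES, PositionWeightMatrix, reverse_complement
from .qpcr import CtRecord
from .transcriptome import ExpressionTable

__all__ = [
    "FieldSpec",
    "SyntheticField",
    "CountTableSpec",
    "PromoterSetSpec",
    "PromoterSet",
    "CtTableSpec",
    "generate_nucleus_field",
    "generate_count_table",
    "generate_promoters",
    "generate_ct_table",
    "radial_weights",
    "forkhead_like_pwm",
]


# ---------------------------------------------------------------------------
# nucleus fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic two-channel microscopy field.

    Intensities are 16-bit-range values matching CCD capture; pixel size is
    arbitrary (the analysis is scale-free).
    """

    width: int = 512
    height: int = 512
    n_nuclei: int = 50
    nucleus_radius_range: tuple[float, float] = (12.0, 18.0)
    ellipticity_range: tuple[float, float] = (0.7, 1.0)  # minor/major axis ratio
    radial_bias: float = 0.0  # β: 0 uniform, >0 peripheral, <0 interior
    probe_fraction: float = 1.0
    n_probe_spots: int = 150
    probe_spot_intensity: float = 4000.0
    psf_sigma: float = 2.0
    dna_level: float = 20000.0
    background_level: float = 400.0
    noise_sd: float = 300.0
    n_shells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if rmin <= 0 or rmax < rmin:
            raise ValueError("nucleus radii must satisfy 0 < min <= max")
        emin, emax = self.ellipticity_range
        if not 0 < emin <= emax <= 1:
            raise ValueError("ellipticity range must satisfy 0 < min <= max <= 1")
        if not 0 <= self.probe_fraction <= 1:
            raise ValueError("probe_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_probe_spots < 1:
            raise ValueError("n_probe_spots must be >= 1")


@dataclass(frozen=True)
class SyntheticField:
    """Generated field plus its ground truth."""

    dna_channel: np.ndarray  # uint16
    probe_channel: np.ndarray  # uint16
    truth_masks: np.ndarray  # int32 labels, 0 = background
    truth_shell_fractions: np.ndarray  # (n_nuclei, n_shells); NaN rows = no probe
    probe_bearing: np.ndarray  # bool per nucleus
    spec: FieldSpec


def radial_weights(dist: np.ndarray, beta: float) -> np.ndarray:
    """Unnormalized placement weight for boundary distances ``dist``.

    β > 0 concentrates probability at the periphery (small d), β < 0 at the
    interior (large d), β = 0 is uniform. d_max is taken from ``dist`` itself.
    """
    dist = np.asarray(dist, dtype=float)
    if beta == 0:
        return np.ones_like(dist)
    d_max = dist.max()
    if d_max <= 0:
        return np.ones_like(dist)
    if beta > 0:
        return ((d_max - dist) / d_max) ** beta
    return (dist / d_max) ** abs(beta)


def _rasterize_ellipse(
    center: tuple[float, float], a: float, b: float, theta: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels inside an ellipse with semi-axes a >= b."""
    cr, cc = center
    rad = int(math.ceil(a)) + 1
    r0, r1 = int(cr) - rad, int(cr) + rad + 1
    c0, c1 = int(cc) - rad, int(cc) + rad + 1
    rr, cc_grid = np.mgrid[max(r0, 0) : min(r1, shape[0]), max(c0, 0) : min(c1, shape[1])]
    dr = rr - cr
    dc = cc_grid - cc
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc_grid[inside]


def generate_nucleus_field(spec: FieldSpec) -> SyntheticField:
    """Render one field of elliptical nuclei with radially biased probe signal."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    labels = np.zeros(shape, dtype=np.int32)

    centers: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    max_tries = 20000
    tries = 0
    placed = 0
    while placed < spec.n_nuclei:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in a "
                f"{spec.width}x{spec.height} field after {max_tries} attempts; "
                "enlarge the field or reduce n_nuclei/radii"
            )
        tries += 1
        a = rng.uniform(*spec.nucleus_radius_range)
        b = a * rng.uniform(*spec.ellipticity_range)
        theta = rng.uniform(0, math.pi)
        margin = a + 2.0  # keep masks off the field border
        if 2 * margin >= min(shape):
            raise RuntimeError("field too small for the requested nucleus radii")
        cr = rng.uniform(margin, spec.height - margin)
        cc = rng.uniform(margin, spec.width - margin)
        if any(
            math.hypot(cr - r0, cc - c0) < a + rad0 + 2.0 for r0, c0, rad0 in centers
        ):
            continue
        rows, cols = _rasterize_ellipse((cr, cc), a, b, theta, shape)
        placed += 1
        labels[rows, cols] = placed
        centers.append((cr, cc, a))

    n = spec.n_nuclei
    probe_bearing = rng.random(n) < spec.probe_fraction if n else np.zeros(0, bool)

    dna = np.full(shape, spec.background_level, dtype=float)
    dna[labels > 0] = spec.dna_level
    spot_img = np.zeros(shape, dtype=float)
    truth_fractions = np.full((n, spec.n_shells), np.nan)

    # one distance transform covers all nuclei: they are disjoint and separated
    dist = ndimage.distance_transform_edt(labels > 0)

    for i in range(n):
        lab = i + 1
        rows, cols = np.nonzero(labels == lab)
        if not probe_bearing[i]:
            continue
        d = dist[rows, cols]
        w = radial_weights(d, spec.radial_bias)
        total = w.sum()
        probs = np.ones_like(w) / len(w) if total <= 0 else w / total
        idx = rng.choice(len(rows), size=spec.n_probe_spots, replace=True, p=probs)
        np.add.at(spot_img, (rows[idx], cols[idx]), spec.probe_spot_intensity)

        # truth bookkeeping from the placement itself
        bbox_mask = np.zeros(shape, dtype=bool)
        bbox_mask[rows, cols] = True
        r0, c0, r1, c1 = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
        rec = NucleusRecord(
            label=lab,
            bbox=(int(r0), int(c0), int(r1), int(c1)),
            mask=bbox_mask[r0:r1, c0:c1],
            area=len(rows),
            centroid=(float(rows.mean()), float(cols.mean())),
        )
        part = erode_equal_area_shells(rec, spec.n_shells)
        shells = part.shell_map[rows[idx] - r0, cols[idx] - c0]
        truth_fractions[i] = np.bincount(
            shells - 1, minlength=spec.n_shells
        ) / float(spec.n_probe_spots)

    probe = ndimage.gaussian_filter(spot_img, spec.psf_sigma)
    if spec.noise_sd > 0:
        dna += rng.normal(0.0, spec.noise_sd, shape)
        probe += rng.normal(0.0, spec.noise_sd / 4.0, shape)

    return SyntheticField(
        dna_channel=np.clip(dna, 0, 65535).astype(np.uint16),
        probe_channel=np.clip(probe, 0, 65535).astype(np.uint16),
        truth_masks=labels,
        truth_shell_fractions=truth_fractions,
        probe_bearing=probe_bearing,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountTableSpec:
    """Negative-binomial count table with planted log2 fold changes.

    ``conditions`` maps condition name → replicate count; the first condition
    is the baseline. ``planted_changes`` maps gene id → (condition, log2fc).
    Gene ids are ``g0001`` … ``g<n_genes>``.
    """

    n_genes: int = 2000
    conditions: tuple[tuple[str, int], ...] = (("proliferative", 2), ("treated", 2))
    library_size_mean: float = 1e6
    dispersion: float = 0.05
    planted_changes: tuple[tuple[str, str, float], ...] = ()  # (gene, condition, log2fc)
    size_factor_sd: float = 0.15
    abundance_shape: float = 2.0  # Gamma shape of expressed-gene abundances
    zero_fraction: float = 0.35  # silent genes (zero abundance, never planted)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if any(reps < 1 for _, reps in self.conditions):
            raise ValueError("replicate counts must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        names = [c for c, _ in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        valid = set(self.gene_ids())
        for gene, cond, _ in self.planted_changes:
            if gene not in valid:
                raise ValueError(f"planted gene {gene!r} not in 1..n_genes")
            if cond not in names:
                raise ValueError(f"planted condition {cond!r} not defined")

    def gene_ids(self) -> list[str]:
        pad = max(4, len(str(self.n_genes)))
        return [f"g{i + 1:0{pad}d}" for i in range(self.n_genes)]


def generate_count_table(spec: CountTableSpec) -> ExpressionTable:
    """Sample an overdispersed count table with the planted effects.

    A ``zero_fraction`` of genes is silent (relative abundance exactly 0,
    mirroring the unexpressed portion of an annotated transcriptome); the rest
    draw Gamma-distributed relative abundances. Planted genes are always drawn
    from the expressed portion so the planted fold change is observable.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}

    rel = rng.gamma(spec.abundance_shape, 1.0, size=spec.n_genes)
    n_zero = round(spec.zero_fraction * spec.n_genes)
    planted_pos = {gene_pos[g] for g, _, _ in spec.planted_changes}
    eligible = np.array(sorted(set(range(spec.n_genes)) - planted_pos))
    if n_zero > len(eligible):
        raise ValueError("zero_fraction leaves no room for the planted genes")
    if n_zero:
        rel[rng.choice(eligible, size=n_zero, replace=False)] = 0.0
    rel /= rel.sum()

    fold = {}
    for gene, cond, lfc in spec.planted_changes:
        fold.setdefault(cond, np.ones(spec.n_genes))[gene_pos[gene]] *= 2.0**lfc

    columns = {}
    sample_conditions = {}
    for cond, reps in spec.conditions:
        cond_rel = rel * fold.get(cond, 1.0)
        for r in range(1, reps + 1):
            sf = math.exp(rng.normal(0.0, spec.size_factor_sd))
            mu = cond_rel * spec.library_size_mean * sf
            if spec.dispersion > 0:
                shape = 1.0 / spec.dispersion
                counts = rng.negative_binomial(shape, shape / (shape + mu))
            else:
                counts = rng.poisson(mu)
            name = f"{cond}_{r}"
            columns[name] = counts
            sample_conditions[name] = cond

    df = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    return ExpressionTable(values=df, sample_conditions=sample_conditions)


# ---------------------------------------------------------------------------
# promoter sets
# ---------------------------------------------------------------------------

def forkhead_like_pwm(strength: float = 97.0, name: str = "FKH_synthetic") -> PositionWeightMatrix:
    """A synthetic, low-entropy forkhead-family-style motif (GTAAACAA core
    with an extended flank) for planted-recovery studies. Not a database
    matrix; the 14-bp width keeps the chance per-promoter hit rate in
    1050-bp background sequence at the percent level at threshold 0.8."""
    consensus = "GTAAACAATGTTTA"
    other = (100.0 - strength) / 3.0
    counts = np.full((4, len(consensus)), other)
    for j, base in enumerate(consensus):
        counts[BASES.index(base), j] = strength
    return PositionWeightMatrix(name=name, counts=counts)


@dataclass(frozen=True)
class PromoterSetSpec:
    """Fixed-length promoter set with a motif planted in a known fraction."""

    n_promoters: int = 200
    length: int = 1050
    gc_content: float = 0.41
    motif: PositionWeightMatrix = field(default_factory=forkhead_like_pwm)
    planted_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if self.length < self.motif.width:
            raise ValueError(
                f"promoter length {self.length} shorter than motif width {self.motif.width}"
            )
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PromoterSet:
    """gene_id → upstream sequence (5'→3', ending at the TSS) plus truth."""

    sequences: dict[str, str]
    planted: frozenset[str]
    spec: PromoterSetSpec

    def __len__(self) -> int:
        return len(self.sequences)


def _sample_motif_instance(pwm: PositionWeightMatrix, rng: np.random.Generator) -> str:
    probs = pwm.probabilities
    return "".join(
        BASES[rng.choice(4, p=probs[:, j] / probs[:, j].sum())]
        for j in range(pwm.width)
    )


def generate_promoters(spec: PromoterSetSpec) -> PromoterSet:
    """i.i.d. background sequence at the stated GC, with planted motif instances.

    Planted promoters receive one instance sampled from the motif's positional
    distributions, on a uniformly chosen strand and position.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_planted = round(spec.planted_fraction * spec.n_promoters)
    planted_idx = set(
        rng.choice(spec.n_promoters, size=n_planted, replace=False).tolist()
    )

    sequences: dict[str, str] = {}
    planted: set[str] = set()
    pad = max(4, len(str(spec.n_promoters)))
    for i in range(spec.n_promoters):
        gid = f"prom{i + 1:0{pad}d}"
        codes = rng.choice(4, size=spec.length, p=base_probs)
        seq = "".join(BASES[c] for c in codes)
        if i in planted_idx:
            instance = _sample_motif_instance(spec.motif, rng)
            if rng.random() < 0.5:
                instance = reverse_complement(instance)
            pos = int(rng.integers(0, spec.length - spec.motif.width + 1))
            seq = seq[:pos] + instance + seq[pos + spec.motif.width :]
            planted.add(gid)
        sequences[gid] = seq
    return PromoterSet(sequences=sequences, planted=frozenset(planted), spec=spec)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtTableSpec:
    """qPCR Ct tables with known true log2 expression changes.

    ``targets`` maps gene → true log2 change in the treated condition;
    ``references`` have true change 0. Ct drops one cycle per log2 unit of
    abundance gained.
    """

    targets: tuple[tuple[str, float], ...] = (("GOI", 1.0),)
    references: tuple[str, ...] = ("PRDX5", "EFEMP2", "FAU", "SPARC", "FKBP10")
    replicates: int = 3
    noise_sd: float = 0.1
    baseline_condition: str = "baseline"
    treated_condition: str = "treated"
    ct_range: tuple[float, float] = (20.0, 28.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        names = [g for g, _ in self.targets] + list(self.references)
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names across targets/references")


def generate_ct_table(spec: CtTableSpec) -> list[CtRecord]:
    """Ct = per-gene baseline − true log2 change + Gaussian(0, noise_sd)."""
    rng = np.random.default_rng(spec.seed)
    records: list[CtRecord] = []
    genes = list(spec.targets) + [(g, 0.0) for g in spec.references]
    for gene, change in genes:
        base_ct = rng.uniform(*spec.ct_range)
        for cond, delta in (
            (spec.baseline_condition, 0.0),
            (spec.treated_condition, change),
        ):
            cts = base_ct - delta + rng.normal(0.0, spec.noise_sd, spec.replicates)
            records.append(CtRecord(gene=gene, condition=cond, cts=tuple(cts)))
    return records
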