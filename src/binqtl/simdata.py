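"""Synthetic F1 populations, phenotypes, and CIELAB color data.

Emulates the structure of a peach F1 mapping population: two outbred parents,
eight chromosomes, Poisson crossovers with uniform positions (no
interference), parent-specific IBD segments carrying no heterozygosity,
genotyping-error and missing-data injection, QTLs with additive + dominance
effects, and Lab color triplets generated from latent color-card grades.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence.spawn`` so that stage-level reruns reproduce.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix import A, B, H, MISSING, GenotypeMatrix, marker_name

#: approximate physical lengths (bp) of the eight peach chromosomes (Pp01-Pp08)
PEACH_CHROM_LENGTHS: tuple[int, ...] = (
    47_851_208,
    30_405_870,
    27_368_013,
    25_843_236,
    18_496_696,
    30_767_194,
    22_388_614,
    22_573_980,
)


@dataclasses.dataclass
class SimConfig:
    """Conditions of the simulated cross.

    Defaults mirror the study design this generator emulates: 235 F1
    individuals, eight chromosomes at peach-like physical lengths, marker
    density of the order of the ~134k segregating SNPs mapped over ~226 Mb,
    and a mix of markers heterozygous in one or both parents.

    Attributes
    ----------
    n_progeny : number of F1 individuals.
    chrom_lengths : physical length in bp per chromosome (1-based positions).
    marker_density : expected markers per Mb.
    map_length_morgans : expected crossovers per chromosome per meiosis
        (scalar or one value per chromosome).
    marker_class_probs : probabilities that a marker is heterozygous in
        parent 1 only, parent 2 only, or both.
    ibd_intervals : per-parent {parent_index(0|1): [(chrom, start, end), ...]}
        regions where that parent carries no heterozygosity.
    error_rate : per-genotype probability of flipping to a random other state.
    missing_rate : per-genotype probability of being set missing.
    seed : master seed; every downstream draw derives from it.
    """

    n_progeny: int = 235
    chrom_lengths: tuple[int, ...] = PEACH_CHROM_LENGTHS
    marker_density: float = 580.0
    map_length_morgans: float | Sequence[float] = 0.65
    marker_class_probs: tuple[float, float, float] = (0.36, 0.44, 0.20)
    ibd_intervals: dict[int, list[tuple[int, int, int]]] = dataclasses.field(default_factory=dict)
    error_rate: float = 0.01
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 2:
            raise ValueError("n_progeny must be >= 2")
        for rate, label in ((self.error_rate, "error_rate"), (self.missing_rate, "missing_rate")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")
        probs = np.asarray(self.marker_class_probs, dtype=float)
        if probs.min() < 0 or probs.sum() <= 0:
            raise ValueError("marker_class_probs must be non-negative and sum > 0")
        for parent, intervals in self.ibd_intervals.items():
            if parent not in (0, 1):
                raise ValueError("ibd_intervals keys must be parent index 0 or 1")
            for chrom, start, end in intervals:
                length = self.chrom_lengths[chrom - 1]
                if not (1 <= start < end <= length):
                    raise ValueError(f"IBD interval ({chrom}, {start}, {end}) outside chromosome bounds")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    def map_length(self, chrom: int) -> float:
        """Expected crossovers per meiosis for 1-based chromosome ``chrom``."""
        if np.isscalar(self.map_length_morgans):
            return float(self.map_length_morgans)
        return float(self.map_length_morgans[chrom - 1])

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = list(d["chrom_lengths"])
        d["marker_class_probs"] = list(d["marker_class_probs"])
        d["ibd_intervals"] = {k: [list(t) for t in v] for k, v in d["ibd_intervals"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["chrom_lengths"] = tuple(d["chrom_lengths"])
        d["marker_class_probs"] = tuple(d["marker_class_probs"])
        d["ibd_intervals"] = {int(k): [tuple(t) for t in v] for k, v in d.get("ibd_intervals", {}).items()}
        return cls(**d)


@dataclasses.dataclass
class Parents:
    """Four parental haplotypes and marker metadata.

    ``haplotypes`` has shape (4, n_markers): rows 0-1 are parent 1's two
    haplotypes, rows 2-3 parent 2's, entries are allele codes 0/1.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def parent_genotypes(self) -> np.ndarray:
        """(n_markers, 2) AHB codes of the two parents (allele sums)."""
        g1 = self.haplotypes[0] + self.haplotypes[1]
        g2 = self.haplotypes[2] + self.haplotypes[3]
        return np.stack([g1, g2], axis=1).astype(np.int8)


@dataclasses.dataclass
class TruePopulation:
    """Simulated truth: transmitted haplotypes and error-free genotypes."""

    parents: Parents
    individuals: list[str]
    #: (2, n_markers, n_progeny) transmitted haplotype index (0/1) from each parent
    transmitted: np.ndarray
    #: (n_markers, n_progeny) allele-count genotypes (== AHB codes)
    true_genotypes: np.ndarray
    #: {(individual, chrom, parent): sorted crossover bp positions}
    crossovers: dict[tuple[int, int, int], np.ndarray]

    @property
    def markers(self) -> pd.DataFrame:
        return self.parents.markers

    def to_genotype_matrix(self, parent_names: tuple[str, str] = ("P1", "P2")) -> GenotypeMatrix:
        """Full matrix with the two parents as the first columns."""
        pg = self.parents.parent_genotypes()
        calls = np.concatenate([pg, self.true_genotypes], axis=1).astype(np.int8)
        individuals = [parent_names[0], parent_names[1]] + list(self.individuals)
        return GenotypeMatrix(self.markers.copy(), individuals, calls, parents=parent_names)


@dataclasses.dataclass
class QTLSpec:
    """A simulated QTL acting through its nearest marker's true genotype.

    ``a`` is the additive effect ((A - B)/2 on the homozygote means), ``d``
    the dominance deviation of the heterozygote from the homozygote midpoint.
    """

    chrom: int
    pos: int
    a: float
    d: float = 0.0
    residual_sd: float = 1.0
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


# --------------------------------------------------------------------------- parents
def simulate_parents(config: SimConfig) -> Parents:
    """Draw marker positions and the four parental haplotypes.

    Marker counts per chromosome are Poisson(density * length); positions are
    uniform and distinct.  Each marker is assigned to be heterozygous in
    parent 1 only, parent 2 only, or both, with ``marker_class_probs``;
    inside a parent's IBD interval that parent is forced homozygous (its two
    haplotypes are identical there), which can render a marker fully
    uninformative — such markers are emitted and left for filtering.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    probs = np.asarray(config.marker_class_probs, dtype=float)
    probs = probs / probs.sum()

    names, chroms, positions = [], [], []
    for c, length in enumerate(config.chrom_lengths, start=1):
        n = rng.poisson(config.marker_density * length / 1e6)
        n = min(n, length)  # distinct 1-based positions must fit
        pos = np.sort(rng.choice(length, size=n, replace=False) + 1)
        positions.append(pos)
        chroms.append(np.full(n, c))
        names.extend(marker_name(c, p) for p in pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    chrom_all = np.concatenate(chroms) if chroms else np.array([], dtype=int)
    markers = pd.DataFrame({"name": names, "chrom": chrom_all.astype(int), "pos": pos_all.astype(int)})
    m = len(markers)

    cls = rng.choice(3, size=m, p=probs)  # 0: P1-only het, 1: P2-only het, 2: both het
    hap = np.zeros((4, m), dtype=np.int8)
    order1 = rng.integers(0, 2, size=m)  # which haplotype of a het parent carries the alt allele
    order2 = rng.integers(0, 2, size=m)
    hom_allele1 = rng.integers(0, 2, size=m)  # allele of a homozygous parent
    hom_allele2 = rng.integers(0, 2, size=m)

    p1_het = (cls == 0) | (cls == 2)
    p2_het = (cls == 1) | (cls == 2)
    hap[0] = np.where(p1_het, order1, hom_allele1)
    hap[1] = np.where(p1_het, 1 - order1, hom_allele1)
    hap[2] = np.where(p2_het, order2, hom_allele2)
    hap[3] = np.where(p2_het, 1 - order2, hom_allele2)

    for parent, intervals in config.ibd_intervals.items():
        rows = (2 * parent, 2 * parent + 1)
        for chrom, start, end in intervals:
            inside = (markers["chrom"].to_numpy() == chrom) & (pos_all >= start) & (pos_all <= end)
            hap[rows[1], inside] = hap[rows[0], inside]
    return Parents(markers, hap)


# --------------------------------------------------------------------------- meiosis
def _transmit(
    rng: np.random.Generator, pos: np.ndarray, length: int, expected_crossovers: float
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: haplotype index at each marker, plus crossover positions."""
    k = rng.poisson(expected_crossovers)
    xo = np.sort(rng.uniform(1, length, size=k))
    start = rng.integers(0, 2)
    hap_idx = (start + np.searchsorted(xo, pos)) % 2
    return hap_idx.astype(np.int8), xo


def simulate_progeny(
    parents: Parents,
    n_progeny: int,
    map_length_morgans: float | Sequence[float],
    seed: int,
    chrom_lengths: Sequence[int] | None = None,
) -> TruePopulation:
    """Simulate F1 progeny by independent meioses in the two parents.

    Per meiosis and chromosome the crossover count is Poisson with mean
    ``map_length_morgans`` and crossover positions are uniform on the physical
    length (no interference).  Genotypes are the sums of the two transmitted
    alleles.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    markers = parents.markers
    chrom_ids = sorted(markers["chrom"].unique())
    if chrom_lengths is None:
        lengths = {c: int(markers.loc[markers["chrom"] == c, "pos"].max()) for c in chrom_ids}
    else:
        lengths = {c: int(chrom_lengths[c - 1]) for c in chrom_ids}

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    m = parents.n_markers
    transmitted = np.zeros((2, m, n_progeny), dtype=np.int8)
    crossovers: dict[tuple[int, int, int], np.ndarray] = {}
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()

    def lam(c: int) -> float:
        if np.isscalar(map_length_morgans):
            return float(map_length_morgans)
        return float(map_length_morgans[c - 1])

    for i in range(n_progeny):
        for c in chrom_ids:
            sel = chrom_arr == c
            pos = pos_arr[sel]
            for parent in (0, 1):
                hap_idx, xo = _transmit(rng, pos, lengths[c], lam(c))
                transmitted[parent, sel, i] = hap_idx
                crossovers[(i, c, parent)] = xo

    # vectorized allele lookup: parent p haplotype rows are 2p + hap_idx
    a1 = np.where(transmitted[0] == 0, parents.haplotypes[0][:, None], parents.haplotypes[1][:, None])
    a2 = np.where(transmitted[1] == 0, parents.haplotypes[2][:, None], parents.haplotypes[3][:, None])
    genotypes = (a1 + a2).astype(np.int8)
    individuals = [f"F1_{i + 1:03d}" for i in range(n_progeny)]
    return TruePopulation(parents, individuals, transmitted, genotypes, crossovers)


# --------------------------------------------------------------------------- noise
def degrade_genotypes(
    truth: TruePopulation | GenotypeMatrix,
    error_rate: float,
    missing_rate: float,
    seed: int,
    parent_names: tuple[str, str] = ("P1", "P2"),
    degrade_parents: bool = False,
) -> tuple[GenotypeMatrix, float, float]:
    """Inject genotyping errors then missingness; returns realized rates.

    Each offspring genotype is independently flipped to one of the other two
    AHB states with probability ``error_rate``, then set missing with
    probability ``missing_rate``.  Parental calls are untouched unless
    ``degrade_parents`` is set.
    """
    for rate, label in ((error_rate, "error_rate"), (missing_rate, "missing_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{label} must be in [0, 1]")
    matrix = truth.to_genotype_matrix(parent_names) if isinstance(truth, TruePopulation) else truth.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cols = np.arange(matrix.n_individuals) if degrade_parents else matrix.offspring_idx
    calls = matrix.calls
    orig = calls[:, cols]

    flip = rng.random(orig.shape) < error_rate
    # flip to one of the other two states, uniformly
    shift = rng.integers(1, 3, size=orig.shape)
    flipped = (orig + shift) % 3
    observed = orig != MISSING
    sub = np.where(flip & observed, flipped, orig)
    realized_error = float(flip[observed].mean()) if observed.any() else 0.0

    miss = rng.random(sub.shape) < missing_rate
    sub = np.where(miss, MISSING, sub)
    realized_missing = float(miss.mean()) if sub.size else 0.0

    calls[:, cols] = sub.astype(np.int8)
    return matrix, realized_error, realized_missing


# --------------------------------------------------------------------------- phenotypes
_EFFECT_BY_GENOTYPE = {A: +1.0, H: 0.0, B: -1.0}  # multiplier on a; H gets d instead


def simulate_phenotypes(
    truth: TruePopulation, qtl_specs: Sequence[QTLSpec], seed: int
) -> pd.DataFrame:
    """Phenotypes as sums of per-QTL genotype effects plus Gaussian noise.

    Effects act through the nearest simulated marker's *true* genotype:
    +a for the A homozygote, d for the heterozygote, -a for the B homozygote.
    QTLs sharing a trait must declare the same residual sd (one residual draw
    per trait per individual).

    Returns a tidy frame with columns individual, trait, value.
    """
    markers = truth.markers
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(truth.individuals)

    by_trait: dict[str, list[QTLSpec]] = {}
    for spec in qtl_specs:
        by_trait.setdefault(spec.trait, []).append(spec)

    records = []
    for trait, specs in by_trait.items():
        sds = {s.residual_sd for s in specs}
        if len(sds) > 1:
            raise ValueError(f"QTLs for trait {trait!r} declare different residual_sd values: {sds}")
        values = np.zeros(n)
        for spec in specs:
            on_chrom = markers["chrom"].to_numpy() == spec.chrom
            if not on_chrom.any():
                raise ValueError(f"QTL chromosome {spec.chrom} has no simulated markers")
            length = markers.loc[on_chrom, "pos"].max()
            if not (1 <= spec.pos <= max(length, spec.pos)):
                raise ValueError(f"QTL position {spec.pos} off chromosome {spec.chrom}")
            idx_on = np.nonzero(on_chrom)[0]
            nearest = idx_on[np.argmin(np.abs(markers["pos"].to_numpy()[idx_on] - spec.pos))]
            g = truth.true_genotypes[nearest]
            values += np.where(g == H, spec.d, np.where(g == A, spec.a, -spec.a))
        sd = specs[0].residual_sd
        values = values + rng.normal(0.0, sd, size=n)
        for ind, v in zip(truth.individuals, values):
            records.append({"individual": ind, "trait": trait, "value": float(v)})
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------- color
def simulate_color(
    n_samples: int = 300,
    coefficients: tuple[float, float, float, float] = (-2.0, 0.01, 0.04, 0.15),
    grade_range: tuple[int, int] = (1, 10),
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """(L, a*, b*) triplets whose linear combination reproduces a latent grade.

    A latent integer grade is drawn uniformly from ``grade_range`` (the
    10-level color card by default).  L and a* are drawn from realistic
    colorimeter ranges for yellow peach flesh; b* is solved so that
    ``b0 + b1*L + b2*a + b3*b`` equals the latent grade exactly.  The
    *recorded* grade is the latent grade plus Gaussian grading noise (the
    card assignment is the noisy measurement), so OLS on (L, a*, b*)
    recovers ``coefficients`` exactly at ``noise_sd == 0`` and without bias
    otherwise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    b0, b1, b2, b3 = coefficients
    if b3 == 0:
        raise ValueError("coefficient b3 must be nonzero (b* carries the grade signal)")
    lo, hi = grade_range
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    grade = rng.integers(lo, hi + 1, size=n_samples).astype(float)
    if np.ptp(grade) == 0:
        warnings.warn("simulated grades have zero variance (collapsed grade range)", stacklevel=2)
    L = rng.normal(60.0, 5.0, size=n_samples)
    a_star = rng.normal(5.0, 3.0, size=n_samples)
    b_star = (grade - b0 - b1 * L - b2 * a_star) / b3
    recorded = grade + rng.normal(0.0, noise_sd, size=n_samples)
    return pd.DataFrame({"L": L, "a": a_star, "b": b_star, "grade": recorded})


# --------------------------------------------------------------------------- one-call convenience
def simulate_population(config: SimConfig) -> tuple[TruePopulation, GenotypeMatrix]:
    """Parents + progeny + degraded observed matrix, all from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed).spawn(3)
    parents = simulate_parents(dataclasses.replace(config, seed=int(ss[0].generate_state(1)[0] % (2**31))))
    truth = simulate_progeny(
        parents,
        config.n_progeny,
        config.map_length_morgans,
        seed=int(ss[1].generate_state(1)[0] % (2**31)),
        chrom_lengths=config.chrom_lengths,
    )
    observed, _, _ = degrade_genotypes(
        truth, config.error_rate, config.missing_rate, seed=int(ss[2].generate_state(1)[0] % (2**31))
    )
    return truth, observed
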