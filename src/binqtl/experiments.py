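"""End-to-end simulation experiments exercising the full pipeline.

These functions wire the generator, filter cascade, binning, map building and
QTL scan together under the study-like conditions used for validation:
error-robustness of the binned map, QTL parameter recovery, and the
permutation test's type-I behaviour.  Problem sizes are desk-scale (a single
or a pair of chromosomes) — see the methods note.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import binning, genofilter, linkmap, qtlscan, simdata
from .matrix import MISSING, GenotypeMatrix


def _spawn_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def simulate_bc_dataset(
    seed: int,
    n_progeny: int = 100,
    chrom_lengths: Sequence[int] = (25_000_000,),
    markers_per_mb: float = 20.0,
    map_length_cm: float = 50.0,
    error_rate: float = 0.01,
    missing_rate: float = 0.05,
) -> tuple[simdata.TruePopulation, GenotypeMatrix]:
    """An F1 population of markers heterozygous in parent 1 only (1:1 set).

    Returns the truth and the filtered, pseudo-testcross-split observed 1:1
    matrix (parent-1 dataset).
    """
    config = simdata.SimConfig(
        n_progeny=n_progeny,
        chrom_lengths=tuple(chrom_lengths),
        marker_density=markers_per_mb,
        map_length_morgans=map_length_cm / 100.0,
        marker_class_probs=(1.0, 0.0, 0.0),
        error_rate=error_rate,
        missing_rate=missing_rate,
        seed=seed,
    )
    truth, observed = simdata.simulate_population(config)
    filtered, _ = genofilter.filter_cascade(observed)
    sets = genofilter.split_testcross(filtered)
    return truth, sets.sf_set


def binned_vs_naive_map(
    seed: int,
    n_progeny: int = 100,
    n_markers_target: int = 500,
    chrom_length: int = 25_000_000,
    map_length_cm: float = 50.0,
    error_rate: float = 0.01,
    missing_rate: float = 0.05,
) -> dict[str, float]:
    """Map length from the one-bin matrix vs the naive unbinned matrix.

    The naive map sums Kosambi distances over consecutive raw markers, so
    every genotyping error contributes spurious recombination; the one-bin
    map should stay near the simulated truth.
    """
    truth, sf = simulate_bc_dataset(
        seed,
        n_progeny=n_progeny,
        chrom_lengths=(chrom_length,),
        markers_per_mb=n_markers_target / (chrom_length / 1e6),
        map_length_cm=map_length_cm,
        error_rate=error_rate,
        missing_rate=missing_rate,
    )
    genotyper = binning.BinGenotyper(design="BC")
    onebin = genotyper.fit(sf).transform(sf)

    def _map_length(mat: GenotypeMatrix) -> float:
        groups = [np.arange(mat.n_markers)]
        gmap = linkmap.build_map(mat, groups=groups, design="BC")
        return gmap.total_cm

    naive_phased = binning.phase_markers(sf)  # align coding so r < 0.5 between neighbours
    naive = GenotypeMatrix(naive_phased.markers, list(naive_phased.individuals), naive_phased.states)
    return {
        "true_cm": map_length_cm,
        "onebin_cm": _map_length(onebin),
        "naive_cm": _map_length(naive),
        "n_bins": onebin.n_markers,
        "n_markers": sf.n_markers,
    }


@dataclasses.dataclass
class RecoveryReplicate:
    peak_error_cm: float
    lod: float
    threshold: float
    recovered: bool


def qtl_recovery_replicate(
    seed: int,
    n_progeny: int = 232,
    qtl_cm: float = 30.0,
    a_in_sd: float = 1.0,
    n_permutations: int = 1000,
    chrom_lengths: Sequence[int] = (25_000_000, 25_000_000),
    map_length_cm: float = 60.0,
    markers_per_mb: float = 2.0,
    max_error_cm: float = 10.0,
) -> RecoveryReplicate:
    """One QTL-recovery replicate on a two-chromosome BC design.

    A QTL of additive effect equal to ``a_in_sd`` phenotypic standard
    deviations sits at ``qtl_cm`` on chromosome 1; recovery means the peak
    lands within ``max_error_cm`` of the truth with LOD above the
    permutation threshold.
    """
    truth, sf = simulate_bc_dataset(
        seed,
        n_progeny=n_progeny,
        chrom_lengths=chrom_lengths,
        markers_per_mb=markers_per_mb,
        map_length_cm=map_length_cm,
    )
    onebin = binning.BinGenotyper(design="BC").fit(sf).transform(sf)
    groups = linkmap.group_markers(onebin, lod_threshold=19.0, design="BC")
    gmap = linkmap.build_map(onebin, groups=groups, design="BC")

    # effect through the true genotype at the marker nearest the QTL position
    qtl_bp = int(qtl_cm / map_length_cm * chrom_lengths[0])
    # class gap equals the 1:1 additive effect a = (A - H); phenotypic sd = gap at a_in_sd = 1
    gap = 1.0
    residual_sd = gap * np.sqrt(1.0 / a_in_sd**2 - 0.25) if a_in_sd**2 < 4 else 0.0
    pheno = simdata.simulate_phenotypes(
        truth,
        [simdata.QTLSpec(chrom=1, pos=qtl_bp, a=gap, d=0.0, residual_sd=residual_sd)],
        seed=_spawn_seed(seed, 1),
    )
    y = pheno.set_index("individual").loc[list(truth.individuals), "value"].to_numpy()

    cfg = qtlscan.ScanConfig(step_cm=1.0, n_permutations=n_permutations, alpha=0.05, seed=_spawn_seed(seed, 2))
    profile = qtlscan.scan_interval_mapping(gmap, onebin, y, design="BC", config=cfg)
    threshold = qtlscan.permutation_threshold(gmap, onebin, y, design="BC", config=cfg)
    peak = profile.iloc[int(profile["lod"].idxmax())]
    # compare on the true scale: physical position -> true cM
    if int(peak["chrom"]) == 1:
        peak_true_cm = peak["bp"] / chrom_lengths[0] * map_length_cm
        err = abs(peak_true_cm - qtl_cm)
    else:
        err = np.inf
    return RecoveryReplicate(
        peak_error_cm=float(err),
        lod=float(peak["lod"]),
        threshold=float(threshold),
        recovered=bool(err <= max_error_cm and peak["lod"] >= threshold),
    )


def qtl_recovery_experiment(seed: int, n_reps: int = 20, **kwargs) -> pd.DataFrame:
    rows = [dataclasses.asdict(qtl_recovery_replicate(_spawn_seed(seed, 10, r), **kwargs)) for r in range(n_reps)]
    return pd.DataFrame(rows)


def type1_error_experiment(
    seed: int,
    n_progeny: int = 232,
    n_permutations: int = 4000,
    n_null: int = 1000,
    alpha: float = 0.05,
    chrom_lengths: Sequence[int] = (25_000_000, 25_000_000),
    map_length_cm: float = 60.0,
    markers_per_mb: float = 2.0,
) -> dict[str, float]:
    """Fraction of null phenotypes whose max LOD exceeds the alpha threshold.

    One genotype dataset; the threshold comes from permutations of a single
    null phenotype draw, then fresh independent Gaussian phenotypes estimate
    the genome-wide type-I error against it.
    """
    truth, sf = simulate_bc_dataset(
        seed, n_progeny=n_progeny, chrom_lengths=chrom_lengths,
        markers_per_mb=markers_per_mb, map_length_cm=map_length_cm,
    )
    onebin = binning.BinGenotyper(design="BC").fit(sf).transform(sf)
    groups = linkmap.group_markers(onebin, lod_threshold=19.0, design="BC")
    gmap = linkmap.build_map(onebin, groups=groups, design="BC")

    rng = np.random.default_rng(_spawn_seed(seed, 3))
    y0 = rng.normal(size=n_progeny)
    cfg = qtlscan.ScanConfig(step_cm=1.0, n_permutations=n_permutations, alpha=alpha, seed=_spawn_seed(seed, 4))
    threshold = qtlscan.permutation_threshold(gmap, onebin, y0, design="BC", config=cfg)

    positions = qtlscan._scan_positions(gmap, onebin, "BC", cfg.step_cm)
    keep = np.ones(n_progeny, dtype=bool)
    nulls = rng.normal(size=(n_progeny, n_null))
    max_lods = qtlscan._max_lod_many(positions, keep, nulls)
    rate = float((max_lods > threshold).mean())
    return {"threshold": threshold, "type1_rate": rate, "n_null": n_null, "alpha": alpha}


def f2_grid_search_rf(counts: np.ndarray, step: float = 2e-5) -> float:
    """Brute-force MLE of the intercross recombination fraction.

    Independent oracle for the EM estimator: evaluates the same likelihood on
    a dense grid over (0, 0.5).
    """
    grid = np.arange(step, 0.5 + step / 2, step)
    lls = np.array([linkmap.f2_loglik(counts, r) for r in grid])
    return float(grid[np.argmax(lls)])
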