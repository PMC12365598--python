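"""Genetic map construction from one-bin matrices.

Two-point linkage LOD grouping (single-linkage at a LOD threshold), Kosambi
distances along physical order, IBD-gap detection (inter-marker gaps of
>= 2.5 Mb, telomeric gaps included), and Table-style map summaries.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix import A, B, H, MISSING, GenotypeMatrix

#: distance cap used when consecutive bins look unlinked (r >= 0.5)
MAX_SEGMENT_CM = 49.9


# ----------------------------------------------------------------- Kosambi
def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 * ln((1 + 2r) / (1 - 2r)).

    Valid for 0 <= r < 0.5; values at or above 0.5 are clamped to
    ``MAX_SEGMENT_CM`` with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    clamp = r_arr >= 0.5
    if clamp.any():
        warnings.warn("recombination fraction >= 0.5 clamped to maximum map distance", stacklevel=2)
    safe = np.clip(r_arr, 0.0, 0.4999999)
    d = 25.0 * np.log((1 + 2 * safe) / (1 - 2 * safe))
    d = np.where(clamp, MAX_SEGMENT_CM, d)
    return float(d) if np.isscalar(r) else d


def kosambi_inv(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: r = 0.5 * tanh(d / 50) with d in cM."""
    d_arr = np.asarray(d_cm, dtype=float)
    r = 0.5 * np.tanh(d_arr / 50.0)
    return float(r) if np.isscalar(d_cm) else r


# ------------------------------------------------------- two-point linkage
def _bc_rf_lod(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    co = (x != MISSING) & (y != MISSING)
    n = int(co.sum())
    if n < 2:
        raise ValueError("fewer than 2 co-called individuals")
    n_r = int((x[co] != y[co]).sum())
    n_nr = n - n_r
    r = n_r / n
    lod = 0.0
    if n_r:
        lod += n_r * np.log10(2 * r)
    if n_nr:
        lod += n_nr * np.log10(2 * (1 - r))
    return r, lod, n


def _f2_joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    co = (x != MISSING) & (y != MISSING)
    if int(co.sum()) < 2:
        raise ValueError("fewer than 2 co-called individuals")
    counts = np.zeros((3, 3), dtype=float)
    for i in (A, H, B):
        xi = x[co] == i
        for j in (A, H, B):
            counts[i, j] = np.sum(xi & (y[co] == j))
    return counts


def _f2_class_probs(r: float) -> np.ndarray:
    """Joint two-locus genotype probabilities for an intercross (phase-unknown
    double heterozygote pooled), indexed [g1, g2] with g in {A,H,B}."""
    p = 1.0 - r
    return np.array(
        [
            [p * p / 4, p * r / 2, r * r / 4],
            [p * r / 2, (p * p + r * r) / 2, p * r / 2],
            [r * r / 4, p * r / 2, p * p / 4],
        ]
    )


def f2_loglik(counts: np.ndarray, r: float) -> float:
    """Log-likelihood of the 3x3 joint genotype counts at recombination r."""
    probs = _f2_class_probs(min(max(r, 1e-12), 0.5))
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    ll = counts * logp
    return float(ll[counts > 0].sum())


def f2_em_rf(counts: np.ndarray, r0: float = 0.25, tol: float = 1e-10, max_iter: int = 1000) -> float:
    """EM estimate of r from F2 joint counts.

    E-step: expected recombinant gametes per class — the double-het class
    contributes 2r^2/(r^2 + (1-r)^2) because its two phases are unresolved.
    M-step: r = expected recombinants / (2n).
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("empty count table")
    # recombinant gametes contributed by each unambiguous class
    rec_weight = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    rec_weight[1, 1] = 0.0  # handled separately
    n_hh = counts[1, 1]
    fixed = float((counts * rec_weight).sum())
    r = r0
    for _ in range(max_iter):
        p = 1.0 - r
        e_hh = 2 * r * r / (r * r + p * p) if (r * r + p * p) > 0 else 0.0
        r_new = (fixed + n_hh * e_hh) / (2 * n)
        r_new = min(max(r_new, 1e-12), 0.5)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    return r


def pairwise_rf_lod(
    calls_i: np.ndarray, calls_j: np.ndarray, design: str = "BC"
) -> tuple[float, float]:
    """Two-point recombination fraction and linkage LOD for one marker pair.

    BC: r is the recombinant fraction among co-called pairs and
    LOD = n_R*log10(2r) + n_NR*log10(2(1-r)).  F2: r by EM over the standard
    intercross likelihood; LOD is the log10 likelihood ratio against r = 0.5.
    """
    if design == "BC":
        r, lod, _ = _bc_rf_lod(calls_i, calls_j)
        return r, lod
    if design == "F2":
        counts = _f2_joint_counts(calls_i, calls_j)
        r = f2_em_rf(counts)
        lod = (f2_loglik(counts, r) - f2_loglik(counts, 0.5)) / np.log(10)
        return r, lod
    raise ValueError("design must be 'BC' or 'F2'")


# ---------------------------------------------------------------- grouping
def group_markers(
    onebin: GenotypeMatrix, lod_threshold: float = 19.0, design: str = "BC"
) -> list[np.ndarray]:
    """Single-linkage clustering of bins at a two-point LOD threshold.

    Bins belong to one linkage group iff connected by a chain of pairs with
    LOD >= threshold.  Returns marker index arrays, each sorted by physical
    order, ordered by majority chromosome.
    """
    calls = onebin.calls
    m = onebin.n_markers
    parent = np.arange(m)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(m):
        for j in range(i + 1, m):
            try:
                _, lod = pairwise_rf_lod(calls[i], calls[j], design)
            except ValueError:
                continue
            if lod >= lod_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    chrom_arr = onebin.markers["chrom"].to_numpy()
    out = [np.array(sorted(g)) for g in groups.values()]
    out.sort(key=lambda g: int(pd.Series(chrom_arr[g]).mode().iloc[0]))
    return out


# ---------------------------------------------------------------- map build
@dataclasses.dataclass
class IBDInterval:
    chrom: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class GeneticMap:
    """Ordered bins per linkage group with cumulative Kosambi cM.

    ``table`` columns: group, name, chrom, pos, cm.  ``ibd`` carries the
    detected IBD intervals, ``chrom_lengths`` the declared physical lengths
    used for coverage and IBD percentages.
    """

    table: pd.DataFrame
    ibd: list[IBDInterval] = dataclasses.field(default_factory=list)
    chrom_lengths: dict[int, int] | None = None

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["group"].unique())

    def group_table(self, g: int) -> pd.DataFrame:
        return self.table[self.table["group"] == g].reset_index(drop=True)

    @property
    def total_cm(self) -> float:
        return float(sum(self.group_table(g)["cm"].max() for g in self.groups))

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_map(
    onebin: GenotypeMatrix,
    groups: Sequence[np.ndarray] | None = None,
    design: str = "BC",
    lod_threshold: float = 19.0,
    chrom_lengths: dict[int, int] | None = None,
    min_ibd_gap: float = 2.5e6,
) -> GeneticMap:
    """Cumulative Kosambi cM along physical order within each linkage group.

    Distances come from consecutive-bin recombination fractions; an
    undefined pair (too few co-called individuals) contributes 0 cM with a
    warning; r >= 0.5 is capped at ``MAX_SEGMENT_CM``.
    """
    if groups is None:
        groups = group_markers(onebin, lod_threshold, design)
    rows = []
    for gi, idx in enumerate(groups, start=1):
        idx = np.asarray(idx)
        order = np.lexsort((onebin.markers["pos"].to_numpy()[idx], onebin.markers["chrom"].to_numpy()[idx]))
        idx = idx[order]
        cm = 0.0
        prev = None
        for i in idx:
            if prev is not None:
                try:
                    r, _ = pairwise_rf_lod(onebin.calls[prev], onebin.calls[i], design)
                except ValueError:
                    warnings.warn("undefined consecutive-pair r; distance imputed 0", stacklevel=2)
                    r = 0.0
                if r >= 0.5:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cm += MAX_SEGMENT_CM
                else:
                    cm += float(kosambi_cm(r))
            row = onebin.markers.iloc[i]
            rows.append(
                {"group": gi, "name": row["name"], "chrom": int(row["chrom"]), "pos": int(row["pos"]), "cm": cm}
            )
            prev = i
    table = pd.DataFrame(rows)
    ibd: list[IBDInterval] = []
    if chrom_lengths is not None:
        positions = {c: onebin.markers.loc[onebin.markers["chrom"] == c, "pos"].to_numpy() for c in chrom_lengths}
        ibd, _, _ = detect_ibd(positions, chrom_lengths, min_gap=min_ibd_gap)
    return GeneticMap(table, ibd, chrom_lengths)


# ---------------------------------------------------------------------- IBD
def detect_ibd(
    marker_positions: dict[int, np.ndarray],
    chrom_lengths: dict[int, int],
    min_gap: float = 2.5e6,
) -> tuple[list[IBDInterval], dict[int, float], float]:
    """Maximal marker-free gaps >= ``min_gap``, treated as possibly IBD.

    Telomeric gaps (before the first and after the last marker) count.
    Returns the intervals, per-chromosome IBD percentages, and the
    genome-wide percentage.
    """
    intervals: list[IBDInterval] = []
    pct: dict[int, float] = {}
    total_ibd = 0
    total_len = 0
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.asarray(marker_positions.get(chrom, np.array([], dtype=int))))
        edges = np.concatenate([[0], pos, [length + 1]])  # virtual markers just off both ends
        chrom_ibd = 0
        for k in range(len(edges) - 1):
            gap_start = int(edges[k]) + 1
            gap_end = int(edges[k + 1]) - 1
            gap_len = gap_end - gap_start + 1
            if gap_len >= min_gap:
                intervals.append(IBDInterval(chrom, gap_start, gap_end))
                chrom_ibd += gap_len
        pct[chrom] = 100.0 * chrom_ibd / length
        total_ibd += chrom_ibd
        total_len += length
    genome_pct = 100.0 * total_ibd / total_len if total_len else 0.0
    return intervals, pct, genome_pct


def ibd_to_bed(intervals: Iterable[IBDInterval], path: str) -> None:
    """Write IBD intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


# ------------------------------------------------------------------ summary
def map_summary(
    gmap: GeneticMap,
    bins: Sequence | None = None,
    chrom_lengths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-group map statistics with a TOTAL row.

    Columns: group, n_bins, n_snps (when ``bins`` with member counts are
    given), mean_snps_per_bin, cm, coverage_pct.  The TOTAL row's
    ``mean_cm_per_bin`` is total cM / total bins rounded to 1 decimal.
    """
    chrom_lengths = chrom_lengths or gmap.chrom_lengths
    snp_by_rep = {}
    if bins is not None:
        snp_by_rep = {b.representative: b.n_markers for b in bins}
    rows = []
    for g in gmap.groups:
        sub = gmap.group_table(g)
        n_bins = len(sub)
        n_snps = int(sum(snp_by_rep.get(nm, 1) for nm in sub["name"])) if snp_by_rep else n_bins
        cm = float(sub["cm"].max())
        coverage = np.nan
        if chrom_lengths is not None:
            chrom = int(sub["chrom"].mode().iloc[0])
            if chrom in chrom_lengths:
                span = int(sub["pos"].max() - sub["pos"].min())
                if span == 0:
                    warnings.warn(f"group {g} has a single bin; coverage span is 0", stacklevel=2)
                coverage = 100.0 * span / chrom_lengths[chrom]
        rows.append(
            {
                "group": g,
                "n_bins": n_bins,
                "n_snps": n_snps,
                "mean_snps_per_bin": n_snps / n_bins,
                "cm": cm,
                "coverage_pct": coverage,
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "group": "TOTAL",
        "n_bins": int(df["n_bins"].sum()),
        "n_snps": int(df["n_snps"].sum()),
        "mean_snps_per_bin": float(df["n_snps"].sum() / df["n_bins"].sum()),
        "cm": float(df["cm"].sum()),
        "coverage_pct": float(df["coverage_pct"].mean()) if df["coverage_pct"].notna().any() else np.nan,
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df.attrs["mean_cm_per_bin"] = round(total["cm"] / total["n_bins"], 1)
    return df


def mean_cm_per_bin(total_cm: float, n_bins: int) -> float:
    """Average inter-bin interval, reported to 1 decimal (e.g. 598.2/676 -> 0.9)."""
    return round(total_cm / n_bins, 1)
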