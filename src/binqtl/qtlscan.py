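"""Interval-mapping QTL detection with permutation thresholds.

The scan is Haley–Knott regression: at each step along a linkage group the
phenotype is regressed on expected QTL genotype scores computed from the
flanking bins via Kosambi-inverted recombination fractions.  LOD is
(n/2)*log10(RSS0/RSS1); the genome-wide significance threshold is the
(1 - alpha) quantile of max-LOD over phenotype permutations.  Additive and
dominance effects follow the pseudo-testcross conventions:
a = (A - B)/2 for 1:2:1 data and (A - H) for 1:1 data; d = H - (A + B)/2.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .linkmap import GeneticMap, IBDInterval, kosambi_inv
from .matrix import A, B, H, MISSING, GenotypeMatrix


@dataclasses.dataclass
class ScanConfig:
    step_cm: float = 1.0
    n_permutations: int = 10_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.step_cm <= 0:
            raise ValueError("step_cm must be > 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 100:
            warnings.warn("fewer than 100 permutations gives a coarse threshold", stacklevel=2)


@dataclasses.dataclass
class QTLResult:
    """One detected QTL, mirroring the standard report table."""

    trait: str
    year: str | int | None
    map_name: str
    group: int
    position_cm: float
    peak_bins: list[str]
    interval_cm: tuple[float, float]
    interval_bp: tuple[int, int]
    lod: float
    pct_ev: float
    a: float
    d: float | None
    d_over_a: float | None
    action: str
    significant: bool = True


# --------------------------------------------------- genotype probabilities
def _bc_transition(r: float) -> np.ndarray:
    return np.array([[1 - r, r], [r, 1 - r]])


def _f2_transition(r: float) -> np.ndarray:
    p = 1.0 - r
    return np.array(
        [
            [p * p, 2 * p * r, r * r],
            [p * r, p * p + r * r, p * r],
            [r * r, 2 * p * r, p * p],
        ]
    )


_PRIOR = {"BC": np.array([0.5, 0.5]), "F2": np.array([0.25, 0.5, 0.25])}


def qtl_genotype_probs(
    left_calls: np.ndarray,
    right_calls: np.ndarray,
    r_left: float,
    r_right: float,
    design: str = "BC",
) -> np.ndarray:
    """Per-individual QTL genotype probabilities given the flanking bins.

    ``r_left``/``r_right`` are the recombination fractions from the left and
    right flank to the scan position.  A missing flank contributes its prior;
    both missing gives the design prior (1/2,1/2 or 1/4,1/2,1/4).
    Probabilities sum to 1 per individual.
    """
    if design not in _PRIOR:
        raise ValueError("design must be 'BC' or 'F2'")
    prior = _PRIOR[design]
    k = prior.size
    # floor keeps contradictory flanking calls (possible at r = 0 after
    # consensus errors) from producing an all-zero posterior
    r_left = min(max(r_left, 1e-9), 0.5)
    r_right = min(max(r_right, 1e-9), 0.5)
    t_l = _bc_transition(r_left) if design == "BC" else _f2_transition(r_left)
    t_r = _bc_transition(r_right) if design == "BC" else _f2_transition(r_right)
    n = left_calls.shape[0]
    probs = np.empty((n, k))
    left_ok = left_calls != MISSING
    right_ok = right_calls != MISSING
    w_left = np.where(left_ok[:, None], t_l[np.clip(left_calls, 0, k - 1)], prior[None, :])
    w_right = np.where(right_ok[:, None], t_r.T[np.clip(right_calls, 0, k - 1)], np.ones((1, k)))
    # P(q | gL) * P(gR | q); when gL missing use prior over q, when gR missing drop the term
    probs = w_left * w_right
    total = probs.sum(axis=1, keepdims=True)
    degenerate = total[:, 0] <= 0
    if degenerate.any():
        probs[degenerate] = prior
        total = probs.sum(axis=1, keepdims=True)
    probs /= total
    return probs


def _design_scores(probs: np.ndarray, design: str) -> np.ndarray:
    """Expected-score columns for the HK regression.

    BC: one column, P(A-class); fitted coefficient is the A-class minus
    H-class mean, i.e. a = (A - H).  F2: columns [P(A) - P(B), P(H)];
    coefficients are a = (A - B)/2 and d = H - (A + B)/2.
    """
    if design == "BC":
        return probs[:, [0]]
    return np.stack([probs[:, 0] - probs[:, 2], probs[:, 1]], axis=1)


# ------------------------------------------------------------------ scanning
@dataclasses.dataclass
class _Position:
    group: int
    cm: float
    chrom: int
    bp: int
    X: np.ndarray  # (n, k) score columns


def _scan_positions(
    gmap: GeneticMap, onebin: GenotypeMatrix, design: str, step_cm: float
) -> list[_Position]:
    """Precompute score columns at every scan position (grid + bin positions)."""
    name_to_row = {nm: i for i, nm in enumerate(onebin.markers["name"])}
    out: list[_Position] = []
    for g in gmap.groups:
        sub = gmap.group_table(g)
        cms = sub["cm"].to_numpy()
        rows = [name_to_row[nm] for nm in sub["name"]]
        calls = onebin.calls[rows]
        grid = np.union1d(np.arange(0.0, cms.max() + 1e-9, step_cm), cms)
        for pos_cm in grid:
            li = int(np.searchsorted(cms, pos_cm + 1e-12) - 1)
            li = max(li, 0)
            ri = int(np.searchsorted(cms, pos_cm - 1e-12))
            ri = min(ri, len(cms) - 1)
            r_l = float(kosambi_inv(max(pos_cm - cms[li], 0.0)))
            r_r = float(kosambi_inv(max(cms[ri] - pos_cm, 0.0)))
            probs = qtl_genotype_probs(calls[li], calls[ri], r_l, r_r, design)
            # interpolate bp linearly between flanking bins
            if cms[ri] > cms[li]:
                frac = (pos_cm - cms[li]) / (cms[ri] - cms[li])
            else:
                frac = 0.0
            bp = int(round(sub["pos"].iloc[li] + frac * (sub["pos"].iloc[ri] - sub["pos"].iloc[li])))
            out.append(_Position(g, float(pos_cm), int(sub["chrom"].iloc[li]), bp, _design_scores(probs, design)))
    return out


def _fit_position(X: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """RSS under the QTL model, RSS under the null, and coefficients."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss1 = float(resid @ resid)
    rss0 = float(((y - y.mean()) ** 2).sum())
    return rss1, rss0, coef


def scan_interval_mapping(
    gmap: GeneticMap,
    onebin: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    design: str = "BC",
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """LOD / %EV / a / d profile over all linkage groups.

    Individuals with missing phenotypes are dropped.  Returns a frame with
    columns group, cm, chrom, bp, lod, pct_ev, a, d.
    """
    config = config or ScanConfig()
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 20:
        raise ValueError("need at least 20 phenotyped individuals")
    positions = _scan_positions(gmap, onebin, design, config.step_cm)
    yk = y[keep]
    n = yk.shape[0]
    zero_var = float(np.var(yk)) == 0.0
    if zero_var:
        warnings.warn("zero-variance phenotype: all-zero profile", stacklevel=2)
    rows = []
    for p in positions:
        if zero_var:
            lod = pct_ev = a_hat = d_hat = 0.0
        else:
            rss1, rss0, coef = _fit_position(p.X[keep], yk)
            lod = (n / 2) * np.log10(rss0 / rss1) if rss1 > 0 else np.inf
            pct_ev = 100.0 * (1 - rss1 / rss0)
            if design == "BC":
                a_hat, d_hat = float(coef[1]), np.nan
            else:
                a_hat, d_hat = float(coef[1]), float(coef[2])
        rows.append(
            {
                "group": p.group,
                "cm": p.cm,
                "chrom": p.chrom,
                "bp": p.bp,
                "lod": max(float(lod), 0.0),
                "pct_ev": float(np.clip(pct_ev, 0.0, 100.0)),
                "a": a_hat,
                "d": d_hat,
            }
        )
    return pd.DataFrame(rows)


def _max_lod_many(positions: list[_Position], keep: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Genome-wide max LOD for each column of phenotype matrix ``Y`` (n, P).

    Vectorized over phenotype vectors: per position, project the centered
    phenotypes onto an orthonormal basis of [1, X] once via QR.
    """
    n, n_pheno = Y.shape
    Yc = Y - Y.mean(axis=0, keepdims=True)
    rss0 = (Yc**2).sum(axis=0)
    best = np.zeros(n_pheno)
    for p in positions:
        design = np.column_stack([np.ones(n), p.X[keep]])
        q, _ = np.linalg.qr(design)
        proj = q.T @ Y
        rss1 = np.maximum((Y**2).sum(axis=0) - (proj**2).sum(axis=0), 1e-300)
        lod = (n / 2) * np.log10(rss0 / rss1)
        np.maximum(best, lod, out=best)
    return best


def permutation_threshold(
    gmap: GeneticMap,
    onebin: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    design: str = "BC",
    config: ScanConfig | None = None,
) -> float:
    """Genome-wide LOD threshold at ``config.alpha`` from phenotype permutations.

    Phenotype vectors are permuted jointly against the genotypes; the
    empirical (1 - alpha) quantile of the per-permutation max LOD is the
    threshold (alpha = 1 returns the minimum of the max-LODs).
    """
    config = config or ScanConfig()
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    yk = y[keep]
    rng = np.random.default_rng(config.seed)
    positions = _scan_positions(gmap, onebin, design, config.step_cm)
    perms = np.stack([rng.permutation(yk) for _ in range(config.n_permutations)], axis=1)
    max_lods = _max_lod_many(positions, keep, perms)
    if config.alpha >= 1.0:
        return float(max_lods.min())
    return float(np.quantile(max_lods, 1.0 - config.alpha))


# ----------------------------------------------------------- post-processing
def lod_support_interval(
    profile: pd.DataFrame,
    peak_idx: int | None = None,
    drop: float = 1.0,
    ibd_intervals: Sequence[IBDInterval] = (),
) -> tuple[tuple[float, float], tuple[int, int], bool]:
    """LOD-drop support interval of a single-group profile, truncated at IBD.

    Returns ((cm_lo, cm_hi), (bp_lo, bp_hi), spans_group_flag).  The bounds
    are the nearest scan positions left/right of the peak where LOD has
    fallen by ``drop``; if the profile never drops on a side the group end is
    used and the flag is set.  If a bound falls inside an IBD interval, the
    IBD boundary nearest the peak replaces it.
    """
    prof = profile.reset_index(drop=True)
    if prof["group"].nunique() != 1:
        raise ValueError("support interval expects a single-group profile")
    if peak_idx is None:
        peak_idx = int(prof["lod"].idxmax())
    peak_lod = float(prof["lod"].iloc[peak_idx])
    target = peak_lod - drop
    flagged = False

    lo_idx = 0
    below = np.nonzero(prof["lod"].to_numpy()[: peak_idx + 1] <= target)[0]
    if below.size:
        lo_idx = int(below[-1])
    else:
        flagged = True
    hi_idx = len(prof) - 1
    below = np.nonzero(prof["lod"].to_numpy()[peak_idx:] <= target)[0]
    if below.size:
        hi_idx = peak_idx + int(below[0])
    else:
        flagged = True

    cm_lo, cm_hi = float(prof["cm"].iloc[lo_idx]), float(prof["cm"].iloc[hi_idx])
    bp_lo, bp_hi = int(prof["bp"].iloc[lo_idx]), int(prof["bp"].iloc[hi_idx])
    chrom = int(prof["chrom"].iloc[peak_idx])
    peak_bp = int(prof["bp"].iloc[peak_idx])
    for iv in ibd_intervals:
        if iv.chrom != chrom:
            continue
        # right side: interval begins past the peak and before the current bound
        if peak_bp < iv.start <= bp_hi:
            bp_hi = iv.start
        # left side: interval ends before the peak and past the current bound
        if bp_lo <= iv.end < peak_bp:
            bp_lo = iv.end
    return (cm_lo, cm_hi), (bp_lo, bp_hi), flagged


def classify_gene_action(a: float, d: float) -> str:
    """Dominance classification from the d/a ratio.

    |d/a| <= 0.25 -> A (additive); 0.25 < |d/a| <= 0.75 -> PD (partly
    dominant); 0.75 < |d/a| <= 1.25 -> D (dominant); beyond 1.25 -> OD
    (overdominant).  Band-edge ties go to the lower-dominance class;
    a == 0 is unclassifiable ('n/a').
    """
    if a == 0 or not np.isfinite(a) or not np.isfinite(d):
        return "n/a"
    ratio = abs(d / a)
    if ratio <= 0.25:
        return "A"
    if ratio <= 0.75:
        return "PD"
    if ratio <= 1.25:
        return "D"
    return "OD"


def segregation_chi2(
    observed_counts: Sequence[int], expected_ratio: Sequence[float] = (1, 1)
) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against an expected ratio.

    No continuity correction; df = classes - 1.  E.g. (85, 91) against 1:1
    gives chi2 = 0.20.
    """
    obs = np.asarray(observed_counts, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.min() < 0 or ratio.min() <= 0:
        raise ValueError("counts must be >= 0 and ratio strictly positive")
    if obs.sum() == 0:
        raise ValueError("all-zero counts")
    expected = ratio / ratio.sum() * obs.sum()
    chi2, p = stats.chisquare(obs, expected)
    return float(chi2), len(obs) - 1, float(p)


def map_major_gene(
    binary_trait: np.ndarray | pd.Series, onebin: GenotypeMatrix, unlinked_threshold: float = 0.3
) -> tuple[str, float, bool]:
    """Place a Mendelian trait on the map as a pseudo-marker.

    The trait (two classes) is compared with every bin's genotype; the bin
    minimizing the mismatch fraction, allowing a global label swap, is
    reported together with that fraction and a linked flag.
    """
    t = pd.Series(binary_trait).to_numpy()
    classes = pd.unique(t[pd.notna(t)])
    if len(classes) != 2:
        raise ValueError("trait must have exactly two classes")
    coded = np.where(pd.isna(t), MISSING, np.where(t == classes[0], 0, 1)).astype(np.int8)
    best_name, best_frac = None, np.inf
    for i in range(onebin.n_markers):
        g = onebin.calls[i]
        co = (g != MISSING) & (coded != MISSING)
        if co.sum() < 2:
            continue
        gs = g[co]
        states = np.unique(gs)
        # map bin states to 0/1 by rank (BC bins are 2-state)
        gbin = np.searchsorted(states, gs) % 2
        mism = (gbin != coded[co]).mean()
        frac = min(mism, 1 - mism)
        if frac < best_frac:
            best_name, best_frac = onebin.markers["name"].iloc[i], float(frac)
    if best_name is None:
        raise ValueError("no bin with enough co-called individuals")
    return best_name, best_frac, best_frac <= unlinked_threshold


def report_qtls(results_per_map: dict[str, list[QTLResult]]) -> list[QTLResult]:
    """Apply the map-choice reporting rules across the SF, ZP and SF x ZP scans.

    For each (trait, year, group) region: if the QTL is significant in one or
    both parental maps (possibly also the combined map), report the entry
    from the map with the highest LOD; a QTL significant only in the combined
    map is not reported.
    """
    buckets: dict[tuple, dict[str, QTLResult]] = {}
    for map_name, results in results_per_map.items():
        for res in results:
            if not res.significant:
                continue
            key = (res.trait, res.year, res.group)
            buckets.setdefault(key, {})[map_name] = res
    combined_names = {n for n in results_per_map if "x" in n.lower() or "×" in n}
    reported = []
    for key, per_map in buckets.items():
        parental = [n for n in per_map if n not in combined_names]
        if not parental:
            continue  # significant only in the combined map
        best = max(per_map.values(), key=lambda r: r.lod)
        reported.append(best)
    reported.sort(key=lambda r: (r.trait, str(r.year), r.group))
    return reported


# ------------------------------------------------------------ estimator API
class IntervalMapper(BaseEstimator):
    """Haley–Knott interval mapping as a fit-shaped estimator.

    Parameters are the map, design, scan step, permutation count, alpha and
    seed; ``fit(onebin, y)`` computes ``profile_``, ``threshold_`` and
    ``peaks_`` (significant QTLs with support intervals and gene action).
    """

    def __init__(
        self,
        gmap: GeneticMap | None = None,
        design: str = "BC",
        step_cm: float = 1.0,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        seed: int | None = None,
        trait: str = "trait",
        year: str | int | None = None,
        map_name: str = "map",
    ):
        self.gmap = gmap
        self.design = design
        self.step_cm = step_cm
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.seed = seed
        self.trait = trait
        self.year = year
        self.map_name = map_name

    def _config(self) -> ScanConfig:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ScanConfig(self.step_cm, self.n_permutations, self.alpha, self.seed)

    def fit(self, X: GenotypeMatrix, y: np.ndarray) -> "IntervalMapper":
        if self.gmap is None:
            raise ValueError("IntervalMapper requires gmap")
        cfg = self._config()
        self.profile_ = scan_interval_mapping(self.gmap, X, y, self.design, cfg)
        self.threshold_ = permutation_threshold(self.gmap, X, y, self.design, cfg)
        self.peaks_ = self._collect_peaks()
        return self

    def _collect_peaks(self) -> list[QTLResult]:
        peaks = []
        for g in sorted(self.profile_["group"].unique()):
            prof = self.profile_[self.profile_["group"] == g].reset_index(drop=True)
            peak_idx = int(prof["lod"].idxmax())
            row = prof.iloc[peak_idx]
            if row["lod"] < self.threshold_:
                continue
            interval_cm, interval_bp, _ = lod_support_interval(
                prof, peak_idx, ibd_intervals=self.gmap.ibd if self.gmap else ()
            )
            a_hat = float(row["a"])
            d_hat = float(row["d"]) if np.isfinite(row["d"]) else None
            if d_hat is None:
                d_over_a, action = None, "n/a"
            else:
                d_over_a = d_hat / a_hat if a_hat else None
                action = classify_gene_action(a_hat, d_hat)
            peaks.append(
                QTLResult(
                    trait=self.trait,
                    year=self.year,
                    map_name=self.map_name,
                    group=int(g),
                    position_cm=float(row["cm"]),
                    peak_bins=[],
                    interval_cm=interval_cm,
                    interval_bp=interval_bp,
                    lod=float(row["lod"]),
                    pct_ev=float(row["pct_ev"]),
                    a=a_hat,
                    d=d_hat,
                    d_over_a=d_over_a,
                    action=action,
                )
            )
        return peaks
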