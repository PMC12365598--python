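"""Marker binning with double-recombination error filtering.

Dense resequencing genotypes carry enough redundancy that a genuine crossover
is witnessed by a long run of contiguous markers, whereas a genotyping error
shows up as a short run that reverts to the flanking state on both sides (an
apparent double recombination, DR).  A DR is accepted as two real crossovers
only if its run spans at least ``min_markers`` contiguous markers AND at
least ``min_span_bp`` of physical distance; otherwise its calls are flagged
as errors.  Terminal runs (no reversion) are single crossovers and are always
accepted.  Accepted breakpoints, pooled over individuals, cut each chromosome
into bins of markers sharing one segregation pattern; each bin gets one
consensus genotype per individual and is represented by its first marker.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import A, B, H, MISSING, GenotypeMatrix


@dataclasses.dataclass
class DRRule:
    """Acceptance rule for double recombinations (both conditions must hold)."""

    min_markers: int = 2
    min_span_bp: int = 100_000


@dataclasses.dataclass
class PhasedMatrix:
    """A 1:1 dataset with per-marker phase flags.

    ``states`` are {0, 1, -1(missing)}: after phasing, 0/1 consistently label
    the two transmitted haplotypes of the segregating parent along each
    chromosome (up to one global inversion per chromosome).  ``flipped``
    records which markers had their coding inverted; flipping twice restores
    the input.
    """

    markers: pd.DataFrame
    individuals: list[str]
    states: np.ndarray
    flipped: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclasses.dataclass
class Bin:
    """A physically contiguous run of markers sharing one segregation pattern."""

    chrom: int
    start: int
    end: int
    members: list[str]
    representative: str
    n_markers: int


@dataclasses.dataclass
class BinningResult:
    bins: list[Bin]
    #: (n_bins, n_individuals) consensus states
    consensus: np.ndarray
    #: (n_markers, n_individuals) calls flagged as errors by the DR rule
    error_mask: np.ndarray
    markers: pd.DataFrame
    individuals: list[str]


def _to_states(matrix: GenotypeMatrix, design: str) -> np.ndarray:
    """1:1 matrices use {0: parental hom (A), 1: het}; F2 keeps {A,H,B}."""
    calls = matrix.offspring_calls().astype(np.int8)
    if design == "BC":
        out = calls.copy()
        out[(calls != MISSING) & (calls > 1)] = MISSING  # stray B: should not occur post-split
        return out
    return calls


# ------------------------------------------------------------------ phasing
def phase_markers(matrix: GenotypeMatrix, design: str = "BC") -> PhasedMatrix:
    """Align the 0/1 coding of a 1:1 dataset along each chromosome.

    Greedy pass in physical order: a marker's coding is flipped iff more than
    half of the co-called individuals disagree with the previous accepted
    (phased) marker; ties keep the current phase.  1:2:1 data are never
    phased — pass them straight to :func:`build_bins`.
    """
    if design != "BC":
        raise ValueError("phasing applies to 1:1 (BC) datasets only")
    states = _to_states(matrix, "BC")
    flipped = np.zeros(matrix.n_markers, dtype=bool)
    chrom_arr = matrix.markers["chrom"].to_numpy()
    for c in np.unique(chrom_arr):
        idx = np.nonzero(chrom_arr == c)[0]
        if idx.size < 2:
            warnings.warn(f"chromosome {c} has <2 markers; phasing skipped", stacklevel=2)
            continue
        prev = None
        for i in idx:
            row = states[i]
            if prev is None:
                prev = row
                continue
            co = (row != MISSING) & (prev != MISSING)
            if co.any():
                mismatch = float((row[co] != prev[co]).mean())
                if mismatch > 0.5:
                    row = np.where(row == MISSING, MISSING, 1 - row).astype(np.int8)
                    states[i] = row
                    flipped[i] = True
            prev = row
    off_names = matrix.offspring
    return PhasedMatrix(matrix.markers.copy(), off_names, states, flipped)


def drop_divergent(
    phased: PhasedMatrix, max_divergence: float = 0.2, window: int = 5
) -> tuple[PhasedMatrix, list[str]]:
    """Discard markers disagreeing with the local phased consensus.

    Automates the manual curation step of removing markers with obvious
    genotype divergence: for each marker, the local consensus is the
    per-individual majority state over a +/- ``window`` marker neighbourhood
    (same chromosome); markers whose calls disagree with it in more than
    ``max_divergence`` of co-called individuals are dropped.
    """
    m, n = phased.states.shape
    chrom_arr = phased.markers["chrom"].to_numpy()
    drop = np.zeros(m, dtype=bool)
    for c in np.unique(chrom_arr):
        idx = np.nonzero(chrom_arr == c)[0]
        sub = phased.states[idx]
        for k, i in enumerate(idx):
            lo, hi = max(0, k - window), min(len(idx), k + window + 1)
            neigh = np.delete(sub[lo:hi], k - lo, axis=0)
            if neigh.size == 0:
                continue
            ones = (neigh == 1).sum(axis=0)
            zeros = (neigh == 0).sum(axis=0)
            consensus = np.where(ones > zeros, 1, np.where(zeros > ones, 0, MISSING)).astype(np.int8)
            co = (phased.states[i] != MISSING) & (consensus != MISSING)
            if co.any() and float((phased.states[i][co] != consensus[co]).mean()) > max_divergence:
                drop[i] = True
    kept = PhasedMatrix(
        phased.markers.loc[~drop].reset_index(drop=True),
        list(phased.individuals),
        phased.states[~drop].copy(),
        phased.flipped[~drop].copy(),
    )
    return kept, list(phased.markers.loc[drop, "name"])


# ------------------------------------------------------- breakpoint detection
@dataclasses.dataclass
class BreakpointResult:
    """One individual's accepted breakpoints and error calls on one chromosome.

    ``breakpoints`` are (left_idx, right_idx) pairs of marker indices (into
    the chromosome's marker vector) bracketing each accepted recombination.
    """

    breakpoints: list[tuple[int, int]]
    error_mask: np.ndarray


def detect_breakpoints(
    states: np.ndarray, positions: np.ndarray, rule: DRRule | None = None
) -> BreakpointResult:
    """Scan one individual's ordered state sequence for real recombinations.

    A maximal same-state run that deviates from the current accepted state and
    reverts to it afterwards is a DR candidate, accepted only if it has
    >= ``rule.min_markers`` markers and spans >= ``rule.min_span_bp``; a
    rejected candidate's calls are flagged as errors.  A deviation followed by
    a *different* third state (possible for 1:2:1 data, e.g. an A<->B
    transition with the intervening H unobserved) is a genuine transition and
    is kept.  Terminal runs (including the leading one) are single
    recombinations and carry no span evidence, so only the marker-count rule
    applies to them: a terminal run shorter than ``min_markers`` is flagged
    as error — a recombination must be witnessed by at least two contiguous
    markers wherever it falls.
    """
    rule = rule or DRRule()
    states = np.asarray(states)
    positions = np.asarray(positions)
    errors = np.zeros(states.shape[0], dtype=bool)
    obs_idx = np.nonzero(states != MISSING)[0]
    if obs_idx.size == 0:
        return BreakpointResult([], errors)
    s = states[obs_idx]
    # maximal runs over the observed sequence
    change = np.nonzero(np.diff(s) != 0)[0]
    run_starts = np.concatenate([[0], change + 1])
    run_ends = np.concatenate([change, [len(s) - 1]])  # inclusive
    run_states = s[run_starts]
    run_lens = run_ends - run_starts + 1
    n_runs = len(run_starts)

    # initial accepted state: the first run long enough to be trusted
    # (a short leading run is indistinguishable from an error)
    trusted = np.nonzero(run_lens >= rule.min_markers)[0]
    cur_state = run_states[trusted[0]] if trusted.size else run_states[0]

    breakpoints: list[tuple[int, int]] = []
    last_accepted: int | None = None
    for r in range(n_runs):
        st, en = run_starts[r], run_ends[r]
        state = run_states[r]
        if state == cur_state:
            last_accepted = int(obs_idx[en])
            continue
        is_terminal = r == n_runs - 1
        reverts = (not is_terminal) and run_states[r + 1] == cur_state
        n_markers = en - st + 1
        if is_terminal or not reverts:
            accept = n_markers >= rule.min_markers
        else:
            span = positions[obs_idx[en]] - positions[obs_idx[st]]
            accept = n_markers >= rule.min_markers and span >= rule.min_span_bp
        if accept:
            if last_accepted is not None:
                breakpoints.append((last_accepted, int(obs_idx[st])))
            cur_state = state
            last_accepted = int(obs_idx[en])
        else:
            errors[obs_idx[st : en + 1]] = True
    return BreakpointResult(breakpoints, errors)


# ---------------------------------------------------------------------- bins
def build_bins(
    data: PhasedMatrix | GenotypeMatrix,
    rule: DRRule | None = None,
    design: str = "BC",
) -> BinningResult:
    """Cut chromosomes at the union of accepted breakpoints and infer bin
    consensus genotypes.

    Bin boundaries are placed before the first marker of each accepted new
    run, pooled over individuals.  Within a bin, an individual's consensus is
    the majority of its non-error, non-missing calls (ties and empty sets
    give missing).
    """
    rule = rule or DRRule()
    if isinstance(data, PhasedMatrix):
        markers, individuals, states = data.markers, data.individuals, data.states
    else:
        markers, individuals = data.markers, data.offspring
        states = _to_states(data, design)
    m, n = states.shape
    if m == 0:
        raise ValueError("no markers to bin")
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    error_mask = np.zeros((m, n), dtype=bool)

    bins: list[Bin] = []
    consensus_rows: list[np.ndarray] = []
    for c in pd.unique(chrom_arr):
        idx = np.nonzero(chrom_arr == c)[0]
        cuts: set[int] = set()
        for j in range(n):
            res = detect_breakpoints(states[idx, j], pos_arr[idx], rule)
            error_mask[idx, j] = res.error_mask
            for _, right in res.breakpoints:
                cuts.add(right)
        starts = [0] + sorted(cuts)
        bounds = starts + [len(idx)]
        for k in range(len(bounds) - 1):
            member_idx = idx[bounds[k] : bounds[k + 1]]
            sub = states[member_idx]
            err = error_mask[member_idx]
            valid = (sub != MISSING) & ~err
            cons = np.full(n, MISSING, dtype=np.int8)
            cand_states = (0, 1) if design == "BC" else (A, H, B)
            counts = np.stack([((sub == st) & valid).sum(axis=0) for st in cand_states])
            best = counts.argmax(axis=0)
            top = counts.max(axis=0)
            runner = np.sort(counts, axis=0)[-2] if counts.shape[0] > 1 else np.zeros(n, dtype=int)
            ok = (top > 0) & (top > runner)  # tie or no data -> missing
            cons[ok] = np.asarray(cand_states, dtype=np.int8)[best[ok]]
            names = list(markers["name"].iloc[member_idx])
            bins.append(
                Bin(
                    chrom=int(c),
                    start=int(pos_arr[member_idx[0]]),
                    end=int(pos_arr[member_idx[-1]]),
                    members=names,
                    representative=names[0],
                    n_markers=len(names),
                )
            )
            consensus_rows.append(cons)
    consensus = np.vstack(consensus_rows)
    return BinningResult(bins, consensus, error_mask, markers, list(individuals))


def make_onebin(result: BinningResult, parents: tuple[str, str] | None = None) -> GenotypeMatrix:
    """One-marker-per-bin matrix named by each bin's representative marker.

    The representative's missing or contradictory calls are replaced by the
    bin majority (the consensus already encodes that rule); in single-marker
    bins, a call flagged as a rejected DR has no remaining support and comes
    out missing.
    """
    rows = []
    for b in result.bins:
        chrom = b.chrom
        pos = int(b.representative.split("_")[-1])
        rows.append({"name": b.representative, "chrom": chrom, "pos": pos})
    markers = pd.DataFrame(rows)
    return GenotypeMatrix(markers, list(result.individuals), result.consensus.copy(), parents=None)


def count_apparent_recombinations(calls: np.ndarray, chrom: np.ndarray) -> float:
    """Mean number of adjacent-marker state changes per individual.

    Computed over non-missing adjacent pairs within chromosomes; on unbinned
    noisy data this count is inflated by genotyping errors, which is the
    motivation for binning.
    """
    total = 0
    n = calls.shape[1]
    for c in np.unique(chrom):
        sub = calls[chrom == c]
        for j in range(n):
            col = sub[:, j]
            obs = col[col != MISSING]
            if obs.size >= 2:
                total += int((np.diff(obs) != 0).sum())
    return total / n


class BinGenotyper(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: raw testcross matrix -> one-bin matrix.

    Pipelines phasing (BC only), optional divergent-marker removal,
    DR-filtered breakpoint detection, and bin consensus calling.  After
    ``transform``, ``bins_``, ``error_mask_`` and (for BC) ``flips_`` hold
    the intermediate artifacts.
    """

    def __init__(
        self,
        design: str = "BC",
        min_dr_markers: int = 2,
        min_dr_span_bp: int = 100_000,
        phase: bool = True,
        drop_divergent_markers: bool = True,
        max_divergence: float = 0.2,
        divergence_window: int = 5,
    ):
        self.design = design
        self.min_dr_markers = min_dr_markers
        self.min_dr_span_bp = min_dr_span_bp
        self.phase = phase
        self.drop_divergent_markers = drop_divergent_markers
        self.max_divergence = max_divergence
        self.divergence_window = divergence_window

    def fit(self, X: GenotypeMatrix, y=None) -> "BinGenotyper":
        if self.design not in ("BC", "F2"):
            raise ValueError("design must be 'BC' or 'F2'")
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        rule = DRRule(self.min_dr_markers, self.min_dr_span_bp)
        if self.design == "BC" and self.phase:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                phased = phase_markers(X, "BC")
            self.flips_ = phased.flipped
            if self.drop_divergent_markers:
                phased, self.divergent_dropped_ = drop_divergent(
                    phased, self.max_divergence, self.divergence_window
                )
            result = build_bins(phased, rule, design="BC")
        else:
            result = build_bins(X, rule, design=self.design)
        self.bins_ = result.bins
        self.error_mask_ = result.error_mask
        self.result_ = result
        return make_onebin(result)
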