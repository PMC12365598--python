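"""Marker filtering cascade, AHB recoding, and pseudo-testcross splitting.

The cascade runs in a fixed order — biallelic (at load) -> informative ->
Mendelian masking -> offspring missingness -> segregation — and is idempotent.
Filtered matrices are then split by the pseudo-testcross strategy into the two
1:1 parental datasets (markers heterozygous in exactly one parent) and the
1:2:1 combined dataset (heterozygous in both parents).
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import A, B, H, MISSING, GenotypeMatrix, mendelian_allowed


@dataclasses.dataclass
class FilterConfig:
    """Thresholds of the filtering cascade.

    A marker is dropped when its offspring missing fraction *exceeds*
    ``max_offspring_missing`` (a marker at exactly the threshold is kept),
    when f(A) > ``fa_max`` or f(A) < ``fa_min``, or when f(H) < ``fh_min``,
    with genotype frequencies computed among non-missing offspring.
    """

    max_offspring_missing: float = 0.20
    fa_max: float = 0.9
    fa_min: float = 0.1
    fh_min: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa_min < self.fa_max <= 1.0:
            raise ValueError("need 0 <= fa_min < fa_max <= 1")
        if not 0.0 <= self.max_offspring_missing <= 1.0:
            raise ValueError("max_offspring_missing must be in [0, 1]")


@dataclasses.dataclass
class TestcrossDatasets:
    """The three pseudo-testcross marker sets.

    ``sf_set``: heterozygous only in parent 1 (1:1 segregation, offspring
    states hom/het); ``zp_set``: heterozygous only in parent 2; ``f2_set``:
    heterozygous in both parents (1:2:1, states A/H/B).  The three sets are
    disjoint by construction.  In the 1:1 sets, calls are recoded to
    {0: homozygote matching the non-segregating parent, 1: heterozygote};
    any residual third state is set missing.
    """

    sf_set: GenotypeMatrix
    zp_set: GenotypeMatrix
    f2_set: GenotypeMatrix


def load_genotypes(
    path: str | os.PathLike, fmt: str | None = None, parents: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Read genotypes from VCF (biallelic records only) or TSV."""
    if fmt is None:
        name = str(path).lower()
        fmt = "vcf" if name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return GenotypeMatrix.from_vcf(path, parents=parents)
    if fmt == "tsv":
        return GenotypeMatrix.from_tsv(path, parents=parents)
    raise ValueError(f"unknown genotype format {fmt!r}")


def drop_uninformative(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Keep markers with both parental calls present and >=1 heterozygous parent."""
    pg = matrix.parent_calls()
    keep = (pg != MISSING).all(axis=1) & (pg == H).any(axis=1)
    return matrix.subset_markers(keep)


def recode_ahb(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Orient AHB codes so that, for markers with one homozygous parent, the
    homozygous parent carries A.

    Raw VCF coding labels the reference homozygote A; orientation makes the
    genotype-frequency rules of :func:`segregation_filter` meaningful for 1:1
    markers regardless of which alternative allele the homozygous parent
    carries.  Markers heterozygous in both parents are left in reference
    orientation.  The recode is an involution-free normalization: re-running
    it is a no-op.
    """
    out = matrix.copy()
    pg = out.parent_calls()
    one_het = ((pg == H).sum(axis=1) == 1) & (pg != MISSING).all(axis=1)
    hom_code = np.where(pg[:, 0] == H, pg[:, 1], pg[:, 0])
    swap = one_het & (hom_code == B)
    sub = out.calls[swap]
    flipped = np.where(sub == A, B, np.where(sub == B, A, sub))
    out.calls[swap] = flipped.astype(np.int8)
    return out


def mendelian_mask(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set offspring calls inconsistent with the parental pair to missing.

    Returns the masked matrix and the number of calls masked.
    """
    out = matrix.copy()
    pg = out.parent_calls()
    off = out.offspring_idx
    n_masked = 0
    # 3x3 parental combinations only; build an allowed-lookup per combo
    for p1 in (A, H, B, MISSING):
        for p2 in (A, H, B, MISSING):
            rows = np.nonzero((pg[:, 0] == p1) & (pg[:, 1] == p2))[0]
            if rows.size == 0:
                continue
            allowed = mendelian_allowed(p1, p2)
            block = out.calls[np.ix_(rows, off)]
            bad = (block != MISSING) & ~np.isin(block, list(allowed))
            n_masked += int(bad.sum())
            block[bad] = MISSING
            out.calls[np.ix_(rows, off)] = block
    return out, n_masked


def missingness_filter(matrix: GenotypeMatrix, config: FilterConfig | None = None) -> GenotypeMatrix:
    """Drop markers whose offspring missing fraction exceeds the threshold."""
    config = config or FilterConfig()
    off = matrix.offspring_calls()
    frac = (off == MISSING).mean(axis=1) if off.shape[1] else np.zeros(matrix.n_markers)
    return matrix.subset_markers(frac <= config.max_offspring_missing)


def segregation_filter(matrix: GenotypeMatrix, config: FilterConfig | None = None) -> GenotypeMatrix:
    """Drop monomorphic-in-progeny and severely distorted markers.

    Rules, applied among non-missing offspring: a single observed genotype
    class; f(A) > fa_max or f(A) < fa_min; f(H) < fh_min.
    """
    config = config or FilterConfig()
    off = matrix.offspring_calls()
    observed = off != MISSING
    n_obs = observed.sum(axis=1)
    zero_obs = n_obs == 0
    if zero_obs.any():
        warnings.warn(f"{int(zero_obs.sum())} markers have no non-missing offspring; dropped", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = (off == A).sum(axis=1) / n_obs
        fh = (off == H).sum(axis=1) / n_obs
    n_classes = ((off == A).any(axis=1).astype(int) + (off == H).any(axis=1).astype(int) + (off == B).any(axis=1).astype(int))
    keep = (
        ~zero_obs
        & (n_classes >= 2)
        & (fa <= config.fa_max)
        & (fa >= config.fa_min)
        & (fh >= config.fh_min)
    )
    return matrix.subset_markers(keep)


def filter_cascade(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Run the full cascade; returns the filtered matrix and a removal report."""
    config = config or FilterConfig()
    report = {"input": matrix.n_markers}
    m = drop_uninformative(matrix)
    report["uninformative_removed"] = report["input"] - m.n_markers
    m = recode_ahb(m)
    m, n_masked = mendelian_mask(m)
    report["mendelian_calls_masked"] = n_masked
    before = m.n_markers
    m = missingness_filter(m, config)
    report["missingness_removed"] = before - m.n_markers
    before = m.n_markers
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = segregation_filter(m, config)
    report["segregation_removed"] = before - m.n_markers
    report["retained"] = m.n_markers
    return m, report


def split_testcross(matrix: GenotypeMatrix) -> TestcrossDatasets:
    """Split a filtered matrix into the sf (P1-het), zp (P2-het), and f2 sets."""
    pg = matrix.parent_calls()
    p1_het = pg[:, 0] == H
    p2_het = pg[:, 1] == H
    sf = matrix.subset_markers(p1_het & ~p2_het)
    zp = matrix.subset_markers(~p1_het & p2_het)
    f2 = matrix.subset_markers(p1_het & p2_het)

    for sub in (sf, zp):
        off = sub.offspring_idx
        block = sub.calls[:, off]
        # after recode_ahb the non-segregating parent's homozygote class is A;
        # offspring are A (parental hom) or H; any stray B should have been
        # Mendelian-masked — set it missing.
        block[block == B] = MISSING
        sub.calls[:, off] = block
    return TestcrossDatasets(sf_set=sf, zp_set=zp, f2_set=f2)


class MarkerFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping the filtering cascade.

    ``transform`` applies the cascade and records the removal counts in
    ``report_``.  Stateless across inputs: ``fit`` only validates parameters.
    """

    def __init__(
        self,
        max_offspring_missing: float = 0.20,
        fa_max: float = 0.9,
        fa_min: float = 0.1,
        fh_min: float = 0.15,
    ):
        self.max_offspring_missing = max_offspring_missing
        self.fa_max = fa_max
        self.fa_min = fa_min
        self.fh_min = fh_min

    def _config(self) -> FilterConfig:
        return FilterConfig(self.max_offspring_missing, self.fa_max, self.fa_min, self.fh_min)

    def fit(self, X: GenotypeMatrix, y=None) -> "MarkerFilter":
        self._config()  # parameter validation
        if X.parents is None:
            raise ValueError("MarkerFilter needs a GenotypeMatrix with flagged parents")
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        out, self.report_ = filter_cascade(X, self._config())
        return out


def write_report(report: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
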