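"""Genotype matrix container and I/O.

Genotypes are held as a dense ``markers x individuals`` array of small integer
codes in AHB terminology: A and B are the homozygotes for the two alternative
alleles, H is the heterozygote, and missing data is ``-1``.  Markers carry a
chromosome, a 1-based physical position, and a name of the form
``Pp{chrom:02d}_{pos}``.  The two parents of the F1 cross, when present, are
ordinary columns flagged by name.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

A = 0
H = 1
B = 2
MISSING = -1

CODE_TO_CHAR = {A: "A", H: "H", B: "B", MISSING: "-"}
CHAR_TO_CODE = {"A": A, "H": H, "B": B, "-": MISSING, ".": MISSING, "NA": MISSING, "U": MISSING}

#: diploid genotype -> set of gamete alleles it can transmit (0 = A allele, 1 = B allele)
_GAMETES = {A: (0,), H: (0, 1), B: (1,)}


def marker_name(chrom: int, pos: int) -> str:
    """Standard marker name, e.g. ``marker_name(6, 13387856) == 'Pp06_13387856'``."""
    return f"Pp{int(chrom):02d}_{int(pos)}"


@dataclasses.dataclass
class GenotypeMatrix:
    """Markers x individuals genotype calls in AHB coding.

    Parameters
    ----------
    markers : DataFrame with columns ``name``, ``chrom`` (int), ``pos`` (1-based int),
        one row per marker, in physical order.
    individuals : ordered sample names.
    calls : int8 array of shape (n_markers, n_individuals) with codes
        {0: A, 1: H, 2: B, -1: missing}.
    parents : optional (name_parent1, name_parent2); both must be in
        ``individuals``.
    """

    markers: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )
        if self.markers["name"].duplicated().any():
            dup = self.markers.loc[self.markers["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            bad = np.nonzero(np.diff(pos) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}: "
                    f"marker {sub['name'].iloc[bad[0] + 1]}"
                )
        if self.parents is not None:
            for p in self.parents:
                if p not in self.individuals:
                    raise ValueError(f"parent {p!r} not among individuals")

    # ------------------------------------------------------------------ shape
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def parent_idx(self) -> tuple[int, int]:
        if self.parents is None:
            raise ValueError("no parents flagged on this matrix")
        return (self.individuals.index(self.parents[0]), self.individuals.index(self.parents[1]))

    @property
    def offspring_idx(self) -> np.ndarray:
        if self.parents is None:
            return np.arange(self.n_individuals)
        pidx = set(self.parent_idx)
        return np.array([i for i in range(self.n_individuals) if i not in pidx], dtype=int)

    @property
    def offspring(self) -> list[str]:
        keep = self.offspring_idx
        return [self.individuals[i] for i in keep]

    def offspring_calls(self) -> np.ndarray:
        return self.calls[:, self.offspring_idx]

    def parent_calls(self) -> np.ndarray:
        """(n_markers, 2) array of the two parental call vectors."""
        i1, i2 = self.parent_idx
        return self.calls[:, [i1, i2]]

    # ------------------------------------------------------------- selection
    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask or index array over markers."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return GenotypeMatrix(
            markers=self.markers.iloc[keep].reset_index(drop=True),
            individuals=list(self.individuals),
            calls=self.calls[keep].copy(),
            parents=self.parents,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.markers.copy(), list(self.individuals), self.calls.copy(), self.parents)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.markers.equals(other.markers)
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
            and self.parents == other.parents
        )

    # ------------------------------------------------------------------- I/O
    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write as TSV: columns marker, chrom, pos, then one column per individual."""
        df = pd.DataFrame(
            {"marker": self.markers["name"], "chrom": self.markers["chrom"], "pos": self.markers["pos"]}
        )
        chars = np.vectorize(CODE_TO_CHAR.get)(self.calls) if self.n_markers else np.empty((0, self.n_individuals))
        for j, ind in enumerate(self.individuals):
            df[ind] = chars[:, j] if self.n_markers else []
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, parents: Sequence[str] | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"marker": str})
        if df.empty and df.columns.size == 0:
            raise ValueError(f"empty genotype file: {path}")
        fixed = ["marker", "chrom", "pos"]
        for col in fixed:
            if col not in df.columns:
                raise ValueError(f"TSV genotype file must have a {col!r} column")
        individuals = [c for c in df.columns if c not in fixed]
        calls = np.full((len(df), len(individuals)), MISSING, dtype=np.int8)
        for j, ind in enumerate(individuals):
            col = df[ind].astype(str).str.strip()
            calls[:, j] = [CHAR_TO_CODE.get(v, MISSING) for v in col]
        markers = pd.DataFrame(
            {"name": df["marker"], "chrom": df["chrom"].astype(int), "pos": df["pos"].astype(int)}
        )
        return cls(markers, individuals, calls, tuple(parents) if parents else None)

    @classmethod
    def from_vcf(cls, path: str | os.PathLike, parents: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Read a multi-sample VCF, keeping biallelic SNP records only.

        Multiallelic records are dropped.  Genotypes are mapped ref-hom -> A,
        het -> H, alt-hom -> B.  Chromosome labels may be plain integers or
        carry a ``Pp``/``chr`` prefix.
        """
        from cyvcf2 import VCF

        if os.path.getsize(path) == 0:
            raise ValueError(f"empty VCF file: {path}")
        vcf = VCF(str(path), gts012=True)
        individuals = list(vcf.samples)
        if parents:
            for p in parents:
                if p not in individuals:
                    raise ValueError(f"parent column {p!r} missing from VCF samples")
        names, chroms, poss, rows = [], [], [], []
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            chrom = _parse_chrom(v.CHROM)
            gt = np.asarray(v.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING
            names.append(marker_name(chrom, v.POS))
            chroms.append(chrom)
            poss.append(v.POS)
            rows.append(gt)
        if not rows:
            raise ValueError(f"no biallelic records in VCF: {path}")
        markers = pd.DataFrame({"name": names, "chrom": chroms, "pos": poss})
        return cls(markers, individuals, np.vstack(rows), tuple(parents) if parents else None)

    def to_vcf(self, path: str | os.PathLike, chrom_lengths: dict[int, int] | None = None) -> None:
        """Write a minimal VCF 4.2 with GT-only biallelic records (REF=A, ALT=T)."""
        gt_str = {A: "0/0", H: "0/1", B: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = sorted(set(int(c) for c in self.markers["chrom"]))
            for c in chroms:
                if chrom_lengths and c in chrom_lengths:
                    fh.write(f"##contig=<ID={c},length={int(chrom_lengths[c])}>\n")
                else:
                    fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.individuals) + "\n")
            for i in range(self.n_markers):
                row = self.markers.iloc[i]
                gts = "\t".join(gt_str[int(g)] for g in self.calls[i])
                fh.write(f"{int(row.chrom)}\t{int(row.pos)}\t{row['name']}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _parse_chrom(label: str) -> int:
    digits = "".join(ch for ch in str(label) if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot parse chromosome label {label!r}")
    return int(digits)


def mendelian_allowed(p1: int, p2: int) -> frozenset[int]:
    """Set of offspring AHB codes consistent with the two parental codes.

    Derived from gamete transmission: each parent passes one of its alleles.
    Parents with a missing call allow everything.
    """
    if p1 == MISSING or p2 == MISSING:
        return frozenset({A, H, B})
    return frozenset(a1 + a2 for a1 in _GAMETES[p1] for a2 in _GAMETES[p2])
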