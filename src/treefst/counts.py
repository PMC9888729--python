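"""Allele-count matrices: loading, validation, pooling.

The basic data unit is a *unit*: either a population sample of ``n_k``
gametes or a single diploid individual treated as a population of two
gametes.  Counts are per-locus copies of one of the two alleles at a
diallelic site; all downstream statistics use ``p (1 - p)`` forms and are
invariant to which allele is counted.  The VCF reader counts the ALT
allele, the TSV reader whatever the file's producer counted — documented,
not configurable.

Missing data is supported per cell; pairwise statistics later restrict to
loci observed in both members of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountMatrix",
    "load_counts_table",
    "write_counts_table",
    "diploids_to_units",
    "pool_units",
    "from_vcf",
]


@dataclass
class AlleleCountMatrix:
    """Per-locus reference-allele counts and gamete totals for K units.

    Attributes
    ----------
    unit_labels : list of str
        K distinct unit names (populations or individuals).
    loci : list of str
        m distinct locus identifiers.
    ref_count : (m, K) int array
        Copies of the counted allele; values at missing cells are ignored.
    n_gametes : (m, K) int array
        Gametes sampled (2 for a diploid individual); may vary by locus.
    missing : (m, K) bool array
        True where no data is available.
    """

    unit_labels: list[str]
    loci: list[str]
    ref_count: np.ndarray
    n_gametes: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.n_gametes = np.asarray(self.n_gametes, dtype=np.int64)
        m, k = self.ref_count.shape
        if self.missing is None:
            self.missing = np.zeros((m, k), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.n_gametes.shape != (m, k) or self.missing.shape != (m, k):
            raise ValueError("ref_count, n_gametes and missing shapes differ")
        if len(self.unit_labels) != k:
            raise ValueError("unit_labels length does not match columns")
        if len(self.loci) != m:
            raise ValueError("loci length does not match rows")
        if len(set(self.unit_labels)) != k:
            raise ValueError("duplicate unit labels")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus identifiers")
        if k < 2:
            raise ValueError("need at least two units")
        obs = ~self.missing
        if np.any(self.ref_count[obs] < 0):
            raise ValueError("negative allele count")
        if np.any(self.n_gametes[obs] < 2):
            i, j = np.argwhere(obs & (self.n_gametes < 2))[0]
            raise ValueError(
                f"unit {self.unit_labels[j]!r} has fewer than 2 gametes at "
                f"locus {self.loci[i]!r}"
            )
        if np.any(self.ref_count[obs] > self.n_gametes[obs]):
            i, j = np.argwhere(obs & (self.ref_count > self.n_gametes))[0]
            raise ValueError(
                f"count exceeds gametes at locus {self.loci[i]!r}, "
                f"unit {self.unit_labels[j]!r}"
            )

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def frequencies(self) -> np.ndarray:
        """Sample allele frequencies p-hat; NaN at missing cells."""
        with np.errstate(invalid="ignore"):
            p = self.ref_count / self.n_gametes
        return np.where(self.missing, np.nan, p)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        obs = ~self.missing
        return (
            self.unit_labels == other.unit_labels
            and self.loci == other.loci
            and np.array_equal(self.missing, other.missing)
            and np.array_equal(self.ref_count[obs], other.ref_count[~other.missing])
            and np.array_equal(self.n_gametes[obs], other.n_gametes[~other.missing])
        )


def load_counts_table(path: str | Path) -> AlleleCountMatrix:
    """Read the counts-TSV dialect.

    Header is ``locus`` followed by ``<unit>_ref`` / ``<unit>_n`` column
    pairs; one locus per body row; literal ``NA`` marks a missing cell
    (both columns of the pair must then be NA).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"],
                     keep_default_na=False)
    if df.columns[0] != "locus":
        raise ValueError(f"{path}: first header column must be 'locus'")
    cols = list(df.columns[1:])
    if len(cols) % 2:
        raise ValueError(f"{path}: expected <unit>_ref/<unit>_n column pairs")
    labels: list[str] = []
    for i in range(0, len(cols), 2):
        rc, nc = cols[i], cols[i + 1]
        if not (rc.endswith("_ref") and nc.endswith("_n")):
            raise ValueError(f"{path}: malformed header pair {rc!r}/{nc!r}")
        if rc[:-4] != nc[:-2]:
            raise ValueError(f"{path}: header pair {rc!r}/{nc!r} names differ")
        labels.append(rc[:-4])
    loci = df["locus"].tolist()
    body = df[cols]
    missing = body.isna().to_numpy()[:, 0::2] | body.isna().to_numpy()[:, 1::2]
    vals = body.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    ref = np.nan_to_num(vals[:, 0::2]).astype(np.int64)
    n = vals[:, 1::2]
    n = np.where(np.isnan(n), 2, n).astype(np.int64)  # placeholder at missing
    return AlleleCountMatrix(labels, loci, ref, n, missing)


def write_counts_table(acm: AlleleCountMatrix, path: str | Path) -> None:
    """Write the counts-TSV dialect (inverse of :func:`load_counts_table`)."""
    cols: dict[str, object] = {"locus": acm.loci}
    for j, lab in enumerate(acm.unit_labels):
        ref = acm.ref_count[:, j].astype(object)
        n = acm.n_gametes[:, j].astype(object)
        miss = acm.missing[:, j]
        ref[miss] = "NA"
        n[miss] = "NA"
        cols[f"{lab}_ref"] = ref
        cols[f"{lab}_n"] = n
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def diploids_to_units(
    genotypes: np.ndarray,
    labels: Sequence[str],
    loci: Sequence[str] | None = None,
) -> AlleleCountMatrix:
    """Treat diploid individuals as populations of two gametes.

    ``genotypes`` is an (m, I) matrix of counted-allele copies coded
    0/1/2, with NaN (or a masked value < 0) for a missing genotype.
    """
    g = np.asarray(genotypes, dtype=float)
    missing = ~np.isfinite(g) | (g < 0)
    vals = np.where(missing, 0, g)
    if not np.isin(vals, (0.0, 1.0, 2.0)).all():
        bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
        raise ValueError(f"genotype value {bad} outside {{0, 1, 2}}")
    m = g.shape[0]
    if loci is None:
        loci = [f"L{i + 1}" for i in range(m)]
    n = np.full(g.shape, 2, dtype=np.int64)
    return AlleleCountMatrix(list(labels), list(loci), vals.astype(np.int64), n, missing)


def pool_units(acm: AlleleCountMatrix, grouping: Mapping[str, str]) -> AlleleCountMatrix:
    """Pool units into groups by summing counts and gametes per locus.

    A group is missing at a locus only if *all* members are missing there;
    otherwise counts come from the observed members.
    """
    for u in acm.unit_labels:
        if u not in grouping:
            raise ValueError(f"grouping does not cover unit {u!r}")
    for u in grouping:
        if u not in acm.unit_labels:
            raise ValueError(f"unknown unit label {u!r} in grouping")
    groups: dict[str, list[int]] = {}
    for j, u in enumerate(acm.unit_labels):
        groups.setdefault(grouping[u], []).append(j)
    if any(not idx for idx in groups.values()):
        raise ValueError("empty group")
    labels = list(groups)
    m = acm.n_loci
    ref = np.zeros((m, len(labels)), dtype=np.int64)
    n = np.zeros_like(ref)
    miss = np.zeros(ref.shape, dtype=bool)
    obs = ~acm.missing
    for gj, lab in enumerate(labels):
        idx = groups[lab]
        o = obs[:, idx]
        ref[:, gj] = np.where(o, acm.ref_count[:, idx], 0).sum(axis=1)
        n[:, gj] = np.where(o, acm.n_gametes[:, idx], 0).sum(axis=1)
        miss[:, gj] = ~o.any(axis=1)
    n[miss] = 2  # placeholder; cell is masked
    return AlleleCountMatrix(labels, list(acm.loci), ref, n, miss)


def from_vcf(
    path: str | Path,
    popmap: Mapping[str, str] | str | Path | None = None,
) -> AlleleCountMatrix:
    """Convert diallelic SNVs from a VCF into an allele-count matrix.

    Counts ALT-allele copies per sample.  ``popmap`` (mapping or two-column
    ``sample<TAB>population`` TSV) pools samples into population units;
    samples absent from the map stay as individual two-gamete units.
    Multi-allelic and non-SNV records are excluded.
    """
    from cyvcf2 import VCF

    if popmap is not None and not isinstance(popmap, Mapping):
        pm = pd.read_csv(popmap, sep="\t", header=None, dtype=str)
        popmap = dict(zip(pm[0], pm[1]))
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    loci: list[str] = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        alt = np.where(gt == 3, 2, gt).astype(float)
        alt[gt == 2] = np.nan
        rows.append(alt)
        ident = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(str(ident))
    if not rows:
        raise ValueError(f"{path}: no diallelic SNVs found")
    acm = diploids_to_units(np.vstack(rows), samples, loci)
    if popmap:
        grouping = {s: popmap.get(s, s) for s in samples}
        acm = pool_units(acm, grouping)
    return acm
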