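"""SNP QC and population-genetic statistics.

Covers the genetic workflow of a germplasm diversity survey: locus filtering
on missingness and minor allele frequency, per-individual heterozygosity,
selection of species-diagnostic SNPs by Fisher's exact test, Ritland's
kinship estimator with distance-class spatial autocorrelation and a
permutation envelope, pairwise Weir & Cockerham Fst, and a spatial
distance-to-centroid summary of clusters.

Genotypes are diploid dosages in {0, 1, 2} (count of the alternate allele)
with NaN for missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from nichepop.geo_core import haversine_km, haversine_km_matrix

__all__ = [
    "GenotypeMatrix",
    "KinshipProfile",
    "FstMatrix",
    "filter_snps",
    "heterozygosity_percent",
    "diagnostic_snps",
    "ritland_kinship",
    "pairwise_kinship",
    "spatial_autocorrelation",
    "pairwise_fst",
    "centroid_distances",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci diploid dosages with metadata.

    ``dosages``: (n_individuals, n_loci) float array with values in
    {0, 1, 2} and NaN for missing.  ``coords`` is an optional
    (n_individuals, 2) lon/lat array.
    """

    dosages: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    groups: list[str] | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        if self.dosages.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length mismatch")
        if self.dosages.shape[1] != len(self.locus_ids):
            raise ValueError("locus_ids length mismatch")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if self.groups is not None and len(self.groups) != self.n_individuals:
            raise ValueError("groups length mismatch")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_individuals, 2):
                raise ValueError("coords must be (n_individuals, 2) lon/lat")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.dosages[:, keep],
            list(self.individual_ids),
            [self.locus_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.locus_ids[i] for i in keep],
            list(self.groups) if self.groups is not None else None,
            None if self.coords is None else self.coords.copy(),
        )

    def subset_individuals(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.dosages[keep],
            [self.individual_ids[i] for i in keep],
            list(self.locus_ids),
            None if self.groups is None else [self.groups[i] for i in keep],
            None if self.coords is None else self.coords[keep],
        )

    # -- I/O ------------------------------------------------------------
    def to_csv(self, genotype_path: str | Path, samples_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.dosages, index=self.individual_ids, columns=self.locus_ids)
        df.to_csv(genotype_path, index_label="id")
        if samples_path is not None:
            meta = pd.DataFrame({"id": self.individual_ids})
            meta["group"] = self.groups if self.groups is not None else ""
            if self.coords is not None:
                meta["lon"] = self.coords[:, 0]
                meta["lat"] = self.coords[:, 1]
            meta.to_csv(samples_path, index=False)

    @classmethod
    def from_csv(
        cls, genotype_path: str | Path, samples_path: str | Path | None = None
    ) -> "GenotypeMatrix":
        df = pd.read_csv(genotype_path, index_col="id")
        groups = None
        coords = None
        ids = [str(i) for i in df.index]
        if samples_path is not None:
            meta = pd.read_csv(samples_path).set_index("id")
            meta = meta.loc[ids]
            if "group" in meta:
                groups = [str(g) for g in meta["group"]]
            if {"lon", "lat"} <= set(meta.columns):
                coords = meta[["lon", "lat"]].to_numpy(dtype=float)
        return cls(df.to_numpy(dtype=float), ids, [str(c) for c in df.columns], groups, coords)

    @classmethod
    def from_vcf(cls, path: str | Path, samples_path: str | Path | None = None) -> "GenotypeMatrix":
        """Read biallelic SNP dosages from the GT field of a VCF."""
        from cyvcf2 import VCF  # optional dependency, imported lazily

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        dosages, loci = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            row = np.array(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
            dos = np.where(row == 3, 2.0, row)
            dos[row == 2] = np.nan
            dosages.append(dos)
            loci.append(var.ID or f"{var.CHROM}:{var.POS}")
        groups = coords = None
        if samples_path is not None:
            meta = pd.read_csv(samples_path).set_index("id").loc[ids]
            groups = [str(g) for g in meta["group"]] if "group" in meta else None
            if {"lon", "lat"} <= set(meta.columns):
                coords = meta[["lon", "lat"]].to_numpy(dtype=float)
        return cls(np.array(dosages).T, ids, loci, groups, coords)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def filter_snps(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, dict]:
    """Drop loci by missingness then by minor allele frequency.

    A locus is dropped if its missing fraction exceeds ``max_missing``, or
    (among survivors) if its MAF is less than *or equal to* ``min_maf``
    computed on non-missing calls.  The report records the counts per rule
    in application order; applying the filter twice is idempotent.
    """
    miss = g.missing_fraction()
    drop_missing = miss > max_missing
    maf = g.maf()
    drop_maf = ~drop_missing & (np.isnan(maf) | (maf <= min_maf))
    keep = ~(drop_missing | drop_maf)
    report = {
        "n_input": g.n_loci,
        "dropped_missingness": int(drop_missing.sum()),
        "dropped_maf": int(drop_maf.sum()),
        "n_retained": int(keep.sum()),
        "order": ["missingness", "maf"],
        "max_missing": max_missing,
        "min_maf": min_maf,
    }
    if report["n_retained"] == 0:
        warnings.warn("all loci removed by filtering", stacklevel=2)
    return g.subset_loci(keep), report


def heterozygosity_percent(g: GenotypeMatrix) -> pd.Series:
    """Percent of non-missing loci heterozygous, per individual.

    Individuals with zero non-missing calls get NaN.
    """
    called = ~np.isnan(g.dosages)
    het = (g.dosages == 1.0) & called
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_called > 0, 100.0 * het.sum(axis=1) / n_called, np.nan)
    return pd.Series(pct, index=g.individual_ids, name="heterozygosity_percent")


def diagnostic_snps(
    g: GenotypeMatrix,
    group_a: str,
    group_b: str,
    p_threshold: float = 5e-8,
) -> tuple[np.ndarray, pd.Series]:
    """Loci whose allele counts differ between two groups below a genome-wide
    Fisher exact threshold.

    For each locus a two-sided Fisher exact test is run on the 2x2 table of
    (group x allele) counts over non-missing calls; loci with p <
    ``p_threshold`` are retained.  Returns (boolean keep mask, p-values
    indexed by locus id).  Monomorphic loci get p = 1 and are never retained.
    """
    if g.groups is None:
        raise ValueError("genotype matrix has no group labels")
    ga = np.array([grp == group_a for grp in g.groups])
    gb = np.array([grp == group_b for grp in g.groups])
    if not ga.any() or not gb.any():
        raise ValueError("both groups must be non-empty")
    pvals = np.ones(g.n_loci)
    for j in range(g.n_loci):
        col = g.dosages[:, j]
        pa = col[ga]
        pb = col[gb]
        pa = pa[~np.isnan(pa)]
        pb = pb[~np.isnan(pb)]
        alt_a, alt_b = pa.sum(), pb.sum()
        ref_a, ref_b = 2 * pa.size - alt_a, 2 * pb.size - alt_b
        if (alt_a + alt_b == 0) or (ref_a + ref_b == 0):
            continue  # monomorphic overall: p stays 1
        _, p = fisher_exact([[ref_a, alt_a], [ref_b, alt_b]], alternative="two-sided")
        pvals[j] = p
    keep = pvals < p_threshold
    return keep, pd.Series(pvals, index=g.locus_ids, name="fisher_p")


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


def ritland_kinship(
    gi: np.ndarray, gj: np.ndarray, allele_freqs: np.ndarray
) -> float:
    """Ritland's kinship estimator between two diploid individuals.

    Per biallelic locus with reference-allele frequency ``p`` (taken as the
    frequency of the allele counted by the dosage) and individual gene
    frequencies ``x = dosage/2``::

        r_locus = x_i*x_j/p + (1-x_i)*(1-x_j)/(1-p) - 1

    The multilocus estimate is the unweighted mean over loci where both
    individuals are genotyped and 0 < p < 1.  Returns NaN when no locus is
    usable.
    """
    gi = np.asarray(gi, dtype=float)
    gj = np.asarray(gj, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    use = ~np.isnan(gi) & ~np.isnan(gj) & (p > 0.0) & (p < 1.0)
    if not use.any():
        return float("nan")
    xi, xj, p = gi[use] / 2.0, gj[use] / 2.0, p[use]
    r = xi * xj / p + (1.0 - xi) * (1.0 - xj) / (1.0 - p) - 1.0
    return float(r.mean())


def pairwise_kinship(g: GenotypeMatrix, allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """Ritland kinship for every pair of individuals (vectorized).

    Allele frequencies default to the whole analyzed sample.  Returns a
    symmetric (n, n) matrix with NaN diagonal.
    """
    p = g.allele_freq() if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    usable_locus = (p > 0.0) & (p < 1.0)
    d = g.dosages[:, usable_locus]
    p = p[usable_locus]
    x = d / 2.0
    ok = ~np.isnan(x)
    x0 = np.where(ok, x, 0.0)
    n = g.n_individuals
    out = np.full((n, n), np.nan)
    inv_p = 1.0 / p
    inv_q = 1.0 / (1.0 - p)
    for i in range(n):
        # loci usable for pair (i, j): both called
        both = ok[i] & ok
        a = (x0[i] * x0) * inv_p
        b = ((1.0 - x0[i]) * (1.0 - x0)) * inv_q
        per_locus = np.where(both, a + b - 1.0, 0.0)
        counts = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[i] = np.where(counts > 0, per_locus.sum(axis=1) / counts, np.nan)
    np.fill_diagonal(out, np.nan)
    return out


@dataclass
class KinshipProfile:
    """Distance-class kinship profile with a permutation envelope."""

    class_upper_km: np.ndarray  # upper distance bound per class
    class_mean_km: np.ndarray
    mean_kinship: np.ndarray
    pair_counts: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    n_permutations: int
    zero_crossing_km: float | None = None  # mean distance of first class with kinship <= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_upper_km": self.class_upper_km,
                "class_mean_km": self.class_mean_km,
                "mean_kinship": self.mean_kinship,
                "pair_count": self.pair_counts,
                "envelope_low": self.envelope_low,
                "envelope_high": self.envelope_high,
            }
        )


def spatial_autocorrelation(
    g: GenotypeMatrix,
    n_classes: int = 20,
    n_permutations: int = 100,
    seed: int = 0,
    envelope: tuple[float, float] = (2.5, 97.5),
) -> KinshipProfile:
    """Kinship vs geographic distance in equal-pair-count classes.

    All pairwise great-circle distances are binned into ``n_classes``
    classes of (as near as possible) equal pair counts; per class the mean
    Ritland kinship (allele frequencies from the whole sample) is reported.
    The null envelope comes from shuffling coordinate assignments among
    individuals ``n_permutations`` times and recomputing the class means
    with the same equal-count binning.  Ties at bin edges are resolved by a
    stable sort on (distance, pair index).
    """
    if g.coords is None:
        raise ValueError("coordinates required for spatial autocorrelation")
    n = g.n_individuals
    iu = np.triu_indices(n, k=1)
    if iu[0].size < n_classes:
        raise ValueError(f"need at least {n_classes} pairs, have {iu[0].size}")
    kin_mat = pairwise_kinship(g)
    kin = kin_mat[iu]
    dist_mat = haversine_km_matrix(g.coords, g.coords)
    rng = np.random.default_rng(seed)

    def class_means(dists: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        order = np.lexsort((np.arange(dists.size), dists))  # stable: distance then pair id
        chunks = np.array_split(order, n_classes)
        mk = np.array([np.nanmean(kin[c]) for c in chunks])
        md = np.array([dists[c].mean() for c in chunks])
        ub = np.array([dists[c].max() for c in chunks])
        cnt = np.array([c.size for c in chunks])
        return mk, md, ub, cnt

    obs_kin, obs_mean_d, obs_upper, counts = class_means(dist_mat[iu])

    null = np.empty((n_permutations, n_classes))
    for it in range(n_permutations):
        perm = rng.permutation(n)
        null[it] = class_means(dist_mat[np.ix_(perm, perm)][iu])[0]
    lo = np.percentile(null, envelope[0], axis=0)
    hi = np.percentile(null, envelope[1], axis=0)

    zero = None
    below = np.flatnonzero(obs_kin <= 0)
    if below.size:
        zero = float(obs_mean_d[below[0]])

    return KinshipProfile(
        class_upper_km=obs_upper,
        class_mean_km=obs_mean_d,
        mean_kinship=obs_kin,
        pair_counts=counts,
        envelope_low=lo,
        envelope_high=hi,
        n_permutations=n_permutations,
        zero_crossing_km=zero,
    )


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    """Pairwise multi-locus Weir & Cockerham theta between groups."""

    group_ids: list[str]
    theta: np.ndarray  # symmetric, NaN diagonal
    n_loci_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.group_ids, columns=self.group_ids)


def _wc_components(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components a, b, c per locus for two
    groups of diploid dosages, plus a usable-locus mask."""
    r = 2
    n1 = (~np.isnan(d1)).sum(axis=0).astype(float)
    n2 = (~np.isnan(d2)).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p1 = np.nanmean(d1, axis=0) / 2.0
        p2 = np.nanmean(d2, axis=0) / 2.0
    # h: frequency of heterozygotes among called individuals
    h1 = np.where(n1 > 0, (d1 == 1.0).sum(axis=0) / np.maximum(n1, 1), np.nan)
    h2 = np.where(n2 > 0, (d2 == 1.0).sum(axis=0) / np.maximum(n2, 1), np.nan)
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    usable = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1) & (nbar > 1)
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c, usable


def wc_theta(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int]:
    """Multi-locus WC84 theta (ratio of sums) for two dosage matrices."""
    a, b, c, usable = _wc_components(d1, d2)
    if not usable.any():
        return float("nan"), 0
    num = a[usable].sum()
    den = (a + b + c)[usable].sum()
    return float(num / den), int(usable.sum())


def pairwise_fst(g: GenotypeMatrix) -> FstMatrix:
    """Pairwise multi-locus Weir & Cockerham theta between all groups.

    Loci monomorphic across a pair (or with fewer than two called
    individuals in either group) are skipped for that pair; if no locus is
    usable the entry is NaN and reported via ``n_loci_used``.
    """
    if g.groups is None:
        raise ValueError("genotype matrix has no group labels")
    groups = sorted(set(g.groups))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    idx = {grp: np.array([i for i, x in enumerate(g.groups) if x == grp]) for grp in groups}
    for grp, members in idx.items():
        if members.size < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 individuals")
    k = len(groups)
    theta = np.full((k, k), np.nan)
    used = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            t, nl = wc_theta(g.dosages[idx[groups[i]]], g.dosages[idx[groups[j]]])
            theta[i, j] = theta[j, i] = t
            used[i, j] = used[j, i] = nl
    return FstMatrix(groups, theta, used)


# ---------------------------------------------------------------------------
# Spatial centroid summary
# ---------------------------------------------------------------------------


def centroid_distances(
    g: GenotypeMatrix, cluster_labels: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance of each member to its cluster's spatial centroid.

    The centroid is the coordinate-wise mean of member lon/lat (a planar
    approximation, adequate at the regional scales considered here).
    Returns ``(members, centroids)``: per-individual distances to the own
    centroid, and per-cluster centroid positions with pairwise centroid
    separations encoded by the ``centroids`` frame index order.  Singleton
    clusters get distance 0 and are flagged.
    """
    if g.coords is None:
        raise ValueError("coordinates required")
    labels = list(cluster_labels) if cluster_labels is not None else list(g.groups or [])
    if len(labels) != g.n_individuals:
        raise ValueError("cluster_labels length mismatch")
    rows = []
    cents = {}
    for grp in sorted(set(labels)):
        members = [i for i, x in enumerate(labels) if x == grp]
        cent = g.coords[members].mean(axis=0)
        cents[grp] = cent
        for i in members:
            rows.append(
                {
                    "id": g.individual_ids[i],
                    "cluster": grp,
                    "distance_km": haversine_km(tuple(g.coords[i]), tuple(cent)),
                    "singleton": len(members) == 1,
                }
            )
    members_df = pd.DataFrame(rows)
    cent_df = pd.DataFrame(
        [{"cluster": grp, "lon": c[0], "lat": c[1]} for grp, c in cents.items()]
    ).set_index("cluster")
    # pairwise centroid separations
    names = list(cent_df.index)
    sep = pd.DataFrame(
        haversine_km_matrix(cent_df[["lon", "lat"]].to_numpy(), cent_df[["lon", "lat"]].to_numpy()),
        index=names,
        columns=names,
    )
    cent_df = cent_df.join(sep.add_prefix("sep_km_"))
    return members_df, cent_df
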