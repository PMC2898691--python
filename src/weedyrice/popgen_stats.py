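"""Diversity and differentiation statistics for haploid STS panels.

All estimators work on the biallelic :class:`~weedyrice.sts_io.SNPMatrix`
and follow a fixed set of aggregation conventions:

* per-kb values divide by the number of non-indel alignment columns of the
  requested site class at each locus, then multiply by 1000;
* sites with missing calls use the per-site effective sample size, both in
  Watterson's harmonic-number weighting and in pairwise-difference
  denominators;
* F_st is the two-population Weir & Cockerham (1984) estimator on haploid
  allele counts, with singleton SNPs (pooled minor-allele count of one)
  dropped, negative per-SNP values clamped to zero before averaging, and
  non-polymorphic loci entering the grand mean as zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sts_io import PopulationPanel, SNPMatrix

__all__ = [
    "SitePartition",
    "FstSummary",
    "SummaryVector",
    "watterson_theta",
    "pi_theta",
    "tajimas_d",
    "diversity_table",
    "site_partition",
    "weir_cockerham_fst",
    "mfh_share",
    "abc_summary_vector",
    "summary_vector_from_arrays",
]


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else np.nan


def _allele_counts(matrix: SNPMatrix, idx: np.ndarray):
    """Per-site minor (1) and total non-missing counts for selected samples."""
    sub = matrix.genotypes[:, idx]
    n1 = (sub == 1).sum(axis=1)
    n = n1 + (sub == 0).sum(axis=1)
    return n1, n


def _per_locus(matrix: SNPMatrix, values: np.ndarray, site_mask: np.ndarray,
               site_class: str, scale_per_kb: bool) -> pd.Series:
    """Sum per-site values within each locus; optionally per-kb normalize."""
    out = {}
    locus_ids = matrix.sites["locus_id"].to_numpy()
    for locus in matrix.loci.index:
        sel = site_mask & (locus_ids == locus)
        total = float(np.nansum(values[sel])) if sel.any() else 0.0
        if scale_per_kb:
            length = matrix.class_length(locus, site_class)
            out[locus] = np.nan if length == 0 else total / length * 1000.0
        else:
            out[locus] = total
    return pd.Series(out, name="value")


def watterson_theta(matrix: SNPMatrix, population: str, site_class: str = "all",
                    per_locus: bool = False):
    """Watterson's theta per kb, weighting each segregating site by the
    harmonic number of its effective (non-missing) sample size."""
    idx = matrix.sample_indices(population)
    n1, n = _allele_counts(matrix, idx)
    seg = (n1 > 0) & (n1 < n) & (n >= 2)
    weights = np.zeros(matrix.n_sites)
    for i in np.flatnonzero(seg):
        weights[i] = 1.0 / _harmonic(int(n[i]))
    series = _per_locus(matrix, weights, matrix.class_mask(site_class),
                        site_class, scale_per_kb=True)
    return series if per_locus else float(series.mean(skipna=True))


def pi_theta(matrix: SNPMatrix, population: str, site_class: str = "all",
             per_locus: bool = False):
    """Nucleotide diversity (mean pairwise difference) per kb."""
    idx = matrix.sample_indices(population)
    n1, n = _allele_counts(matrix, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            n >= 2, 2.0 * n1 * (n - n1) / (n * (n - 1.0)), 0.0
        )
    series = _per_locus(matrix, contrib, matrix.class_mask(site_class),
                        site_class, scale_per_kb=True)
    return series if per_locus else float(series.mean(skipna=True))


def _tajima_constants(n: int):
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(matrix: SNPMatrix, population: str, site_class: str = "all",
              per_locus: bool = False):
    """Tajima's (1989) D per locus, NaN when S = 0 or fewer than 4
    haplotypes carry data; the scalar form averages defined loci."""
    idx = matrix.sample_indices(population)
    n1, n = _allele_counts(matrix, idx)
    mask = matrix.class_mask(site_class)
    seg = (n1 > 0) & (n1 < n) & (n >= 2) & mask
    with np.errstate(divide="ignore", invalid="ignore"):
        pair_diffs = np.where(n >= 2, 2.0 * n1 * (n - n1) / (n * (n - 1.0)), 0.0)

    locus_ids = matrix.sites["locus_id"].to_numpy()
    out = {}
    for locus in matrix.loci.index:
        sel = seg & (locus_ids == locus)
        S = int(sel.sum())
        if S == 0:
            out[locus] = np.nan
            continue
        n_eff = int(round(float(np.mean(n[sel]))))
        if n_eff < 4:
            out[locus] = np.nan
            continue
        k_hat = float(np.sum(pair_diffs[sel]))
        a1, e1, e2 = _tajima_constants(n_eff)
        var = e1 * S + e2 * S * (S - 1)
        out[locus] = (k_hat - S / a1) / np.sqrt(var)
    series = pd.Series(out, name="tajimas_d")
    return series if per_locus else float(series.mean(skipna=True))


def diversity_table(matrix: SNPMatrix, population: str,
                    site_classes: Sequence[str] = ("all", "silent",
                                                   "synonymous",
                                                   "nonsynonymous")) -> pd.DataFrame:
    """Per-locus diversity table with a trailing mean row.

    Columns are (statistic, site_class) pairs for Watterson's theta per kb,
    pi per kb, Tajima's D and the segregating-site count S; the last row
    holds the across-locus mean (mean of defined per-locus values, with
    monomorphic loci contributing zeros to theta but not to D).
    """
    idx = matrix.sample_indices(population)
    n1, n = _allele_counts(matrix, idx)
    seg = (n1 > 0) & (n1 < n) & (n >= 2)
    locus_ids = matrix.sites["locus_id"].to_numpy()

    blocks = {}
    for cls in site_classes:
        mask = matrix.class_mask(cls)
        blocks[("theta_w_per_kb", cls)] = watterson_theta(
            matrix, population, cls, per_locus=True)
        blocks[("theta_pi_per_kb", cls)] = pi_theta(
            matrix, population, cls, per_locus=True)
        blocks[("tajimas_d", cls)] = tajimas_d(
            matrix, population, cls, per_locus=True)
        blocks[("S", cls)] = pd.Series(
            {locus: int(np.sum(seg & mask & (locus_ids == locus)))
             for locus in matrix.loci.index})
    table = pd.DataFrame(blocks)
    mean_row = table.mean(skipna=True)
    table.loc["mean"] = mean_row
    return table


def polymorphic_locus_count(matrix: SNPMatrix, population: str,
                            site_class: str = "all") -> int:
    idx = matrix.sample_indices(population)
    n1, n = _allele_counts(matrix, idx)
    seg = (n1 > 0) & (n1 < n) & (n >= 2) & matrix.class_mask(site_class)
    return int(matrix.sites.loc[seg, "locus_id"].nunique())


# ---------------------------------------------------------------------------
# Two-population site partition


@dataclass
class SitePartition:
    """Counts of shared polymorphisms, private polymorphisms and fixed
    differences between two population samples, with parallel counts after
    excluding sites whose pooled minor-allele count is one (singletons)."""

    shared: int
    private1: int
    private2: int
    fixed: int
    shared_nosingle: int
    private1_nosingle: int
    private2_nosingle: int
    fixed_nosingle: int

    @property
    def total(self) -> int:
        return self.shared + self.private1 + self.private2 + self.fixed

    def as_dict(self) -> dict:
        return asdict(self)


def _partition_counts(n1_a, n_a, n1_b, n_b, site_sel):
    poly_a = (n1_a > 0) & (n1_a < n_a)
    poly_b = (n1_b > 0) & (n1_b < n_b)
    # monomorphic samples carry allele 1 iff every observed call is 1
    mono_allele_a = np.where(n1_a == n_a, 1, 0)
    mono_allele_b = np.where(n1_b == n_b, 1, 0)
    shared = site_sel & poly_a & poly_b
    private1 = site_sel & poly_a & ~poly_b
    private2 = site_sel & ~poly_a & poly_b
    fixed = site_sel & ~poly_a & ~poly_b & (mono_allele_a != mono_allele_b)
    return int(shared.sum()), int(private1.sum()), int(private2.sum()), int(fixed.sum())


def site_partition(matrix: SNPMatrix, pop1: str, pop2: str,
                   site_class: str = "all") -> SitePartition:
    """Classify every site with data in both samples as shared, private to
    one population, or a fixed difference."""
    idx1 = matrix.sample_indices(pop1)
    idx2 = matrix.sample_indices(pop2)
    n1_a, n_a = _allele_counts(matrix, idx1)
    n1_b, n_b = _allele_counts(matrix, idx2)
    covered = (n_a >= 1) & (n_b >= 1) & matrix.class_mask(site_class)
    full = _partition_counts(n1_a, n_a, n1_b, n_b, covered)

    minor_union = np.minimum(n1_a + n1_b, (n_a + n_b) - (n1_a + n1_b))
    nosingle = covered & (minor_union != 1)
    reduced = _partition_counts(n1_a, n_a, n1_b, n_b, nosingle)
    return SitePartition(*full, *reduced)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_st


@dataclass
class FstSummary:
    per_snp: pd.DataFrame          # locus_id, column, raw, fst (clamped)
    per_locus: pd.Series           # mean clamped F_st per locus, 0 if empty
    grand_mean: float
    median: float


def _wc_haploid(n1: int, p1: float, n2: int, p2: float) -> float:
    """Weir & Cockerham (1984) theta-hat for two haploid samples.

    Haploid samples contribute one allele each, so the analysis reduces to
    the between/within mean squares of allele indicators."""
    r = 2
    n_tot = n1 + n2
    n_c = (n_tot - (n1 * n1 + n2 * n2) / n_tot) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    msp = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - r)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return np.nan
    return (msp - msg) / denom


def weir_cockerham_fst(matrix: SNPMatrix, pop1: str, pop2: str,
                       site_class: str = "all") -> FstSummary:
    """Per-SNP, per-locus and grand-mean F_st between two populations.

    Singleton SNPs (pooled minor count of one) are dropped before
    estimation; per-SNP estimates below zero are set to zero before the
    per-locus mean; loci without any retained polymorphic SNP contribute
    zero to the grand mean and median.
    """
    idx1 = matrix.sample_indices(pop1)
    idx2 = matrix.sample_indices(pop2)
    n1_a, n_a = _allele_counts(matrix, idx1)
    n1_b, n_b = _allele_counts(matrix, idx2)
    mask = matrix.class_mask(site_class)

    rows = []
    for i in np.flatnonzero(mask):
        na, nb = int(n_a[i]), int(n_b[i])
        if na < 2 or nb < 2:
            continue
        c1, c2 = int(n1_a[i]), int(n1_b[i])
        pooled_minor = min(c1 + c2, na + nb - c1 - c2)
        if pooled_minor == 0:       # not polymorphic in this pair
            continue
        if pooled_minor == 1:       # singleton SNP: dropped
            continue
        raw = _wc_haploid(na, c1 / na, nb, c2 / nb)
        if np.isnan(raw):
            continue
        rows.append({
            "locus_id": matrix.sites["locus_id"].iloc[i],
            "column": int(matrix.sites["column"].iloc[i]),
            "raw": raw,
            "fst": min(max(raw, 0.0), 1.0),
        })
    per_snp = pd.DataFrame(rows, columns=["locus_id", "column", "raw", "fst"])

    per_locus = pd.Series(0.0, index=matrix.loci.index, name="fst")
    if not per_snp.empty:
        means = per_snp.groupby("locus_id")["fst"].mean()
        per_locus.loc[means.index] = means
    else:
        warnings.warn(f"no polymorphic SNPs between {pop1!r} and {pop2!r}",
                      stacklevel=2)
    grand_mean = float(per_locus.mean()) if len(per_locus) else 0.0
    median = float(per_locus.median()) if len(per_locus) else 0.0
    return FstSummary(per_snp, per_locus, grand_mean, median)


# ---------------------------------------------------------------------------
# Most-frequent-haplotype sharing


def mfh_share(data, pop1: str, pop2: str,
              panel: PopulationPanel | None = None) -> float:
    """Fraction of loci at which two populations share the same
    most-frequent complete haplotype (ties resolved lexicographically).

    ``data`` is either an :class:`SNPMatrix` or a list of
    :class:`STSAlignment` (with ``panel`` supplied). Loci lacking a complete
    haplotype in either population are excluded with a warning.
    """
    if isinstance(data, SNPMatrix):
        loci = []
        locus_ids = data.sites["locus_id"].to_numpy()
        idx1 = data.sample_indices(pop1)
        idx2 = data.sample_indices(pop2)
        for locus in data.loci.index:
            sel = locus_ids == locus
            block = data.genotypes[sel]
            haps1 = ["".join(map(str, block[:, j])) for j in idx1
                     if not np.any(block[:, j] < 0)]
            haps2 = ["".join(map(str, block[:, j])) for j in idx2
                     if not np.any(block[:, j] < 0)]
            loci.append((locus, haps1, haps2))
    else:
        if panel is None:
            raise ValueError("alignment input requires a PopulationPanel")
        loci = []
        for aln in data:
            haps1 = [s for sid, s in zip(aln.sample_ids, aln.sequences)
                     if panel[sid] == pop1 and "N" not in s and "-" not in s]
            haps2 = [s for sid, s in zip(aln.sample_ids, aln.sequences)
                     if panel[sid] == pop2 and "N" not in s and "-" not in s]
            loci.append((aln.locus_id, haps1, haps2))

    def mfh(haps: list[str]) -> str:
        counts: dict[str, int] = {}
        for h in haps:
            counts[h] = counts.get(h, 0) + 1
        return sorted(counts, key=lambda h: (-counts[h], h))[0]

    used = shared = 0
    for locus, haps1, haps2 in loci:
        if not haps1 or not haps2:
            warnings.warn(f"{locus}: no complete haplotype in one population",
                          stacklevel=2)
            continue
        used += 1
        shared += int(mfh(haps1) == mfh(haps2))
    if used == 0:
        raise ValueError("no locus with complete haplotypes in both populations")
    return shared / used


# ---------------------------------------------------------------------------
# Pooled ABC summary vector


STAT_NAMES = (
    "pi_combined", "s_weed", "s_progenitor", "fixed",
    "private_weed", "private_progenitor", "shared", "s_union",
)


@dataclass
class SummaryVector:
    """The eight pooled statistics the rejection sampler compares.

    Pooled over all loci: combined-sample nucleotide diversity per kb, the
    segregating-site counts within each population, and the fixed / private /
    shared partition between them. The eighth slot defaults to S in the
    pooled sample.
    """

    pi_combined: float
    s_weed: float
    s_progenitor: float
    fixed: float
    private_weed: float
    private_progenitor: float
    shared: float
    s_union: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STAT_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in STAT_NAMES}

    @classmethod
    def from_array(cls, arr) -> "SummaryVector":
        return cls(*[float(x) for x in arr])


def abc_summary_vector(matrix: SNPMatrix, weed: str, progenitor: str,
                       site_class: str = "all",
                       eighth: str = "s_union") -> SummaryVector:
    """Compute the pooled summary vector from an SNP matrix.

    Pooled pi is the combined-sample mean pairwise difference summed over
    all sites divided by the total class length across loci (per kb), not a
    mean of per-locus values.

    The first seven statistics are fixed; the eighth slot is configurable:
    's_union' (default) counts segregating sites in the pooled sample,
    'singletons_union' counts pooled singleton sites (sensitive to recent
    growth). A non-default choice is logged.
    """
    idx_w = matrix.sample_indices(weed)
    idx_p = matrix.sample_indices(progenitor)
    idx_u = np.concatenate([idx_w, idx_p])
    mask = matrix.class_mask(site_class)

    def seg_count(idx):
        n1, n = _allele_counts(matrix, idx)
        return int(np.sum((n1 > 0) & (n1 < n) & (n >= 2) & mask))

    n1_u, n_u = _allele_counts(matrix, idx_u)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(n_u >= 2,
                           2.0 * n1_u * (n_u - n1_u) / (n_u * (n_u - 1.0)), 0.0)
    total_len = sum(matrix.class_length(locus, site_class)
                    for locus in matrix.loci.index)
    pi_combined = float(np.sum(contrib[mask])) / total_len * 1000.0 if total_len else 0.0

    if eighth == "s_union":
        slot8 = seg_count(idx_u)
    elif eighth == "singletons_union":
        minor = np.minimum(n1_u, n_u - n1_u)
        slot8 = int(np.sum((minor == 1) & mask))
        warnings.warn("eighth summary statistic set to 'singletons_union'",
                      stacklevel=2)
    else:
        raise ValueError(f"unknown eighth statistic {eighth!r}")

    part = site_partition(matrix, weed, progenitor, site_class)
    return SummaryVector(
        pi_combined=pi_combined,
        s_weed=seg_count(idx_w),
        s_progenitor=seg_count(idx_p),
        fixed=part.fixed,
        private_weed=part.private1,
        private_progenitor=part.private2,
        shared=part.shared,
        s_union=slot8,
    )


def summary_vector_from_arrays(locus_genotypes: Iterable[np.ndarray],
                               n_weed: int, total_length_bp: float) -> np.ndarray:
    """Fast path for simulated data: same eight statistics straight from
    per-locus 0/1 arrays (sites x haplotypes, weed haplotypes first, no
    missing data). Returns a plain float array ordered as
    :data:`STAT_NAMES`."""
    s_w = s_p = s_u = fixed = priv_w = priv_p = shared = 0
    pi_sum = 0.0
    for g in locus_genotypes:
        if g.size == 0:
            continue
        n_tot = g.shape[1]
        n_p = n_tot - n_weed
        c_w = g[:, :n_weed].sum(axis=1)
        c_u = g.sum(axis=1)
        c_p = c_u - c_w
        poly_w = (c_w > 0) & (c_w < n_weed)
        poly_p = (c_p > 0) & (c_p < n_p)
        poly_u = (c_u > 0) & (c_u < n_tot)
        s_w += int(poly_w.sum())
        s_p += int(poly_p.sum())
        s_u += int(poly_u.sum())
        shared += int((poly_w & poly_p).sum())
        priv_w += int((poly_w & ~poly_p).sum())
        priv_p += int((poly_p & ~poly_w).sum())
        mono_w = np.where(c_w == n_weed, 1, 0)
        mono_p = np.where(c_p == n_p, 1, 0)
        fixed += int((~poly_w & ~poly_p & (mono_w != mono_p)).sum())
        pi_sum += float(np.sum(2.0 * c_u * (n_tot - c_u) / (n_tot * (n_tot - 1.0))))
    pi_combined = pi_sum / total_length_bp * 1000.0 if total_length_bp else 0.0
    return np.array([pi_combined, s_w, s_p, fixed, priv_w, priv_p, shared, s_u],
                    dtype=float)
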