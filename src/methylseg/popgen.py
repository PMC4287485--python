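"""Population-level statistics for methylome variation.

Covers the expected-discovery curve of variable positions under a beta
frequency prior, the branched-reference binomial homozygosity test with
common/segregating variant classification, gain/loss classification of
sites in methylation-machinery mutants, permutation Z-scores for
region-set overlap, and kinship-based heritability of region
methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import betaln, gammaln

from .fdr import storey_qvalues


# ---------------------------------------------------------------------------
# beta frequency prior and discovery curve

@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on the population frequency of the derived state."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("a and b must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def sd(self) -> float:
        a, b = self.a, self.b
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0))))


def beta_prior_moments(prior: BetaPrior) -> tuple:
    """Closed-form (mean, sd) of the beta prior."""
    return prior.mean, prior.sd


def fit_beta_prior(sfs, n_strains: int) -> BetaPrior:
    """ML fit of (a, b) to a site-frequency spectrum.

    ``sfs[k]`` is the number of sites where k of ``n_strains`` carry the
    derived (non-ancestral) state; the counts are modelled as
    beta-binomial draws.
    """
    sfs = np.asarray(sfs, dtype=float)
    if sfs.size != n_strains + 1:
        raise ValueError("spectrum must have n_strains + 1 entries (k = 0..n)")
    if sfs.sum() <= 0:
        raise ValueError("all-zero spectrum")
    k = np.arange(n_strains + 1, dtype=float)
    n = float(n_strains)
    lchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    def nll(theta):
        a, b = np.exp(theta)
        ll = lchoose + betaln(k + a, n - k + b) - betaln(a, b)
        return -float(np.sum(sfs * ll))

    res = optimize.minimize(
        nll, np.log([0.5, 0.5]), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    a, b = np.exp(res.x)
    return BetaPrior(float(a), float(b))


def _expect_undetected(prior: BetaPrior, n: float) -> float:
    """E[(1-f)^n] under Beta(a, b): B(a, b+n) / B(a, b)."""
    return float(np.exp(betaln(prior.a, prior.b + n) - betaln(prior.a, prior.b)))


@dataclass(frozen=True)
class DiscoveryCurve:
    """Expected number of variable sites discovered in n individuals."""

    prior: BetaPrior
    total_sites: float

    def __call__(self, n) -> float:
        return self.delta(n)

    def delta(self, n) -> float:
        """Delta(n) = N * (1 - E[(1-f)^n]); monotone, Delta(0) = 0."""
        n = float(n)
        if n < 0:
            raise ValueError("n must be >= 0")
        return self.total_sites * (1.0 - _expect_undetected(self.prior, n))


def discovery_curve(prior: BetaPrior, total_sites: float) -> DiscoveryCurve:
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    return DiscoveryCurve(prior, float(total_sites))


def estimate_total_sites(prior: BetaPrior, delta_n: float, n: int) -> float:
    """Invert the discovery curve: N from an observed Delta(n)."""
    detect = 1.0 - _expect_undetected(prior, n)
    if detect <= 0:
        raise ValueError("detection probability is zero")
    return float(delta_n) / detect


# ---------------------------------------------------------------------------
# branched-reference homozygosity test and variant classification

@dataclass(frozen=True)
class HaplotypeReadCounts:
    r_b: int  # branch-supporting reads
    r_ref: int  # reference-haplotype reads

    def __post_init__(self) -> None:
        if self.r_b < 0 or self.r_ref < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.r_b + self.r_ref


MISSING_DATA_MAX_COVERAGE = 3  # accumulated coverage <= 3x is missing data


def homozygosity_pvalue(counts: HaplotypeReadCounts, af_null: float = 0.95) -> float:
    """Lower-tail binomial p-value of the major allele count.

    Under homozygosity the major haplotype should carry ~``af_null`` of
    the reads; too few major-allele reads reject the single-haplotype
    null (heterozygous-like signal).
    """
    if counts.total == 0:
        raise ValueError("zero total coverage")
    major = max(counts.r_b, counts.r_ref)
    return float(stats.binom.cdf(major, counts.total, af_null))


def homozygosity_calls(
    counts_list, af_null: float = 0.95, alpha_fdr: float = 0.05
) -> list:
    """Per-variant-site calls with joint Storey FDR across all tests.

    Returns, per entry, one of ``present-branch``, ``present-reference``,
    ``ambiguous`` (homozygosity rejected) or ``missing`` (coverage <=
    3x).  FDR is computed jointly over all testable sites.
    """
    calls = [None] * len(counts_list)
    testable, pvals = [], []
    for i, c in enumerate(counts_list):
        if c.total <= MISSING_DATA_MAX_COVERAGE:
            calls[i] = "missing"
        else:
            testable.append(i)
            pvals.append(homozygosity_pvalue(c, af_null))
    if testable:
        q = storey_qvalues(pvals)
        for i, qv in zip(testable, q):
            c = counts_list[i]
            if qv < alpha_fdr:
                calls[i] = "ambiguous"
            else:
                calls[i] = "present-branch" if c.r_b >= c.r_ref else "present-reference"
    return calls


def classify_variant(calls, counts, min_informative: int = 7) -> str:
    """Classify one variant across strains.

    ``calls``/``counts`` are per-strain homozygosity calls and read
    counts.  A strain supports the branch when its call is
    ``present-branch``, or when the test was ambiguous but the branch
    read count exceeds the reference count at least 2-fold (rescue
    rule); symmetrically for the reference.  With fewer than
    ``min_informative`` informative strains the variant is
    ``insufficient``; otherwise it is ``common`` (branch everywhere),
    ``not present`` (reference everywhere) or ``segregating``.
    """
    branch, ref = 0, 0
    informative = 0
    for call, c in zip(calls, counts):
        if call == "missing":
            continue
        informative += 1
        if call == "present-branch":
            branch += 1
        elif call == "present-reference":
            ref += 1
        elif call == "ambiguous":
            if c.r_b >= 2 * c.r_ref:
                branch += 1
            elif c.r_ref >= 2 * c.r_b:
                ref += 1
    if informative < min_informative:
        return "insufficient"
    if branch > 0 and ref == 0:
        return "common"
    if ref > 0 and branch == 0:
        return "not present"
    if branch > 0 and ref > 0:
        return "segregating"
    return "insufficient"


# ---------------------------------------------------------------------------
# mutant gain/loss classification

def is_methylated_in_wt(wt1: float, wt2: float) -> bool:
    """Methylated in wild type: both rates >= 10% and one above 20%."""
    return wt1 >= 0.10 and wt2 >= 0.10 and (wt1 > 0.20 or wt2 > 0.20)


def mutant_gain_loss(wt1: float, wt2: float, mutant: float) -> str:
    """Classify a site's methylation change in a mutant vs two WT samples."""
    vals = (wt1, wt2, mutant)
    if any(v is None or np.isnan(v) for v in vals):
        return "not-assessable"
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError("rates must lie in [0, 1]")
    if is_methylated_in_wt(wt1, wt2) and mutant < 0.10:
        return "lost"
    if (wt1 < 0.10 or wt2 < 0.10) and mutant > 0.20:
        return "gained"
    return "unchanged"


# ---------------------------------------------------------------------------
# region-set overlap permutation test

def _count_overlaps(set_a, set_b) -> int:
    """Number of regions in set_a overlapping >= 1 region in set_b."""
    import bisect

    by_chrom: dict = {}
    for c, s, e in set_b:
        by_chrom.setdefault(c, []).append((s, e))
    starts_by_chrom = {}
    for c in by_chrom:
        by_chrom[c].sort()
        starts_by_chrom[c] = [iv[0] for iv in by_chrom[c]]
    count = 0
    for c, s, e in set_a:
        ivs = by_chrom.get(c)
        if not ivs:
            continue
        i = bisect.bisect_right(starts_by_chrom[c], e)
        if any(ivs[j][1] >= s for j in range(i)):
            count += 1
    return count


def _place_regions(lengths, universe, rng):
    """Randomly place regions of given lengths within universe segments."""
    placed = []
    seg_len = np.array([e - s + 1 for _, s, e in universe])
    for l in lengths:
        w = np.maximum(0, seg_len - l + 1)
        if w.sum() == 0:
            raise ValueError(f"no universe segment can hold a region of length {l}")
        i = rng.choice(len(universe), p=w / w.sum())
        chrom, s, _ = universe[i]
        start = s + rng.integers(0, w[i])
        placed.append((chrom, int(start), int(start + l - 1)))
    return placed


def overlap_permutation_z(
    set_a, set_b, universe, n_perm: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Permutation test for overlap between two region sets.

    Both sets are randomly re-placed within the universe segments
    (lengths preserved, placement uniform over valid starts weighted by
    segment capacity); the observed overlap count is compared with the
    permutation distribution.  Returns (observed, Z, empirical p).
    """
    if rng is None:
        rng = np.random.default_rng()
    set_a = sorted(set_a)
    set_b = sorted(set_b)
    obs = _count_overlaps(set_a, set_b)
    len_a = [e - s + 1 for _, s, e in set_a]
    len_b = [e - s + 1 for _, s, e in set_b]
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = _place_regions(len_a, universe, rng)
        pb = _place_regions(len_b, universe, rng)
        null[i] = _count_overlaps(pa, pb)
    sd = null.std(ddof=1)
    z = (obs - null.mean()) / sd if sd > 0 else float("inf") if obs > null.mean() else 0.0
    p_emp = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return int(obs), float(z), float(p_emp)


# ---------------------------------------------------------------------------
# genotype input

def read_genotype_matrix(path, format: str = "tsv"):
    """Strain x variant genotype matrix (biallelic, haploid-coded 0/1).

    ``tsv``: first column strain id, remaining columns variants.
    ``vcf``: plain or bgzipped VCF; haploid or homozygous-diploid calls
    are coded 0/1, anything heterozygous or missing becomes NaN.
    Returns a pandas DataFrame indexed by strain.
    """
    import pandas as pd

    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if format == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        cols, names = [], []
        for var in vcf:
            gts = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            col = np.where(gts == 0, 0.0,
                           np.where(gts == 2, 1.0, np.nan))
            cols.append(col)
            names.append(f"{var.CHROM}:{var.POS}")
        return pd.DataFrame(
            np.column_stack(cols) if cols else np.empty((len(samples), 0)),
            index=samples, columns=names,
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# kinship and heritability

def kinship_matrix(genotypes) -> np.ndarray:
    """GCTA-style kinship from a strain x variant genotype matrix.

    Columns are standardised (zero-variance variants dropped) and the
    cross-product is divided by the number of variants used, so the
    diagonal is ~1.
    """
    G = np.asarray(genotypes, dtype=float)
    mean = G.mean(axis=0)
    sd = G.std(axis=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("no polymorphic variants")
    Z = (G[:, keep] - mean[keep]) / sd[keep]
    K = Z @ Z.T / keep.sum()
    return (K + K.T) / 2.0


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float


def _reml_loglik(h2, S, yt, xt):
    lam = h2 * S + (1.0 - h2)
    w = 1.0 / lam
    xtx = float(np.sum(xt * xt * w))
    beta = float(np.sum(xt * yt * w)) / xtx
    r = yt - xt * beta
    n = yt.size
    sigma_p2 = float(np.sum(r * r * w)) / (n - 1)
    ll = -0.5 * (
        (n - 1) * (np.log(2 * np.pi * sigma_p2) + 1.0)
        + float(np.sum(np.log(lam)))
        + np.log(xtx)
    )
    return ll, sigma_p2


def heritability_lmm(phenotype, K) -> HeritabilityEstimate:
    """REML fit of y = mu + g + e with cov(g) = sigma_g^2 K.

    The kinship matrix is eigendecomposed once and the restricted
    likelihood is profiled over h2 = sigma_g^2 / (sigma_g^2 +
    sigma_e^2); the standard error comes from the curvature of the
    restricted log-likelihood at the optimum.
    """
    y = np.asarray(phenotype, dtype=float)
    K = np.asarray(K, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if K.shape != (n, n):
        raise ValueError("kinship matrix shape mismatch")
    if np.any(np.isnan(y)):
        raise ValueError("phenotype has missing values")
    S, U = np.linalg.eigh(K)
    if S.min() < -1e-6 * max(1.0, S.max()):
        raise ValueError("kinship matrix is not positive semi-definite")
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    eps = 1e-6
    res = optimize.minimize_scalar(
        lambda h: -_reml_loglik(h, S, yt, xt)[0],
        bounds=(eps, 1.0 - eps),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll, sigma_p2 = _reml_loglik(h2, S, yt, xt)

    # numeric curvature for the standard error
    d = 1e-4
    lo, hi = max(eps, h2 - d), min(1 - eps, h2 + d)
    ll_lo = _reml_loglik(lo, S, yt, xt)[0]
    ll_hi = _reml_loglik(hi, S, yt, xt)[0]
    curv = (ll_hi - 2 * ll + ll_lo) / ((hi - h2) * (h2 - lo))
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else float("inf")

    # snap boundary solutions to the boundary
    if h2 < 10 * eps:
        h2 = 0.0
    elif h2 > 1 - 10 * eps:
        h2 = 1.0
    return HeritabilityEstimate(
        h2=h2, se=se,
        sigma_g2=h2 * sigma_p2, sigma_e2=(1.0 - h2) * sigma_p2,
    )


def log_mean_methylation(rates, floor: float = 1e-3) -> np.ndarray:
    """Phenotype transform: natural log of (mean rate + floor)."""
    r = np.asarray(rates, dtype=float)
    return np.log(r + floor)
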