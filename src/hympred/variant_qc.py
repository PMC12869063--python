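"""GBS-style SNP quality control.

Parses a VCF into a :class:`~hympred.containers.GenotypeMatrix` and applies
the filter cascade typical of reduced-representation genotyping: per-site
read depth, call rate, an exact Hardy-Weinberg test, minor allele
frequency, and finally per-individual missingness.  Filters run in that
fixed order and every removed record is charged to the first criterion it
fails, so the audit counts partition the removals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from hympred.containers import MISSING, GenotypeMatrix

__all__ = [
    "QcThresholds",
    "SiteFilterResult",
    "QcResult",
    "read_vcf",
    "hwe_exact_test",
    "apply_site_filters",
    "filter_individuals",
    "run_qc",
    "write_audit",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds.  Defaults follow common GBS practice.

    A threshold set to its fully permissive value (0, or infinity for
    ``depth_max``) disables that check entirely; otherwise call rate, HWE
    p-value and MAF comparisons are strict (``>``), depth bounds inclusive,
    and individual missingness uses "more than" (an individual at exactly
    the limit is kept).
    """

    depth_min: float = 9.0
    depth_max: float = 300.0
    min_call_rate: float = 0.80
    hwe_p_min: float = 1e-4
    maf_min: float = 0.02
    max_individual_missing: float = 0.30

    def __post_init__(self) -> None:
        if self.depth_min < 0 or self.depth_max < self.depth_min:
            raise ValueError("need 0 <= depth_min <= depth_max")
        for name in ("min_call_rate", "hwe_p_min", "maf_min",
                     "max_individual_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SiteFilterResult:
    kept: np.ndarray  # indices of retained sites
    audit: dict = field(default_factory=dict)  # first-failure counts per criterion


@dataclass
class QcResult:
    genotypes: GenotypeMatrix
    kept_sites: np.ndarray
    kept_individuals: np.ndarray
    site_audit: dict
    n_individuals_removed: int


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into coded genotypes (count of alternate alleles).

    Only biallelic SNP records are retained; multi-allelic records are
    skipped and counted in the variant table's ``attrs['n_multiallelic']``.
    Per-site mean depth comes from FORMAT DP when present, else INFO DP
    divided by the sample count.
    """
    vcf = VCF(path, gts012=True)
    ids = list(vcf.samples)
    n = len(ids)
    rows, codes_list, depth_list = [], [], []
    n_multi = 0
    has_geno_depth = True
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        codes_list.append(gt)
        site_depth = np.nan
        geno_dp = None
        try:
            geno_dp = v.format("DP")
        except Exception:
            geno_dp = None
        if geno_dp is not None:
            d = np.asarray(geno_dp, dtype=float).ravel()
            d[d < 0] = np.nan
            site_depth = float(np.nanmean(d)) if np.any(np.isfinite(d)) else np.nan
            depth_list.append(d)
        else:
            has_geno_depth = False
            info_dp = v.INFO.get("DP")
            if info_dp is not None and n > 0:
                site_depth = float(info_dp) / n
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], site_depth))
    if rows:
        codes = np.vstack(codes_list).T
    else:
        codes = np.empty((n, 0), dtype=np.int8)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth"])
    variants.attrs["n_multiallelic"] = n_multi
    geno_depth = None
    if has_geno_depth and depth_list:
        geno_depth = np.vstack(depth_list).T
    return GenotypeMatrix(codes=codes, ids=ids, variants=variants,
                          geno_depth=geno_depth)


def _hwe_het_probabilities(n_minor: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` diploids and ``n_minor`` copies of the minor allele, the
    attainable heterozygote counts share the parity of ``n_minor`` and
    have probability proportional to  n! / (nAA! nAa! naa!) * 2**nAa,
    normalised over all attainable counts.
    """
    het_min = n_minor % 2
    het_max = min(n_minor, 2 * n - n_minor)
    hets = np.arange(het_min, het_max + 1, 2)
    n_minor_hom = (n_minor - hets) // 2
    n_major_hom = n - hets - n_minor_hom
    logp = (
        hets * math.log(2.0)
        - np.array([math.lgamma(h + 1) for h in hets])
        - np.array([math.lgamma(a + 1) for a in n_minor_hom])
        - np.array([math.lgamma(b + 1) for b in n_major_hom])
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic site.

    Conditional on the observed allele counts, the p-value is the sum of
    probabilities of all heterozygote counts whose probability does not
    exceed that of the observed count (two-sided, no mid-p correction).
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts) or any(int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_minor = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets, probs = _hwe_het_probabilities(n_minor, n)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    # 1e-12 relative slack guards against float ties in the enumeration.
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _site_stats(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Call rate, MAF and HWE p-value per site, on non-missing calls."""
    miss = codes == MISSING
    n_called = (~miss).sum(axis=0)
    call_rate = n_called / codes.shape[0] if codes.shape[0] else n_called * 0.0
    dose = codes.astype(float)
    dose[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dose, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    hwe = np.ones(codes.shape[1])
    for j in range(codes.shape[1]):
        col = codes[:, j]
        n_bb = int((col == 2).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 0).sum())
        if n_aa + n_ab + n_bb >= 1:
            hwe[j] = hwe_exact_test(n_aa, n_ab, n_bb)
    return np.asarray(call_rate, dtype=float), maf, hwe


def apply_site_filters(
    gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> SiteFilterResult:
    """Keep sites passing depth, call-rate, HWE and MAF in cascade order.

    The audit charges each removed site to the first criterion it fails,
    so audit counts plus kept sites sum to the input site count.
    """
    depth = gm.variants["depth"].to_numpy(dtype=float)
    call_rate, maf, hwe = _site_stats(gm.codes)

    depth_enabled = thresholds.depth_min > 0 or np.isfinite(thresholds.depth_max)
    pass_depth = (
        (depth >= thresholds.depth_min) & (depth <= thresholds.depth_max)
        if depth_enabled
        else np.ones_like(maf, dtype=bool)
    )
    pass_call = (
        call_rate > thresholds.min_call_rate
        if thresholds.min_call_rate > 0
        else np.ones_like(maf, dtype=bool)
    )
    pass_hwe = (
        hwe > thresholds.hwe_p_min
        if thresholds.hwe_p_min > 0
        else np.ones_like(maf, dtype=bool)
    )
    pass_maf = (
        maf > thresholds.maf_min
        if thresholds.maf_min > 0
        else np.ones_like(maf, dtype=bool)
    )

    audit = {"depth": 0, "call_rate": 0, "hwe": 0, "maf": 0}
    kept = []
    for j in range(gm.n_variants):
        if not pass_depth[j]:
            audit["depth"] += 1
        elif not pass_call[j]:
            audit["call_rate"] += 1
        elif not pass_hwe[j]:
            audit["hwe"] += 1
        elif not pass_maf[j]:
            audit["maf"] += 1
        else:
            kept.append(j)
    return SiteFilterResult(kept=np.asarray(kept, dtype=int), audit=audit)


def filter_individuals(
    gm: GenotypeMatrix,
    max_missing: float = 0.30,
    site_index: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of individuals with missingness not exceeding ``max_missing``.

    Removal uses strictly-more-than semantics: an individual missing
    exactly the threshold fraction of retained sites is kept.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    codes = gm.codes if site_index is None else gm.codes[:, site_index]
    if codes.shape[1] == 0:
        return np.arange(gm.n_individuals)
    frac = (codes == MISSING).mean(axis=1)
    return np.flatnonzero(frac <= max_missing + 1e-12)


def mask_genotypes_by_depth(
    gm: GenotypeMatrix, thresholds: QcThresholds
) -> GenotypeMatrix:
    """Per-genotype depth mode: set calls with out-of-range depth missing.

    An alternative to the default per-site mean-depth criterion, for data
    carrying FORMAT DP.  Typically followed by :func:`run_qc` with the
    site-level depth check disabled.
    """
    if gm.geno_depth is None:
        raise ValueError("per-genotype depth filtering needs FORMAT DP data")
    codes = gm.codes.copy()
    bad = (gm.geno_depth < thresholds.depth_min) | (
        gm.geno_depth > thresholds.depth_max
    )
    codes[bad & (codes != MISSING)] = MISSING
    return GenotypeMatrix(codes=codes, ids=gm.ids, variants=gm.variants,
                          geno_depth=gm.geno_depth)


def run_qc(gm: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()) -> QcResult:
    """Full cascade: site filters, then the individual-missingness filter."""
    sites = apply_site_filters(gm, thresholds)
    inds = filter_individuals(gm, thresholds.max_individual_missing, sites.kept)
    filtered = gm.subset(individuals=inds, variants=sites.kept)
    return QcResult(
        genotypes=filtered,
        kept_sites=sites.kept,
        kept_individuals=inds,
        site_audit=sites.audit,
        n_individuals_removed=gm.n_individuals - inds.size,
    )


def write_audit(result: QcResult, path: str) -> None:
    """Write the per-criterion removal counts as a TSV."""
    rows = [("sites_input", len(result.kept_sites)
             + sum(result.site_audit.values()))]
    rows += [(f"sites_removed_{k}", v) for k, v in result.site_audit.items()]
    rows += [
        ("sites_kept", len(result.kept_sites)),
        ("individuals_removed_missingness", result.n_individuals_removed),
        ("individuals_kept", len(result.kept_individuals)),
    ]
    pd.DataFrame(rows, columns=["metric", "count"]).to_csv(
        path, sep="\t", index=False
    )
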