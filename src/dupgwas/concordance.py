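"""Between-measurement and between-GWAS concordance statistics.

When the same trait is measured twice and scanned twice, the agreement of
the two association scans can be summarised by: the correlation of trait
values, of per-SNP allele effects and of -log10 p; the number of SNPs
significant in both scans; the per-scan false positive rate FPR = E_p/O_p
(expected over observed significant SNPs, capped at 100%); clusters of
significant SNPs along the map; and the ranking of chromosomes by their
significant-SNP counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_gwas import GwasResult

__all__ = [
    "TraitSummary",
    "ConcordanceReport",
    "RegionCluster",
    "trait_summary",
    "compare_traits",
    "fpr",
    "compare_gwas",
    "region_clusters",
    "chromosome_summary",
]


@dataclass
class TraitSummary:
    """Sample statistics of one trait column (mm)."""

    n: int
    mean: float
    sd: float
    sem: float
    cv: float
    min: float
    max: float

    def as_dict(self) -> dict:
        return asdict(self)


def trait_summary(values: pd.Series | np.ndarray) -> TraitSummary:
    """n, mean, s.d. (n-1), s.e.m., coefficient of variation and range."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    return TraitSummary(
        n=len(v),
        mean=mean,
        sd=sd,
        sem=sd / np.sqrt(len(v)),
        cv=sd / mean if mean != 0 else np.nan,
        min=float(v.min()),
        max=float(v.max()),
    )


def compare_traits(y1: pd.Series | np.ndarray, y2: pd.Series | np.ndarray) -> dict:
    """Pairwise agreement of two measurements of one trait.

    Returns Pearson r, the OLS slope of y2 on y1 with its s.e., the mean
    signed difference (y2 - y1) and the mean absolute difference, all in mm.
    """
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    if len(a) != len(b):
        raise ValueError("unpaired inputs")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    r = float(np.corrcoef(a, b)[0, 1])
    res = stats.linregress(a, b)
    return {
        "n": n,
        "r": r,
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "mean_difference": float((b - a).mean()),
        "mean_abs_difference": float(np.abs(b - a).mean()),
    }


def fpr(n_snps_tested: int, alpha: float, n_observed_significant: int) -> float:
    """False positive rate E_p / O_p as an integer percentage, capped at 100.

    E_p = n_snps_tested * alpha is the count expected under the global null;
    O_p the observed significant count.  Values above 100% (fewer hits than
    expected) are capped; O_p = 0 leaves the rate undefined (NaN).
    """
    if n_snps_tested < 1 or n_observed_significant < 0:
        raise ValueError("counts must be non-negative (n_snps_tested >= 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_observed_significant == 0:
        return float("nan")
    e_p = n_snps_tested * alpha
    return float(min(100, round(100.0 * e_p / n_observed_significant)))


def expected_r_effects(r_traits: float) -> float:
    """Attenuation rule of thumb: between-scan allele-effect correlation
    approximately equals the squared correlation between the two trait
    measurements, so agreement collapses quickly once repeatability drops
    below ~0.95."""
    if not -1 <= r_traits <= 1:
        raise ValueError("correlation must lie in [-1, 1]")
    return r_traits**2


@dataclass
class RegionCluster:
    """A run of significant SNPs on one chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int
    n_significant: int
    n_total: int  # all SNPs falling within [start_bp, end_bp]

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def region_clusters(
    res: GwasResult, alpha: float = 0.001, max_gap_bp: int = 1_000_000
) -> list[RegionCluster]:
    """Chain significant SNPs into map clusters.

    Consecutive significant SNPs on one chromosome are chained while their
    separation is <= ``max_gap_bp``; each cluster reports its span (first to
    last significant SNP), the significant count and the total SNP count
    inside the span.  Clusters are returned sorted by significant count
    (largest first), then chromosome/position.
    """
    sig = res.significant(alpha)
    clusters: list[RegionCluster] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        segments = np.split(pos, breaks + 1)
        chrom_all = res.table[(res.table["chrom"] == chrom)]
        for seg in segments:
            start, end = int(seg[0]), int(seg[-1])
            n_total = int(((chrom_all["pos"] >= start) & (chrom_all["pos"] <= end)).sum())
            clusters.append(
                RegionCluster(str(chrom), start, end, n_significant=len(seg), n_total=n_total)
            )
    return sorted(clusters, key=lambda c: (-c.n_significant, c.chromosome, c.start_bp))


def chromosome_summary(
    res: GwasResult, alpha: float = 0.001, top_n: int = 5, share: str = "top1"
) -> dict:
    """Chromosomes ranked by significant-SNP count, plus the share statistic.

    ``share="top1"`` (default) is 100 x significant SNPs on the top-ranked
    chromosome over all significant SNPs; ``share="top{n}"`` sums the top n.
    Ties rank by smaller chromosome label (numeric where possible).
    """
    sig = res.significant(alpha)
    if sig.empty:
        return {"ranking": [], "counts": {}, "share_percent": float("nan")}

    def chrom_key(c):
        try:
            return (0, float(c))
        except ValueError:
            return (1, c)

    counts = sig.groupby("chrom")["snp"].count()
    ranked = sorted(counts.index, key=lambda c: (-counts[c], chrom_key(c)))
    top = ranked[:top_n]
    k = 1 if share == "top1" else min(int(share.replace("top", "")), len(ranked))
    share_pct = 100.0 * sum(counts[c] for c in ranked[:k]) / counts.sum()
    return {
        "ranking": top,
        "counts": {c: int(counts[c]) for c in top},
        "share_percent": float(share_pct),
    }


@dataclass
class ConcordanceReport:
    """All between-scan comparison statistics for one pair of GWAS."""

    trait_comparison: dict
    r_effects: float
    r_logp: float
    n_common_tested: int
    shared_significant: dict  # alpha -> list of SNP ids
    n_significant: dict  # alpha -> (count scan 1, count scan 2)
    fpr_percent: dict  # alpha -> (scan 1, scan 2)
    clusters_1: list[RegionCluster] = field(default_factory=list)
    clusters_2: list[RegionCluster] = field(default_factory=list)
    chromosomes_1: dict = field(default_factory=dict)
    chromosomes_2: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, RegionCluster):
                return {**asdict(o), "span_kb": o.span_kb}
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(asdict_safe(self), fh, indent=2, default=default)

    def to_tsv(self, path: str | Path) -> None:
        """Human-readable one-row-per-alpha table of the scan comparison."""
        rows = []
        for alpha in self.shared_significant:
            n1, n2 = self.n_significant[alpha]
            f1, f2 = self.fpr_percent[alpha]
            rows.append(
                {
                    "alpha": alpha,
                    "n_sig_1": n1,
                    "n_sig_2": n2,
                    "fpr_1_pct": f1,
                    "fpr_2_pct": f2,
                    "n_common": len(self.shared_significant[alpha]),
                    "r_effects": self.r_effects,
                    "r_logp": self.r_logp,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")


def asdict_safe(report: ConcordanceReport) -> dict:
    d = asdict(report)
    d["clusters_1"] = [{**asdict(c), "span_kb": c.span_kb} for c in report.clusters_1]
    d["clusters_2"] = [{**asdict(c), "span_kb": c.span_kb} for c in report.clusters_2]
    return d


def compare_gwas(
    res1: GwasResult,
    res2: GwasResult,
    alphas: Sequence[float] = (0.001, 0.0001),
    y1: pd.Series | None = None,
    y2: pd.Series | None = None,
    e_p_snp_count: int | None = None,
    max_gap_bp: int = 1_000_000,
) -> ConcordanceReport:
    """Compare two association scans over their common tested SNPs.

    Correlations of allele effects and of -log10 p are computed on the
    intersection of SNPs tested in both scans.  FPR uses the scan's own
    tested-SNP count unless ``e_p_snp_count`` (e.g. the array size) is given.
    Trait vectors, if supplied, are compared on their shared animals.
    """
    t1 = res1.table.set_index("snp")
    t2 = res2.table.set_index("snp")
    common = t1.index[t1["tested"]].intersection(t2.index[t2["tested"]])
    if len(common) == 0:
        raise ValueError("the two scans share no tested SNPs")
    b1, b2 = t1.loc[common, "b"], t2.loc[common, "b"]
    lp1 = -np.log10(t1.loc[common, "p"].astype(float))
    lp2 = -np.log10(t2.loc[common, "p"].astype(float))
    r_effects = float(np.corrcoef(b1, b2)[0, 1])
    r_logp = float(np.corrcoef(lp1, lp2)[0, 1])

    shared, n_sig, fprs = {}, {}, {}
    for alpha in alphas:
        s1 = set(res1.significant(alpha)["snp"])
        s2 = set(res2.significant(alpha)["snp"])
        shared[alpha] = sorted(s1 & s2)
        n_sig[alpha] = (len(s1), len(s2))
        n1 = e_p_snp_count or res1.n_tested
        n2 = e_p_snp_count or res2.n_tested
        fprs[alpha] = (fpr(n1, alpha, len(s1)), fpr(n2, alpha, len(s2)))

    trait_cmp = {}
    if y1 is not None and y2 is not None:
        ids = y1.dropna().index.intersection(y2.dropna().index)
        trait_cmp = compare_traits(y1.loc[ids], y2.loc[ids])

    alpha0 = alphas[0]
    return ConcordanceReport(
        trait_comparison=trait_cmp,
        r_effects=r_effects,
        r_logp=r_logp,
        n_common_tested=len(common),
        shared_significant=shared,
        n_significant=n_sig,
        fpr_percent=fprs,
        clusters_1=region_clusters(res1, alpha0, max_gap_bp),
        clusters_2=region_clusters(res2, alpha0, max_gap_bp),
        chromosomes_1=chromosome_summary(res1, alpha0),
        chromosomes_2=chromosome_summary(res2, alpha0),
        metadata={
            "trait_1": res1.metadata.get("trait"),
            "trait_2": res2.metadata.get("trait"),
            "alphas": list(alphas),
        },
    )
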