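"""Single-SNP association scan under the animal model.

The model is ``y = X beta + g b + a + e`` with a polygenic animal effect
``a ~ N(0, A sigma2_a)`` structured by the pedigree numerator relationship
matrix and residual ``e ~ N(0, sigma2_e I)``.  Each SNP is tested one at a
time by generalised least squares on the allele dosage g in {0, 1, 2}; the
test is the t-ratio of the allele effect over its standard error.

Variance components are estimated by REML using the spectral decomposition
of A: with A = U diag(s) U', the covariance V = sigma2_a A + sigma2_e I is
diagonal in the rotated basis, so each likelihood evaluation is O(n) after
a single O(n^3) eigendecomposition, and the REML criterion is maximised by
a bounded one-dimensional search over the variance ratio.  In ``p3d`` mode
("population parameters previously determined") the components are
estimated once under the null model and reused for every SNP; ``exact``
mode re-estimates them per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Pedigree, RelationshipMatrix, build_nrm

logger = logging.getLogger(__name__)

__all__ = [
    "FixedDesign",
    "VarianceComponents",
    "NullModelFit",
    "SnpAssociation",
    "GwasResult",
    "build_fixed_design",
    "fit_null_model",
    "snp_association",
    "run_gwas",
    "trend_test",
]


class RankError(ValueError):
    """Fixed-effect design is rank deficient."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class FixedDesign:
    """Full-rank fixed-effect design matrix with intercept.

    Factor columns are expanded to treatment-coded dummies (first level
    dropped).  Herd is treated as nested in breed by composing a
    ``breed:herd`` label before expansion, and sex/slaughter-group arrive
    already concatenated as one ``ssg`` factor.
    """

    matrix: np.ndarray
    columns: list[str]
    animals: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        r = np.linalg.matrix_rank(self.matrix)
        if r < self.matrix.shape[1]:
            aliased = _aliased_columns(self.matrix, self.columns)
            raise RankError(f"design matrix rank deficient; aliased columns: {aliased}")

    @property
    def rank(self) -> int:
        return self.matrix.shape[1]

    def subset(self, animals: Sequence[str]) -> "FixedDesign":
        pos = {a: i for i, a in enumerate(self.animals)}
        idx = [pos[a] for a in animals]
        M = self.matrix[idx]
        keep = [j for j in range(M.shape[1]) if j == 0 or M[:, j].std() > 0]
        M = M[:, keep]
        # dropping empty levels can still leave aliasing; prune to full rank
        q, r = np.linalg.qr(M)
        indep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
        M = M[:, indep]
        cols = [self.columns[keep[j]] for j in np.flatnonzero(indep)]
        return FixedDesign(M, cols, list(animals))


def _aliased_columns(M: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(M)
    d = np.abs(np.diag(r))
    bad = d <= 1e-9 * max(1.0, d.max())
    return [n for n, b in zip(names, bad) if b]


def build_fixed_design(
    factors: pd.DataFrame,
    breed_col: str = "breed",
    herd_col: str = "herd",
    ssg_col: str = "ssg",
) -> FixedDesign:
    """Intercept + herd-nested-in-breed + ssg dummies from a factor table."""
    df = factors.copy()
    pieces = [pd.Series(1.0, index=df.index, name="intercept")]
    if herd_col in df:
        lab = df[herd_col].astype(str)
        if breed_col in df:
            # nest herd in breed; herds already labelled by breed stay as-is
            lab = pd.Series(
                [h if h.startswith(b) else f"{b}:{h}"
                 for b, h in zip(df[breed_col].astype(str), lab)],
                index=df.index,
            )
        pieces.append(pd.get_dummies(lab, prefix="herd", drop_first=True, dtype=float))
    if ssg_col in df:
        pieces.append(
            pd.get_dummies(df[ssg_col].astype(str), prefix="ssg", drop_first=True, dtype=float)
        )
    X = pd.concat(pieces, axis=1)
    return FixedDesign(X.to_numpy(), list(X.columns), [str(a) for a in df.index])


@dataclass
class VarianceComponents:
    sigma2_a: float  # polygenic variance, mm^2
    sigma2_e: float  # residual variance, mm^2

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")
        if self.sigma2_a == 0 and self.sigma2_e == 0:
            raise ValueError("variance components cannot both be 0")


@dataclass
class EigenA:
    """Cached spectral decomposition of a relationship matrix."""

    animals: list[str]
    s: np.ndarray
    U: np.ndarray

    @classmethod
    def from_matrix(cls, A: RelationshipMatrix) -> "EigenA":
        s, U = np.linalg.eigh(A.values)
        return cls(list(A.animals), np.maximum(s, 0.0), U)


@dataclass
class NullModelFit:
    """REML fit of the no-SNP animal model."""

    vc: VarianceComponents
    beta: np.ndarray
    columns: list[str]
    animals: list[str]
    adjusted: pd.Series  # y - X beta (genetic + residual retained)
    loglik: float
    eigen: EigenA
    _y: np.ndarray
    _X: np.ndarray

    def blup_a(self) -> pd.Series:
        """BLUP of the polygenic effect, a_hat = sigma2_a A V^-1 (y - X beta)."""
        s, U = self.eigen.s, self.eigen.U
        d = self.vc.sigma2_a * s + self.vc.sigma2_e
        resid = self._y - self._X @ self.beta
        w = (U.T @ resid) / d
        a_hat = U @ (self.vc.sigma2_a * s * w)
        return pd.Series(a_hat, index=self.animals, name="blup_a")

    def adjusted_phenotype(self, subtract_blup: bool = False) -> pd.Series:
        if not subtract_blup:
            return self.adjusted
        return self.adjusted - self.blup_a()


def _reml_profile(lam: float, ys: np.ndarray, Xs: np.ndarray, s: np.ndarray):
    """Profiled REML criterion at variance ratio lam = sigma2_a/sigma2_e."""
    n, p = Xs.shape
    d = lam * s + 1.0
    w = 1.0 / d
    Xw = Xs * w[:, None]
    XtX = Xs.T @ Xw
    Xty = Xw.T @ ys
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    resid = ys - Xs @ beta
    rss = float(resid @ (resid * w))
    if rss <= 0:
        return -np.inf, None, None
    sigma2_e = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return -np.inf, None, None
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + np.sum(np.log(d)) + logdet_xtx)
    return ll, beta, sigma2_e


def fit_null_model(
    y: pd.Series | np.ndarray,
    X: FixedDesign | np.ndarray,
    A: RelationshipMatrix | EigenA,
) -> NullModelFit:
    """REML estimates of (sigma2_a, sigma2_e) for y = X beta + a + e.

    Returns the variance components, GLS fixed-effect estimates and the
    adjusted phenotype y - X beta_hat (polygenic and residual variation
    retained).  Deterministic given the inputs.
    """
    if isinstance(X, FixedDesign):
        animals, Xmat, cols = X.animals, X.matrix, X.columns
    else:
        Xmat = np.asarray(X, dtype=float)
        animals = list(y.index) if isinstance(y, pd.Series) else [str(i) for i in range(len(Xmat))]
        cols = [f"x{j}" for j in range(Xmat.shape[1])]
        if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
            raise RankError(
                f"design matrix rank deficient; aliased columns: {_aliased_columns(Xmat, cols)}"
            )
    yv = np.asarray(y, dtype=float)
    if isinstance(A, RelationshipMatrix):
        eigen = EigenA.from_matrix(A.reorder(animals))
    else:
        eigen = A
        if eigen.animals != list(animals):
            raise ValueError("eigendecomposition animal order does not match design")
    n, p = Xmat.shape
    if len(yv) != n or len(eigen.s) != n:
        raise ValueError("dimension mismatch between y, X and A")

    ys = eigen.U.T @ yv
    Xs = eigen.U.T @ Xmat

    trace: list[tuple[float, float]] = []

    def neg(loglam: float) -> float:
        ll, _, _ = _reml_profile(float(np.exp(loglam)), ys, Xs, eigen.s)
        trace.append((float(np.exp(loglam)), ll))
        return -ll

    # coarse grid then bounded refinement over log lambda
    grid = np.linspace(-12.0, 12.0, 25)
    vals = np.array([neg(g) for g in grid])
    if not np.isfinite(vals).any():
        raise ConvergenceError("REML criterion not finite anywhere on the grid", trace)
    k = int(np.nanargmin(vals))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    ll_lam, _, _ = _reml_profile(lam, ys, Xs, eigen.s)
    # boundary: no polygenic variance; ties (flat criterion) break to lam = 0
    ll0, _, _ = _reml_profile(0.0, ys, Xs, eigen.s)
    if ll0 >= ll_lam - 1e-6:
        lam = 0.0
    ll, beta, sigma2_e = _reml_profile(lam, ys, Xs, eigen.s)
    if beta is None or not np.isfinite(ll):
        raise ConvergenceError("REML optimisation failed to converge", trace)
    vc = VarianceComponents(sigma2_a=lam * sigma2_e, sigma2_e=sigma2_e)
    adjusted = pd.Series(yv - Xmat @ beta, index=animals, name="adjusted")
    return NullModelFit(
        vc=vc, beta=beta, columns=cols, animals=list(animals), adjusted=adjusted,
        loglik=ll, eigen=eigen, _y=yv, _X=Xmat,
    )


def reml_loglik(vc: VarianceComponents, fit: NullModelFit) -> float:
    """Unprofiled REML log-likelihood at arbitrary variance components."""
    s, U = fit.eigen.s, fit.eigen.U
    d = vc.sigma2_a * s + vc.sigma2_e
    if np.any(d <= 0):
        return -np.inf
    ys = U.T @ fit._y
    Xs = U.T @ fit._X
    w = 1.0 / d
    XtX = Xs.T @ (Xs * w[:, None])
    beta = np.linalg.solve(XtX, (Xs * w[:, None]).T @ ys)
    resid = ys - Xs @ beta
    sign, logdet = np.linalg.slogdet(XtX)
    return float(-0.5 * (np.sum(np.log(d)) + logdet + resid @ (resid * w)))


def vc_standard_errors(fit: NullModelFit, rel_step: float = 1e-4) -> tuple[float, float]:
    """Asymptotic s.e. of (sigma2_a, sigma2_e) from the numeric REML Hessian."""
    theta = np.array([fit.vc.sigma2_a, fit.vc.sigma2_e])
    scale = np.maximum(np.abs(theta), 1e-3 * max(theta.sum(), 1.0))
    h = rel_step * scale

    def ll(t):
        return reml_loglik(VarianceComponents(max(t[0], 0.0), max(t[1], 1e-12)), fit)

    H = np.zeros((2, 2))
    f0 = ll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            if i == j:
                H[i, i] = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    cov = np.linalg.inv(-H)
    return float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))


@dataclass
class SnpAssociation:
    """Per-SNP allele-effect estimate from the single-SNP animal model."""

    snp_id: str
    chromosome: str = ""
    position_bp: int = 0
    allele: str = "A"
    f: float = np.nan  # reference-allele frequency in the analysed animals
    b: float = np.nan  # allele effect, mm per copy
    se: float = np.nan
    t: float = np.nan
    p: float = np.nan
    tested: bool = True
    n: int = 0


def _whiten(eigen: EigenA, vc: VarianceComponents):
    d = vc.sigma2_a * eigen.s + vc.sigma2_e
    return eigen.U.T / np.sqrt(d)[:, None]


def snp_association(
    y: np.ndarray | pd.Series,
    X: FixedDesign | np.ndarray,
    A: RelationshipMatrix | EigenA,
    g: np.ndarray | pd.Series,
    vc: VarianceComponents,
    snp_id: str = "snp",
) -> SnpAssociation:
    """GLS fit of one SNP: y = X beta + g b + a + e, V = sigma2_a A + sigma2_e I.

    Animals with missing phenotype or genotype are dropped casewise.  The
    standard error is the GLS sampling s.e. of b with the residual scale
    re-estimated from the fitted model; the p-value is two-sided Student t
    with df = n - rank(X) - 1.  A monomorphic dosage yields an untested flag.
    """
    yv = np.asarray(y, dtype=float)
    gv = np.asarray(g, dtype=float)
    Xmat = X.matrix if isinstance(X, FixedDesign) else np.asarray(X, dtype=float)
    keep = np.isfinite(yv) & np.isfinite(gv)
    if not keep.all():
        yv, gv, Xmat = yv[keep], gv[keep], Xmat[keep]
        if isinstance(A, RelationshipMatrix):
            animals = [a for a, k in zip(A.animals, keep) if k]
            A = A.reorder(animals)
        else:
            raise ValueError("casewise deletion requires the full RelationshipMatrix")
    n, p = Xmat.shape
    f = float(gv.mean() / 2.0)
    if np.ptp(gv) == 0:
        return SnpAssociation(snp_id, f=f, tested=False, n=n)
    if n <= p + 1:
        raise ValueError(f"too few animals (n={n}) for rank(X)={p} plus a SNP effect")
    eigen = EigenA.from_matrix(A) if isinstance(A, RelationshipMatrix) else A
    W = _whiten(eigen, vc)
    ys, Xs, gs = W @ yv, W @ Xmat, W @ gv
    Q, _ = np.linalg.qr(Xs)
    ry = ys - Q @ (Q.T @ ys)
    rg = gs - Q @ (Q.T @ gs)
    sxx = float(rg @ rg)
    if sxx <= 1e-12:
        return SnpAssociation(snp_id, f=f, tested=False, n=n)
    b = float(rg @ ry) / sxx
    df = n - p - 1
    rss = float(ry @ ry) - b * b * sxx
    sigma2 = max(rss, 0.0) / df
    se = float(np.sqrt(sigma2 / sxx))
    t = b / se if se > 0 else np.inf
    pval = float(2.0 * stats.t.sf(abs(t), df))
    return SnpAssociation(snp_id, f=f, b=b, se=se, t=t, p=max(pval, np.finfo(float).tiny),
                          tested=True, n=n)


@dataclass
class GwasResult:
    """Per-SNP association table plus scan metadata, map-sorted."""

    table: pd.DataFrame  # snp, chrom, pos, allele, f, b, se, t, p, tested, n
    metadata: dict = field(default_factory=dict)

    def significant(self, alpha: float) -> pd.DataFrame:
        t = self.table
        return t[(t["tested"]) & (t["p"] < alpha)]

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_gwas(
    y: pd.Series,
    factors: pd.DataFrame,
    relationship: Pedigree | RelationshipMatrix,
    dosages: pd.DataFrame,
    snp_map: pd.DataFrame | None = None,
    mode: str = "p3d",
    vc: VarianceComponents | None = None,
    trait_name: str = "trait",
    alphas: Sequence[float] = (0.001, 0.0001),
) -> GwasResult:
    """Single-SNP scan over a dosage matrix (animals x SNPs).

    ``p3d`` estimates variance components once under the null model and
    reuses them for every SNP; ``exact`` re-estimates them per SNP with the
    SNP in the fixed part.  Animals are the intersection of the phenotype,
    factor and genotype tables (phenotype order); SNPs with any missing
    dosage are handled casewise, monomorphic SNPs are flagged untested.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = [a for a in y.index if np.isfinite(y.get(a, np.nan))]
    ids = [a for a in ids if a in dosages.index and a in factors.index]
    if not ids:
        raise ValueError("no animals shared by phenotypes, factors and genotypes")
    yv = y.loc[ids]
    design = build_fixed_design(factors.loc[ids])
    design = design.subset(ids)  # prune empty/aliased levels on this subset
    if isinstance(relationship, Pedigree):
        A = build_nrm(relationship, order=ids)
    else:
        A = relationship.reorder(ids)
    eigen = EigenA.from_matrix(A)
    null = fit_null_model(yv, design, eigen)
    vc_used = vc or null.vc

    G = dosages.loc[ids].to_numpy(dtype=float)
    n, m = G.shape
    p = design.rank
    snp_ids = list(dosages.columns)

    polymorphic = np.nanstd(G, axis=0) > 0
    has_missing = np.isnan(G).any(axis=0)
    freqs = np.nanmean(G, axis=0) / 2.0

    b = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    nn = np.full(m, n)
    tested = polymorphic.copy()

    easy = polymorphic & ~has_missing
    if mode == "p3d" and easy.any():
        W = _whiten(eigen, vc_used)
        ys = W @ yv.to_numpy(dtype=float)
        Xs = W @ design.matrix
        Gs = W @ G[:, easy]
        Q, _ = np.linalg.qr(Xs)
        ry = ys - Q @ (Q.T @ ys)
        RG = Gs - Q @ (Q.T @ Gs)
        sxx = np.einsum("ij,ij->j", RG, RG)
        sxy = RG.T @ ry
        ok = sxx > 1e-12
        df = n - p - 1
        bb = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        rss = float(ry @ ry) - bb * bb * sxx
        sig2 = np.maximum(rss, 0.0) / df
        sse = np.sqrt(sig2 / np.where(ok, sxx, np.nan))
        tt = bb / sse
        pp = 2.0 * stats.t.sf(np.abs(tt), df)
        cols = np.flatnonzero(easy)
        b[cols], se[cols], tstat[cols], pval[cols] = bb, sse, tt, pp
        tested[cols] = ok
    else:
        for j in np.flatnonzero(easy):
            res = _one_snp(yv, design, A, eigen, G[:, j], mode, vc_used, snp_ids[j])
            b[j], se[j], tstat[j], pval[j], tested[j], nn[j] = (
                res.b, res.se, res.t, res.p, res.tested, res.n,
            )
    for j in np.flatnonzero(polymorphic & has_missing):
        res = _one_snp(yv, design, A, eigen, G[:, j], mode, vc_used, snp_ids[j])
        b[j], se[j], tstat[j], pval[j], tested[j], nn[j] = (
            res.b, res.se, res.t, res.p, res.tested, res.n,
        )

    pval = np.where(tested, np.maximum(pval, np.finfo(float).tiny), np.nan)
    table = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": "0",
            "pos": 0,
            "allele": "A",
            "f": freqs,
            "b": b,
            "se": se,
            "t": tstat,
            "p": pval,
            "tested": tested,
            "n": nn,
        }
    )
    if snp_map is not None:
        mp = snp_map.set_index("snp")
        table["chrom"] = table["snp"].map(mp["chrom"]).astype(str)
        table["pos"] = table["snp"].map(mp["pos"]).astype(int)
        chrom_order = {c: i for i, c in enumerate(mp["chrom"].unique())}
        table = table.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
    n_skipped = int((~tested).sum())
    if tested.sum() == 0:
        logger.warning("no polymorphic SNPs: empty association scan")
    logger.info(
        "GWAS %s: %d animals, %d SNPs tested, %d skipped (mode=%s)",
        trait_name, n, int(tested.sum()), n_skipped, mode,
    )
    return GwasResult(
        table=table,
        metadata={
            "trait": trait_name,
            "n_animals": n,
            "n_snps_tested": int(tested.sum()),
            "n_snps_skipped": n_skipped,
            "mode": mode,
            "alphas": list(alphas),
            "sigma2_a": vc_used.sigma2_a,
            "sigma2_e": vc_used.sigma2_e,
        },
    )


def _one_snp(yv, design, A, eigen, g, mode, vc, snp_id):
    missing = ~np.isfinite(np.asarray(g, dtype=float))
    if mode == "exact":
        if missing.any():
            ids = [a for a, miss in zip(design.animals, missing) if not miss]
            sub_design = design.subset(ids)
            Xg = np.column_stack([sub_design.matrix, np.asarray(g, float)[~missing]])
            sub_A = A.reorder(ids)
            fit = fit_null_model(yv.loc[ids], Xg, sub_A)
            return snp_association(
                yv.loc[ids], sub_design, sub_A, np.asarray(g, float)[~missing], fit.vc, snp_id
            )
        gv = np.asarray(g, dtype=float)
        if np.ptp(gv) == 0:
            return SnpAssociation(snp_id, f=float(gv.mean() / 2), tested=False, n=len(gv))
        Xg = np.column_stack([design.matrix, gv])
        fit = fit_null_model(yv, Xg, eigen)
        return snp_association(yv, design, eigen, gv, fit.vc, snp_id)
    return snp_association(yv, design, A, g, vc, snp_id)


def trend_test(status: np.ndarray | pd.Series, g: np.ndarray | pd.Series):
    """Cochran-Armitage trend test of affected status on allele dosage.

    Scores (0, 1, 2).  Returns the signed standard-normal statistic
    z = T / sqrt(Var T) with T = sum_j w_j (N r_j - R n_j), where r_j / n_j
    are affected / total counts in dosage class j, R the total affected and
    N the sample size; the two-sided p comes from the asymptotic normal null.
    """
    sv = np.asarray(status, dtype=int)
    gv = np.asarray(g, dtype=int)
    if set(np.unique(sv)) - {0, 1}:
        raise ValueError("status must be binary 0/1")
    if sv.min() == sv.max():
        raise ValueError("both affected and unaffected animals are required")
    if np.ptp(gv) == 0:
        raise ValueError("monomorphic genotype")
    N = len(sv)
    R = int(sv.sum())
    w = np.array([0.0, 1.0, 2.0])
    n_j = np.array([(gv == j).sum() for j in (0, 1, 2)], dtype=float)
    r_j = np.array([(sv[gv == j] == 1).sum() for j in (0, 1, 2)], dtype=float)
    T = float(np.sum(w * (N * r_j - R * n_j)))
    var = R * (N - R) * (N * np.sum(w**2 * n_j) - np.sum(w * n_j) ** 2) / N
    if var <= 0:
        raise ValueError("degenerate trend-test variance")
    z = T / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p
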