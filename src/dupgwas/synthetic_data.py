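"""Synthetic populations with duplicate error-contaminated trait measurements.

The generator emulates the data structure the pipeline analyses: a multi-breed
half-sib pedigree (sires with unrelated dams), a panel of mapped biallelic
SNPs gene-dropped through the pedigree, one or more QTL, a polygenic animal
effect with covariance ``A * sigma2_a``, herd-within-breed and sex-by-slaughter
-group fixed effects, and two integer-millimetre measurements of the trait per
animal whose errors combine small measurement noise, rare large "operator
blunder" deviations, a constant between-team offset, digit heaping at a
preferred value, rounding to 1 mm and a floor at zero.

Two linkage modes are provided.  ``independent`` gene-drops every locus
independently (no LD); ``blocks`` draws founder haplotypes from a small pool
per chromosome block and transmits whole blocks, creating local LD so that
clusters of significant SNPs form around a QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .pedigree import Pedigree, PedigreeRecord, build_nrm, write_pedigree

__all__ = [
    "QtlSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_population",
    "simulate_measurements",
    "calibrate_error_sd",
]


@dataclass(frozen=True)
class QtlSpec:
    """One biallelic QTL: location, additive effect and allele frequency."""

    chromosome: str
    position_bp: int
    effect_mm: float  # mm of trait per copy of the reference allele
    freq: float


def _default_chrom_lengths() -> dict[str, int]:
    return {str(c): 60_000_000 for c in range(1, 15)}


def _default_qtls() -> list[QtlSpec]:
    # two linked QTL ~1 Mb apart on one chromosome
    return [
        QtlSpec("14", 24_000_000, 1.0, 0.30),
        QtlSpec("14", 25_200_000, 0.8, 0.25),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults at the study's cohort scale.

    The defaults produce a genotyped cohort of roughly 940 half-sib offspring
    of 94 sires across 7 breeds, 2 000 mapped SNPs on 14 chromosomes, two
    linked QTL ~1 Mb apart, variance components sigma2_a = sigma2_e = 8 mm²
    (heritability 0.5) around an 11 mm trait mean, and a duplicate-measurement
    error model (2 mm noise, 5% blunders of 8 mm s.d., +0.9 mm offset on the
    second measurement, heaping at 10 mm) whose between-measurement
    correlation lands near 0.7.
    """

    seed: int = 0
    # pedigree
    n_sires: int = 94
    sibship_range: tuple[int, int] = (1, 19)
    founder_generations: int = 1  # 2 links sires to founder grandparents
    n_breeds: int = 7
    herds_per_breed: int = 2
    n_slaughter_groups: int = 4
    # genotypes
    n_snps: int = 2000
    chrom_lengths: dict[str, int] = field(default_factory=_default_chrom_lengths)
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    qtl_specs: list[QtlSpec] = field(default_factory=_default_qtls)
    ld_mode: str = "independent"  # or "blocks"
    block_kb: float = 250.0
    n_block_haplotypes: int = 8
    # trait model (mm / mm^2)
    sigma2_a: float = 8.0
    sigma2_e: float = 8.0
    trait_mean: float = 11.0
    herd_sd: float = 1.5
    ssg_sd: float = 1.0
    # duplicate-measurement error model (mm)
    sigma_small: float = 2.0
    blunder_prob: float = 0.05
    sigma_blunder: float = 8.0
    offset_delta: float = 0.9
    heaping_value: float = 10.0
    heaping_prob: float = 0.10

    def __post_init__(self) -> None:
        self.qtl_specs = [
            q if isinstance(q, QtlSpec) else QtlSpec(str(q[0]), int(q[1]), float(q[2]), float(q[3]))
            if not isinstance(q, dict) else QtlSpec(**q)
            for q in self.qtl_specs
        ]
        self.chrom_lengths = {str(k): int(v) for k, v in self.chrom_lengths.items()}
        self.validate()

    def validate(self) -> None:
        if min(self.sigma2_a, self.sigma2_e) < 0:
            raise ValueError("variance components must be >= 0")
        for p in (self.blunder_prob, self.heaping_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        if self.sibship_range[0] < 1 or self.sibship_range[0] > self.sibship_range[1]:
            raise ValueError("invalid sibship_range")
        if self.ld_mode not in ("independent", "blocks"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        for q in self.qtl_specs:
            if not 0 < q.freq < 1:
                raise ValueError(f"monomorphic QTL (freq={q.freq}) at {q.chromosome}:{q.position_bp}")
            if q.chromosome not in self.chrom_lengths:
                raise ValueError(f"QTL chromosome {q.chromosome!r} not in chrom_lengths")
            if not 0 <= q.position_bp <= self.chrom_lengths[q.chromosome]:
                raise ValueError("QTL position outside its chromosome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sibship_range" in data:
            data["sibship_range"] = tuple(data["sibship_range"])
        if "allele_freq_range" in data:
            data["allele_freq_range"] = tuple(data["allele_freq_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sibship_range"] = list(self.sibship_range)
        data["allele_freq_range"] = list(self.allele_freq_range)
        data["qtl_specs"] = [asdict(q) for q in self.qtl_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    """A simulated population: pedigree, genotypes, liabilities, measurements.

    Haplotype arrays cover every pedigree animal (row order = ``animals``);
    ``hap_paternal``/``hap_maternal`` hold counts (0/1) of the reference
    allele "A".  ``cohort`` lists the phenotyped offspring generation, which
    is what the association scan analyses.
    """

    config: SimulationConfig
    pedigree: Pedigree
    animals: list[str]
    cohort: list[str]
    snp_map: pd.DataFrame  # columns snp, chrom, pos
    hap_paternal: np.ndarray
    hap_maternal: np.ndarray
    qtl: pd.DataFrame  # chrom, pos, effect_mm, freq
    qtl_dosage: np.ndarray  # animals x n_qtl
    factors: pd.DataFrame  # index animal: breed, herd, ssg
    y_true: pd.Series
    measurement_1: pd.Series
    measurement_2: pd.Series

    @property
    def dosages(self) -> np.ndarray:
        """Reference-allele dosage matrix (animals x SNPs), values {0,1,2}."""
        return (self.hap_paternal + self.hap_maternal).astype(np.int8)

    def phenotype_table(self, include_y_true: bool = True) -> pd.DataFrame:
        """Phenotype CSV contents for the genotyped cohort."""
        df = self.factors.loc[self.cohort].copy()
        df.insert(0, "animal", df.index)
        df["m1"] = self.measurement_1.loc[self.cohort].astype(int).values
        df["m2"] = self.measurement_2.loc[self.cohort].astype(int).values
        if include_y_true:
            df["y_true"] = self.y_true.loc[self.cohort].values
        return df.reset_index(drop=True)

    def cohort_dosages(self) -> pd.DataFrame:
        idx = [self.animals.index(a) for a in self.cohort]
        return pd.DataFrame(
            self.dosages[idx], index=self.cohort, columns=self.snp_map["snp"].tolist()
        )

    # ------------------------------------------------------------- writers

    def write_pedigree_file(self, path: str | Path) -> None:
        write_pedigree(self.pedigree, path)

    def write_phenotypes_csv(self, path: str | Path, include_y_true: bool = True) -> None:
        self.phenotype_table(include_y_true).to_csv(path, index=False)

    def write_dosage_tsv(self, path: str | Path) -> None:
        self.cohort_dosages().to_csv(path, sep="\t", index_label="animal")

    def write_ped_map(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write PLINK text .ped/.map; reference allele "A", alternate "B"."""
        prefix = Path(prefix)
        ped_path = prefix.with_suffix(".ped")
        map_path = prefix.with_suffix(".map")
        self.snp_map.assign(cm=0)[["chrom", "snp", "cm", "pos"]].to_csv(
            map_path, sep="\t", header=False, index=False
        )
        idx = {a: i for i, a in enumerate(self.animals)}
        code = np.array(["B", "A"])
        with open(ped_path, "w") as fh:
            for a in self.cohort:
                i = idx[a]
                rec = self.pedigree.record(a)
                alleles = np.empty(2 * len(self.snp_map), dtype="U1")
                alleles[0::2] = code[self.hap_paternal[i]]
                alleles[1::2] = code[self.hap_maternal[i]]
                fh.write(
                    f"FAM {a} {rec.sire or '0'} {rec.dam or '0'} 0 -9 "
                    + " ".join(alleles)
                    + "\n"
                )
        return ped_path, map_path


# ---------------------------------------------------------------- helpers

def calibrate_error_sd(target_r: float, var_y: float) -> float:
    """Error s.d. giving corr(m1, m2) = ``target_r`` under classical error.

    With m_k = y + e_k, e_k ~ N(0, s²) independent, corr(m1, m2) =
    var(y)/(var(y)+s²); inverting gives s = sqrt(var_y (1-r)/r).
    """
    if not 0 < target_r <= 1:
        raise ValueError("target_r must lie in (0, 1]")
    if var_y <= 0:
        raise ValueError("var_y must be positive")
    return float(np.sqrt(var_y * (1.0 - target_r) / target_r))


def simulate_measurements(
    y_true: np.ndarray | pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two error-contaminated integer-mm measurements of a true value.

    Each measurement is ``round(max(0, y + delta_k + eps_k))`` where
    ``delta_1 = 0``, ``delta_2 = offset_delta`` and ``eps`` is drawn from
    N(0, sigma_small²) with probability 1 - blunder_prob, otherwise from
    N(0, sigma_blunder²) (the contaminated-normal "operator blunder"),
    independently per animal and per measurement.  Rounded values within
    2 mm of ``heaping_value`` are then attracted to it with probability
    ``heaping_prob`` (digit preference of manual scoring).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = np.asarray(y_true, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y_true must be finite")
    out = []
    for delta in (0.0, config.offset_delta):
        blunder = rng.random(y.shape) < config.blunder_prob
        sd = np.where(blunder, config.sigma_blunder, config.sigma_small)
        eps = rng.standard_normal(y.shape) * sd
        m = np.round(np.maximum(0.0, y + delta + eps))
        near = np.abs(m - config.heaping_value) <= 2.0
        heap = near & (rng.random(y.shape) < config.heaping_prob)
        m = np.where(heap, config.heaping_value, m)
        out.append(m)
    return out[0], out[1]


def _build_pedigree(config: SimulationConfig, rng: np.random.Generator):
    """Half-sib pedigree: sires (optionally with founder parents), one
    unrelated dam per offspring."""
    breeds = [f"B{b+1}" for b in range(config.n_breeds)]
    records: list[PedigreeRecord] = []
    sires, sire_breed = [], {}
    for s in range(config.n_sires):
        breed = breeds[s % config.n_breeds]
        sid = f"S{s+1}"
        sire_parents = (None, None)
        if config.founder_generations >= 2:
            gs, gd = f"GS{s+1}", f"GD{s+1}"
            records.append(PedigreeRecord(gs, breed=breed))
            records.append(PedigreeRecord(gd, breed=breed))
            sire_parents = (gs, gd)
        records.append(PedigreeRecord(sid, *sire_parents, breed=breed))
        sires.append(sid)
        sire_breed[sid] = breed
    lo, hi = config.sibship_range
    sibships = rng.integers(lo, hi + 1, size=config.n_sires)
    cohort = []
    k = 0
    for sid, nsib in zip(sires, sibships):
        breed = sire_breed[sid]
        for _ in range(nsib):
            k += 1
            dam = f"D{k}"
            kid = f"O{k}"
            herd = f"{breed}_h{rng.integers(1, config.herds_per_breed + 1)}"
            records.append(PedigreeRecord(dam, breed=breed, herd=herd))
            records.append(PedigreeRecord(kid, sid, dam, breed=breed, herd=herd))
            cohort.append(kid)
    return Pedigree(records), cohort


def _snp_positions(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(config.n_snps, lengths / lengths.sum())
    rows = []
    for c, n, L in zip(chroms, counts, lengths):
        pos = np.sort(rng.integers(1, int(L), size=n))
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["chrom", "pos"])
    df["snp"] = [f"snp{i:05d}_{c}_{p}" for i, (c, p) in enumerate(zip(df["chrom"], df["pos"]))]
    return df[["snp", "chrom", "pos"]]


def _drop_genotypes(ped, animals, loci, freqs, config, rng):
    is_qtl = loci["is_qtl"].to_numpy() if "is_qtl" in loci else np.zeros(len(loci), bool)
    """Gene-drop haplotypes through the pedigree.

    ``loci``: DataFrame with chrom/pos (map-sorted within chromosome).
    Founders draw alleles at the given frequencies; offspring receive one
    allele from each parent.  In ``blocks`` mode founder haplotypes come from
    a small per-block pool and meioses transmit whole blocks, giving local LD.
    """
    n_loci = len(loci)
    pos_of = {a: i for i, a in enumerate(animals)}
    hap_p = np.zeros((len(animals), n_loci), dtype=np.uint8)
    hap_m = np.zeros((len(animals), n_loci), dtype=np.uint8)

    if config.ld_mode == "blocks":
        block_bp = int(config.block_kb * 1000)
        block_id = np.zeros(n_loci, dtype=np.int64)
        bid = 0
        for c in loci["chrom"].unique():
            mask = (loci["chrom"] == c).to_numpy()
            ids = (loci.loc[mask, "pos"].to_numpy() // block_bp)
            _, inv = np.unique(ids, return_inverse=True)
            block_id[mask] = inv + bid
            bid += inv.max() + 1 if len(inv) else 0
        n_blocks = bid
        # per-block founder haplotype pool
        K = config.n_block_haplotypes
        pool = (rng.random((K, n_loci)) < freqs).astype(np.uint8)
        # a small pool can lose a QTL allele entirely; pin QTL pool columns
        # to carry the configured frequency (at least one copy of each allele)
        for j in np.flatnonzero(is_qtl):
            k = int(np.clip(round(freqs[j] * K), 1, K - 1))
            col = np.zeros(K, dtype=np.uint8)
            col[rng.choice(K, size=k, replace=False)] = 1
            pool[:, j] = col

        def founder_hap():
            choice = rng.integers(0, config.n_block_haplotypes, size=n_blocks)
            return pool[choice[block_id], np.arange(n_loci)]

        def meiosis(hp, hm):
            pick = rng.integers(0, 2, size=n_blocks)[block_id].astype(bool)
            return np.where(pick, hp, hm)

    else:

        def founder_hap():
            return (rng.random(n_loci) < freqs).astype(np.uint8)

        def meiosis(hp, hm):
            pick = rng.integers(0, 2, size=n_loci).astype(bool)
            return np.where(pick, hp, hm)

    idx = {r.animal: r for r in ped}
    for a in ped.topological_order():
        i = pos_of[a]
        rec = idx[a]
        for parent, target in ((rec.sire, hap_p), (rec.dam, hap_m)):
            if parent is None:
                target[i] = founder_hap()
            else:
                j = pos_of[parent]
                target[i] = meiosis(hap_p[j], hap_m[j])
    return hap_p, hap_m


def simulate_population(config: SimulationConfig) -> SimulatedStudy:
    """Generate a full study: pedigree, genotypes, liabilities, measurements.

    The true liability is ``y = mu + herd + ssg + sum_q dosage_q * effect_q
    + a + e`` with ``a ~ N(0, A sigma2_a)`` over the whole pedigree and
    ``e ~ N(0, sigma2_e I)``; the two measurements then contaminate ``y``
    via :func:`simulate_measurements`.  Bit-reproducible for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ped, cohort = _build_pedigree(config, rng)
    animals = ped.animals
    n = len(animals)

    # combined locus table: panel SNPs + QTL, map-sorted
    panel = _snp_positions(config, rng)
    lo, hi = config.allele_freq_range
    panel_freqs = rng.uniform(lo, hi, size=len(panel))
    qtl_df = pd.DataFrame(
        {
            "chrom": [q.chromosome for q in config.qtl_specs],
            "pos": [q.position_bp for q in config.qtl_specs],
            "effect_mm": [q.effect_mm for q in config.qtl_specs],
            "freq": [q.freq for q in config.qtl_specs],
        }
    )
    loci = pd.concat(
        [
            panel.assign(freq=panel_freqs, is_qtl=False),
            pd.DataFrame(
                {
                    "snp": [f"qtl_{c}_{p}" for c, p in zip(qtl_df["chrom"], qtl_df["pos"])],
                    "chrom": qtl_df["chrom"],
                    "pos": qtl_df["pos"],
                    "freq": qtl_df["freq"],
                    "is_qtl": True,
                }
            ),
        ],
        ignore_index=True,
    )
    chrom_order = {c: i for i, c in enumerate(config.chrom_lengths)}
    loci = loci.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
    ).reset_index(drop=True)

    hap_p, hap_m = _drop_genotypes(
        ped, animals, loci, loci["freq"].to_numpy(), config, rng
    )

    qtl_cols = np.flatnonzero(loci["is_qtl"].to_numpy())
    panel_cols = np.flatnonzero(~loci["is_qtl"].to_numpy())
    # QTL column order must follow the configured list, not map order
    qtl_key = {f"qtl_{q.chromosome}_{q.position_bp}": k for k, q in enumerate(config.qtl_specs)}
    qtl_cols = qtl_cols[np.argsort([qtl_key[loci["snp"].iloc[c]] for c in qtl_cols])]
    qtl_dosage = (hap_p[:, qtl_cols] + hap_m[:, qtl_cols]).astype(np.int8)

    snp_map = loci.iloc[panel_cols][["snp", "chrom", "pos"]].reset_index(drop=True)
    hap_p = np.ascontiguousarray(hap_p[:, panel_cols])
    hap_m = np.ascontiguousarray(hap_m[:, panel_cols])

    # fixed-effect factors for every animal
    breeds = [r.breed or "B1" for r in ped]
    herds = [
        r.herd or f"{r.breed or 'B1'}_h{rng.integers(1, config.herds_per_breed + 1)}"
        for r in ped
    ]
    ssg = [
        f"{rng.choice(['M', 'F'])}{rng.integers(1, config.n_slaughter_groups + 1)}"
        for _ in animals
    ]
    factors = pd.DataFrame({"breed": breeds, "herd": herds, "ssg": ssg}, index=animals)

    herd_levels = sorted(set(herds))
    ssg_levels = sorted(set(ssg))
    herd_eff = dict(zip(herd_levels, rng.standard_normal(len(herd_levels)) * config.herd_sd))
    ssg_eff = dict(zip(ssg_levels, rng.standard_normal(len(ssg_levels)) * config.ssg_sd))

    # polygenic effect over the full pedigree
    if config.sigma2_a > 0:
        A = build_nrm(ped).values
        L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        a = L @ rng.standard_normal(n) * np.sqrt(config.sigma2_a)
    else:
        a = np.zeros(n)
    e = rng.standard_normal(n) * np.sqrt(config.sigma2_e)

    qtl_effects = qtl_df["effect_mm"].to_numpy()
    y = (
        config.trait_mean
        + np.array([herd_eff[h] for h in herds])
        + np.array([ssg_eff[s] for s in ssg])
        + qtl_dosage @ qtl_effects
        + a
        + e
    )
    y_true = pd.Series(y, index=animals, name="y_true")

    m1, m2 = simulate_measurements(y, config, rng)
    return SimulatedStudy(
        config=config,
        pedigree=ped,
        animals=animals,
        cohort=cohort,
        snp_map=snp_map,
        hap_paternal=hap_p,
        hap_maternal=hap_m,
        qtl=qtl_df,
        qtl_dosage=qtl_dosage,
        factors=factors,
        y_true=y_true,
        measurement_1=pd.Series(m1, index=animals, name="m1"),
        measurement_2=pd.Series(m2, index=animals, name="m2"),
    )
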