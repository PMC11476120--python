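"""Synthetic dairy-herd generator.

Produces pedigrees, gene-dropped SNP genotypes, repeated test-day records
with the additive + permanent-environment + residual structure of the
repeatability animal model, and milk FT-MIR spectra built as Beer-Lambert
linear mixtures of component signatures.  Every downstream stage of the
pipeline (spectral preprocessing, PLSR calibration, phenotype correction,
REML, GWAS, validation) can therefore be exercised without external data.

The trait model behind each test-day record is

    y = mu + parity + lactation-stage + season + HTD + u + c + e

with u the animal's additive genetic value (a QTN part from a handful of
large-effect markers plus an infinitesimal polygenic part propagated down
the pedigree), c a per-cow permanent-environment deviate, HTD a random
herd-test-date contemporary-group effect and e the record residual.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# The instrument layout emulated throughout: 1060 absorbance points on
# 925.66-5010.15 cm^-1, with two noise-prone water-associated regions.
N_WAVES = 1060
WAVE_MIN = 925.66
WAVE_MAX = 5010.15
NOISE_REGIONS = ((1597.21, 1712.95), (3063.25, 3641.95))

SEASONS = ("Spring", "Summer", "Autumn", "Winter")


def default_wavenumbers() -> np.ndarray:
    """Uniform 1060-point wavenumber grid (cm^-1)."""
    return np.linspace(WAVE_MIN, WAVE_MAX, N_WAVES)


def season_of_month(month: int) -> str:
    """Calving season from calving month (Mar-May=Spring, ... Dec-Feb=Winter)."""
    if month in (3, 4, 5):
        return "Spring"
    if month in (6, 7, 8):
        return "Summer"
    if month in (9, 10, 11):
        return "Autumn"
    return "Winter"


@dataclass
class SimConfig:
    """Parameters of the synthetic herd.

    Variances are on the trait scale (trait units squared); the additive
    variance ``sigma_u2`` is partitioned between ``n_qtn`` marked SNPs and an
    infinitesimal polygenic component according to ``qtn_variance_frac``.
    """

    n_founders: int = 200
    n_generations: int = 3
    matings_per_generation: int = 400
    offspring_per_mating: int = 1
    n_snps: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtn: int = 5
    qtn_effect_sd: float | None = None  # None: scaled to qtn_variance_frac * sigma_u2
    qtn_variance_frac: float = 0.5
    mu: float = 10.0
    sigma_u2: float = 0.3
    sigma_c2: float = 0.2
    sigma_e2: float = 0.5
    records_per_cow: tuple[int, int] = (4, 7)
    fixed_effect_sizes: dict = field(default_factory=dict)
    n_htd: int = 40
    htd_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("sigma_u2", "sigma_c2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_qtn > self.n_snps:
            raise ValueError("n_qtn cannot exceed n_snps")
        if not 0.0 <= self.qtn_variance_frac <= 1.0:
            raise ValueError("qtn_variance_frac must lie in [0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Pedigree:
    """Topologically ordered pedigree; parent id 0 means unknown."""

    animal: np.ndarray  # int ids, 1-based
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray

    def __len__(self) -> int:
        return len(self.animal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam,
             "generation": self.generation}
        )

    def index_of(self) -> dict[int, int]:
        return {int(a): i for i, a in enumerate(self.animal)}


@dataclass
class GenotypeMatrix:
    """0/1/2 dosages of allele B; NaN encodes missing."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray  # animals x snps, float (NaN = missing)

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids, self.snp_ids[mask],
                              self.chrom[mask], self.pos[mask],
                              self.dosage[:, mask])

    def subset_animals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids[mask], self.snp_ids, self.chrom,
                              self.pos, self.dosage[mask])


@dataclass
class TraitTruth:
    """Realized simulation truth for one trait."""

    animal_ids: np.ndarray
    u: np.ndarray             # total additive value per animal
    c: np.ndarray             # permanent environment per animal
    qtn_indices: np.ndarray   # column indices into the genotype matrix
    qtn_effects: np.ndarray
    sigma_poly2: float


# ----------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random-mating multi-generation pedigree, parents always in the
    previous generation, topologically ordered."""
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config.n_generations == 0 and config.matings_per_generation > 0:
        raise ValueError("no parents available: n_generations=0 but matings requested")
    rng = np.random.default_rng(config.seed)
    animal, sire, dam, gen = [], [], [], []
    next_id = 1
    prev: list[int] = []
    for i in range(config.n_founders):
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        prev.append(next_id)
        next_id += 1
    for g in range(1, config.n_generations + 1):
        if not prev:
            raise ValueError("no parents available")
        # split previous generation into sires and dams
        prev_arr = np.array(prev)
        rng.shuffle(prev_arr)
        half = len(prev_arr) // 2
        sires_pool, dams_pool = prev_arr[:half], prev_arr[half:]
        if len(sires_pool) == 0 or len(dams_pool) == 0:
            raise ValueError("no parents available")
        cur: list[int] = []
        for _ in range(config.matings_per_generation):
            s = int(rng.choice(sires_pool))
            d = int(rng.choice(dams_pool))
            for _ in range(config.offspring_per_mating):
                animal.append(next_id)
                sire.append(s)
                dam.append(d)
                gen.append(g)
                cur.append(next_id)
                next_id += 1
        prev = cur
    return Pedigree(np.array(animal), np.array(sire), np.array(dam),
                    np.array(gen))


# ----------------------------------------------------------------------------
# genotypes (gene dropping)


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Founders from Hardy-Weinberg at per-SNP MAF; descendants get one
    allele per parent by Mendelian transmission."""
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_snps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], m)
    # SNP map: chromosomes 1-29 and X, positions strictly increasing within chrom
    chroms = [str(c) for c in range(1, 30)] + ["X"]
    chrom_assign = np.sort(rng.integers(0, len(chroms), m))
    chrom = np.array([chroms[i] for i in chrom_assign])
    pos = np.empty(m, dtype=np.int64)
    for ci in range(len(chroms)):
        idx = np.where(chrom_assign == ci)[0]
        if idx.size:
            draw = np.sort(rng.integers(1, 150_000_000, idx.size))
            pos[idx] = draw + np.arange(idx.size)  # break ties: strictly increasing
    snp_ids = np.array([f"SNP{i+1:06d}" for i in range(m)])

    n = len(ped)
    idx = ped.index_of()
    # two haplotype arrays of allele-B indicators
    h1 = np.zeros((n, m), dtype=np.int8)
    h2 = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == 0 or d == 0:
            h1[i] = rng.random(m) < maf
            h2[i] = rng.random(m) < maf
        else:
            si, di = idx[int(s)], idx[int(d)]
            pick_s = rng.random(m) < 0.5
            pick_d = rng.random(m) < 0.5
            h1[i] = np.where(pick_s, h1[si], h2[si])
            h2[i] = np.where(pick_d, h1[di], h2[di])
    dosage = (h1 + h2).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan
    return GenotypeMatrix(ped.animal.copy(), snp_ids, chrom, pos, dosage)


# ----------------------------------------------------------------------------
# phenotypes


def _inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F from the tabular relationship matrix."""
    from .genparams import build_A  # local import to avoid cycle at import time

    A = build_A(ped).matrix
    return np.diag(A) - 1.0


DEFAULT_PARITY_EFFECTS = {1: 0.0, 2: 0.15, 3: 0.25, 4: 0.20, 5: 0.10}
DEFAULT_SEASON_EFFECTS = {"Spring": 0.0, "Summer": -0.15, "Autumn": 0.05,
                          "Winter": 0.10}


def _lactation_curve(dim: np.ndarray, scale: float) -> np.ndarray:
    # Wilmink-shaped stage effect: early rise, late decline
    return scale * (np.exp(-0.05 * dim) - 0.002 * dim)


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix,
    config: SimConfig,
    record_cows: np.ndarray | None = None,
) -> tuple[pd.DataFrame, TraitTruth]:
    """Repeated test-day records for the recorded cows.

    ``record_cows`` defaults to the last-generation animals.  Returns the
    record table and the realized truth (u, c, QTN effects).
    """
    rng = np.random.default_rng(config.seed + 2)
    n = len(ped)
    idx = ped.index_of()
    if record_cows is None:
        record_cows = ped.animal[ped.generation == ped.generation.max()]
    missing = set(map(int, record_cows)) - set(map(int, ped.animal))
    if missing:
        raise ValueError(f"animals absent from pedigree: {sorted(missing)[:5]}")

    # --- additive genetic values: QTN part + pedigree polygenic part
    dos = np.nan_to_num(geno.dosage, nan=1.0)
    if config.n_qtn > 0 and config.sigma_u2 > 0 and config.qtn_variance_frac > 0:
        qtn_idx = rng.choice(geno.n_snps, config.n_qtn, replace=False)
        raw = rng.standard_normal(config.n_qtn)
        if config.qtn_effect_sd is not None:
            effects = raw * config.qtn_effect_sd
        else:
            p = dos[:, qtn_idx].mean(axis=0) / 2.0
            var_raw = float(np.sum(2 * p * (1 - p) * raw**2))
            target = config.qtn_variance_frac * config.sigma_u2
            effects = raw * np.sqrt(target / max(var_raw, 1e-12))
        u_qtn_all = dos[:, qtn_idx] @ effects
        sigma_poly2 = config.sigma_u2 * (1 - config.qtn_variance_frac)
    else:
        qtn_idx = np.array([], dtype=int)
        effects = np.array([])
        u_qtn_all = np.zeros(n)
        sigma_poly2 = config.sigma_u2

    # polygenic gene flow with Mendelian sampling, inbreeding-adjusted
    F = _inbreeding(ped) if config.n_generations > 0 and sigma_poly2 > 0 else np.zeros(n)
    u_poly = np.zeros(n)
    sp = np.sqrt(sigma_poly2) if sigma_poly2 > 0 else 0.0
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s == 0 or d == 0 or sp == 0.0:
            u_poly[i] = rng.normal(0.0, sp) if sp > 0 else 0.0
        else:
            si, di = idx[s], idx[d]
            fbar = 0.5 * (F[si] + F[di])
            ms_sd = np.sqrt(0.5 * sigma_poly2 * (1 - fbar))
            u_poly[i] = 0.5 * (u_poly[si] + u_poly[di]) + rng.normal(0.0, ms_sd)
    u_all = u_qtn_all + u_poly

    c_all = rng.normal(0.0, np.sqrt(config.sigma_c2), n) if config.sigma_c2 > 0 \
        else np.zeros(n)

    parity_eff = dict(DEFAULT_PARITY_EFFECTS)
    season_eff = dict(DEFAULT_SEASON_EFFECTS)
    lact_scale = 0.3
    if config.fixed_effect_sizes:
        parity_eff.update(config.fixed_effect_sizes.get("parity", {}))
        season_eff.update(config.fixed_effect_sizes.get("season", {}))
        lact_scale = config.fixed_effect_sizes.get("lactation_scale", lact_scale)
    if not config.fixed_effect_sizes and config.sigma_u2 == 0 and \
            config.sigma_c2 == 0 and config.sigma_e2 == 0:
        # degenerate configuration used to check the generator identity
        parity_eff = {k: 0.0 for k in parity_eff}
        season_eff = {k: 0.0 for k in season_eff}
        lact_scale = 0.0

    htd_labels = np.array([f"H{h+1:03d}" for h in range(config.n_htd)])
    htd_eff = rng.normal(0.0, config.htd_sd, config.n_htd) \
        if config.htd_sd > 0 else np.zeros(config.n_htd)

    rows = []
    lo, hi = config.records_per_cow
    for cow in record_cows:
        i = idx[int(cow)]
        n_rec = int(rng.integers(lo, hi + 1))
        base_parity = int(rng.integers(1, 7))
        calving_month = int(rng.integers(1, 13))
        for r in range(n_rec):
            parity = min(base_parity + r // 3, 10)
            dim = int(rng.integers(5, 366))
            h = int(rng.integers(0, config.n_htd))
            season = season_of_month(calving_month)
            pe = parity_eff.get(min(parity, 5), 0.0)
            le = float(_lactation_curve(np.array([dim]), lact_scale)[0])
            se = season_eff.get(season, 0.0)
            e = rng.normal(0.0, np.sqrt(config.sigma_e2)) \
                if config.sigma_e2 > 0 else 0.0
            y = (config.mu + pe + le + se + htd_eff[h]
                 + u_all[i] + c_all[i] + e)
            rows.append((int(cow), parity, dim, calving_month, season,
                         htd_labels[h], y))
    records = pd.DataFrame(
        rows, columns=["animal", "parity", "dim", "calving_month", "season",
                       "htd", "y"])
    truth = TraitTruth(ped.animal.copy(), u_all, c_all, qtn_idx, effects,
                       sigma_poly2)
    return records, truth


# ----------------------------------------------------------------------------
# spectra


def gaussian_profile(wavenumbers: np.ndarray, peaks) -> np.ndarray:
    """Sum of Gaussian peaks; ``peaks`` is a list of (center, width, height)."""
    w = np.asarray(wavenumbers, float)
    out = np.zeros_like(w)
    for center, width, height in peaks:
        out += height * np.exp(-0.5 * ((w - center) / width) ** 2)
    return out


def default_component_profiles(component_names, wavenumbers=None) -> dict:
    """Deterministic Gaussian-peak signatures, one per named milk component.

    Peak centers are drawn from plausible mid-IR bands (ester carbonyl around
    1745, C-H stretch 2850-2960, fingerprint 1000-1500 cm^-1) with a stable
    per-name RNG, so the same name always yields the same signature.
    """
    if wavenumbers is None:
        wavenumbers = default_wavenumbers()
    bands = [(1000.0, 1500.0), (1730.0, 1770.0), (2840.0, 2980.0)]
    profiles = {}
    for name in component_names:
        rng = np.random.default_rng(zlib.crc32(name.encode()) % (2**31))
        peaks = []
        for lo, hi in bands:
            center = rng.uniform(lo, hi)
            width = rng.uniform(8.0, 25.0)
            height = rng.uniform(0.2, 1.0)
            peaks.append((center, width, height))
        profiles[name] = gaussian_profile(wavenumbers, peaks)
    return profiles


def default_baseline(wavenumbers: np.ndarray) -> np.ndarray:
    w = (np.asarray(wavenumbers, float) - WAVE_MIN) / (WAVE_MAX - WAVE_MIN)
    return 0.1 + 0.05 * w - 0.03 * w**2


def simulate_spectra(
    records: pd.DataFrame,
    component_profiles: dict,
    noise_sd: float = 0.002,
    wavenumbers: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
    noise_region_factor: float = 6.0,
    seed: int = 0,
    strict: bool = True,
):
    """Beer-Lambert mixtures: absorbance = sum_k conc_k * phi_k + baseline + eps.

    ``records`` must carry one concentration column per profile key; ``eps``
    has its standard deviation inflated by ``noise_region_factor`` inside the
    two designated noise regions.  Returns a :class:`mirfa.spectra.SpectrumSet`.
    """
    from .spectra import SpectrumSet

    if wavenumbers is None:
        wavenumbers = default_wavenumbers()
    wavenumbers = np.asarray(wavenumbers, float)
    if strict and len(wavenumbers) != N_WAVES:
        raise ValueError(f"strict mode requires a {N_WAVES}-point grid")
    if baseline is None:
        baseline = default_baseline(wavenumbers)
    rng = np.random.default_rng(seed)
    n = len(records)
    absorb = np.tile(np.asarray(baseline, float), (n, 1))
    for name, profile in component_profiles.items():
        conc = records[name].to_numpy(float)
        absorb += np.outer(conc, np.asarray(profile, float))
    if noise_sd > 0:
        sd = np.full(len(wavenumbers), noise_sd)
        for lo, hi in NOISE_REGIONS:
            sd[(wavenumbers >= lo) & (wavenumbers <= hi)] *= noise_region_factor
        absorb += rng.standard_normal(absorb.shape) * sd
    sample_ids = records["sample_id"].to_numpy() if "sample_id" in records \
        else np.array([f"S{i+1:05d}" for i in range(n)])
    return SpectrumSet(wavenumbers=wavenumbers, absorbance=absorb,
                       sample_ids=sample_ids, tag="raw")


# ----------------------------------------------------------------------------
# writers


def write_outputs(outdir, ped: Pedigree, geno: GenotypeMatrix,
                  records: pd.DataFrame, truth: TraitTruth,
                  spectra=None) -> None:
    """Write the standard text artifacts (pedigree/genotype/record/truth TSVs,
    PED/MAP text, spectra CSV)."""
    from .spectra import write_spectra_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped.to_frame().to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    dos = pd.DataFrame(geno.dosage, columns=geno.snp_ids)
    dos.insert(0, "animal", geno.animal_ids)
    dos.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    records.to_csv(outdir / "records.tsv", sep="\t", index=False)
    tr = pd.DataFrame({"animal": truth.animal_ids, "u": truth.u, "c": truth.c})
    tr.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.DataFrame({"qtn_index": truth.qtn_indices,
                  "effect": truth.qtn_effects}).to_csv(
        outdir / "qtn_effects.tsv", sep="\t", index=False)
    write_ped_map(outdir, geno)
    if spectra is not None:
        write_spectra_csv(outdir / "spectra.csv", spectra)


def write_ped_map(outdir, geno: GenotypeMatrix) -> None:
    """PLINK-style PED/MAP text files (alleles A/B, 0 0 for missing)."""
    outdir = Path(outdir)
    with open(outdir / "genotypes.map", "w") as fh:
        for sid, ch, p in zip(geno.snp_ids, geno.chrom, geno.pos):
            ch_code = "30" if ch == "X" else ch
            fh.write(f"{ch_code}\t{sid}\t0\t{p}\n")
    allele_pairs = {0: "A A", 1: "A B", 2: "B B"}
    with open(outdir / "genotypes.ped", "w") as fh:
        for i, aid in enumerate(geno.animal_ids):
            row = [str(aid), str(aid), "0", "0", "2", "-9"]
            for d in geno.dosage[i]:
                row.append("0 0" if np.isnan(d) else allele_pairs[int(d)])
            fh.write("\t".join(row) + "\n")
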