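"""Seeded generator for structured genotype/phenotype cohorts.

Emulates the statistical structure the discovery pipeline assumes: several
regional populations with Balding-Nichols divergent allele frequencies, LD
blocks built from shared latent haplotypes, a handful of strong-effect causal
SNPs feeding an additive liability, ordered liability cutpoints producing
5-grade ordinal eye and hair phenotypes (with red hair driven by a dedicated
recessive locus), genotype missingness, and synthetic QUAL/DP fields so the
variant QC step is exercisable.  All randomness flows from a single seed.

Default parameters mirror a 300-sample cohort drawn from four North Eurasian
regions; cutpoints default to liability quantiles reproducing realistic class
proportions (roughly one third light eyes, a small intermediate class, and a
~6% red-hair fraction).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Regional allele frequencies are clipped to [EPS_FREQ, 1 - EPS_FREQ].
EPS_FREQ = 1e-4

#: Default liability quantiles for the 4 eye-grade cutpoints (grades 0-4).
EYE_GRADE_QUANTILES = (0.18, 0.33, 0.36, 0.66)
#: Default liability quantiles for the 3 hair cutpoints (grades 1-4; grade 0
#: is red and comes from the recessive locus instead).
HAIR_GRADE_QUANTILES = (0.14, 0.27, 0.45)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    ``divergence`` is the Balding-Nichols drift parameter (FST-like, in
    [0, 1)); ``causal_effects`` are additive liability effects per causal SNP
    in liability units; ``grade_thresholds``/``hair_thresholds`` are absolute
    liability cutpoints, or ``None`` to place them at the cohort liability
    quantiles above; ``ld_block_size`` SNPs share latent haplotypes per block.
    """

    n_samples_per_region: int = 75
    regions: tuple[str, ...] = ("Caucasus", "EuropeanRussia", "WestSiberia", "NorthAsia")
    n_snps: int = 5000
    n_causal: int = 5
    causal_effects: tuple[float, ...] | None = None  # defaults to 1.0 each
    n_causal_hair: int | None = None                 # defaults to n_causal
    hair_effects: tuple[float, ...] | None = None
    divergence: float = 0.1
    ld_block_size: int = 5
    ld_recombination: float = 0.1
    grade_thresholds: tuple[float, float, float, float] | None = None
    hair_thresholds: tuple[float, float, float] | None = None
    noise_sd: float = 0.8
    missing_rate: float = 0.02
    populations_per_region: int = 2
    red_locus_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError(f"divergence must be in [0,1), got {self.divergence}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if not 0.0 <= self.ld_recombination <= 1.0:
            raise ValueError("ld_recombination must be in [0,1]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.causal_effects is None:
            self.causal_effects = tuple(1.0 for _ in range(self.n_causal))
        if len(self.causal_effects) != self.n_causal:
            raise ValueError("causal_effects length must equal n_causal")
        if self.n_causal_hair is None:
            self.n_causal_hair = self.n_causal
        if self.hair_effects is None:
            self.hair_effects = tuple(1.0 for _ in range(self.n_causal_hair))
        if len(self.hair_effects) != self.n_causal_hair:
            raise ValueError("hair_effects length must equal n_causal_hair")
        for name, cuts in (("grade_thresholds", self.grade_thresholds),
                           ("hair_thresholds", self.hair_thresholds)):
            if cuts is not None and not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {cuts}")
        if self.n_causal + self.n_causal_hair + 1 > self.n_blocks:
            raise ValueError(
                "not enough LD blocks to host distinct eye/hair/red causal loci"
            )
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.populations_per_region < 1:
            raise ValueError("populations_per_region must be >= 1")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_region * self.n_regions

    @property
    def n_blocks(self) -> int:
        return -(-self.n_snps // self.ld_block_size)


@dataclass
class TruthManifest:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    base_freqs: np.ndarray            # ancestral frequency per SNP
    region_freqs: np.ndarray          # n_regions x n_snps
    block_of: np.ndarray              # LD block index per SNP
    eye_causal_ids: list[str] = field(default_factory=list)
    hair_causal_ids: list[str] = field(default_factory=list)
    red_locus_id: str | None = None
    eye_effects: np.ndarray | None = None
    hair_effects: np.ndarray | None = None
    qual: np.ndarray | None = None
    depth: np.ndarray | None = None
    eye_liability: np.ndarray | None = None
    hair_liability: np.ndarray | None = None
    eye_thresholds: tuple | None = None
    hair_thresholds: tuple | None = None
    eye_heritability: float | None = None
    hair_heritability: float | None = None
    #: true pre-missingness genotype codes (liability uses these, not the
    #: masked matrix); not serialized
    true_codes: np.ndarray | None = None

    def block_members(self, snp_id: str) -> list[str]:
        """All SNP ids sharing the LD block of ``snp_id`` (including itself)."""
        idx = self.snp_ids.index(snp_id)
        block = self.block_of[idx]
        return [s for s, b in zip(self.snp_ids, self.block_of) if b == block]


def simulate_regional_frequencies(
    base_freq: float,
    divergence: float,
    n_regions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-region allele frequencies under the Balding-Nichols model.

    Each regional frequency follows a Beta distribution with mean
    ``base_freq`` and variance ``base_freq * (1 - base_freq) * divergence``;
    with ``divergence = 0`` every region equals ``base_freq`` exactly.
    Frequencies are clipped to ``[EPS_FREQ, 1 - EPS_FREQ]``.

    ``base_freq`` may be scalar or an array of per-SNP frequencies, in which
    case an ``n_regions x n_snps`` array is returned.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence must be in [0,1), got {divergence}")
    p = np.atleast_1d(np.asarray(base_freq, dtype=float))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("base_freq must lie strictly inside (0,1)")
    if divergence == 0.0:
        out = np.tile(p, (n_regions, 1))
    else:
        scale = (1.0 - divergence) / divergence
        a = np.broadcast_to(p * scale, (n_regions, p.size))
        b = np.broadcast_to((1.0 - p) * scale, (n_regions, p.size))
        out = rng.beta(a, b)
    out = np.clip(out, EPS_FREQ, 1.0 - EPS_FREQ)
    if np.isscalar(base_freq) or np.ndim(base_freq) == 0:
        return out[:, 0]
    return out


def _snp_coordinates(config: SimulationConfig, rng: np.random.Generator):
    """Deterministic chrom/pos plus random ref/alt alleles for each SNP."""
    chrom = ["1"] * config.n_snps
    pos = 10_000 + 100 * np.arange(config.n_snps)
    ref_idx = rng.integers(0, 4, size=config.n_snps)
    alt_shift = rng.integers(1, 4, size=config.n_snps)
    ref = [_BASES[i] for i in ref_idx]
    alt = [_BASES[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    ids = [f"{c}:{p}_{r}_{a}" for c, p, r, a in zip(chrom, pos, ref, alt)]
    return chrom, pos, ref, alt, ids


def _pick_causal_indices(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Place causal loci at the centers of evenly spaced, disjoint LD blocks.

    Eye loci, hair loci and the red locus occupy distinct blocks so the two
    traits have their own causal architecture.
    """
    n_needed = config.n_causal + config.n_causal_hair + 1
    blocks = np.linspace(0, config.n_blocks - 1, n_needed).round().astype(int)
    blocks = np.unique(blocks)
    assert blocks.size == n_needed, "causal blocks collided"
    centers = np.minimum(
        blocks * config.ld_block_size + config.ld_block_size // 2,
        config.n_snps - 1,
    )
    eye = centers[: config.n_causal]
    hair = centers[config.n_causal : config.n_causal + config.n_causal_hair]
    red = int(centers[-1])
    return eye, hair, red


def simulate_genotypes(
    config: SimulationConfig,
    freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthManifest]:
    """Generate regional genotypes with LD blocks and missingness.

    SNPs within an LD block of a region are generated from two shared latent
    haplotype variables per sample (with per-SNP recombination), so block
    members are positively correlated; blocks are independent of each other.
    ``freqs`` may supply an ``n_regions x n_snps`` frequency matrix; by
    default frequencies are drawn via :func:`simulate_regional_frequencies`
    from uniform ancestral frequencies (causal SNPs restricted to
    intermediate frequencies so they stay polymorphic everywhere).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chrom, pos, ref, alt, snp_ids = _snp_coordinates(config, rng)
    eye_idx, hair_idx, red_idx = _pick_causal_indices(config)
    block_of = np.arange(config.n_snps) // config.ld_block_size

    # one ancestral frequency per LD block with small within-block jitter:
    # haplotype-sharing only yields tight LD between SNPs of similar frequency
    block_base = rng.uniform(0.05, 0.95, size=config.n_blocks)
    causal_blocks = block_of[np.concatenate([eye_idx, hair_idx])]
    block_base[causal_blocks] = rng.uniform(0.3, 0.7, size=causal_blocks.size)
    block_base[block_of[red_idx]] = config.red_locus_freq
    base = np.clip(
        block_base[block_of] + rng.normal(0.0, 0.05, size=config.n_snps),
        0.05, 0.95,
    )
    base[red_idx] = config.red_locus_freq
    if freqs is None:
        # drift acts on haplotypes, i.e. per block: all members of a block
        # shift together, preserving within-block LD in every region
        block_region = simulate_regional_frequencies(
            block_base, config.divergence, config.n_regions, rng
        )
        offsets = base - block_base[block_of]
        freqs = np.clip(
            block_region[:, block_of] + offsets[np.newaxis, :],
            EPS_FREQ, 1.0 - EPS_FREQ,
        )
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (config.n_regions, config.n_snps):
        raise ValueError(
            f"freqs must have shape {(config.n_regions, config.n_snps)}, "
            f"got {freqs.shape}"
        )

    n_r = config.n_samples_per_region
    codes = np.empty((config.n_samples, config.n_snps), dtype=np.int8)
    for r in range(config.n_regions):
        rows = slice(r * n_r, (r + 1) * n_r)
        p = freqs[r]
        # two latent haplotype uniforms per sample, shared within a block
        shared = rng.random((n_r, 2, config.n_blocks))
        u = shared[:, :, block_of]
        if config.ld_recombination > 0:
            recomb = rng.random((n_r, 2, config.n_snps)) < config.ld_recombination
            fresh = rng.random((n_r, 2, config.n_snps))
            u = np.where(recomb, fresh, u)
        alleles = u < p[np.newaxis, np.newaxis, :]
        codes[rows] = alleles.sum(axis=1)

    mask = (
        rng.random(codes.shape) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros(codes.shape, dtype=bool)
    )
    true_codes = codes.copy()
    codes[mask] = 0  # masked cells carry no value

    sample_ids = [
        f"{region}_S{i:03d}"
        for region in config.regions
        for i in range(n_r)
    ]
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        codes=codes,
        missing_mask=mask,
    )
    manifest = TruthManifest(
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        base_freqs=base,
        region_freqs=freqs,
        block_of=block_of,
        eye_causal_ids=[snp_ids[i] for i in eye_idx],
        hair_causal_ids=[snp_ids[i] for i in hair_idx],
        red_locus_id=snp_ids[red_idx],
        eye_effects=np.asarray(config.causal_effects, dtype=float),
        hair_effects=np.asarray(config.hair_effects, dtype=float),
        qual=rng.uniform(20.0, 100.0, size=config.n_snps),
        depth=rng.poisson(30, size=config.n_snps).astype(float),
        true_codes=true_codes,
    )
    return matrix, manifest


def _grades_from_liability(liability, thresholds) -> np.ndarray:
    """Grade = number of cutpoints strictly below the liability."""
    return np.searchsorted(np.asarray(thresholds), liability, side="left")


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    manifest: TruthManifest,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate ordinal eye/hair grades from additive liabilities.

    Eye liability is the effect-weighted sum of the causal genotype codes plus
    Gaussian noise; the eye grade counts how many of the four cutpoints lie
    below it (0-4).  Hair grades 1-4 come analogously from the hair causal
    set and three cutpoints, while two copies of the red-locus allele force
    hair grade 0 (recessive red).  Liabilities use the true (pre-missingness)
    genotype codes.  When cutpoints are not set in the config, they are placed
    at the cohort liability quantiles defined module-level.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    idx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    n = genotypes.n_samples
    codes = (manifest.true_codes if manifest.true_codes is not None
             else genotypes.codes).astype(float)

    eye_cols = [idx[s] for s in manifest.eye_causal_ids]
    eye_liab = codes[:, eye_cols] @ manifest.eye_effects
    eye_liab = eye_liab + rng.normal(0.0, config.noise_sd, size=n)
    if config.grade_thresholds is not None:
        eye_cuts = tuple(config.grade_thresholds)
    else:
        eye_cuts = tuple(np.quantile(eye_liab, EYE_GRADE_QUANTILES))
    eye_grade = _grades_from_liability(eye_liab, eye_cuts)

    hair_cols = [idx[s] for s in manifest.hair_causal_ids]
    hair_liab = codes[:, hair_cols] @ manifest.hair_effects
    hair_liab = hair_liab + rng.normal(0.0, config.noise_sd, size=n)
    if config.hair_thresholds is not None:
        hair_cuts = tuple(config.hair_thresholds)
    else:
        hair_cuts = tuple(np.quantile(hair_liab, HAIR_GRADE_QUANTILES))
    hair_grade = 1 + _grades_from_liability(hair_liab, hair_cuts)
    red = codes[:, idx[manifest.red_locus_id]] >= 2.0
    hair_grade = np.where(red, 0, hair_grade)

    manifest.eye_liability = eye_liab
    manifest.hair_liability = hair_liab
    manifest.eye_thresholds = eye_cuts
    manifest.hair_thresholds = hair_cuts
    genetic = codes[:, eye_cols] @ manifest.eye_effects
    var_g = float(np.var(genetic))
    manifest.eye_heritability = var_g / (var_g + config.noise_sd**2)
    genetic_h = codes[:, hair_cols] @ manifest.hair_effects
    var_gh = float(np.var(genetic_h))
    manifest.hair_heritability = var_gh / (var_gh + config.noise_sd**2)

    n_r = config.n_samples_per_region
    k = config.populations_per_region
    populations = []
    regions = []
    for region in config.regions:
        for i in range(n_r):
            populations.append(f"{region}_P{i * k // n_r + 1}")
            regions.append(region)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "population": populations,
            "region": regions,
            "eye_grade": eye_grade.astype(int),
            "hair_grade": hair_grade.astype(int),
        }
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthManifest]:
    """Run the whole generator from the single seed in the config."""
    rng = np.random.default_rng(config.seed)
    genotypes, manifest = simulate_genotypes(config, rng=rng)
    phenotypes = simulate_phenotypes(genotypes, manifest, config, rng=rng)
    return genotypes, phenotypes, manifest


def write_dataset(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    manifest: TruthManifest,
    out_dir: str,
) -> dict[str, Path]:
    """Write a VCF 4.2, a phenotype TSV and a JSON truth manifest.

    The VCF carries GT per sample plus synthetic QUAL and INFO/DP so the QC
    filters are exercisable.  Output is deterministic: identical inputs give
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if list(phenotypes["sample_id"]) != list(genotypes.sample_ids):
        raise ValueError("phenotype and genotype sample sets differ")

    vcf_path = out / "cohort.vcf"
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pigsnp-synthetic\n")
        for c in sorted(set(manifest.chrom), key=str):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for j in range(genotypes.n_snps):
            cells = gt_strings[genotypes.codes[:, j]]
            cells = np.where(genotypes.missing_mask[:, j], "./.", cells)
            fh.write(
                f"{manifest.chrom[j]}\t{manifest.pos[j]}\t.\t{manifest.ref[j]}\t"
                f"{manifest.alt[j]}\t{manifest.qual[j]:.2f}\t.\t"
                f"DP={int(manifest.depth[j])}\tGT\t" + "\t".join(cells) + "\n"
            )

    pheno_path = out / "phenotypes.tsv"
    phenotypes.to_csv(pheno_path, sep="\t", index=False)

    manifest_path = out / "truth.json"
    causal = sorted(set(manifest.eye_causal_ids + manifest.hair_causal_ids
                        + [manifest.red_locus_id]))
    causal_idx = [manifest.snp_ids.index(s) for s in causal]
    payload = {
        "eye_causal_snp_ids": manifest.eye_causal_ids,
        "hair_causal_snp_ids": manifest.hair_causal_ids,
        "red_locus_id": manifest.red_locus_id,
        "eye_effects": list(map(float, manifest.eye_effects)),
        "hair_effects": list(map(float, manifest.hair_effects)),
        "causal_base_freqs": {s: float(manifest.base_freqs[i])
                              for s, i in zip(causal, causal_idx)},
        "causal_region_freqs": {s: [float(v) for v in manifest.region_freqs[:, i]]
                                for s, i in zip(causal, causal_idx)},
        "causal_block_members": {s: manifest.block_members(s) for s in causal},
        "eye_thresholds": list(manifest.eye_thresholds)
        if manifest.eye_thresholds else None,
        "hair_thresholds": list(manifest.hair_thresholds)
        if manifest.hair_thresholds else None,
        "eye_heritability": manifest.eye_heritability,
        "hair_heritability": manifest.hair_heritability,
        "eye_liability": [round(float(x), 6) for x in manifest.eye_liability]
        if manifest.eye_liability is not None else None,
        "hair_liability": [round(float(x), 6) for x in manifest.hair_liability]
        if manifest.hair_liability is not None else None,
    }
    with open(manifest_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {"vcf": vcf_path, "phenotypes": pheno_path, "manifest": manifest_path}
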