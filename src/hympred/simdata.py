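"""Synthetic haplodiploid populations with brood (shared-host) structure.

The generator mimics a mass-reared outbred parasitoid culture: a finite
population of diploid females and haploid males is advanced for a burn-in
period so that drift and recombination build linkage disequilibrium, after
which two cohorts of females are sampled a few generations apart.  Each
sampled female develops in a brood: all brood-mates share one mother, one
father, and one host (the fly pupa the brood developed in), which induces
both full-sib genetic covariance and a common-environment phenotype effect.

Inheritance is haplodiploid: daughters receive one recombinant maternal
gamete plus the father's entire haploid genome; sons receive a recombinant
maternal gamete only.  Recombination therefore happens exclusively in
female meiosis, modelled as Poisson crossovers on the genetic map with no
interference.

Phenotypes follow an additive model with a host effect::

    y = mean + sum_qtl(allele count * effect) + host_effect + residual

where host effects are drawn i.i.d. per host and shared by brood-mates.
In the default "realized" scaling mode the three components are rescaled
so the cohort variance decomposition hits the trait targets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hympred.containers import MISSING, GenotypeMatrix, SampleTable

__all__ = [
    "TraitArchitecture",
    "SimConfig",
    "GeneticMap",
    "Population",
    "SimResult",
    "build_map",
    "simulate_founders",
    "meiosis_female",
    "advance_generation",
    "sample_broods",
    "assign_phenotypes",
    "simulate",
    "write_vcf",
    "write_plink",
    "write_samples_csv",
]

#: Gregarious parasitoids lay large clutches in a single pupa; broods
#: larger than this are biologically implausible and rejected.
MAX_BROOD_SIZE = 60


@dataclass(frozen=True)
class TraitArchitecture:
    """Target architecture of one simulated trait.

    ``h2_target`` is the narrow-sense heritability of the additive genomic
    component, ``host_variance_fraction`` the share of phenotypic variance
    explained by the shared rearing host (large, 0.34-0.56, for body-size
    traits; small, ~0.08, for shape ratios).  ``scaling='realized'``
    rescales simulated components so the cohort variances hit the targets
    exactly; ``'expected'`` scales by theoretical factors only.
    """

    name: str
    h2_target: float
    host_variance_fraction: float
    mean: float = 0.0
    phenotype_sd: float = 1.0
    n_qtl: int = 200
    scaling: str = "realized"

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if not 0.0 <= self.host_variance_fraction <= 1.0:
            raise ValueError("host_variance_fraction must be in [0, 1]")
        if self.h2_target + self.host_variance_fraction > 1.0 + 1e-12:
            raise ValueError("h2_target + host_variance_fraction must be <= 1")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be positive")
        if self.phenotype_sd <= 0:
            raise ValueError("phenotype_sd must be positive")
        if self.scaling not in ("realized", "expected"):
            raise ValueError("scaling must be 'realized' or 'expected'")


def _default_traits() -> tuple[TraitArchitecture, ...]:
    # One size-like trait (large host share) and one ratio-like trait
    # (small host share), spanning the h2 range seen in wasp wing traits.
    return (
        TraitArchitecture("size", h2_target=0.22, host_variance_fraction=0.45,
                          mean=600.0, phenotype_sd=40.0),
        TraitArchitecture("ratio", h2_target=0.22, host_variance_fraction=0.08,
                          mean=2.2, phenotype_sd=0.04),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the gene-drop simulation.

    Defaults emulate the study population the package targets: five
    chromosomes totalling 446.9 cM, ~8,639 GBS SNPs, effective population
    size 236, and two sampled generations of 717 and 513 females, only the
    second of which has recorded host identities.
    """

    n_chromosomes: int = 5
    chrom_lengths_cm: tuple[float, ...] = (89.38, 89.38, 89.38, 89.38, 89.38)
    n_snps: int = 8639
    n_founder_haplotypes: int = 472
    ne: int = 236
    n_burnin_generations: int = 100
    n_females_sampled: tuple[int, ...] = (717, 513)
    hosts_per_generation: int = 120
    max_brood_size: int = MAX_BROOD_SIZE
    generations_between_cohorts: int = 3
    founder_freq_range: tuple[float, float] = (0.05, 0.5)
    bp_per_cm: float = 660_000.0
    missing_rate: float = 0.0
    depth_mean: float = 60.0
    #: "all": every brood shares its host effect (realistic: hosts act on
    #: every generation even when unrecorded).  "recorded": only the last
    #: (host-recorded) cohort shares host effects; earlier cohorts receive
    #: the host variance as individual-level noise, which is the exact
    #: generative mirror of the fitted model (their host term is the zero
    #: block and the variance sits in their own residual).
    shared_host_effects: str = "all"
    traits: tuple[TraitArchitecture, ...] = field(default_factory=_default_traits)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or len(self.chrom_lengths_cm) != self.n_chromosomes:
            raise ValueError("need one map length per chromosome")
        if any(length < 0 for length in self.chrom_lengths_cm):
            raise ValueError("chromosome lengths must be non-negative")
        if sum(self.chrom_lengths_cm) <= 0:
            raise ValueError("total map length must be positive")
        for name in ("n_snps", "n_founder_haplotypes", "ne",
                     "hosts_per_generation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_burnin_generations < 0:
            raise ValueError("n_burnin_generations must be >= 0")
        if any(n < 1 for n in self.n_females_sampled):
            raise ValueError("each sampled cohort must have >= 1 female")
        if not 1 <= self.max_brood_size <= MAX_BROOD_SIZE:
            raise ValueError(f"max_brood_size must be in [1, {MAX_BROOD_SIZE}]")
        lo, hi = self.founder_freq_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("founder_freq_range must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.shared_host_effects not in ("all", "recorded"):
            raise ValueError("shared_host_effects must be 'all' or 'recorded'")


@dataclass(frozen=True)
class GeneticMap:
    """SNP coordinates: chromosome index, bp position, cM position."""

    chrom: np.ndarray  # int, 0-based chromosome index per SNP
    pos_bp: np.ndarray  # int, 1-based physical position
    pos_cm: np.ndarray  # float, genetic position within chromosome
    chrom_lengths_cm: tuple[float, ...]

    @property
    def n_snps(self) -> int:
        return self.pos_bp.size

    def chrom_slice(self, c: int) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class Population:
    """Current adult generation: diploid females, haploid males.

    ``females`` has shape (n_females, 2, n_snps); ``males`` has shape
    (n_males, n_snps).  Entries are 0/1 alternate-allele indicators.
    """

    females: np.ndarray
    males: np.ndarray

    @property
    def n_females(self) -> int:
        return self.females.shape[0]

    @property
    def n_males(self) -> int:
        return self.males.shape[0]


@dataclass
class SimResult:
    """Full output of one simulation run."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    gmap: GeneticMap
    truth: dict
    config: SimConfig


def build_map(config: SimConfig, rng: np.random.Generator) -> GeneticMap:
    """Place SNPs on the genome, proportionally to chromosome map length."""
    lengths = np.asarray(config.chrom_lengths_cm, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("every chromosome needs positive map length to carry SNPs")
    probs = lengths / lengths.sum()
    counts = rng.multinomial(config.n_snps, probs)
    # Guarantee at least one SNP per chromosome when possible.
    while np.any(counts == 0) and config.n_snps >= config.n_chromosomes:
        donor = int(np.argmax(counts))
        counts[int(np.argmin(counts))] += 1
        counts[donor] -= 1
    chroms, bps, cms = [], [], []
    for c, (n_c, length) in enumerate(zip(counts, lengths)):
        if n_c == 0:
            continue
        chrom_bp = max(int(round(length * config.bp_per_cm)), int(n_c))
        pos = np.sort(rng.choice(chrom_bp, size=int(n_c), replace=False)) + 1
        chroms.append(np.full(int(n_c), c, dtype=np.int32))
        bps.append(pos.astype(np.int64))
        cms.append((pos - 1) / config.bp_per_cm)
    return GeneticMap(
        chrom=np.concatenate(chroms),
        pos_bp=np.concatenate(bps),
        pos_cm=np.concatenate(cms),
        chrom_lengths_cm=config.chrom_lengths_cm,
    )


def simulate_founders(
    config: SimConfig, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw founder haplotypes from the founder allele-frequency spectrum.

    Per-locus alternate-allele frequencies are Uniform over
    ``config.founder_freq_range`` and haplotypes are drawn in linkage
    equilibrium; LD is built later by the finite-population burn-in.
    Returns an (n_founder_haplotypes, n_snps) 0/1 array.
    """
    lo, hi = config.founder_freq_range
    freqs = rng.uniform(lo, hi, size=gmap.n_snps)
    haps = (rng.random((config.n_founder_haplotypes, gmap.n_snps)) < freqs)
    return haps.astype(np.int8)


def _founder_population(
    config: SimConfig, founders: np.ndarray, rng: np.random.Generator
) -> Population:
    """Assemble the initial adult population from founder haplotypes."""
    nf = max(config.ne // 2, 1)
    nm = max(config.ne - nf, 1)
    pick = lambda n: rng.integers(0, founders.shape[0], size=n)
    females = founders[pick(2 * nf)].reshape(nf, 2, -1)
    males = founders[pick(nm)]
    return Population(females=females.copy(), males=males.copy())


def meiosis_female(
    mother: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from a diploid female.

    Crossover counts per chromosome are Poisson with mean map-length/100
    (Haldane, no interference); positions are uniform on the cM map.  A
    0 cM chromosome is transmitted as an intact copy of one haplotype.
    """
    if mother.ndim != 2 or mother.shape[0] != 2:
        raise ValueError("mother must be a (2, n_snps) diploid genome")
    gamete = np.empty(mother.shape[1], dtype=np.int8)
    for c in range(len(gmap.chrom_lengths_cm)):
        sl = gmap.chrom_slice(c)
        if sl.stop == sl.start:
            continue
        length = gmap.chrom_lengths_cm[c]
        start_hap = int(rng.integers(2))
        n_xo = rng.poisson(length / 100.0) if length > 0 else 0
        if n_xo == 0:
            gamete[sl] = mother[start_hap, sl]
            continue
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        crossings = np.searchsorted(xo, gmap.pos_cm[sl], side="right")
        hap = (start_hap + crossings) % 2
        cols = np.arange(sl.start, sl.stop)
        gamete[sl] = mother[hap, cols]
    return gamete


def advance_generation(
    population: Population, gmap: GeneticMap, config: SimConfig,
    rng: np.random.Generator,
    n_females: int | None = None, n_males: int | None = None,
) -> Population:
    """Random mating to the next adult generation at size ``ne``.

    Each daughter = maternal recombinant gamete + the entire genome of a
    random haploid father; each son = a maternal recombinant gamete only
    (arrhenotoky: males develop from unfertilised eggs).
    """
    if population.n_females == 0 or population.n_males == 0:
        raise RuntimeError("population extinct: need at least one female and one male")
    nf = population.n_females if n_females is None else n_females
    nm = population.n_males if n_males is None else n_males
    mothers_f = rng.integers(0, population.n_females, size=nf)
    fathers_f = rng.integers(0, population.n_males, size=nf)
    mothers_m = rng.integers(0, population.n_females, size=nm)
    females = np.empty((nf, 2, gmap.n_snps), dtype=np.int8)
    for i in range(nf):
        females[i, 0] = meiosis_female(population.females[mothers_f[i]], gmap, rng)
        females[i, 1] = population.males[fathers_f[i]]
    males = np.empty((nm, gmap.n_snps), dtype=np.int8)
    for i in range(nm):
        males[i] = meiosis_female(population.females[mothers_m[i]], gmap, rng)
    return Population(females=females, males=males)


def sample_broods(
    population: Population, gmap: GeneticMap, config: SimConfig,
    rng: np.random.Generator, n_females: int, n_hosts: int,
    generation_label: str,
) -> tuple[np.ndarray, list[str]]:
    """Sample a phenotyping cohort of females structured into broods.

    ``n_hosts`` mother/father pairs are drawn from the current adults;
    each pair's brood develops in one host, so brood-mates are full sibs
    sharing a host id.  Returns (genotypes (n, 2, n_snps), host ids).
    """
    if population.n_females == 0 or population.n_males == 0:
        raise RuntimeError("population extinct: cannot sample a cohort")
    base, extra = divmod(n_females, n_hosts)
    brood_sizes = [base + (1 if h < extra else 0) for h in range(n_hosts)]
    if max(brood_sizes) > config.max_brood_size:
        raise ValueError(
            f"brood size {max(brood_sizes)} exceeds max {config.max_brood_size}; "
            "increase hosts_per_generation"
        )
    mothers = rng.choice(population.n_females, size=n_hosts,
                         replace=n_hosts > population.n_females)
    fathers = rng.choice(population.n_males, size=n_hosts,
                         replace=n_hosts > population.n_males)
    genomes = np.empty((n_females, 2, gmap.n_snps), dtype=np.int8)
    hosts: list[str] = []
    row = 0
    for h, size in enumerate(brood_sizes):
        mother = population.females[mothers[h]]
        father = population.males[fathers[h]]
        host_id = f"{generation_label}_h{h:04d}"
        for _ in range(size):
            genomes[row, 0] = meiosis_female(mother, gmap, rng)
            genomes[row, 1] = father
            hosts.append(host_id)
            row += 1
    return genomes, hosts


def assign_phenotypes(
    codes: np.ndarray,
    hosts: list[str] | np.ndarray,
    trait: TraitArchitecture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Simulate one trait on a cohort of genotyped females.

    QTL are a random subset of segregating loci with normal effects; a
    host effect is drawn once per host and shared by its brood; the
    residual is i.i.d. normal.  In 'realized' mode every component is
    rescaled so its cohort variance equals its target share of
    ``phenotype_sd**2`` exactly; 'expected' mode uses theoretical scale
    factors only, so realized shares fluctuate with sampling.
    Returns (phenotypes, truth) where truth holds the additive values,
    host effects and QTL bookkeeping.
    """
    codes = np.asarray(codes)
    n, m = codes.shape
    hosts = np.asarray(hosts)
    if hosts.size != n:
        raise ValueError("need one host id per individual")
    sigma_p2 = trait.phenotype_sd**2
    resid_frac = 1.0 - trait.h2_target - trait.host_variance_fraction

    freqs = codes.mean(axis=0) / 2.0
    segregating = np.flatnonzero((freqs > 0) & (freqs < 1))
    g = np.zeros(n)
    qtl_idx = np.array([], dtype=int)
    effects = np.array([])
    if trait.h2_target > 0 and segregating.size > 0:
        n_qtl = min(trait.n_qtl, segregating.size)
        qtl_idx = np.sort(rng.choice(segregating, size=n_qtl, replace=False))
        effects = rng.standard_normal(n_qtl)
        w = codes[:, qtl_idx] - 2.0 * freqs[qtl_idx]
        g = w @ effects
        target = trait.h2_target * sigma_p2
        if trait.scaling == "realized":
            scale = np.sqrt(target / g.var()) if g.var() > 0 else 0.0
        else:
            expected_var = float(np.sum(2 * freqs[qtl_idx] * (1 - freqs[qtl_idx])))
            scale = np.sqrt(target / expected_var) if expected_var > 0 else 0.0
        effects = effects * scale
        g = g * scale

    host_labels, host_of = np.unique(hosts, return_inverse=True)
    c = np.zeros(n)
    host_effects = np.zeros(host_labels.size)
    if trait.host_variance_fraction > 0:
        host_effects = rng.standard_normal(host_labels.size)
        c = host_effects[host_of]
        target = trait.host_variance_fraction * sigma_p2
        if trait.scaling == "realized":
            scale = np.sqrt(target / c.var()) if c.var() > 0 else 0.0
        else:
            scale = np.sqrt(target)
        host_effects = host_effects * scale
        c = c * scale

    e = rng.standard_normal(n)
    if resid_frac > 1e-12:
        target = resid_frac * sigma_p2
        if trait.scaling == "realized":
            e = e * np.sqrt(target / e.var())
        else:
            e = e * np.sqrt(target)
    else:
        e = np.zeros(n)

    y = trait.mean + g + c + e
    truth = {
        "qtl_idx": qtl_idx,
        "qtl_effects": effects,
        "additive": g,
        "host_effects": dict(zip(host_labels.tolist(), host_effects.tolist())),
        "host_component": c,
        "residual": e,
        "variance_parts": {
            "additive": float(np.var(g)),
            "host": float(np.var(c)),
            "residual": float(np.var(e)),
        },
    }
    return y, truth


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: burn-in, two sampled cohorts, phenotypes.

    The first cohort mirrors an earlier generation whose host identities
    were not recorded (its host column is exported as missing even though
    host effects acted on its phenotypes); the second cohort carries host
    ids.  Identical config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    gmap = build_map(config, rng)
    founders = simulate_founders(config, gmap, rng)
    pop = _founder_population(config, founders, rng)
    for _ in range(config.n_burnin_generations):
        pop = advance_generation(pop, gmap, config, rng)

    cohorts: list[tuple[str, np.ndarray, list[str]]] = []
    labels = [f"G{i + 1}" for i in range(len(config.n_females_sampled))]
    for k, (label, n_f) in enumerate(zip(labels, config.n_females_sampled)):
        genomes, hosts = sample_broods(
            pop, gmap, config, rng, n_f, config.hosts_per_generation, label
        )
        cohorts.append((label, genomes, hosts))
        if k < len(labels) - 1:
            for _ in range(config.generations_between_cohorts):
                pop = advance_generation(pop, gmap, config, rng)

    all_codes = np.concatenate(
        [genomes.sum(axis=1, dtype=np.int8) for _, genomes, _ in cohorts]
    )
    all_haplotypes = np.concatenate([genomes for _, genomes, _ in cohorts])
    generation = np.concatenate(
        [np.full(len(h), label) for label, _, h in cohorts]
    )
    all_hosts = np.concatenate([np.asarray(h) for _, _, h in cohorts])
    ids = [f"{generation[i]}_i{i:05d}" for i in range(all_codes.shape[0])]

    truth: dict = {"traits": {}, "haplotypes": all_haplotypes, "hosts_all": all_hosts}
    if config.shared_host_effects == "recorded":
        # Earlier cohorts: host variance acts per individual, not per brood.
        pheno_hosts = np.array(
            [h if gen == labels[-1] else f"solo_{i}"
             for i, (h, gen) in enumerate(zip(all_hosts, generation))]
        )
    else:
        pheno_hosts = all_hosts
    pheno = {}
    for trait in config.traits:
        y, t_truth = assign_phenotypes(all_codes, pheno_hosts, trait, rng)
        pheno[trait.name] = y
        truth["traits"][trait.name] = t_truth

    # Host ids are exported only for the last cohort, mirroring a study
    # design where earlier generations were collected without brood records.
    host_col = pd.array(
        [h if gen == labels[-1] else pd.NA for h, gen in zip(all_hosts, generation)]
    )
    frame = pd.DataFrame({"id": ids, "generation": generation, "host": host_col})
    for name, y in pheno.items():
        frame[name] = y
    samples = SampleTable(frame=frame, trait_columns=list(pheno))

    depth = rng.gamma(shape=10.0, scale=config.depth_mean / 10.0, size=gmap.n_snps)
    codes = all_codes.copy()
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes[mask] = MISSING
    variants = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in gmap.chrom],
            "pos": gmap.pos_bp,
            "ref": "A",
            "alt": "T",
            "depth": depth,
        }
    )
    gm = GenotypeMatrix(codes=codes, ids=ids, variants=variants)
    return SimResult(genotypes=gm, samples=samples, gmap=gmap, truth=truth,
                     config=config)


# ---------------------------------------------------------------------------
# Writers (plain-text formats)
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a VCFv4.2 text file with GT calls and site INFO DP.

    INFO DP follows the usual convention of total read depth across
    samples (per-site mean depth times sample count, rounded).
    """
    var = gm.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hympred-simdata\n")
        for chrom in pd.unique(var["chrom"]):
            max_pos = int(var.loc[var["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.ids) + "\n")
        n = gm.n_individuals
        for j in range(gm.n_variants):
            row = var.iloc[j]
            dp = int(round(float(row["depth"]) * n))
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.codes[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\tsnp{j:06d}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\tDP={dp}\tGT\t{gts}\n"
            )


def write_plink(gm: GenotypeMatrix, prefix: str) -> None:
    """Write PLINK-dialect text files ``prefix.ped`` and ``prefix.map``."""
    var = gm.variants
    with open(f"{prefix}.map", "w") as fh:
        for j in range(gm.n_variants):
            row = var.iloc[j]
            fh.write(f"{row['chrom']}\tsnp{j:06d}\t0\t{int(row['pos'])}\n")
    allele_pairs = {0: "{r} {r}", 1: "{r} {a}", 2: "{a} {a}", MISSING: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in enumerate(gm.ids):
            cells = [
                allele_pairs[int(gm.codes[i, j])].format(
                    r=var.iloc[j]["ref"], a=var.iloc[j]["alt"]
                )
                for j in range(gm.n_variants)
            ]
            fh.write(f"FAM1 {ind} 0 0 2 -9 " + " ".join(cells) + "\n")


def write_samples_csv(samples: SampleTable, path: str) -> None:
    """Write the sample/phenotype table as a headered CSV."""
    samples.frame.to_csv(path, index=False)


def read_samples_csv(path: str) -> SampleTable:
    """Read a sample/phenotype CSV written by :func:`write_samples_csv`."""
    frame = pd.read_csv(path, dtype={"id": str, "generation": str, "host": "string"})
    return SampleTable(frame=frame)
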