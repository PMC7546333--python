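"""Forward simulation of a hybrid-like rice variant and its selfed F2 population.

The generator emulates the genotype-level structure of a spike-stalk-injection
experiment: a near-homozygous recipient cultivar, a variant that behaves like an
interspecific F1 (high heterozygosity, all non-recipient alleles in coupling
phase on one haplotype, plus a small load of homozygous de novo mutations), and
a population of selfed progeny lines genotyped sparsely at low depth, RAD-seq
style.

Only polymorphic (or deliberately planted) sites are materialised; per-base
rates are applied to the physical chromosome lengths, so realised site counts
are binomial draws against the configured rates.  Meiosis is simulated without
crossover interference: crossover counts are Poisson with mean equal to the
chromosome's genetic length in Morgans, and crossover positions are uniform on
the genetic map (taken to be linear in physical position).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allele encoding used throughout: integers 0..3 for A, C, G, T; -1 missing.
BASES = "ACGT"
MISSING = -1


def encode_base(b: str) -> int:
    """Map a single-character base to its integer code."""
    try:
        return BASES.index(b.upper())
    except ValueError:
        raise ValueError(f"allele {b!r} is not one of A, C, G, T") from None


def decode_base(code: int) -> str:
    if code == MISSING:
        return "."
    return BASES[code]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    genetic_length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.name}: length_bp must be >= 1")
        if self.genetic_length_cM < 0:
            raise ValueError(f"{self.name}: genetic_length_cM must be >= 0")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with physical and genetic lengths."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout has no chromosomes")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    @property
    def total_cM(self) -> float:
        return sum(c.genetic_length_cM for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in layout")

    @classmethod
    def from_spec(cls, spec: list) -> "GenomeLayout":
        """Build from a list of (name, length_bp, genetic_length_cM) triples."""
        return cls(tuple(Chromosome(str(n), int(l), float(g)) for n, l, g in spec))


# Rice-like physical lengths (Mb) for the 12 chromosomes and the genetic
# lengths of the study's F2 map (cM).  ``bp_scale`` shrinks the physical
# genome (and hence site counts) while keeping the genetic map intact, which
# is how the test-suite and acceptance runs keep within desk-scale budgets.
_RICE_BP_MB = [43.3, 35.9, 36.4, 35.5, 30.0, 31.2, 29.7, 28.4, 23.0, 23.2, 29.0, 27.5]
_RICE_CM = [234.8, 150.9, 187.2, 95.8, 91.7, 98.7, 126.5, 126.8, 92.2, 78.2, 104.5, 102.4]


def rice_layout(bp_scale: float = 1.0, n_chromosomes: int = 12) -> GenomeLayout:
    """A 12-chromosome rice-like layout; genetic lengths total 1489.7 cM."""
    if not 0 < n_chromosomes <= 12:
        raise ValueError("n_chromosomes must be in 1..12")
    chroms = tuple(
        Chromosome(f"chr{i + 1:02d}", max(1, int(_RICE_BP_MB[i] * 1e6 * bp_scale)), _RICE_CM[i])
        for i in range(n_chromosomes)
    )
    return GenomeLayout(chroms)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class QTLSpec:
    """A planted QTL: position plus additive/dominance effects in trait units."""

    chrom: str
    pos: int
    additive: float
    dominance: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    Defaults are the study conditions: recipient heterozygosity 3.36e-4,
    variant heterozygosity 25.96e-4 with homozygous mutations at 0.182e-4,
    216 selfed lines observed at 5.97% site coverage and 3.23x mean depth.
    """

    het_rate_recipient: float = 3.36e-4
    het_rate_variant: float = 25.96e-4
    mut_rate_variant: float = 0.182e-4
    n_lines: int = 216
    selfing_generations: int = 1
    site_coverage: float = 0.0597
    mean_depth: float = 3.23
    base_error: float = 0.01
    qtls: list[QTLSpec] = field(default_factory=list)
    residual_sd: float = 1.0
    trait_mean: float = 100.0
    trait_name: str = "PH"
    # Population-level de novo mutations planted in the progeny (monomorphic
    # founder sites acquiring a novel allele in a subset of lines).
    n_population_mutation_sites: int = 0
    population_mutation_carrier_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("het_rate_recipient", "het_rate_variant", "mut_rate_variant",
                     "site_coverage", "population_mutation_carrier_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.het_rate_recipient + self.het_rate_variant + self.mut_rate_variant > 1.0:
            raise ValueError("per-site rates sum to more than 1")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

#: Site-kind labels recorded in the truth set.
KIND_REC_HET = "rec_het"       # recipient heterozygous (variant copies it)
KIND_VAR_HET = "var_het"       # variant heterozygous, recipient homozygous
KIND_VAR_HOM = "var_hom"       # variant homozygous for a non-recipient allele
KIND_POP_MUT = "pop_mut"       # monomorphic in founders; mutated in progeny


@dataclass
class FounderPair:
    """Recipient genotype and phased variant haplotypes on a shared site universe.

    ``sites`` columns: chrom, pos (1-based), ref, rec1, rec2, var1, var2 —
    allele integer codes.  The variant's unordered genotype is {var1, var2};
    at heterozygous variant sites the non-recipient allele sits on haplotype 2
    (coupling phase).
    """

    sites: pd.DataFrame

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def variant_is_het(self) -> np.ndarray:
        return (self.sites["var1"] != self.sites["var2"]).to_numpy()

    def recipient_is_hom(self) -> np.ndarray:
        return (self.sites["rec1"] == self.sites["rec2"]).to_numpy()

    def marker_mask(self) -> np.ndarray:
        """Sites usable as F2 markers: recipient homozygous, variant heterozygous."""
        return self.recipient_is_hom() & self.variant_is_het()


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    site_kind: np.ndarray                 # str per site
    crossovers: pd.DataFrame              # line, generation, gamete, chrom, pos
    population_mutations: pd.DataFrame    # site_index, chrom, pos, allele, n_carriers
    mutation_carriers: dict               # site_index -> np.ndarray of line indices
    qtls: pd.DataFrame                    # chrom, pos, site_index, additive, dominance
    config: SimulationConfig
    seed: int


def simulate_founders(
    layout: GenomeLayout, config: SimulationConfig, rng: np.random.Generator
) -> tuple[FounderPair, np.ndarray]:
    """Draw the founder site universe and genotypes.

    Returns the founder pair and the per-site kind labels.  Site counts per
    chromosome are Binomial(length_bp, rate); positions are uniform without
    replacement, so realised rates sit within binomial noise of their targets.

    The configured heterozygosity rates are each founder's *total* genomic
    heterozygosity.  The variant inherits the recipient's residual
    heterozygous sites (it is derived from it), so additional variant-only
    heterozygous sites are planted at rate het_rate_variant -
    het_rate_recipient; with het_rate_variant = 0 the variant is identical
    to the recipient at every site.
    """
    config.validate()
    extra_het = max(0.0, config.het_rate_variant - config.het_rate_recipient)
    recs = []
    kinds = []
    for chrom in layout.chromosomes:
        L = chrom.length_bp
        n_rec_het = rng.binomial(L, config.het_rate_recipient)
        n_var_het = rng.binomial(L, extra_het)
        n_var_hom = rng.binomial(L, config.mut_rate_variant)
        n_pop_mut = int(round(config.n_population_mutation_sites * L / layout.total_bp))
        n_total = n_rec_het + n_var_het + n_var_hom + n_pop_mut
        if n_total == 0:
            continue
        if n_total > L:
            raise ValueError(f"{chrom.name}: more sites requested than bases")
        pos = np.sort(rng.choice(L, size=n_total, replace=False) + 1)
        kind = np.concatenate([
            np.repeat(KIND_REC_HET, n_rec_het),
            np.repeat(KIND_VAR_HET, n_var_het),
            np.repeat(KIND_VAR_HOM, n_var_hom),
            np.repeat(KIND_POP_MUT, n_pop_mut),
        ])
        rng.shuffle(kind)

        ref = rng.integers(0, 4, n_total).astype(np.int8)
        # non-reference alternate allele per site (uniform over the other 3)
        alt = ((ref + rng.integers(1, 4, n_total)) % 4).astype(np.int8)

        rec1 = ref.copy()
        rec2 = ref.copy()
        var1 = ref.copy()
        var2 = ref.copy()

        m = kind == KIND_REC_HET
        rec2[m] = alt[m]          # recipient ref/alt
        var1[m] = rec1[m]         # variant copies the recipient genotype
        var2[m] = rec2[m]
        m = kind == KIND_VAR_HET
        var2[m] = alt[m]          # coupling phase: novel allele on haplotype 2
        m = kind == KIND_VAR_HOM
        var1[m] = alt[m]
        var2[m] = alt[m]
        # KIND_POP_MUT sites stay monomorphic ref/ref in both founders.

        recs.append(pd.DataFrame({
            "chrom": chrom.name, "pos": pos, "ref": ref,
            "rec1": rec1, "rec2": rec2, "var1": var1, "var2": var2,
        }))
        kinds.append(kind)

    if not recs:
        sites = pd.DataFrame(
            columns=["chrom", "pos", "ref", "rec1", "rec2", "var1", "var2"])
        return FounderPair(sites), np.array([], dtype=object)
    sites = pd.concat(recs, ignore_index=True)
    return FounderPair(sites), np.concatenate(kinds)


# ---------------------------------------------------------------------------
# Meiosis and selfing
# ---------------------------------------------------------------------------


def simulate_meiosis(
    hap1: np.ndarray,
    hap2: np.ndarray,
    pos_bp: np.ndarray,
    length_bp: int,
    genetic_length_cM: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a phased pair: Poisson crossovers, no interference.

    Returns (gamete alleles, crossover positions in bp).  The genetic map is
    linear in physical position, so crossover positions are uniform on
    (0, length_bp).  The starting haplotype is chosen with probability 1/2.
    """
    if len(hap1) != len(hap2):
        raise ValueError("haplotypes have unequal site counts")
    if genetic_length_cM < 0:
        raise ValueError("genetic_length_cM must be >= 0")
    n_x = rng.poisson(genetic_length_cM / 100.0)
    xo = np.sort(rng.uniform(0.0, float(length_bp), n_x))
    start = int(rng.integers(0, 2))
    # haplotype index at each site flips at every crossover left of the site
    flips = np.searchsorted(xo, pos_bp, side="left")
    hap_idx = (start + flips) % 2
    gamete = np.where(hap_idx == 0, hap1, hap2)
    return gamete.astype(np.int8), xo


@dataclass
class Population:
    """Phased true genotypes of the selfed lines over the founder site universe."""

    sites: pd.DataFrame          # shared with FounderPair
    hap1: np.ndarray             # (n_lines, n_sites) int8
    hap2: np.ndarray
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return self.hap1.shape[0]

    def genotype_codes(self, site_index: np.ndarray, b_allele: np.ndarray) -> np.ndarray:
        """Count of ``b_allele`` copies per line at the given sites: 0/1/2."""
        g1 = self.hap1[:, site_index] == b_allele
        g2 = self.hap2[:, site_index] == b_allele
        return (g1.astype(np.int8) + g2.astype(np.int8))


def self_population(
    founders: FounderPair,
    layout: GenomeLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    site_kind: np.ndarray | None = None,
) -> tuple[Population, TruthSet]:
    """Produce ``n_lines`` progeny by ``selfing_generations`` rounds of selfing.

    Each generation every line is replaced by the union of two independent
    gametes drawn from its own haplotype pair.  At g=0 every line equals the
    founder variant.  Crossovers are recorded in the truth set.
    """
    config.validate()
    sites = founders.sites
    n_sites = len(sites)
    chrom_index = {}
    for name in layout.names:
        idx = np.flatnonzero((sites["chrom"] == name).to_numpy())
        if idx.size:
            chrom_index[name] = (idx, sites["pos"].to_numpy()[idx])

    n = config.n_lines
    g = config.selfing_generations
    hap1 = np.tile(sites["var1"].to_numpy(np.int8), (n, 1))
    hap2 = np.tile(sites["var2"].to_numpy(np.int8), (n, 1))

    xo_rows: list[tuple] = []
    for line in range(n):
        h1, h2 = hap1[line], hap2[line]
        for gen in range(g):
            new = [np.empty(n_sites, np.int8), np.empty(n_sites, np.int8)]
            for name, (idx, pos) in chrom_index.items():
                chrom = layout.chromosome(name)
                for which in (0, 1):
                    gam, xo = simulate_meiosis(
                        h1[idx], h2[idx], pos, chrom.length_bp,
                        chrom.genetic_length_cM, rng)
                    new[which][idx] = gam
                    for p in xo:
                        xo_rows.append((line, gen + 1, which + 1, name, float(p)))
            h1, h2 = new
        hap1[line], hap2[line] = h1, h2

    crossovers = pd.DataFrame(
        xo_rows, columns=["line", "generation", "gamete", "chrom", "pos"])

    # Plant population-level de novo mutations at the monomorphic sites.
    if site_kind is None:
        site_kind = np.repeat("unknown", n_sites)
    mut_rows: list[tuple] = []
    carriers: dict[int, np.ndarray] = {}
    ref = sites["ref"].to_numpy(np.int8)
    for si in np.flatnonzero(site_kind == KIND_POP_MUT):
        novel = np.int8((ref[si] + rng.integers(1, 4)) % 4)
        carry = np.flatnonzero(
            rng.random(n) < config.population_mutation_carrier_fraction)
        hap1[carry, si] = novel
        hap2[carry, si] = novel
        carriers[int(si)] = carry
        mut_rows.append((int(si), sites["chrom"].iloc[si],
                         int(sites["pos"].iloc[si]), int(novel), len(carry)))
    population_mutations = pd.DataFrame(
        mut_rows, columns=["site_index", "chrom", "pos", "allele", "n_carriers"])

    line_ids = [f"L{i + 1:04d}" for i in range(n)]
    pop = Population(sites, hap1, hap2, line_ids)
    truth = TruthSet(
        site_kind=site_kind,
        crossovers=crossovers,
        population_mutations=population_mutations,
        mutation_carriers=carriers,
        qtls=pd.DataFrame(columns=["chrom", "pos", "site_index", "additive", "dominance"]),
        config=config,
        seed=config.seed,
    )
    return pop, truth


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def additive_effect_for_r2(
    r2: float, residual_sd: float = 1.0, selfing_generations: int = 1
) -> float:
    """Additive effect size giving a target variance share for a single QTL.

    In a selfed population the additive genotype code x in {-1, 0, +1} has
    variance Var(x) = 1 - 2^-g at an unlinked founder-heterozygous site
    (1/2 at g=1).  Choosing a = sd * sqrt(r2 / ((1 - r2) Var(x))) makes the
    QTL explain a fraction r2 of the total trait variance.
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    var_x = 1.0 - 2.0 ** (-selfing_generations)
    if var_x == 0:
        raise ValueError("no segregation at g=0")
    return residual_sd * math.sqrt(r2 / ((1.0 - r2) * var_x))


def simulate_traits(
    population: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: TruthSet | None = None,
) -> pd.DataFrame:
    """Trait table: y = mu + sum(a_i x_i + d_i z_i) + N(0, sigma^2).

    Each planted QTL is snapped to the nearest variant-heterozygous marker
    site on its chromosome; the additive code x counts non-recipient alleles
    minus one, and the dominance code z is 1 for heterozygotes.
    """
    sites = population.sites
    n = population.n_lines
    y = np.full(n, config.trait_mean, dtype=float)
    qtl_rows = []
    founder_het = (sites["var1"] != sites["var2"]).to_numpy()
    for q in config.qtls:
        on_chrom = (sites["chrom"] == q.chrom).to_numpy() & founder_het
        if not on_chrom.any():
            raise ValueError(f"no heterozygous founder site on {q.chrom} to host a QTL")
        pos = sites["pos"].to_numpy()
        cand = np.flatnonzero(on_chrom)
        si = cand[np.argmin(np.abs(pos[cand] - q.pos))]
        b = np.int8(sites["var2"].iloc[si])  # non-recipient allele (coupling phase)
        code = population.genotype_codes(np.array([si]), np.array([b]))[:, 0]
        x = code.astype(float) - 1.0
        z = (code == 1).astype(float)
        y += q.additive * x + q.dominance * z
        qtl_rows.append((q.chrom, int(sites["pos"].iloc[si]), int(si),
                         q.additive, q.dominance))
    if config.residual_sd > 0:
        y += rng.normal(0.0, config.residual_sd, n)
    if truth is not None:
        truth.qtls = pd.DataFrame(
            qtl_rows, columns=["chrom", "pos", "site_index", "additive", "dominance"])
    return pd.DataFrame({"line_id": population.line_ids, config.trait_name: y})


# ---------------------------------------------------------------------------
# Sparse observations
# ---------------------------------------------------------------------------


def _zero_truncated_poisson(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(lam) conditioned on being positive (depth given a site is covered)."""
    out = rng.poisson(lam, size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(lam, int(zeros.sum()))
        zeros = out == 0
    return out


def simulate_observations(
    population: Population, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Sparse per-line allele counts.

    Each (line, site) is observed with probability ``site_coverage``; given
    observation, read depth is zero-truncated Poisson(``mean_depth``); each
    read samples one of the line's two alleles uniformly and is flipped to a
    uniformly chosen different base with probability ``base_error``.

    Returns a long-form frame: line_id, chrom, pos, n_A, n_C, n_G, n_T.
    """
    config.validate()
    sites = population.sites
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    frames = []
    for li in range(population.n_lines):
        obs = np.flatnonzero(rng.random(len(sites)) < config.site_coverage)
        if obs.size == 0:
            continue
        depth = _zero_truncated_poisson(config.mean_depth, obs.size, rng)
        a1 = population.hap1[li, obs]
        a2 = population.hap2[li, obs]
        k1 = rng.binomial(depth, 0.5)
        k2 = depth - k1
        counts = np.zeros((obs.size, 4), dtype=np.int32)
        for k, alle in ((k1, a1), (k2, a2)):
            if config.base_error > 0:
                e = rng.binomial(k, config.base_error)
            else:
                e = np.zeros_like(k)
            np.add.at(counts, (np.arange(obs.size), alle), k - e)
            n_err = int(e.sum())
            if n_err:
                rows = np.repeat(np.arange(obs.size), e)
                true = np.repeat(alle, e)
                wrong = (true + rng.integers(1, 4, n_err)) % 4
                np.add.at(counts, (rows, wrong), 1)
        frames.append(pd.DataFrame({
            "line_id": population.line_ids[li],
            "chrom": chrom[obs], "pos": pos[obs],
            "n_A": counts[:, 0], "n_C": counts[:, 1],
            "n_G": counts[:, 2], "n_T": counts[:, 3],
        }))
    if not frames:
        return pd.DataFrame(
            columns=["line_id", "chrom", "pos", "n_A", "n_C", "n_G", "n_T"])
    return pd.concat(frames, ignore_index=True)
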