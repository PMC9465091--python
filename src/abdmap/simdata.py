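"""Gene-drop simulator for recessive-lethal mapping fixtures.

Emulates the data structure the mapping pipeline assumes: a rare breed in
which a new fully penetrant recessive lethal arose on one founder
chromosome.  All modern carriers share that founder haplotype identical by
descent around the causal site; affected offspring of carrier x carrier
matings are homozygous for it and therefore sit inside a long run of
homozygosity, while their obligate-carrier parents are heterozygous.

The simulation is a classical gene drop.  Founder haplotypes are drawn
site-wise from per-site allele frequencies (linkage equilibrium outside
the founder segment — enough structure to exercise every pipeline stage
without a coalescent).  The shared founder segment is a fixed allele
pattern spanning ``ibd_halflength_bp`` either side of the causal site,
tagged with an ancestry label so the emitted truth records the exact IBD
boundaries each case ends up with after recombination.  Meioses recombine
with Poisson crossovers at ``recombination_rate`` cM/Mb through
``pedigree_depth`` generations of carrier-lineage matings; cases are bred
from carrier pairs and accepted when homozygous for the causal allele.

Genotype error flips homozygote <-> heterozygote symmetrically (the
simplest model that breaks ROH runs the way real miscalls do), calls drop
to missing at ``missing_rate``, and GQ/DP are drawn to mimic ~30x WGS.
Output is a valid VCF 4.2 with GT:GQ:DP, a phenotype table and a truth
table; everything is deterministic under the config seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .vcfio import PhenotypeMap

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate", "null_simulate"]

_CAUSAL_ANCESTRY = 0  # ancestry label of the shared founder segment


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the gene-drop simulation.

    Defaults mirror a desk-scale version of a nine-animal WGS design:
    three affected calves and their six carrier parents, one causal splice
    variant on a ~6 Mb shared founder haplotype, deep-coverage quality
    fields, and low miscall/missingness rates typical of ~30x short-read
    calling.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 20_000_000
    snv_density: float = 25.0  # sites per Mb
    maf_min: float = 0.05
    maf_max: float = 0.5
    causal_chrom: str = "2"
    causal_pos: int = 10_000_000
    ibd_halflength_bp: int = 3_000_000
    n_cases: int = 3
    n_controls: int = 6
    genotype_error_rate: float = 0.001
    missing_rate: float = 0.001
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    dp_mean: float = 30.0
    recombination_rate: float = 1.0  # cM/Mb
    pedigree_depth: int = 3
    rs_fraction: float = 0.9  # background sites carrying a (fake) rsID
    high_impact_fraction: float = 0.01  # background sites annotated HIGH
    moderate_fraction: float = 0.10
    seed: int = 17
    max_tries: int = 500

    def __post_init__(self) -> None:
        for rate in (self.genotype_error_rate, self.missing_rate,
                     self.rs_fraction, self.high_impact_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.snv_density <= 0:
            raise ValueError("snv_density must be > 0")
        if not 1 <= int(self.causal_chrom) <= self.n_chromosomes:
            raise ValueError("causal_chrom outside simulated chromosomes")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            raise ValueError("causal_pos outside its chromosome")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample counts must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    causal_chrom: str
    causal_pos: int
    genotypes: dict[str, tuple[int, int]]  # pre-error diplotype at causal site
    ibd_regions: dict[str, tuple[int, int]]  # per-case homozygous-IBD span

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# record\tsample\tchrom\tpos_or_start\tend_or_gt\n")
            fh.write(f"causal\t.\t{self.causal_chrom}\t{self.causal_pos}\t.\n")
            for s, (a, b) in self.genotypes.items():
                fh.write(f"genotype\t{s}\t{self.causal_chrom}\t{self.causal_pos}\t{a}/{b}\n")
            for s, (lo, hi) in self.ibd_regions.items():
                fh.write(f"ibd\t{s}\t{self.causal_chrom}\t{lo}\t{hi}\n")

    @classmethod
    def read(cls, path: str | Path) -> "SimTruth":
        causal_chrom, causal_pos = "", 0
        genotypes: dict[str, tuple[int, int]] = {}
        ibd: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                kind, sample, chrom, a, b = line.rstrip("\n").split("\t")
                if kind == "causal":
                    causal_chrom, causal_pos = chrom, int(a)
                elif kind == "genotype":
                    x, y = b.split("/")
                    genotypes[sample] = (int(x), int(y))
                elif kind == "ibd":
                    ibd[sample] = (int(a), int(b))
        return cls(causal_chrom, causal_pos, genotypes, ibd)


@dataclass
class SimResult:
    """Paths and in-memory objects from one simulation run."""

    vcf_path: Path
    phenotype_path: Path
    truth_path: Optional[Path]
    phenotypes: PhenotypeMap
    truth: Optional[SimTruth]


class _Haplotype:
    __slots__ = ("alleles", "ancestry")

    def __init__(self, alleles: np.ndarray, ancestry: np.ndarray):
        self.alleles = alleles
        self.ancestry = ancestry


class _Genome:
    """Site map shared by all individuals in one simulation."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator,
                 with_causal: bool):
        self.cfg = cfg
        self.chroms = [str(i + 1) for i in range(cfg.n_chromosomes)]
        self.positions: dict[str, np.ndarray] = {}
        self.mafs: dict[str, np.ndarray] = {}
        n_sites = max(1, round(cfg.snv_density * cfg.chrom_length_bp / 1e6))
        for chrom in self.chroms:
            pos = np.sort(
                rng.choice(cfg.chrom_length_bp, size=n_sites, replace=False)
            ).astype(np.int64) + 1
            if with_causal and chrom == cfg.causal_chrom:
                if cfg.causal_pos not in pos:
                    pos = np.sort(np.append(pos, cfg.causal_pos))
            self.positions[chrom] = pos
            self.mafs[chrom] = rng.uniform(cfg.maf_min, cfg.maf_max, size=len(pos))
        self.with_causal = with_causal
        if with_causal:
            cpos = self.positions[cfg.causal_chrom]
            self.causal_index = int(np.searchsorted(cpos, cfg.causal_pos))
            lo = cfg.causal_pos - cfg.ibd_halflength_bp
            hi = cfg.causal_pos + cfg.ibd_halflength_bp
            self.window = (
                int(np.searchsorted(cpos, lo, side="left")),
                int(np.searchsorted(cpos, hi, side="right")),
            )
            # the fixed allele pattern of the shared founder segment
            w0, w1 = self.window
            self.founder_pattern = (
                rng.random(w1 - w0) < self.mafs[cfg.causal_chrom][w0:w1]
            ).astype(np.uint8)
            self.founder_pattern[self.causal_index - w0] = 1
        self._next_ancestry = _CAUSAL_ANCESTRY + 1

    def new_ancestry(self) -> int:
        a = self._next_ancestry
        self._next_ancestry += 1
        return a

    def founder_hap(self, chrom: str, rng: np.random.Generator,
                    carrier_segment: bool = False) -> _Haplotype:
        alleles = (rng.random(len(self.positions[chrom]))
                   < self.mafs[chrom]).astype(np.uint8)
        ancestry = np.full(len(alleles), self.new_ancestry(), dtype=np.int32)
        if self.with_causal and chrom == self.cfg.causal_chrom:
            # the causal allele is new: absent from every background haplotype
            alleles[self.causal_index] = 0
        if carrier_segment and chrom == self.cfg.causal_chrom:
            w0, w1 = self.window
            alleles[w0:w1] = self.founder_pattern
            ancestry[w0:w1] = _CAUSAL_ANCESTRY
        return _Haplotype(alleles, ancestry)


class _Individual:
    __slots__ = ("haps",)

    def __init__(self, haps: dict[str, tuple[_Haplotype, _Haplotype]]):
        self.haps = haps


def _founder(genome: _Genome, rng: np.random.Generator,
             carrier: bool = False) -> _Individual:
    haps = {}
    for chrom in genome.chroms:
        h1 = genome.founder_hap(chrom, rng, carrier_segment=carrier)
        h2 = genome.founder_hap(chrom, rng)
        haps[chrom] = (h1, h2)
    return _Individual(haps)


def _meiosis(ind: _Individual, chrom: str, genome: _Genome,
             rng: np.random.Generator) -> _Haplotype:
    cfg = genome.cfg
    pos = genome.positions[chrom]
    morgans = cfg.chrom_length_bp * cfg.recombination_rate / 1e6 / 100.0
    n_x = rng.poisson(morgans)
    h1, h2 = ind.haps[chrom]
    phase = int(rng.integers(2))
    if n_x == 0:
        src = h1 if phase == 0 else h2
        return _Haplotype(src.alleles.copy(), src.ancestry.copy())
    breaks = np.sort(rng.integers(1, cfg.chrom_length_bp + 1, size=n_x))
    # segment index at each site = number of breakpoints passed
    seg = np.searchsorted(breaks, pos, side="left")
    use_h2 = (seg + phase) % 2 == 1
    alleles = np.where(use_h2, h2.alleles, h1.alleles).astype(np.uint8)
    ancestry = np.where(use_h2, h2.ancestry, h1.ancestry).astype(np.int32)
    return _Haplotype(alleles, ancestry)


def _mate(p1: _Individual, p2: _Individual, genome: _Genome,
          rng: np.random.Generator) -> _Individual:
    return _Individual(
        {c: (_meiosis(p1, c, genome, rng), _meiosis(p2, c, genome, rng))
         for c in genome.chroms}
    )


def _causal_count(ind: _Individual, genome: _Genome) -> int:
    c, i = genome.cfg.causal_chrom, genome.causal_index
    h1, h2 = ind.haps[c]
    return int(h1.ancestry[i] == _CAUSAL_ANCESTRY) + int(
        h2.ancestry[i] == _CAUSAL_ANCESTRY
    )


def _breed_carrier_lineages(genome: _Genome, rng: np.random.Generator):
    """Carrier parents, each at the foot of an independent descent of the
    founder segment through ``pedigree_depth`` meioses."""
    cfg = genome.cfg
    carriers = []
    for _ in range(cfg.n_controls):
        parent = _founder(genome, rng, carrier=True)
        for _gen in range(cfg.pedigree_depth):
            for attempt in range(cfg.max_tries):
                child = _mate(parent, _founder(genome, rng), genome, rng)
                if _causal_count(child, genome) >= 1:
                    parent = child
                    break
            else:
                raise RuntimeError(
                    "could not breed a carrier lineage within "
                    f"{cfg.max_tries} tries; increase max_tries or change seed"
                )
        carriers.append(parent)
    return carriers


def _breed_cases(carriers, genome: _Genome, rng: np.random.Generator):
    cfg = genome.cfg
    if len(carriers) < 2:
        raise ValueError("need >= 2 carrier parents to breed affected cases")
    cases = []
    for k in range(cfg.n_cases):
        p1 = carriers[(2 * k) % len(carriers)]
        p2 = carriers[(2 * k + 1) % len(carriers)]
        for attempt in range(cfg.max_tries):
            child = _mate(p1, p2, genome, rng)
            if _causal_count(child, genome) == 2:
                cases.append(child)
                break
        else:
            raise RuntimeError(
                f"no homozygous-causal offspring in {cfg.max_tries} matings; "
                "increase max_tries, deepen the pedigree, or change seed"
            )
    return cases


def _case_ibd_region(ind: _Individual, genome: _Genome) -> tuple[int, int]:
    """Span over which *both* haplotypes carry the founder segment."""
    c = genome.cfg.causal_chrom
    pos = genome.positions[c]
    h1, h2 = ind.haps[c]
    both = (h1.ancestry == _CAUSAL_ANCESTRY) & (h2.ancestry == _CAUSAL_ANCESTRY)
    i = genome.causal_index
    lo = i
    while lo > 0 and both[lo - 1]:
        lo -= 1
    hi = i
    while hi < len(both) - 1 and both[hi + 1]:
        hi += 1
    return int(pos[lo]), int(pos[hi])


def _annotation(genome: _Genome, chrom: str, site_index: int,
                alt: str, rng: np.random.Generator, cfg: SimConfig) -> str:
    if genome.with_causal and chrom == cfg.causal_chrom \
            and site_index == genome.causal_index:
        return f"{alt}|splice_acceptor_variant|HIGH|GCK|tx_causal|deleterious(0.01)"
    u = rng.random()
    if u < cfg.high_impact_fraction:
        return f"{alt}|stop_gained|HIGH|BG{site_index}|tx{site_index}|deleterious(0.03)"
    if u < cfg.high_impact_fraction + cfg.moderate_fraction:
        return f"{alt}|missense_variant|MODERATE|BG{site_index}|tx{site_index}|tolerated(0.4)"
    return f"{alt}|intron_variant|MODIFIER|BG{site_index}|tx{site_index}|"


_BASES = np.array(list("ACGT"))


def _write_vcf(
    path: Path,
    genome: _Genome,
    individuals: list[_Individual],
    sample_names: list[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=abdmap-simdata\n")
    for chrom in genome.chroms:
        buf.write(f"##contig=<ID={chrom},length={cfg.chrom_length_bp}>\n")
    buf.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
    buf.write(
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        'annotations. Format: Allele|Consequence|IMPACT|SYMBOL|Feature|SIFT">\n'
    )
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(sample_names) + "\n")
    rs_counter = 100000
    for chrom in genome.chroms:
        pos = genome.positions[chrom]
        for j in range(len(pos)):
            is_causal = (
                genome.with_causal
                and chrom == cfg.causal_chrom
                and j == genome.causal_index
            )
            ref, alt = rng.choice(4, size=2, replace=False)
            ref_b, alt_b = _BASES[ref], _BASES[alt]
            if is_causal:
                ref_b, alt_b = "A", "T"
                vid = "."
            elif rng.random() < cfg.rs_fraction:
                rs_counter += 1
                vid = f"rs{rs_counter}"
            else:
                vid = "."
            gts = []
            depths = []
            for ind in individuals:
                h1, h2 = ind.haps[chrom]
                a, b = int(h1.alleles[j]), int(h2.alleles[j])
                # symmetric zygosity-flip error model
                if rng.random() < cfg.genotype_error_rate:
                    if a == b:
                        a, b = (0, 1)
                    else:
                        a = b = int(rng.integers(2))
                dp = int(rng.poisson(cfg.dp_mean))
                gq = int(np.clip(round(rng.normal(cfg.gq_mean, cfg.gq_sd)), 0, 99))
                if rng.random() < cfg.missing_rate:
                    gts.append(f"./.:{gq}:{dp}")
                else:
                    gts.append(f"{min(a,b)}/{max(a,b)}:{gq}:{dp}")
                depths.append(dp)
            qual = max(0.0, rng.normal(3000.0, 500.0))
            csq = _annotation(genome, chrom, j, str(alt_b), rng, cfg)
            info = f"DP={sum(depths)};CSQ={csq}"
            buf.write(
                f"{chrom}\t{pos[j]}\t{vid}\t{ref_b}\t{alt_b}\t{qual:.1f}\t"
                f"PASS\t{info}\tGT:GQ:DP\t" + "\t".join(gts) + "\n"
            )
    path.write_text(buf.getvalue())


def simulate(cfg: SimConfig, out_dir: str | Path) -> SimResult:
    """Run the gene drop and write VCF, phenotype and truth files.

    Deterministic under ``cfg.seed``: identical configs produce
    byte-identical files.
    """
    if cfg.n_cases < 1 or cfg.n_controls < 2:
        raise ValueError("need >= 1 case and >= 2 controls (carrier parents)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = _Genome(cfg, rng, with_causal=True)
    carriers = _breed_carrier_lineages(genome, rng)
    cases = _breed_cases(carriers, genome, rng)

    sample_names = [f"case_{i+1}" for i in range(cfg.n_cases)] + [
        f"carrier_{i+1}" for i in range(cfg.n_controls)
    ]
    individuals = cases + carriers
    phen = PhenotypeMap(
        cases=sample_names[: cfg.n_cases], controls=sample_names[cfg.n_cases :]
    )

    ci = genome.causal_index
    cc = cfg.causal_chrom
    genotypes = {}
    for name, ind in zip(sample_names, individuals):
        h1, h2 = ind.haps[cc]
        pair = sorted((int(h1.alleles[ci]), int(h2.alleles[ci])))
        genotypes[name] = (pair[0], pair[1])
    truth = SimTruth(
        causal_chrom=cc,
        causal_pos=cfg.causal_pos,
        genotypes=genotypes,
        ibd_regions={
            name: _case_ibd_region(ind, genome)
            for name, ind in zip(sample_names[: cfg.n_cases], cases)
        },
    )

    vcf_path = out_dir / "sim.vcf"
    phen_path = out_dir / "phenotypes.tsv"
    truth_path = out_dir / "truth.tsv"
    _write_vcf(vcf_path, genome, individuals, sample_names, cfg, rng)
    from .vcfio import write_phenotypes

    write_phenotypes(phen, phen_path)
    truth.write(truth_path)
    return SimResult(vcf_path, phen_path, truth_path, phen, truth)


def null_simulate(
    cfg: SimConfig, out_dir: str | Path, uniform_thirds: bool = False
) -> SimResult:
    """Simulate with no planted variant and random phenotype labels.

    Samples are unrelated founders.  With ``uniform_thirds`` each genotype
    is drawn uniformly from {hom-ref, het, hom-alt} with perfect quality
    and no error/missingness — the null under which the genotype-criteria
    expectation S/3^(n+m) holds exactly.
    """
    n_samples = cfg.n_cases + cfg.n_controls
    if n_samples < 1:
        raise ValueError("need at least one sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    eff_cfg = cfg
    if uniform_thirds:
        eff_cfg = replace(cfg, genotype_error_rate=0.0, missing_rate=0.0,
                          gq_sd=0.0, gq_mean=99.0, dp_mean=60.0)
    genome = _Genome(eff_cfg, rng, with_causal=False)
    individuals = []
    for _ in range(n_samples):
        ind = _founder(genome, rng)
        individuals.append(ind)
    if uniform_thirds:
        for ind in individuals:
            for chrom in genome.chroms:
                h1, h2 = ind.haps[chrom]
                z = rng.integers(3, size=len(h1.alleles))
                h1.alleles = (z >= 1).astype(np.uint8)  # het or hom-alt
                h2.alleles = (z == 2).astype(np.uint8)  # hom-alt only
    labels = rng.permutation(n_samples)
    sample_names = [f"animal_{i+1}" for i in range(n_samples)]
    phen = PhenotypeMap(
        cases=[sample_names[i] for i in sorted(labels[: cfg.n_cases])],
        controls=[sample_names[i] for i in sorted(labels[cfg.n_cases :])],
    )
    vcf_path = out_dir / "null.vcf"
    phen_path = out_dir / "phenotypes.tsv"
    _write_vcf(vcf_path, genome, individuals, sample_names, eff_cfg, rng)
    from .vcfio import write_phenotypes

    write_phenotypes(phen, phen_path)
    return SimResult(vcf_path, phen_path, None, phen, None)
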