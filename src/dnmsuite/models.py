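"""Domain types shared across the pipeline.

The pipeline's unit records are small frozen-ish dataclasses; bulk data
(variant sites, read-fragment observations, truth tables) travels as pandas
DataFrames with the column schemas declared here, so every stage can operate
vectorised and every table round-trips through plain TSV/VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

# Column schema for the per-trio site table (one row per variant site).
# Genotypes are unphased VCF strings ("0/0", "0/1", "1/1", "./.");
# ad_*_ref/ad_*_alt are allele depths, dp_* total depths.
SITE_COLUMNS = [
    "trio", "chrom", "pos", "ref", "alt",
    "gt_f", "gt_m", "gt_c",
    "ad_f_ref", "ad_f_alt", "dp_f",
    "ad_m_ref", "ad_m_alt", "dp_m",
    "ad_c_ref", "ad_c_alt", "dp_c",
]

# Truth table schema (simulator ground truth, hidden from callers).
TRUTH_COLUMNS = ["trio", "chrom", "pos", "ref", "alt", "origin", "cluster_id"]

# Long-format fragment observation table: one row per (fragment, site)
# observation. `hap` is the source-haplotype side channel ("P" paternal /
# "M" maternal), carried for truth checks only — phasing never reads it.
FRAGMENT_COLUMNS = [
    "trio", "frag_id", "individual", "chrom", "pos", "allele",
    "start1", "start2", "hap",
]


@dataclass
class RateModel:
    """Germline mutation-rate model driving the cohort simulator.

    The expected DNM count per child is linear in parental ages at
    conception: ``intercept + beta_paternal * father_age +
    beta_maternal * mother_age``.  ``paternal_origin_prob`` is the marginal
    fraction of DNMs arising on the paternal haplotype; a small fraction of
    DNMs occur in multi-mutation clusters (single mutational events on one
    parental haplotype) with a maternal bias.
    """

    intercept: float = 29.3
    beta_paternal: float = 1.09
    beta_maternal: float = 0.30
    paternal_origin_prob: float = 0.75
    cluster_fraction: float = 0.03
    cluster_mean_size: float = 2.2
    cluster_max_span: int = 20_000
    cluster_maternal_origin_prob: float = 0.6

    def __post_init__(self) -> None:
        for name in ("paternal_origin_prob", "cluster_fraction",
                     "cluster_maternal_origin_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.cluster_mean_size < 2:
            raise ValueError("cluster_mean_size must be >= 2")
        if self.cluster_max_span <= 0:
            raise ValueError("cluster_max_span must be positive")
        # expected count must be nonnegative over the supported age range
        for fa in (18, 70):
            for ma in (18, 70):
                mu = (self.intercept + self.beta_paternal * fa
                      + self.beta_maternal * ma)
                if mu < 0:
                    raise ValueError(
                        f"expected DNM count negative ({mu:.2f}) at ages "
                        f"({fa}, {ma})")


def _default_windows() -> list[tuple[str, int]]:
    # 2.5 Gb across 20 named windows: close enough to autosomal genome
    # scale that chance 20-kb proximity of independent DNMs stays rare,
    # as it is in real data.
    return [(f"chr{i}", 125_000_000) for i in range(1, 21)]


@dataclass
class SimulationConfig:
    """Sequencing-and-cohort parameters for the simulator.

    Coverage and read length default to a 38x paired-end 150 bp design.
    ``het_snp_density`` is the expected number of inherited heterozygous
    SNPs per bp *per parent* (default 1/1200, human-like). Age samplers are
    callables ``rng -> float`` (years).

    ``snp_neighborhood`` restricts inherited-SNP generation to within that
    many bp of each DNM (default 6000, i.e. the 5-kb phasing window plus an
    insert length).  Inherited SNPs only influence the analysis through
    phasing, which is local to each DNM, so this is a pure desk-scale
    economy; ``None`` generates SNPs across whole windows.
    """

    n_trios: int = 50
    genome_windows: list[tuple[str, int]] = field(default_factory=_default_windows)
    het_snp_density: float = 1 / 1200
    coverage: float = 38.0
    read_length: int = 150
    insert_size_mean: float = 350.0
    insert_size_sd: float = 50.0
    base_error_rate: float = 0.005
    snp_neighborhood: Optional[int] = 6000
    seed: int = 0
    father_age_sampler: Optional[Callable] = None
    mother_age_sampler: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be nonnegative")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        seen: dict[str, list[tuple[int, int]]] = {}
        for chrom, length in self.genome_windows:
            if length <= 0:
                raise ValueError(f"window length must be positive: {chrom}")
            seen.setdefault(chrom, []).append((1, length))
        for chrom, ivals in seen.items():
            if len(ivals) > 1:
                raise ValueError(
                    f"overlapping windows on {chrom}: one window per "
                    "chromosome name is supported")

    def sample_father_age(self, rng: np.random.Generator) -> float:
        if self.father_age_sampler is not None:
            return float(self.father_age_sampler(rng))
        return float(rng.uniform(24.0, 56.0))

    def sample_mother_age(self, rng: np.random.Generator) -> float:
        if self.mother_age_sampler is not None:
            return float(self.mother_age_sampler(rng))
        return float(rng.uniform(23.0, 42.0))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated DNM."""

    trio: str
    chrom: str
    pos: int
    ref: str
    alt: str
    true_origin: str            # "paternal" | "maternal"
    cluster_id: Optional[str] = None


@dataclass(frozen=True)
class TrioSite:
    """One genomic site with genotypes and allele depths for a trio."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gt_f: str
    gt_m: str
    gt_c: str
    ad_f: Tuple[int, int]
    ad_m: Tuple[int, int]
    ad_c: Tuple[int, int]
    dp_f: int = -1
    dp_m: int = -1
    dp_c: int = -1

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for name in ("f", "m", "c"):
            ad = getattr(self, f"ad_{name}")
            if min(ad) < 0:
                raise ValueError("allele depths must be nonnegative")
            dp = getattr(self, f"dp_{name}")
            if dp < 0:
                object.__setattr__(self, f"dp_{name}", sum(ad))
            elif dp < sum(ad):
                raise ValueError("total depth below sum of allele depths")


@dataclass(frozen=True)
class ReadFragment:
    """A paired-end read fragment with its observed alleles.

    ``observed`` maps 1-based site position -> observed base at that site.
    ``hap`` records the source haplotype ("P"/"M"), a simulator truth
    side-channel that phasing must not consult.
    """

    frag_id: str
    individual: str
    chrom: str
    start1: int
    start2: int
    observed: dict
    hap: str = "?"


@dataclass
class CallerConfig:
    """Thresholds for the two calling rules and the consensus filter."""

    min_child_alt_reads: int = 10
    min_depth: int = 10
    max_parent_alt_reads: int = 1
    base_error_rate: float = 0.005
    posterior_threshold: float = 0.5
    prior_dnm: float = 1e-7
    allele_freq: float = 1e-3

    def __post_init__(self) -> None:
        if self.min_child_alt_reads < 1:
            raise ValueError("min_child_alt_reads must be >= 1")
        for name in ("base_error_rate", "posterior_threshold", "prior_dnm",
                     "allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class DnmCall:
    """A consensus de novo call for one child."""

    trio: str
    chrom: str
    pos: int
    ref: str
    alt: str
    child_alt_reads: int
    rule_a: bool
    rule_b: bool
    replicate_confirmed: bool = False
    origin: str = "unphased"    # paternal | maternal | unphased

    @property
    def key(self) -> tuple:
        return (self.trio, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class InformativeSnp:
    """A parentally informative SNP: a child-het site whose parental
    genotypes force a unique allele-to-parent attribution."""

    chrom: str
    pos: int
    father_allele: str          # child allele attributable to the father
    mother_allele: str          # child allele attributable to the mother


@dataclass
class PhaserConfig:
    window: int = 5000
    min_supporting_fragments: int = 1
    allow_transitive_chaining: bool = True
    use_ref_allele_evidence: bool = True

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_supporting_fragments < 1:
            raise ValueError("min_supporting_fragments must be >= 1")


@dataclass
class OriginAssignment:
    trio: str
    chrom: str
    pos: int
    verdict: str                # paternal | maternal | unphased
    paternal_fragments: int = 0
    maternal_fragments: int = 0
    chain_length: int = 0       # number of linked variant sites used

    @property
    def key(self) -> tuple:
        return (self.trio, self.chrom, self.pos)


@dataclass
class DnmCluster:
    """>= 2 DNMs of one child within the linkage distance of each other."""

    cluster_id: str
    trio: str
    chrom: str
    positions: list             # sorted member positions
    same_allele: Optional[bool] = None   # None == unknown (<2 phased members)

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0]


@dataclass(frozen=True)
class CohortRecord:
    """One child of the cohort table."""

    child_id: str
    method: str                 # spontaneous | IVF | ICSI-TESE
    age_group: str              # "<35" | ">45"
    dnm_count: int
    maternal_age: float
    paternal_age: float
    fertility_status: str = ""


@dataclass
class RegressionFit:
    """A fitted regression with per-term inference and overall fit."""

    params: dict
    bse: dict
    tvalues: dict
    pvalues: dict
    df_resid: int
    r_squared: Optional[float]
    f_stat: Optional[float]
    f_df: Optional[Tuple[int, int]]
    f_pvalue: Optional[float]
    n: int


@dataclass
class TestResult:
    name: str                   # "t", "F", "z", "q"
    statistic: float
    df: object                  # int or (int, int)
    pvalue: float
    adjusted_pvalue: Optional[float] = None
    term: str = ""
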