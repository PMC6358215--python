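"""Stochastic forward simulation of gene-drive crosses.

The generative model follows the causal order of events in a fly cross:

1. *Germline modification at gametogenesis.*  In a drive/wild-type
   heterozygote with a germline-available Cas9 source, the wild-type allele
   is converted to a drive copy (homology-directed repair) with probability
   ``c``, or to a resistance allele (end-joining) with probability ``r``,
   sex-specific; otherwise it stays wild-type.  One of the two (possibly
   modified) alleles is then transmitted uniformly.  Resistance and drive
   homologs are never cut — their target site is destroyed.
2. *Fertilization.*  The support locus segregates independently and
   Mendelianly.  At an X-linked target, fathers transmit their target allele
   to daughters only.
3. *Embryo-stage modification.*  If the mother deposited both Cas9 and gRNA
   into the egg, each wild-type target allele of the zygote is independently
   cut and repaired to a resistance allele with probability ``e_cut``, or
   mosaically cut (phenotype-visible, state unchanged) with probability
   ``e_mosaic``.  Either deposition missing means no embryo activity at all.

Cas9 availability in the germline has two routes: a genomic source (support
transgene, or the drive construct itself in standard systems) uses the
ordinary conversion/resistance rates; an individual with no genomic Cas9 but
which itself received maternally deposited Cas9 as an egg may retain enough
carried-over protein for germline activity.  Carryover is all-or-nothing per
individual (probability ``p_active``), and when active uses its own rates
``c_carry``/``r_carry``.  Carried-over Cas9 never persists a second
generation: deposition into the next egg is recomputed from genotype alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    FEMALE,
    MALE,
    DepositionState,
    DriveSystemConfig,
    LocusGenotype,
    MosaicFlag,
    NO_DEPOSITION,
    PhenotypeRecord,
    Sex,
    SupportAllele,
    TargetAllele,
    deposition_of_mother,
    phenotype_of,
)

__all__ = [
    "DriveParams",
    "CrossDesign",
    "CountTable",
    "germline_transmit",
    "embryo_modify",
    "simulate_cross",
    "simulate_experiment",
]


@dataclass(frozen=True)
class DriveParams:
    """Probabilities of the inheritance model.

    Defaults describe the split drive targeting X-linked *yellow*: 74%
    female germline conversion, 74% embryo resistance formation when both
    Cas9 and gRNA are maternally deposited, and a carryover model in which
    15 of 16 Cas9-less but carryover-exposed females show ~54% conversion
    while the rest show none.  Rates without a measured value (germline
    resistance under genomic Cas9, the functional-repair fraction
    ``r1_fraction``, embryo mosaicism) default to zero and are free
    parameters.

    Attributes
    ----------
    c_f, c_m
        Probability that the wild-type allele of a drive/wild heterozygote
        is converted to a drive allele in the female / male germline.
    r_f, r_m
        Probability it instead becomes a resistance allele in the germline.
    r1_fraction
        Probability a newly formed resistance allele preserves target-gene
        function (r1) rather than disrupting it (r2).
    e_cut, e_mosaic
        Per-allele probabilities that a wild-type target allele in the
        zygote is fully cut to resistance, or mosaically cut, when both
        maternal depositions are present.
    p_active
        Probability that a carryover-exposed individual without genomic
        Cas9 has germline-active carried-over Cas9.
    c_carry, r_carry
        Conversion / germline-resistance probabilities under carried-over
        Cas9 (used in place of ``c``/``r`` when no genomic Cas9 exists).
    """

    c_f: float = 0.74
    c_m: float = 0.0
    r_f: float = 0.0
    r_m: float = 0.0
    r1_fraction: float = 0.0
    e_cut: float = 0.74
    e_mosaic: float = 0.0
    p_active: float = 15 / 16
    c_carry: float = 0.54
    r_carry: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "c_f", "c_m", "r_f", "r_m", "r1_fraction",
            "e_cut", "e_mosaic", "p_active", "c_carry", "r_carry",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.c_f + self.r_f > 1.0 + 1e-12:
            raise ValueError("c_f + r_f must not exceed 1")
        if self.c_m + self.r_m > 1.0 + 1e-12:
            raise ValueError("c_m + r_m must not exceed 1")
        if self.e_cut + self.e_mosaic > 1.0 + 1e-12:
            raise ValueError("e_cut + e_mosaic must not exceed 1")
        if self.c_carry + self.r_carry > 1.0 + 1e-12:
            raise ValueError("c_carry + r_carry must not exceed 1")


@dataclass(frozen=True)
class CrossDesign:
    """One cross setup: parental genotypes, architecture and estimator protocol.

    ``mother_deposition_received`` is what the *mother herself* received as
    an egg; it drives the Cas9-carryover route when she has no genomic Cas9.

    The last three fields pin the estimation conventions appropriate to the
    design: which offspring enter the drive-inheritance denominator
    (``"all"`` or ``"daughters"``), which phenotype channel reads out embryo
    resistance (``"yellow"``, ``"egfp"`` or ``None``), and whether yellow
    non-dsRed sons give a clean germline-resistance readout.
    """

    name: str
    description: str
    mother: LocusGenotype
    father: LocusGenotype
    config: DriveSystemConfig
    mother_deposition_received: DepositionState = NO_DEPOSITION
    father_deposition_received: DepositionState = NO_DEPOSITION
    conversion_denominator: str = "all"
    embryo_readout: str | None = None
    germline_r2_sons: bool = False

    def __post_init__(self) -> None:
        self.mother.validate(self.config)
        self.father.validate(self.config)
        if self.mother.sex is not FEMALE or self.father.sex is not MALE:
            raise ValueError("cross requires a female mother and a male father")
        if self.conversion_denominator not in ("all", "daughters"):
            raise ValueError("conversion_denominator must be 'all' or 'daughters'")
        if self.embryo_readout not in (None, "yellow", "egfp"):
            raise ValueError("embryo_readout must be None, 'yellow' or 'egfp'")


@dataclass
class CountTable:
    """Phenotype tallies pooled over the crosses of one design.

    Keys are ``(sex, dsred, egfp, body)`` in their string/bool TSV forms.
    """

    name: str = ""
    counts: dict[tuple[str, bool, str, str], int] = field(default_factory=dict)
    n_crosses: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, phenotype: PhenotypeRecord, n: int = 1) -> None:
        key = phenotype.key()
        self.counts[key] = self.counts.get(key, 0) + n

    def add_key(self, key: tuple[str, bool, str, str], n: int) -> None:
        if n < 0:
            raise ValueError("counts must be non-negative")
        self.counts[key] = self.counts.get(key, 0) + n

    def count_where(
        self,
        sex: str | None = None,
        dsred: bool | None = None,
        egfp: str | None = None,
        body: str | None = None,
    ) -> int:
        """Sum of tallies matching every non-None field."""
        total = 0
        for (k_sex, k_dsred, k_egfp, k_body), n in self.counts.items():
            if sex is not None and k_sex != sex:
                continue
            if dsred is not None and k_dsred != dsred:
                continue
            if egfp is not None and k_egfp != egfp:
                continue
            if body is not None and k_body != body:
                continue
            total += n
        return total

    def merged(self, other: "CountTable") -> "CountTable":
        out = CountTable(
            name=self.name, counts=dict(self.counts),
            n_crosses=self.n_crosses + other.n_crosses,
        )
        for key, n in other.counts.items():
            out.add_key(key, n)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        mine = {k: v for k, v in self.counts.items() if v}
        theirs = {k: v for k, v in other.counts.items() if v}
        return mine == theirs and self.name == other.name \
            and self.n_crosses == other.n_crosses


def _resistance_allele(r1_fraction: float, rng: np.random.Generator) -> TargetAllele:
    return TargetAllele.R1 if rng.random() < r1_fraction else TargetAllele.R2


def _germline_rates(
    parent: LocusGenotype,
    parent_deposition_received: DepositionState,
    params: DriveParams,
    config: DriveSystemConfig,
    rng: np.random.Generator,
    carryover_active: bool | None = None,
) -> tuple[float, float]:
    """Effective (conversion, resistance) rates in this parent's germline.

    Returns (0, 0) when no Cas9 is available.  The carryover activity draw
    is all-or-nothing per individual; pass ``carryover_active`` to reuse a
    single per-fly draw across many gametes.
    """
    if parent.has_genomic_cas9(config):
        if parent.sex is FEMALE:
            return params.c_f, params.r_f
        return params.c_m, params.r_m
    if parent_deposition_received.cas9_deposited:
        if carryover_active is None:
            carryover_active = rng.random() < params.p_active
        if carryover_active:
            return params.c_carry, params.r_carry
    return 0.0, 0.0


def germline_transmit(
    parent: LocusGenotype,
    parent_deposition_received: DepositionState,
    params: DriveParams,
    config: DriveSystemConfig,
    rng: np.random.Generator,
    carryover_active: bool | None = None,
) -> tuple[TargetAllele, SupportAllele]:
    """Draw one gamete (target allele, support allele) from a parent.

    Homing happens only in exact drive/wild-type heterozygotes with an
    available Cas9 source and the drive's own gRNA; every other genotype
    transmits Mendelianly.  Mosaically cut alleles are germline wild-type
    and remain convertible.
    """
    support = parent.support_alleles[rng.integers(2)]

    alleles = parent.target_alleles
    if (
        len(alleles) == 2
        and parent.n_drive() == 1
        and parent.n_wild() == 1
    ):
        c, r = _germline_rates(
            parent, parent_deposition_received, params, config, rng,
            carryover_active,
        )
        if c > 0.0 or r > 0.0:
            u = rng.random()
            if u < c:
                new_wild = TargetAllele.DRIVE
            elif u < c + r:
                new_wild = _resistance_allele(params.r1_fraction, rng)
            else:
                new_wild = TargetAllele.WILD
            alleles = tuple(
                new_wild if a is TargetAllele.WILD else a for a in alleles
            )

    if len(alleles) == 1:
        target = alleles[0]
    else:
        target = alleles[rng.integers(2)]
    return target, support


def embryo_modify(
    zygote: LocusGenotype,
    mother_dep: DepositionState,
    params: DriveParams,
    rng: np.random.Generator,
) -> LocusGenotype:
    """Apply early-embryo Cas9 activity to a freshly formed zygote.

    Requires *both* maternal Cas9 and maternal gRNA; otherwise the zygote is
    returned unchanged.  Each wild-type target allele is independently fully
    cut to a resistance allele (probability ``e_cut``) or mosaically cut
    (``e_mosaic``).  Drive and resistance alleles are never modified.
    """
    if not mother_dep.both:
        return zygote
    if params.e_cut == 0.0 and params.e_mosaic == 0.0:
        return zygote
    new_alleles = []
    new_flags = []
    for allele, flag in zip(zygote.target_alleles, zygote.mosaic_flags):
        if allele.cleavable and flag is MosaicFlag.INTACT:
            u = rng.random()
            if u < params.e_cut:
                allele = _resistance_allele(params.r1_fraction, rng)
                flag = MosaicFlag.FULL_CUT
            elif u < params.e_cut + params.e_mosaic:
                flag = MosaicFlag.MOSAIC_CUT
        new_alleles.append(allele)
        new_flags.append(flag)
    return zygote.with_target(tuple(new_alleles), tuple(new_flags))


def simulate_cross(
    design: CrossDesign,
    params: DriveParams,
    n_offspring: int,
    rng: np.random.Generator,
) -> list[tuple[LocusGenotype, PhenotypeRecord]]:
    """Simulate the offspring of a single mating pair.

    Offspring sex is 1:1.  At an X-linked target the father's target gamete
    goes to daughters only; sons receive their single target allele from
    the mother.  Maternal deposition into each egg is computed from the
    design's mother genotype; per-individual Cas9-carryover activity of each
    parent is drawn once for the whole cross.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    config = design.config
    x_linked = config.target_linkage == "X"
    egg_dep = deposition_of_mother(design.mother, config)

    def activity(parent: LocusGenotype, received: DepositionState) -> bool | None:
        if not parent.has_genomic_cas9(config) and received.cas9_deposited:
            return bool(rng.random() < params.p_active)
        return None  # irrelevant; no carryover route

    mother_active = activity(design.mother, design.mother_deposition_received)
    father_active = activity(design.father, design.father_deposition_received)

    out = []
    for _ in range(n_offspring):
        sex = FEMALE if rng.random() < 0.5 else MALE
        m_target, m_support = germline_transmit(
            design.mother, design.mother_deposition_received, params, config,
            rng, carryover_active=mother_active,
        )
        f_target, f_support = germline_transmit(
            design.father, design.father_deposition_received, params, config,
            rng, carryover_active=father_active,
        )
        if x_linked and sex is MALE:
            targets: tuple[TargetAllele, ...] = (m_target,)
        else:
            targets = (m_target, f_target)
        zygote = LocusGenotype(
            sex=sex,
            target_alleles=targets,
            support_alleles=(m_support, f_support),
        )
        zygote = embryo_modify(zygote, egg_dep, params, rng)
        out.append((zygote, phenotype_of(zygote, config)))
    return out


def simulate_experiment(
    design: CrossDesign,
    params: DriveParams,
    n_crosses: int,
    n_per_cross: int,
    seed: int,
    return_per_cross: bool = False,
) -> CountTable | list[CountTable]:
    """Pool phenotype counts over independent replicate crosses.

    Each cross uses an independent random substream derived from
    ``(seed, cross index)``, so results are reproducible regardless of
    execution order; per-fly stochastic state (notably carryover activity
    of the parents) is redrawn for every cross.
    """
    if n_crosses < 0 or (n_crosses > 0 and n_per_cross < 1):
        raise ValueError("need n_crosses >= 0 and n_per_cross >= 1")
    tables = []
    pooled = CountTable(name=design.name)
    for i in range(n_crosses):
        rng = np.random.default_rng([int(seed), i])
        table = CountTable(name=design.name, n_crosses=1)
        for _, phen in simulate_cross(design, params, n_per_cross, rng):
            table.add(phen)
        tables.append(table)
        for key, n in table.counts.items():
            pooled.add_key(key, n)
        pooled.n_crosses += 1
    if return_per_cross:
        return tables
    return pooled
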