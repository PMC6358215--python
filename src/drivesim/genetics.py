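"""Alleles, genotypes, drive-system configurations and the genotype->phenotype map.

The model tracks two loci per fly:

* the *target* locus — the site the drive homes into.  Alleles are wild-type
  (``WILD``), drive (``DRIVE``, carrying the gRNA cassette and the dsRed eye
  marker), or resistance alleles created by end-joining repair of a Cas9 cut:
  ``R1`` preserves the function of the target gene, ``R2`` disrupts it.  The
  drive insertion itself also disrupts the target gene.
* the *support* locus — an unlinked autosomal site that may carry a Cas9
  transgene marked with EGFP (the supporting element of a split-drive system)
  or nothing (``ABSENT``).

Three drive architectures are supported: a *standard* homing drive whose
construct carries its own Cas9, a *split* drive whose gRNA element and Cas9
sit at unlinked loci, and a *synthetic-target* drive that homes into an
engineered EGFP gene absent from wild populations.  The target may be
autosomal or X-linked; at an X-linked target males are hemizygous and carry a
single allele.

Maternal deposition — Cas9 protein and/or gRNA loaded into the egg by the
mother — is derived purely from the mother's genotype (one-generation memory:
deposition received by the mother herself never propagates to her eggs).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace


class TargetAllele(enum.Enum):
    """Allele state at the drive's target locus."""

    WILD = "wild"
    DRIVE = "drive"
    R1 = "r1"  # resistance allele preserving target-gene function
    R2 = "r2"  # resistance allele disrupting target-gene function

    @property
    def functional(self) -> bool:
        """True if the allele preserves the function of the target gene."""
        return self in (TargetAllele.WILD, TargetAllele.R1)

    @property
    def cleavable(self) -> bool:
        """Only intact wild-type target sites can be cut."""
        return self is TargetAllele.WILD


class SupportAllele(enum.Enum):
    """Allele state at the unlinked support locus (EGFP-marked Cas9)."""

    CAS9 = "cas9"
    ABSENT = "absent"


class MosaicFlag(enum.Enum):
    """Embryo-stage modification history of one target allele."""

    INTACT = "intact"
    MOSAIC_CUT = "mosaic_cut"  # partial embryonic cutting; allele state unchanged
    FULL_CUT = "full_cut"  # allele converted to resistance in the early embryo


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"


FEMALE = Sex.FEMALE
MALE = Sex.MALE


@dataclass(frozen=True)
class DriveSystemConfig:
    """Architecture of a drive system.

    Parameters
    ----------
    system
        ``"standard"`` (drive construct carries Cas9), ``"split"`` (Cas9 on
        the unlinked support locus) or ``"synthetic_target"`` (a standard
        construct homing into an engineered EGFP target).
    target_linkage
        ``"X"`` or ``"autosome"``.
    drive_carries_cas9
        Whether the drive construct itself provides Cas9.  Forced true for
        standard systems and false for split systems.
    target_functional_marker
        Visible phenotype reporting a functional target gene:
        ``"yellow_body"`` (recessive body-colour marker, as for *yellow* and,
        isomorphically, other recessive visible markers), ``"egfp_eye"``
        (intact synthetic EGFP target fluoresces) or ``"none"``.
    """

    system: str
    target_linkage: str
    drive_carries_cas9: bool
    target_functional_marker: str

    def __post_init__(self) -> None:
        if self.system not in ("standard", "split", "synthetic_target"):
            raise ValueError(f"unknown drive system {self.system!r}")
        if self.target_linkage not in ("X", "autosome"):
            raise ValueError(f"unknown linkage {self.target_linkage!r}")
        if self.target_functional_marker not in ("yellow_body", "egfp_eye", "none"):
            raise ValueError(
                f"unknown target marker {self.target_functional_marker!r}"
            )
        if self.system == "standard" and not self.drive_carries_cas9:
            raise ValueError("a standard drive construct must carry Cas9")
        if self.system == "split" and self.drive_carries_cas9:
            raise ValueError("a split drive construct must not carry Cas9")
        if (
            self.system == "synthetic_target"
            and self.target_functional_marker != "egfp_eye"
        ):
            raise ValueError(
                "synthetic-target systems report target function via EGFP eyes"
            )


@dataclass(frozen=True)
class DepositionState:
    """Maternal load received by an egg: Cas9 protein and/or gRNA."""

    cas9_deposited: bool = False
    grna_deposited: bool = False

    @property
    def both(self) -> bool:
        return self.cas9_deposited and self.grna_deposited


NO_DEPOSITION = DepositionState(False, False)


@dataclass(frozen=True)
class LocusGenotype:
    """Two-locus genotype (plus sex) of a single fly.

    ``target_alleles`` has length 2, or 1 for a male at an X-linked target.
    ``mosaic_flags`` parallels ``target_alleles`` and records embryo-stage
    modification history; flags default to intact.
    """

    sex: Sex
    target_alleles: tuple[TargetAllele, ...]
    support_alleles: tuple[SupportAllele, SupportAllele]
    mosaic_flags: tuple[MosaicFlag, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.mosaic_flags:
            object.__setattr__(
                self, "mosaic_flags", (MosaicFlag.INTACT,) * len(self.target_alleles)
            )
        if len(self.mosaic_flags) != len(self.target_alleles):
            raise ValueError("one mosaic flag per target allele required")
        if len(self.support_alleles) != 2:
            raise ValueError("support locus is autosomal: exactly two alleles")

    def validate(self, config: DriveSystemConfig) -> None:
        """Check allele-list lengths against sex and target linkage."""
        expected = 1 if (config.target_linkage == "X" and self.sex is MALE) else 2
        if len(self.target_alleles) != expected:
            raise ValueError(
                f"{self.sex.value} at {config.target_linkage}-linked target "
                f"requires {expected} target allele(s), got {len(self.target_alleles)}"
            )

    # -- convenience predicates -------------------------------------------
    @property
    def has_drive(self) -> bool:
        return TargetAllele.DRIVE in self.target_alleles

    @property
    def has_support_cas9(self) -> bool:
        return SupportAllele.CAS9 in self.support_alleles

    def has_genomic_cas9(self, config: DriveSystemConfig) -> bool:
        """Any genomically encoded Cas9 source: support transgene, or the
        drive construct itself when the architecture includes Cas9."""
        return self.has_support_cas9 or (config.drive_carries_cas9 and self.has_drive)

    def n_drive(self) -> int:
        return sum(a is TargetAllele.DRIVE for a in self.target_alleles)

    def n_wild(self) -> int:
        return sum(a is TargetAllele.WILD for a in self.target_alleles)

    def with_target(
        self,
        target_alleles: tuple[TargetAllele, ...],
        mosaic_flags: tuple[MosaicFlag, ...],
    ) -> "LocusGenotype":
        return replace(
            self, target_alleles=target_alleles, mosaic_flags=mosaic_flags
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Observable marker states of one fly as scored at the microscope.

    ``egfp`` is ``"na"`` for systems with no EGFP anywhere (standard drives
    at natural targets).  Mosaic categories are emitted post-classification:
    the >=50%-coverage scoring rule for drive-carrying eyes is assumed to
    have been applied already.
    """

    sex: Sex
    dsred: bool
    egfp: str  # full | mosaic | none | na
    body: str  # wild | yellow | mosaic_yellow

    EGFP_VALUES = ("full", "mosaic", "none", "na")
    BODY_VALUES = ("wild", "yellow", "mosaic_yellow")

    def __post_init__(self) -> None:
        if self.egfp not in self.EGFP_VALUES:
            raise ValueError(f"unknown egfp class {self.egfp!r}")
        if self.body not in self.BODY_VALUES:
            raise ValueError(f"unknown body class {self.body!r}")

    def key(self) -> tuple[str, bool, str, str]:
        return (self.sex.value, self.dsred, self.egfp, self.body)


def deposition_of_mother(
    mother: LocusGenotype, config: DriveSystemConfig
) -> DepositionState:
    """Maternal Cas9/gRNA load the mother places into each of her eggs.

    gRNA is deposited iff the mother carries at least one drive allele (the
    gRNA cassette rides on the drive construct); Cas9 is deposited iff she
    carries any genomic Cas9 source.  One-generation memory: deposition the
    mother received as an egg plays no role here.
    """
    if mother.sex is not FEMALE:
        raise ValueError("deposition is maternal: genotype must be female")
    return DepositionState(
        cas9_deposited=mother.has_genomic_cas9(config),
        grna_deposited=mother.has_drive,
    )


def functional_target_count(g: LocusGenotype) -> int:
    """Number of target alleles that preserve target-gene function."""
    return sum(a.functional for a in g.target_alleles)


def phenotype_of(g: LocusGenotype, config: DriveSystemConfig) -> PhenotypeRecord:
    """Map a genotype to the marker phenotypes a scorer would record.

    dsRed reports drive carriage exactly (markers are taken as perfectly
    penetrant).  For a synthetic EGFP target, eye EGFP reports the state of
    the target alleles themselves (full / mosaic / none).  For a split system
    the EGFP channel instead reports carriage of the Cas9 supporting element.
    A recessive body-colour marker shows when no functional target allele
    remains; partial embryonic cutting of an otherwise functional genotype
    scores as mosaic.
    """
    g.validate(config)
    dsred = g.has_drive
    n_func = functional_target_count(g)
    any_mosaic = any(
        f is MosaicFlag.MOSAIC_CUT and a.functional
        for a, f in zip(g.target_alleles, g.mosaic_flags)
    )

    if config.target_functional_marker == "egfp_eye":
        if n_func == 0:
            egfp = "none"
        elif any_mosaic:
            egfp = "mosaic"
        else:
            egfp = "full"
    elif config.system == "split":
        # EGFP marks the Cas9 supporting element, not the target.
        egfp = "full" if g.has_support_cas9 else "none"
    else:
        egfp = "na"

    if config.target_functional_marker == "yellow_body":
        if n_func == 0:
            body = "yellow"
        elif any_mosaic:
            body = "mosaic_yellow"
        else:
            body = "wild"
    else:
        body = "wild"

    return PhenotypeRecord(sex=g.sex, dsred=dsred, egfp=egfp, body=body)
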