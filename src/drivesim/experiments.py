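"""Catalog of cross designs and the parameter-recovery harness.

The catalog enumerates the cross setups used to characterise the drive
systems:

* ``D1-*`` — synthetic-target drives: drive/EGFP heterozygote crossed to an
  EGFP homozygote, through mothers (sites B, E, Y) and fathers (autosomal
  sites B, E only; site Y is X-linked, so males are hemizygous and male
  conversion is undefined).
* ``D2`` — full split drive: drive/+ ; Cas9/+ female crossed to w1118 males.
* ``D3a``/``D3b`` — Mendelian controls where the mother deposits gRNA
  without Cas9, or Cas9 without gRNA.
* ``D4`` — Cas9-carryover cross: mosaic-yellow females that inherited the
  drive (but no Cas9 gene) from a Cas9-bearing mother, crossed to w1118.
* ``D5`` — paternal-drive carryover cross: drive-het females whose drive
  allele came from the father, with maternally deposited Cas9 only.
* ``D6`` — standard drive targeting *yellow*: het female x w1118.

``TABLE1_PARAMS`` carries the published per-drive performance rates used to
parameterise reproduction runs; ``run_recovery`` and ``table1_reproduction``
check that the estimators recover whatever the simulator was fed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .estimate import EstimateWithError, conversion_efficiency, get_estimator
from .genetics import (
    FEMALE,
    MALE,
    DepositionState,
    DriveSystemConfig,
    LocusGenotype,
    NO_DEPOSITION,
    Sex,
    SupportAllele,
    TargetAllele,
)
from .simulate import CountTable, CrossDesign, DriveParams, simulate_experiment

__all__ = [
    "design_catalog",
    "get_design",
    "RecoveryReport",
    "run_recovery",
    "mendelian_check",
    "per_fly_conversion",
    "TABLE1_PARAMS",
    "table1_reproduction",
]

_W = TargetAllele.WILD
_D = TargetAllele.DRIVE
_CAS = SupportAllele.CAS9
_ABS = SupportAllele.ABSENT

SPLIT_X = DriveSystemConfig(
    system="split", target_linkage="X",
    drive_carries_cas9=False, target_functional_marker="yellow_body",
)
STANDARD_X = DriveSystemConfig(
    system="standard", target_linkage="X",
    drive_carries_cas9=True, target_functional_marker="yellow_body",
)
STANDARD_AUTO = DriveSystemConfig(
    system="standard", target_linkage="autosome",
    drive_carries_cas9=True, target_functional_marker="yellow_body",
)
SYNTH_AUTO = DriveSystemConfig(
    system="synthetic_target", target_linkage="autosome",
    drive_carries_cas9=True, target_functional_marker="egfp_eye",
)
SYNTH_X = DriveSystemConfig(
    system="synthetic_target", target_linkage="X",
    drive_carries_cas9=True, target_functional_marker="egfp_eye",
)


def _fly(
    sex: Sex,
    targets: tuple[TargetAllele, ...],
    support: tuple[SupportAllele, SupportAllele] = (_ABS, _ABS),
) -> LocusGenotype:
    return LocusGenotype(sex=sex, target_alleles=targets, support_alleles=support)


def _synth_het_design(code: str, config: DriveSystemConfig, het_sex: Sex) -> CrossDesign:
    """Drive/EGFP heterozygote x EGFP homozygote for a synthetic target."""
    if het_sex is FEMALE:
        mother = _fly(FEMALE, (_D, _W))
        father = _fly(MALE, (_W,) if config.target_linkage == "X" else (_W, _W))
        parent = "female"
    else:
        mother = _fly(FEMALE, (_W, _W))
        father = _fly(MALE, (_D, _W))
        parent = "male"
    return CrossDesign(
        name=code,
        description=f"drive/EGFP het {parent} x EGFP homozygote",
        mother=mother,
        father=father,
        config=config,
        conversion_denominator="all",
        # embryo readout only meaningful when the het parent is the mother
        embryo_readout="egfp" if het_sex is FEMALE else None,
    )


def design_catalog() -> dict[str, CrossDesign]:
    """All cross designs, keyed by their short code."""
    designs = [
        _synth_het_design("D1-siteB-female", SYNTH_AUTO, FEMALE),
        _synth_het_design("D1-siteB-male", SYNTH_AUTO, MALE),
        _synth_het_design("D1-siteE-female", SYNTH_AUTO, FEMALE),
        _synth_het_design("D1-siteE-male", SYNTH_AUTO, MALE),
        _synth_het_design("D1-siteY-female", SYNTH_X, FEMALE),
        CrossDesign(
            name="D2",
            description="split drive/+ ; Cas9/+ female x w1118 male",
            mother=_fly(FEMALE, (_D, _W), (_CAS, _ABS)),
            father=_fly(MALE, (_W,)),
            config=SPLIT_X,
            conversion_denominator="all",
            embryo_readout="yellow",
        ),
        CrossDesign(
            name="D3a",
            description="drive-het female (no Cas9) x Cas9-homozygous male",
            mother=_fly(FEMALE, (_D, _W)),
            father=_fly(MALE, (_W,), (_CAS, _CAS)),
            config=SPLIT_X,
            conversion_denominator="all",
        ),
        CrossDesign(
            name="D3b",
            description="Cas9-homozygous female (no drive) x drive male (no Cas9)",
            mother=_fly(FEMALE, (_W, _W), (_CAS, _CAS)),
            father=_fly(MALE, (_D,)),
            config=SPLIT_X,
            conversion_denominator="all",
        ),
        CrossDesign(
            name="D4",
            description=(
                "mosaic-yellow drive-het female, no genomic Cas9, "
                "maternal-Cas9 carryover, x w1118 male"
            ),
            mother=_fly(FEMALE, (_D, _W)),
            father=_fly(MALE, (_W,)),
            config=SPLIT_X,
            mother_deposition_received=DepositionState(True, True),
            conversion_denominator="all",
            germline_r2_sons=True,
        ),
        CrossDesign(
            name="D5",
            description=(
                "drive-het female (paternal drive allele), no genomic Cas9, "
                "maternally deposited Cas9 only, x w1118 male"
            ),
            mother=_fly(FEMALE, (_D, _W)),
            father=_fly(MALE, (_W,)),
            config=SPLIT_X,
            mother_deposition_received=DepositionState(True, False),
            conversion_denominator="all",
            germline_r2_sons=True,
        ),
        CrossDesign(
            name="D6",
            description="standard yellow-drive het female x w1118 male",
            mother=_fly(FEMALE, (_D, _W)),
            father=_fly(MALE, (_W,)),
            config=STANDARD_X,
            conversion_denominator="all",
            embryo_readout="yellow",
        ),
    ]
    return {d.name: d for d in designs}


def get_design(name: str) -> CrossDesign:
    catalog = design_catalog()
    try:
        return catalog[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; choose from {sorted(catalog)}"
        ) from None


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a simulate-then-estimate parameter-recovery run."""

    design: str
    parameter: str
    true_value: float
    mean_estimate: float
    empirical_se: float
    replicates: int
    seed: int

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.true_value


def run_recovery(
    design: CrossDesign,
    true_params: DriveParams,
    estimator: str,
    n_crosses: int,
    n_per_cross: int,
    replicates: int,
    seed: int,
    true_value: float | None = None,
) -> RecoveryReport:
    """Simulate replicate experiments and estimate back a known parameter.

    ``true_value`` defaults to the simulation parameter the estimator
    targets under the standard protocols (conversion -> the het parent's
    ``c``; embryo readouts -> ``e_cut``; son readout -> the effective
    germline resistance rate).  ``empirical_se`` is the standard error of
    the replicate mean.
    """
    fn = get_estimator(estimator)
    if true_value is None:
        true_value = _default_truth(design, true_params, estimator)
    points = []
    for rep in range(replicates):
        table = simulate_experiment(
            design, true_params, n_crosses, n_per_cross, seed=_subseed(seed, rep)
        )
        if estimator in ("conversion_efficiency", "drive_inheritance_rate"):
            est: EstimateWithError = fn(table, design.conversion_denominator)
        elif estimator == "embryo_r2_rate_egfp":
            est = fn(table, daughters_only=design.config.target_linkage == "X")
        else:
            est = fn(table)
        points.append(est.point)
    arr = np.asarray(points)
    return RecoveryReport(
        design=design.name,
        parameter=estimator,
        true_value=float(true_value),
        mean_estimate=float(arr.mean()),
        empirical_se=float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
        replicates=replicates,
        seed=seed,
    )


def _subseed(seed: int, rep: int) -> int:
    # distinct, reproducible, and small enough for np.default_rng lists
    return (int(seed) * 100_003 + rep) % (2**31 - 1)


def _uses_carryover(design: CrossDesign) -> bool:
    return (
        not design.mother.has_genomic_cas9(design.config)
        and design.mother_deposition_received.cas9_deposited
    )


def _default_truth(
    design: CrossDesign, params: DriveParams, estimator: str
) -> float:
    carry = _uses_carryover(design)
    het_parent_is_mother = design.mother.n_drive() == 1 and design.mother.n_wild() == 1
    if estimator == "conversion_efficiency":
        if carry:
            return params.p_active * params.c_carry
        return params.c_f if het_parent_is_mother else params.c_m
    if estimator == "drive_inheritance_rate":
        c = (
            params.p_active * params.c_carry
            if carry
            else (params.c_f if het_parent_is_mother else params.c_m)
        )
        return (1 + c) / 2
    if estimator in ("embryo_r2_rate_yellow", "embryo_r2_rate_egfp"):
        return params.e_cut * (1 - params.r1_fraction)
    if estimator == "germline_r2_rate_sons":
        r = params.p_active * params.r_carry if carry else params.r_f
        return r * (1 - params.r1_fraction)
    raise KeyError(f"no default truth for estimator {estimator!r}")


def mendelian_check(t: CountTable, alpha: float = 0.01) -> tuple[bool, float]:
    """Exact binomial test of the dsRed fraction against 1:1 inheritance.

    Returns ``(passes, p_value)``: the cross is consistent with Mendelian
    transmission when the two-sided p-value is not below ``alpha``.
    """
    n = t.total
    if n == 0:
        raise ValueError("mendelian_check needs at least one offspring")
    k = t.count_where(dsred=True)
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return bool(p >= alpha), float(p)


def per_fly_conversion(
    design: CrossDesign,
    params: DriveParams,
    n_females: int,
    n_per_female: int,
    seed: int,
) -> list[float]:
    """Per-mother conversion-efficiency estimates (one cross per female).

    Exposes the between-fly distribution that pooling hides — e.g. the
    all-or-nothing pattern of Cas9 carryover, where most carryover-exposed
    females convert at ``c_carry`` and a minority not at all.
    """
    tables = simulate_experiment(
        design, params, n_females, n_per_female, seed, return_per_cross=True
    )
    return [
        conversion_efficiency(t, design.conversion_denominator).point
        for t in tables
    ]


# Published per-drive performance rates: female conversion, male conversion
# (None where the target is X-linked and het fathers cannot exist), and the
# embryo r2 rate, expressed as the simulator parameters that encode them.
TABLE1_PARAMS: dict[str, dict] = {
    "EGFP site B": dict(c_f=0.52, c_m=0.32, e_cut=0.88, design="D1-siteB"),
    "EGFP site E": dict(c_f=0.54, c_m=0.46, e_cut=0.91, design="D1-siteE"),
    "EGFP site Y": dict(c_f=0.53, c_m=None, e_cut=0.80, design="D1-siteY"),
    "cinnabar": dict(c_f=0.54, c_m=0.39, e_cut=1.00, design="standard-auto"),
    "white": dict(c_f=0.59, c_m=None, e_cut=0.77, design="standard-X"),
    "Split-yellow": dict(c_f=0.74, c_m=None, e_cut=0.74, design="D2"),
    "yellow": dict(c_f=0.63, c_m=None, e_cut=0.20, design="D6"),
}


def _drive_designs(spec: str) -> dict[str, CrossDesign]:
    """Female- and male-parent het crosses realising one drive's rows."""
    catalog = design_catalog()
    if spec in ("D1-siteB", "D1-siteE", "D1-siteY"):
        out = {"female": catalog[f"{spec}-female"]}
        if f"{spec}-male" in catalog:
            out["male"] = catalog[f"{spec}-male"]
        return out
    if spec == "D2":
        return {"female": catalog["D2"]}
    if spec == "D6":
        return {"female": catalog["D6"]}
    if spec == "standard-X":
        return {"female": replace(catalog["D6"], name="standard-X-female")}
    if spec == "standard-auto":
        mother = _fly(FEMALE, (_D, _W))
        father_het = _fly(MALE, (_D, _W))
        father_wt = _fly(MALE, (_W, _W))
        mother_wt = _fly(FEMALE, (_W, _W))
        return {
            "female": CrossDesign(
                name="standard-auto-female",
                description="autosomal standard-drive het female x wild-type male",
                mother=mother, father=father_wt, config=STANDARD_AUTO,
                conversion_denominator="all", embryo_readout="yellow",
            ),
            "male": CrossDesign(
                name="standard-auto-male",
                description="autosomal standard-drive het male x wild-type female",
                mother=mother_wt, father=father_het, config=STANDARD_AUTO,
                conversion_denominator="all",
            ),
        }
    raise KeyError(f"unknown drive design spec {spec!r}")


def table1_reproduction(
    params_per_drive: dict[str, dict] | None = None,
    seed: int = 1,
    n_crosses: int = 40,
    n_per_cross: int = 100,
    replicates: int = 20,
):
    """Recover every published per-drive rate from fresh simulations.

    Returns a DataFrame with one row per drive and recovered male/female
    conversion efficiencies and embryo r2 rates (NaN where the quantity is
    undefined by construction, e.g. male conversion at X-linked targets).
    """
    import pandas as pd

    if params_per_drive is None:
        params_per_drive = TABLE1_PARAMS
    rows = []
    for i, (drive, spec) in enumerate(params_per_drive.items()):
        designs = _drive_designs(spec["design"])
        params = DriveParams(
            c_f=spec["c_f"],
            c_m=spec["c_m"] if spec["c_m"] is not None else 0.0,
            e_cut=spec["e_cut"],
            r_f=0.0, r_m=0.0, r1_fraction=0.0, e_mosaic=0.0,
        )
        row: dict = {"drive": drive}
        for sex_label, conv_key, truth in (
            ("female", "female_conversion", spec["c_f"]),
            ("male", "male_conversion", spec["c_m"]),
        ):
            if truth is None or sex_label not in designs:
                row[conv_key] = float("nan")
                continue
            rep = run_recovery(
                designs[sex_label], params, "conversion_efficiency",
                n_crosses, n_per_cross, replicates,
                seed=_subseed(seed, 1000 + 10 * i) + (0 if sex_label == "female" else 1),
            )
            row[conv_key] = rep.mean_estimate
            row[f"{conv_key}_se"] = rep.empirical_se
        female = designs["female"]
        if female.embryo_readout is not None:
            rep = run_recovery(
                female, params, f"embryo_r2_rate_{female.embryo_readout}",
                n_crosses, n_per_cross, replicates,
                seed=_subseed(seed, 2000 + 10 * i),
            )
            row["embryo_r2_rate"] = rep.mean_estimate
            row["embryo_r2_rate_se"] = rep.empirical_se
        rows.append(row)
    return pd.DataFrame(rows)
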