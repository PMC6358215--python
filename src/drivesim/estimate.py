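"""Drive-performance estimators over phenotype count tables.

All estimators consume a :class:`~drivesim.simulate.CountTable` — tallies of
(sex, dsRed, EGFP, body-colour) classes pooled over the crosses of one
design — and return a point estimate with a binomial standard error and a
Wilson 95% confidence interval.

The key quantities:

* *drive inheritance rate* ``p`` — fraction of scoreable offspring carrying
  dsRed (a drive allele).
* *drive conversion efficiency* ``c = 2p - 1`` — fraction of the
  heterozygous parent's wild-type (or synthetic-target) alleles converted to
  drive copies in the germline.  Mendelian transmission gives ``c = 0``;
  negative values signal sub-Mendelian transmission and are reported as-is.
* *embryo r2 resistance rate* — fraction of paternal target alleles
  disrupted in the early embryo, read among dsRed offspring either from a
  recessive body-colour marker (full yellow among dsRed daughters) or from
  loss of the synthetic EGFP target (non-EGFP among dsRed offspring).
* *germline r2 rate from sons* — at an X-linked target with no embryo
  cutting, yellow non-dsRed sons carry exactly the maternal resistance
  gametes, so twice their frequency estimates the per-wild-allele germline
  resistance rate.

A statsmodels-style front end is provided: build a
:class:`CrossExperimentModel` from a count table plus its design, call
``fit()``, and read estimates off the returned :class:`DrivePerformanceResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .simulate import CountTable, CrossDesign

__all__ = [
    "EstimateWithError",
    "ContingencyTable2x2",
    "wilson_ci",
    "drive_inheritance_rate",
    "conversion_efficiency",
    "embryo_r2_rate_yellow",
    "embryo_r2_rate_egfp",
    "germline_r2_rate_sons",
    "fisher_exact_2x2",
    "jackknife_se",
    "CrossExperimentModel",
    "DrivePerformanceResults",
]


class UndefinedEstimateError(ValueError):
    """Raised when an estimator's denominator is empty."""


@dataclass(frozen=True)
class EstimateWithError:
    """A proportion or efficiency with its uncertainty.

    ``point`` is a fraction in [0, 1] for proportions, or an efficiency in
    [-1, 1] on the ``2p - 1`` scale.  ``se`` is the binomial standard error
    on the same scale; ``ci_low``/``ci_high`` bound the Wilson 95% interval.
    ``n`` is the informative denominator.
    """

    point: float
    se: float
    n: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("point estimate must lie inside its interval")

    @property
    def percent(self) -> float:
        return 100.0 * self.point

    def __str__(self) -> str:
        return f"{self.percent:.1f} ± {100 * self.se:.1f}% (n={self.n})"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts [[a, b], [c, d]] of a 2x2 contingency table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise UndefinedEstimateError("Wilson interval needs n >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    # boundary cases are exact analytically; clamp float error
    low = 0.0 if successes == 0 else max(0.0, float(centre - half))
    high = 1.0 if successes == n else min(1.0, float(centre + half))
    return low, high


def _proportion_estimate(successes: int, n: int, what: str) -> EstimateWithError:
    if n < 1:
        raise UndefinedEstimateError(f"{what}: empty denominator")
    p = successes / n
    se = math.sqrt(p * (1 - p) / n)
    low, high = wilson_ci(successes, n)
    return EstimateWithError(point=p, se=se, n=n, ci_low=low, ci_high=high)


def drive_inheritance_rate(
    t: CountTable, denominator: str = "all"
) -> EstimateWithError:
    """Fraction of scoreable offspring carrying dsRed.

    ``denominator="all"`` uses every offspring (maternal transmission, or
    autosomal targets through either parent); ``"daughters"`` restricts to
    daughters, the only recipients of a paternal X-linked target allele.
    """
    if denominator == "all":
        n = t.total
        k = t.count_where(dsred=True)
    elif denominator == "daughters":
        n = t.count_where(sex="female")
        k = t.count_where(sex="female", dsred=True)
    else:
        raise ValueError("denominator must be 'all' or 'daughters'")
    return _proportion_estimate(k, n, "drive inheritance rate")


def conversion_efficiency(
    t: CountTable, denominator: str = "all"
) -> EstimateWithError:
    """Germline drive conversion efficiency ``2p - 1``.

    No clamping: estimates below zero are reported as-is, signalling
    sub-Mendelian transmission rather than being hidden.
    """
    p = drive_inheritance_rate(t, denominator)
    return EstimateWithError(
        point=2 * p.point - 1,
        se=2 * p.se,
        n=p.n,
        ci_low=2 * p.ci_low - 1,
        ci_high=2 * p.ci_high - 1,
    )


def embryo_r2_rate_yellow(t: CountTable) -> EstimateWithError:
    """Early-embryo r2 rate from a recessive body-colour readout.

    In a drive-het mother (depositing both Cas9 and gRNA) crossed to a
    wild-type-target father, a dsRed daughter's maternal allele is the
    drive, so she is fully yellow iff her paternal wild-type allele was
    disrupted in the embryo.  Mosaic-yellow daughters keep a functional
    allele and stay out of the numerator.
    """
    n = t.count_where(sex="female", dsred=True)
    k = t.count_where(sex="female", dsred=True, body="yellow")
    return _proportion_estimate(k, n, "embryo r2 rate (yellow)")


def embryo_r2_rate_egfp(
    t: CountTable, daughters_only: bool = False
) -> EstimateWithError:
    """Early-embryo r2 rate from loss of the synthetic EGFP target.

    Among dsRed progeny of a drive/EGFP-het mother crossed to an EGFP
    homozygote, the maternal allele is the drive and absence of any EGFP
    signal means the paternal target allele was disrupted in the embryo.
    Mosaic-EGFP offspring count as retaining the allele.  At an X-linked
    target pass ``daughters_only=True``: sons receive no paternal allele,
    so a dsRed son lacks EGFP regardless of embryo activity and would
    inflate the rate.
    """
    sex = "female" if daughters_only else None
    n = t.count_where(sex=sex, dsred=True)
    k = t.count_where(sex=sex, dsred=True, egfp="none")
    return _proportion_estimate(k, n, "embryo r2 rate (EGFP)")


def germline_r2_rate_sons(t: CountTable) -> EstimateWithError:
    """Germline r2 formation rate per wild-type allele, from sons.

    Valid only when no embryo cutting occurs in the offspring generation
    (mother deposits no Cas9).  A son's single X-linked target allele is a
    uniform draw from the mother's two germline products, so yellow
    non-dsRed sons (maternal r2 gametes) occur at half the per-allele rate;
    the estimate doubles their frequency.  The standard error and interval
    are doubled along with the point.
    """
    n = t.count_where(sex="male")
    k = t.count_where(sex="male", dsred=False, body="yellow")
    half = _proportion_estimate(k, n, "germline r2 rate (sons)")
    return EstimateWithError(
        point=2 * half.point,
        se=2 * half.se,
        n=half.n,
        ci_low=2 * half.ci_low,
        ci_high=min(2 * half.ci_high, 2.0),
    )


_TIE_RTOL = 1e-7


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities that do not exceed the observed table's probability
    (within a relative tie tolerance of 1e-7).  Returns 1.0 for an empty
    table by convention.
    """
    n = t.total
    if n == 0:
        return 1.0
    row1 = t.a + t.b
    col1 = t.a + t.c
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(k, n, col1, row1)
    p_obs = stats.hypergeom.pmf(t.a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    if p >= 1.0 - 1e-12:  # full mass: exact 1 up to float summation error
        return 1.0
    return p


def jackknife_se(
    per_cross: Sequence[CountTable],
    estimator: Callable[[CountTable], EstimateWithError],
) -> float:
    """Delete-one-cross jackknife standard error of a pooled estimator.

    A secondary uncertainty that reflects between-cross overdispersion the
    pooled binomial SE cannot see.  Crosses whose leave-one-out pool leaves
    the estimator undefined are skipped.
    """
    if len(per_cross) < 2:
        raise ValueError("jackknife needs at least two crosses")
    pooled = per_cross[0]
    for t in per_cross[1:]:
        pooled = pooled.merged(t)
    loo = []
    for i in range(len(per_cross)):
        rest = CountTable(name=pooled.name, counts=dict(pooled.counts))
        for key, cnt in per_cross[i].counts.items():
            rest.counts[key] = rest.counts[key] - cnt
        try:
            loo.append(estimator(rest).point)
        except UndefinedEstimateError:
            continue
    m = len(loo)
    if m < 2:
        raise UndefinedEstimateError("too few informative crosses for jackknife")
    loo_arr = np.asarray(loo)
    return float(math.sqrt((m - 1) / m * ((loo_arr - loo_arr.mean()) ** 2).sum()))


_ESTIMATORS: dict[str, Callable[..., EstimateWithError]] = {
    "drive_inheritance_rate": drive_inheritance_rate,
    "conversion_efficiency": conversion_efficiency,
    "embryo_r2_rate_yellow": embryo_r2_rate_yellow,
    "embryo_r2_rate_egfp": embryo_r2_rate_egfp,
    "germline_r2_rate_sons": germline_r2_rate_sons,
}


def get_estimator(name: str) -> Callable[..., EstimateWithError]:
    try:
        return _ESTIMATORS[name]
    except KeyError:
        raise KeyError(
            f"unknown estimator {name!r}; choose from {sorted(_ESTIMATORS)}"
        ) from None


class CrossExperimentModel:
    """Drive-performance model for one cross design's phenotype counts.

    Parameters
    ----------
    counts
        Pooled phenotype tallies of the experiment.
    design
        The :class:`~drivesim.simulate.CrossDesign` that produced them; its
        estimator-protocol fields decide which parameters are identifiable
        (denominator convention, embryo readout channel, son-based germline
        r2 readout).
    per_cross
        Optional per-cross tables enabling the jackknife SE diagnostic.
    """

    def __init__(
        self,
        counts: CountTable,
        design: CrossDesign,
        per_cross: Sequence[CountTable] | None = None,
    ) -> None:
        self.counts = counts
        self.design = design
        self.per_cross = list(per_cross) if per_cross is not None else None

    @classmethod
    def from_dataframe(cls, df, design: CrossDesign) -> "CrossExperimentModel":
        """Build from a DataFrame with columns sex, dsred, egfp, body, count."""
        from .io import count_table_from_frame

        return cls(count_table_from_frame(df, name=design.name), design)

    def fit(self) -> "DrivePerformanceResults":
        """Estimate every parameter the design identifies."""
        denom = self.design.conversion_denominator
        estimates: dict[str, EstimateWithError] = {
            "drive_inheritance_rate": drive_inheritance_rate(self.counts, denom),
            "conversion_efficiency": conversion_efficiency(self.counts, denom),
        }
        x_linked = self.design.config.target_linkage == "X"
        if self.design.embryo_readout == "yellow":
            estimates["embryo_r2_rate"] = embryo_r2_rate_yellow(self.counts)
        elif self.design.embryo_readout == "egfp":
            estimates["embryo_r2_rate"] = embryo_r2_rate_egfp(
                self.counts, daughters_only=x_linked
            )
        if self.design.germline_r2_sons:
            estimates["germline_r2_rate"] = germline_r2_rate_sons(self.counts)

        jack: dict[str, float] = {}
        if self.per_cross is not None and len(self.per_cross) >= 2:
            protocol: dict[str, Callable[[CountTable], EstimateWithError]] = {
                "conversion_efficiency": lambda t: conversion_efficiency(t, denom),
            }
            if self.design.embryo_readout == "yellow":
                protocol["embryo_r2_rate"] = embryo_r2_rate_yellow
            elif self.design.embryo_readout == "egfp":
                protocol["embryo_r2_rate"] = lambda t: embryo_r2_rate_egfp(
                    t, daughters_only=x_linked
                )
            if self.design.germline_r2_sons:
                protocol["germline_r2_rate"] = germline_r2_rate_sons
            for name, fn in protocol.items():
                try:
                    jack[name] = jackknife_se(self.per_cross, fn)
                except (UndefinedEstimateError, ValueError):
                    continue
        return DrivePerformanceResults(self, estimates, jack)


class DrivePerformanceResults:
    """Fitted drive-performance parameters with uncertainties."""

    def __init__(
        self,
        model: CrossExperimentModel,
        estimates: dict[str, EstimateWithError],
        jackknife: dict[str, float],
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.jackknife = jackknife

    def __getitem__(self, name: str) -> EstimateWithError:
        return self.estimates[name]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, e in self.estimates.items():
            rows.append(
                {
                    "parameter": name,
                    "point": e.point,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n": e.n,
                    "jackknife_se": self.jackknife.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        design = self.model.design
        lines = [
            "Drive performance estimates",
            "=" * 64,
            f"design: {design.name} — {design.description}",
            f"offspring scored: {self.model.counts.total}"
            f" (crosses pooled: {self.model.counts.n_crosses})",
            "-" * 64,
            f"{'parameter':<26}{'estimate':>10}{'SE':>8}{'95% CI':>18}",
        ]
        for name, e in self.estimates.items():
            ci = f"[{100 * e.ci_low:5.1f}, {100 * e.ci_high:5.1f}]"
            lines.append(
                f"{name:<26}{e.percent:>9.1f}%{100 * e.se:>7.1f}%{ci:>18}"
            )
        if self.jackknife:
            lines.append("-" * 64)
            for name, se in self.jackknife.items():
                lines.append(f"jackknife SE ({name}): {100 * se:.2f}%")
        lines.append("=" * 64)
        return "\n".join(lines)
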