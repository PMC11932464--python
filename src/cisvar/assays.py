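"""Quantification of perturbation read-outs.

Two desk-side calculations used downstream of enhancer perturbation
experiments:

* ``ddct_fold_change`` — the classical 2^-ddCt relative-expression model for
  qPCR: per condition, dCt = Ct(target) - Ct(reference); ddCt is the treated
  minus control dCt, and the fold change is 2^-ddCt (amplification efficiency
  fixed at 2).  A two-sided t-test on the per-replicate dCt values supplies
  the p-value.
* ``reporter_normalize`` — dual-luciferase normalisation: firefly counts are
  divided by the co-transfected renilla control per well, and construct means
  are expressed relative to a designated control construct.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "FoldChangeResult",
    "ReporterRecord",
    "ddct_fold_change",
    "reporter_normalize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: threshold cycle for a gene in a sample/condition."""

    sample_id: str
    condition: str
    gene: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be finite and positive, got {self.ct}")


@dataclass(frozen=True)
class FoldChangeResult:
    fold_change: float
    delta_delta_ct: float
    p_value: float | None
    n_treated: int
    n_control: int

    def __post_init__(self) -> None:
        expected = 2.0 ** (-self.delta_delta_ct)
        if not math.isclose(self.fold_change, expected, rel_tol=1e-12):
            raise ValueError("fold_change must equal 2^-ddCt")


@dataclass(frozen=True)
class ReporterRecord:
    construct: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValueError("firefly light units must be nonnegative")
        if self.renilla <= 0:
            raise ValueError("renilla light units must be positive (zero renilla is unusable)")


def _cts(
    table: Iterable[CtRecord], condition: str, gene: str
) -> dict[int, list[float]]:
    out: dict[int, list[float]] = {}
    for rec in table:
        if rec.condition == condition and rec.gene == gene:
            out.setdefault(rec.replicate, []).append(rec.ct)
    return out


def _delta_cts(
    table: Sequence[CtRecord], condition: str, target_gene: str, reference_gene: str
) -> list[float]:
    """Per-replicate dCt values for one condition.

    When replicate indices align between target and reference the pairing is
    used; otherwise each gene is averaged and a single condition-mean dCt is
    returned (with a logged note).
    """
    target = _cts(table, condition, target_gene)
    reference = _cts(table, condition, reference_gene)
    if not target:
        raise ValueError(f"no Ct values for ({condition!r}, {target_gene!r})")
    if not reference:
        raise ValueError(f"no Ct values for ({condition!r}, {reference_gene!r})")
    if set(target) == set(reference):
        return [
            float(np.mean(target[r])) - float(np.mean(reference[r]))
            for r in sorted(target)
        ]
    logger.info(
        "replicate indices differ between %s and %s in condition %s; "
        "falling back to condition-mean dCt",
        target_gene,
        reference_gene,
        condition,
    )
    t_mean = float(np.mean([c for cs in target.values() for c in cs]))
    r_mean = float(np.mean([c for cs in reference.values() for c in cs]))
    return [t_mean - r_mean]


def ddct_fold_change(
    table: Sequence[CtRecord],
    target_gene: str,
    reference_gene: str,
    treated_condition: str,
    control_condition: str,
    equal_var: bool = False,
) -> FoldChangeResult:
    """Relative expression of the target gene in treated vs control.

    The p-value is a two-sided t-test (Welch by default) comparing the
    per-replicate dCt values between conditions; it is ``None`` when either
    condition has a single replicate.
    """
    d_treated = _delta_cts(table, treated_condition, target_gene, reference_gene)
    d_control = _delta_cts(table, control_condition, target_gene, reference_gene)
    ddct = float(np.mean(d_treated) - np.mean(d_control))
    fc = 2.0 ** (-ddct)
    p_value: float | None = None
    degenerate = np.ptp(d_treated) == 0 and np.ptp(d_control) == 0
    if len(d_treated) >= 2 and len(d_control) >= 2 and not degenerate:
        p_value = float(
            stats.ttest_ind(d_treated, d_control, equal_var=equal_var).pvalue
        )
    return FoldChangeResult(
        fold_change=fc,
        delta_delta_ct=ddct,
        p_value=p_value,
        n_treated=len(d_treated),
        n_control=len(d_control),
    )


def reporter_normalize(
    records: Sequence[ReporterRecord], control_construct: str
) -> dict[str, float]:
    """Per-construct fold change of the firefly/renilla ratio over control."""
    ratios: dict[str, list[float]] = {}
    for rec in records:
        ratios.setdefault(rec.construct, []).append(rec.firefly / rec.renilla)
    if control_construct not in ratios:
        raise ValueError(f"control construct {control_construct!r} has no records")
    control_mean = float(np.mean(ratios[control_construct]))
    return {
        construct: float(np.mean(vals)) / control_mean
        for construct, vals in ratios.items()
    }
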