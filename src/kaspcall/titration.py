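"""Limit-of-detection analysis for mutant-allele titration series.

Genomic DNA of a homozygous-wildtype line is mixed with DNA of a
heterozygous edited clone so that the mutant allele is present at a known
nominal percentage (0, 1, 2.5, 5, 10, 15, 20, 25, 50), each level run in
replicate on the KASP platform.  Each nonzero level's measured
mutant-allele fractions are compared with the 0% (homozygous wildtype)
replicates by a two-sided two-sample Student's t-test; the limit of
detection (LOD) is the smallest nominal level significant at a stringent
alpha (0.001 by default).  The LOD is a threshold crossing over the
discrete tested levels, not a fitted detection curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plate_model import ConfigurationError, ValidationError, well_sequence

#: The nine mixture levels of the reference sensitivity assay (% mutant allele).
DEFAULT_LEVELS = (0.0, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 50.0)

#: Floor on the pooled variance so that noise-free fixtures with a real
#: mean difference are called significant rather than dividing by zero.
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class TitrationLevel:
    """One nominal mixture level with its replicate fraction measurements."""

    nominal_percent_mut: float
    frac_mut: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.nominal_percent_mut <= 100.0:
            raise ValidationError(
                f"nominal level {self.nominal_percent_mut} outside [0, 100]"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.frac_mut):
            raise ValidationError(
                f"level {self.nominal_percent_mut}: fractions outside [0, 1]"
            )

    @property
    def n_replicates(self) -> int:
        return len(self.frac_mut)


@dataclass(frozen=True)
class LevelResult:
    nominal_percent_mut: float
    mean_frac_mut: float
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class TitrationResult:
    """Per-level statistics and the limit of detection.

    ``lod_percent`` is None when no tested level reaches significance
    ("not detected").
    """

    levels: tuple[LevelResult, ...]
    lod_percent: float | None
    alpha: float

    @property
    def detected(self) -> bool:
        return self.lod_percent is not None


def two_sample_t(sample: Sequence[float], control: Sequence[float],
                 welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test, pooled-variance by default.

    Hand-evaluated textbook formula so that the variance floor (needed for
    noise-free inputs) can be applied; agrees with
    ``scipy.stats.ttest_ind`` away from the floor.  Returns ``(t, p)``;
    degenerate variance with equal means reports ``(0, 1)``.
    """
    a = np.asarray(sample, dtype=float)
    c = np.asarray(control, dtype=float)
    n1, n0 = len(a), len(c)
    if n1 < 2 or n0 < 2:
        raise ConfigurationError("each group needs >= 2 replicates")
    v1, v0 = a.var(ddof=1), c.var(ddof=1)
    diff = a.mean() - c.mean()
    if welch:
        se2 = max(v1 / n1 + v0 / n0, VARIANCE_FLOOR)
        df = se2 ** 2 / max(
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1),
            VARIANCE_FLOOR ** 2,
        )
        df = min(df, n1 + n0 - 2)
    else:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se2 = max(sp2, VARIANCE_FLOOR) * (1.0 / n1 + 1.0 / n0)
        df = n1 + n0 - 2
    if diff == 0.0:
        return 0.0, 1.0
    t = diff / math.sqrt(se2)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), p


def lod_analysis(levels: Iterable[TitrationLevel], alpha: float = 0.001,
                 welch: bool = False) -> TitrationResult:
    """Test each nonzero level against the 0% control; report the LOD.

    Levels are reported in ascending nominal order; p-values are reported
    as computed, with no monotonicity enforcement and no multiple-testing
    correction (a single stringent alpha plays that role).
    """
    levels = sorted(levels, key=lambda lv: lv.nominal_percent_mut)
    control = next((lv for lv in levels if lv.nominal_percent_mut == 0.0), None)
    if control is None:
        raise ConfigurationError("titration series lacks the 0% control level")
    if control.n_replicates < 2:
        raise ConfigurationError("0% control needs >= 2 replicates")
    results = [LevelResult(0.0, float(np.mean(control.frac_mut)), 0.0, 1.0)]
    lod: float | None = None
    for lv in levels:
        if lv.nominal_percent_mut == 0.0:
            continue
        t, p = two_sample_t(lv.frac_mut, control.frac_mut, welch=welch)
        results.append(LevelResult(
            lv.nominal_percent_mut, float(np.mean(lv.frac_mut)), t, p))
        if p < alpha and lod is None:
            lod = lv.nominal_percent_mut
    return TitrationResult(levels=tuple(results), lod_percent=lod, alpha=alpha)


def mixture_series_design(percent_levels: Sequence[float] = DEFAULT_LEVELS,
                          replicates: int = 4) -> pd.DataFrame:
    """Deterministic level x replicate to well assignment.

    Returns a table with columns ``plate_id, well, sample_id,
    nominal_percent_mut, replicate`` (row-major well order), round-trippable
    through the plate CSV dialect once fluorescence is attached.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if 0.0 not in [float(p) for p in percent_levels]:
        raise ValidationError("titration design must include the 0% control")
    for p in percent_levels:
        if not 0.0 <= float(p) <= 100.0:
            raise ValidationError(f"level {p} outside [0, 100]")
    rows = []
    wells = well_sequence(len(percent_levels) * replicates)
    for level in percent_levels:
        for rep in range(1, replicates + 1):
            plate_id, well = next(wells)
            rows.append({
                "plate_id": plate_id,
                "well": well,
                "sample_id": f"mix{float(level):g}pct_r{rep}",
                "nominal_percent_mut": float(level),
                "replicate": rep,
            })
    return pd.DataFrame(rows)
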