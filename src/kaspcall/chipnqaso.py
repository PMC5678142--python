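"""ChIPnQASO: input-normalized allele-specific occupancy quantitation.

After chromatin immunoprecipitation (ChIP) at a heterozygous SNP, the
pulled-down DNA is genotyped on the KASP platform alongside the sheared
input chromatin.  The input is heterozygous, so its two channel signals
*define* the 50%/50% point: dividing each channel by the input mean for
that channel cancels channel-specific primer/fluorophore efficiency, and
renormalizing gives the allelic fraction of the immunoprecipitated DNA,

    frac_mut = (y / factor_mut) / (y / factor_mut + x / factor_wt),

a ratio-of-ratios that is invariant to any gain applied identically to
input and IP wells and maps the input itself to exactly 0.5.  The
preference ratio ``frac_mut / (1 - frac_mut)`` is then the headline
statistic (e.g. 2:1 binding preference of TCF7L2 for the rs6983267 G
allele; ~1:1 for CTCF).  IgG isotype-control wells are carried through
descriptively, never used for normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genotype_calling import (
    CallerParams,
    NormalizedReading,
    amplification_threshold,
    normalize_readings,
)
from .plate_model import PlatePanel, QuantitationError, ValidationError


@dataclass(frozen=True)
class ConversionFactors:
    """Per-channel input-DNA means that anchor the 50% allelic point."""

    factor_mut: float
    factor_wt: float
    n_input_wells: int

    def __post_init__(self) -> None:
        if self.factor_mut <= 0 or self.factor_wt <= 0:
            raise QuantitationError(
                "conversion factors must be strictly positive "
                f"(got mut={self.factor_mut}, wt={self.factor_wt}); "
                "input wells have no usable signal"
            )
        if self.n_input_wells < 1:
            raise QuantitationError("need at least one input well")


@dataclass(frozen=True)
class AllelicQuant:
    """Replicate-summarized allelic fractions for one sample x antibody."""

    sample_id: str
    antibody: str
    frac_mut: tuple[float, ...]
    mean_frac_mut: float
    sd_frac_mut: float
    preference_ratio: float
    flags: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.frac_mut)


def compute_conversion_factors(input_readings: Sequence[NormalizedReading],
                               amp_threshold: float = 0.0,
                               ) -> ConversionFactors:
    """Pool input wells by per-channel means (multiple wells average linearly).

    Wells at or below ``amp_threshold`` are excluded as failed reactions.
    """
    usable = [r for r in input_readings if r.magnitude > amp_threshold]
    if not usable:
        raise QuantitationError(
            "no input well above the amplification threshold"
        )
    return ConversionFactors(
        factor_mut=float(np.mean([r.y for r in usable])),
        factor_wt=float(np.mean([r.x for r in usable])),
        n_input_wells=len(usable),
    )


def allelic_fraction(reading: NormalizedReading,
                     factors: ConversionFactors) -> float:
    """Mutant-allele fraction of one well relative to input DNA."""
    if reading.magnitude <= 0:
        raise QuantitationError(
            f"well {reading.well}: no IP signal, allelic fraction undefined"
        )
    ym = reading.y / factors.factor_mut
    xw = reading.x / factors.factor_wt
    return ym / (ym + xw)


def summarize_replicates(records: Iterable[tuple[str, str, float]],
                         ) -> list[AllelicQuant]:
    """Group per-replicate fractions by (sample, antibody) and summarize.

    ``records`` yields ``(sample_id, antibody, frac_mut)`` triples.  The
    sample standard deviation is 0 (flagged ``single_replicate``) for
    n = 1.  The preference ratio is computed from the mean fraction;
    a mean of exactly 1 yields ``inf``.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for sample_id, antibody, frac in records:
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(
                f"{sample_id}/{antibody}: frac_mut {frac} outside [0, 1]"
            )
        key = (sample_id, antibody)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(frac)
    if not groups:
        raise ValidationError("no replicates to summarize")
    out = []
    for key in order:
        fracs = groups[key]
        flags: list[str] = []
        mean = float(np.mean(fracs))
        if len(fracs) > 1:
            # exact zero for identical replicates (np.std returns ~1e-17)
            sd = 0.0 if len(set(fracs)) == 1 \
                else float(np.std(fracs, ddof=1))
        else:
            sd = 0.0
            flags.append("single_replicate")
        ratio = math.inf if mean >= 1.0 else mean / (1.0 - mean)
        out.append(AllelicQuant(
            sample_id=key[0], antibody=key[1], frac_mut=tuple(fracs),
            mean_frac_mut=mean, sd_frac_mut=sd, preference_ratio=ratio,
            flags=tuple(flags),
        ))
    return out


def quantify_panel(panel: PlatePanel,
                   params: CallerParams | None = None) -> list[AllelicQuant]:
    """Full quantitation of a ChIPnQASO plate.

    Normalizes against the NTC baseline, derives conversion factors from
    the ``input_dna`` wells, converts every ``ip`` and ``igg`` well to an
    allelic fraction, and summarizes replicates per sample x antibody.
    IgG wells below the amplification threshold (the expected case — IgG
    pulls down near-background DNA) are excluded from fractions and the
    group is flagged ``low_signal``; input wells are reported under
    antibody ``"input"`` as a self-check (their mean is 0.5 by
    construction).
    """
    params = params or CallerParams()
    normalized, ntc = normalize_readings(panel)
    threshold = amplification_threshold(ntc, params)
    factors = compute_conversion_factors(
        [r for r in normalized if r.role == "input_dna"], threshold)

    records: list[tuple[str, str, float]] = []
    low_signal: set[tuple[str, str]] = set()
    for r in normalized:
        if r.role == "input_dna":
            records.append((r.sample_id, "input", allelic_fraction(r, factors)))
        elif r.role in ("ip", "igg"):
            antibody = r.antibody if r.role == "ip" else (r.antibody or "IgG")
            if r.magnitude > threshold:
                records.append((r.sample_id, antibody,
                                allelic_fraction(r, factors)))
            else:
                low_signal.add((r.sample_id, antibody))
    quants = summarize_replicates(records)
    # groups whose every well was sub-threshold still appear, flagged, empty
    summarized = {(q.sample_id, q.antibody) for q in quants}
    flagged = []
    for q in quants:
        if (q.sample_id, q.antibody) in low_signal:
            q = AllelicQuant(
                sample_id=q.sample_id, antibody=q.antibody,
                frac_mut=q.frac_mut, mean_frac_mut=q.mean_frac_mut,
                sd_frac_mut=q.sd_frac_mut,
                preference_ratio=q.preference_ratio,
                flags=q.flags + ("low_signal",),
            )
        flagged.append(q)
    for key in sorted(low_signal - summarized):
        flagged.append(AllelicQuant(
            sample_id=key[0], antibody=key[1], frac_mut=(),
            mean_frac_mut=float("nan"), sd_frac_mut=float("nan"),
            preference_ratio=float("nan"), flags=("low_signal", "no_signal"),
        ))
    return flagged
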