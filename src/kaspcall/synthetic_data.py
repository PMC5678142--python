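"""Synthetic generators for every input the pipeline consumes.

No public raw data accompany the assays this package analyses, so the
generators stand in for the instruments.  They emulate:

* KASP endpoint fluorescence of a genotype mixture: the measured
  mutant-allele fraction is the true fraction plus a small spurious
  background and additive Gaussian noise; the total amplification
  magnitude scales with the fraction of amplifiable template and carries
  multiplicative noise; each channel sits on a no-template baseline;
  an optional channel-efficiency multiplier models FAM/HEX gain asymmetry.
* clone populations with per-allele edit outcomes (WT / HDR / NHEJ);
  NHEJ alleles disrupt the allele-specific primer site and contribute no
  amplifiable template — a well of two NHEJ alleles reads like an NTC,
  an HDR/NHEJ compound reads as homozygous-mutant at half magnitude.
* ChIP pulldown at a heterozygous SNP with a true allelic preference
  ratio rho (IP mutant fraction rho/(rho+1)), input at 50%, and IgG wells
  with near-background template.
* titration series of mutant/wildtype genomic DNA mixtures.
* merged amplicon reads with indels at the nuclease cut site.

Every generator takes a ``numpy.random.Generator`` and is byte-reproducible
for a fixed seed; every simulated well and read carries a truth label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chipnqaso import allelic_fraction, compute_conversion_factors
from .editing_metrics import HDR, NHEJ, WT, AmpliconAssay
from .genotype_calling import (
    CallerParams,
    amplification_threshold,
    normalize_readings,
)
from .plate_model import (
    PlatePanel,
    ValidationError,
    WellReading,
    well_sequence,
)
from .titration import DEFAULT_LEVELS, TitrationLevel

ALLELE_STATES = (WT, HDR, NHEJ)


@dataclass(frozen=True)
class SimParams:
    """Noise and gain parameters of the fluorescence model.

    gain
        Expected magnitude (summed channels above baseline) of a fully
        amplified well, in RFU.
    fraction_noise_sd
        Additive Gaussian noise on the measured mutant-allele fraction.
    background_fraction
        Spurious mutant-channel fraction at 0% mutant template (primer
        cross-talk); attenuates linearly to 0 as the true fraction
        approaches 1.
    magnitude_cv
        Coefficient of variation of the multiplicative magnitude noise.
    ntc_mean, ntc_sd
        Per-channel no-template baseline, RFU.
    channel_efficiency
        Mutant-channel (FAM) gain multiplier relative to wildtype (HEX).
    """

    gain: float = 2000.0
    fraction_noise_sd: float = 0.008
    background_fraction: float = 0.005
    magnitude_cv: float = 0.08
    ntc_mean: float = 60.0
    ntc_sd: float = 12.0
    channel_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.channel_efficiency <= 0:
            raise ValidationError("gain and channel_efficiency must be > 0")
        if min(self.fraction_noise_sd, self.background_fraction,
               self.magnitude_cv, self.ntc_sd) < 0:
            raise ValidationError("noise parameters must be >= 0")

    def noise_free(self) -> "SimParams":
        """Copy with every stochastic term switched off."""
        return replace(self, fraction_noise_sd=0.0, background_fraction=0.0,
                       magnitude_cv=0.0, ntc_sd=0.0)


@dataclass(frozen=True)
class CloneTruth:
    """Generative ground truth of one well's cell population."""

    sample_id: str
    alleles: tuple[str, ...]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if any(a not in ALLELE_STATES for a in self.alleles):
            raise ValidationError(f"invalid allele states in {self.alleles}")

    @property
    def n_cells(self) -> int:
        return len(self.alleles) // self.ploidy

    @property
    def amplifiable_fraction(self) -> float:
        return sum(a != NHEJ for a in self.alleles) / len(self.alleles)

    @property
    def mut_fraction_amplifiable(self) -> float:
        """Mutant fraction among alleles the allele-specific primers see."""
        amp = [a for a in self.alleles if a != NHEJ]
        if not amp:
            return 0.0
        return sum(a == HDR for a in amp) / len(amp)

    @property
    def genotype_class(self) -> str:
        """Truth label in caller vocabulary for a single-cell diploid well."""
        states = sorted(self.alleles)
        if all(a == NHEJ for a in states):
            return "NO_AMP"
        amp = [a for a in states if a != NHEJ]
        frac = sum(a == HDR for a in amp) / len(amp)
        if frac == 0.0:
            return "WT_WT"
        if frac == 1.0:
            return "MUT_MUT"
        return "WT_MUT"


# --------------------------------------------------------------------------
# Fluorescence
# --------------------------------------------------------------------------

def simulate_reading(true_frac_mut: float, amplifiable_frac: float,
                     params: SimParams, rng: np.random.Generator, *,
                     plate_id: str = "plate1", well: str = "A1",
                     sample_id: str = "sim", role: str = "clone",
                     antibody: str = "") -> WellReading:
    """Draw one well's two-channel fluorescence.

    ``true_frac_mut`` is the mutant fraction among amplifiable template;
    ``amplifiable_frac`` scales the magnitude (0 for an NTC-like well).
    """
    if not 0.0 <= true_frac_mut <= 1.0 or not 0.0 <= amplifiable_frac <= 1.0:
        raise ValidationError("fractions must lie in [0, 1]")
    f = true_frac_mut + params.background_fraction * (1.0 - true_frac_mut)
    f += rng.normal(0.0, params.fraction_noise_sd)
    f = min(max(f, 0.0), 1.0)
    magnitude = params.gain * amplifiable_frac \
        * (1.0 + rng.normal(0.0, params.magnitude_cv))
    magnitude = max(magnitude, 0.0)
    ntc_mut = params.ntc_mean + rng.normal(0.0, params.ntc_sd)
    ntc_wt = params.ntc_mean + rng.normal(0.0, params.ntc_sd)
    return WellReading(
        plate_id=plate_id, well=well, sample_id=sample_id, role=role,
        antibody=antibody,
        rfu_mut=max(ntc_mut + magnitude * f * params.channel_efficiency, 0.0),
        rfu_wt=max(ntc_wt + magnitude * (1.0 - f), 0.0),
    )


_ANCHORS = (
    # role, true mutant fraction, amplifiable fraction
    ("control_wt_wt", 0.0, 1.0),
    ("control_wt_mut", 0.5, 1.0),
    ("control_mut_mut", 1.0, 1.0),
    ("ntc", 0.0, 0.0),
)

#: Default anchor-well counts per simulated panel: four genotype controls
#: per class and twelve NTCs, typical of a controls block on a 384-well
#: run and enough NTCs for a stable noise-band estimate.
N_CONTROLS_PER_CLASS = 4
N_NTC = 12


def _anchor_wells(params: SimParams, rng: np.random.Generator,
                  wells: Iterable[tuple[str, str]],
                  n_controls: int = N_CONTROLS_PER_CLASS,
                  n_ntc: int = N_NTC) -> list[WellReading]:
    readings = []
    for role, frac, amp in _ANCHORS:
        count = n_ntc if role == "ntc" else n_controls
        for i in range(count):
            plate_id, well = next(wells)
            readings.append(simulate_reading(
                frac, amp, params, rng, plate_id=plate_id, well=well,
                sample_id=f"{role}_{i + 1}", role=role))
    return readings


# --------------------------------------------------------------------------
# Clone screens
# --------------------------------------------------------------------------

def simulate_panel_from_truths(truths: Sequence[CloneTruth],
                               params: SimParams,
                               rng: np.random.Generator,
                               assay_id: str = "sim_assay",
                               n_controls_per_class: int = N_CONTROLS_PER_CLASS,
                               n_ntc: int = N_NTC) -> PlatePanel:
    """Build a panel (anchors first, then one clone well per truth)."""
    n_anchor = 3 * n_controls_per_class + n_ntc
    wells = well_sequence(n_anchor + len(truths))
    readings = _anchor_wells(params, rng, wells, n_controls_per_class, n_ntc)
    for truth in truths:
        plate_id, well = next(wells)
        readings.append(simulate_reading(
            truth.mut_fraction_amplifiable, truth.amplifiable_fraction,
            params, rng, plate_id=plate_id, well=well,
            sample_id=truth.sample_id, role="clone"))
    return PlatePanel(assay_id=assay_id, allele_mut="MUT", allele_wt="WT",
                      readings=readings).validate()


def simulate_clone_screen(n_clones: int, cells_per_well: int,
                          p_hdr_allele: float, p_nhej_allele: float,
                          params: SimParams, rng: np.random.Generator,
                          ploidy: int = 2,
                          ) -> tuple[PlatePanel, list[CloneTruth]]:
    """Simulate a clone screen with independent per-allele edit outcomes.

    Each of the ``ploidy * cells_per_well`` founding alleles of a well is
    HDR with probability ``p_hdr_allele``, NHEJ with ``p_nhej_allele``,
    else unedited.
    """
    if p_hdr_allele < 0 or p_nhej_allele < 0 \
            or p_hdr_allele + p_nhej_allele > 1:
        raise ValidationError("allele outcome probabilities must be >= 0 "
                              "and sum to <= 1")
    if n_clones < 1 or cells_per_well < 1:
        raise ValidationError("n_clones and cells_per_well must be >= 1")
    n_alleles = ploidy * cells_per_well
    truths = []
    for i in range(n_clones):
        draws = rng.random(n_alleles)
        alleles = tuple(
            HDR if d < p_hdr_allele
            else NHEJ if d < p_hdr_allele + p_nhej_allele
            else WT
            for d in draws
        )
        truths.append(CloneTruth(sample_id=f"clone_{i + 1}", alleles=alleles,
                                 ploidy=ploidy))
    return simulate_panel_from_truths(truths, params, rng), truths


# --------------------------------------------------------------------------
# Titration
# --------------------------------------------------------------------------

N_INPUT_WELLS = 4


def simulate_titration(levels: Sequence[float], replicates: int,
                       params: SimParams, rng: np.random.Generator,
                       ) -> tuple[list[TitrationLevel], PlatePanel]:
    """Simulate a mixture titration and quantitate it end to end.

    Builds a panel of NTC wells, input wells at a true 50% mutant
    fraction, and ``replicates`` wells per nominal level; measured
    fractions are recovered through the input-normalized quantitation
    path (baseline subtraction, conversion factors, allelic fraction).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if 0.0 not in [float(p) for p in levels]:
        raise ValidationError("titration must include the 0% control level")
    if len({float(p) for p in levels}) != len(levels):
        raise ValidationError("titration levels must be distinct")
    n_wells = N_NTC + N_INPUT_WELLS + len(levels) * replicates
    wells = well_sequence(n_wells)
    readings = []
    for i in range(N_NTC):
        plate_id, well = next(wells)
        readings.append(simulate_reading(
            0.0, 0.0, params, rng, plate_id=plate_id, well=well,
            sample_id=f"ntc_{i + 1}", role="ntc"))
    for i in range(N_INPUT_WELLS):
        plate_id, well = next(wells)
        readings.append(simulate_reading(
            0.5, 1.0, params, rng, plate_id=plate_id, well=well,
            sample_id=f"input_{i + 1}", role="input_dna"))
    level_wells: dict[float, list[str]] = {}
    for level in levels:
        level = float(level)
        level_wells[level] = []
        for rep in range(1, replicates + 1):
            plate_id, well = next(wells)
            readings.append(simulate_reading(
                level / 100.0, 1.0, params, rng, plate_id=plate_id,
                well=well, sample_id=f"mix{level:g}pct_r{rep}", role="clone"))
            level_wells[level].append(well)
    panel = PlatePanel(assay_id="titration", allele_mut="T", allele_wt="G",
                       readings=readings).validate()

    normalized, ntc = normalize_readings(panel)
    threshold = amplification_threshold(ntc, CallerParams())
    factors = compute_conversion_factors(
        [r for r in normalized if r.role == "input_dna"], threshold)
    frac_by_well = {r.well: allelic_fraction(r, factors)
                    for r in normalized if r.role == "clone"}
    titration = [
        TitrationLevel(
            nominal_percent_mut=level,
            frac_mut=tuple(frac_by_well[w] for w in level_wells[level]),
        )
        for level in level_wells
    ]
    return titration, panel


def titration_lod_default(seed: int = 1234, alpha: float = 0.001) -> float | None:
    """LOD of the reference nine-level, four-replicate design at defaults."""
    from .titration import lod_analysis

    rng = np.random.default_rng(seed)
    levels, _ = simulate_titration(DEFAULT_LEVELS, 4, SimParams(), rng)
    return lod_analysis(levels, alpha=alpha).lod_percent


# --------------------------------------------------------------------------
# ChIP
# --------------------------------------------------------------------------

IGG_AMPLIFIABLE_FRAC = 0.02


def simulate_chip(preference_ratio: float, n_bio_replicates: int,
                  technical_duplicates: int, params: SimParams,
                  rng: np.random.Generator, antibody: str = "TCF7L2",
                  ) -> tuple[PlatePanel, dict[str, float]]:
    """Simulate a ChIPnQASO run at a heterozygous SNP.

    The IP wells' true mutant fraction is ``rho / (rho + 1)`` for
    preference ratio rho; input wells sit at 0.5 and IgG wells carry
    near-background template.  Any channel-efficiency asymmetry in
    ``params`` applies identically to all wells and cancels in the
    quantitation.
    """
    if preference_ratio <= 0:
        raise ValidationError("preference_ratio must be > 0")
    if n_bio_replicates < 1 or technical_duplicates < 1:
        raise ValidationError("replicate counts must be >= 1")
    ip_frac = preference_ratio / (preference_ratio + 1.0)
    n_per_group = n_bio_replicates * technical_duplicates
    wells = well_sequence(N_NTC + 3 * n_per_group)
    readings = []
    for i in range(N_NTC):
        plate_id, well = next(wells)
        readings.append(simulate_reading(
            0.0, 0.0, params, rng, plate_id=plate_id, well=well,
            sample_id=f"ntc_{i + 1}", role="ntc"))
    groups = (
        ("input_dna", "", 0.5, 1.0),
        ("ip", antibody, ip_frac, 1.0),
        ("igg", "IgG", 0.5, IGG_AMPLIFIABLE_FRAC),
    )
    for role, ab, frac, amp in groups:
        for bio in range(1, n_bio_replicates + 1):
            for tech in range(1, technical_duplicates + 1):
                plate_id, well = next(wells)
                readings.append(simulate_reading(
                    frac, amp, params, rng, plate_id=plate_id, well=well,
                    sample_id=f"bio{bio}", role=role, antibody=ab))
    panel = PlatePanel(assay_id="chipnqaso", allele_mut="T", allele_wt="G",
                       readings=readings).validate()
    truth = {"preference_ratio": preference_ratio, "ip_frac_mut": ip_frac,
             "input_frac_mut": 0.5}
    return panel, truth


# --------------------------------------------------------------------------
# Amplicon reads
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def random_amplicon_assay(rng: np.random.Generator, length: int = 217,
                          trim: int = 20, nhej_window: int = 10,
                          ) -> AmpliconAssay:
    """Synthetic assay fixture: random amplicon, G>T edit at the cut site.

    Mirrors the geometry of a single-base-substitution HDR assay (217-bp
    amplicon, central blunt cut, expected-HDR amplicon differing from the
    reference only at the edited base).
    """
    seq = rng.choice(_BASES, size=length)
    cut = length // 2
    seq[cut] = "G"
    reference = "".join(seq)
    hdr = reference[:cut] + "T" + reference[cut + 1:]
    return AmpliconAssay(reference_amplicon=reference,
                         expected_hdr_amplicon=hdr, cut_site=cut,
                         trim=trim, nhej_window=nhej_window)


def simulate_amplicon_reads(assay: AmpliconAssay, p_hdr: float, p_nhej: float,
                            n_reads: int, rng: np.random.Generator,
                            indel_sizes: Sequence[int] = tuple(range(1, 11)),
                            deletion_prob: float = 0.75,
                            revcomp_fraction: float = 0.0,
                            ) -> tuple[list[tuple[str, str]], list[str]]:
    """Draw merged amplicon reads with truth labels.

    NHEJ reads carry one indel at the cut site: a deletion (probability
    ``deletion_prob``, spanning the cut) or an insertion of random bases
    at the cut, size drawn uniformly from ``indel_sizes``.  A
    ``revcomp_fraction`` of reads is emitted reverse-complemented.
    """
    if p_hdr < 0 or p_nhej < 0 or p_hdr + p_nhej > 1:
        raise ValidationError("read outcome probabilities must be >= 0 "
                              "and sum to <= 1")
    if any(s < 1 for s in indel_sizes):
        raise ValidationError("indel sizes must be >= 1")
    ref = assay.reference_amplicon
    cut = assay.cut_site
    reads, labels = [], []
    for i in range(n_reads):
        d = rng.random()
        if d < p_hdr:
            label, seq = HDR, assay.expected_hdr_amplicon
        elif d < p_hdr + p_nhej:
            label = NHEJ
            size = int(rng.choice(np.asarray(indel_sizes)))
            if rng.random() < deletion_prob:
                start = max(cut - size // 2, 0)
                seq = ref[:start] + ref[start + size:]
            else:
                insert = "".join(rng.choice(_BASES, size=size))
                seq = ref[:cut] + insert + ref[cut:]
        else:
            label, seq = WT, ref
        if revcomp_fraction > 0 and rng.random() < revcomp_fraction:
            seq = seq.translate(_COMPLEMENT)[::-1]
        reads.append((f"read_{i + 1}", seq))
        labels.append(label)
    return reads, labels


def write_reads_fasta(reads: Iterable[tuple[str, str]],
                      path: str | Path) -> None:
    """Write reads as FASTA (deterministic byte layout for fixed input)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for read_id, seq in reads:
            handle.write(f">{read_id}\n{seq}\n")
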