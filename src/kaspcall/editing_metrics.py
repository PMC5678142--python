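"""Editing-outcome arithmetic and a minimal amplicon-read classifier.

Covers the bookkeeping around a CRISPR HDR clone screen:

* T7 endonuclease I INDEL fraction from three gel band intensities,
  ``%INDEL = (1 - sqrt(uncut / total)) * 100`` in its published band form;
* genotype frequency tables and allelic efficiency — the fraction of all
  screened alleles carrying the precise edit,
  ``(n_het + ploidy * n_hom) / (ploidy * n_total)``;
* mutant-allele percentage of a multi-cell-of-origin well (e.g. one
  heterozygous cell among ten diploid cells -> 1 of 20 alleles = 5%);
* a simplified HDR/NHEJ classifier for merged amplicon reads: a read
  whose trimmed core matches the expected HDR amplicon exactly is HDR;
  otherwise the read is globally aligned to the reference and called NHEJ
  if the alignment shows an insertion or deletion within a window around
  the nuclease cut site, WT if indel-free near the cut and near-identical
  overall, else UNCLASSIFIED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

from .plate_model import ValidationError

HDR, NHEJ, WT, UNCLASSIFIED = "HDR", "NHEJ", "WT", "UNCLASSIFIED"

_VALID_BASES = frozenset("ACGTN")


# --------------------------------------------------------------------------
# T7 endonuclease I assay
# --------------------------------------------------------------------------

def t7_indel_percent(cut_band1: float, cut_band2: float,
                     uncut_band: float) -> float:
    """INDEL percentage from T7 gel band intensities.

    ``(1 - (1 - (cut1 + cut2) / (cut1 + cut2 + uncut)) ** (1/2)) * 100``.
    Scale-invariant in the three intensities; undefined when all are zero.
    """
    for name, band in (("cut_band1", cut_band1), ("cut_band2", cut_band2),
                       ("uncut_band", uncut_band)):
        if band < 0:
            raise ValidationError(f"{name} must be >= 0, got {band}")
    total = cut_band1 + cut_band2 + uncut_band
    if total == 0:
        raise ValidationError("all three band intensities are zero; "
                              "INDEL fraction undefined")
    cut_fraction = (cut_band1 + cut_band2) / total
    return (1.0 - math.sqrt(1.0 - cut_fraction)) * 100.0


# --------------------------------------------------------------------------
# Genotype frequency accounting
# --------------------------------------------------------------------------

def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GenotypeCounts:
    """Clone counts per genotype from a single-cell screen."""

    n_wt_wt: int
    n_wt_mut: int
    n_mut_mut: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        if min(self.n_wt_wt, self.n_wt_mut, self.n_mut_mut) < 0:
            raise ValidationError("genotype counts must be non-negative")
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_wt_wt + self.n_wt_mut + self.n_mut_mut


@dataclass(frozen=True)
class FrequencyTable:
    """Genotype percentages and allelic efficiency (unrounded + display).

    ``*_display`` values are half-up rounded to one decimal, the style of
    published screen summaries; the unrounded values are retained for
    downstream arithmetic.
    """

    counts: GenotypeCounts
    pct_wt_wt: float
    pct_wt_mut: float
    pct_mut_mut: float
    allelic_efficiency: float

    @property
    def pct_wt_wt_display(self) -> float:
        return round_half_up(self.pct_wt_wt)

    @property
    def pct_wt_mut_display(self) -> float:
        return round_half_up(self.pct_wt_mut)

    @property
    def pct_mut_mut_display(self) -> float:
        return round_half_up(self.pct_mut_mut)

    @property
    def allelic_efficiency_display(self) -> float:
        return round_half_up(self.allelic_efficiency)


def frequency_table(counts: GenotypeCounts) -> FrequencyTable:
    """Genotype percentages and allelic efficiency for a screen.

    Allelic efficiency counts one edited allele per heterozygote and
    ``ploidy`` per homozygous-mutant clone, over all screened alleles.
    """
    n = counts.n_total
    if n < 1:
        raise ValidationError("no clones counted")
    edited_alleles = counts.n_wt_mut + counts.n_mut_mut * counts.ploidy
    return FrequencyTable(
        counts=counts,
        pct_wt_wt=counts.n_wt_wt / n * 100.0,
        pct_wt_mut=counts.n_wt_mut / n * 100.0,
        pct_mut_mut=counts.n_mut_mut / n * 100.0,
        allelic_efficiency=edited_alleles / (n * counts.ploidy) * 100.0,
    )


def multiwell_mut_fraction(n_cells: int, n_het_cells: int,
                           n_hom_cells: int = 0, ploidy: int = 2) -> float:
    """Mutant-allele percentage of a multi-cell-of-origin well."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if min(n_het_cells, n_hom_cells) < 0 or ploidy < 1:
        raise ValidationError("cell counts must be >= 0 and ploidy >= 1")
    if n_het_cells + n_hom_cells > n_cells:
        raise ValidationError("edited cells exceed total cells")
    return (n_het_cells + n_hom_cells * ploidy) / (n_cells * ploidy) * 100.0


# --------------------------------------------------------------------------
# Amplicon-read HDR/NHEJ classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconAssay:
    """Reference geometry of one amplicon-sequencing assay.

    ``cut_site`` is the 0-based offset of the blunt cleavage point between
    reference bases; an indel overlapping ``cut_site +/- nhej_window`` is
    scored as NHEJ.  ``trim`` bases are removed from each read end before
    the exact HDR match (merged-read ends have uneven quality).
    """

    reference_amplicon: str
    expected_hdr_amplicon: str
    cut_site: int
    trim: int = 20
    nhej_window: int = 10
    min_wt_identity: float = 0.98

    def __post_init__(self) -> None:
        for name, seq in (("reference_amplicon", self.reference_amplicon),
                          ("expected_hdr_amplicon", self.expected_hdr_amplicon)):
            if not seq or set(seq.upper()) - _VALID_BASES:
                raise ValidationError(
                    f"{name} must be a non-empty sequence over A,C,G,T,N"
                )
        if not 0 <= self.cut_site <= len(self.reference_amplicon):
            raise ValidationError("cut_site outside the reference amplicon")
        if self.trim < 0 or self.nhej_window < 0:
            raise ValidationError("trim and nhej_window must be >= 0")


@dataclass(frozen=True)
class EditOutcome:
    read_id: str
    outcome: str
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReadSummary:
    n_reads: int
    hdr_percent: float
    nhej_percent: float
    wt_percent: float
    unclassified_percent: float


def _make_aligner() -> Align.PairwiseAligner:
    # fixed scoring of the global aligner; not fitted to data
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-0.5,
    )
    return aligner


def _indel_in_window(alignment, cut_site: int, window: int) -> bool:
    """True if any alignment gap overlaps [cut-window, cut+window]."""
    lo, hi = cut_site - window, cut_site + window
    target, query = alignment.aligned  # aligned blocks, gap = inter-block jump
    for k in range(len(target) - 1):
        t_gap = target[k + 1][0] - target[k][1]   # deletion in the read
        q_gap = query[k + 1][0] - query[k][1]     # insertion in the read
        if t_gap > 0:  # reference interval [target[k][1], target[k+1][0]) deleted
            if target[k][1] <= hi and target[k + 1][0] > lo:
                return True
        if q_gap > 0:  # insertion at reference coordinate target[k][1]
            if lo <= target[k][1] <= hi:
                return True
    # end gaps (unaligned reference beyond the read) are length artefacts of
    # merged reads, not repair events, and are deliberately not scored
    return False


def _identity(alignment) -> float:
    counts = alignment.counts()
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    if aligned_len == 0:
        return 0.0
    return counts.identities / aligned_len


def classify_read(read_id: str, sequence: str, assay: AmpliconAssay,
                  aligner: Align.PairwiseAligner | None = None) -> EditOutcome:
    """Classify one merged read as HDR, NHEJ, WT or UNCLASSIFIED.

    HDR exact-match takes precedence over alignment-based calls, so a read
    can never be both HDR and NHEJ.
    """
    seq = sequence.upper()
    if len(seq) < 2 * assay.trim + 1:
        return EditOutcome(read_id, UNCLASSIFIED, flags=("short",))
    core = seq[assay.trim: len(seq) - assay.trim]
    hdr = assay.expected_hdr_amplicon.upper()
    if core in hdr or reverse_complement(core) in hdr:
        return EditOutcome(read_id, HDR)
    ref = assay.reference_amplicon.upper()
    # fast path: an exact reference substring has no indel and full identity
    if core in ref or reverse_complement(core) in ref:
        return EditOutcome(read_id, WT)
    aligner = aligner or _make_aligner()
    best = None
    for candidate in (seq, reverse_complement(seq)):
        alignment = aligner.align(ref, candidate)[0]
        if best is None or alignment.score > best.score:
            best = alignment
    if _indel_in_window(best, assay.cut_site, assay.nhej_window):
        return EditOutcome(read_id, NHEJ)
    if _identity(best) >= assay.min_wt_identity:
        return EditOutcome(read_id, WT)
    return EditOutcome(read_id, UNCLASSIFIED)


def classify_reads(reads: Iterable[tuple[str, str]], assay: AmpliconAssay,
                   ) -> tuple[list[EditOutcome], ReadSummary]:
    """Classify every read and summarize outcome percentages.

    ``reads`` yields ``(read_id, sequence)`` pairs (see :func:`read_reads`
    for FASTA/FASTQ input).  Summary percentages sum to 100 over all reads.
    """
    aligner = _make_aligner()
    outcomes = [classify_read(rid, seq, assay, aligner) for rid, seq in reads]
    if not outcomes:
        raise ValidationError("no reads to classify")
    n = len(outcomes)
    count = {k: 0 for k in (HDR, NHEJ, WT, UNCLASSIFIED)}
    for o in outcomes:
        count[o.outcome] += 1
    summary = ReadSummary(
        n_reads=n,
        hdr_percent=count[HDR] / n * 100.0,
        nhej_percent=count[NHEJ] / n * 100.0,
        wt_percent=count[WT] / n * 100.0,
        unclassified_percent=count[UNCLASSIFIED] / n * 100.0,
    )
    return outcomes, summary


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Load merged reads from FASTA or FASTQ (quality ignored)."""
    path = Path(path)
    suffix = path.suffix.lower()
    fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
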