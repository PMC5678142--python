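"""Control-anchored genotype calling from two-channel KASP fluorescence.

The instrument's cluster plot places each well at (wildtype-channel RFU,
mutant-channel RFU).  After subtracting the no-template-control (NTC)
baseline per channel, a well is described in polar coordinates:

* ``magnitude = x + y`` — total amplification signal; wells at or below the
  NTC noise band did not amplify (both allele-specific primers failed,
  the signature of NHEJ on both alleles);
* ``angle = atan2(y, x)`` in degrees — allelic composition, 0° for pure
  wildtype signal, 90° for pure mutant signal, ~45° for a balanced
  heterozygote (with equal channel gains).

Genotype-control wells of known genotype anchor one angular centroid per
class (WT/WT, WT/Mut, Mut/Mut); clones are called by standardized angular
distance (z) to the nearest centroid.  Wells that amplify but sit between
two adjacent centroids beyond the confident band are flagged INTERMEDIATE —
the signature of a mixed population (multi-cell-of-origin well or mosaic
clone) containing a minority edited allele.  A confident class call whose
magnitude falls well below the class's control median raises the
half-signal flag: one allele amplifies, the other (NHEJ) does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .plate_model import (
    CONTROL_ROLES,
    ConfigurationError,
    PlatePanel,
    ValidationError,
)

#: Genotype classes in increasing mutant-allele order.
GENOTYPE_CLASSES = ("wt_wt", "wt_mut", "mut_mut")

#: Call labels.
WT_WT, WT_MUT, MUT_MUT = "WT_WT", "WT_MUT", "MUT_MUT"
NO_AMP, INTERMEDIATE, AMBIGUOUS = "NO_AMP", "INTERMEDIATE", "AMBIGUOUS"

_CLASS_TO_CALL = {"wt_wt": WT_WT, "wt_mut": WT_MUT, "mut_mut": MUT_MUT}


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizedReading:
    """A well after per-channel NTC baseline subtraction.

    ``x`` is the wildtype-channel signal, ``y`` the mutant-channel signal,
    both clamped at zero.  ``angle`` is undefined (None) when the well has
    no signal at all.
    """

    sample_id: str
    well: str
    role: str
    x: float
    y: float
    antibody: str = ""

    @property
    def magnitude(self) -> float:
        return self.x + self.y

    @property
    def angle(self) -> float | None:
        if self.magnitude <= 0:
            return None
        return math.degrees(math.atan2(self.y, self.x))


@dataclass(frozen=True)
class NtcSummary:
    """Per-channel NTC statistics and the raw-magnitude noise band.

    ``mag_mean``/``mag_sd`` are computed on baseline-subtracted NTC
    magnitudes *before* clamping at zero (the clamp would bias the noise
    band low); with the NTC wells' own means subtracted, ``mag_mean`` is
    zero by construction.
    """

    mean_wt: float
    sd_wt: float
    mean_mut: float
    sd_mut: float
    n: int
    mag_mean: float
    mag_sd: float


@dataclass(frozen=True)
class ClusterClass:
    centroid_angle: float
    angle_sd: float
    median_magnitude: float


@dataclass(frozen=True)
class ClusterModel:
    """Control-derived cluster geometry plus the amplification threshold."""

    classes: dict[str, ClusterClass]
    amp_threshold: float

    def __post_init__(self) -> None:
        a = [self.classes[c].centroid_angle for c in GENOTYPE_CLASSES]
        if not (a[0] < a[1] < a[2]):
            raise ValidationError(
                "control centroids out of order "
                f"(wt_wt={a[0]:.2f}, wt_mut={a[1]:.2f}, mut_mut={a[2]:.2f} deg); "
                "check control labelling"
            )
        if self.amp_threshold < 0:
            raise ValidationError("amp_threshold must be >= 0")


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the caller.

    ntc_sd_multiplier
        k in ``amp_threshold = mean + k * sd`` of the NTC raw magnitudes.
    max_angle_z
        Largest standardized angular distance for a confident class call.
    half_signal_ratio
        Fraction of the class median magnitude below which the half-signal
        flag is raised for a confident call.
    angle_sd_floor
        Lower bound (degrees) on each class's angular dispersion, so that
        tight (or noise-free) control sets keep a usable confident band.
        0.75 deg puts the WT/WT confident boundary at 2.25 deg, below the
        3.0 deg of the smallest designed mixed-population signal (one
        heterozygous cell in ten, mutant-allele fraction 5%).
    min_controls_per_class
        Minimum amplified control wells required per genotype class.
    """

    ntc_sd_multiplier: float = 5.0
    max_angle_z: float = 3.0
    half_signal_ratio: float = 0.6
    angle_sd_floor: float = 0.75
    min_controls_per_class: int = 2

    def __post_init__(self) -> None:
        for name in ("ntc_sd_multiplier", "max_angle_z", "half_signal_ratio",
                     "angle_sd_floor", "min_controls_per_class"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"CallerParams.{name} must be positive")


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample categorical call with quality flags.

    ``angle_z`` is the standardized angular distance to ``nearest_class``
    (NaN for NO_AMP wells, which have no defined angle).
    """

    sample_id: str
    well: str
    call: str
    half_signal_flag: bool = False
    nearest_class: str | None = None
    angle: float | None = None
    magnitude: float = 0.0
    angle_z: float = float("nan")


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def normalize_readings(panel: PlatePanel,
                       ) -> tuple[list[NormalizedReading], NtcSummary]:
    """Subtract the per-channel NTC baseline from every well.

    Returns all wells (controls and NTCs included, with roles carried
    through) plus the NTC summary used for amplification thresholding.
    """
    ntcs = panel.by_role("ntc")
    if not ntcs:
        raise ConfigurationError("panel contains no ntc wells; "
                                 "baseline subtraction is undefined")
    wt = np.array([r.rfu_wt for r in ntcs], dtype=float)
    mut = np.array([r.rfu_mut for r in ntcs], dtype=float)
    mean_wt, mean_mut = float(wt.mean()), float(mut.mean())
    sd_wt = float(wt.std(ddof=1)) if len(ntcs) > 1 else 0.0
    sd_mut = float(mut.std(ddof=1)) if len(ntcs) > 1 else 0.0
    raw_mags = (wt - mean_wt) + (mut - mean_mut)
    summary = NtcSummary(
        mean_wt=mean_wt, sd_wt=sd_wt, mean_mut=mean_mut, sd_mut=sd_mut,
        n=len(ntcs),
        mag_mean=float(raw_mags.mean()),
        mag_sd=float(raw_mags.std(ddof=1)) if len(ntcs) > 1 else 0.0,
    )
    normalized = [
        NormalizedReading(
            sample_id=r.sample_id, well=r.well, role=r.role,
            antibody=r.antibody,
            x=max(r.rfu_wt - mean_wt, 0.0),
            y=max(r.rfu_mut - mean_mut, 0.0),
        )
        for r in panel.readings
    ]
    return normalized, summary


def amplification_threshold(ntc: NtcSummary, params: CallerParams) -> float:
    """Magnitude below which a well is considered not to have amplified."""
    return max(ntc.mag_mean + params.ntc_sd_multiplier * ntc.mag_sd, 0.0)


# --------------------------------------------------------------------------
# Cluster fitting
# --------------------------------------------------------------------------

def fit_control_clusters(readings: Iterable[NormalizedReading],
                         ntc: NtcSummary,
                         params: CallerParams | None = None) -> ClusterModel:
    """Anchor per-class angular centroids on the genotype-control wells.

    Controls at or below the amplification threshold are excluded; each
    class must retain at least ``min_controls_per_class`` wells.  The
    centroid ordering WT/WT < WT/Mut < Mut/Mut is enforced — a violation
    means mislabelled controls.
    """
    params = params or CallerParams()
    threshold = amplification_threshold(ntc, params)
    classes: dict[str, ClusterClass] = {}
    for role, cls in zip(CONTROL_ROLES, GENOTYPE_CLASSES):
        angles = [r.angle for r in readings
                  if r.role == role and r.magnitude > threshold
                  and r.angle is not None]
        mags = [r.magnitude for r in readings
                if r.role == role and r.magnitude > threshold]
        if len(angles) < params.min_controls_per_class:
            raise ConfigurationError(
                f"genotype class {cls!r}: only {len(angles)} amplified control "
                f"wells, need >= {params.min_controls_per_class}"
            )
        arr = np.array(angles, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        classes[cls] = ClusterClass(
            centroid_angle=float(arr.mean()),
            angle_sd=max(sd, params.angle_sd_floor),
            median_magnitude=float(median(mags)),
        )
    return ClusterModel(classes=classes, amp_threshold=threshold)


# --------------------------------------------------------------------------
# Calling
# --------------------------------------------------------------------------

def _call_one(r: NormalizedReading, model: ClusterModel,
              params: CallerParams) -> GenotypeCall:
    if r.magnitude <= model.amp_threshold or r.angle is None:
        return GenotypeCall(sample_id=r.sample_id, well=r.well, call=NO_AMP,
                            magnitude=r.magnitude, angle=r.angle)
    angle = r.angle
    zs = {cls: abs(angle - model.classes[cls].centroid_angle)
          / model.classes[cls].angle_sd
          for cls in GENOTYPE_CLASSES}
    # ties broken toward the lower-mutant class (GENOTYPE_CLASSES order):
    # conservative, fewer false HDR positives
    nearest = min(GENOTYPE_CLASSES, key=lambda c: (zs[c], GENOTYPE_CLASSES.index(c)))
    z = zs[nearest]
    if z <= params.max_angle_z:
        cls = model.classes[nearest]
        half = r.magnitude < params.half_signal_ratio * cls.median_magnitude
        return GenotypeCall(
            sample_id=r.sample_id, well=r.well, call=_CLASS_TO_CALL[nearest],
            half_signal_flag=half, nearest_class=nearest, angle=angle,
            magnitude=r.magnitude, angle_z=z,
        )
    centroids = [model.classes[c].centroid_angle for c in GENOTYPE_CLASSES]
    between = (centroids[0] < angle < centroids[1]
               or centroids[1] < angle < centroids[2])
    call = INTERMEDIATE if between else AMBIGUOUS
    return GenotypeCall(
        sample_id=r.sample_id, well=r.well, call=call,
        nearest_class=nearest, angle=angle, magnitude=r.magnitude, angle_z=z,
    )


def call_genotypes(readings: Iterable[NormalizedReading],
                   model: ClusterModel,
                   params: CallerParams | None = None,
                   roles: Sequence[str] = ("clone",)) -> list[GenotypeCall]:
    """Call every well with a role in ``roles`` (clones by default).

    Every well receives exactly one call; there is no error path.
    """
    params = params or CallerParams()
    return [_call_one(r, model, params) for r in readings if r.role in roles]


def detect_intermediate_wells(calls: Iterable[GenotypeCall],
                              model: ClusterModel) -> list[GenotypeCall]:
    """Candidate mixed-population wells, most HDR-like first.

    Returns the INTERMEDIATE calls ordered by ascending standardized
    angular distance to the heterozygous centroid, i.e. the well whose
    allelic composition is closest to a balanced heterozygote — the
    strongest evidence for edited cells in the mixture — comes first.
    """
    het = model.classes["wt_mut"]

    def het_z(c: GenotypeCall) -> float:
        assert c.angle is not None
        return abs(c.angle - het.centroid_angle) / het.angle_sd

    return sorted((c for c in calls if c.call == INTERMEDIATE), key=het_z)


# --------------------------------------------------------------------------
# Plotting (optional output mirroring the instrument's cluster viewer)
# --------------------------------------------------------------------------

_CALL_COLORS = {
    WT_WT: "tab:green", WT_MUT: "tab:orange", MUT_MUT: "tab:blue",
    NO_AMP: "black", INTERMEDIATE: "tab:red", AMBIGUOUS: "tab:gray",
}


def plot_clusters(readings: Iterable[NormalizedReading],
                  calls: Iterable[GenotypeCall], path: str) -> None:
    """Save a cluster plot (wildtype channel vs mutant channel) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_well = {(c.well): c for c in calls}
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in readings:
        call = by_well.get(r.well)
        color = _CALL_COLORS.get(call.call, "tab:gray") if call else "0.8"
        marker = "^" if call and call.half_signal_flag else "o"
        ax.scatter(r.x, r.y, c=color, marker=marker, s=18)
    ax.set_xlabel("wildtype-allele signal (RFU, baseline-subtracted)")
    ax.set_ylabel("mutant-allele signal (RFU, baseline-subtracted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
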