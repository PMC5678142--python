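"""Data model and I/O for two-channel endpoint-fluorescence genotyping plates.

A KASP (Kompetitive Allele-Specific PCR) run reports, for every well of a
384-well plate, one endpoint relative-fluorescence value (RFU) per allele
channel: FAM for the mutant/variant allele and HEX for the wildtype allele,
by the convention fixed here.  This module defines the well-level record
(:class:`WellReading`), the per-assay container (:class:`PlatePanel`), a
canonical CSV dialect for both, and layout validation against minimum
control requirements.

The canonical CSV dialect is: one leading metadata comment line
``# assay_id=<id>;allele_mut=<m>;allele_wt=<w>``, then the header
``plate_id,well,sample_id,role,antibody,rfu_mut,rfu_wt``, UTF-8,
comma-separated, ``\\n`` line endings, RFUs printed to 6 significant
digits.  ``write_plate_csv`` followed by ``read_plate_csv`` is the
identity on valid panels.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class KaspError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(KaspError):
    """A file does not conform to the canonical dialect (names the column)."""


class ValidationError(KaspError):
    """A record violates a domain invariant (names the well or field)."""


class ConfigurationError(KaspError):
    """An operation's preconditions on the run layout are not met."""


class QuantitationError(KaspError):
    """Allelic quantitation is undefined for the given signal."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

#: Accepted well roles.  ``control_*`` wells carry genomic DNA of known
#: genotype, ``ntc`` is the no-template control, ``input_dna``/``ip``/``igg``
#: are the ChIPnQASO roles (sheared input chromatin, antibody pulldown,
#: isotype control).
ROLES = frozenset({
    "clone", "control_wt_wt", "control_wt_mut", "control_mut_mut",
    "ntc", "input_dna", "ip", "igg",
})

#: Genotype-control roles in increasing mutant-allele order.
CONTROL_ROLES = ("control_wt_wt", "control_wt_mut", "control_mut_mut")

_WELL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")

CSV_COLUMNS = ("plate_id", "well", "sample_id", "role", "antibody",
               "rfu_mut", "rfu_wt")


def validate_well(well: str) -> str:
    """Check ``well`` against the 384-well grid (rows A-P, columns 1-24).

    96-well identifiers (A-H, 1-12) are a subset and pass unchanged.
    """
    m = _WELL_RE.match(well)
    if not m or not 1 <= int(m.group(2)) <= 24:
        raise ValidationError(
            f"invalid well identifier {well!r}: expected row A-P + column 1-24"
        )
    return well


@dataclass(frozen=True)
class WellReading:
    """One well's two-channel raw endpoint fluorescence.

    ``rfu_mut`` is the mutant/variant-allele channel (FAM by convention),
    ``rfu_wt`` the wildtype-allele channel (HEX).  Both are arbitrary
    instrument units, non-negative.
    """

    plate_id: str
    well: str
    sample_id: str
    role: str
    rfu_mut: float
    rfu_wt: float
    antibody: str = ""

    def __post_init__(self) -> None:
        validate_well(self.well)
        if self.role not in ROLES:
            raise ValidationError(
                f"well {self.well}: unknown role {self.role!r} "
                f"(expected one of {sorted(ROLES)})"
            )
        if self.rfu_mut < 0 or self.rfu_wt < 0:
            raise ValidationError(
                f"well {self.well}: negative RFU "
                f"(rfu_mut={self.rfu_mut}, rfu_wt={self.rfu_wt})"
            )
        if self.role == "ip" and not self.antibody:
            raise ValidationError(
                f"well {self.well}: role 'ip' requires a non-empty antibody"
            )


@dataclass
class PlatePanel:
    """All readings of one assay run (one KASP marker, possibly several plates).

    ``allele_mut``/``allele_wt`` are display labels for the two competing
    allele-specific primers (e.g. ``"T"`` and ``"G"`` for rs6983267).
    """

    assay_id: str = ""
    allele_mut: str = ""
    allele_wt: str = ""
    readings: list[WellReading] = field(default_factory=list)

    def validate(self) -> "PlatePanel":
        if not self.readings:
            raise ValidationError("panel has no readings")
        seen: set[tuple[str, str]] = set()
        for r in self.readings:
            key = (r.plate_id, r.well)
            if key in seen:
                raise ValidationError(
                    f"duplicate well {r.well!r} on plate {r.plate_id!r}"
                )
            seen.add(key)
        return self

    def by_role(self, *roles: str) -> list[WellReading]:
        return [r for r in self.readings if r.role in roles]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.readings:
            counts[r.role] = counts.get(r.role, 0) + 1
        return counts


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_META_RE = re.compile(r"^#\s*assay_id=(.*);allele_mut=(.*);allele_wt=(.*)$")


def _parse_rfu(text: str, column: str, well: str) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(
            f"well {well}: column {column!r} is not numeric: {text!r}"
        ) from exc
    if value < 0:
        raise ValidationError(f"well {well}: negative RFU in column {column!r}")
    return value


def read_plate_csv(path: str | Path) -> PlatePanel:
    """Read a plate table in the canonical dialect.

    Raises :class:`FormatError` for a missing/invalid column and
    :class:`ValidationError` for negative RFUs, duplicate wells or
    unknown roles, always naming the offending column or well.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as handle:
        first = handle.readline()
        assay_id = allele_mut = allele_wt = ""
        meta = _META_RE.match(first.strip())
        if meta:
            assay_id, allele_mut, allele_wt = meta.groups()
            header_line = handle.readline()
        else:
            header_line = first
        reader = csv.reader(io.StringIO(header_line))
        header = next(reader, [])
        for column in CSV_COLUMNS:
            if column not in header:
                raise FormatError(f"missing required column {column!r}")
        idx = {name: header.index(name) for name in CSV_COLUMNS}
        readings = []
        for lineno, row in enumerate(csv.reader(handle), start=2):
            if not row:
                continue
            if len(row) < len(header):
                raise FormatError(f"line {lineno}: expected {len(header)} fields")
            well = row[idx["well"]]
            readings.append(WellReading(
                plate_id=row[idx["plate_id"]],
                well=well,
                sample_id=row[idx["sample_id"]],
                role=row[idx["role"]],
                antibody=row[idx["antibody"]],
                rfu_mut=_parse_rfu(row[idx["rfu_mut"]], "rfu_mut", well),
                rfu_wt=_parse_rfu(row[idx["rfu_wt"]], "rfu_wt", well),
            ))
    panel = PlatePanel(assay_id=assay_id, allele_mut=allele_mut,
                       allele_wt=allele_wt, readings=readings)
    return panel.validate()


def _format_rfu(value: float) -> str:
    return format(float(value), ".6g")


def write_plate_csv(panel: PlatePanel, path: str | Path) -> None:
    """Write ``panel`` in the canonical dialect (see module docstring)."""
    panel.validate()
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write(
            f"# assay_id={panel.assay_id};allele_mut={panel.allele_mut};"
            f"allele_wt={panel.allele_wt}\n"
        )
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in panel.readings:
            writer.writerow([
                r.plate_id, r.well, r.sample_id, r.role, r.antibody,
                _format_rfu(r.rfu_mut), _format_rfu(r.rfu_wt),
            ])


# --------------------------------------------------------------------------
# Layout validation
# --------------------------------------------------------------------------

#: Minimum wells per role for a callable genotyping run: the cluster caller
#: needs at least two anchors per genotype class and two no-template wells.
DEFAULT_REQUIREMENTS: Mapping[str, int] = {
    "ntc": 2,
    "control_wt_wt": 2,
    "control_wt_mut": 2,
    "control_mut_mut": 2,
}


@dataclass(frozen=True)
class LayoutReport:
    """Outcome of :func:`validate_layout`.

    ``deficits`` maps each under-represented role to ``(have, need)``.
    """

    ok: bool
    deficits: Mapping[str, tuple[int, int]]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "layout ok"
        parts = [f"{role}: have {have}, need {need}"
                 for role, (have, need) in sorted(self.deficits.items())]
        return "layout deficits: " + "; ".join(parts)


def validate_layout(panel: PlatePanel,
                    requirements: Mapping[str, int] | None = None,
                    ) -> LayoutReport:
    """Report roles whose well count falls below ``requirements``."""
    if requirements is None:
        requirements = DEFAULT_REQUIREMENTS
    counts = panel.role_counts()
    deficits = {
        role: (counts.get(role, 0), need)
        for role, need in requirements.items()
        if counts.get(role, 0) < need
    }
    return LayoutReport(ok=not deficits, deficits=deficits)


def well_sequence(n: int, columns: int = 24, rows: str = "ABCDEFGHIJKLMNOP",
                  ) -> Iterable[tuple[str, str]]:
    """Yield ``n`` (plate_id, well) pairs row-major, spilling onto new plates.

    Used by the simulators and the titration designer for deterministic
    well assignment.
    """
    per_plate = len(rows) * columns
    for i in range(n):
        plate = i // per_plate + 1
        j = i % per_plate
        yield f"plate{plate}", f"{rows[j // columns]}{j % columns + 1}"
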