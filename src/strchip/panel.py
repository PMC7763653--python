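"""STR marker panel: locus metadata, multiplex-set structure, size/repeat conversion.

An STR locus is characterised by its repeat motif length (4 bp for the
tetranucleotide markers used here), the total length of the non-repeat
flanking sequence amplified by its primer pair, and the size window in which
its amplicons are expected.  Because loci co-amplified in one multiplex set
have pairwise-disjoint size windows, the estimated fragment size alone
identifies the locus, and the repeat number follows by inverting

    amplicon_size = flank_offset + repeat_unit * repeats.

The default panel carries nine murine tetranucleotide loci (18-3, 4-2, 6-7,
9-2, 15-3, 6-4, 12-1, 5-5, X-1) distributed over four multiplex sets, plus
the human sentinel locus D8S1106 in set 2 used purely to flag human
cross-contamination.  Amplicon sizes span 130-515 bp, inside the 25-1000 bp
sizing range of a DNA-1000-class chip.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, NamedTuple, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import PanelValidationError

#: Sizing range of the chip in bp; fragments outside it are flagged, not sized.
SIZING_RANGE_BP = (25.0, 1000.0)

#: Valid multiplex-set identifiers.
MULTIPLEX_SETS = (1, 2, 3, 4)

#: Maximum number of co-amplified loci per well.
MAX_LOCI_PER_SET = 3


class STRLocus(BaseModel):
    """One STR marker: motif length, flank length, expected size window, set."""

    model_config = {"frozen": True}

    name: str = Field(min_length=1)
    species: Literal["mouse", "human"]
    repeat_unit_bp: int = Field(default=4, ge=1)
    flank_offset_bp: int = Field(ge=0)
    size_range_bp: tuple[int, int]
    multiplex_set: int

    @field_validator("multiplex_set")
    @classmethod
    def _set_id_valid(cls, v: int) -> int:
        if v not in MULTIPLEX_SETS:
            raise ValueError(f"multiplex_set must be one of {MULTIPLEX_SETS}, got {v}")
        return v

    @model_validator(mode="after")
    def _check_geometry(self) -> "STRLocus":
        lo, hi = self.size_range_bp
        if not lo < hi:
            raise ValueError(f"locus {self.name}: size range [{lo}, {hi}] is empty")
        if lo < SIZING_RANGE_BP[0] or hi > SIZING_RANGE_BP[1]:
            raise ValueError(
                f"locus {self.name}: range [{lo}, {hi}] outside chip sizing "
                f"range {SIZING_RANGE_BP}"
            )
        if self.flank_offset_bp >= lo:
            raise ValueError(
                f"locus {self.name}: flank offset {self.flank_offset_bp} must be "
                f"below the range start {lo} (zero-repeat amplicon shorter than "
                "any callable allele)"
            )
        # Range endpoints sit on the allele-size grid so every integer repeat
        # count between them maps to an in-range size and vice versa.
        for bound in (lo, hi):
            if (bound - self.flank_offset_bp) % self.repeat_unit_bp != 0:
                raise ValueError(
                    f"locus {self.name}: range bound {bound} is not a valid "
                    f"allele size (offset {self.flank_offset_bp}, unit "
                    f"{self.repeat_unit_bp})"
                )
        return self

    @property
    def min_repeats(self) -> int:
        return (self.size_range_bp[0] - self.flank_offset_bp) // self.repeat_unit_bp

    @property
    def max_repeats(self) -> int:
        return (self.size_range_bp[1] - self.flank_offset_bp) // self.repeat_unit_bp


class Panel(BaseModel):
    """A full marker panel plus the sizing ladder and internal-marker sizes."""

    model_config = {"frozen": True}

    loci: tuple[STRLocus, ...]
    ladder_sizes_bp: tuple[int, ...]
    lower_marker_bp: int = Field(gt=0)
    upper_marker_bp: int = Field(gt=0)

    @model_validator(mode="after")
    def _check_panel(self) -> "Panel":
        if not self.loci:
            raise ValueError("panel defines no loci")
        names = [loc.name for loc in self.loci]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate locus names: {sorted(dupes)}")
        for set_id in MULTIPLEX_SETS:
            members = [loc for loc in self.loci if loc.multiplex_set == set_id]
            if len(members) > MAX_LOCI_PER_SET:
                raise ValueError(
                    f"multiplex set {set_id} has {len(members)} loci "
                    f"({', '.join(m.name for m in members)}); at most "
                    f"{MAX_LOCI_PER_SET} markers can share a well"
                )
            members.sort(key=lambda m: m.size_range_bp[0])
            for a, b in zip(members, members[1:]):
                if b.size_range_bp[0] <= a.size_range_bp[1]:
                    raise ValueError(
                        f"multiplex set {set_id}: size ranges of loci "
                        f"{a.name} {list(a.size_range_bp)} and "
                        f"{b.name} {list(b.size_range_bp)} overlap; size alone "
                        "must identify the locus"
                    )
        if list(self.ladder_sizes_bp) != sorted(set(self.ladder_sizes_bp)):
            raise ValueError("ladder sizes must be strictly ascending")
        if self.ladder_sizes_bp:
            if self.lower_marker_bp >= self.ladder_sizes_bp[0]:
                raise ValueError("lower marker must be smaller than every ladder rung")
            if self.upper_marker_bp <= self.ladder_sizes_bp[-1]:
                raise ValueError("upper marker must be larger than every ladder rung")
        return self

    # -- convenience -------------------------------------------------------
    def locus(self, name: str) -> STRLocus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(f"no locus named {name!r} in panel")

    def set_loci(self, set_id: int) -> list[STRLocus]:
        if set_id not in MULTIPLEX_SETS:
            raise ValueError(f"invalid multiplex set {set_id}")
        return sorted(
            (loc for loc in self.loci if loc.multiplex_set == set_id),
            key=lambda m: m.size_range_bp[0],
        )

    @property
    def mouse_loci(self) -> list[STRLocus]:
        return [loc for loc in self.loci if loc.species == "mouse"]

    @property
    def human_loci(self) -> list[STRLocus]:
        return [loc for loc in self.loci if loc.species == "human"]

    @property
    def size_span_bp(self) -> tuple[int, int]:
        """Overall [min, max] predicted amplicon size across all loci."""
        return (
            min(loc.size_range_bp[0] for loc in self.loci),
            max(loc.size_range_bp[1] for loc in self.loci),
        )


class RepeatCall(NamedTuple):
    """Nearest integer repeat count for an estimated size, with the leftover bp."""

    repeats: int
    residual_bp: float


def predicted_size(locus: STRLocus, repeats: int) -> int:
    """Predicted amplicon size in bp for an integer repeat count.

    size = flank_offset + repeat_unit * repeats; strictly increasing in
    ``repeats``.
    """
    if repeats < 1:
        raise ValueError(f"repeat count must be >= 1, got {repeats}")
    return locus.flank_offset_bp + locus.repeat_unit_bp * repeats


def repeats_from_size(
    locus: STRLocus, size_bp: float, tolerance_bp: Optional[float] = None
) -> Optional[RepeatCall]:
    """Invert :func:`predicted_size`: nearest integer repeat count for a size.

    Returns ``None`` (a no-call, not an exception) when the size falls outside
    the locus window extended by ``tolerance_bp`` (default: half a repeat
    unit), or when the residual to the nearest allele exceeds half a unit.
    Ties at exactly half a unit round up, deterministically.
    """
    if tolerance_bp is None:
        tolerance_bp = locus.repeat_unit_bp / 2.0
    lo, hi = locus.size_range_bp
    if not (lo - tolerance_bp <= size_bp <= hi + tolerance_bp):
        return None
    unit = locus.repeat_unit_bp
    repeats = int((size_bp - locus.flank_offset_bp) / unit + 0.5)
    repeats = max(locus.min_repeats, min(locus.max_repeats, repeats))
    residual = size_bp - predicted_size(locus, repeats)
    if abs(residual) > unit / 2.0 + 1e-9:
        return None
    return RepeatCall(repeats=repeats, residual_bp=residual)


def locus_for_size(panel: Panel, set_id: int, size_bp: float) -> Optional[STRLocus]:
    """The unique locus of a multiplex set whose closed size window contains
    ``size_bp``, or ``None``.  Boundary sizes belong to the locus (closed
    intervals); uniqueness is guaranteed by the panel's disjointness rule."""
    for loc in panel.set_loci(set_id):  # raises on invalid set_id
        lo, hi = loc.size_range_bp
        if lo <= size_bp <= hi:
            return loc
    return None


# -- configuration I/O -----------------------------------------------------

def _panel_from_mapping(doc: dict) -> Panel:
    try:
        loci = tuple(STRLocus(**entry) for entry in doc.get("loci", []))
        return Panel(
            loci=loci,
            ladder_sizes_bp=tuple(doc["ladder_sizes_bp"]),
            lower_marker_bp=doc["lower_marker_bp"],
            upper_marker_bp=doc["upper_marker_bp"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PanelValidationError(str(exc)) from exc


def load_panel(config_path: str | Path) -> Panel:
    """Load and validate a panel from a YAML config file.

    The schema is a mapping with keys ``ladder_sizes_bp`` (ascending list),
    ``lower_marker_bp``, ``upper_marker_bp`` and ``loci`` (list of locus
    records with keys matching :class:`STRLocus` fields).  All panel
    invariants are checked on load; violations raise
    :class:`PanelValidationError` naming the offending loci.
    """
    path = Path(config_path)
    if not path.is_file():
        raise FileNotFoundError(f"panel config not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelValidationError(f"panel config {path} is not a mapping")
    return _panel_from_mapping(doc)


def default_panel() -> Panel:
    """The shipped 9-mouse-locus + D8S1106 panel (see ``data/panel_default.yaml``)."""
    ref = resources.files("strchip.data").joinpath("panel_default.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _panel_from_mapping(doc)
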