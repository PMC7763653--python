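"""Allele calling: sized peaks → per-locus repeat calls → a sample's STR profile.

Peaks from each multiplex well are attached to loci by their size window,
then reduced to one or two allele calls per locus.  The tallest peak is
always an allele; a second peak is accepted as the other allele when it
reaches ``het_ratio`` of the tallest height, unless it sits one repeat unit
below a taller peak at less than ``stutter_ratio`` of that peak's height, in
which case it is discarded as PCR stutter.  More than two surviving peaks are
truncated to the top two and flagged ``extra_allele`` — the downstream
contamination check consumes that flag.

A profile maps each locus name to a sorted tuple of repeat counts; loci with
one distinct allele are stored as a single value (reference tables print one
number, which may mean homozygous or a single detectable allele — the model
stays agnostic) and an empty tuple marks an explicit no-call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ProfileError
from .panel import MULTIPLEX_SETS, Panel, STRLocus, repeats_from_size
from .simulate import Electropherogram
from .traceproc import DEFAULT_MIN_SNR, SizedPeak, fit_calibration, size_peaks

DEFAULT_HET_RATIO = 0.4
DEFAULT_STUTTER_RATIO = 0.3

#: How far a peak-to-peak spacing may deviate from one repeat unit and still
#: count as a stutter position, in bp.
STUTTER_POSITION_TOL_BP = 1.5

FLAG_STUTTER = "stutter_filtered_neighbor"
FLAG_OFF_SCALE = "off_scale"
FLAG_EXTRA = "extra_allele"


@dataclass(frozen=True)
class AlleleCall:
    """One called allele at one locus."""

    locus: str
    repeats: int
    size_bp: float
    height_fu: float
    residual_bp: float
    flags: frozenset[str] = frozenset()


@dataclass
class STRProfile:
    """Per-locus repeat calls for one sample.

    ``alleles`` maps locus name → sorted tuple of distinct repeat counts; an
    empty tuple is an explicit no-call.  ``locus_flags`` carries calling
    flags per locus (e.g. ``extra_allele``).
    """

    label: str
    alleles: dict[str, tuple[int, ...]]
    locus_flags: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = {
            name: tuple(sorted(set(reps))) for name, reps in self.alleles.items()
        }

    def called_loci(self) -> list[str]:
        return [name for name, reps in self.alleles.items() if reps]

    def species_flags(self, panel: Panel) -> tuple[bool, bool]:
        """(murine loci called, human locus called) under a panel's species map."""
        murine = any(
            self.alleles.get(loc.name) for loc in panel.mouse_loci
        )
        human = any(self.alleles.get(loc.name) for loc in panel.human_loci)
        return murine, human


def assign_loci(
    sized_peaks: Sequence[SizedPeak], panel: Panel, set_id: int
) -> tuple[dict[str, list[SizedPeak]], list[SizedPeak]]:
    """Attach each in-range peak to the locus whose size window contains it.

    Returns ``(locus name → peaks, unassigned peaks)``; unassignable peaks
    are reported, never fatal.
    """
    loci = panel.set_loci(set_id)
    assigned: dict[str, list[SizedPeak]] = {}
    unassigned: list[SizedPeak] = []
    for peak in sized_peaks:
        if not peak.in_sizing_range:
            unassigned.append(peak)
            continue
        for locus in loci:
            lo, hi = locus.size_range_bp
            if lo <= peak.size_bp <= hi:
                assigned.setdefault(locus.name, []).append(peak)
                break
        else:
            unassigned.append(peak)
    return assigned, unassigned


def call_alleles(
    locus_peaks: Sequence[SizedPeak],
    locus: STRLocus,
    het_ratio: float = DEFAULT_HET_RATIO,
    stutter_ratio: float = DEFAULT_STUTTER_RATIO,
    size_offset_bp: float = 0.0,
) -> list[AlleleCall]:
    """Reduce the peaks of one locus to one or two allele calls.

    ``size_offset_bp`` is a per-locus systematic sizing correction
    (calibrated against a known reference sample; default 0) subtracted from
    every estimated size before repeat conversion.
    """
    if not locus_peaks:
        return []
    by_height = sorted(locus_peaks, key=lambda p: -p.height_fu)
    flags: set[str] = set()

    def is_stutter(p: SizedPeak) -> bool:
        for q in by_height:
            if q.height_fu <= p.height_fu:
                continue
            spacing = q.size_bp - p.size_bp
            if (
                abs(spacing - locus.repeat_unit_bp) <= STUTTER_POSITION_TOL_BP
                and p.height_fu < stutter_ratio * q.height_fu
            ):
                return True
        return False

    survivors = []
    for p in by_height:
        if is_stutter(p):
            flags.add(FLAG_STUTTER)
        else:
            survivors.append(p)
    if not survivors:
        return []
    tallest = survivors[0]
    qualifying = [tallest] + [
        p for p in survivors[1:] if p.height_fu >= het_ratio * tallest.height_fu
    ]
    if len(qualifying) > 2:
        flags.add(FLAG_EXTRA)
        qualifying = qualifying[:2]

    calls = []
    for p in qualifying:
        if not p.in_sizing_range:
            flags.add(FLAG_OFF_SCALE)
            continue
        rc = repeats_from_size(locus, p.size_bp - size_offset_bp)
        if rc is None:
            continue
        calls.append(
            AlleleCall(
                locus=locus.name,
                repeats=rc.repeats,
                size_bp=p.size_bp,
                height_fu=p.height_fu,
                residual_bp=rc.residual_bp,
                flags=frozenset(flags),
            )
        )
    return sorted(calls, key=lambda c: c.repeats)


def build_profile(
    per_set_calls: Mapping[int, Mapping[str, Sequence[AlleleCall]]],
    panel: Panel,
    sample_label: str,
) -> STRProfile:
    """Merge per-set allele calls into one profile.

    Every murine panel locus missing from the calls is recorded as an
    explicit no-call; the human sentinel locus enters the species flags (via
    the panel) rather than the murine genotype, though its calls are kept for
    inspection.  A locus appearing in more than one set is an error.
    """
    alleles: dict[str, tuple[int, ...]] = {}
    locus_flags: dict[str, frozenset[str]] = {}
    seen: dict[str, int] = {}
    for set_id, locus_map in per_set_calls.items():
        for locus_name, calls in locus_map.items():
            if locus_name in seen:
                raise ProfileError(
                    f"locus {locus_name} reported by both set {seen[locus_name]} "
                    f"and set {set_id}"
                )
            seen[locus_name] = set_id
            if calls:
                alleles[locus_name] = tuple(sorted({c.repeats for c in calls}))
                fl = frozenset().union(*(c.flags for c in calls))
                if fl:
                    locus_flags[locus_name] = fl
    for locus in panel.mouse_loci:
        alleles.setdefault(locus.name, ())
    return STRProfile(label=sample_label, alleles=alleles, locus_flags=locus_flags)


def call_sample(
    ladder_trace: Electropherogram,
    set_traces: Mapping[int, Electropherogram],
    panel: Panel,
    sample_label: str,
    min_snr: float = DEFAULT_MIN_SNR,
    het_ratio: float = DEFAULT_HET_RATIO,
    stutter_ratio: float = DEFAULT_STUTTER_RATIO,
) -> STRProfile:
    """Full calling chain for one chip run: calibrate, size, assign, call, merge."""
    calibration = fit_calibration(ladder_trace, panel.ladder_sizes_bp, min_snr=min_snr)
    per_set: dict[int, dict[str, list[AlleleCall]]] = {}
    for set_id, trace in set_traces.items():
        if set_id not in MULTIPLEX_SETS:
            raise ValueError(f"invalid multiplex set {set_id}")
        sized = size_peaks(trace, calibration, min_snr=min_snr)
        assigned, _ = assign_loci(sized, panel, set_id)
        per_set[set_id] = {
            name: call_alleles(
                peaks, panel.locus(name), het_ratio=het_ratio, stutter_ratio=stutter_ratio
            )
            for name, peaks in assigned.items()
        }
    return build_profile(per_set, panel, sample_label)


# -- profile I/O and packaged reference fixtures ---------------------------

def _profiles_from_doc(doc: Mapping[str, Mapping[str, Iterable[int]]]) -> dict[str, STRProfile]:
    out = {}
    for label, locus_map in doc.items():
        alleles = {name: tuple(int(r) for r in reps) for name, reps in locus_map.items()}
        out[label] = STRProfile(label=label, alleles=alleles)
    return out


def read_profiles(path: str | Path) -> dict[str, STRProfile]:
    """Read profiles from a YAML file mapping label → {locus: [repeats, ...]}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ProfileError(f"profile file {path} is not a mapping")
    return _profiles_from_doc(doc)


def write_profiles(path: str | Path, profiles: Iterable[STRProfile]) -> None:
    doc = {p.label: {k: list(v) for k, v in p.alleles.items()} for p in profiles}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def profiles_to_table(
    profiles: Iterable[STRProfile], panel: Panel, sep: str = "\t"
) -> str:
    """Delimited export, one row per sample, murine loci as columns."""
    loci = [loc.name for loc in panel.mouse_loci]
    lines = [sep.join(["Cell Line"] + loci)]
    for p in profiles:
        cells = [", ".join(str(r) for r in p.alleles.get(n, ())) or "-" for n in loci]
        lines.append(sep.join([p.label] + cells))
    return "\n".join(lines) + "\n"


def reference_profiles() -> dict[str, STRProfile]:
    """The six packaged murine reference profiles (three HoxB8-FL, three mPDAC)."""
    ref = resources.files("strchip.data").joinpath("reference_profiles.yaml")
    return _profiles_from_doc(yaml.safe_load(ref.read_text()))


def synthetic_human_profile() -> STRProfile:
    """Synthetic stand-in MM.1S profile carrying only the human sentinel locus.

    The real MM.1S D8S1106 genotype is not published alongside the murine
    reference profiles; the packaged alleles are an invented placeholder
    inside the panel's D8S1106 window, sufficient for cross-species
    contamination simulations.
    """
    ref = resources.files("strchip.data").joinpath("synthetic_human_mm1s.yaml")
    return _profiles_from_doc(yaml.safe_load(ref.read_text()))["MM.1S"]
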