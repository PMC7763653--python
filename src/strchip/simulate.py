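"""Synthetic lab-on-chip electropherograms: ladder, sample and mixture wells.

A well's trace is fluorescence (FU) sampled on a uniform migration-time grid.
Fragments migrate with a log-mobility law

    t(size) = t0 + slope * log10(size_bp)

which is monotone and concave in size, and each fragment contributes a
Gaussian peak in the time domain whose height is proportional to its relative
amount.  Every well additionally carries the two internal alignment markers
(lower/upper, 15 and 1500 bp by default) injected with the sample, and i.i.d.
Gaussian baseline noise.  An optional PCR-stutter artifact places a shadow
peak one repeat unit below each fragment at a configurable fraction of its
height.

All randomness is drawn from ``numpy.random.default_rng(seed)`` with the seed
an explicit argument, so any trace is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .errors import TraceError
from .panel import Panel, predicted_size

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .genotype import STRProfile

Fragment = tuple[float, float]  # (size_bp, relative amount)


@dataclass
class Electropherogram:
    """A sampled fluorescence trace for one chip well."""

    time_s: np.ndarray
    fu: np.ndarray
    well_kind: str = "sample"  # "ladder" or "sample"
    label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fu = np.asarray(self.fu, dtype=float)
        if self.time_s.shape != self.fu.shape or self.time_s.ndim != 1:
            raise TraceError("time and fluorescence vectors must be equal-length 1-D")
        if self.time_s.size and not np.all(np.diff(self.time_s) > 0):
            raise TraceError("migration time must be strictly increasing")
        if not np.all(np.isfinite(self.fu)):
            raise TraceError("fluorescence values must be finite")

    def __len__(self) -> int:
        return self.time_s.size


class MigrationModel(BaseModel):
    """Parameters of the simulated chip run.

    ``t0``/``slope`` fix the log-mobility law (seconds, seconds per decade of
    bp); ``peak_sigma_s`` the Gaussian peak width; ``noise_sd_fu`` the
    baseline noise; ``stutter_fraction`` the relative height of the optional
    stutter shadow one repeat unit (``stutter_offset_bp``) below each
    fragment.  The remaining fields control the sampling grid and peak
    amplitudes.
    """

    model_config = {"frozen": True}

    t0: float = 10.0
    slope: float = Field(default=40.0, gt=0)
    peak_sigma_s: float = Field(default=0.08, gt=0)
    noise_sd_fu: float = Field(default=1.0, ge=0)
    stutter_fraction: float = Field(default=0.0, ge=0, lt=1)
    stutter_offset_bp: float = Field(default=4.0, gt=0)
    dt_s: float = Field(default=0.01, gt=0)
    peak_height_fu: float = Field(default=60.0, gt=0)
    marker_height_fu: float = Field(default=150.0, gt=0)
    pad_s: float = Field(default=2.0, ge=0)

    def migration_time(self, size_bp: float | np.ndarray) -> float | np.ndarray:
        """Peak-centre migration time for a fragment size."""
        return self.t0 + self.slope * np.log10(size_bp)


DEFAULT_MODEL = MigrationModel()


def amplicons_for_profile(
    panel: Panel, set_id: int, profile: "STRProfile"
) -> list[Fragment]:
    """PCR products expected for one multiplex set of a sample.

    Each distinct allele yields one fragment at its predicted size.  A locus
    with a single distinct allele contributes one fragment at double relative
    amount (both genome copies feed one product); two distinct alleles give
    two fragments at single amount each.  Loci of the set absent from the
    profile (e.g. the human sentinel in a murine sample) simply do not
    amplify.
    """
    fragments: list[Fragment] = []
    for locus in panel.set_loci(set_id):
        alleles = profile.alleles.get(locus.name, ())
        if not alleles:
            continue
        distinct = sorted(set(alleles))
        amount = 2.0 if len(distinct) == 1 else 1.0
        for rep in distinct:
            size = predicted_size(locus, rep)
            lo, hi = locus.size_range_bp
            if not lo <= size <= hi:
                raise TraceError(
                    f"allele {rep} of locus {locus.name} predicts {size} bp, "
                    f"outside its window [{lo}, {hi}]"
                )
            fragments.append((float(size), amount))
    return fragments


def simulate_trace(
    fragments: Sequence[Fragment],
    model: MigrationModel,
    seed: int,
    *,
    lower_marker_bp: float = 15.0,
    upper_marker_bp: float = 1500.0,
    well_kind: str = "sample",
    label: str = "",
) -> Electropherogram:
    """Render fragments plus the two internal markers into a noisy trace.

    Deterministic for a fixed seed.  Fragments of zero amount are dropped, so
    a mixture at fraction 0 or 1 reproduces the corresponding pure trace
    bit-for-bit under the same seed.
    """
    fragments = [(s, a) for s, a in fragments if a > 0]
    for size, _ in fragments:
        if not lower_marker_bp <= size <= upper_marker_bp:
            raise TraceError(
                f"fragment of {size} bp lies outside the internal-marker "
                f"bounds [{lower_marker_bp}, {upper_marker_bp}]"
            )
    t_lo = float(model.migration_time(lower_marker_bp))
    t_hi = float(model.migration_time(upper_marker_bp))
    n = int(round((t_hi - t_lo + 2 * model.pad_s) / model.dt_s)) + 1
    time = t_lo - model.pad_s + model.dt_s * np.arange(n)

    centers = [t_lo, t_hi]
    heights = [model.marker_height_fu, model.marker_height_fu]
    for size, amount in fragments:
        centers.append(float(model.migration_time(size)))
        heights.append(amount * model.peak_height_fu)
        if model.stutter_fraction > 0 and size - model.stutter_offset_bp > 0:
            centers.append(float(model.migration_time(size - model.stutter_offset_bp)))
            heights.append(amount * model.peak_height_fu * model.stutter_fraction)

    fu = np.zeros_like(time)
    for c, h in zip(centers, heights):
        fu += h * np.exp(-0.5 * ((time - c) / model.peak_sigma_s) ** 2)
    if model.noise_sd_fu > 0:
        rng = np.random.default_rng(seed)
        fu = fu + rng.normal(0.0, model.noise_sd_fu, size=fu.shape)
    return Electropherogram(time_s=time, fu=fu, well_kind=well_kind, label=label)


def simulate_ladder_trace(
    panel: Panel, model: MigrationModel, seed: int, label: str = "ladder"
) -> Electropherogram:
    """One ladder well: a unit-amount peak per rung plus both markers."""
    if not panel.ladder_sizes_bp:
        raise TraceError("panel defines an empty ladder")
    fragments = [(float(s), 1.0) for s in panel.ladder_sizes_bp]
    return simulate_trace(
        fragments,
        model,
        seed,
        lower_marker_bp=panel.lower_marker_bp,
        upper_marker_bp=panel.upper_marker_bp,
        well_kind="ladder",
        label=label,
    )


def simulate_sample_trace(
    panel: Panel,
    set_id: int,
    profile: "STRProfile",
    model: MigrationModel,
    seed: int,
    label: str = "",
) -> Electropherogram:
    """Convenience: amplicons for one multiplex set rendered into a trace."""
    fragments = amplicons_for_profile(panel, set_id, profile)
    return simulate_trace(
        fragments,
        model,
        seed,
        lower_marker_bp=panel.lower_marker_bp,
        upper_marker_bp=panel.upper_marker_bp,
        label=label or f"{profile.label}/set{set_id}",
    )


def simulate_mixture(
    panel: Panel,
    set_id: int,
    profile_a: "STRProfile",
    profile_b: "STRProfile",
    fraction_b: float,
    model: MigrationModel,
    seed: int,
    label: str = "",
) -> Electropherogram:
    """Two-genome mixture well: amounts scaled by (1-f) and f.

    Profiles may be of different species; a locus only amplifies from the
    profile that carries it, so the human sentinel appears only at the human
    genome's share.
    """
    if not 0.0 <= fraction_b <= 1.0:
        raise ValueError(f"fraction_b must be in [0, 1], got {fraction_b}")
    frags_a = amplicons_for_profile(panel, set_id, profile_a)
    frags_b = amplicons_for_profile(panel, set_id, profile_b)
    fragments = [(s, a * (1.0 - fraction_b)) for s, a in frags_a]
    fragments += [(s, a * fraction_b) for s, a in frags_b]
    return simulate_trace(
        fragments,
        model,
        seed,
        lower_marker_bp=panel.lower_marker_bp,
        upper_marker_bp=panel.upper_marker_bp,
        label=label or f"{profile_a.label}+{profile_b.label}@{fraction_b}/set{set_id}",
    )


def simulate_sample_wells(
    panel: Panel,
    profile: "STRProfile",
    model: MigrationModel,
    seed: int,
) -> tuple[Electropherogram, dict[int, Electropherogram]]:
    """One chip run for a sample: a ladder well plus one well per multiplex set.

    Per-well seeds are derived from ``seed`` so wells carry independent noise
    while the whole run stays reproducible.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=5)
    ladder = simulate_ladder_trace(panel, model, int(sub[0]))
    wells = {
        set_id: simulate_sample_trace(panel, set_id, profile, model, int(sub[i + 1]))
        for i, set_id in enumerate((1, 2, 3, 4))
    }
    return ladder, wells


# -- trace file I/O --------------------------------------------------------

def write_trace(path: str | Path, trace: Electropherogram) -> None:
    """Two-column TSV (time_s, fu) with a commented header carrying metadata."""
    header = f"well_kind: {trace.well_kind}\nlabel: {trace.label}\ntime_s\tfu"
    np.savetxt(
        path,
        np.column_stack([trace.time_s, trace.fu]),
        delimiter="\t",
        header=header,
        fmt="%.6f",
    )


def read_trace(path: str | Path) -> Electropherogram:
    well_kind, label = "sample", ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("well_kind:"):
                well_kind = body.split(":", 1)[1].strip()
            elif body.startswith("label:"):
                label = body.split(":", 1)[1].strip()
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim != 2 or data.shape[1] != 2:
        raise TraceError(f"trace file {path} is not a two-column table")
    return Electropherogram(
        time_s=data[:, 0], fu=data[:, 1], well_kind=well_kind, label=label
    )
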