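"""Profile comparison: identity matching, passage stability, contamination.

Match scoring follows the shared-allele statistics used in standard STR
authentication practice (the ASN-0002 convention for human lines):

    tanabe          = 2 * shared / (n_query + n_reference)
    masters_query   = shared / n_query
    masters_ref     = shared / n_reference

computed over loci called in both profiles, with the human sentinel locus
excluded from murine match scores.  The default verdict bands (match >= 0.8,
related >= 0.55) are the convention's; their transfer to murine panels is a
configuration choice, so both thresholds are explicit in every result.

Contamination checks come in two flavours: interspecies (the human sentinel
amplifies alongside murine loci in one sample) and intraspecies (a murine
profile carries more alleles than a single genome should — either loci with
more than two called alleles, or, when a reference database is supplied,
alleles beyond those of the best-covered reference line).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .errors import ProfileError
from .genotype import FLAG_EXTRA, STRProfile
from .panel import Panel, locus_for_size
from .traceproc import SizedPeak

MATCH_THRESHOLD = 0.8
RELATED_THRESHOLD = 0.55
DEFAULT_MIN_EXTRA_LOCI = 2

Algorithm = Literal["tanabe", "masters_query", "masters_ref"]


@dataclass(frozen=True)
class ComparisonResult:
    query_label: str
    reference_label: str
    per_locus_shared: dict[str, int]
    n_shared: int
    n_query_alleles: int
    n_ref_alleles: int
    score: float
    algorithm: str
    verdict: Literal["match", "related", "mismatch"]
    match_threshold: float = MATCH_THRESHOLD
    related_threshold: float = RELATED_THRESHOLD


@dataclass
class ContaminationReport:
    label: str
    interspecies_flag: bool = False
    intraspecies_flag: bool = False
    species: Literal["mouse", "human", "mixed", "unknown"] = "unknown"
    supporting_loci: list[str] = field(default_factory=list)
    secondary_profile: Optional[STRProfile] = None


def match_score(
    query: STRProfile,
    reference: STRProfile,
    algorithm: Algorithm = "tanabe",
    panel: Optional[Panel] = None,
    match_threshold: float = MATCH_THRESHOLD,
    related_threshold: float = RELATED_THRESHOLD,
) -> ComparisonResult:
    """Shared-allele match score between two profiles.

    Scored over loci called in both profiles; when a panel is given, only its
    murine loci are scored (the human sentinel never contributes to identity).
    Alleles count by distinct value (a single printed value counts once).
    """
    loci = [n for n in query.called_loci() if reference.alleles.get(n)]
    if panel is not None:
        murine = {loc.name for loc in panel.mouse_loci}
        loci = sorted(n for n in loci if n in murine)
    if not loci:
        raise ProfileError(
            f"profiles {query.label!r} and {reference.label!r} share no called loci"
        )
    per_locus = {}
    n_shared = n_q = n_r = 0
    for name in loci:
        q = Counter(query.alleles[name])
        r = Counter(reference.alleles[name])
        shared = sum((q & r).values())
        per_locus[name] = shared
        n_shared += shared
        n_q += sum(q.values())
        n_r += sum(r.values())
    if algorithm == "tanabe":
        score = 2.0 * n_shared / (n_q + n_r)
    elif algorithm == "masters_query":
        score = n_shared / n_q
    elif algorithm == "masters_ref":
        score = n_shared / n_r
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    verdict = (
        "match"
        if score >= match_threshold
        else "related" if score >= related_threshold else "mismatch"
    )
    return ComparisonResult(
        query_label=query.label,
        reference_label=reference.label,
        per_locus_shared=per_locus,
        n_shared=n_shared,
        n_query_alleles=n_q,
        n_ref_alleles=n_r,
        score=score,
        algorithm=algorithm,
        verdict=verdict,
        match_threshold=match_threshold,
        related_threshold=related_threshold,
    )


def authenticate_against_db(
    query: STRProfile,
    db: Sequence[STRProfile],
    algorithm: Algorithm = "tanabe",
    panel: Optional[Panel] = None,
    match_threshold: float = MATCH_THRESHOLD,
    related_threshold: float = RELATED_THRESHOLD,
) -> list[ComparisonResult]:
    """Rank a query against a reference database.

    Results sorted by descending score, ties broken by reference label; the
    first element carries the best verdict.
    """
    if not db:
        raise ProfileError("empty reference database")
    results = [
        match_score(
            query,
            ref,
            algorithm=algorithm,
            panel=panel,
            match_threshold=match_threshold,
            related_threshold=related_threshold,
        )
        for ref in db
    ]
    return sorted(results, key=lambda r: (-r.score, r.reference_label))


@dataclass(frozen=True)
class StabilityReport:
    label: str
    stable: bool
    n_profiles: int
    discordant_loci: tuple[str, ...]


def check_passage_stability(profiles: Sequence[STRProfile]) -> StabilityReport:
    """Are repeated profilings of one line (e.g. early/late passage, after
    cryo-recovery) identical at every commonly called locus?"""
    if len(profiles) < 2:
        raise ProfileError(
            f"stability check needs >=2 profiles, got {len(profiles)}"
        )
    discordant: set[str] = set()
    for i, a in enumerate(profiles):
        for b in profiles[i + 1 :]:
            for name in a.called_loci():
                if b.alleles.get(name) and a.alleles[name] != b.alleles[name]:
                    discordant.add(name)
    return StabilityReport(
        label=profiles[0].label,
        stable=not discordant,
        n_profiles=len(profiles),
        discordant_loci=tuple(sorted(discordant)),
    )


def detect_interspecies(
    data: STRProfile | Sequence[SizedPeak],
    panel: Panel,
    set_id: int = 2,
) -> ContaminationReport:
    """Flag human-in-mouse contamination from the sentinel locus.

    Accepts either a called profile or the sized peaks of a sentinel-bearing
    multiplex well.  The flag raises only when the human sentinel and at
    least one murine locus show signal together; a pure human sample is
    reported as human, not as contaminated.
    """
    if isinstance(data, STRProfile):
        murine, human = data.species_flags(panel)
        label = data.label
    else:
        murine = human = False
        label = ""
        for peak in data:
            if not peak.in_sizing_range:
                continue
            locus = locus_for_size(panel, set_id, peak.size_bp)
            if locus is None:
                continue
            if locus.species == "human":
                human = True
            else:
                murine = True
    species: str = "unknown"
    if murine and human:
        species = "mixed"
    elif murine:
        species = "mouse"
    elif human:
        species = "human"
    support = [loc.name for loc in panel.human_loci] if (murine and human) else []
    return ContaminationReport(
        label=label,
        interspecies_flag=murine and human,
        species=species,  # type: ignore[arg-type]
        supporting_loci=support,
    )


def detect_intraspecies(
    profile: STRProfile,
    min_extra_loci: int = DEFAULT_MIN_EXTRA_LOCI,
    reference_db: Optional[Sequence[STRProfile]] = None,
    panel: Optional[Panel] = None,
) -> ContaminationReport:
    """Flag mouse-in-mouse contamination from surplus alleles.

    Two sources of evidence count as supporting loci: loci whose calls carry
    the ``extra_allele`` flag (more than two peaks survived calling), and —
    when a reference database is supplied — loci where the profile holds
    alleles beyond those of the reference line that best covers it (highest
    masters_ref score).  The flag raises when at least ``min_extra_loci``
    loci support it; a clean single-source profile never raises.
    """
    support = {
        name
        for name, flags in profile.locus_flags.items()
        if FLAG_EXTRA in flags
    }
    secondary: Optional[STRProfile] = None
    if reference_db:
        best = authenticate_against_db(
            profile, reference_db, algorithm="masters_ref", panel=panel
        )[0]
        ref = next(p for p in reference_db if p.label == best.reference_label)
        extras: dict[str, set[int]] = {}
        for name in profile.called_loci():
            ref_alleles = ref.alleles.get(name)
            if ref_alleles and set(profile.alleles[name]) > set(ref_alleles):
                support.add(name)
                extras[name] = set(profile.alleles[name]) - set(ref_alleles)
        if extras:
            # Candidate contaminant: the other reference best covering the
            # surplus alleles.
            def coverage(p: STRProfile) -> tuple[int, int]:
                surplus = sum(
                    len(extras[n] & set(p.alleles.get(n, ()))) for n in extras
                )
                overall = sum(
                    len(set(profile.alleles[n]) & set(p.alleles.get(n, ())))
                    for n in profile.called_loci()
                )
                return surplus, overall

            others = [p for p in reference_db if p.label != ref.label]
            if others:
                secondary = max(others, key=coverage)
                if coverage(secondary)[0] == 0:
                    secondary = None
    flag = len(support) >= min_extra_loci
    return ContaminationReport(
        label=profile.label,
        intraspecies_flag=flag,
        species="mouse",
        supporting_loci=sorted(support),
        secondary_profile=secondary if flag else None,
    )
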