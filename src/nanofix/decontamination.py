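"""Viral decontamination and microbial dark-matter classification.

Two screens remove putative viral sequences: (a) the best reference-database
hit is annotated as a virus, and (b) any hit against a metavirome set reaches
>=80% identity with >=80% mutual alignment coverage.  Surviving sequences are
then binned by divergence from their best reference hit into two nested
tiers, proxies for novel lineages:

* **light dark matter** — best hit with mutual coverage > 80% and %ID < 90;
* **dark matter** — as above but %ID < 70 (dark ⊆ light dark matter).

Sequences with no reference hit, with a sub-coverage best hit, or whose best
hit carries an override taxonomy (CPR, DPANN, domain-only or unassigned
labels — likely bona fide ultrasmall prokaryotes) belong to both tiers
regardless of identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .io_model import AlignmentHit, TaxonAnnotation

LIGHT_DARK = "light_dark"
DARK = "dark"

#: Taxonomic labels that force assignment to both dark-matter tiers.
DEFAULT_OVERRIDE_GROUPS = frozenset(
    ("DPANN", "CPR", "unassigned_bacteria", "unassigned_archaea",
     "candidate", "unclassified")
)

VIRAL_MIN_IDENTITY = 80.0   # metavirome screen, inclusive
VIRAL_MIN_COVERAGE = 0.8    # metavirome screen, inclusive


def mutual_coverage(hit: AlignmentHit) -> float:
    """Smaller of query-side and subject-side alignment coverage, in [0, 1].

    Subject coordinates may be reversed; the span is ``|send - sstart| + 1``.
    """
    return min(hit.query_span / hit.qlen, hit.subject_span / hit.slen)


@dataclass(frozen=True, slots=True)
class DarkMatterCall:
    seq_id: str
    best_ref_hit: Optional[AlignmentHit]
    tier_membership: frozenset[str]
    reason: str

    def __post_init__(self) -> None:
        if DARK in self.tier_membership and LIGHT_DARK not in self.tier_membership:
            raise ValueError(f"{self.seq_id}: dark without light_dark")
        if self.reason == "known_similar" and self.tier_membership:
            raise ValueError(f"{self.seq_id}: known_similar must have empty membership")

    @property
    def is_dark(self) -> bool:
        return DARK in self.tier_membership

    @property
    def is_light_dark(self) -> bool:
        return LIGHT_DARK in self.tier_membership


def flag_viral(
    seq_id: str,
    best_ref_hit: Optional[AlignmentHit],
    viral_hits: Iterable[AlignmentHit] = (),
    taxonomy: Mapping[str, TaxonAnnotation] | None = None,
    min_identity: float = VIRAL_MIN_IDENTITY,
    min_coverage: float = VIRAL_MIN_COVERAGE,
) -> tuple[bool, Optional[str]]:
    """Return (flagged, reason) for the two viral screens.

    Screen (a) consults the best reference hit's taxonomic group; screen (b)
    fires on *any* metavirome hit with identity and mutual coverage at or
    above the thresholds.  A sequence absent from both hit sets is clean.
    """
    taxonomy = taxonomy or {}
    if best_ref_hit is not None:
        ann = taxonomy.get(best_ref_hit.subject_id)
        if ann is not None and ann.group == "viruses":
            return True, "best_ref_hit_viral"
    for hit in viral_hits:
        if hit.pct_identity >= min_identity and mutual_coverage(hit) >= min_coverage:
            return True, "metavirome_match"
    return False, None


def classify_dark_matter(
    seq_id: str,
    best_ref_hit: Optional[AlignmentHit],
    taxonomy: Mapping[str, TaxonAnnotation] | None = None,
    override_groups: frozenset[str] = DEFAULT_OVERRIDE_GROUPS,
    strict_coverage: bool = False,
    min_coverage: float = 0.8,
) -> DarkMatterCall:
    """Classify one sequence into the nested dark-matter tiers.

    ``best_ref_hit`` must be the tie-broken best reference hit, or ``None``
    when the sequence had no reference hit at all.  The %ID boundaries are
    strict as printed (<90 light dark matter, <70 dark matter), so a best hit
    at exactly 70.0% identity falls in light dark matter only.

    A best hit with mutual coverage <= ``min_coverage`` carries insufficient
    evidence of similarity; by default such sequences join both tiers, while
    ``strict_coverage=True`` excludes them from both instead.
    """
    taxonomy = taxonomy or {}
    both = frozenset((LIGHT_DARK, DARK))
    if best_ref_hit is None:
        return DarkMatterCall(seq_id, None, both, "no_hit")
    ann = taxonomy.get(best_ref_hit.subject_id)
    if ann is not None and ann.group in override_groups:
        return DarkMatterCall(seq_id, best_ref_hit, both, "override_taxon")
    if mutual_coverage(best_ref_hit) <= min_coverage:
        membership = frozenset() if strict_coverage else both
        return DarkMatterCall(seq_id, best_ref_hit, membership, "low_coverage")
    pid = best_ref_hit.pct_identity
    if pid < 70.0:
        return DarkMatterCall(seq_id, best_ref_hit, both, "low_identity_lt70")
    if pid < 90.0:
        return DarkMatterCall(
            seq_id, best_ref_hit, frozenset((LIGHT_DARK,)), "identity_70_to_90"
        )
    return DarkMatterCall(seq_id, best_ref_hit, frozenset(), "known_similar")


def write_calls(
    calls: Mapping[str, DarkMatterCall],
    viral_flags: Mapping[str, tuple[bool, Optional[str]]],
    path,
) -> None:
    """Per-sequence call table: seq_id, viral flag, tiers, reason."""
    with open(path, "w") as fh:
        fh.write("seq_id\tviral\tviral_reason\ttiers\treason\n")
        for seq_id in sorted(set(calls) | set(viral_flags)):
            viral, vreason = viral_flags.get(seq_id, (False, None))
            call = calls.get(seq_id)
            tiers = ",".join(sorted(call.tier_membership)) if call else ""
            reason = call.reason if call else ""
            fh.write(f"{seq_id}\t{int(viral)}\t{vreason or ''}\t{tiers}\t{reason}\n")
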