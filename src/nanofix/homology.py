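"""KO homolog assignment and per-(site, depth, dataset) KO presence sets.

Environmental sequences are assigned KEGG Orthology (KO) terms from tabular
alignments against KEGG pathway proteins, with the homology criteria
%ID > 25, E-value < 1e-5 and mutual alignment coverage > 70% — all strict,
as printed.  A sequence may support several KOs (paralog ambiguity);
presence/absence downstream is robust to that, so KO sets simply union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .decontamination import DARK, LIGHT_DARK, DarkMatterCall, mutual_coverage
from .io_model import AlignmentHit, SequenceMeta

logger = logging.getLogger(__name__)

MIN_IDENTITY = 25.0     # strict: pct_identity must exceed this
MAX_EVALUE = 1e-5       # strict: evalue must be below this
MIN_COVERAGE = 0.7      # strict: mutual coverage must exceed this

POOL_SITE = "pool"
POOL_DEPTH = "ALL"


@dataclass(frozen=True, slots=True)
class DatasetLabel:
    """One dataset stringency: a cluster tier plus a divergence cut."""

    tier: str                      # PU | UO | WUO
    divergence: str = "all"        # all | light_dark | dark

    def __post_init__(self) -> None:
        if self.tier not in ("PU", "UO", "WUO"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.divergence not in ("all", LIGHT_DARK, DARK):
            raise ValueError(f"unknown divergence {self.divergence!r}")

    def __str__(self) -> str:
        if self.divergence == "all":
            return self.tier
        suffix = "ld" if self.divergence == LIGHT_DARK else "dm"
        return f"{self.tier}_{suffix}"

    @classmethod
    def parse(cls, label: str) -> "DatasetLabel":
        tier, _, suffix = label.partition("_")
        divergence = {"": "all", "ld": LIGHT_DARK, "dm": DARK}.get(suffix)
        if divergence is None:
            raise ValueError(f"unknown dataset label {label!r}")
        return cls(tier, divergence)


#: The seven standard stringencies, least to most stringent: the full PU set,
#: then the six filtered datasets analysed per site.
STANDARD_DATASETS: tuple[DatasetLabel, ...] = (
    DatasetLabel("PU"),
    DatasetLabel("UO"),
    DatasetLabel("UO", LIGHT_DARK),
    DatasetLabel("UO", DARK),
    DatasetLabel("WUO"),
    DatasetLabel("WUO", LIGHT_DARK),
    DatasetLabel("WUO", DARK),
)

#: The six filtered datasets compared against PU in enrichment tests.
FILTERED_DATASETS: tuple[DatasetLabel, ...] = STANDARD_DATASETS[1:]


def best_hit(hits: Sequence[AlignmentHit]) -> Optional[AlignmentHit]:
    """Best hit for one query: max bitscore, ties by lower E-value, then
    higher %identity, then lexicographically smallest subject id.

    Empty input returns ``None`` (absence is a signal, not an error).
    """
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id))


def group_by_query(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def best_hits_by_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    return {q: best_hit(hs) for q, hs in group_by_query(hits).items()}


@dataclass(frozen=True, slots=True)
class KOAssignment:
    seq_id: str
    ko_ids: frozenset[str]
    supporting_hits: tuple[tuple[str, AlignmentHit], ...]  # (ko, best supporting hit)

    def hit_for(self, ko: str) -> AlignmentHit:
        for k, h in self.supporting_hits:
            if k == ko:
                return h
        raise KeyError(ko)


def hit_passes(
    hit: AlignmentHit,
    min_identity: float = MIN_IDENTITY,
    max_evalue: float = MAX_EVALUE,
    min_coverage: float = MIN_COVERAGE,
) -> bool:
    """Homology criterion: all three thresholds, strictly."""
    return (
        hit.pct_identity > min_identity
        and hit.evalue < max_evalue
        and mutual_coverage(hit) > min_coverage
    )


def filter_homologs(
    hits: Iterable[AlignmentHit],
    ko_map: Mapping[str, str],
    min_identity: float = MIN_IDENTITY,
    max_evalue: float = MAX_EVALUE,
    min_coverage: float = MIN_COVERAGE,
) -> tuple[list[KOAssignment], int]:
    """Assign KOs to query sequences from hits passing all three thresholds.

    Returns the assignments (sorted by seq_id) and the number of hits skipped
    because their subject did not resolve to a KO (also logged as a warning).
    """
    supporters: dict[str, dict[str, list[AlignmentHit]]] = {}
    n_unresolved = 0
    for hit in hits:
        ko = ko_map.get(hit.subject_id)
        if ko is None:
            n_unresolved += 1
            continue
        if hit_passes(hit, min_identity, max_evalue, min_coverage):
            supporters.setdefault(hit.query_id, {}).setdefault(ko, []).append(hit)
    if n_unresolved:
        logger.warning("%d hits skipped: subject not resolvable to a KO", n_unresolved)
    assignments = []
    for seq_id in sorted(supporters):
        per_ko = supporters[seq_id]
        best_per_ko = tuple((ko, best_hit(per_ko[ko])) for ko in sorted(per_ko))
        assignments.append(
            KOAssignment(seq_id, frozenset(per_ko), best_per_ko)
        )
    return assignments, n_unresolved


@dataclass(frozen=True, slots=True)
class KOPresence:
    key: tuple[str, str, str]   # (site_id, depth, dataset label)
    kos: frozenset[str]
    n_sequences: int


def sequence_datasets(
    meta: SequenceMeta,
    cluster_tiers: Mapping[str, frozenset[str]],
    dark_call: Optional[DarkMatterCall],
    viral: bool,
    datasets: Sequence[DatasetLabel] = STANDARD_DATASETS,
    ultrasmall_only: bool = True,
    drop_viral: bool = True,
) -> list[DatasetLabel]:
    """Datasets one sequence belongs to: tier via its cluster's labels,
    divergence via its dark-matter call; viral sequences drop out unless
    ``drop_viral`` is off (used when profiling pre-removal composition)."""
    if drop_viral and viral:
        return []
    if ultrasmall_only and meta.size_fraction != "ultrasmall":
        return []
    out = []
    for ds in datasets:
        if meta.cluster_id not in cluster_tiers.get(ds.tier, frozenset()):
            continue
        if ds.divergence != "all":
            if dark_call is None or ds.divergence not in dark_call.tier_membership:
                continue
        out.append(ds)
    return out


def ko_presence(
    assignments: Iterable[KOAssignment],
    meta: Iterable[SequenceMeta],
    cluster_tiers: Mapping[str, frozenset[str]],
    dark_calls: Mapping[str, DarkMatterCall],
    viral_flags: Mapping[str, bool] | None = None,
    datasets: Sequence[DatasetLabel] = STANDARD_DATASETS,
    ultrasmall_only: bool = True,
) -> dict[tuple[str, str, str], KOPresence]:
    """Union KO sets per (site, depth, dataset) key, plus pool keys.

    The pool key ``("pool", "ALL", dataset)`` unions all sites for each
    dataset; every (site, depth) observed in the metadata gets a key for
    every dataset, empty sets included, so downstream completeness grids are
    total.
    """
    viral_flags = viral_flags or {}
    meta_by_id = {m.seq_id: m for m in meta}
    kos_by_key: dict[tuple[str, str, str], set[str]] = {}
    seqs_by_key: dict[tuple[str, str, str], set[str]] = {}
    site_depths = sorted({(m.site_id, m.depth) for m in meta_by_id.values()})
    for site, depth in site_depths + [(POOL_SITE, POOL_DEPTH)]:
        for ds in datasets:
            key = (site, depth, str(ds))
            kos_by_key[key] = set()
            seqs_by_key[key] = set()
    for a in assignments:
        m = meta_by_id.get(a.seq_id)
        if m is None:
            raise KeyError(f"assignment for unknown sequence {a.seq_id!r}")
        member_of = sequence_datasets(
            m, cluster_tiers, dark_calls.get(a.seq_id),
            viral_flags.get(a.seq_id, False), datasets, ultrasmall_only,
        )
        for ds in member_of:
            for key in ((m.site_id, m.depth, str(ds)), (POOL_SITE, POOL_DEPTH, str(ds))):
                kos_by_key[key] |= a.ko_ids
                seqs_by_key[key].add(a.seq_id)
    return {
        key: KOPresence(key, frozenset(kos_by_key[key]), len(seqs_by_key[key]))
        for key in kos_by_key
    }


def write_presence(presence: Mapping[tuple[str, str, str], KOPresence], path) -> None:
    """Serialize presence sets as TSV (site, depth, dataset, KO)."""
    with open(path, "w") as fh:
        fh.write("site_id\tdepth\tdataset\tko_id\n")
        for key in sorted(presence):
            site, depth, ds = key
            for ko in sorted(presence[key].kos):
                fh.write(f"{site}\t{depth}\t{ds}\t{ko}\n")
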