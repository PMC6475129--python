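"""Nested size-fraction dataset filtration (PU / UO / WUO).

Cluster-level selection over CD-HIT-style similarity clusters:

* **PU** ("Potentially Ultrasmall") — clusters with at least one member
  sequenced from the ultrasmall (<0.22 µm) size fraction;
* **UO** ("Ultrasmall Only") — PU clusters whose members come exclusively
  from the ultrasmall fraction;
* **WUO** ("Widespread Ultrasmall Only") — UO clusters whose ultrasmall
  members occur at two or more distinct sampling sites (site identity
  ignores depth; station ids such as "038" index stations).

Membership is decided per cluster, but the downstream *sequence* sets are,
by default, the ultrasmall-fraction members of the selected clusters; the
all-members variant is exposed as well because PU clusters may contain
other-fraction sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io_model import SequenceMeta

TIERS = ("PU", "UO", "WUO")


@dataclass(frozen=True, slots=True)
class ClusterProfile:
    """Size-fraction and site profile of one similarity cluster."""

    cluster_id: str
    fractions_present: frozenset[str]
    ultrasmall_sites: frozenset[str]
    member_seq_ids: frozenset[str]
    ultrasmall_seq_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.fractions_present:
            raise ValueError(f"cluster {self.cluster_id}: no fractions present")
        has_ultra = "ultrasmall" in self.fractions_present
        if has_ultra != bool(self.ultrasmall_sites):
            raise ValueError(
                f"cluster {self.cluster_id}: ultrasmall_sites inconsistent with fractions"
            )


def profile_clusters(meta: Iterable[SequenceMeta]) -> dict[str, ClusterProfile]:
    """Aggregate per-sequence metadata into one profile per cluster.

    Deterministic regardless of input row order (profiles are keyed and all
    member sets are order-free); empty input yields an empty mapping.
    """
    fractions: dict[str, set[str]] = {}
    ultra_sites: dict[str, set[str]] = {}
    members: dict[str, set[str]] = {}
    ultra_members: dict[str, set[str]] = {}
    for rec in meta:
        cid = rec.cluster_id
        fractions.setdefault(cid, set()).add(rec.size_fraction)
        members.setdefault(cid, set()).add(rec.seq_id)
        ultra_sites.setdefault(cid, set())
        ultra_members.setdefault(cid, set())
        if rec.size_fraction == "ultrasmall":
            ultra_sites[cid].add(rec.site_id)
            ultra_members[cid].add(rec.seq_id)
    return {
        cid: ClusterProfile(
            cluster_id=cid,
            fractions_present=frozenset(fractions[cid]),
            ultrasmall_sites=frozenset(ultra_sites[cid]),
            member_seq_ids=frozenset(members[cid]),
            ultrasmall_seq_ids=frozenset(ultra_members[cid]),
        )
        for cid in sorted(fractions)
    }


def select_datasets(profiles: Mapping[str, ClusterProfile]) -> dict[str, frozenset[str]]:
    """Assign clusters to the nested PU ⊇ UO ⊇ WUO tiers."""
    pu = {c for c, p in profiles.items() if "ultrasmall" in p.fractions_present}
    uo = {c for c in pu if profiles[c].fractions_present == frozenset(("ultrasmall",))}
    wuo = {c for c in uo if len(profiles[c].ultrasmall_sites) >= 2}
    return {"PU": frozenset(pu), "UO": frozenset(uo), "WUO": frozenset(wuo)}


def dataset_sequences(
    profiles: Mapping[str, ClusterProfile],
    tiers: Mapping[str, frozenset[str]],
    ultrasmall_only: bool = True,
) -> dict[str, frozenset[str]]:
    """Sequence-level dataset membership for each tier.

    With ``ultrasmall_only`` (default) only ultrasmall-fraction members of the
    selected clusters are counted; otherwise all members are (the two differ
    for PU only, since UO/WUO clusters have no other-fraction members).
    """
    out: dict[str, frozenset[str]] = {}
    for tier, clusters in tiers.items():
        seqs: set[str] = set()
        for cid in clusters:
            p = profiles[cid]
            seqs |= p.ultrasmall_seq_ids if ultrasmall_only else p.member_seq_ids
        out[tier] = frozenset(seqs)
    return out


def write_dataset_table(tiers: Mapping[str, frozenset[str]], path) -> None:
    """Emit a ``cluster_id<TAB>tier`` table, one row per (cluster, tier)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\ttier\n")
        for tier in TIERS:
            for cid in sorted(tiers.get(tier, ())):
                fh.write(f"{cid}\t{tier}\n")
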