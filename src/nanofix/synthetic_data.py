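"""Synthetic input bundles with planted ground truth.

The pipeline's contracts consume *hit tables*, not raw sequences, so the
generator fabricates alignment records directly instead of simulating
proteins and running an aligner: every planted (sequence, subject) pair gets
a percent identity drawn from its class distribution, with coverage,
bitscore and E-value made consistent with it (E-value is a deterministic
monotone function of bitscore and lengths; only its ordering and the 1e-5
threshold crossing matter downstream).

Four planted cluster classes emulate what the real size-fraction data
contains:

* ``novel_ultrasmall`` — ultrasmall-only clusters from undescribed lineages;
  reference identities default to Uniform(45, 68)% (dark matter), a fraction
  have no reference hit at all, and about half are widespread (>= 2 sites);
* ``known_regular`` — ultrasmall-only clusters highly similar (92-99%) to
  known organisms: UO members but contamination, excluded from dark tiers;
* ``viral`` — clusters removed by either viral screen (virus-annotated best
  reference hit, or a metavirome match at >= 80% identity / coverage);
* ``shared_fraction`` — clusters that also occur in larger size fractions,
  hence PU but never UO.

Per-site KO repertoires are planted on widespread dark-matter carrier
sequences by emitting qualifying hits against KEGG-protein subject ids, with
each pathway's target completeness realised exactly as a prefix of its
module list; the planted truth is therefore identical across dataset
stringencies at a site, and the pool row equals the per-site maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import (
    AlignmentHit,
    ModuleDefinition,
    PathwaySpec,
    SequenceMeta,
    TaxonAnnotation,
    read_hits,
    read_ko_map,
    read_module_definitions,
    read_sequence_meta,
    read_taxonomy,
    write_hits,
    write_ko_map,
    write_module_definitions,
    write_sequence_meta,
    write_taxonomy,
)
from .io_model import And, KOAtom, Or
from .homology import POOL_DEPTH, POOL_SITE, STANDARD_DATASETS

CLASSES = ("novel_ultrasmall", "known_regular", "viral", "shared_fraction")

DEFAULT_SITES = (("037", "MES"), ("038", "MES"), ("039", "SRF"),
                 ("065", "DCM"), ("122", "SRF"))

#: Per-site target completeness fractions for the six pathways (feasible
#: exactly given the default module counts: CBB 5, rTCA 4, HBC 4, WL 4,
#: DH 5, HB 4).
DEFAULT_PLANTED = {
    ("037", "CBB"): 1.0, ("037", "rTCA"): 0.75, ("037", "HBC"): 0.5,
    ("037", "WL"): 0.75, ("037", "DH"): 1.0, ("037", "HB"): 0.75,
    ("038", "CBB"): 0.8, ("038", "rTCA"): 1.0, ("038", "HBC"): 1.0,
    ("038", "WL"): 0.5, ("038", "DH"): 0.8, ("038", "HB"): 0.5,
    ("039", "CBB"): 0.6, ("039", "rTCA"): 0.5, ("039", "HBC"): 0.25,
    ("039", "WL"): 0.0, ("039", "DH"): 0.6, ("039", "HB"): 0.25,
    ("065", "CBB"): 0.4, ("065", "rTCA"): 0.0, ("065", "HBC"): 0.0,
    ("065", "WL"): 0.25, ("065", "DH"): 0.2, ("065", "HB"): 0.0,
    ("122", "CBB"): 0.2, ("122", "rTCA"): 0.25, ("122", "HBC"): 0.0,
    ("122", "WL"): 0.0, ("122", "DH"): 0.4, ("122", "HB"): 1.0,
}

_DEFAULT_MODULE_TABLE = [
    ("CBB", "CBB_m1", "*K01100 K01101"),
    ("CBB", "CBB_m2", "K01110,K01111"),
    ("CBB", "CBB_m3", "K01120 (K01121,K01122)"),
    ("CBB", "CBB_m4", "K01130"),
    ("CBB", "CBB_m5", "K01140 -K01199"),
    ("rTCA", "rTCA_m1", "*K01200"),
    ("rTCA", "rTCA_m2", "K01210,K01211"),
    ("rTCA", "rTCA_m3", "K01220"),
    ("rTCA", "rTCA_m4", "K01230 K01231"),
    ("HBC", "HBC_m1", "*K01300 -K01399"),
    ("HBC", "HBC_m2", "K01310"),
    ("HBC", "HBC_m3", "K01320,K01321"),
    ("HBC", "HBC_m4", "K01330"),
    ("WL", "WL_m1", "*K01400"),
    ("WL", "WL_m2", "K01410 K01411"),
    ("WL", "WL_m3", "K01420,K01421"),
    ("WL", "WL_m4", "K01430"),
    ("DH", "DH_m1", "*K01500"),
    ("DH", "DH_m2", "K01510"),
    ("DH", "DH_m3", "K01520,K01521"),
    ("DH", "DH_m4", "K01530 K01531"),
    ("DH", "DH_m5", "K01540"),
    ("HB", "HB_m1", "*K01600"),
    ("HB", "HB_m2", "K01610"),
    ("HB", "HB_m3", "K01620,K01621"),
    ("HB", "HB_m4", "K01630"),
]

_NOVEL_GROUP_PROBS = {
    "known_bacteria": 0.35, "CPR": 0.20, "unassigned_bacteria": 0.15,
    "DPANN": 0.10, "known_archaea": 0.10, "unassigned_archaea": 0.05,
    "known_eukaryota": 0.05,
}
_KNOWN_GROUP_PROBS = {"known_bacteria": 0.8, "known_archaea": 0.1,
                      "known_eukaryota": 0.1}


class ConfigError(ValueError):
    """A synthetic configuration is internally infeasible."""


def default_pathways() -> list[PathwaySpec]:
    """The six carbon-fixation pathway stand-ins used by default bundles.

    Module counts and boolean shapes (AND chains, OR alternatives, one key
    enzyme in the first module, a couple of optional enzymes) mimic the
    KEGG-derived logic; KO identifiers are fabricated in disjoint blocks so
    pathways never share enzymes.
    """
    grouped: dict[str, list[ModuleDefinition]] = {}
    order: list[str] = []
    for pathway_id, module_id, definition in _DEFAULT_MODULE_TABLE:
        if pathway_id not in grouped:
            grouped[pathway_id] = []
            order.append(pathway_id)
        grouped[pathway_id].append(ModuleDefinition.from_string(module_id, definition))
    return [PathwaySpec(pid, tuple(grouped[pid])) for pid in order]


def satisfying_kos(module: ModuleDefinition) -> frozenset[str]:
    """A deterministic minimal-ish KO set satisfying the module expression
    (first alternative of every OR)."""

    def walk(expr) -> frozenset[str]:
        if isinstance(expr, KOAtom):
            return frozenset((expr.ko,))
        if isinstance(expr, Or):
            return walk(expr.terms[0])
        if isinstance(expr, And):
            return frozenset().union(*(walk(t) for t in expr.terms))
        raise TypeError(type(expr))

    return walk(module.expression)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic bundle (defaults = the conditions
    every recovery test runs under: 5 sites, ~600 clusters / ~2,000
    sequences, the six default pathways, noise-free)."""

    seed: int = 0
    sites: tuple[tuple[str, str], ...] = DEFAULT_SITES
    n_clusters: int = 600
    class_mixture: tuple[tuple[str, float], ...] = (
        ("novel_ultrasmall", 0.6), ("known_regular", 0.2),
        ("viral", 0.1), ("shared_fraction", 0.1),
    )
    p_widespread_novel: float = 0.5
    p_widespread_known: float = 0.3
    members_lambda: float = 0.8          # members per site ~ 1 + Poisson
    identity_novel: tuple[float, float] = (45.0, 68.0)
    identity_known: tuple[float, float] = (92.0, 99.0)
    identity_shared: tuple[float, float] = (70.0, 95.0)
    identity_viral: tuple[float, float] = (85.0, 99.0)
    p_no_hit_novel: float = 0.25
    p_extra_hit: float = 0.3
    coverage_range: tuple[float, float] = (0.82, 0.98)
    kegg_identity: tuple[float, float] = (30.0, 60.0)
    kegg_coverage: tuple[float, float] = (0.75, 0.95)
    identity_noise: float = 0.0          # P(redraw identity ~ U(30, 99))
    carriers_per_ko: int = 2
    planted_completeness: tuple[tuple[tuple[str, str], float], ...] = tuple(
        sorted(DEFAULT_PLANTED.items())
    )
    reads_lognormal: tuple[float, float] = (16.0, 0.4)
    coverage_gamma: tuple[float, float] = (2.0, 5.0)

    def mixture(self) -> dict[str, float]:
        mix = dict(self.class_mixture)
        total = sum(mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"class mixture sums to {total}, not 1")
        unknown = set(mix) - set(CLASSES)
        if unknown:
            raise ConfigError(f"unknown class(es) {sorted(unknown)}")
        return mix

    def planted(self) -> dict[tuple[str, str], float]:
        planted = dict(self.planted_completeness)
        for (site, pw), frac in planted.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"planted completeness for {pw} at {site} "
                                  f"outside [0,1]: {frac}")
        return planted


@dataclass
class Bundle:
    """One complete set of pipeline inputs, in memory."""

    meta: list[SequenceMeta]
    nr_hits: list[AlignmentHit]
    virome_hits: list[AlignmentHit]
    kegg_hits: list[AlignmentHit]
    taxonomy: dict[str, TaxonAnnotation]
    pathways: list[PathwaySpec]
    ko_map: dict[str, str]
    effort: dict[tuple[str, str], tuple[int, int, int, float]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sequence_meta(self.meta, outdir / "meta.tsv")
        write_hits(self.nr_hits, outdir / "nr_hits.tsv")
        write_hits(self.virome_hits, outdir / "virome_hits.tsv")
        write_hits(self.kegg_hits, outdir / "kegg_hits.tsv")
        write_taxonomy(self.taxonomy, outdir / "tax.tsv")
        write_module_definitions(self.pathways, outdir / "modules.tsv")
        write_ko_map(self.ko_map, outdir / "ko_map.tsv")
        with open(outdir / "effort.tsv", "w") as fh:
            fh.write("site_id\tdepth\tn_reads\tn_hq_reads\tn_predicted_genes"
                     "\tavg_read_cov_per_protein\n")
            for (site, depth) in sorted(self.effort):
                reads, hq, genes, cov = self.effort[(site, depth)]
                fh.write(f"{site}\t{depth}\t{reads}\t{hq}\t{genes}\t{cov:.4f}\n")

    @classmethod
    def read(cls, indir) -> "Bundle":
        indir = Path(indir)
        effort: dict[tuple[str, str], tuple[int, int, int, float]] = {}
        effort_path = indir / "effort.tsv"
        if effort_path.exists():
            with open(effort_path) as fh:
                next(fh)
                for line in fh:
                    site, depth, reads, hq, genes, cov = line.rstrip("\n").split("\t")
                    effort[(site, depth)] = (int(reads), int(hq), int(genes), float(cov))
        return cls(
            meta=read_sequence_meta(indir / "meta.tsv"),
            nr_hits=read_hits(indir / "nr_hits.tsv"),
            virome_hits=read_hits(indir / "virome_hits.tsv"),
            kegg_hits=read_hits(indir / "kegg_hits.tsv"),
            taxonomy=read_taxonomy(indir / "tax.tsv"),
            pathways=read_module_definitions(indir / "modules.tsv"),
            ko_map=read_ko_map(indir / "ko_map.tsv"),
            effort=effort,
        )


@dataclass
class SyntheticTruth:
    """Planted labels and repertoires, internally consistent with the bundle."""

    cluster_class: dict[str, str]
    cluster_tiers: dict[str, frozenset[str]]
    viral_seqs: frozenset[str]
    divergence: dict[str, frozenset[str]]        # seq -> subset of {light_dark, dark}
    seq_group: dict[str, str]                    # best-hit taxonomic group
    ko_sets: dict[tuple[str, str, str], frozenset[str]]
    completeness: dict[tuple[str, str, str, str], float]  # (site, depth, ds, pathway)

    def to_json(self, path) -> None:
        payload = {
            "cluster_class": self.cluster_class,
            "cluster_tiers": {c: sorted(t) for c, t in self.cluster_tiers.items()},
            "viral_seqs": sorted(self.viral_seqs),
            "divergence": {s: sorted(d) for s, d in self.divergence.items()},
            "seq_group": self.seq_group,
            "ko_sets": {"|".join(k): sorted(v) for k, v in self.ko_sets.items()},
            "completeness": {"|".join(k): v for k, v in self.completeness.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cluster_class=d["cluster_class"],
            cluster_tiers={c: frozenset(t) for c, t in d["cluster_tiers"].items()},
            viral_seqs=frozenset(d["viral_seqs"]),
            divergence={s: frozenset(v) for s, v in d["divergence"].items()},
            seq_group=d["seq_group"],
            ko_sets={tuple(k.split("|")): frozenset(v)
                     for k, v in d["ko_sets"].items()},
            completeness={tuple(k.split("|")): v
                          for k, v in d["completeness"].items()},
        )


def _make_hit(rng, query_id, subject_id, qlen, pident, coverage, scale=1.0,
              slen=None) -> AlignmentHit:
    """Fabricate one alignment consistent with (identity, mutual coverage).

    qstart is pinned to 1 and the subject span mirrors the query span, so the
    realised mutual coverage is ``round(coverage*qlen)/qlen`` — within 1/(2
    qlen) of the requested value, which the class distributions keep clear of
    every decision boundary.  ``scale`` < 1 produces a deliberately weaker
    secondary hit (lower bitscore, higher E-value) for best-hit tie-breaking.
    """
    slen = int(slen if slen is not None else qlen)
    span = max(1, min(qlen, round(coverage * qlen)))
    sspan = max(1, min(slen, span))
    aln_len = span
    mismatches = round(aln_len * (1 - pident / 100.0))
    bitscore = round(scale * max(40.0, 2.0 * aln_len * pident / 100.0), 1)
    evalue = min(10.0, max(1e-180, qlen * slen * 2.0 ** (-bitscore)))
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        pct_identity=round(pident, 2), aln_len=aln_len,
        mismatches=mismatches, gap_opens=0,
        qstart=1, qend=span, sstart=1, send=sspan,
        evalue=evalue, bitscore=bitscore, qlen=qlen, slen=slen,
    )


def _choice(rng, probs: Mapping[str, float]) -> str:
    keys = sorted(probs)
    weights = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def generate(config: SynthConfig) -> tuple[Bundle, SyntheticTruth]:
    """Generate a complete input bundle plus its planted truth.

    Deterministic for a fixed config (same seed -> byte-identical files).
    Raises :class:`ConfigError` when a planted completeness fraction is not
    an exact multiple of 1/n_modules for its pathway, or when planting is
    requested with fewer than two sites (widespread carriers need two).
    """
    rng = np.random.default_rng(config.seed)
    mixture = config.mixture()
    planted = config.planted()
    pathways = default_pathways()
    pathway_by_id = {p.pathway_id: p for p in pathways}
    sites = list(config.sites)
    site_ids = [s for s, _ in sites]
    depth_of = dict(sites)
    if len(set(site_ids)) != len(site_ids):
        raise ConfigError("duplicate site ids")

    planted_modules: dict[tuple[str, str], int] = {}
    for (site, pw), frac in sorted(planted.items()):
        spec = pathway_by_id.get(pw)
        if spec is None:
            raise ConfigError(f"planted completeness names unknown pathway {pw!r}")
        if site not in depth_of:
            raise ConfigError(f"planted completeness names unknown site {site!r}")
        k = frac * len(spec.modules)
        if abs(k - round(k)) > 1e-9:
            raise ConfigError(
                f"planted completeness {frac} infeasible for pathway {pw} "
                f"({len(spec.modules)} modules)"
            )
        planted_modules[(site, pw)] = int(round(k))
    if any(k > 0 for k in planted_modules.values()) and len(sites) < 2:
        raise ConfigError("planting KO repertoires requires at least two sites")

    # --- cluster skeletons -------------------------------------------------
    n_per_class = {
        cls: int(round(config.n_clusters * mixture.get(cls, 0.0))) for cls in CLASSES
    }
    drift = config.n_clusters - sum(n_per_class.values())
    n_per_class["novel_ultrasmall"] += drift

    meta: list[SequenceMeta] = []
    nr_hits: list[AlignmentHit] = []
    virome_hits: list[AlignmentHit] = []
    taxonomy: dict[str, TaxonAnnotation] = {}
    cluster_class: dict[str, str] = {}
    seq_class: dict[str, str] = {}
    seq_best_nr: dict[str, AlignmentHit] = {}
    seq_group: dict[str, str] = {}
    nr_counter = 0
    vir_counter = 0

    def new_subject(group: str) -> str:
        nonlocal nr_counter
        subject = f"nr{nr_counter:06d}"
        nr_counter += 1
        taxonomy[subject] = TaxonAnnotation(subject, group, ("root", group))
        return subject

    def draw_identity(lo: float, hi: float) -> float:
        pid = rng.uniform(lo, hi)
        if config.identity_noise > 0 and rng.random() < config.identity_noise:
            pid = rng.uniform(30.0, 99.0)
        return pid

    def emit_nr(seq: SequenceMeta, pident: float, group: str) -> None:
        cov = rng.uniform(*config.coverage_range)
        subject = new_subject(group)
        best = _make_hit(rng, seq.seq_id, subject, seq.length_aa, pident, cov)
        nr_hits.append(best)
        seq_best_nr[seq.seq_id] = best
        seq_group[seq.seq_id] = group
        if rng.random() < config.p_extra_hit:
            weaker = _make_hit(
                rng, seq.seq_id, new_subject(group), seq.length_aa,
                pident * rng.uniform(0.6, 0.9),
                rng.uniform(*config.coverage_range), scale=rng.uniform(0.5, 0.9),
            )
            nr_hits.append(weaker)

    def make_members(cid: str, chosen_sites: list[str], fraction: str,
                     cls: str) -> list[SequenceMeta]:
        members = []
        for site in chosen_sites:
            n = 1 + int(rng.poisson(config.members_lambda))
            for _ in range(n):
                idx = len(members)
                seq_id = f"{cid}_s{idx:03d}"
                depth = depth_of[site]
                frac_tag = "lt022" if fraction == "ultrasmall" else "gt022"
                members.append(SequenceMeta(
                    seq_id=seq_id, cluster_id=cid,
                    sample_id=f"TARA_{site}_{depth}_{frac_tag}",
                    site_id=site, depth=depth, size_fraction=fraction,
                    length_aa=int(rng.integers(120, 400)),
                ))
                seq_class[seq_id] = cls
        return members

    cluster_idx = 0
    for cls in CLASSES:
        for _ in range(max(0, n_per_class[cls])):
            cid = f"CL{cluster_idx:05d}"
            cluster_idx += 1
            cluster_class[cid] = cls
            if cls in ("novel_ultrasmall", "known_regular"):
                p_wide = (config.p_widespread_novel if cls == "novel_ultrasmall"
                          else config.p_widespread_known)
                widespread = len(sites) >= 2 and rng.random() < p_wide
                if widespread:
                    k = min(len(sites), 2 + int(rng.random() < 0.3))
                    chosen = [site_ids[i] for i in
                              sorted(rng.choice(len(sites), size=k, replace=False))]
                else:
                    chosen = [site_ids[int(rng.integers(len(sites)))]]
                members = make_members(cid, chosen, "ultrasmall", cls)
                meta.extend(members)
                for seq in members:
                    if cls == "novel_ultrasmall":
                        if rng.random() < config.p_no_hit_novel:
                            seq_group[seq.seq_id] = "unclassified"
                            continue
                        emit_nr(seq, draw_identity(*config.identity_novel),
                                _choice(rng, _NOVEL_GROUP_PROBS))
                    else:
                        emit_nr(seq, draw_identity(*config.identity_known),
                                _choice(rng, _KNOWN_GROUP_PROBS))
            elif cls == "viral":
                chosen = [site_ids[int(rng.integers(len(sites)))]]
                members = make_members(cid, chosen, "ultrasmall", cls)
                meta.extend(members)
                for seq in members:
                    if rng.random() < 0.6:  # screen (a): virus-annotated best hit
                        emit_nr(seq, draw_identity(*config.identity_viral), "viruses")
                    else:                    # screen (b): metavirome match
                        seq_group[seq.seq_id] = "unclassified"
                        subject = f"vir{vir_counter:05d}"
                        vir_counter += 1
                        taxonomy[subject] = TaxonAnnotation(
                            subject, "viruses", ("root", "viruses"))
                        virome_hits.append(_make_hit(
                            rng, seq.seq_id, subject, seq.length_aa,
                            rng.uniform(85.0, 99.0), rng.uniform(0.85, 0.98),
                        ))
            else:  # shared_fraction: ultrasmall members plus other-fraction ones
                chosen = [site_ids[int(rng.integers(len(sites)))]]
                members = make_members(cid, chosen, "ultrasmall", cls)
                other_site = [site_ids[int(rng.integers(len(sites)))]]
                others = make_members(cid + "x", other_site, "other", cls)
                others = [replace(o, cluster_id=cid,
                                  seq_id=f"{cid}_o{i:03d}") for i, o in enumerate(others)]
                for o in others:
                    seq_class[o.seq_id] = cls
                members = members + others
                meta.extend(members)
                for seq in members:
                    emit_nr(seq, draw_identity(*config.identity_shared),
                            _choice(rng, _KNOWN_GROUP_PROBS))

    # --- derived per-sequence labels (from realised values) ----------------
    viral_seqs: set[str] = set()
    vir_by_query: dict[str, list[AlignmentHit]] = {}
    for h in virome_hits:
        vir_by_query.setdefault(h.query_id, []).append(h)
    for seq in meta:
        best = seq_best_nr.get(seq.seq_id)
        if best is not None and taxonomy[best.subject_id].group == "viruses":
            viral_seqs.add(seq.seq_id)
            continue
        for h in vir_by_query.get(seq.seq_id, ()):
            qcov = (h.qend - h.qstart + 1) / h.qlen
            scov = (abs(h.send - h.sstart) + 1) / h.slen
            if h.pct_identity >= 80.0 and min(qcov, scov) >= 0.8:
                viral_seqs.add(seq.seq_id)
                break

    override = {"DPANN", "CPR", "unassigned_bacteria", "unassigned_archaea",
                "candidate", "unclassified"}
    divergence: dict[str, frozenset[str]] = {}
    both = frozenset(("light_dark", "dark"))
    for seq in meta:
        best = seq_best_nr.get(seq.seq_id)
        if best is None:
            divergence[seq.seq_id] = both
            continue
        group = taxonomy[best.subject_id].group
        qcov = (best.qend - best.qstart + 1) / best.qlen
        scov = (abs(best.send - best.sstart) + 1) / best.slen
        cov = min(qcov, scov)
        if group in override or cov <= 0.8 or best.pct_identity < 70.0:
            divergence[seq.seq_id] = both
        elif best.pct_identity < 90.0:
            divergence[seq.seq_id] = frozenset(("light_dark",))
        else:
            divergence[seq.seq_id] = frozenset()

    # --- cluster tiers -----------------------------------------------------
    frac_by_cluster: dict[str, set[str]] = {}
    ultra_sites: dict[str, set[str]] = {}
    for seq in meta:
        frac_by_cluster.setdefault(seq.cluster_id, set()).add(seq.size_fraction)
        if seq.size_fraction == "ultrasmall":
            ultra_sites.setdefault(seq.cluster_id, set()).add(seq.site_id)
    cluster_tiers: dict[str, frozenset[str]] = {}
    for cid, fracs in frac_by_cluster.items():
        tiers: set[str] = set()
        if "ultrasmall" in fracs:
            tiers.add("PU")
            if fracs == {"ultrasmall"}:
                tiers.add("UO")
                if len(ultra_sites.get(cid, ())) >= 2:
                    tiers.add("WUO")
        cluster_tiers[cid] = frozenset(tiers)

    # --- carrier pools and KO planting -------------------------------------
    meta_by_id = {m.seq_id: m for m in meta}
    carriers: dict[str, list[str]] = {s: [] for s in site_ids}
    for seq in meta:
        if (seq.seq_id not in viral_seqs
                and "WUO" in cluster_tiers[seq.cluster_id]
                and divergence[seq.seq_id] == both):
            carriers[seq.site_id].append(seq.seq_id)
    sites_needing = sorted({site for (site, pw), k in planted_modules.items() if k > 0})
    for site in sites_needing:
        if not carriers[site]:
            # dedicated widespread dark carrier cluster for this site
            cid = f"CL{cluster_idx:05d}"
            cluster_idx += 1
            cluster_class[cid] = "novel_ultrasmall"
            partner = next(s for s in site_ids if s != site)
            for j, s in enumerate((site, partner)):
                seq_id = f"{cid}_s{j:03d}"
                rec = SequenceMeta(
                    seq_id=seq_id, cluster_id=cid,
                    sample_id=f"TARA_{s}_{depth_of[s]}_lt022",
                    site_id=s, depth=depth_of[s], size_fraction="ultrasmall",
                    length_aa=int(rng.integers(120, 400)),
                )
                meta.append(rec)
                meta_by_id[seq_id] = rec
                seq_class[seq_id] = "novel_ultrasmall"
                seq_group[seq_id] = "unclassified"
                divergence[seq_id] = both
            cluster_tiers[cid] = frozenset(("PU", "UO", "WUO"))
            carriers[site].append(f"{cid}_s000")

    kegg_hits: list[AlignmentHit] = []
    ko_map: dict[str, str] = {}
    planted_kos_by_site: dict[str, set[str]] = {s: set() for s in site_ids}
    seq_planted_kos: dict[str, set[str]] = {}
    for site in site_ids:
        pool = sorted(carriers[site])
        if not pool:
            continue
        cursor = 0
        site_kos: set[str] = set()
        for pw in sorted(pathway_by_id):
            k = planted_modules.get((site, pw), 0)
            for module in pathway_by_id[pw].modules[:k]:
                site_kos |= satisfying_kos(module)
        planted_kos_by_site[site] = site_kos
        for ko in sorted(site_kos):
            subject = f"{ko}_ref"
            ko_map[subject] = ko
            for _ in range(config.carriers_per_ko):
                seq_id = pool[cursor % len(pool)]
                cursor += 1
                if ko in seq_planted_kos.setdefault(seq_id, set()):
                    continue
                seq_planted_kos[seq_id].add(ko)
                qlen = meta_by_id[seq_id].length_aa
                kegg_hits.append(_make_hit(
                    rng, seq_id, subject, qlen,
                    rng.uniform(*config.kegg_identity),
                    rng.uniform(*config.kegg_coverage),
                ))

    # --- truth KO sets and completeness ------------------------------------
    ko_sets: dict[tuple[str, str, str], frozenset[str]] = {}
    site_depths = sorted({(m.site_id, m.depth) for m in meta})
    keys = site_depths + [(POOL_SITE, POOL_DEPTH)]
    for site, depth in keys:
        for ds in STANDARD_DATASETS:
            acc: set[str] = set()
            for seq_id, kos in seq_planted_kos.items():
                m = meta_by_id[seq_id]
                if site != POOL_SITE and (m.site_id, m.depth) != (site, depth):
                    continue
                if seq_id in viral_seqs or m.size_fraction != "ultrasmall":
                    continue
                if ds.tier not in cluster_tiers[m.cluster_id]:
                    continue
                if ds.divergence != "all" and ds.divergence not in divergence[seq_id]:
                    continue
                acc |= kos
            ko_sets[(site, depth, str(ds))] = frozenset(acc)

    completeness: dict[tuple[str, str, str, str], float] = {}
    for (site, depth, ds), kos in ko_sets.items():
        for pw, spec in pathway_by_id.items():
            n_present = sum(m.expression.evaluate(kos) for m in spec.modules)
            completeness[(site, depth, ds, pw)] = 100.0 * n_present / len(spec.modules)

    # --- effort covariates --------------------------------------------------
    effort: dict[tuple[str, str], tuple[int, int, int, float]] = {}
    mu, sigma = config.reads_lognormal
    shape, scale = config.coverage_gamma
    for site, depth in site_depths:
        reads = int(rng.lognormal(mu, sigma))
        hq = int(reads * rng.uniform(0.8, 0.95))
        genes = int(hq * rng.uniform(0.02, 0.08))
        cov = float(rng.gamma(shape, scale))
        effort[(site, depth)] = (reads, hq, max(1, genes), round(cov, 4))

    meta_sorted = sorted(meta, key=lambda m: m.seq_id)
    bundle = Bundle(
        meta=meta_sorted,
        nr_hits=sorted(nr_hits, key=lambda h: (h.query_id, h.subject_id)),
        virome_hits=sorted(virome_hits, key=lambda h: (h.query_id, h.subject_id)),
        kegg_hits=sorted(kegg_hits, key=lambda h: (h.query_id, h.subject_id)),
        taxonomy=taxonomy,
        pathways=pathways,
        ko_map=ko_map,
        effort=effort,
    )
    truth = SyntheticTruth(
        cluster_class=cluster_class,
        cluster_tiers=cluster_tiers,
        viral_seqs=frozenset(viral_seqs),
        divergence=divergence,
        seq_group=seq_group,
        ko_sets=ko_sets,
        completeness=completeness,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Independent self-check (naive re-derivation of every planted label)
# ---------------------------------------------------------------------------


def _naive_mutual_cov(h: AlignmentHit) -> float:
    q = (h.qend - h.qstart + 1) / h.qlen
    lo, hi = (h.sstart, h.send) if h.sstart <= h.send else (h.send, h.sstart)
    s = (hi - lo + 1) / h.slen
    return q if q < s else s


def self_check(bundle: Bundle, truth: SyntheticTruth) -> list[str]:
    """Re-derive labels from the bundle with a plain, loop-based
    reimplementation of the filtration rules and compare against the truth.
    Returns a list of human-readable mismatch descriptions (empty = pass)."""
    mismatches: list[str] = []

    # tiers
    fracs: dict[str, set[str]] = {}
    usites: dict[str, set[str]] = {}
    for m in bundle.meta:
        fracs.setdefault(m.cluster_id, set()).add(m.size_fraction)
        if m.size_fraction == "ultrasmall":
            usites.setdefault(m.cluster_id, set()).add(m.site_id)
    for cid in fracs:
        tiers = set()
        if "ultrasmall" in fracs[cid]:
            tiers.add("PU")
            if fracs[cid] == {"ultrasmall"}:
                tiers.add("UO")
                if len(usites.get(cid, ())) >= 2:
                    tiers.add("WUO")
        if frozenset(tiers) != truth.cluster_tiers.get(cid, frozenset()):
            mismatches.append(f"cluster {cid}: tiers {sorted(tiers)} != truth")

    # best nr hits, naive scan
    best: dict[str, AlignmentHit] = {}
    for h in bundle.nr_hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        a = (-h.bitscore, h.evalue, -h.pct_identity, h.subject_id)
        b = (-cur.bitscore, cur.evalue, -cur.pct_identity, cur.subject_id)
        if a < b:
            best[h.query_id] = h

    # viral flags
    vir: dict[str, list[AlignmentHit]] = {}
    for h in bundle.virome_hits:
        vir.setdefault(h.query_id, []).append(h)
    derived_viral = set()
    for m in bundle.meta:
        b = best.get(m.seq_id)
        if b is not None and bundle.taxonomy[b.subject_id].group == "viruses":
            derived_viral.add(m.seq_id)
            continue
        for h in vir.get(m.seq_id, ()):
            if h.pct_identity >= 80.0 and _naive_mutual_cov(h) >= 0.8:
                derived_viral.add(m.seq_id)
                break
    if derived_viral != set(truth.viral_seqs):
        delta = derived_viral ^ set(truth.viral_seqs)
        mismatches.append(f"viral flags differ for {sorted(delta)[:5]}")

    # divergence tiers
    override = {"DPANN", "CPR", "unassigned_bacteria", "unassigned_archaea",
                "candidate", "unclassified"}
    for m in bundle.meta:
        b = best.get(m.seq_id)
        if b is None:
            tiers = {"light_dark", "dark"}
        else:
            group = bundle.taxonomy[b.subject_id].group
            if group in override or _naive_mutual_cov(b) <= 0.8 or b.pct_identity < 70:
                tiers = {"light_dark", "dark"}
            elif b.pct_identity < 90:
                tiers = {"light_dark"}
            else:
                tiers = set()
        if frozenset(tiers) != truth.divergence.get(m.seq_id, frozenset()):
            mismatches.append(f"sequence {m.seq_id}: divergence {sorted(tiers)} != truth")

    # KO sets per (site, depth, dataset) + pool
    meta_by_id = {m.seq_id: m for m in bundle.meta}
    seq_kos: dict[str, set[str]] = {}
    for h in bundle.kegg_hits:
        ko = bundle.ko_map.get(h.subject_id)
        if ko is None:
            continue
        if h.pct_identity > 25.0 and h.evalue < 1e-5 and _naive_mutual_cov(h) > 0.7:
            seq_kos.setdefault(h.query_id, set()).add(ko)
    for (site, depth, ds_label), truth_kos in truth.ko_sets.items():
        tier, _, suffix = ds_label.partition("_")
        div = {"": "all", "ld": "light_dark", "dm": "dark"}[suffix]
        acc: set[str] = set()
        for seq_id, kos in seq_kos.items():
            m = meta_by_id[seq_id]
            if site != POOL_SITE and (m.site_id, m.depth) != (site, depth):
                continue
            if seq_id in derived_viral or m.size_fraction != "ultrasmall":
                continue
            tiers_for = set()
            if "ultrasmall" in fracs[m.cluster_id]:
                tiers_for.add("PU")
                if fracs[m.cluster_id] == {"ultrasmall"}:
                    tiers_for.add("UO")
                    if len(usites.get(m.cluster_id, ())) >= 2:
                        tiers_for.add("WUO")
            if tier not in tiers_for:
                continue
            if div != "all":
                b = best.get(seq_id)
                if b is None:
                    dtiers = {"light_dark", "dark"}
                else:
                    group = bundle.taxonomy[b.subject_id].group
                    if (group in override or _naive_mutual_cov(b) <= 0.8
                            or b.pct_identity < 70):
                        dtiers = {"light_dark", "dark"}
                    elif b.pct_identity < 90:
                        dtiers = {"light_dark"}
                    else:
                        dtiers = set()
                if div not in dtiers:
                    continue
            acc |= kos
        if frozenset(acc) != truth_kos:
            mismatches.append(
                f"KO set ({site}, {depth}, {ds_label}): derived != truth "
                f"(delta {sorted(frozenset(acc) ^ truth_kos)[:5]})"
            )

    # completeness, naive recursive evaluation
    def naive_eval(expr, kos) -> bool:
        if isinstance(expr, KOAtom):
            return expr.ko in kos
        if isinstance(expr, And):
            for t in expr.terms:
                if not naive_eval(t, kos):
                    return False
            return True
        if isinstance(expr, Or):
            for t in expr.terms:
                if naive_eval(t, kos):
                    return True
            return False
        raise TypeError(type(expr))

    spec_by_id = {p.pathway_id: p for p in bundle.pathways}
    for (site, depth, ds_label, pw), truth_pct in truth.completeness.items():
        kos = truth.ko_sets[(site, depth, ds_label)]
        spec = spec_by_id[pw]
        n = sum(naive_eval(mod.expression, kos) for mod in spec.modules)
        pct = 100.0 * n / len(spec.modules)
        if abs(pct - truth_pct) > 1e-9:
            mismatches.append(
                f"completeness ({site}, {depth}, {ds_label}, {pw}): "
                f"{pct} != {truth_pct}"
            )
    return mismatches


# ---------------------------------------------------------------------------
# Enrichment-scenario count simulation
# ---------------------------------------------------------------------------

DEFAULT_GROUP_PROPORTIONS = {
    "known_bacteria": 0.30, "known_archaea": 0.06, "known_eukaryota": 0.05,
    "unclassified": 0.22, "unassigned_bacteria": 0.10,
    "unassigned_archaea": 0.05, "viruses": 0.10, "CPR": 0.08, "DPANN": 0.04,
}


def simulate_enrichment_counts(
    rng: np.random.Generator | int,
    n_per_group: int = 500,
    datasets: Sequence[str] = ("UO", "UO_ld", "UO_dm", "WUO", "WUO_ld", "WUO_dm"),
    proportions: Mapping[str, float] | None = None,
    shift: Mapping[tuple[str, str], float] | None = None,
) -> tuple[dict[tuple[str, str], int], dict[str, int]]:
    """Simulate group x dataset sequence counts plus a PU baseline.

    Both the PU baseline and every dataset are multinomial draws of
    ``n_per_group * n_groups`` sequences over the group proportions (so each
    group holds ``n_per_group`` sequences in expectation under uniform
    proportions); dataset proportions are multiplied by any
    ``shift[(group, dataset)]`` factors (the planted enrichment scenario).
    With no shift this is the null scenario used for type-I calibration.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    props = dict(proportions or DEFAULT_GROUP_PROPORTIONS)
    groups = sorted(props)
    weights = np.array([props[g] for g in groups], dtype=float)
    weights = weights / weights.sum()
    total = n_per_group * len(groups)
    pu_draw = rng.multinomial(total, weights)
    pu_counts = {g: int(c) for g, c in zip(groups, pu_draw)}
    counts: dict[tuple[str, str], int] = {}
    for ds in datasets:
        w = weights.copy()
        if shift:
            for i, g in enumerate(groups):
                w[i] *= shift.get((g, ds), 1.0)
            w = w / w.sum()
        draw = rng.multinomial(total, w)
        for g, c in zip(groups, draw):
            counts[(g, ds)] = int(c)
    return counts, pu_counts
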