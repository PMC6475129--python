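"""End-to-end orchestration: filter -> decon -> homologs -> completeness
-> stats -> ssn, with artifact writing and a run manifest.

All biological thresholds live in :class:`RunConfig` with the published
values as defaults, so the zero-configuration run reproduces the reference
analysis settings exactly.  Every stage logs how many records it removed and
why, and the manifest records input checksums and the thresholds used, so a
rerun over identical inputs is bitwise reproducible (timestamps excluded by
not recording any).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .completeness import (
    CompletenessCell,
    CompletenessMatrix,
    build_matrix,
    pathway_completeness,
    ribosome_completeness,
)
from .decontamination import (
    DEFAULT_OVERRIDE_GROUPS,
    DarkMatterCall,
    classify_dark_matter,
    flag_viral,
    write_calls,
)
from .fraction_filter import (
    dataset_sequences,
    profile_clusters,
    select_datasets,
    write_dataset_table,
)
from .homology import (
    FILTERED_DATASETS,
    STANDARD_DATASETS,
    KOAssignment,
    KOPresence,
    best_hits_by_query,
    filter_homologs,
    group_by_query,
    ko_presence,
    sequence_datasets,
    write_presence,
)
from .io_model import DEFAULT_GROUPS
from .ssn import build_network, connected_components, write_edges, write_families
from .stats import run_enrichment, write_enrichment
from .synthetic_data import Bundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline thresholds; defaults are the published analysis values."""

    homolog_min_identity: float = 25.0     # strict >
    homolog_max_evalue: float = 1e-5       # strict <
    homolog_min_coverage: float = 0.7      # strict >
    viral_min_identity: float = 80.0       # inclusive >=
    viral_min_coverage: float = 0.8        # inclusive >=
    dark_min_coverage: float = 0.8         # best-hit coverage must exceed
    strict_coverage: bool = False
    flag_threshold: float = 60.0           # inclusive >=
    ssn_min_identity: float = 30.0         # inclusive >=
    ssn_min_coverage: float = 0.8          # inclusive >=
    override_groups: tuple[str, ...] = tuple(sorted(DEFAULT_OVERRIDE_GROUPS))
    groups: tuple[str, ...] = DEFAULT_GROUPS
    ultrasmall_only: bool = True

    def __post_init__(self) -> None:
        for name in ("homolog_min_identity", "viral_min_identity",
                     "ssn_min_identity", "flag_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} outside [0, 100]: {v}")
        for name in ("homolog_min_coverage", "viral_min_coverage",
                     "dark_min_coverage", "ssn_min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.homolog_max_evalue <= 0:
            raise ValueError("homolog_max_evalue must be positive")


@dataclass
class PipelineResult:
    profiles: dict
    cluster_tiers: dict[str, frozenset[str]]
    tier_sequences: dict[str, frozenset[str]]
    viral_flags: dict[str, tuple[bool, Optional[str]]]
    dark_calls: dict[str, DarkMatterCall]
    assignments: list[KOAssignment]
    presence: dict[tuple[str, str, str], KOPresence]
    cells: list[CompletenessCell]
    matrix: CompletenessMatrix
    group_counts: dict[tuple[str, str], int]
    pu_group_counts: dict[str, int]
    enrichment: list
    ssn_edges: set[tuple[str, str]]
    families: list
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_bundle(bundle: Bundle, config: RunConfig | None = None) -> PipelineResult:
    """Run every stage over an in-memory bundle."""
    config = config or RunConfig()
    counts: dict[str, int] = {}

    # 1. size-fraction filtration
    profiles = profile_clusters(bundle.meta)
    tiers = select_datasets(profiles)
    tier_seqs = dataset_sequences(profiles, tiers, config.ultrasmall_only)
    counts["clusters_total"] = len(profiles)
    for tier in ("PU", "UO", "WUO"):
        counts[f"clusters_{tier}"] = len(tiers[tier])
        counts[f"sequences_{tier}"] = len(tier_seqs[tier])

    # 2. decontamination
    override = frozenset(config.override_groups)
    nr_best = best_hits_by_query(bundle.nr_hits)
    vir_by_query = group_by_query(bundle.virome_hits)
    viral_flags: dict[str, tuple[bool, Optional[str]]] = {}
    dark_calls: dict[str, DarkMatterCall] = {}
    for m in bundle.meta:
        best = nr_best.get(m.seq_id)
        viral_flags[m.seq_id] = flag_viral(
            m.seq_id, best, vir_by_query.get(m.seq_id, ()), bundle.taxonomy,
            config.viral_min_identity, config.viral_min_coverage,
        )
        dark_calls[m.seq_id] = classify_dark_matter(
            m.seq_id, best, bundle.taxonomy, override,
            config.strict_coverage, config.dark_min_coverage,
        )
    counts["viral_removed"] = sum(flag for flag, _ in viral_flags.values())
    counts["dark_matter"] = sum(c.is_dark for c in dark_calls.values())
    counts["light_dark_matter"] = sum(c.is_light_dark for c in dark_calls.values())

    # 3. KO homology
    assignments, n_unresolved = filter_homologs(
        bundle.kegg_hits, bundle.ko_map,
        config.homolog_min_identity, config.homolog_max_evalue,
        config.homolog_min_coverage,
    )
    counts["kegg_hits_unresolved"] = n_unresolved
    counts["ko_homolog_sequences"] = len(assignments)
    viral_bool = {s: f for s, (f, _) in viral_flags.items()}
    presence = ko_presence(
        assignments, bundle.meta, tiers, dark_calls, viral_bool,
        STANDARD_DATASETS, config.ultrasmall_only,
    )

    # 4. completeness matrix
    cells = [
        pathway_completeness(spec, pres.kos, key, config.flag_threshold)
        if spec.key_kos else ribosome_completeness(spec, pres.kos, key)
        for key, pres in presence.items()
        for spec in bundle.pathways
    ]
    datasets = [str(ds) for ds in STANDARD_DATASETS]
    pathway_ids = [p.pathway_id for p in bundle.pathways]
    matrix = build_matrix(cells, datasets, pathway_ids)

    # 5. enrichment (dataset composition, counted before viral removal)
    group_counts: dict[tuple[str, str], int] = {}
    pu_counts: dict[str, int] = {g: 0 for g in config.groups}
    for m in bundle.meta:
        best = nr_best.get(m.seq_id)
        group = (bundle.taxonomy[best.subject_id].group if best is not None
                 else "unclassified")
        if group not in pu_counts:
            continue
        member_of = sequence_datasets(
            m, tiers, dark_calls.get(m.seq_id), viral=False,
            datasets=STANDARD_DATASETS, ultrasmall_only=config.ultrasmall_only,
            drop_viral=False,
        )
        for ds in member_of:
            if ds.tier == "PU" and ds.divergence == "all":
                pu_counts[group] += 1
            else:
                group_counts[(group, str(ds))] = group_counts.get((group, str(ds)), 0) + 1
    filtered = [str(ds) for ds in FILTERED_DATASETS]
    for g in config.groups:
        for ds in filtered:
            group_counts.setdefault((g, ds), 0)
    enrichment = run_enrichment(group_counts, pu_counts, config.groups, filtered)
    counts["enrichment_tests"] = len(enrichment)

    # 6. sequence similarity network over the KEGG-homolog alignments
    edges = build_network(bundle.kegg_hits, config.ssn_min_identity,
                          config.ssn_min_coverage)
    nodes = {h.query_id for h in bundle.kegg_hits} | {
        h.subject_id for h in bundle.kegg_hits}
    families = connected_components(nodes, edges)
    counts["ssn_edges"] = len(edges)
    counts["gene_families"] = len(families)

    for stage, n in counts.items():
        logger.info("stage count %s = %d", stage, n)
    return PipelineResult(
        profiles=profiles, cluster_tiers=tiers, tier_sequences=tier_seqs,
        viral_flags=viral_flags, dark_calls=dark_calls,
        assignments=assignments, presence=presence, cells=cells, matrix=matrix,
        group_counts=group_counts, pu_group_counts=pu_counts,
        enrichment=enrichment, ssn_edges=edges, families=families,
        stage_counts=counts,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


REQUIRED_INPUTS = ("meta.tsv", "nr_hits.tsv", "virome_hits.tsv", "kegg_hits.tsv",
                   "tax.tsv", "modules.tsv", "ko_map.tsv")


def run_pipeline(indir, outdir, config: RunConfig | None = None) -> PipelineResult:
    """Load a bundle directory, run all stages, write artifacts + manifest.

    A missing input fails before any stage runs, naming the file; a stage
    failure leaves earlier artifacts in place with the manifest marking the
    failure point.
    """
    indir, outdir = Path(indir), Path(outdir)
    config = config or RunConfig()
    missing = [name for name in REQUIRED_INPUTS if not (indir / name).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "inputs": {name: _sha256(indir / name) for name in REQUIRED_INPUTS},
        "thresholds": asdict(config),
        "status": "running",
        "stage_counts": {},
    }

    def save_manifest() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    try:
        bundle = Bundle.read(indir)
        result = run_bundle(bundle, config)
        write_dataset_table(result.cluster_tiers, outdir / "datasets.tsv")
        write_calls(result.dark_calls, result.viral_flags, outdir / "decon_calls.tsv")
        write_presence(result.presence, outdir / "ko_presence.tsv")
        result.matrix.write_tsv(outdir / "completeness.tsv")
        result.matrix.write_flags_tsv(outdir / "completeness_flags.tsv")
        with open(outdir / "dendrogram.nwk", "w") as fh:
            fh.write(result.matrix.to_newick() + "\n")
        write_enrichment(result.enrichment, outdir / "enrichment.tsv")
        write_edges(result.ssn_edges, outdir / "ssn_edges.tsv")
        write_families(result.families, outdir / "gene_families.tsv")
        manifest["status"] = "ok"
        manifest["stage_counts"] = result.stage_counts
        save_manifest()
        return result
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        save_manifest()
        raise
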