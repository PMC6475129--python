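"""Pathway completeness scoring and the clustered completeness matrix.

A pathway is a list of modules (reaction blocks expressed as boolean logic
over KOs).  A module is *present* in a KO set when its required-enzyme
expression is satisfiable from that set; optional enzymes never count toward
presence but are reported when observed.  Pathway completeness at a key is
the percentage of its modules present, and a pathway is *flagged* as
credibly occurring when completeness reaches the flag threshold (default
60%, inclusive) with every key enzyme of the pathway detected.

Ribosomal protein complexes, scored the same way with one single-KO module
per protein, serve as positive controls and carry no key-enzyme flag.

The assembled matrix has one row per (site, depth) plus a "pool" row that
unions all sites, and one column per (dataset stringency, pathway).  Rows
(pool excluded) are ordered by Ward agglomerative clustering on their
completeness vectors; the dendrogram is exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .homology import POOL_DEPTH, POOL_SITE
from .io_model import ModuleDefinition, PathwaySpec

FLAG_THRESHOLD = 60.0  # percent completeness, inclusive


def eval_module(module: ModuleDefinition, kos: frozenset[str] | set[str]
                ) -> tuple[bool, frozenset[str]]:
    """Evaluate one module: (present, optional KOs observed)."""
    present = module.expression.evaluate(kos)
    optional_found = module.optional_kos & frozenset(kos)
    return present, optional_found


@dataclass(frozen=True, slots=True)
class CompletenessCell:
    key: tuple[str, str, str]
    pathway_id: str
    completeness_pct: float
    all_key_enzymes: bool
    flagged: bool
    optional_found: frozenset[str]
    n_modules_present: int
    n_modules: int

    def __post_init__(self) -> None:
        # The numeric flag threshold is enforced where it is known (it is
        # configurable); the structural half of the invariant lives here.
        if self.flagged and not self.all_key_enzymes:
            raise ValueError(f"{self.key}/{self.pathway_id}: flag without key enzymes")


def pathway_completeness(
    pathway: PathwaySpec,
    kos: frozenset[str] | set[str],
    key: tuple[str, str, str] = ("", "", ""),
    flag_threshold: float = FLAG_THRESHOLD,
) -> CompletenessCell:
    """Score one pathway against one KO set.

    ``all_key_enzymes`` requires the pathway to declare at least one key
    enzyme and all of them to be present; a key-less pathway can never flag
    (use :func:`ribosome_completeness` for positive-control complexes).
    """
    kos = frozenset(kos)
    n_present = 0
    optional_found: set[str] = set()
    for module in pathway.modules:
        present, opt = eval_module(module, kos)
        n_present += present
        optional_found |= opt
    pct = 100.0 * n_present / len(pathway.modules)
    key_kos = pathway.key_kos
    all_key = bool(key_kos) and key_kos <= kos
    flagged = all_key and pct >= flag_threshold
    return CompletenessCell(
        key, pathway.pathway_id, pct, all_key, flagged,
        frozenset(optional_found), n_present, len(pathway.modules),
    )


def ribosome_completeness(
    complex_spec: PathwaySpec,
    kos: frozenset[str] | set[str],
    key: tuple[str, str, str] = ("", "", ""),
) -> CompletenessCell:
    """Completeness of a ribosomal complex: fraction of its protein KOs
    present; never flagged.  A KO shared between the bacterial and archaeal
    complexes contributes to both, each complex being scored against its own
    full protein list."""
    cell = pathway_completeness(complex_spec, kos, key, flag_threshold=np.inf)
    return CompletenessCell(
        cell.key, cell.pathway_id, cell.completeness_pct, False, False,
        cell.optional_found, cell.n_modules_present, cell.n_modules,
    )


def ribosome_specs(
    n_shared: int = 31, n_bact_only: int = 24, n_arch_only: int = 36
) -> tuple[PathwaySpec, PathwaySpec]:
    """Synthetic stand-ins for the bacterial/archaeal ribosomal complexes:
    55 and 67 protein KOs respectively, sharing 31 (the published tallies).

    One single-KO module per ribosomal protein; KO ids are fabricated in
    disjoint blocks (shared K02600+, bacterial-only K02700+, archaeal-only
    K02800+)."""
    shared = [f"K{2600 + i:05d}" for i in range(n_shared)]
    bact = shared + [f"K{2700 + i:05d}" for i in range(n_bact_only)]
    arch = shared + [f"K{2800 + i:05d}" for i in range(n_arch_only)]

    def spec(pathway_id: str, kos: list[str]) -> PathwaySpec:
        modules = tuple(
            ModuleDefinition.from_string(f"{pathway_id}_rp{i:02d}", ko)
            for i, ko in enumerate(kos)
        )
        return PathwaySpec(pathway_id, modules)

    return spec("ribosome_bact", bact), spec("ribosome_arch", arch)


@dataclass(slots=True)
class CompletenessMatrix:
    row_keys: list[tuple[str, str]]          # (site, depth), pool last
    columns: list[tuple[str, str]]           # (dataset label, pathway id)
    values: np.ndarray                       # rows x columns, percent
    cells: dict[tuple[tuple[str, str, str], str], CompletenessCell]
    row_order: list[int]                     # permutation of row indices
    linkage_matrix: Optional[np.ndarray]     # scipy linkage over non-pool rows

    def row_label(self, index: int) -> str:
        site, depth = self.row_keys[index]
        return site if site == POOL_SITE else f"{site}_{depth}"

    @property
    def ordered_labels(self) -> list[str]:
        return [self.row_label(i) for i in self.row_order]

    def cell(self, site: str, depth: str, dataset: str, pathway: str) -> CompletenessCell:
        return self.cells[((site, depth, dataset), pathway)]

    @property
    def has_pool(self) -> bool:
        return bool(self.row_keys) and self.row_keys[-1][0] == POOL_SITE

    def to_newick(self) -> str:
        """Dendrogram over the clustered (non-pool) rows, with branch heights."""
        n = len(self.row_keys) - (1 if self.has_pool else 0)
        if self.linkage_matrix is None or n < 2:
            return f"({self.row_label(0)}:0.0);" if n == 1 else ";"
        tree = to_tree(self.linkage_matrix)
        labels = [self.row_label(i) for i in range(n)]

        def fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            header = ["row"] + [f"{ds}:{pw}" for ds, pw in self.columns]
            fh.write("\t".join(header) + "\n")
            for i in self.row_order:
                vals = [f"{v:.2f}" for v in self.values[i]]
                fh.write("\t".join([self.row_label(i)] + vals) + "\n")

    def write_flags_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("row\tdataset\tpathway\tcompleteness_pct\tall_key_enzymes"
                     "\tflagged\toptional_found\n")
            for i in self.row_order:
                site, depth = self.row_keys[i]
                for ds, pw in self.columns:
                    cell = self.cells[((site, depth, ds), pw)]
                    fh.write(
                        f"{self.row_label(i)}\t{ds}\t{pw}\t{cell.completeness_pct:.2f}"
                        f"\t{int(cell.all_key_enzymes)}\t{int(cell.flagged)}"
                        f"\t{','.join(sorted(cell.optional_found))}\n"
                    )


_DEPTH_ORDER = {"SRF": 0, "DCM": 1, "MES": 2, "MIX": 3}


def build_matrix(
    cells: Iterable[CompletenessCell],
    datasets: Sequence[str] | None = None,
    pathways: Sequence[str] | None = None,
) -> CompletenessMatrix:
    """Assemble cells into the clustered completeness matrix.

    Rows are (site, depth) keys sorted by site then depth; the pool row is
    appended last and excluded from clustering.  Row order comes from Ward
    linkage (Euclidean distance) on each row's concatenated completeness
    vector across all dataset stringencies.  The grid must be complete.
    """
    cells = list(cells)
    by_key: dict[tuple[tuple[str, str, str], str], CompletenessCell] = {}
    for c in cells:
        by_key[(c.key, c.pathway_id)] = c
    sites = sorted(
        {(c.key[0], c.key[1]) for c in cells if c.key[0] != POOL_SITE},
        key=lambda sd: (sd[0], _DEPTH_ORDER.get(sd[1], 99)),
    )
    has_pool = any(c.key[0] == POOL_SITE for c in cells)
    row_keys = sites + ([(POOL_SITE, POOL_DEPTH)] if has_pool else [])
    if datasets is None:
        datasets = sorted({c.key[2] for c in cells})
    if pathways is None:
        pathways = sorted({c.pathway_id for c in cells})
    columns = [(ds, pw) for ds in datasets for pw in pathways]
    values = np.empty((len(row_keys), len(columns)))
    for i, (site, depth) in enumerate(row_keys):
        for j, (ds, pw) in enumerate(columns):
            cell = by_key.get(((site, depth, ds), pw))
            if cell is None:
                raise KeyError(f"missing cell ({site}, {depth}, {ds}) x {pw}")
            values[i, j] = cell.completeness_pct
    n = len(sites)
    if n >= 2:
        Z = linkage(values[:n], method="ward")
        order = list(leaves_list(Z))
    else:
        Z = None
        order = list(range(n))
    if has_pool:
        order.append(n)  # pool row last, never clustered
    return CompletenessMatrix(row_keys, columns, values, by_key, order, Z)
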