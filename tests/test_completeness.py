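"""Module evaluation, completeness scoring, flags, and matrix clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanofix.completeness import (
    build_matrix,
    eval_module,
    pathway_completeness,
    ribosome_completeness,
    ribosome_specs,
)
from nanofix.io_model import ModuleDefinition, PathwaySpec

M = ModuleDefinition.from_string


def spec(pathway_id, *definitions):
    return PathwaySpec(
        pathway_id,
        tuple(M(f"{pathway_id}_m{i}", d) for i, d in enumerate(definitions)),
    )


class TestEvalModule:
    def test_and_of_or_satisfied(self):
        module = M("m", "K00001 (K00002,K00003)")
        assert eval_module(module, {"K00001", "K00003"})[0]

    def test_and_of_or_unsatisfied(self):
        module = M("m", "K00001 (K00002,K00003)")
        assert not eval_module(module, {"K00002", "K00003"})[0]

    def test_optional_reported_but_not_required(self):
        module = M("m", "K00001 -K00009")
        present, optional_found = eval_module(module, {"K00001", "K00009"})
        assert present and optional_found == frozenset({"K00009"})
        # optional alone does not make the module present
        assert not eval_module(module, {"K00009"})[0]


class TestPathwayCompleteness:
    def test_fraction_of_modules_present(self):
        pw = spec("P", "*K00001", "K00002", "K00003", "K00004")
        cell = pathway_completeness(pw, {"K00001", "K00002"})
        assert cell.completeness_pct == 50.0
        assert cell.all_key_enzymes and not cell.flagged  # below 60%

    def test_empty_ko_set_scores_zero(self):
        pw = spec("P", "*K00001", "K00002")
        cell = pathway_completeness(pw, frozenset())
        assert cell.completeness_pct == 0.0 and not cell.flagged

    def test_full_completeness_without_key_enzyme_not_flagged(self):
        pw = spec("P", "*K00001,K00009", "K00002")
        # both modules satisfiable via alternatives, key enzyme itself absent
        cell = pathway_completeness(pw, {"K00009", "K00002"})
        assert cell.completeness_pct == 100.0
        assert not cell.all_key_enzymes and not cell.flagged

    def test_flag_fires_at_exactly_sixty_percent(self):
        pw = spec("P", "*K00001", "K00002", "K00003", "K00004", "K00005")
        cell = pathway_completeness(pw, {"K00001", "K00002", "K00003"})
        assert cell.completeness_pct == 60.0 and cell.flagged

    def test_just_below_threshold_not_flagged(self):
        pw = spec("P", "*K00001", "K00002", "K00003", "K00004")
        cell = pathway_completeness(pw, {"K00001", "K00002"})
        assert cell.completeness_pct == 50.0 and not cell.flagged

    @given(
        kos=st.sets(st.integers(0, 30).map(lambda i: f"K{i:05d}"), max_size=10),
        extra=st.integers(0, 30).map(lambda i: f"K{i:05d}"),
        defs=st.lists(
            st.sampled_from([
                "K00001", "K00002 K00003", "K00004,K00005",
                "K00006 (K00007,K00008)", "*K00010", "K00011 -K00012",
            ]),
            min_size=1, max_size=5, unique=True,
        ),
    )
    def test_adding_a_ko_never_decreases_completeness(self, kos, extra, defs):
        pw = spec("P", *defs)
        before = pathway_completeness(pw, kos).completeness_pct
        after = pathway_completeness(pw, set(kos) | {extra}).completeness_pct
        assert after >= before


class TestRibosomeComplexes:
    def test_published_sizes_and_sharing(self):
        bact, arch = ribosome_specs()
        assert len(bact.modules) == 55 and len(arch.modules) == 67
        assert len(bact.all_kos() & arch.all_kos()) == 31

    def test_fraction_present(self):
        bact, _ = ribosome_specs()
        eleven = {next(iter(m.expression.kos())) for m in bact.modules[:11]}
        cell = ribosome_completeness(bact, eleven)
        assert cell.completeness_pct == pytest.approx(20.0)
        assert not cell.flagged

    def test_all_present_is_complete(self):
        bact, _ = ribosome_specs()
        assert ribosome_completeness(bact, bact.all_kos()).completeness_pct == 100.0

    def test_shared_protein_counts_for_both_complexes(self):
        bact, arch = ribosome_specs()
        shared_ko = sorted(bact.all_kos() & arch.all_kos())[0]
        for cx in (bact, arch):
            cell = ribosome_completeness(cx, {shared_ko})
            assert cell.n_modules_present == 1


# --- matrix assembly and clustering ----------------------------------------


def cells_from_values(values, datasets=("D",), pathways=None):
    """Build a cell grid from a rows x pathways array of percentages."""
    from nanofix.completeness import CompletenessCell

    values = np.asarray(values, dtype=float)
    if pathways is None:
        pathways = [f"P{j}" for j in range(values.shape[1])]
    cells = []
    for i, row in enumerate(values):
        for ds in datasets:
            for j, pw in enumerate(pathways):
                cells.append(CompletenessCell(
                    (f"{i:03d}", "SRF", ds), pw, float(row[j]),
                    False, False, frozenset(), 0, 1,
                ))
    return cells


def naive_ward(X):
    """O(n^3) Lance-Williams Ward agglomeration (independent of scipy)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = {(i, j): float(np.linalg.norm(X[i] - X[j]))
         for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(
            ((pair, dist) for pair, dist in d.items()
             if pair[0] in active and pair[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        merges.append((i, j, h, sizes[i] + sizes[j]))
        for k in active - {i, j}:
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            dij = d[(i, j)]
            ni, nj, nk = sizes[i], sizes[j], sizes[k]
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            d[tuple(sorted((next_id, k)))] = float(new)
        sizes[next_id] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return merges


class TestBuildMatrix:
    def test_identical_rows_merge_at_height_zero(self):
        cells = cells_from_values([[10, 20], [10, 20], [90, 90]])
        matrix = build_matrix(cells)
        assert matrix.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(matrix.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_duplicates_merge_first_matching_naive_oracle(self):
        values = np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0], [0.0, 0.0, 0.0],
                           [40.0, 50.0, 60.0], [42.0, 48.0, 61.0]])
        matrix = build_matrix(cells_from_values(values))
        merges = naive_ward(values)
        # duplicate rows 0 and 2 merge first at height 0
        assert merges[0][:3] == (0, 2, 0.0)
        got_heights = sorted(matrix.linkage_matrix[:, 2])
        expected_heights = sorted(m[2] for m in merges)
        assert got_heights == pytest.approx(expected_heights, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_heights_match_naive_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, size=(8, 4)).round(1)
        matrix = build_matrix(cells_from_values(values))
        expected = sorted(m[2] for m in naive_ward(values))
        assert sorted(matrix.linkage_matrix[:, 2]) == pytest.approx(expected, rel=1e-9)

    def test_single_row_identity_order(self):
        matrix = build_matrix(cells_from_values([[50, 50]]))
        assert matrix.row_order == [0]
        assert matrix.linkage_matrix is None
        assert matrix.to_newick() == "(000_SRF:0.0);"

    def test_pool_row_last_and_not_clustered(self, default_result):
        matrix = default_result.matrix
        assert matrix.row_keys[matrix.row_order[-1]][0] == "pool"
        assert len(matrix.linkage_matrix) == len(matrix.row_keys) - 2

    def test_newick_has_all_leaves(self, default_result):
        nwk = default_result.matrix.to_newick()
        for i in range(len(default_result.matrix.row_keys) - 1):
            assert default_result.matrix.row_label(i) in nwk


class TestBundleProperties:
    def test_pool_dominates_every_site(self, default_result):
        by = {(c.key, c.pathway_id): c.completeness_pct for c in default_result.cells}
        for (key, pw), pct in by.items():
            if key[0] == "pool":
                continue
            pool_pct = by[(("pool", "ALL", key[2]), pw)]
            assert pool_pct >= pct - 1e-9

    def test_stringency_monotone(self, default_result):
        by = {(c.key, c.pathway_id): c.completeness_pct for c in default_result.cells}
        order = ["PU", "UO", "WUO"]
        for (key, pw), pct in by.items():
            site, depth, ds = key
            if ds in ("UO", "WUO"):
                parent = order[order.index(ds) - 1]
                assert by[((site, depth, parent), pw)] >= pct - 1e-9

    def test_planted_completeness_recovered_exactly(self, default_bundle, default_result):
        _, truth = default_bundle
        for c in default_result.cells:
            site, depth, ds = c.key
            assert c.completeness_pct == truth.completeness[(site, depth, ds, c.pathway_id)]
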