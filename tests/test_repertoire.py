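"""Clonotype identity, rescue, diversity/overlap, and specificity filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrspot.repertoire import (
    AlphaChain,
    CellRecord,
    CloneKey,
    InvalidGeneError,
    NonProductiveError,
    RepertoireCounts,
    VdjdbRecord,
    aggregate_repertoire,
    build_clone_key,
    bystander_fraction,
    cefx_specific_clones,
    classify_clone_phenotype,
    clone_rank_cumulative,
    morisita_horn,
    normalize_gene_family,
    pairwise_overlap_matrix,
    rescue_beta_by_alpha,
    shannon_index,
    vdjdb_lookup,
)

from conftest import random_repertoire

K1 = CloneKey("TRBV6", "TRBJ2", "CASSLGQAYEQYF")
K2 = CloneKey("TRBV9", "TRBJ1", "CASSPDRGF")


class TestGeneFamily:
    @pytest.mark.parametrize(
        "gene,family",
        [
            ("TRBV6-2*01", "TRBV6"),
            ("TRBJ2-7", "TRBJ2"),
            ("TRBV20-1/TRBV20OR9-2", "TRBV20"),  # first listed gene
            ("TRBV9", "TRBV9"),
            ("TRAV14/DV4", "TRAV14"),
            ("TRAJ33*02", "TRAJ33"),
        ],
    )
    def test_family_normalization(self, gene, family):
        assert normalize_gene_family(gene) == family

    @pytest.mark.parametrize("bad", ["", "  ", "IGHV1-2", "V6-2", "6-2*01"])
    def test_invalid_names_rejected(self, bad):
        with pytest.raises(InvalidGeneError):
            normalize_gene_family(bad)


class TestCloneKey:
    def test_family_level_identity(self):
        """Members of the same V/J families with one junction are one clone."""
        a = build_clone_key("TRBV6-2*01", "TRBJ2-7", "CASSLGQAYEQYF")
        b = build_clone_key("TRBV6-3", "TRBJ2-7*01", "CASSLGQAYEQYF")
        assert a == b
        assert a.v_family == "TRBV6" and a.j_family == "TRBJ2"

    def test_cdr3_mismatch_distinguishes(self):
        a = build_clone_key("TRBV6-2", "TRBJ2-7", "CASSLGQAYEQYF")
        b = build_clone_key("TRBV6-2", "TRBJ2-7", "CASSLGQAYEQYV")
        assert a != b

    @pytest.mark.parametrize("cdr3", ["CASS*GF", "CASS_GF", "", "CASSxF"])
    def test_nonproductive_rejected(self, cdr3):
        with pytest.raises(NonProductiveError):
            build_clone_key("TRBV9", "TRBJ1-1", cdr3)

    def test_alpha_genes_rejected_for_beta_key(self):
        with pytest.raises(InvalidGeneError):
            build_clone_key("TRAV1-2", "TRBJ1-1", "CASSF")


def _cell(cid, beta=None, alphas=(), metacluster="unassigned", rescued=False):
    return CellRecord(
        cell_id=cid, beta=beta, alphas=alphas, metacluster=metacluster,
        beta_is_rescued=rescued,
    )


ALPHA = AlphaChain("TRAV1-2", "TRAJ33", "CAVMDSNYQLIW", "TGTGCAGTG")
ALPHA2 = AlphaChain("TRAV8-4", "TRAJ12", "CAVSDSWGKLQF", "TGTGCTGTG")


class TestAlphaRescue:
    def test_unanimous_alpha_sharers_rescue(self):
        cells = [
            _cell("x", alphas=(ALPHA,)),
            _cell("a", beta=K1, alphas=(ALPHA,)),
            _cell("b", beta=K1, alphas=(ALPHA,)),
            _cell("c", beta=K1, alphas=(ALPHA,)),
        ]
        out = rescue_beta_by_alpha(cells)
        assert out[0].beta == K1 and out[0].beta_is_rescued

    def test_split_evidence_blocks_rescue(self):
        cells = [
            _cell("x", alphas=(ALPHA,)),
            _cell("a", beta=K1, alphas=(ALPHA,)),
            _cell("b", beta=K2, alphas=(ALPHA,)),
        ]
        assert rescue_beta_by_alpha(cells)[0].beta is None

    def test_no_sharers_no_rescue(self):
        cells = [_cell("x", alphas=(ALPHA,)), _cell("a", beta=K1, alphas=(ALPHA2,))]
        assert rescue_beta_by_alpha(cells)[0].beta is None

    def test_two_alphas_conflicting_assignments_block(self):
        cells = [
            _cell("x", alphas=(ALPHA, ALPHA2)),
            _cell("a", beta=K1, alphas=(ALPHA,)),
            _cell("b", beta=K2, alphas=(ALPHA2,)),
        ]
        assert rescue_beta_by_alpha(cells)[0].beta is None

    def test_idempotent_and_never_touches_determined(self):
        cells = [
            _cell("x", alphas=(ALPHA,)),
            _cell("a", beta=K1, alphas=(ALPHA,)),
            _cell("y", alphas=(ALPHA2,)),  # only rescued x shares this alpha later
        ]
        once = rescue_beta_by_alpha(cells)
        twice = rescue_beta_by_alpha(once)
        assert once == twice
        assert once[1].beta == K1 and not once[1].beta_is_rescued


class TestDiversity:
    def test_uniform_shannon_is_ln_k(self):
        for k in (1, 2, 4, 10):
            rep = RepertoireCounts(
                {CloneKey(f"TRBV{i+1}", "TRBJ1", "CASSF"): 3 for i in range(k)}
            )
            assert shannon_index(rep) == pytest.approx(math.log(k))

    def test_skewed_counts(self):
        rep = RepertoireCounts({K1: 2, K2: 1, CloneKey("TRBV1", "TRBJ1", "CF"): 1})
        assert shannon_index(rep) == pytest.approx(1.0397, abs=1e-4)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            shannon_index(RepertoireCounts({}))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rep = random_repertoire(rng)
            total = sum(rep.entries.values())
            expected = -sum(
                (c / total) * math.log(c / total) for c in rep.entries.values()
            )
            assert shannon_index(rep) == pytest.approx(expected)


def _mh_oracle(x, y):
    keys = set(x.entries) | set(y.entries)
    X = sum(x.entries.values())
    Y = sum(y.entries.values())
    sxy = sum(x.count(k) * y.count(k) for k in keys)
    dx = sum(c * c for c in x.entries.values()) / X**2
    dy = sum(c * c for c in y.entries.values()) / Y**2
    return 2 * sxy / ((dx + dy) * X * Y)


class TestMorisitaHorn:
    def test_self_overlap_is_one(self):
        rep = RepertoireCounts({K1: 5, K2: 2})
        assert morisita_horn(rep, rep) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        x = RepertoireCounts({K1: 5})
        y = RepertoireCounts({K2: 3})
        assert morisita_horn(x, y) == 0.0

    def test_partial_overlap_value(self):
        x = RepertoireCounts({K1: 1, K2: 1})
        y = RepertoireCounts({K1: 1})
        assert morisita_horn(x, y) == pytest.approx(2 / 3)

    def test_matches_brute_force_and_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = random_repertoire(rng)
            y = random_repertoire(rng)
            mh = morisita_horn(x, y)
            assert mh == pytest.approx(_mh_oracle(x, y))
            assert mh == pytest.approx(morisita_horn(y, x))
            assert 0.0 <= mh <= 1.0 + 1e-12

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=8), st.integers(1, 5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_identical_frequency_vectors_give_one(self, counts, scale):
        keys = [CloneKey(f"TRBV{i+1}", "TRBJ1", "CASSF") for i in range(len(counts))]
        x = RepertoireCounts(dict(zip(keys, counts)))
        y = RepertoireCounts({k: c * scale for k, c in zip(keys, counts)})
        assert morisita_horn(x, y) == pytest.approx(1.0)

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(2)
        reps = [random_repertoire(rng) for _ in range(4)]
        mat = pairwise_overlap_matrix(reps)
        assert np.allclose(np.diag(mat), 1.0)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert mat[i, j] == pytest.approx(morisita_horn(reps[i], reps[j]))

    def test_pairwise_matrix_flags_empty(self):
        reps = [RepertoireCounts({K1: 1}), RepertoireCounts({})]
        mat = pairwise_overlap_matrix(reps)
        assert np.isnan(mat[1]).all() and np.isnan(mat[:, 1]).all()
        assert mat[0, 0] == 1.0


class TestAggregateAndRank:
    def test_aggregation_sums_weights(self):
        rep = aggregate_repertoire([(K1, 1), (K1, 2), (K2, 1)])
        assert rep.entries == {K1: 3, K2: 1} and rep.total == 4

    def test_empty_aggregation(self):
        rep = aggregate_repertoire([])
        assert rep.total == 0 and len(rep) == 0

    def test_cumulative_frequencies(self):
        keys = [CloneKey(f"TRBV{i}", "TRBJ1", "CASSF") for i in (1, 2, 3)]
        rep = RepertoireCounts(dict(zip(keys, (6, 3, 1))))
        entries = clone_rank_cumulative(rep)
        assert [e.cumulative_frequency for e in entries] == pytest.approx(
            [0.6, 0.9, 1.0]
        )
        assert [e.rank for e in entries] == [1, 2, 3]

    def test_uniform_half_coverage_rank(self):
        rep = RepertoireCounts(
            {CloneKey(f"TRBV{i+1}", "TRBJ1", "CASSF"): 1 for i in range(10)}
        )
        entries = clone_rank_cumulative(rep)
        first_half = min(e.rank for e in entries if e.cumulative_frequency >= 0.5)
        assert first_half == 5
        assert entries[-1].cumulative_frequency == pytest.approx(1.0)


class TestPhenotypeClassification:
    def _cells(self, clone, labels):
        return [
            _cell(f"c{i}", beta=clone, metacluster=m) for i, m in enumerate(labels)
        ]

    def test_strict_majority_calls(self):
        call = classify_clone_phenotype(K1, self._cells(K1, "AAAB"))
        assert call.call == "AD" and call.n_cells_A == 3

    def test_tie_is_ambiguous(self):
        assert classify_clone_phenotype(K1, self._cells(K1, "AABB")).call == "ambiguous"

    def test_naive_only_is_unclassified(self):
        cells = self._cells(K1, ["naive"] * 4)
        assert classify_clone_phenotype(K1, cells).call == "unclassified"

    def test_other_clones_ignored(self):
        cells = self._cells(K1, "AA") + self._cells(K2, "BBBB")
        assert classify_clone_phenotype(K1, cells).call == "AD"


def _cefx_oracle(pos, neg):
    out = set()
    for k in set(pos.entries) | set(neg.entries):
        c = pos.count(k)
        if c < 2:
            continue
        fp = c / pos.total
        fn = neg.count(k) / neg.total if neg.total else 0.0
        if fp >= 5 * fn:
            out.add(k)
    return out


class TestCefxFilter:
    def test_absent_from_negative_passes_ratio(self):
        pos = random_repertoire(np.random.default_rng(3), 4)
        pos.entries[K1] = 3
        neg = RepertoireCounts({K2: 200})
        assert K1 in cefx_specific_clones(pos, neg)

    def test_ratio_below_five_excluded(self):
        filler = CloneKey("TRBV1", "TRBJ1", "CASSF")
        pos = RepertoireCounts({K1: 2, filler: 98})
        neg = RepertoireCounts({K1: 1, filler: 99})
        # freq ratio = 2 < 5
        assert K1 not in cefx_specific_clones(pos, neg)

    def test_single_count_excluded(self):
        filler = CloneKey("TRBV1", "TRBJ1", "CASSF")
        pos = RepertoireCounts({K1: 1, filler: 9})
        neg = RepertoireCounts({filler: 10})
        assert K1 not in cefx_specific_clones(pos, neg)

    def test_empty_positive_gives_empty_set(self):
        assert cefx_specific_clones(RepertoireCounts({}), RepertoireCounts({K1: 1})) == set()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            pos = random_repertoire(rng, max_count=10)
            neg = random_repertoire(rng, max_count=10)
            assert cefx_specific_clones(pos, neg) == _cefx_oracle(pos, neg)


class TestBystanderFraction:
    def test_simple_percentages(self):
        cells = [_cell(f"c{i}", beta=K1 if i < 2 else K2) for i in range(100)]
        assert bystander_fraction(cells, {K1}) == pytest.approx(2.0)
        assert bystander_fraction(cells, set()) == 0.0

    def test_empty_population_is_error(self):
        with pytest.raises(ValueError):
            bystander_fraction([], {K1})

    def test_random_assignment_recovers_rate(self):
        rng = np.random.default_rng(5)
        cells = [
            _cell(f"c{i}", beta=K1 if rng.random() < 0.05 else K2)
            for i in range(10_000)
        ]
        # binomial 99.9% CI around 5% at n=10,000 is about +-0.7 points
        assert bystander_fraction(cells, {K1}) == pytest.approx(5.0, abs=0.75)


DB = [
    VdjdbRecord(
        cdr3_a="CAVMDSNYQLIW", trav="TRAV1-2", traj="TRAJ33",
        cdr3_b="CASSLGQAYEQYF", trbv="TRBV6-2", trbj="TRBJ2-7",
        epitope="VLEETSVML", species="CMV",
    )
]


class TestVdjdbLookup:
    def _cell(self, trbv="TRBV6-2", cdr3b="CASSLGQAYEQYF", alphas=(ALPHA,)):
        return CellRecord(
            cell_id="c", beta=K1, alphas=alphas,
            beta_v_gene=trbv, beta_j_gene="TRBJ2-7", beta_cdr3_aa=cdr3b,
        )

    def test_six_field_match(self):
        assert vdjdb_lookup(self._cell(), DB) == DB

    def test_gene_level_mismatch_blocks(self):
        # same family, different gene: exact-gene rule must reject
        assert vdjdb_lookup(self._cell(trbv="TRBV6-3"), DB) == []

    def test_beta_only_agreement_is_no_match(self):
        cell = self._cell(alphas=(ALPHA2,))
        assert vdjdb_lookup(cell, DB) == []

    def test_missing_chain_is_no_match(self):
        cell = CellRecord(cell_id="c", beta=K1, alphas=(ALPHA,))
        assert vdjdb_lookup(cell, DB) == []

    def test_allele_suffixes_ignored(self):
        db = [VdjdbRecord(
            cdr3_a=DB[0].cdr3_a, trav=DB[0].trav, traj=DB[0].traj,
            cdr3_b=DB[0].cdr3_b, trbv="TRBV6-2*01", trbj=DB[0].trbj,
        )]
        assert len(vdjdb_lookup(self._cell(), db)) == 1
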