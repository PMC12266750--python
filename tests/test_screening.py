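import itertools

import numpy as np
import pandas as pd
import pytest

from polygero.chem import Fingerprint, qed_score, smiles_to_inchikey
from polygero.screening import (
    FunnelConfig,
    binarize_probabilities,
    diversity_select,
    exclude_known,
    polypharm_filter,
    run_funnel,
)
from polygero.types import inchikey_skeleton

REQUIRED = ("drd2", "hrh1", "htr6")


class TestBinarize:
    def test_threshold_inclusive(self):
        probs = pd.DataFrame({"drd2": [0.5, 0.499]}, index=["a", "b"])
        bits = binarize_probabilities(probs, 0.5)
        assert bits["drd2"].tolist() == [1, 0]

    def test_all_zero(self):
        probs = pd.DataFrame(np.zeros((3, 2)), columns=["x", "y"])
        assert binarize_probabilities(probs).to_numpy().sum() == 0

    def test_cluster_bit_is_max_over_member_tasks(self):
        probs = pd.DataFrame({"DRD2": [0.3], "DRD3": [0.7]}, index=["a"])
        bits = binarize_probabilities(probs, 0.5,
                                      task_to_cluster={"DRD2": "drd2", "DRD3": "drd2"})
        assert bits.loc["a", "drd2"] == 1

    def test_unmapped_task_rejected(self):
        probs = pd.DataFrame({"DRD2": [0.3], "HRH1": [0.7]}, index=["a"])
        with pytest.raises(ValueError, match="HRH1"):
            binarize_probabilities(probs, 0.5, task_to_cluster={"DRD2": "drd2"})


class TestPolypharmFilter:
    def test_two_of_three_passes(self):
        bits = pd.DataFrame([[1, 1, 0]], columns=REQUIRED)
        assert polypharm_filter(bits, REQUIRED, 2).tolist() == [True]

    def test_one_of_three_fails(self):
        bits = pd.DataFrame([[0, 1, 0]], columns=REQUIRED)
        assert polypharm_filter(bits, REQUIRED, 2).tolist() == [False]

    def test_all_eight_patterns_for_each_min_count(self):
        bits = pd.DataFrame(list(itertools.product([0, 1], repeat=3)), columns=REQUIRED)
        for min_count in (1, 2, 3):
            got = polypharm_filter(bits, REQUIRED, min_count)
            expected = [sum(row) >= min_count for row in bits.to_numpy()]
            assert got.tolist() == expected

    def test_min_count_above_size_rejected(self):
        bits = pd.DataFrame([[1, 1, 1]], columns=REQUIRED)
        with pytest.raises(ValueError):
            polypharm_filter(bits, REQUIRED, 4)


class TestExcludeKnown:
    def test_empty_exclusion(self):
        table = pd.DataFrame({"smiles": ["CCO"]})
        assert exclude_known(table, set()).tolist() == [False]

    def test_skeleton_matching_is_salt_insensitive(self):
        # ethanol vs an arbitrary key sharing only the 14-char skeleton
        key = smiles_to_inchikey("CCO")
        salt_variant = inchikey_skeleton(key) + "-ZZZZZZZZZZ-M"
        table = pd.DataFrame({"smiles": ["CCO", "c1ccccc1"]})
        flags = exclude_known(table, {salt_variant})
        assert flags.tolist() == [True, False]

    def test_planted_known_compounds_flagged(self, toy_library):
        lib = toy_library[:5]
        table = pd.DataFrame({"smiles": [s for _, s in lib]})
        excluded = {smiles_to_inchikey(lib[1][1]), smiles_to_inchikey(lib[3][1])}
        flags = exclude_known(table, excluded)
        assert flags.tolist() == [False, True, False, True, False]


def sphere_fps(ids):
    """Two tight fingerprint spheres plus controllable extras."""
    base1, base2 = set(range(12)), set(range(50, 62))
    mapping = {
        "s1a": base1, "s1b": base1 - {0} | {90}, "s1c": base1 - {1} | {91},
        "s2a": base2, "s2b": base2 - {50} | {92},
    }
    return [Fingerprint(i, frozenset(mapping[i])) for i in ids]


class TestDiversitySelect:
    def test_one_pick_per_sphere(self):
        ids = ["s1a", "s1b", "s1c", "s2a", "s2b"]
        table = pd.DataFrame({"compound_id": ids,
                              "mean_required_prob": [0.9, 0.5, 0.4, 0.8, 0.3]},
                             index=ids)
        selected, rank = diversity_select(table, sphere_fps(ids), k=2, cutoff=0.8)
        assert selected.sum() == 2
        # highest-probability member of each sphere, larger sphere first
        assert selected["s1a"] and selected["s2a"]
        assert rank["s1a"] == 1 and rank["s2a"] == 2

    def test_identical_candidates_one_pick(self):
        ids = ["x", "y", "z"]
        fps = [Fingerprint(i, frozenset({1, 2, 3})) for i in ids]
        table = pd.DataFrame({"compound_id": ids}, index=ids)
        selected, _ = diversity_select(table, fps, k=5, cutoff=0.8)
        assert selected.sum() == 1

    def test_k_one_picks_largest_cluster_representative(self):
        ids = ["s1a", "s1b", "s1c", "s2a", "s2b"]
        table = pd.DataFrame({"compound_id": ids,
                              "mean_required_prob": [0.1, 0.9, 0.2, 0.9, 0.9]},
                             index=ids)
        selected, _ = diversity_select(table, sphere_fps(ids), k=1, cutoff=0.8)
        assert selected.sum() == 1 and selected["s1b"]


def hand_funnel_fixture():
    """20 compounds with hand-assigned bits and exclusions.

    Per-stage survivors are computable by inspection: 2 excluded; of the
    remaining 18, those with >= 2 of the three required bits pass the
    polypharmacology rule; QED is left unconstrained (min_qed=0).
    """
    from polygero.synth import generate_smiles_library

    lib = generate_smiles_library(20, seed=42)
    ids = [cid for cid, _ in lib]
    rng = np.random.default_rng(0)
    bits = pd.DataFrame(0, index=ids, columns=list(REQUIRED))
    # compounds 0-9 active on two clusters, 10-14 on one, 15-19 on none
    bits.iloc[0:10, 0] = 1
    bits.iloc[0:10, 1] = 1
    bits.iloc[10:15, 2] = 1
    excluded_keys = {smiles_to_inchikey(lib[0][1]), smiles_to_inchikey(lib[12][1])}
    return lib, bits.astype(float), excluded_keys


class TestRunFunnel:
    def test_ledger_matches_hand_computation(self):
        lib, bits, excluded_keys = hand_funnel_fixture()
        cfg = FunnelConfig(min_qed=0.0, k=4)
        table, ledger = run_funnel(lib, bits, cfg, excluded_keys)
        assert ledger["library"] == 20
        assert ledger["not_excluded"] == 18
        # 10 two-cluster actives minus the one excluded two-cluster compound
        assert ledger["polypharm"] == 9
        assert ledger["qed"] == 9          # min_qed 0 passes every survivor
        # independent recount with per-compound predicates
        recount = int(sum(
            (not table.loc[c, "excluded"]) and bits.loc[c, list(REQUIRED)].sum() >= 2
            for c in table.index))
        assert ledger["polypharm"] == recount
        # diversity stage: one pick per Butina cluster among survivors, capped at k
        from polygero.chem import butina_cluster, fingerprints_for
        survivors = table.index[table["qed_pass"]]
        fps = fingerprints_for([(c, table.loc[c, "smiles"]) for c in survivors])
        n_clusters = len(set(butina_cluster(fps, 0.8)))
        assert ledger["selected"] == min(4, n_clusters) == int(table["selected"].sum())

    def test_flag_monotonicity_and_ledger_nonincreasing(self):
        lib, bits, excluded_keys = hand_funnel_fixture()
        table, ledger = run_funnel(lib, bits, FunnelConfig(min_qed=0.3, k=4),
                                   excluded_keys)
        counts = list(ledger.values())
        assert counts == sorted(counts, reverse=True)
        for _, row in table.iterrows():
            if row["selected"]:
                assert row["qed_pass"]
            if row["qed_pass"]:
                assert row["polypharm_pass"]
            if row["polypharm_pass"]:
                assert not row["excluded"]

    def test_nothing_passes_polypharm(self, toy_library):
        lib = toy_library[:10]
        ids = [c for c, _ in lib]
        bits = pd.DataFrame(0.0, index=ids, columns=list(REQUIRED))
        table, ledger = run_funnel(lib, bits, FunnelConfig(k=3))
        assert ledger["polypharm"] == 0 and ledger["selected"] == 0
        assert not table["selected"].any()

    def test_known_activity_and_probability_sources_agree(self, toy_library):
        """A 0/1 known-activity matrix and the equivalent confident
        probability matrix give identical downstream funnels."""
        lib = toy_library[:15]
        ids = [c for c, _ in lib]
        rng = np.random.default_rng(3)
        bits = pd.DataFrame(rng.integers(0, 2, (15, 3)).astype(float),
                            index=ids, columns=list(REQUIRED))
        probs = bits.replace({1.0: 0.95, 0.0: 0.05})
        t1, l1 = run_funnel(lib, bits, FunnelConfig(k=3))
        t2, l2 = run_funnel(lib, probs, FunnelConfig(k=3))
        assert l1 == l2
        assert t1["selected"].tolist() == t2["selected"].tolist()

    def test_random_funnels_are_monotone(self, toy_library, rng):
        ids = [c for c, _ in toy_library]
        for seed in range(5):
            r = np.random.default_rng(seed)
            probs = pd.DataFrame(r.random((len(ids), 3)), index=ids,
                                 columns=list(REQUIRED))
            _, ledger = run_funnel(toy_library, probs, FunnelConfig(k=6))
            counts = list(ledger.values())
            assert counts == sorted(counts, reverse=True)

    def test_exclusion_polypharm_order_commutes(self):
        """exclude_known and polypharm_filter are per-compound predicates, so
        the surviving set is order-independent."""
        lib, bits, excluded_keys = hand_funnel_fixture()
        ids = [c for c, _ in lib]
        table = pd.DataFrame({"smiles": [s for _, s in lib]}, index=ids)
        excl = exclude_known(table, excluded_keys)
        poly = polypharm_filter(bits.astype(int), REQUIRED, 2)
        a_then_b = poly & ~excl
        b_then_a = ~excl & poly
        assert a_then_b.tolist() == b_then_a.tolist()
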