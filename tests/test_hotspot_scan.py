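"""Hotspot calling rules, exact binomial enrichment, overlap test, families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotspotscan import (
    OrthologGroup,
    Thresholds,
    binomial_upper_tail,
    call_hotspots,
    detect_expansions,
    go_enrichment,
    merge_ortholog_groups,
    overlap_test,
)
from hotspotscan.divergence import GeneDivergenceProfile


def _profile(gene_id, prot_intra_by_species, prot_incomparable=False):
    vals = list(prot_intra_by_species.values())
    return GeneDivergenceProfile(
        gene_id=gene_id, dna_min_inter=2.0, dna_max_intra=0.5,
        dna_max_intra_by_species={k: 0.5 for k in prot_intra_by_species},
        prot_min_inter=2.0, prot_max_intra=max(vals) if vals else 0.0,
        prot_max_intra_by_species=prot_intra_by_species,
        count_min_inter=5, count_max_intra=1, n_comparable_sites=300,
        prot_incomparable=prot_incomparable,
    )


def test_low_protein_support_is_not_raw():
    profiles = {"g": _profile("g", {"A": 0.0, "B": 0.0})}
    calls = call_hotspots(profiles, {"g": (100.0, 90.0)})
    assert calls.raw_hotspots == set()


def test_conserved_needs_only_one_quiet_species():
    profiles = {"g": _profile("g", {"A": 0.0, "B": 1.0})}
    calls = call_hotspots(profiles, {"g": (100.0, 100.0)})
    assert calls.conserved_hotspots == {"g"}


def test_support_threshold_inclusive_at_95():
    profiles = {"g": _profile("g", {"A": 0.0, "B": 0.0})}
    assert call_hotspots(profiles, {"g": (95.0, 95.0)}).raw_hotspots == {"g"}


def test_unconserved_gene_dropped_from_conserved_set():
    profiles = {"g": _profile("g", {"A": 0.8, "B": 1.2})}
    calls = call_hotspots(profiles, {"g": (100.0, 100.0)})
    assert calls.raw_hotspots == {"g"} and calls.conserved_hotspots == set()


def test_mismatched_gene_sets_rejected():
    with pytest.raises(ValueError):
        call_hotspots({"g": _profile("g", {"A": 0.0})}, {"h": (100.0, 100.0)})


@given(st.floats(min_value=95.0, max_value=100.0))
@settings(max_examples=30, deadline=None)
def test_raising_support_threshold_never_adds_hotspots(cut):
    profiles = {f"g{i}": _profile(f"g{i}", {"A": 0.0, "B": 0.0}) for i in range(6)}
    supports = {f"g{i}": (94.0 + 1.2 * i, 100.0) for i in range(6)}
    base = call_hotspots(profiles, supports, Thresholds(support_min=95.0))
    tighter = call_hotspots(profiles, supports, Thresholds(support_min=cut))
    assert tighter.raw_hotspots <= base.raw_hotspots


# --- binomial tail -----------------------------------------------------------

def exact_tail_oracle(m, N, p):
    """Independent oracle: direct summation of C(N,k) p^k (1-p)^(N-k).

    Binomial coefficients are carried as exact integers (iterative recurrence),
    each term is exponentiated from the log of the exact coefficient, the
    smaller tail side is summed with math.fsum, and the complement is taken
    when the lower side is smaller — keeping absolute error well below 1e-12
    even at N = 10^4."""
    if m == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    logp, log1mp = math.log(p), math.log1p(-p)

    def pmf_terms(k_start, k_stop):
        c = math.comb(N, k_start)
        terms = []
        for k in range(k_start, k_stop):
            if k > k_start:
                c = c * (N - k + 1) // k
            terms.append(math.exp(math.log(c) + k * logp + (N - k) * log1mp))
        return terms

    if m <= N - m + 1:
        lower = math.fsum(pmf_terms(0, m))
        return min(max(1.0 - lower, 0.0), 1.0)
    return min(math.fsum(pmf_terms(m, N + 1)), 1.0)


def test_binomial_trivial_values():
    assert binomial_upper_tail(0, 10, 0.3) == 1.0
    assert binomial_upper_tail(3, 3, 0.5) == pytest.approx(0.125)
    assert binomial_upper_tail(3, 10, 0.05) == pytest.approx(0.011503557379, abs=1e-10)


def test_binomial_bad_inputs_rejected():
    with pytest.raises(ValueError):
        binomial_upper_tail(5, 3, 0.5)
    with pytest.raises(ValueError):
        binomial_upper_tail(1, 3, 1.5)


def test_binomial_nonincreasing_in_m():
    vals = [binomial_upper_tail(m, 50, 0.2) for m in range(51)]
    assert vals[0] == 1.0
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert all(0 < v <= 1 for v in vals)


# --- enrichment --------------------------------------------------------------

def test_universal_term_never_enriched():
    universe = {f"g{i}" for i in range(20)}
    ann = {g: {"GO:ALL"} for g in universe}
    res = go_enrichment(set(list(universe)[:5]), universe, ann)
    (r,) = res
    assert r.p_bg == 1.0 and r.p_value == 1.0 and not r.enriched


def test_gene_set_equal_to_universe_not_enriched_for_common_terms():
    universe = {f"g{i}" for i in range(40)}
    ann = {g: ({"GO:A"} if i < 20 else set()) for i, g in enumerate(sorted(universe))}
    res = go_enrichment(universe, universe, ann)
    (r,) = res
    assert r.m == 20 and r.N == 40 and r.p_bg == 0.5
    assert r.p_value == pytest.approx(exact_tail_oracle(20, 40, 0.5), abs=1e-12)
    assert not r.enriched


def test_enrichment_detects_planted_signal():
    rng = np.random.default_rng(0)
    universe = {f"g{i}" for i in range(200)}
    target = set(sorted(universe)[:20])
    ann = {}
    for g in sorted(universe):
        terms = set()
        if rng.random() < (0.6 if g in target else 0.05):
            terms.add("GO:SIG")
        if rng.random() < 0.10:
            terms.add("GO:NOISE")
        if terms:
            ann[g] = terms
    res = {r.term: r for r in go_enrichment(target, universe, ann)}
    assert res["GO:SIG"].enriched
    assert not res["GO:NOISE"].enriched


def test_enrichment_empty_universe_rejected():
    with pytest.raises(ValueError):
        go_enrichment(set(), set(), {})


def test_annotated_only_flag_shrinks_universe():
    universe = {"g1", "g2", "g3", "g4"}
    ann = {"g1": {"GO:A"}, "g2": {"GO:A"}}
    r_all = go_enrichment({"g1"}, universe, ann)[0]
    r_ann = go_enrichment({"g1"}, universe, ann, annotated_only=True)[0]
    assert r_all.p_bg == 0.5 and r_ann.p_bg == 1.0


# --- overlap test ------------------------------------------------------------

def test_disjoint_hotspot_groups_give_p_one():
    groups = {f"og{i}": ({f"c{i}"}, {f"p{i}"}) for i in range(10)}
    res = overlap_test(groups, {"c0", "c1"}, {"p5", "p6"})
    assert res.direction_1.m == 0
    assert res.direction_1.p_value == 1.0 and res.direction_2.p_value == 1.0


def test_identical_hotspot_groups_closed_form():
    groups = {f"og{i}": ({f"c{i}"}, {f"p{i}"}) for i in range(100)}
    hot1 = {f"c{i}" for i in range(10)}
    hot2 = {f"p{i}" for i in range(10)}
    res = overlap_test(groups, hot1, hot2)
    assert res.direction_1.m == 10 and res.direction_1.N == 10
    assert res.direction_1.p_bg == pytest.approx(0.1)
    assert res.direction_1.p_value == pytest.approx(0.1 ** 10, rel=1e-9)
    assert res.conservative_p == max(res.direction_1.p_value, res.direction_2.p_value)


def test_overlap_p_matches_permutation_null():
    """Empirical tail frequency of m under label permutation matches the
    binomial p-value within Monte-Carlo error."""
    rng = np.random.default_rng(7)
    n_groups = 60
    groups = {f"og{i}": ({f"c{i}"}, {f"p{i}"}) for i in range(n_groups)}
    hot1 = {f"c{i}" for i in rng.choice(n_groups, size=12, replace=False)}
    hot2_idx = rng.choice(n_groups, size=15, replace=False)
    hot2 = {f"p{i}" for i in hot2_idx}
    res = overlap_test(groups, hot1, hot2)
    m_obs = res.direction_1.m

    null = []
    for _ in range(3000):
        perm = rng.choice(n_groups, size=15, replace=False)
        fake2 = {f"p{i}" for i in perm}
        with1 = {g for g, (a, b) in groups.items() if a & hot1}
        with2 = {g for g, (a, b) in groups.items() if b & fake2}
        null.append(len(with1 & with2))
    emp = np.mean([x >= m_obs for x in null])
    # hypergeometric null vs binomial model: agree loosely at these sizes
    assert emp == pytest.approx(res.direction_1.p_value, abs=0.08)


def test_overlap_no_shared_groups_rejected():
    with pytest.raises(ValueError):
        overlap_test({"og1": (set(), {"p1"})}, set(), set())


# --- ortholog families -------------------------------------------------------

def test_transitive_merge_through_shared_dmel():
    groups = [
        OrthologGroup("g1", {"cal": [("a", 100)]}, frozenset({"A"})),
        OrthologGroup("g2", {"cal": [("b", 100)]}, frozenset({"A", "B"})),
        OrthologGroup("g3", {"cal": [("c", 100)]}, frozenset({"B"})),
    ]
    table = merge_ortholog_groups(groups)
    assert len(table.families) == 1
    assert table.families[0].count("cal") == 3


def test_disjoint_dmel_sets_unmerged():
    groups = [
        OrthologGroup("g1", {"cal": [("a", 100)]}, frozenset({"A"})),
        OrthologGroup("g2", {"cal": [("b", 100)]}, frozenset({"B"})),
        OrthologGroup("g3", {"cal": [("c", 100)]}, frozenset()),
    ]
    assert len(merge_ortholog_groups(groups).families) == 3


def test_duplicate_gene_across_groups_names_it():
    groups = [
        OrthologGroup("g1", {"cal": [("dup", 100)]}, frozenset()),
        OrthologGroup("g2", {"cal": [("dup", 100)]}, frozenset()),
    ]
    with pytest.raises(ValueError, match="dup"):
        merge_ortholog_groups(groups)


def test_family_partition_matches_connected_components_oracle():
    nx = pytest.importorskip("networkx")
    rng = np.random.default_rng(13)
    for _ in range(10):
        n = int(rng.integers(5, 25))
        groups = []
        for i in range(n):
            dmel = frozenset(f"D{j}" for j in rng.choice(12, size=rng.integers(0, 4), replace=False))
            groups.append(OrthologGroup(f"g{i}", {"cal": [(f"gene{i}", 100)]}, dmel))
        table = merge_ortholog_groups(groups)

        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if groups[i].dmel_ids & groups[j].dmel_ids:
                    g.add_edge(i, j)
        expected = {frozenset(f"g{i}" for i in comp) for comp in nx.connected_components(g)}
        got = {frozenset(f.family_id.split("+")) for f in table.families}
        assert got == expected


# --- expansions --------------------------------------------------------------

def _family(counts_lengths):
    from hotspotscan.hotspot_scan import Family, FamilyTable

    fam = Family("f1", {sp: [(f"{sp}{i}", ln) for i in range(c)]
                        for sp, (c, ln) in counts_lengths.items()})
    return FamilyTable([fam], sorted(counts_lengths))


def test_expansion_rule_arithmetic():
    # focal 4 genes / 2000 residues vs others averaging 2 genes / 1200 residues
    table = _family({"cal": (4, 500), "s1": (2, 600), "s2": (2, 600)})
    assert detect_expansions(table, "cal") == ["f1"]


def test_expansion_boundary_is_strict():
    table = _family({"cal": (3, 1000), "s1": (2, 100), "s2": (2, 100)})
    # count 3 vs 1.5 * mean(2,2) = 3 -> not expanded
    assert detect_expansions(table, "cal") == []


def test_expansion_requires_both_count_and_length():
    table = _family({"cal": (4, 100), "s1": (2, 600), "s2": (2, 600)})
    # count passes (4 > 3) but length 400 <= 1.5 * 1200
    assert detect_expansions(table, "cal") == []


def test_absent_species_count_as_zero_in_average():
    from hotspotscan.hotspot_scan import Family, FamilyTable

    fam = Family("f1", {"cal": [("a", 500), ("b", 500)]})
    table = FamilyTable([fam], ["cal", "s1", "s2"])
    # others average 0 genes/0 residues; focal strictly exceeds 1.5 * 0
    assert detect_expansions(table, "cal") == ["f1"]


def test_missing_focal_species_rejected():
    table = _family({"s1": (2, 100), "s2": (2, 100)})
    with pytest.raises(ValueError):
        detect_expansions(table, "cal")
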