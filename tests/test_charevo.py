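"""Ancestral-state reconstruction and alignment site mapping, checked
against exhaustive brute-force oracles on small trees."""

from itertools import product

import dendropy
import numpy as np
import pytest

from heliovis.charevo import (
    HELICONIINI_TREE_NEWICK,
    SER116ALA_STATES,
    fitch_parsimony,
    load_tree,
    map_reference_site,
    mk_ml_ancestral,
)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementations under test)


def all_rooted_binary_newicks(tips):
    """Every rooted binary labelled topology over *tips*, as Newick strings."""
    tips = list(tips)
    if len(tips) == 1:
        return [tips[0]]
    out = []
    rest = tips[1:]
    first = tips[0]
    # choose the subset joined with the first tip on the left of the root
    for bits in product([0, 1], repeat=len(rest)):
        left = [first] + [t for t, b in zip(rest, bits) if b == 0]
        right = [t for t, b in zip(rest, bits) if b == 1]
        if not right:
            continue
        for lsub in all_rooted_binary_newicks(left):
            for rsub in all_rooted_binary_newicks(right):
                out.append(f"({lsub},{rsub})")
    return out


def brute_force_min_changes(newick, states):
    """Minimum change count by exhaustive enumeration of internal states."""
    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = np.inf
    for assign in product([0, 1], repeat=len(internals)):
        state = dict(zip(internals, assign))
        for leaf in tree.leaf_node_iter():
            state[leaf] = states[leaf.taxon.label.replace(" ", "_")]
        changes = sum(
            state[n] != state[n.parent_node]
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = min(best, changes)
    return int(best)


def brute_force_likelihood(newick, states, rate):
    """Mk likelihood by summation over all internal-state assignments."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]

    def p(t, same):
        e = np.exp(-2.0 * rate * t)
        return 0.5 + 0.5 * e if same else 0.5 - 0.5 * e

    total = 0.0
    for assign in product([0, 1], repeat=len(internals)):
        state = dict(zip(internals, assign))
        for leaf in tree.leaf_node_iter():
            state[leaf] = states[leaf.taxon.label.replace(" ", "_")]
        lik = 0.5  # uniform root prior
        for n in tree.preorder_node_iter():
            if n.parent_node is None:
                continue
            bl = n.edge.length if n.edge.length is not None else 1.0
            lik *= p(bl, state[n] == state[n.parent_node])
        total += lik
    return total


# ---------------------------------------------------------------------------
# Fitch parsimony


def test_uniform_character_needs_no_changes():
    states = {t: 0 for t in SER116ALA_STATES}
    res = fitch_parsimony(HELICONIINI_TREE_NEWICK, states)
    assert res.n_changes == 0
    assert res.change_edges == []


def test_ala116_arose_once_in_ismenius_numata_ancestor():
    """The silvaniform Ser116Ala substitution maps to exactly one origin, on
    the edge subtending the (H. ismenius, H. numata) pair."""
    res = fitch_parsimony(HELICONIINI_TREE_NEWICK, SER116ALA_STATES)
    assert res.n_changes == 1
    assert len(res.change_edges) == 1
    assert res.change_edges[0] == frozenset({"Heliconius_ismenius", "Heliconius_numata"})
    # the assigned ancestral state at the root is Ser (0)
    root_clade = frozenset(SER116ALA_STATES)
    assert res.node_states[root_clade] == 0


def test_fitch_matches_exhaustive_enumeration_on_all_4_tip_trees():
    """Exact agreement with brute force over every topology x state pattern."""
    tips = ["a", "b", "c", "d"]
    newicks = all_rooted_binary_newicks(tips)
    assert len(newicks) == 15  # (2*4-3)!! rooted binary labelled topologies
    for nwk in newicks:
        for pattern in product([0, 1], repeat=4):
            states = dict(zip(tips, pattern))
            res = fitch_parsimony(nwk + ";", states)
            assert res.n_changes == brute_force_min_changes(nwk, states)


def test_fitch_assignment_achieves_reported_count():
    """The returned internal assignment realizes the minimum change count."""
    nwk = "((a,b),((c,d),(e,f)));"
    states = {"a": 0, "b": 1, "c": 1, "d": 1, "e": 0, "f": 1}
    res = fitch_parsimony(nwk, states)
    assert len(res.change_edges) == res.n_changes


def test_parsimony_invariant_under_tip_relabeling():
    states = dict(SER116ALA_STATES)
    res1 = fitch_parsimony(HELICONIINI_TREE_NEWICK, states)
    swapped = HELICONIINI_TREE_NEWICK.replace("Heliconius_erato", "TMP").replace(
        "Heliconius_hecale", "Heliconius_erato"
    ).replace("TMP", "Heliconius_hecale")
    res2 = fitch_parsimony(swapped, states)
    assert res1.n_changes == res2.n_changes


def test_parsimony_invariant_under_rerooting():
    """The minimum change count of an unordered character does not depend on
    root placement."""
    base = load_tree("((a:1,b:1):1,((c:1,d:1):1,(e:1,f:1):1):1);")
    states = {"a": 0, "b": 1, "c": 1, "d": 1, "e": 0, "f": 0}
    ref = fitch_parsimony(base, states).n_changes
    for edge_node in list(base.preorder_node_iter())[1:]:
        t = base.clone(depth=1)
        target = next(
            n for n in t.preorder_node_iter()
            if {lf.taxon.label for lf in n.leaf_iter()}
            == {lf.taxon.label for lf in edge_node.leaf_iter()}
        )
        if target.edge.length is None:
            continue
        t.reroot_at_edge(target.edge, update_bipartitions=False)
        assert fitch_parsimony(t, states).n_changes == ref


def test_tip_state_mismatch_rejected():
    with pytest.raises(ValueError, match="absent from the tree"):
        fitch_parsimony("((a,b),c);", {"a": 0, "b": 1, "z": 0, "c": 1})
    with pytest.raises(ValueError, match="without character states"):
        fitch_parsimony("((a,b),c);", {"a": 0, "b": 1})


# ---------------------------------------------------------------------------
# Mk maximum-likelihood ancestral states


def test_two_tip_symmetry_gives_half_half():
    res = mk_ml_ancestral("(a:1,b:1);", {"a": 0, "b": 1}, rate=1.0)
    probs = res.node_probabilities[frozenset({"a", "b"})]
    assert probs[0] == pytest.approx(0.5, abs=1e-12)
    assert probs[1] == pytest.approx(0.5, abs=1e-12)


def test_pruning_likelihood_matches_brute_force_on_random_trees(rng):
    """Pruning likelihood equals exhaustive enumeration to 1e-10 relative on
    random 5- and 6-tip trees."""
    for n_tips in (5, 6):
        taxa = [f"t{i}" for i in range(n_tips)]
        for rep in range(3):
            # random topology via random sequential joins, random lengths
            parts = [f"{t}:{rng.uniform(0.1, 2.0):.3f}" for t in taxa]
            while len(parts) > 1:
                i, j = sorted(rng.choice(len(parts), size=2, replace=False))
                b = parts.pop(j)
                a = parts.pop(i)
                parts.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.3f}")
            nwk = parts[0].rsplit(":", 1)[0] + ";"
            states = {t: int(rng.integers(0, 2)) for t in taxa}
            if len(set(states.values())) < 2:
                states[taxa[0]] = 1 - states[taxa[0]]
            rate = float(rng.uniform(0.1, 2.0))
            res = mk_ml_ancestral(nwk, states, rate=rate)
            brute = brute_force_likelihood(nwk, states, rate)
            assert np.exp(res.log_likelihood) == pytest.approx(brute, rel=1e-10)


def test_low_rate_limit_matches_parsimony_on_fixture():
    """As the rate goes to zero, ML MAP states coincide with the
    most-parsimonious assignment."""
    fitch = fitch_parsimony(HELICONIINI_TREE_NEWICK, SER116ALA_STATES)
    ml = mk_ml_ancestral(HELICONIINI_TREE_NEWICK, SER116ALA_STATES, rate=1e-4)
    assert ml.unit_lengths_substituted  # fixture topology carries no lengths
    for tips, probs in ml.node_probabilities.items():
        assert fitch.node_states[tips] == int(np.argmax(probs))


def test_probabilities_normalized():
    res = mk_ml_ancestral(HELICONIINI_TREE_NEWICK, SER116ALA_STATES, rate=0.7)
    for probs in res.node_probabilities.values():
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= probs[0] <= 1.0


def test_nonpositive_rate_rejected():
    with pytest.raises(ValueError, match="rate"):
        mk_ml_ancestral(HELICONIINI_TREE_NEWICK, SER116ALA_STATES, rate=0.0)


# ---------------------------------------------------------------------------
# alignment site mapping

TOY_ALIGNMENT = """>squid_rhodopsin
---MGRDLRDNE
>seq_ser1
---MGRDSRDNE
>seq_ser2
---MGRDSRD-E
>seq_ala1
---MGRDARDNE
>seq_ala2
---MGRDARDNE
"""


def test_ungapped_reference_column_is_position_minus_one():
    aln = ">ref\nMGRDLRDNE\n>other\nMGRDSRDNE\n"
    m = map_reference_site(aln, "ref", 5)
    assert m.column == 4
    assert m.residues["other"] == "S"


def test_leading_gaps_shift_column():
    """Three leading gap columns shift the mapped column by three."""
    m = map_reference_site(TOY_ALIGNMENT, "squid_rhodopsin", 5)
    assert m.column == 4 + 3
    assert m.residues == {
        "squid_rhodopsin": "L",
        "seq_ser1": "S",
        "seq_ser2": "S",
        "seq_ala1": "A",
        "seq_ala2": "A",
    }


def test_gap_in_non_reference_sequence_reported():
    m = map_reference_site(TOY_ALIGNMENT, "squid_rhodopsin", 8)
    assert m.residues["seq_ser2"] == "-"


def test_site_mapping_round_trip():
    """column -> ungapped position -> column is the identity."""
    ref_seq = "---MGRDLRDNE"
    for pos in range(1, 10):
        m = map_reference_site(TOY_ALIGNMENT, "squid_rhodopsin", pos)
        ungapped = ref_seq[: m.column + 1].replace("-", "")
        assert len(ungapped) == pos


def test_position_beyond_reference_rejected():
    with pytest.raises(ValueError, match="beyond"):
        map_reference_site(TOY_ALIGNMENT, "squid_rhodopsin", 50)
    with pytest.raises(ValueError, match="not present"):
        map_reference_site(TOY_ALIGNMENT, "nope", 3)
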