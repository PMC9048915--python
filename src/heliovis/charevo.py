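"""Ancestral-state reconstruction of binary opsin characters and
alignment-column-to-reference-residue mapping.

Two reconstruction methods are provided for binary characters (e.g. the
Ser116Ala substitution in the blue opsin, or loss of UVRh2 expression) on a
rooted species tree:

* :func:`fitch_parsimony` -- the Fitch (1971) algorithm for unordered
  characters: minimum change count, one most-parsimonious internal-state
  assignment, and the list of edges on which changes occur.
* :func:`mk_ml_ancestral` -- marginal maximum-likelihood ancestral states
  under the symmetric two-state Mk model (single rate, uniform root prior;
  the default binary-likelihood setup of standard character-mapping tools),
  computed by Felsenstein pruning / message passing on the tree.

Site numbering in opsin alignments conventionally follows a reference
sequence (squid rhodopsin for the blue-opsin tuning sites);
:func:`map_reference_site` converts a 1-based ungapped reference residue
number to the alignment column and reports each sequence's residue there.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
from Bio import AlignIO

__all__ = [
    "FitchResult",
    "MkResult",
    "SiteMapping",
    "load_tree",
    "fitch_parsimony",
    "mk_ml_ancestral",
    "map_reference_site",
    "HELICONIINI_TREE_NEWICK",
    "SER116ALA_STATES",
]

# Species tree for the Heliconiini taxa whose blue-opsin residue 116 states
# are established: Eueides outgroup, the erato clade, the melpomene/cydno
# clade and the silvaniforms (H. hecale, and the sister pair H. ismenius +
# H. numata).
HELICONIINI_TREE_NEWICK = (
    "(Eueides_isabella,(Heliconius_erato,(Heliconius_melpomene,"
    "(Heliconius_hecale,(Heliconius_ismenius,Heliconius_numata)))));"
)

# Ala at blue-opsin site 116 (squid-rhodopsin numbering): 1 = Ala, 0 = Ser.
SER116ALA_STATES = {
    "Eueides_isabella": 0,
    "Heliconius_erato": 0,
    "Heliconius_melpomene": 0,
    "Heliconius_hecale": 0,
    "Heliconius_ismenius": 1,
    "Heliconius_numata": 1,
}


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick tree (string or file path)."""
    if "(" in newick:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    else:
        tree = dendropy.Tree.get(path=newick, schema="newick")
    labels = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip names must be unique")
    return tree


def _tip_label(node) -> str:
    return node.taxon.label.replace(" ", "_")


def _check_states(tree: dendropy.Tree, tip_states: dict[str, int]) -> None:
    tips = {_tip_label(lf) for lf in tree.leaf_node_iter()}
    missing = set(tip_states) - tips
    if missing:
        raise ValueError(f"character states given for taxa absent from the tree: {sorted(missing)}")
    unscored = tips - set(tip_states)
    if unscored:
        raise ValueError(f"tree tips without character states: {sorted(unscored)}")
    known = [s for s in tip_states.values() if s in (0, 1)]
    if len(known) < 2:
        raise ValueError("need at least two tips with known (0/1) state")


@dataclass(frozen=True)
class FitchResult:
    """Most-parsimonious reconstruction of a binary character."""

    n_changes: int
    node_states: dict  # frozenset of subtended tips -> state (tips included)
    change_edges: list  # frozensets of tips subtended by the child of each change edge


def fitch_parsimony(tree, tip_states: dict[str, int]) -> FitchResult:
    """Fitch parsimony for an unordered binary character.

    *tree* is a dendropy Tree or a Newick string; *tip_states* maps tip label
    to 0/1 (tips may use ``None`` for unknown, which is treated as the full
    state set and adds no cost).  Nodes are identified in the result by the
    frozenset of tip labels they subtend.  The downpass counts the minimum
    number of changes; the uppass picks one most-parsimonious assignment
    deterministically (ties resolve to state 0 at the root and to the parent
    state below it).
    """
    if isinstance(tree, str):
        tree = load_tree(tree)
    _check_states(tree, tip_states)
    # Fitch requires bifurcating internal nodes; resolve polytomies on a copy.
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()

    state_sets: dict = {}
    n_changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states.get(_tip_label(node))
            state_sets[node] = {0, 1} if s is None else {int(s)}
        else:
            child_sets = [state_sets[c] for c in node.child_nodes()]
            inter = set.intersection(*child_sets)
            if inter:
                state_sets[node] = inter
            else:
                state_sets[node] = set.union(*child_sets)
                n_changes += 1

    assignment: dict = {}
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        tipsets[node] = (
            frozenset([_tip_label(node)])
            if node.is_leaf()
            else frozenset().union(*(tipsets[c] for c in node.child_nodes()))
        )
    for node in tree.preorder_node_iter():
        ss = state_sets[node]
        if node.parent_node is None:
            assignment[node] = min(ss)
        else:
            parent_state = assignment[node.parent_node]
            assignment[node] = parent_state if parent_state in ss else min(ss)

    change_edges = [
        tipsets[node]
        for node in tree.preorder_node_iter()
        if node.parent_node is not None and assignment[node] != assignment[node.parent_node]
    ]
    node_states = {tipsets[n]: assignment[n] for n in assignment}
    return FitchResult(n_changes=n_changes, node_states=node_states, change_edges=change_edges)


@dataclass(frozen=True)
class MkResult:
    """Marginal ancestral-state probabilities under the 2-state Mk model."""

    log_likelihood: float
    node_probabilities: dict  # frozenset of subtended tips -> (P(0), P(1))
    unit_lengths_substituted: bool


def _p_transition(t: float, rate: float) -> np.ndarray:
    """Symmetric 2-state transition matrix over branch length t."""
    same = 0.5 + 0.5 * np.exp(-2.0 * rate * t)
    diff = 1.0 - same
    return np.array([[same, diff], [diff, same]])


def mk_ml_ancestral(tree, tip_states: dict[str, int], rate: float = 1.0) -> MkResult:
    """Marginal ancestral state probabilities by sum-product message passing.

    The model is the symmetric two-state Mk process with a single *rate* per
    unit branch length and a uniform root prior; under this reversible model
    the marginal at a node equals the normalized product of the messages
    arriving from all its neighbors, so marginals are exact for every
    internal node, not just the root.  Missing branch lengths are replaced
    by unit lengths (flagged in the result).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if isinstance(tree, str):
        tree = load_tree(tree)
    _check_states(tree, tip_states)

    # Undirected adjacency with branch lengths.
    nodes = list(tree.preorder_node_iter())
    unit_sub = False
    adj: dict = {n: [] for n in nodes}
    for node in nodes:
        for child in node.child_nodes():
            bl = child.edge.length
            if bl is None:
                bl, unit_sub = 1.0, True
            adj[node].append((child, float(bl)))
            adj[child].append((node, float(bl)))

    def tip_vector(node) -> np.ndarray:
        s = tip_states.get(_tip_label(node))
        if s is None:
            return np.ones(2)
        v = np.zeros(2)
        v[int(s)] = 1.0
        return v

    messages: dict = {}

    def message(src, dst, length) -> np.ndarray:
        """Message src -> dst: P-matrix applied to src's product of inputs."""
        key = (id(src), id(dst))
        if key in messages:
            return messages[key]
        if src.is_leaf():
            below = tip_vector(src)
        else:
            below = np.ones(2)
            for nbr, bl in adj[src]:
                if nbr is not dst:
                    below = below * message(nbr, src, bl)
        out = _p_transition(length, rate) @ below
        messages[key] = out
        return out

    prior = np.array([0.5, 0.5])
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        tipsets[node] = (
            frozenset([_tip_label(node)])
            if node.is_leaf()
            else frozenset().union(*(tipsets[c] for c in node.child_nodes()))
        )

    node_probs: dict = {}
    log_lik = None
    for node in nodes:
        if node.is_leaf():
            continue
        belief = prior.copy()
        for nbr, bl in adj[node]:
            belief = belief * message(nbr, node, bl)
        total = belief.sum()
        if log_lik is None:
            log_lik = float(np.log(total))
        node_probs[tipsets[node]] = tuple(belief / total)

    return MkResult(
        log_likelihood=float(log_lik),
        node_probabilities=node_probs,
        unit_lengths_substituted=unit_sub,
    )


@dataclass(frozen=True)
class SiteMapping:
    """One reference residue located in an alignment."""

    reference_id: str
    reference_position: int  # 1-based ungapped residue index
    column: int              # 0-based alignment column
    residues: dict           # sequence id -> one-letter residue ('-' for gaps)


def map_reference_site(alignment, reference_id: str, reference_position: int) -> SiteMapping:
    """Locate a 1-based ungapped *reference_position* in a protein MSA.

    *alignment* is a Bio.Align.MultipleSeqAlignment, a FASTA path, or FASTA
    text.  Returns the 0-based alignment column whose ungapped reference
    residue counter equals *reference_position*, plus every sequence's
    residue at that column (gaps reported as ``"-"``).
    """
    if isinstance(alignment, str):
        if alignment.lstrip().startswith(">"):
            alignment = AlignIO.read(StringIO(alignment), "fasta")
        else:
            alignment = AlignIO.read(alignment, "fasta")
    ref = next((rec for rec in alignment if rec.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference sequence {reference_id!r} not present in the alignment")
    if reference_position < 1:
        raise ValueError("reference_position is 1-based and must be >= 1")
    count = 0
    column = None
    for i, residue in enumerate(str(ref.seq)):
        if residue != "-":
            count += 1
            if count == reference_position:
                column = i
                break
    if column is None:
        raise ValueError(
            f"reference_position {reference_position} beyond the ungapped length ({count}) of {reference_id!r}"
        )
    residues = {rec.id: str(rec.seq)[column] for rec in alignment}
    return SiteMapping(
        reference_id=reference_id,
        reference_position=reference_position,
        column=column,
        residues=residues,
    )
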