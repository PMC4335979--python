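"""Synthetic inputs with recorded ground truth.

Four generators emulate the data the comparative analysis consumes:

* a rooted binary species tree (Yule topology, exponential branch lengths);
* a gene family evolved forward along that tree by a linear birth-death
  process (duplications split a lineage in place, losses terminate it);
* protein sequences evolved along the surviving gene tree under a 20-state
  equal-rates substitution model, embedded in proteomes of unrelated
  uniform-random decoy proteins;
* substrate-concentration time series with linear decay segments and
  Gaussian noise.

Every generator is a pure function of its inputs and a seed.  Default
parameters are the conditions the downstream recovery checks assume: six
species, duplication rate 0.3 and loss rate 0.1 per unit branch length,
substitution rate 0.2, 500-residue family proteins among 20 decoys per
proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import AMINO_ACIDS, SeqRecord, TreeNode
from .rates import TimeSeries

DUPLICATION = "duplication"
LOSS = "loss"


@dataclass
class SimulationConfig:
    """Parameters of the gene-family and sequence simulators.

    Rates are events per unit branch length (branch lengths are in expected
    substitutions per site for the species tree, so rates are relative to
    that scale).
    """

    n_species: int = 6
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    root_copies: int = 1
    seq_length: int = 500
    subst_rate: float = 0.2
    n_decoys_per_species: int = 20
    seed: int = 0
    branch_length_mean: float = 0.1
    decoy_length_min: int = 200
    decoy_length_max: int = 800

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.dup_rate < 0 or self.loss_rate < 0 or self.subst_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.root_copies < 1 or self.seq_length < 1:
            raise ValueError("root_copies and seq_length must be >= 1")
        if self.n_decoys_per_species < 0:
            raise ValueError("n_decoys_per_species must be >= 0")


def simulate_species_tree(n_species: int, seed: int,
                          branch_length_mean: float = 0.1) -> TreeNode:
    """Yule-topology rooted binary tree with exponential branch lengths.

    Leaves are named sp1..spN and internal nodes anc1.. in preorder, so the
    same seed always yields the same Newick string.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    root.add_child(TreeNode())
    root.add_child(TreeNode())
    leaves = list(root.children)
    while len(leaves) < n_species:
        k = int(rng.integers(len(leaves)))
        node = leaves.pop(k)
        node.add_child(TreeNode())
        node.add_child(TreeNode())
        leaves.extend(node.children)
    n_leaf = n_int = 0
    for node in root.preorder():
        if node.is_leaf():
            n_leaf += 1
            node.name = f"sp{n_leaf}"
        elif node is not root:
            n_int += 1
            node.name = f"anc{n_int}"
        else:
            node.name = "root"
        if node is not root:
            node.length = float(rng.exponential(branch_length_mean))
    return root


# ---------------------------------------------------------------------------
# Gene family birth-death simulation
# ---------------------------------------------------------------------------

@dataclass
class HistoryNode:
    """A node of the complete (unpruned) gene-lineage history."""

    kind: str                 # 'spec' | 'dup' | 'loss' | 'leaf'
    species: TreeNode         # node whose stem branch holds the point
    height: float             # distance from the species root
    children: List["HistoryNode"] = field(default_factory=list)

    def extant(self) -> bool:
        if self.kind == "leaf":
            return True
        if self.kind == "loss":
            return False
        return any(c.extant() for c in self.children)


@dataclass
class GeneFamilyTruth:
    """A simulated gene family with its full event history."""

    species_tree: TreeNode
    gene_tree: Optional[TreeNode]     # None when the family went extinct
    events: List[Tuple[str, str, float]]  # (type, species branch name, height)
    n_duplications: int
    n_losses: int
    history: HistoryNode
    extinct: bool

    def surviving_leaves(self) -> List[str]:
        return [] if self.gene_tree is None else self.gene_tree.leaf_names()


def simulate_gene_family(species_tree: TreeNode,
                         config: SimulationConfig,
                         seed: Optional[int] = None) -> GeneFamilyTruth:
    """Forward birth-death simulation of one gene family.

    A lineage traversing a species branch of length t accrues duplications
    and losses as competing Poisson processes with rates ``dup_rate * t``
    and ``loss_rate * t``.  Lineages alive at an internal species node
    speciate into both children; lineages alive at a leaf become genes
    named ``species__k``.  The pruned gene tree (extinct lineages removed,
    unary nodes suppressed, branch lengths in species-tree units) and the
    complete event list are returned.
    """
    stree = species_tree.copy()
    for node in stree.preorder():
        if node is not stree and node.length is None:
            raise ValueError("species tree must have branch lengths on all branches")
    counter = 0
    for node in stree.preorder():
        if node.name is None:
            counter += 1
            node.name = f"anc{counter}" if node.children else f"sp{counter}"
    heights = {id(stree): 0.0}
    for node in stree.preorder():
        for c in node.children:
            heights[id(c)] = heights[id(node)] + c.length

    rng = np.random.default_rng(config.seed if seed is None else seed)
    total_rate = config.dup_rate + config.loss_rate
    events: List[Tuple[str, str, float]] = []

    def run_branch(s: TreeNode, t0: float) -> HistoryNode:
        """Evolve a lineage inside the stem branch of ``s`` from offset t0."""
        top = heights[id(s)] - s.length
        t = t0
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + wait >= s.length:
                break
            t += wait
            if rng.random() < config.dup_rate / total_rate:
                events.append((DUPLICATION, s.name, top + t))
                node = HistoryNode("dup", s, top + t)
                node.children.append(run_branch(s, t))
                node.children.append(run_branch(s, t))
                return node
            events.append((LOSS, s.name, top + t))
            return HistoryNode("loss", s, top + t)
        if s.is_leaf():
            return HistoryNode("leaf", s, heights[id(s)])
        node = HistoryNode("spec", s, heights[id(s)])
        for c in s.children:
            node.children.append(run_branch(c, 0.0))
        return node

    def found_copy() -> HistoryNode:
        node = HistoryNode("spec", stree, 0.0)
        for c in stree.children:
            node.children.append(run_branch(c, 0.0))
        return node

    copies = [found_copy() for _ in range(config.root_copies)]
    history = copies[0]
    for extra in copies[1:]:
        # additional founder copies join under pre-root duplication nodes
        joined = HistoryNode("dup", stree, 0.0)
        joined.children = [history, extra]
        history = joined

    # prune to the surviving gene tree
    leaf_counter: Dict[str, int] = {}

    def prune(h: HistoryNode) -> Optional[Tuple[TreeNode, float]]:
        if h.kind == "loss":
            return None
        if h.kind == "leaf":
            sp = h.species.name
            leaf_counter[sp] = leaf_counter.get(sp, 0) + 1
            return TreeNode(name=f"{sp}__{leaf_counter[sp]}"), h.height
        kept = [p for p in (prune(c) for c in h.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node = TreeNode()
        for child, child_height in kept:
            child.length = child_height - h.height
            node.add_child(child)
        return node, h.height

    pruned = prune(history)
    gene_tree = None
    if pruned is not None:
        gene_tree, _ = pruned
        gene_tree.length = None
    n_dup = sum(1 for e in events if e[0] == DUPLICATION)
    n_loss = len(events) - n_dup
    return GeneFamilyTruth(stree, gene_tree, events, n_dup, n_loss,
                           history, extinct=pruned is None)


def is_fully_observable(truth: GeneFamilyTruth) -> bool:
    """True when the surviving gene tree reveals the complete event history.

    Parsimony reconciliation of the pruned gene tree recovers the true
    duplication and loss counts exactly iff (i) the founding speciation
    kept extant descendants on both sides, (ii) every duplication kept
    extant descendants on both sides and is still "anchored" at its true
    species branch (the species LCA of its surviving descendants is the
    branch it occurred on), and (iii) every extinct side of a speciation is
    a bare loss: the lineage died childless within its birth branch.
    Otherwise parsimony can only under-count (events above the surviving
    root, or collapsed below a displaced duplication, are invisible).
    """
    if truth.extinct:
        return False

    extant_cache: Dict[int, bool] = {}

    def extant(h: HistoryNode) -> bool:
        key = id(h)
        if key not in extant_cache:
            if h.kind == "leaf":
                extant_cache[key] = True
            elif h.kind == "loss":
                extant_cache[key] = False
            else:
                extant_cache[key] = any(extant(c) for c in h.children)
        return extant_cache[key]

    depth = {}
    for node in truth.species_tree.preorder():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = depth[id(a)], depth[id(b)]
        while da > db:
            a, da = a.parent, da - 1
        while db > da:
            b, db = b.parent, db - 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def surviving_image(h: HistoryNode) -> Optional[TreeNode]:
        if h.kind == "leaf":
            return h.species
        image = None
        for c in h.children:
            ci = surviving_image(c)
            if ci is not None:
                image = ci if image is None else lca(image, ci)
        return image

    def check(h: HistoryNode, at_root: bool) -> bool:
        if h.kind in ("leaf", "loss"):
            return True
        sides = [extant(c) for c in h.children]
        if h.kind == "dup":
            if not all(sides):
                return False
            if surviving_image(h) is not h.species:
                return False
        else:  # speciation
            if at_root:
                if not all(sides):
                    return False
            else:
                if not any(sides):
                    return False
            for c, alive in zip(h.children, sides):
                if not alive and c.kind != "loss":
                    return False
        return all(check(c, at_root=(at_root and h.kind == "dup"))
                   for c in h.children)

    return check(truth.history, at_root=True)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


def evolve_sequences(gene_tree: TreeNode, config: SimulationConfig,
                     root_seq: Optional[str] = None,
                     seed: Optional[int] = None,
                     species: Optional[List[str]] = None
                     ) -> Dict[str, List[SeqRecord]]:
    """Evolve family sequences along the gene tree and embed them in
    decoy proteomes.

    Along a branch of length t each site substitutes independently with
    probability ``1 - exp(-subst_rate * t)``, the replacement drawn
    uniformly from the 19 other residues (20-state equal-rates model).
    ``n_decoys_per_species`` uniform-random decoy proteins with lengths
    uniform in [decoy_length_min, decoy_length_max] are appended to every
    proteome.  ``species`` defaults to the species present in the gene
    tree; pass the full species list to also build proteomes for species
    whose family copies were all lost.
    """
    if config.subst_rate < 0:
        raise ValueError("subst_rate must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = config.seq_length
    if root_seq is None:
        root = _AA[rng.integers(0, 20, size=L)]
    else:
        if len(root_seq) != L:
            raise ValueError("root_seq length must equal config.seq_length")
        root = np.frombuffer(root_seq.upper().encode(), dtype="S1").copy()
    aa_index = {aa: k for k, aa in enumerate(_AA)}

    family: Dict[str, List[SeqRecord]] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            p = 1.0 - np.exp(-config.subst_rate * t)
            child_seq = seq.copy()
            if p > 0:
                hit = np.flatnonzero(rng.random(L) < p)
                if hit.size:
                    old = np.array([aa_index[a] for a in child_seq[hit]])
                    offsets = rng.integers(1, 20, size=hit.size)
                    child_seq[hit] = _AA[(old + offsets) % 20]
            if child.is_leaf():
                sp = child.name.split("__")[0]
                family.setdefault(sp, []).append(
                    SeqRecord(id=child.name, residues=child_seq.tobytes().decode(),
                              species=sp, description="family"))
            else:
                walk(child, child_seq)

    if gene_tree is not None:
        if gene_tree.is_leaf():
            sp = gene_tree.name.split("__")[0]
            family[sp] = [SeqRecord(id=gene_tree.name,
                                    residues=root.tobytes().decode(),
                                    species=sp, description="family")]
        else:
            walk(gene_tree, root)

    if species is None:
        species = sorted(family)
    proteomes: Dict[str, List[SeqRecord]] = {}
    for sp in species:
        records = list(family.get(sp, []))
        for k in range(config.n_decoys_per_species):
            n = int(rng.integers(config.decoy_length_min,
                                 config.decoy_length_max + 1))
            seq = _AA[rng.integers(0, 20, size=n)].tobytes().decode()
            records.append(SeqRecord(id=f"{sp}__decoy{k + 1}", residues=seq,
                                     species=sp, description="decoy"))
        proteomes[sp] = records
    return proteomes


# ---------------------------------------------------------------------------
# Consumption time series
# ---------------------------------------------------------------------------

@dataclass
class ConsumptionTruth:
    """Ground truth for one substrate consumption curve (g/L, h)."""

    substrate: str
    c0: float
    true_rate: float
    noise_sd: float
    times: List[float]
    strain: str = "synthetic"
    breakpoint: Optional[float] = None
    rate_after: Optional[float] = None

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.true_rate < 0:
            raise ValueError("true_rate must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")


def simulate_consumption_series(truth: ConsumptionTruth, seed: int) -> TimeSeries:
    """Piecewise-linear decay clipped at zero, plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.times, dtype=float)
    if truth.breakpoint is None:
        c = np.maximum(0.0, truth.c0 - truth.true_rate * t)
    else:
        bp = truth.breakpoint
        rate_after = truth.true_rate if truth.rate_after is None else truth.rate_after
        c_b = max(0.0, truth.c0 - truth.true_rate * bp)
        c = np.where(t < bp,
                     np.maximum(0.0, truth.c0 - truth.true_rate * t),
                     np.maximum(0.0, c_b - rate_after * (t - bp)))
    if truth.noise_sd > 0:
        c = np.maximum(0.0, c + rng.normal(0.0, truth.noise_sd, size=t.size))
    return TimeSeries(substrate=truth.substrate, strain=truth.strain,
                      points=list(zip(t.tolist(), c.tolist())))
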