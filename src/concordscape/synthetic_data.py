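"""Generators with known truth for every pipeline stage.

The fixture emulates a transcriptome supermatrix for a rapid island
radiation: ~24 taxa in five ingroup clades plus an outgroup, a species tree
whose radiation-base internodes are short in coalescent units (so gene trees
disagree there, like the contentious deep branches of a recent radiation)
while clade stems are long (so clades are cleanly monophyletic), hundreds of
genes whose trees are drawn from the multispecies coalescent, JC69 sequences
on each gene tree, and an Mk trait history on the species-tree time scale.

MSC gene trees are simulated with msprime on a demography built from the
species tree with haploid samples and population size 1, so all times are in
coalescent units; the classic concordance probability 1 - (2/3) e^(-T) for an
internode of length T is the closed-form oracle the simulator is tested
against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from . import trait_mapping
from .phylo_core import (
    CladeMap,
    GenePartition,
    MultipleAlignment,
    Node,
    PhyloError,
    PhyloTree,
    restrict_tree,
    write_partitions,
    write_trees,
)
from .quartet_likelihood import SubstitutionModel, jc69, transition_probability
from .trait_mapping import CharacterHistory, MkModel


# ---------------------------------------------------------------------------
# Multispecies-coalescent gene trees
# ---------------------------------------------------------------------------

def expected_concordance(T: float) -> float:
    """P(a gene tree resolves an internode of length T concordantly).

    1 - (2/3) e^(-T): the probability that the two lineages entering the
    internode coalesce within it, plus one third of the remainder.
    """
    if T < 0:
        raise PhyloError("internode length must be nonnegative")
    return 1.0 - (2.0 / 3.0) * math.exp(-T)


def _msprime_seed(rng_or_seed) -> int:
    ss = (rng_or_seed if isinstance(rng_or_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_or_seed))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 2) + 1


def simulate_msc_gene_trees(species_tree: PhyloTree, n_genes: int,
                            seed: int | np.random.SeedSequence = 0,
                            ) -> list[PhyloTree]:
    """Independent gene trees under the multispecies coalescent.

    ``species_tree`` must be ultrametric with branch lengths in coalescent
    units; one haploid lineage is sampled per leaf.  Returned gene-tree
    branch lengths are in coalescent units.
    """
    newick = species_tree.to_newick()
    demography = msprime.Demography.from_species_tree(newick, initial_size=1.0)
    samples = {leaf: 1 for leaf in species_tree.leaf_labels()}
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        num_replicates=n_genes,
        random_seed=_msprime_seed(seed),
    )
    pop_names = {p.id: p.name for p in demography.populations}
    out = []
    for ts in reps:
        tree = ts.first()
        labels = {
            u: pop_names[ts.node(u).population] for u in ts.samples()
        }
        out.append(PhyloTree.from_newick(
            tree.as_newick(node_labels=labels, include_branch_lengths=True)
        ))
    return out


def drop_taxa(trees: Sequence[PhyloTree], occupancy: float,
              rng: np.random.Generator) -> list[PhyloTree]:
    """Randomly prune taxa so each is present with probability ``occupancy``."""
    out = []
    for t in trees:
        taxa = t.leaf_labels()
        keep = [x for x in taxa if rng.random() < occupancy]
        if len(keep) < 4:
            keep = list(rng.choice(taxa, size=4, replace=False))
        out.append(restrict_tree(t, keep))
    return out


def scale_tree(tree: PhyloTree, factor: float) -> PhyloTree:
    """Copy with every branch length multiplied by ``factor``."""
    t = tree.copy()
    for node in t.preorder():
        if node.length is not None:
            node.length = node.length * factor
    return t


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_sequences(tree: PhyloTree, n_sites: int,
                       model: SubstitutionModel | None = None,
                       rng: np.random.Generator | int | None = None,
                       ) -> MultipleAlignment:
    """iid sites evolved down the tree; branch lengths in substitutions/site."""
    model = model or jc69()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(4, size=n_sites, p=model.freqs)
    states[id(tree.root)] = root_states
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise PhyloError(f"missing branch length above {node.label!r}")
        P = transition_probability(model, node.length)
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=np.int64)
        for s in range(4):
            mask = parent_states == s
            n = int(mask.sum())
            if n:
                child[mask] = rng.choice(4, size=n, p=P[s])
        states[id(node)] = child
    bases = np.array(list("ACGT"))
    taxa, rows = [], []
    for leaf in tree.leaves():
        taxa.append(leaf.label)
        rows.append("".join(bases[states[id(leaf)]]))
    return MultipleAlignment(taxa, rows)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_mk_traits(tree: PhyloTree, model: MkModel,
                       seed: int | np.random.Generator = 0,
                       ) -> tuple[dict, CharacterHistory]:
    """Forward Mk simulation root->tips; returns tip states and the true history."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    prior = model.prior()
    root_state = int(rng.choice(model.k, p=prior))
    node_states = {tree.root: root_state}
    branch_segments = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise PhyloError(f"missing branch length above {node.label!r}")
        state = node_states[node.parent]
        t_left = node.length
        segs: list[tuple[float, int]] = []
        seg_start = 0.0
        elapsed = 0.0
        while True:
            rate = -model.Q[state, state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if elapsed + wait >= t_left:
                segs.append((t_left - seg_start, state))
                break
            elapsed += wait
            weights = np.clip(model.Q[state].copy(), 0, None)
            weights[state] = 0.0
            new_state = int(rng.choice(model.k, p=weights / weights.sum()))
            segs.append((elapsed - seg_start, state))
            seg_start = elapsed
            state = new_state
        node_states[node] = state
        branch_segments[node] = [(d, model.states[s]) for d, s in segs]
    history = CharacterHistory(
        tree,
        {n: model.states[s] for n, s in node_states.items()},
        branch_segments,
    )
    tip_states = {leaf.label: history.node_states[leaf] for leaf in tree.leaves()}
    return tip_states, history


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    # clade name -> number of taxa (OUT is the outgroup clade)
    "clade_sizes": {"OUT": 3, "PNA": 6, "PRI": 2, "HAL": 4, "MM": 5, "AMC": 4},
    # planted ingroup arrangement, newick over clade names (no outgroup)
    "ingroup_topology": "((PNA,PRI),(HAL,(MM,AMC)));",
    # coalescent-unit ages of the radiation-base nodes (root of ingroup last);
    # consecutive differences are the short contentious internodes
    "radiation_ages": [5.32, 5.42, 5.55, 5.7],
    "crown_age": 2.0,          # age of each clade's crown
    "root_age": 12.0,          # split of the outgroup
    "n_genes": 200,
    "sites_per_gene": 300,
    "subst_scale": 0.02,       # substitutions/site per coalescent unit
    "occupancy": 1.0,
    "trait_states": ("bark", "leaf", "fungus", "generalist"),
    "trait_rate": 0.05,        # ER rate per state pair per coalescent unit
}


@dataclass
class SimulationBundle:
    species_tree: PhyloTree            # coalescent units, ultrametric
    clade_map: CladeMap
    gene_trees: list                   # coalescent units
    gene_alignments: list              # one MultipleAlignment per gene
    supermatrix: MultipleAlignment
    partitions: list
    trait_table: pd.DataFrame          # species, substrate, count
    tip_states: dict
    trait_history: CharacterHistory
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trees([self.species_tree], outdir / "species_tree.nwk")
        write_trees(self.gene_trees, outdir / "gene_trees.nwk")
        self.supermatrix.to_fasta(outdir / "supermatrix.fasta")
        write_partitions(self.partitions, outdir / "partitions.txt")
        self.clade_map.to_tsv(outdir / "clade_map.tsv")
        self.trait_table.to_csv(outdir / "rearing_records.csv", index=False)
        genes_dir = outdir / "genes"
        genes_dir.mkdir(exist_ok=True)
        for part, aln in zip(self.partitions, self.gene_alignments):
            aln.to_fasta(genes_dir / f"{part.name}.fasta")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _ladder_ages(n: int, crown_age: float) -> list[float]:
    """Node ages for a ladder subtree of n taxa, spread below the crown."""
    if n == 1:
        return []
    return [crown_age * (i + 1) / (n - 1) for i in range(n - 1)]


def _build_clade_subtree(name: str, size: int, crown_age: float,
                         stem_top_age: float) -> Node:
    """Ultrametric ladder of ``size`` taxa named <name>_1.. with a stem branch."""
    taxa = [f"{name}_{i + 1}" for i in range(size)]
    if size == 1:
        return Node(label=taxa[0], length=stem_top_age)
    ages = _ladder_ages(size, crown_age)  # increasing; last == crown_age
    sub = Node()
    sub.add_child(Node(label=taxa[0], length=ages[0]))
    sub.add_child(Node(label=taxa[1], length=ages[0]))
    prev_age = ages[0]
    for i in range(2, size):
        age = ages[i - 1]
        parent = Node()
        sub.length = age - prev_age
        parent.add_child(sub)
        parent.add_child(Node(label=taxa[i], length=age))
        sub = parent
        prev_age = age
    sub.length = stem_top_age - crown_age
    return sub


def _validate_config(config: Mapping) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(cfg)
    if unknown:
        raise PhyloError(
            f"unknown fixture config keys {sorted(unknown)}; "
            f"accepted: {sorted(cfg)}"
        )
    cfg.update(config)
    return cfg


def make_fixture(config: Mapping | None = None,
                 seed: int = 0) -> SimulationBundle:
    """Simulate a complete study bundle with known truth.

    The default emulates a ~24-taxon, 200-gene supermatrix: five ingroup
    clades on a planted arrangement with short radiation-base internodes
    (discordance-prone deep branches) plus a distant outgroup, JC69 sequences
    per gene, and an ER trait history with rearing records matching the tip
    states.
    """
    cfg = _validate_config(config or {})
    ss = np.random.SeedSequence(seed)
    s_genes, s_seqs, s_trait, s_records, s_occ = ss.spawn(5)

    species_tree = build_species_tree(cfg)
    clade_map = CladeMap(
        {
            f"{clade}_{i + 1}": clade
            for clade, size in cfg["clade_sizes"].items()
            for i in range(size)
        },
        outgroup="OUT",
    )

    gene_trees = simulate_msc_gene_trees(species_tree, cfg["n_genes"], s_genes)
    if cfg["occupancy"] < 1.0:
        gene_trees = drop_taxa(gene_trees, cfg["occupancy"],
                               np.random.default_rng(s_occ))

    seq_streams = s_seqs.spawn(cfg["n_genes"])
    gene_alignments = []
    partitions = []
    pos = 0
    for i, (gt, stream) in enumerate(zip(gene_trees, seq_streams)):
        scaled = scale_tree(gt, cfg["subst_scale"])
        aln = simulate_sequences(scaled, cfg["sites_per_gene"],
                                 rng=np.random.default_rng(stream))
        gene_alignments.append(aln)
        partitions.append(GenePartition(f"gene{i + 1:04d}", pos,
                                        pos + cfg["sites_per_gene"]))
        pos += cfg["sites_per_gene"]
    supermatrix = MultipleAlignment.concatenate(
        gene_alignments, all_taxa=sorted(clade_map.taxa())
    )

    trait_model = trait_mapping.mk_er(cfg["trait_states"], cfg["trait_rate"])
    tip_states, trait_history = simulate_mk_traits(
        species_tree, trait_model, np.random.default_rng(s_trait)
    )
    trait_table = _rearing_records(tip_states,
                                   np.random.default_rng(s_records))

    manifest = {
        "seed": seed,
        "config": {k: (dict(v) if isinstance(v, Mapping) else
                       list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in cfg.items()},
        "n_taxa": len(clade_map.taxa()),
        "n_genes": cfg["n_genes"],
        "n_sites": supermatrix.n_sites,
        "true_ingroup_topology": cfg["ingroup_topology"],
        "true_trait_transitions": trait_history.n_transitions(),
        "files": ["species_tree.nwk", "gene_trees.nwk", "supermatrix.fasta",
                  "partitions.txt", "clade_map.tsv", "rearing_records.csv",
                  "manifest.json"],
    }
    return SimulationBundle(species_tree, clade_map, gene_trees,
                            gene_alignments, supermatrix, partitions,
                            trait_table, tip_states, trait_history, manifest)


def build_species_tree(config: Mapping | None = None) -> PhyloTree:
    """Ultrametric species tree (coalescent units) for the fixture config."""
    cfg = _validate_config(config or {})
    skeleton = PhyloTree.from_newick(cfg["ingroup_topology"])
    ingroup_clades = skeleton.leaf_labels()
    sizes = cfg["clade_sizes"]
    missing = set(ingroup_clades + ["OUT"]) - set(sizes)
    if missing:
        raise PhyloError(f"clade_sizes missing entries for {sorted(missing)}")
    ages = list(cfg["radiation_ages"])
    internal_nodes = [n for n in skeleton.postorder() if not n.is_leaf]
    if len(ages) != len(internal_nodes):
        raise PhyloError(
            f"radiation_ages needs {len(internal_nodes)} entries "
            f"(one per ingroup internal node, root last)"
        )
    # assign ages to skeleton internals: postorder order, root gets the last
    node_age: dict = {}
    non_root = [n for n in internal_nodes if n is not skeleton.root]
    for node, age in zip(non_root, sorted(ages)[: len(non_root)]):
        node_age[node] = age
    node_age[skeleton.root] = max(ages)
    # fix parent > child age violations by construction order
    for node in skeleton.postorder():
        if node.is_leaf or node is skeleton.root:
            continue
        if node_age[node] >= node_age[node.parent]:
            raise PhyloError("radiation_ages must allow parent > child ages")

    crown = cfg["crown_age"]

    def expand(node: Node) -> Node:
        if node.is_leaf:
            return _build_clade_subtree(node.label, sizes[node.label], crown,
                                        node_age[node.parent])
        new = Node()
        for child in node.children:
            new.add_child(expand(child))
        if node.parent is not None:
            new.length = node_age[node.parent] - node_age[node]
        return new

    ingroup = expand(skeleton.root)
    ingroup.length = cfg["root_age"] - node_age[skeleton.root]
    root = Node()
    root.add_child(ingroup)
    out_sub = _build_clade_subtree("OUT", sizes["OUT"], crown, cfg["root_age"])
    root.add_child(out_sub)
    return PhyloTree(root, rooted=True)


def _rearing_records(tip_states: Mapping[str, str],
                     rng: np.random.Generator) -> pd.DataFrame:
    """Rearing-record counts consistent with each species' true trait state.

    Specialists get most records in their substrate (with occasional strays
    kept below the 1/4 generalist trigger); generalists get records split
    across two or three substrates.  A record count of ~6-14 per species
    mimics sparse field rearing data.
    """
    substrates = sorted({s for s in tip_states.values() if s != "generalist"})
    rows = []
    for species in sorted(tip_states):
        state = tip_states[species]
        total = int(rng.integers(6, 15))
        if state == "generalist":
            others = list(rng.choice(substrates, size=2, replace=False))
            a = int(round(total * float(rng.uniform(0.35, 0.5))))
            counts = {others[0]: a, others[1]: total - a}
        else:
            stray_pool = [s for s in substrates if s != state]
            n_stray = int(rng.integers(0, 2)) if total >= 9 else 0
            counts = {state: total - n_stray}
            if n_stray:
                counts[str(rng.choice(stray_pool))] = n_stray
        for substrate, count in counts.items():
            rows.append({"species": species, "substrate": substrate,
                         "count": count})
    return pd.DataFrame(rows)
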