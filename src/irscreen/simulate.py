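"""Sequence-evolution simulators with known ground truth.

Ortholog families are evolved along a species tree under a 20-state
uniform-replacement Poisson model: along a branch of effective length
d (expected substitutions per site, optionally scaled by a per-branch rate
multiplier), each site receives Poisson(d) substitution events, each
replacing the current residue uniformly among the other 19. The model is
deliberately simple because it has a closed-form expected pairwise identity,

    E[identity] = 1/20 + (19/20) * exp(-20 d / 19)

for two leaves at total path distance d, which serves as an exact oracle for
the screen. Codon families evolve under a kappa-biased nucleotide proposal
process with per-site omega classes: proposals creating stop codons are
rejected and nonsynonymous proposals are accepted with probability
min(1, omega), so omega is the ground-truth nonsynonymous/synonymous rate
ratio at each site.

Lineage acceleration is modelled as a rate multiplier on the focal terminal
branch, the synthetic twin of the focal-lineage acceleration the screen is
designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqio import OrthologGroup, ProteinRecord, write_fasta
from .selection import CodonAlignment, _AA, _STOPS

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)

#: Glires-consistent toy topology: the house mouse groups with human and
#: rabbit against bovine, and the human-mouse path is shorter than the
#: human-bovine path, matching the phylogenetic expectation the Identity
#: Ratio argues from.
DEFAULT_TREE = "((human:0.09,(rabbit:0.10,house_mouse:0.12):0.02):0.02,bovine:0.16);"

SENSE_CODONS = tuple(sorted(_AA))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def parse_species_tree(newick: str, panel: Sequence[str] | None = None):
    """Parse a rooted Newick species tree and validate it against a panel."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = leaf.taxon.label.replace(" ", "_")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in species tree")
    if panel is not None:
        missing = set(panel) - leaves
        if missing:
            raise ValueError(f"species tree is missing panel leaves: {sorted(missing)}")
    return tree


def branch_key(node) -> str:
    """Stable branch identifier: leaf label, or '+'-joined sorted leaf set."""
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _branch_multipliers(tree, rates: Mapping[str, float] | None) -> dict[str, float]:
    keys = {branch_key(node) for node in tree.preorder_node_iter()}
    multipliers = {k: 1.0 for k in keys}
    for key, mult in (rates or {}).items():
        if key not in keys:
            raise ValueError(f"unknown branch key {key!r}; known: {sorted(keys)}")
        if mult <= 0:
            raise ValueError(f"branch multiplier for {key!r} must be positive")
        multipliers[key] = float(mult)
    return multipliers


def expected_pairwise_identity(d: float) -> float:
    """Closed-form expected site identity at total path distance ``d``."""
    return 1 / 20 + (19 / 20) * math.exp(-20.0 * d / 19.0)


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one simulated protein family."""

    gene_symbol: str
    seed: int
    branch_multipliers: dict
    accelerated: bool = False


def _evolve_uniform(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(d) events per site; each replaces uniformly among the other 19."""
    out = seq.copy()
    if d <= 0:
        return out
    remaining = rng.poisson(d, size=out.size)
    while (mask := remaining > 0).any():
        idx = np.flatnonzero(mask)
        out[idx] = (out[idx] + rng.integers(1, 20, size=idx.size)) % 20
        remaining[idx] -= 1
    return out


def simulate_protein_family(
    tree,
    length: int,
    rates: Mapping[str, float] | None = None,
    seed: int = 0,
    gene_symbol: str = "GENE1",
) -> tuple[OrthologGroup, FamilyTruth]:
    """Evolve one protein family along ``tree``; identical seed, identical output."""
    if isinstance(tree, str):
        tree = parse_species_tree(tree)
    if length < 1:
        raise ValueError("length must be >= 1")
    multipliers = _branch_multipliers(tree, rates)
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    states = {id(root): rng.integers(0, 20, size=length)}
    members: dict[str, ProteinRecord] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        d = (node.edge.length or 0.0) * multipliers[branch_key(node)]
        states[id(node)] = _evolve_uniform(states[id(node.parent_node)], d, rng)
        if node.is_leaf():
            species = node.taxon.label
            sequence = _AA_INDEX[states[id(node)]].tobytes().decode()
            members[species] = ProteinRecord(
                accession=f"SIM-{gene_symbol}-{species}",
                gene_symbol=gene_symbol,
                species=species,
                sequence=sequence,
            )
    truth = FamilyTruth(
        gene_symbol=gene_symbol,
        seed=seed,
        branch_multipliers=multipliers,
        accelerated=any(m != 1.0 for m in multipliers.values()),
    )
    return OrthologGroup(gene_symbol, members), truth


# ---------------------------------------------------------------------------
# Codon families


@dataclass(frozen=True)
class CodonTruth:
    """Ground truth for one simulated codon family."""

    seed: int
    site_omega: tuple[float, ...]  # per-codon omega, fixed at the root
    kappa: float


def _mutate_codon(codon: str, omega: float, kappa: float, rng) -> str:
    """One proposal event: kappa-biased nucleotide change with omega filtering."""
    pos = int(rng.integers(3))
    current = codon[pos]
    others = [nt for nt in "ACGT" if nt != current]
    weights = np.array(
        [kappa if nt == _TRANSITION[current] else 1.0 for nt in others]
    )
    target = others[int(rng.choice(3, p=weights / weights.sum()))]
    proposal = codon[:pos] + target + codon[pos + 1 :]
    if proposal in _STOPS:
        return codon
    if _AA[proposal] != _AA[codon] and rng.random() >= min(1.0, omega):
        return codon
    return proposal


def simulate_codon_family(
    tree,
    n_codons: int,
    kappa: float = 2.0,
    omega_classes: Sequence[tuple[float, float]] = ((1.0, 1.0),),
    seed: int = 0,
) -> tuple[dict[str, str], CodonTruth]:
    """Evolve a codon alignment along ``tree`` with per-site omega classes.

    Returns leaf label -> gap-free CDS, plus the ground truth. Branch lengths
    are proposal intensities per nucleotide site (3d proposals per codon).
    """
    if isinstance(tree, str):
        tree = parse_species_tree(tree)
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    omegas = np.array([w for w, _ in omega_classes], dtype=float)
    props = np.array([p for _, p in omega_classes], dtype=float)
    if (omegas < 0).any():
        raise ValueError("omega values must be >= 0")
    if props.sum() <= 0:
        raise ValueError("omega-class proportions must not all be zero")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("omega-class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    site_omega = omegas[rng.choice(len(omegas), size=n_codons, p=props)]
    root_codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    root = tree.seed_node
    states = {id(root): root_codons}
    leaves: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        d = node.edge.length or 0.0
        parent = states[id(node.parent_node)]
        child = list(parent)
        if d > 0:
            n_events = rng.poisson(3.0 * d, size=n_codons)
            for i in np.flatnonzero(n_events):
                for _ in range(n_events[i]):
                    child[i] = _mutate_codon(child[i], site_omega[i], kappa, rng)
        states[id(node)] = child
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(child)
    truth = CodonTruth(seed=seed, site_omega=tuple(site_omega), kappa=kappa)
    return leaves, truth


def codon_alignment_pair(leaves: Mapping[str, str], a: str, b: str) -> CodonAlignment:
    """The (gap-free by construction) codon alignment of two simulated leaves."""
    return CodonAlignment(leaves[a], leaves[b])


# ---------------------------------------------------------------------------
# Screen-scale datasets


def generate_screen_dataset(
    n_genes: int,
    frac_accelerated: float,
    acceleration: float,
    tree: str | None = None,
    length: int = 300,
    seed: int = 0,
    focal: str = "house_mouse",
    out_dir=None,
) -> tuple[list[OrthologGroup], pd.DataFrame]:
    """Simulate a whole screening panel with a known accelerated subset.

    A fraction of genes (drawn without replacement) carries ``acceleration``
    as a rate multiplier on the focal terminal branch; the rest evolve at the
    tree's base rates. Optionally writes per-gene FASTA, a truth TSV and a
    run manifest under ``out_dir``.
    """
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4 (the outlier fence needs >= 4 genes)")
    if not 0 <= frac_accelerated <= 1:
        raise ValueError("frac_accelerated must be in [0, 1]")
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    newick = tree or DEFAULT_TREE
    parsed = parse_species_tree(newick, panel=[focal])
    rng = np.random.default_rng(seed)
    n_acc = int(round(frac_accelerated * n_genes))
    accelerated = set(rng.choice(n_genes, size=n_acc, replace=False).tolist())
    gene_seeds = [
        int(s) for s in rng.integers(0, 2**31 - 1, size=n_genes)
    ]
    groups: list[OrthologGroup] = []
    truth_rows = []
    for i in range(n_genes):
        gene = f"GENE{i + 1:04d}"
        rates = {focal: float(acceleration)} if i in accelerated else None
        group, _ = simulate_protein_family(
            parsed, length, rates=rates, seed=gene_seeds[i], gene_symbol=gene
        )
        groups.append(group)
        truth_rows.append(
            {
                "gene": gene,
                "accelerated": i in accelerated,
                "focal_multiplier": float(acceleration) if i in accelerated else 1.0,
                "seed": gene_seeds[i],
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for group in groups:
            write_fasta(
                [group.members[sp] for sp in sorted(group.members)],
                out / f"{group.gene_symbol}.fasta",
            )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "manifest.txt", "w") as fh:
            for k, v in (
                ("tree", newick),
                ("n_genes", n_genes),
                ("frac_accelerated", frac_accelerated),
                ("acceleration", acceleration),
                ("length", length),
                ("focal", focal),
                ("seed", seed),
            ):
                fh.write(f"{k}={v}\n")
    return groups, truth
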