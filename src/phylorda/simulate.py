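"""Synthetic species-trait datasets with known phylogenetic and ecological
signal.

The generator emulates the statistical structure the comparative analysis
assumes: a pure-birth (Yule) tree; latent continuous traits composed of a
Brownian-motion (BM) component evolved on the tree, an effect of an assigned
ecological category, and i.i.d. noise,

    z = a * BM_std + b * eco_effect_std + noise_sd * N(0, 1),

with the BM and ecological components standardized across species so the
latent variance shares are a² : b² : noise_sd².  Observable trait rows are
then shaped like the empirical table: mean fecundity and reproductive
frequency from latents, reproductive mode by median thresholding of a latent,
reproductive potential by the derivation rule, the driving ecological
category as substrate use, and an inert habitat classification.  Categories
can be spread as contiguous blocks of the tree's leaf order (phylogenetically
clustered, inducing ecology–phylogeny covariation) or i.i.d. uniform.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .traits import (
    CodedMatrix,
    SpeciesTraitRow,
    build_ecology_matrix,
    make_trait_row,
)
from .tree import PhyloTree, parse_newick

__all__ = ["SimConfig", "SimDataset", "simulate_tree", "evolve_bm", "generate_dataset"]

_SUBSTRATE_LEVELS = ("aquatic", "terrestrial", "arboreal", "fossorial")
_HABITAT_LEVELS = ("forest", "wetland", "savanna", "generalist")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    ``phylo_weight`` (a) and ``eco_weight`` (b) scale the standardized BM and
    ecological components of each latent trait; ``noise_sd`` scales the
    residual.  ``eco_clustered_on_tree`` makes ecological categories
    phylogenetically clustered, so that ecology and phylogeny share variance.
    """

    n_species: int = 24
    birth_rate: float = 1.0
    phylo_weight: float = 1.0
    eco_weight: float = 0.5
    noise_sd: float = 0.5
    n_numeric_traits: int = 2
    n_categorical_traits: int = 1
    n_eco_categories: int = 3
    eco_clustered_on_tree: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.birth_rate <= 0 or self.noise_sd <= 0:
            raise ValueError("birth_rate and noise_sd must be positive")
        if not (np.isfinite(self.phylo_weight) and np.isfinite(self.eco_weight)):
            raise ValueError("weights must be finite")
        if self.phylo_weight < 0 or self.eco_weight < 0:
            raise ValueError("weights must be nonnegative")
        if not 2 <= self.n_eco_categories <= len(_SUBSTRATE_LEVELS):
            raise ValueError("n_eco_categories must be in [2, 4]")


@dataclass
class SimDataset:
    """A simulated dataset plus its generating truth."""

    tree: PhyloTree
    rows: list[SpeciesTraitRow]
    eco_matrix: CodedMatrix
    truth: dict = field(default_factory=dict)

    def traits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species_id for r in self.rows],
                "tribe": [r.tribe for r in self.rows],
                "N": [r.n_individuals for r in self.rows],
                "RM": ["O" if r.mode == "oviparous" else "V" for r in self.rows],
                "RF": [r.rf for r in self.rows],
                "RP": [r.rp_class[0].upper() for r in self.rows],
                "MF": [r.mf for r in self.rows],
                "SU": [
                    {"aquatic": "AQ", "terrestrial": "T", "arboreal": "A",
                     "fossorial": "F"}[r.substrate]
                    for r in self.rows
                ],
                "HU": [
                    {"forest": "Fo", "wetland": "W", "savanna": "S",
                     "generalist": "G"}[r.habitat]
                    for r in self.rows
                ],
            }
        )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.traits_frame().to_csv(out / "traits.csv", index=False)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Simulate a pure-birth (Yule) ultrametric tree with ``n_species`` leaves."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    width = len(str(n_species))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda lf: lf.taxon.label), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    # round-trip through our parser for a clean, label-preserving wrapper
    newick = tree.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True).strip()
    return parse_newick(newick)


def evolve_bm(
    tree: PhyloTree, sigma: float, root_value: float = 0.0, seed: int = 0
) -> pd.Series:
    """Evolve one continuous trait by Brownian motion along the tree.

    Leaf values are jointly normal with covariance sigma² times shared
    root-to-node path length.  Requires branch lengths on every edge.
    """
    if not tree.has_branch_lengths():
        raise ValueError("Brownian motion needs branch lengths on every edge")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            parent = values[id(node.parent_node)]
            step = rng.normal(0.0, sigma * np.sqrt(node.edge.length))
            values[id(node)] = parent + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="bm").sort_index()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _assign_categories(
    tree: PhyloTree, n_categories: int, clustered: bool, rng: np.random.Generator
) -> dict[str, int]:
    leaves_in_order = [lf.taxon.label for lf in tree.tree.leaf_node_iter()]
    n = len(leaves_in_order)
    if clustered:
        # contiguous blocks of the tree's leaf order: each category occupies
        # one neighbourhood of the tree
        bounds = np.linspace(0, n, n_categories + 1).astype(int)
        assign = {}
        for c in range(n_categories):
            for sp in leaves_in_order[bounds[c]:bounds[c + 1]]:
                assign[sp] = c
        return assign
    return {sp: int(rng.integers(n_categories)) for sp in leaves_in_order}


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate a complete synthetic dataset under ``config``.

    The returned truth record stores the weights, the expected latent-variance
    shares a²/(a²+b²+s²) etc., and the per-trait realized variance shares of
    the three components.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, seed=cfg.seed)
    species = sorted(tree.leaf_labels)

    category = _assign_categories(tree, cfg.n_eco_categories,
                                  cfg.eco_clustered_on_tree, rng)
    cat_vec = np.array([category[sp] for sp in species])

    n_latent = cfg.n_numeric_traits + cfg.n_categorical_traits + 1  # +1 drives RF
    a, b, s = cfg.phylo_weight, cfg.eco_weight, cfg.noise_sd
    latents = np.zeros((len(species), n_latent))
    realized = []
    for j in range(n_latent):
        bm = evolve_bm(tree, sigma=1.0, seed=int(rng.integers(2**31)))
        bm_part = _standardize(bm.loc[species].to_numpy())
        effects = rng.normal(size=cfg.n_eco_categories)
        eco_part = _standardize(effects[cat_vec])
        noise = rng.normal(size=len(species))
        latents[:, j] = a * bm_part + b * eco_part + s * noise
        tot = latents[:, j].var(ddof=1)
        realized.append(
            {
                "phylo": float(a**2 * np.var(bm_part, ddof=1) / tot) if tot else 0.0,
                "eco": float(b**2 * np.var(eco_part, ddof=1) / tot) if tot else 0.0,
                "noise": float(s**2 * np.var(noise, ddof=1) / tot) if tot else 0.0,
            }
        )

    mf = np.round(np.clip(11.0 + 3.5 * latents[:, 0], 1.0, None), 2)
    rf = np.round(np.clip(0.65 + 0.15 * latents[:, 1], 0.05, 1.0), 2)
    mode_latent = latents[:, 2]
    viviparous = mode_latent <= np.median(mode_latent)
    habitat_assign = {
        sp: _HABITAT_LEVELS[int(rng.integers(len(_HABITAT_LEVELS)))] for sp in species
    }
    rows = [
        make_trait_row(
            species_id=sp,
            tribe=f"group{category[sp] + 1}",
            n_individuals=30,
            mode="viviparous" if viviparous[i] else "oviparous",
            rf=float(rf[i]),
            mf=float(mf[i]),
            substrate=_SUBSTRATE_LEVELS[category[sp]],
            habitat=habitat_assign[sp],
        )
        for i, sp in enumerate(species)
    ]
    eco_matrix = build_ecology_matrix(rows)
    denom = a**2 + b**2 + s**2
    truth = {
        "a": a,
        "b": b,
        "noise_sd": s,
        "expected_shares": {
            "phylo": a**2 / denom,
            "eco": b**2 / denom,
            "noise": s**2 / denom,
        },
        "realized_shares": realized,
        "eco_clustered_on_tree": cfg.eco_clustered_on_tree,
        "seed": cfg.seed,
    }
    return SimDataset(tree=tree, rows=rows, eco_matrix=eco_matrix, truth=truth)
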