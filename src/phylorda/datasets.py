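"""Packaged worked example: 17 South American xenodontine snake species.

The trait table transcribes the published community table (reproductive mode,
frequency, potential, mean fecundity, substrate and habitat use for 918 adult
females across six tribes); the companion tree encodes the groupings that are
certain from the published phylogeny — the six tribes, the multi-species
genera, and the sister relationship of the monotypic aquatic tribe
Hydrodynastini with Pseudoboini — with an unresolved backbone polytomy.  The
single-species tribe Hydrodynastini is carried as a labelled unifurcation so
it can serve as a candidate clade variable.

One printed row is internally inconsistent: Erythrolamprus poecilogyrus has
RF 0.6 and MF 8 (product 4.8, category "low") but is printed "medium".  The
fixture keeps the printed letter; the row is flagged
``rp_class_consistent=False`` rather than silently corrected.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .traits import SpeciesTraitRow, make_trait_row
from .tree import PhyloTree, parse_newick

__all__ = ["load_fixture", "load_species_csv"]

_MODE = {"O": "oviparous", "V": "viviparous"}
_RP = {"L": "low", "M": "medium", "H": "high"}
_SUBSTRATE = {"AQ": "aquatic", "T": "terrestrial", "A": "arboreal", "F": "fossorial"}
_HABITAT = {"Fo": "forest", "FO": "forest", "W": "wetland", "S": "savanna",
            "G": "generalist"}


def _row_from_record(rec: dict) -> SpeciesTraitRow:
    try:
        return make_trait_row(
            species_id=rec["species"],
            tribe=rec["tribe"],
            n_individuals=int(rec["N"]),
            mode=_MODE[rec["RM"]],
            rf=float(rec["RF"]),
            mf=float(rec["MF"]),
            substrate=_SUBSTRATE[rec["SU"]],
            habitat=_HABITAT[rec["HU"]],
            rp_class=_RP[rec["RP"]],
        )
    except KeyError as exc:
        raise ValueError(f"unknown code {exc} in row for {rec.get('species')!r}")


def load_species_csv(path) -> list[SpeciesTraitRow]:
    """Read a species trait table in the published letter-code format.

    Expected columns: species, tribe, N, RM (O/V), RF, RP (L/M/H), MF,
    SU (AQ/T/A/F), HU (Fo/W/S/G).
    """
    frame = pd.read_csv(path)
    required = {"species", "tribe", "N", "RM", "RF", "RP", "MF", "SU", "HU"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"species CSV is missing columns: {sorted(missing)}")
    return [_row_from_record(rec) for rec in frame.to_dict(orient="records")]


def load_fixture() -> tuple[list[SpeciesTraitRow], PhyloTree, dict]:
    """Load the packaged snake community dataset.

    Returns the 17 trait rows, the fixture tree, and provenance notes
    (including which rows carry a printed trait category that disagrees with
    the derivation rule).
    """
    data = resources.files("phylorda") / "data"
    rows = load_species_csv(data / "xenodontinae_traits.csv")
    tree = parse_newick((data / "xenodontinae_tree.nwk").read_text())
    inconsistent = [r.species_id for r in rows if not r.rp_class_consistent]
    notes = {
        "n_species": len(rows),
        "n_individuals": sum(r.n_individuals for r in rows),
        "rp_class_as_printed": inconsistent,
        "tree_checksum": tree.checksum(),
        "backbone": "root polytomy; tribes, multi-species genera and "
        "(Hydrodynastini, Pseudoboini) encoded as clades",
    }
    return rows, tree, notes
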