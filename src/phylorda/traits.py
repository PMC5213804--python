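"""Species-level reproductive traits: derivation from specimen records and
numeric coding for ordination.

The species unit of analysis is a row of reproductive attributes (reproductive
mode, frequency, mean fecundity, reproductive potential) plus two ecological
classifications (substrate use, habitat use).  Continuous attributes are
derived from mature-female specimen records; categorical attributes are
expanded to full (redundant) dummy blocks so that every category keeps its own
arrow in a triplot.  All coded matrices are column-centered before ordination;
under ``scaling="correlation"`` columns are additionally brought to unit
variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpecimenRecord",
    "SpeciesTraitRow",
    "CodingSpec",
    "CodedMatrix",
    "ReproductionMatrixEncoder",
    "EcologyMatrixEncoder",
    "summarize_species",
    "classify_frequency",
    "reproductive_potential",
    "classify_potential",
    "build_response_matrix",
    "build_ecology_matrix",
]

MODES = ("oviparous", "viviparous")
FREQ_CLASSES = ("annual", "biennial")
RP_CLASSES = ("low", "medium", "high")
SUBSTRATES = ("aquatic", "terrestrial", "arboreal", "fossorial")
HABITATS = ("forest", "wetland", "savanna", "generalist")


class InsufficientDataError(ValueError):
    """No usable mature-female records for a species."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One adult female with her reproductive status.

    ``is_reproductive`` means vitellogenic follicles or oviductal eggs were
    present; ``clutch_count`` counts oviductal eggs plus embryos and is only
    defined for reproductive females.
    """

    species_id: str
    is_mature_female: bool
    is_reproductive: bool
    clutch_count: int | None = None
    in_reproductive_season: bool = True
    svl_mm: float | None = None
    largest_follicle_mm: float | None = None

    def __post_init__(self) -> None:
        if self.clutch_count is not None:
            if self.clutch_count < 0:
                raise ValueError("clutch_count must be nonnegative")
            if not self.is_reproductive:
                raise ValueError("clutch_count present implies a reproductive female")
        if self.is_reproductive and not self.is_mature_female:
            raise ValueError("a reproductive female must be mature")
        for name in ("svl_mm", "largest_follicle_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SpeciesTraitRow:
    """Per-species trait summary matching one row of the worked-example table.

    ``rp_value`` is mean fecundity x reproductive frequency (potential
    neonates per female per year).  ``rp_class_consistent`` is False when the
    carried (as-printed) class disagrees with the class recomputed from
    ``rp_value``; such rows are kept as printed but flagged.
    """

    species_id: str
    tribe: str
    n_individuals: int
    mode: str
    rf: float
    freq_class: str
    mf: float
    rp_value: float
    rp_class: str
    substrate: str
    habitat: str
    rp_class_consistent: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown reproductive mode {self.mode!r}")
        if self.freq_class not in FREQ_CLASSES:
            raise ValueError(f"unknown frequency class {self.freq_class!r}")
        if self.rp_class not in RP_CLASSES:
            raise ValueError(f"unknown potential class {self.rp_class!r}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if not 0.0 <= self.rf <= 1.0:
            raise ValueError("rf must lie in [0, 1]")
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not math.isclose(self.rp_value, self.mf * self.rf, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"{self.species_id}: rp_value {self.rp_value} != mf*rf {self.mf * self.rf}"
            )
        if self.freq_class != classify_frequency(self.rf):
            raise ValueError(
                f"{self.species_id}: freq_class {self.freq_class!r} inconsistent "
                f"with rf={self.rf}"
            )


@dataclass(frozen=True)
class CodingSpec:
    """How a trait table was turned into numbers."""

    numeric: tuple[str, ...]
    dummy_blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)
    centered: bool = True
    standardized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "dummy_blocks", dict(self.dummy_blocks))


@dataclass
class CodedMatrix:
    """Labelled numeric matrix plus its coding provenance.

    Used both as the response ("main") matrix and as explanatory ("external")
    matrices.  ``values`` is a species x variables DataFrame whose columns are
    centered (mean zero) and, if ``spec.standardized``, unit variance.
    """

    values: pd.DataFrame
    spec: CodingSpec

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_labels(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, columns: Sequence[str]) -> "CodedMatrix":
        return CodedMatrix(self.values[list(columns)].copy(), self.spec)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="species")


def summarize_species(
    records: Iterable[SpecimenRecord], species_id: str
) -> dict[str, float | int | None]:
    """Derive reproductive frequency and mean fecundity for one species.

    RF is the proportion of reproductive females among mature females sampled
    in the reproductive season.  MF is the mean clutch count (oviductal eggs +
    embryos) over females for which a count exists; with no counts MF is
    ``None`` (missing, never zero).
    """
    in_season = [
        r
        for r in records
        if r.species_id == species_id and r.is_mature_female and r.in_reproductive_season
    ]
    if not in_season:
        raise InsufficientDataError(
            f"insufficient data: no mature females in the reproductive season "
            f"for {species_id!r}"
        )
    n_repro = sum(r.is_reproductive for r in in_season)
    rf = n_repro / len(in_season)
    counts = [r.clutch_count for r in in_season if r.clutch_count is not None]
    mf = float(np.mean(counts)) if counts else None
    return {"species_id": species_id, "n": len(in_season), "rf": rf, "mf": mf}


def classify_frequency(rf: float) -> str:
    """Annual vs biennial cycle from reproductive frequency.

    Half or less of mature females reproductive in the breeding season is the
    signature of a biennial (or longer) cycle.
    """
    if not 0.0 <= rf <= 1.0:
        raise ValueError(f"rf must lie in [0, 1], got {rf}")
    return "biennial" if rf <= 0.5 else "annual"


def classify_potential(rp_value: float) -> str:
    """Low / medium / high reproductive potential.

    Below 5 is low, above 10 is high; the closed interval [5, 10] is medium so
    that the rule is total.
    """
    if rp_value < 0:
        raise ValueError("rp_value must be nonnegative")
    if rp_value < 5:
        return "low"
    if rp_value > 10:
        return "high"
    return "medium"


def reproductive_potential(mf: float, rf: float) -> tuple[float, str]:
    """Reproductive potential MF x RF and its category."""
    if mf < 0:
        raise ValueError("mf must be nonnegative")
    if not 0.0 <= rf <= 1.0:
        raise ValueError(f"rf must lie in [0, 1], got {rf}")
    rp = mf * rf
    return rp, classify_potential(rp)


def _rows_to_frame(rows: Iterable[SpeciesTraitRow]) -> pd.DataFrame:
    rows = list(rows)
    if not rows:
        raise ValueError("no trait rows supplied")
    seen: set[str] = set()
    for r in rows:
        if r.species_id in seen:
            raise ValueError(f"duplicate species {r.species_id!r}")
        seen.add(r.species_id)
    return pd.DataFrame(
        {
            "mf": [r.mf for r in rows],
            "rf": [r.rf for r in rows],
            "mode": [r.mode for r in rows],
            "freq_class": [r.freq_class for r in rows],
            "rp_class": [r.rp_class for r in rows],
            "substrate": [r.substrate for r in rows],
            "habitat": [r.habitat for r in rows],
        },
        index=pd.Index([r.species_id for r in rows], name="species"),
    )


def _dummies(series: pd.Series, levels: Sequence[str], prefix: str) -> pd.DataFrame:
    unknown = set(series) - set(levels)
    if unknown:
        raise ValueError(f"unknown {prefix} label(s): {sorted(unknown)}")
    return pd.DataFrame(
        {f"{prefix}_{lv}": (series == lv).astype(float) for lv in levels},
        index=series.index,
    )


def _finish(values: pd.DataFrame, spec: CodingSpec) -> CodedMatrix:
    out = values - values.mean(axis=0)
    if spec.standardized:
        sd = out.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        out = out / sd
    return CodedMatrix(out, spec)


class ReproductionMatrixEncoder(TransformerMixin, BaseEstimator):
    """Code reproductive traits into the ordination response matrix.

    Parameters
    ----------
    scaling : {"covariance", "correlation"}
        ``"covariance"`` centers columns only (a variance–covariance
        ordination); ``"correlation"`` additionally standardizes each column
        to unit variance, removing the dominance of mean fecundity's scale.
    frequency_coding : {"binary", "numeric"}
        Enter reproductive frequency as annual/biennial dummies or as the
        numeric RF proportion.
    """

    def __init__(
        self,
        scaling: Literal["covariance", "correlation"] = "correlation",
        frequency_coding: Literal["binary", "numeric"] = "binary",
    ):
        self.scaling = scaling
        self.frequency_coding = frequency_coding

    def fit(self, rows: Iterable[SpeciesTraitRow], y=None):
        if self.scaling not in ("covariance", "correlation"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.frequency_coding not in ("binary", "numeric"):
            raise ValueError(f"unknown frequency_coding {self.frequency_coding!r}")
        self.n_features_in_ = 1
        return self

    def transform(self, rows: Iterable[SpeciesTraitRow]) -> CodedMatrix:
        self.fit(rows)
        frame = _rows_to_frame(rows)
        if frame["mf"].isna().any():
            missing = frame.index[frame["mf"].isna()][0]
            raise ValueError(f"missing trait 'mf' for species {missing!r}")
        blocks = [frame[["mf"]].astype(float)]
        dummy_blocks: dict[str, tuple[str, ...]] = {}
        blocks.append(_dummies(frame["mode"], MODES, "mode"))
        dummy_blocks["mode"] = tuple(f"mode_{m}" for m in MODES)
        if self.frequency_coding == "binary":
            blocks.append(_dummies(frame["freq_class"], FREQ_CLASSES, "freq"))
            dummy_blocks["freq"] = tuple(f"freq_{f}" for f in FREQ_CLASSES)
            numeric = ("mf",)
        else:
            blocks.append(frame[["rf"]].astype(float))
            numeric = ("mf", "rf")
        blocks.append(_dummies(frame["rp_class"], RP_CLASSES, "rp"))
        dummy_blocks["rp"] = tuple(f"rp_{c}" for c in RP_CLASSES)
        spec = CodingSpec(
            numeric=numeric,
            dummy_blocks=dummy_blocks,
            centered=True,
            standardized=self.scaling == "correlation",
        )
        return _finish(pd.concat(blocks, axis=1), spec)


class EcologyMatrixEncoder(TransformerMixin, BaseEstimator):
    """Code substrate and habitat use into the external ecological matrix.

    Produces one centered dummy column per category (4 substrate + 4 habitat);
    full redundant coding is kept, rank deficiency being the ordination
    engine's concern.
    """

    def fit(self, rows: Iterable[SpeciesTraitRow], y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, rows: Iterable[SpeciesTraitRow]) -> CodedMatrix:
        frame = _rows_to_frame(rows)
        su = _dummies(frame["substrate"], SUBSTRATES, "substrate")
        hu = _dummies(frame["habitat"], HABITATS, "habitat")
        spec = CodingSpec(
            numeric=(),
            dummy_blocks={
                "substrate": tuple(su.columns),
                "habitat": tuple(hu.columns),
            },
            centered=True,
            standardized=False,
        )
        return _finish(pd.concat([su, hu], axis=1), spec)


def build_response_matrix(
    rows: Iterable[SpeciesTraitRow],
    scaling: Literal["covariance", "correlation"] = "correlation",
    frequency_coding: Literal["binary", "numeric"] = "binary",
) -> CodedMatrix:
    """Functional wrapper over :class:`ReproductionMatrixEncoder`."""
    return ReproductionMatrixEncoder(
        scaling=scaling, frequency_coding=frequency_coding
    ).fit_transform(rows)


def build_ecology_matrix(rows: Iterable[SpeciesTraitRow]) -> CodedMatrix:
    """Functional wrapper over :class:`EcologyMatrixEncoder`."""
    return EcologyMatrixEncoder().fit_transform(rows)


def make_trait_row(
    species_id: str,
    tribe: str,
    n_individuals: int,
    mode: str,
    rf: float,
    mf: float,
    substrate: str,
    habitat: str,
    rp_class: str | None = None,
) -> SpeciesTraitRow:
    """Build a :class:`SpeciesTraitRow`, deriving the classified fields.

    If ``rp_class`` is given it is carried as printed and checked against the
    category recomputed from ``mf * rf``; a disagreement sets
    ``rp_class_consistent=False`` instead of raising, so published tables can
    be ingested verbatim.
    """
    rp_value, derived = reproductive_potential(mf, rf)
    carried = rp_class if rp_class is not None else derived
    return SpeciesTraitRow(
        species_id=species_id,
        tribe=tribe,
        n_individuals=n_individuals,
        mode=mode,
        rf=rf,
        freq_class=classify_frequency(rf),
        mf=mf,
        rp_value=rp_value,
        rp_class=carried,
        substrate=substrate,
        habitat=habitat,
        rp_class_consistent=carried == derived,
    )
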