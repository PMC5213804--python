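"""Canonical phylogenetic ordination: clade tests, forward selection and
variance partitioning.

The inference procedure is: (1) test each candidate explanatory column
(ecological category or clade indicator) marginally with a permutation
pseudo-F test; (2) build a reduced explanatory matrix by forward stepwise
selection — at each step the candidate adding the most explained inertia is
admitted if its conditional permutation test passes the significance level;
(3) partition the response variance over the selected ecological and
phylogenetic matrices into unique, shared and unexplained fractions using
three nested RDA fits.

Significance decisions in forward selection default to the mid-p variant of
the permutation p-value.  With few species the permutation null of a small
clade is strongly discrete — a single-species clade among n species can never
reach p below 1/n under the +1 convention, so a strict cutoff would silently
bar every monotypic group from selection regardless of effect size.  Mid-p
counts tied statistics half and is asymptotically identical to the +1 rule
for continuous statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .rda import fit_rda, permutation_test
from .traits import CodedMatrix

__all__ = [
    "CladeTestTable",
    "SelectionStep",
    "ForwardSelector",
    "VarPartition",
    "marginal_clade_tests",
    "forward_select",
    "variance_partition",
    "run_full_cpo",
]


def _name_seed(seed: int, name: str) -> int:
    """Stable per-variable seed, independent of column order."""
    import zlib

    return int(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())])
        .generate_state(1)[0] % (2**31)
    )


def _columns_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CodedMatrix):
        return matrix.values
    if hasattr(matrix, "as_coded"):
        return matrix.as_coded().values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    raise TypeError("expected a CodedMatrix, CladeMatrix or DataFrame")


@dataclass
class CladeTestTable:
    """Per-clade marginal RDA fractions with permutation tests."""

    table: pd.DataFrame  # columns: fraction, pseudo_f, p_value, mid_p, seed

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("fraction", ascending=False)

    def to_csv(self, path) -> None:
        self.ranked().to_csv(path, index_label="clade")


def marginal_clade_tests(
    Y, clades, n_permutations: int = 9999, seed: int = 0
) -> CladeTestTable:
    """Single-constraint RDA + permutation test for every clade column.

    Fractions are of the total inertia of ``Y``.  Each clade gets its own
    substream of the seeded generator, so the table does not depend on
    column order.
    """
    cl = _columns_frame(clades)
    if cl.shape[1] == 0:
        raise ValueError("empty clade set")
    rows = {}
    for col in cl.columns:
        col_seed = _name_seed(seed, col)
        x = cl[[col]]
        model = fit_rda(Y, x)
        perm = permutation_test(Y, x, n_permutations=n_permutations, seed=col_seed)
        rows[col] = {
            "fraction": model.explained_fraction_,
            "pseudo_f": perm.observed_f,
            "p_value": perm.p_value,
            "mid_p": perm.mid_p,
            "seed": col_seed,
        }
    return CladeTestTable(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass(frozen=True)
class SelectionStep:
    """One forward-selection step."""

    variable: str
    added_fraction: float
    cumulative_fraction: float
    pseudo_f: float
    p_value: float
    mid_p: float
    seed: int


class ForwardSelector(BaseEstimator):
    """Forward stepwise selection of explanatory columns for an RDA.

    At each step the remaining candidate with the largest additional
    explained inertia (ties broken by column label) is tested conditionally
    on the current selection; it joins the model when significant at
    ``alpha``.  Selection stops at the first failure.

    Parameters
    ----------
    alpha : significance level for the conditional permutation test.
    n_permutations : Monte-Carlo permutations per step.
    selection_rule : {"mid_p", "p_value"}
        Which p variant the alpha cutoff is applied to (see module docstring).
    scheme : permutation scheme for conditional steps.

    Attributes
    ----------
    selected_ : list of selected column labels, in selection order.
    steps_ : list of :class:`SelectionStep` (includes the first failing step).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 9999,
        selection_rule: Literal["mid_p", "p_value"] = "mid_p",
        scheme: Literal["reduced_model", "unrestricted"] = "reduced_model",
        seed: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.selection_rule = selection_rule
        self.scheme = scheme
        self.seed = seed

    def fit(self, X, Y) -> "ForwardSelector":
        """Select from candidate columns ``X`` to explain response ``Y``."""
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        cand = _columns_frame(X)
        selected: list[str] = []
        steps: list[SelectionStep] = []
        step_idx = 0
        while len(selected) < cand.shape[1]:
            base = cand[selected] if selected else None
            f_base = fit_rda(Y, base).explained_fraction_ if selected else 0.0
            best_col, best_add = None, -np.inf
            for col in sorted(c for c in cand.columns if c not in selected):
                trial = cand[selected + [col]]
                add = fit_rda(Y, trial).explained_fraction_ - f_base
                if add > best_add + 1e-12:
                    best_col, best_add = col, add
            if best_col is None:
                break
            step_seed = int(
                np.random.SeedSequence([self.seed, step_idx]).generate_state(1)[0]
                % (2**31)
            )
            perm = permutation_test(
                Y,
                cand[[best_col]],
                W=base,
                n_permutations=self.n_permutations,
                seed=step_seed,
                scheme=self.scheme,
            )
            decision_p = perm.mid_p if self.selection_rule == "mid_p" else perm.p_value
            steps.append(
                SelectionStep(
                    variable=best_col,
                    added_fraction=best_add,
                    cumulative_fraction=f_base + best_add,
                    pseudo_f=perm.observed_f,
                    p_value=perm.p_value,
                    mid_p=perm.mid_p,
                    seed=step_seed,
                )
            )
            step_idx += 1
            if decision_p > self.alpha:
                break
            selected.append(best_col)
        self.selected_ = selected
        self.steps_ = steps
        return self

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps_]).set_index("variable")


def forward_select(
    Y,
    candidates,
    alpha: float = 0.05,
    n_permutations: int = 9999,
    seed: int = 0,
    selection_rule: Literal["mid_p", "p_value"] = "mid_p",
    scheme: Literal["reduced_model", "unrestricted"] = "reduced_model",
) -> ForwardSelector:
    """Functional wrapper over :class:`ForwardSelector`."""
    return ForwardSelector(
        alpha=alpha,
        n_permutations=n_permutations,
        selection_rule=selection_rule,
        scheme=scheme,
        seed=seed,
    ).fit(candidates, Y)


@dataclass(frozen=True)
class VarPartition:
    """Three-way partition of explained variance over two explanatory sets.

    All fractions are of the total inertia of the response:
    A (unique to the phylogenetic set), B (unique to the ecological set),
    C (shared), U (unexplained); A + B + C + U = 1.  C can be negative with
    suppressor structure and is reported as computed.
    """

    unique_phylo: float
    unique_eco: float
    shared: float
    unexplained: float
    r_eco: float
    r_phylo: float
    r_joint: float

    @property
    def total_joint(self) -> float:
        return self.unique_phylo + self.unique_eco + self.shared

    def as_dict(self) -> dict[str, float]:
        return {
            "A_unique_phylo": self.unique_phylo,
            "B_unique_eco": self.unique_eco,
            "C_shared": self.shared,
            "U_unexplained": self.unexplained,
            "R_eco": self.r_eco,
            "R_phylo": self.r_phylo,
            "R_joint": self.r_joint,
        }


def variance_partition(Y, X_eco, X_phylo) -> VarPartition:
    """Partition response variance over ecological and phylogenetic sets.

    Computed from three fits (eco alone, phylo alone, both); the unique
    fractions equal the corresponding partial-RDA fractions by construction
    and that identity is verified here to numerical precision.
    """
    eco = _columns_frame(X_eco)
    phy = _columns_frame(X_phylo)
    joint = pd.concat([eco, phy], axis=1)
    if joint.isna().any().any():
        raise ValueError("ecological and phylogenetic matrices are misaligned")
    r_eco = fit_rda(Y, eco).explained_fraction_
    r_phy = fit_rda(Y, phy).explained_fraction_
    r_joint = fit_rda(Y, joint).explained_fraction_
    a = r_joint - r_eco
    b = r_joint - r_phy
    c = r_eco + r_phy - r_joint
    u = 1.0 - r_joint
    # cross-check against the partial-RDA route
    a_partial = fit_rda(Y, phy, W=eco).explained_fraction_
    b_partial = fit_rda(Y, eco, W=phy).explained_fraction_
    for direct, partial, name in ((a, a_partial, "A"), (b, b_partial, "B")):
        if abs(direct - partial) > 1e-8:
            raise AssertionError(
                f"partition fraction {name} disagrees with partial RDA: "
                f"{direct} vs {partial}"
            )
    return VarPartition(
        unique_phylo=a,
        unique_eco=b,
        shared=c,
        unexplained=u,
        r_eco=r_eco,
        r_phylo=r_phy,
        r_joint=r_joint,
    )


def run_full_cpo(
    trait_rows,
    tree,
    config=None,
    include_ecology: bool = True,
) -> dict:
    """End-to-end analysis: ecological RDA, CPO and the partial-CPO partition.

    Stages: (1) forward selection over the ecological dummies; (2) marginal
    clade tests and forward selection over the clade candidates; (3) variance
    partition over the two selected sets, plus triplot scores of the joint
    model.  Returns a JSON-serializable report dict.  If no ecological
    columns are available (or none is selected) the partition is omitted and
    the report contains the CPO stages only.
    """
    from .config import AnalysisConfig
    from .traits import build_ecology_matrix, build_response_matrix
    from .tree import clade_indicators

    cfg = config or AnalysisConfig(seed=0)
    report: dict = {"config": cfg.as_dict(), "stages": {}}

    Y = build_response_matrix(
        trait_rows, scaling=cfg.scaling, frequency_coding=cfg.frequency_coding
    )
    report["total_inertia"] = fit_rda(Y, Y).total_inertia_

    # ---- stage 1: ecology
    eco = build_ecology_matrix(trait_rows) if include_ecology else None
    if eco is not None and eco.values.shape[1] > 0:
        sel_eco = forward_select(
            Y,
            eco,
            alpha=cfg.alpha,
            n_permutations=cfg.n_permutations,
            seed=_stage_seed(cfg.seed, "ecology"),
            selection_rule=cfg.selection_rule,
            scheme=cfg.partial_permutation,
        )
        eco_sel = sel_eco.selected_
        report["stages"]["ecology"] = {
            "selected": eco_sel,
            "steps": _steps_payload(sel_eco),
            "full_model_fraction": fit_rda(Y, eco).explained_fraction_,
        }
    else:
        eco_sel = []

    # ---- stage 2: phylogeny (CPO)
    clades = clade_indicators(
        tree,
        exclude_root=True,
        min_size=cfg.min_clade_size,
        labelled_only=cfg.candidate_clades == "labelled_only",
    )
    marg = marginal_clade_tests(
        Y,
        clades,
        n_permutations=cfg.n_permutations,
        seed=_stage_seed(cfg.seed, "marginal"),
    )
    sel_phy = forward_select(
        Y,
        clades,
        alpha=cfg.alpha,
        n_permutations=cfg.n_permutations,
        seed=_stage_seed(cfg.seed, "clades"),
        selection_rule=cfg.selection_rule,
        scheme=cfg.partial_permutation,
    )
    phylo_sel = sel_phy.selected_
    cpo_stage = {
        "marginal_tests": marg.ranked().to_dict(orient="index"),
        "selected": phylo_sel,
        "steps": _steps_payload(sel_phy),
        "all_clades_fraction": fit_rda(Y, clades).explained_fraction_,
    }
    if phylo_sel:
        model = fit_rda(Y, clades.subset(phylo_sel))
        cpo_stage["selected_model_fraction"] = model.explained_fraction_
        cpo_stage["first_two_axes_of_canonical"] = model.axis_variation(2)
    report["stages"]["cpo"] = cpo_stage

    # ---- stage 3: partial CPO / variance partition
    if eco_sel and phylo_sel:
        X_eco = eco.subset(eco_sel)
        X_phy = clades.subset(phylo_sel)
        part = variance_partition(Y, X_eco, X_phy)
        joint = pd.concat([X_eco.values, X_phy.values.add_prefix("clade_")], axis=1)
        joint_model = fit_rda(Y, joint)
        report["stages"]["pcpo"] = {
            "partition": part.as_dict(),
            "joint_pseudo_f": joint_model.pseudo_f(),
            "first_two_axes_of_canonical": joint_model.axis_variation(2),
            "triplot": {
                key: frame.round(6).to_dict(orient="index")
                for key, frame in joint_model.triplot_scores().items()
            },
        }
    report["seed"] = cfg.seed
    return report


def _stage_seed(seed: int, stage: str) -> int:
    h = np.random.SeedSequence([seed, sum(ord(c) for c in stage)])
    return int(h.generate_state(1)[0] % (2**31))


def _steps_payload(selector: ForwardSelector) -> list[dict]:
    return [
        {
            "variable": s.variable,
            "added_fraction": s.added_fraction,
            "cumulative_fraction": s.cumulative_fraction,
            "pseudo_f": s.pseudo_f,
            "p_value": s.p_value,
            "mid_p": s.mid_p,
            "seed": s.seed,
        }
        for s in selector.steps_
    ]
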