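"""Analysis configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class AnalysisConfig:
    """Options of the full CPO pipeline.

    ``seed`` must be given explicitly: every permutation test in a run is
    seeded from it, making reports exactly reproducible.
    """

    seed: int
    scaling: str = "correlation"
    frequency_coding: str = "binary"
    candidate_clades: str = "labelled_only"
    min_clade_size: int = 1
    n_permutations: int = 9999
    alpha: float = 0.05
    partial_permutation: str = "reduced_model"
    selection_rule: str = "mid_p"

    def __post_init__(self) -> None:
        if self.scaling not in ("covariance", "correlation"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.frequency_coding not in ("binary", "numeric"):
            raise ValueError(f"unknown frequency_coding {self.frequency_coding!r}")
        if self.candidate_clades not in ("all_nodes", "labelled_only"):
            raise ValueError(f"unknown candidate_clades {self.candidate_clades!r}")
        if self.partial_permutation not in ("reduced_model", "unrestricted"):
            raise ValueError(
                f"unknown partial_permutation {self.partial_permutation!r}"
            )
        if self.selection_rule not in ("mid_p", "p_value"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_clade_size < 1:
            raise ValueError("min_clade_size must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)
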