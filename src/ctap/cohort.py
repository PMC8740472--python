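"""Cohort assembly: studies + CP declarations -> comparison pairs, M and M'."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cohort_io import CPSpec, ExpressionStudy
from .comparison_pairs import (
    CohortMatrix,
    ComparisonPair,
    build_big_matrix,
    build_comparison_pair,
    control_col,
    test_col,
)
from .tqn import TQNParams, trimmed_quantile_normalize

__all__ = ["Cohort", "assemble_cohort"]


@dataclass(frozen=True)
class Cohort:
    """Assembled cohort: CPs, the raw matrix M, and its TQN-normalized M'."""

    cps: tuple[ComparisonPair, ...]
    matrix: CohortMatrix
    m_prime: CohortMatrix

    @property
    def contexts(self) -> dict[int, str]:
        return {cp.cp_id: cp.context for cp in self.cps}

    @property
    def genes(self) -> list[str]:
        return self.matrix.genes

    def cp(self, cp_id: int) -> ComparisonPair:
        for cp in self.cps:
            if cp.cp_id == cp_id:
                return cp
        raise KeyError(f"no CP with id {cp_id}")


def assemble_cohort(
    studies: Sequence[ExpressionStudy],
    cp_specs: Sequence[CPSpec],
    tqn_params: TQNParams | None = None,
    *,
    fc_scale: str = "raw",
) -> Cohort:
    """Build all comparison pairs, the big matrix M, and the normalized M'.

    ``fc_scale`` selects the scale on which log2 fold changes are computed:
    ``"raw"`` (default) takes them from the original population means before
    normalization; ``"normalized"`` recomputes them from the corresponding
    columns of M'.
    """
    if fc_scale not in ("raw", "normalized"):
        raise ValueError(f"fc_scale must be 'raw' or 'normalized', got {fc_scale!r}")
    by_id = {s.study_id: s for s in studies}
    cps = []
    for spec in cp_specs:
        if spec.study_id not in by_id:
            raise KeyError(f"CP {spec.cp_id}: unknown study {spec.study_id!r}")
        cps.append(build_comparison_pair(by_id[spec.study_id], spec))
    matrix = build_big_matrix(cps)
    m_prime = trimmed_quantile_normalize(matrix, tqn_params)
    if fc_scale == "normalized":
        from .comparison_pairs import LAPLACE
        import numpy as np

        renorm = []
        for cp in cps:
            e_c = m_prime.values[control_col(cp.cp_id)].clip(lower=0.0)
            e_t = m_prime.values[test_col(cp.cp_id)].clip(lower=0.0)
            fc = np.log2((e_t + LAPLACE) / (e_c + LAPLACE))
            renorm.append(
                ComparisonPair(cp.cp_id, cp.context, e_c, e_t, fc[cp.genes])
            )
        cps = renorm
    return Cohort(cps=tuple(cps), matrix=matrix, m_prime=m_prime)
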