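"""Comparison pairs and the unnormalized cohort matrix.

A comparison pair (CP) contrasts a test population against a control
population within one study.  Per gene, both populations are averaged and the
log2 ratio

    R_i = log2((E_t + 0.01) / (E_c + 0.01))

is taken, with the +0.01 Laplacian correction damping ratios of near-zero
intensities.  All CPs are then assembled into the cohort ("big") matrix M with
two columns per CP — one for the control-population mean, one for the test —
over the union of all genes; genes unmeasured in a CP's study are imputed as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CPSpec, ExpressionStudy, PopulationSpec

__all__ = [
    "LAPLACE",
    "ComparisonPair",
    "CohortMatrix",
    "population_mean",
    "log2_ratio",
    "build_comparison_pair",
    "build_big_matrix",
    "control_col",
    "test_col",
]

LAPLACE = 0.01  # additive correction applied to both populations


def control_col(cp_id: int) -> str:
    return f"{cp_id}:control"


def test_col(cp_id: int) -> str:
    return f"{cp_id}:test"


@dataclass(frozen=True)
class ComparisonPair:
    """One test-vs-control contrast summarized as per-gene log2 ratios."""

    cp_id: int
    context: str
    control_mean: pd.Series  # gene -> E_c
    test_mean: pd.Series  # gene -> E_t
    log2fc: pd.Series  # gene -> R_i

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    def to_table(self) -> pd.DataFrame:
        """The two-column export form: gene symbol, log2 ratio."""
        return pd.DataFrame(
            {"gene": self.log2fc.index, "log2fc": self.log2fc.to_numpy()}
        )

    def write(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CohortMatrix:
    """Gene x (2 x #CP) intensity matrix, columns '<cp>:control', '<cp>:test'."""

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cps(self) -> int:
        return len(self.values.columns) // 2

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path: str | Path) -> "CohortMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="gene"))


def population_mean(study: ExpressionStudy, pop: PopulationSpec) -> pd.Series:
    """Per-gene arithmetic mean intensity over a population's samples."""
    missing = [s for s in pop.sample_ids if s not in study.values.columns]
    if missing:
        raise ValueError(
            f"population {pop.label!r} references samples {missing} absent "
            f"from study {study.study_id!r}"
        )
    return study.values[list(pop.sample_ids)].mean(axis=1)


def log2_ratio(e_t: float, e_c: float) -> float:
    """Laplacian-corrected log2 ratio of test over control intensity."""
    if e_t < 0 or e_c < 0:
        raise ValueError(f"negative intensity (e_t={e_t}, e_c={e_c})")
    return float(np.log2((e_t + LAPLACE) / (e_c + LAPLACE)))


def _log2_ratio_vec(e_t: pd.Series, e_c: pd.Series) -> pd.Series:
    if (e_t < 0).any() or (e_c < 0).any():
        raise ValueError("negative intensity in population means")
    return np.log2((e_t + LAPLACE) / (e_c + LAPLACE))


def build_comparison_pair(study: ExpressionStudy, spec: CPSpec) -> ComparisonPair:
    """Average the two populations and take per-gene log2 ratios."""
    e_c = population_mean(study, spec.control)
    e_t = population_mean(study, spec.test)
    return ComparisonPair(
        cp_id=spec.cp_id,
        context=spec.context,
        control_mean=e_c,
        test_mean=e_t,
        log2fc=_log2_ratio_vec(e_t, e_c),
    )


def build_big_matrix(cps: Sequence[ComparisonPair]) -> CohortMatrix:
    """Assemble the cohort matrix M over the union of all CP gene sets.

    Column order follows CP order, control before test within each CP.  Genes
    unmeasured in a CP's study take value 0 in both of that CP's columns.
    """
    if not cps:
        raise ValueError("at least one comparison pair required")
    genes = sorted(set().union(*(set(cp.genes) for cp in cps)))
    cols: dict[str, pd.Series] = {}
    for cp in cps:
        cols[control_col(cp.cp_id)] = cp.control_mean
        cols[test_col(cp.cp_id)] = cp.test_mean
    frame = pd.DataFrame(cols, index=genes, dtype=float).fillna(0.0)
    return CohortMatrix(frame)
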