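"""The five-value feature vector: log2 fold change plus four Z-scores.

Per gene and comparison pair the learner sees

    (R_i, Z_Cic, Z_Cit, Z_Ric, Z_Rit)

where R_i is the CP's log2 fold change, Z_C* are column-wise Z-scores of the
gene's control/test value against all genes of that column of the normalized
cohort matrix M', and Z_R* are row-wise Z-scores of the same two values
against the gene's full row across every column of M'.  The column Z-scores
carry absolute transcript abundance relative to the sample, the row Z-scores
relative to the gene's own behaviour across the cohort — the signal behind
the Gene-Present-Sufficiently / Gene-Absent-Insufficiently calls.

Standard deviations use the population (divide-by-n) convention.  Degenerate
rows or columns (sigma = 0, e.g. a gene zero-imputed everywhere) yield Z = 0
with a warning under the default lenient mode, or raise under strict mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .comparison_pairs import CohortMatrix, ComparisonPair, control_col, test_col

__all__ = [
    "FEATURE_NAMES",
    "GeneFeatures",
    "DegenerateStatsError",
    "row_zscore",
    "col_zscore",
    "assemble_features",
    "feature_table",
]

FEATURE_NAMES = ("log2fc", "z_col_control", "z_col_test",
                 "z_row_control", "z_row_test")


class DegenerateStatsError(ValueError):
    """Zero-variance row or column under strict mode."""


@dataclass(frozen=True)
class GeneFeatures:
    """Ordered 5-feature vector for one gene in one comparison pair."""

    log2fc: float
    z_col_control: float
    z_col_test: float
    z_row_control: float
    z_row_test: float

    def as_array(self) -> np.ndarray:
        return np.array([self.log2fc, self.z_col_control, self.z_col_test,
                         self.z_row_control, self.z_row_test])


def _z(value: float, mu: float, sigma: float, what: str, strict: bool) -> float:
    if sigma > 0.0:
        return (value - mu) / sigma
    if strict:
        raise DegenerateStatsError(f"{what}: zero standard deviation")
    warnings.warn(f"{what}: zero standard deviation, Z set to 0", stacklevel=3)
    return 0.0


def row_zscore(
    m_prime: CohortMatrix, gene: str, column: str, *, strict: bool = False
) -> float:
    """Z-score of a gene's value in one column against its full row of M'."""
    row = m_prime.values.loc[gene].to_numpy(dtype=float)
    value = float(m_prime.values.at[gene, column])
    return _z(value, float(row.mean()), float(row.std()),
              f"row {gene!r}", strict)


def col_zscore(
    m_prime: CohortMatrix, gene: str, column: str, *, strict: bool = False
) -> float:
    """Z-score of a gene's value against all genes of one column of M'."""
    col = m_prime.values[column].to_numpy(dtype=float)
    value = float(m_prime.values.at[gene, column])
    return _z(value, float(col.mean()), float(col.std()),
              f"column {column!r}", strict)


def assemble_features(
    cp: ComparisonPair,
    m_prime: CohortMatrix,
    gene: str,
    *,
    strict: bool = False,
) -> GeneFeatures:
    """Assemble the 5-feature vector of one gene in one comparison pair.

    Feature 1 is the CP's log2 fold change (0 for genes zero-imputed into the
    cohort matrix but unmeasured in this CP's study, consistent with
    log2((0+0.01)/(0+0.01))).  Features 2-3 are column Z-scores in the CP's
    control and test columns, features 4-5 the row Z-scores at the same two
    columns.
    """
    if gene not in m_prime.values.index:
        raise KeyError(f"gene {gene!r} absent from cohort matrix")
    c_col, t_col = control_col(cp.cp_id), test_col(cp.cp_id)
    fc = float(cp.log2fc.get(gene, 0.0))
    return GeneFeatures(
        log2fc=fc,
        z_col_control=col_zscore(m_prime, gene, c_col, strict=strict),
        z_col_test=col_zscore(m_prime, gene, t_col, strict=strict),
        z_row_control=row_zscore(m_prime, gene, c_col, strict=strict),
        z_row_test=row_zscore(m_prime, gene, t_col, strict=strict),
    )


def feature_table(
    cps: Sequence[ComparisonPair],
    m_prime: CohortMatrix,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """All-gene (or selected-gene) feature table over the given CPs.

    Vectorized equivalent of calling :func:`assemble_features` per (gene, CP);
    returns a DataFrame with columns (cp_id, context, gene, f1..f5).
    """
    frame = m_prime.values
    arr = frame.to_numpy(dtype=float)
    row_mu = arr.mean(axis=1)
    row_sd = arr.std(axis=1)
    col_mu = arr.mean(axis=0)
    col_sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_row = (arr - row_mu[:, None]) / row_sd[:, None]
        z_col = (arr - col_mu[None, :]) / col_sd[None, :]
    z_row[row_sd == 0.0, :] = 0.0
    z_col[:, col_sd == 0.0] = 0.0
    if genes is None:
        genes = list(frame.index)
    idx = frame.index.get_indexer(pd.Index(genes))
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes absent from cohort matrix: {missing}")
    col_pos = {c: j for j, c in enumerate(frame.columns)}
    blocks = []
    for cp in cps:
        jc, jt = col_pos[control_col(cp.cp_id)], col_pos[test_col(cp.cp_id)]
        fc = cp.log2fc.reindex(genes).fillna(0.0).to_numpy()
        blocks.append(pd.DataFrame({
            "cp_id": cp.cp_id,
            "context": cp.context,
            "gene": list(genes),
            "log2fc": fc,
            "z_col_control": z_col[idx, jc],
            "z_col_test": z_col[idx, jt],
            "z_row_control": z_row[idx, jc],
            "z_row_test": z_row[idx, jt],
        }))
    return pd.concat(blocks, ignore_index=True)
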