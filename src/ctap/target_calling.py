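"""Consensus target calling with error tolerance and GP/GA annotation.

A candidate gene is an Up target of a transcription factor when its predicted
per-CP regulation follows the TF's own known direction in (almost) every
comparison pair, and a Down target when it consistently opposes it.  "Almost"
is governed by the error tolerance rate T: the fraction of CPs allowed to
disagree with the hypothesized pattern.  Each per-CP prediction is annotated
against the raw fold change: an Up prediction overriding a negative log2FC is
a Gene-Present-Sufficiently (GP) call, a Down prediction overriding a
positive log2FC a Gene-Absent-Insufficiently (GA) call; CPs where two models
disagree are marked ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import Cohort
from .features import FEATURE_NAMES, feature_table
from .learning import TrainedModel

__all__ = [
    "CandidateList",
    "ToleranceConfig",
    "TargetCall",
    "Log2FCRule",
    "ModelPredictor",
    "predict_candidate",
    "call_direction",
    "annotate_pattern",
    "call_targets",
    "compare_models",
]


@dataclass(frozen=True)
class CandidateList:
    """ChIP-derived candidate targets of one TF, uppercase symbols."""

    tf: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"empty candidate list for {self.tf!r}")
        object.__setattr__(self, "tf", self.tf.upper())
        object.__setattr__(self, "genes", tuple(g.upper() for g in self.genes))


@dataclass(frozen=True)
class ToleranceConfig:
    """Error tolerance rate T and the scope of the CP denominator."""

    t: float = 0.05
    scope: str = "all_cps"

    def __post_init__(self) -> None:
        if not 0.0 <= self.t < 0.5:
            raise ValueError(f"tolerance must lie in [0, 0.5), got {self.t}")
        if self.scope not in ("all_cps", "per_context"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class TargetCall:
    """Per-candidate verdict with per-CP predictions and pattern annotations."""

    gene: str
    tf: str
    direction: str  # Up | Down | none
    per_cp_prediction: Mapping[int, int]
    mismatch_fraction_follow: float
    mismatch_fraction_oppose: float
    patterns: Mapping[int, str]


class Log2FCRule:
    """Fold-change-only predictor: the sign of the CP's log2 ratio.

    Values with |log2fc| <= threshold emit 0 (no signal), which mismatches
    both the follow and the oppose hypothesis.
    """

    def __init__(self, threshold: float = 0.0):
        if threshold < 0:
            raise ValueError("threshold must be >= 0")
        self.threshold = threshold

    def predict_gene(self, cohort: Cohort, gene: str) -> dict[int, int]:
        out = {}
        for cp in cohort.cps:
            fc = float(cp.log2fc.get(gene, 0.0))
            if fc > self.threshold:
                out[cp.cp_id] = 1
            elif fc < -self.threshold:
                out[cp.cp_id] = -1
            else:
                out[cp.cp_id] = 0
        return out


class ModelPredictor:
    """Trained-classifier predictor over the cohort's 5-feature vectors."""

    def __init__(self, trained: TrainedModel):
        self.trained = trained

    def predict_gene(self, cohort: Cohort, gene: str) -> dict[int, int]:
        feats = feature_table(cohort.cps, cohort.m_prime, [gene])
        preds = self.trained.predict(
            feats[list(FEATURE_NAMES)].to_numpy(dtype=float)
        )
        return dict(zip(feats["cp_id"].astype(int), (int(p) for p in preds)))


def predict_candidate(predictor, cohort: Cohort, gene: str) -> dict[int, int]:
    """One +/-1 prediction per CP; empty mapping (with a warning) if the gene
    is absent from the cohort."""
    gene = gene.upper()
    if gene not in cohort.m_prime.values.index:
        warnings.warn(f"candidate {gene!r} absent from cohort; skipped")
        return {}
    return predictor.predict_gene(cohort, gene)


def call_direction(
    per_cp_prediction: Mapping[int, int],
    contexts: Mapping[int, str],
    tf_direction: Mapping[str, int],
    tol: ToleranceConfig,
) -> tuple[str, float, float]:
    """Classify a candidate as Up / Down / none under tolerance T.

    The FOLLOW hypothesis expects the prediction to equal the TF's direction
    in each CP's context, OPPOSE its negation.  A candidate is an Up target
    iff only FOLLOW's mismatch fraction is within T, a Down target iff only
    OPPOSE's is; anything else (including both within T) is none.  Under
    scope ``per_context`` the fraction must be within T in each context
    separately, and the worst context's fraction is reported.
    """
    cp_ids = [c for c in contexts if c in per_cp_prediction]
    if not cp_ids:
        raise ValueError("no CPs in scope")

    def fraction(expected_sign: int) -> float:
        mism = {
            cp: per_cp_prediction[cp] != expected_sign * tf_direction[contexts[cp]]
            for cp in cp_ids
        }
        if tol.scope == "all_cps":
            return sum(mism.values()) / len(cp_ids)
        per_ctx = []
        for ctx in sorted({contexts[c] for c in cp_ids}):
            members = [c for c in cp_ids if contexts[c] == ctx]
            per_ctx.append(sum(mism[c] for c in members) / len(members))
        return max(per_ctx)

    follow = fraction(+1)
    oppose = fraction(-1)
    if follow <= tol.t and oppose > tol.t:
        return "Up", follow, oppose
    if oppose <= tol.t and follow > tol.t:
        return "Down", follow, oppose
    return "none", follow, oppose


def annotate_pattern(
    prediction: int,
    log2fc: float,
    co_model_prediction: int | None = None,
) -> str:
    """GP/GA/regular/ambiguous annotation of one per-CP prediction.

    GP: an Up prediction overriding a negative fold change (transcript still
    present sufficiently).  GA: a Down prediction overriding a positive fold
    change (transcript absent insufficiently).  If a co-model's prediction is
    supplied and disagrees, the cell is ambiguous.
    """
    if co_model_prediction is not None and co_model_prediction != prediction:
        return "ambiguous"
    if prediction == 1 and log2fc < 0:
        return "GP"
    if prediction == -1 and log2fc > 0:
        return "GA"
    return "regular"


def call_targets(
    predictor,
    cohort: Cohort,
    candidates: CandidateList,
    tf_direction: Mapping[str, int],
    tol: ToleranceConfig = ToleranceConfig(),
    *,
    co_predictor=None,
) -> tuple[list[TargetCall], list[str]]:
    """Call every candidate gene; returns (calls, skipped genes).

    Candidates absent from the cohort are collected in the skipped list
    rather than silently dropped.
    """
    contexts = cohort.contexts
    calls: list[TargetCall] = []
    skipped: list[str] = []
    for gene in candidates.genes:
        preds = predict_candidate(predictor, cohort, gene)
        if not preds:
            skipped.append(gene)
            continue
        co_preds = (
            predict_candidate(co_predictor, cohort, gene)
            if co_predictor is not None
            else {}
        )
        direction, mm_follow, mm_oppose = call_direction(
            preds, contexts, tf_direction, tol
        )
        patterns = {}
        for cp in cohort.cps:
            fc = float(cp.log2fc.get(gene, 0.0))
            patterns[cp.cp_id] = annotate_pattern(
                preds[cp.cp_id], fc, co_preds.get(cp.cp_id)
            )
        calls.append(TargetCall(
            gene=gene, tf=candidates.tf, direction=direction,
            per_cp_prediction=preds,
            mismatch_fraction_follow=mm_follow,
            mismatch_fraction_oppose=mm_oppose,
            patterns=patterns,
        ))
    return calls, skipped


def calls_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Tabular export of target calls (one row per candidate)."""
    rows = []
    for c in calls:
        cp_ids = sorted(c.per_cp_prediction)
        rows.append({
            "gene": c.gene, "tf": c.tf, "direction": c.direction,
            "mismatch_follow": c.mismatch_fraction_follow,
            "mismatch_oppose": c.mismatch_fraction_oppose,
            "predictions": ",".join(
                f"{'+' if c.per_cp_prediction[i] > 0 else '-' if c.per_cp_prediction[i] < 0 else '0'}"
                for i in cp_ids
            ),
            "patterns": ",".join(c.patterns[i] for i in cp_ids),
        })
    return pd.DataFrame(rows)


def compare_models(
    call_sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], set[str]]:
    """Exact overlap partition of >= 2 methods' called-gene sets.

    Returns a mapping from the tuple of method names sharing a region to the
    genes exclusive to that region; region gene counts sum to the union size.
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets to compare")
    sets = {name: set(genes) for name, genes in call_sets.items()}
    names = sorted(sets)
    partition: dict[tuple[str, ...], set[str]] = {}
    for gene in set().union(*sets.values()):
        region = tuple(n for n in names if gene in sets[n])
        partition.setdefault(region, set()).add(gene)
    return partition
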