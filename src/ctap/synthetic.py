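"""Synthetic multi-study cohorts with planted regulation signal.

The generator emulates the structure the pipeline is built for: several
independent studies measured on platforms with different multiplicative
gains and additive offsets, each contributing one or more comparison pairs
(half OCU, half OCD), with three replicate samples per population.  Gene
content:

* background genes — log-normal baseline abundance, no directed signal;
* functional-group marker genes — shifted by +/- the effect size in each
  test population according to the group's expected state for the CP's
  context (a configurable fraction of (gene, CP) instances is instead
  "abundance-coded": a modest opposite fold change combined with a strong
  abundance shift in both of the CP's columns, the signature the GP/GA
  notions describe);
* the two transcription factors, moving with their known directions;
* planted candidate targets per TF with ground truth — clean followers and
  opposers, plus gp_case/ga_case genes whose fold change alone points the
  wrong way in half of the CPs while their abundance carries the true
  signal (gp_case genes additionally sit in the top baseline-abundance
  quantile, ga_case genes in the bottom).

All randomness flows from one seeded generator; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, assemble_cohort
from .cohort_io import CPSpec, ExpressionStudy, PopulationSpec
from .functional_groups import (
    DEFAULT_TF_DIRECTIONS,
    FunctionalGroup,
    bundled_fg_registry,
    expected_label,
)
from .target_calling import TargetCall
from .tqn import TQNParams

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "simulated_cohort",
           "truth_evaluation"]

PLANTED_ROLES = ("follower", "opposer", "gp_case", "ga_case")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the 16-CP osteoclast cohort design: 11 studies, 8 CPs
    per context, 3 replicates per population, and the bundled 14-group
    marker registry with the two TFs.  ``effect_size`` is the mean |log2FC|
    of directed genes; ``noise_sd`` the replicate-level log2 noise.
    """

    n_studies: int = 11
    n_cps_per_context: int = 8
    n_background_genes: int = 2000
    replicates_per_population: int = 3
    fg_registry: tuple[FunctionalGroup, ...] | None = None  # None -> bundled
    tf_directions: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TF_DIRECTIONS.items()}
    )
    effect_size: float = 1.0
    noise_sd: float = 0.25
    platform_log2_gain_range: tuple[float, float] = (-1.0, 1.0)
    platform_offset_range: tuple[float, float] = (0.0, 10.0)
    planted_targets: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "IRF8": {"follower": 5, "opposer": 5, "gp_case": 3, "ga_case": 3},
            "NFATC1": {"follower": 5, "opposer": 5, "gp_case": 3, "ga_case": 3},
        }
    )
    n_decoy_candidates: int = 20
    background_drift_sd: float = 0.1
    abundance_coded_fraction: float = 0.2
    coded_fold_change: float = 0.3
    coded_abundance_shift: float = 3.0
    baseline_log2_mean: float = 6.6  # ~100 intensity units
    baseline_log2_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cps_per_context < 1 or self.n_studies < 1:
            raise ValueError("need at least one study and one CP per context")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0 or self.background_drift_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if not 0.0 <= self.abundance_coded_fraction <= 1.0:
            raise ValueError("abundance_coded_fraction must lie in [0, 1]")
        for tf, counts in self.planted_targets.items():
            for role, k in counts.items():
                if role not in PLANTED_ROLES or k < 0:
                    raise ValueError(f"bad planted-target entry {tf}:{role}={k}")

    def registry(self) -> tuple[FunctionalGroup, ...]:
        return self.fg_registry or tuple(bundled_fg_registry())


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated cohort.

    ``roles`` maps gene -> role ("background", "fg", "tf", or
    "<role>:<TF>").  ``true_direction`` maps gene -> {cp_id -> +/-1} for
    every directed gene.  ``expected_call`` maps (tf, gene) -> Up/Down, the
    call a perfect model makes at T = 0 in the noiseless limit.
    ``candidates`` maps tf -> candidate gene list (planted + decoys).
    """

    roles: Mapping[str, str]
    true_direction: Mapping[str, Mapping[int, int]]
    expected_call: Mapping[tuple[str, str], str]
    candidates: Mapping[str, tuple[str, ...]]


def _cp_layout(config: SimConfig) -> list[tuple[int, str, str]]:
    """(cp_id, context, study_id) triples; CPs assigned round-robin."""
    n_cps = 2 * config.n_cps_per_context
    layout = []
    for i in range(n_cps):
        context = "OCU" if i % 2 == 0 else "OCD"
        study = f"SIM{(i % config.n_studies) + 1:03d}"
        layout.append((i + 1, context, study))
    return layout


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[ExpressionStudy], list[CPSpec], SimTruth]:
    """Generate the studies, CP declarations, and ground truth."""
    rng = np.random.default_rng(config.seed)
    registry = config.registry()
    tf_directions = {k.upper(): dict(v) for k, v in config.tf_directions.items()}
    layout = _cp_layout(config)

    # --- gene universe and roles -----------------------------------------
    roles: dict[str, str] = {}
    background = [f"BG{i + 1:05d}" for i in range(config.n_background_genes)]
    for g in background:
        roles[g] = "background"
    fg_direction: dict[str, FunctionalGroup] = {}
    for fg in registry:
        for g in fg.genes:
            if g not in fg_direction:  # first-group rule for recurring genes
                fg_direction[g] = fg
                roles[g] = "fg"
    for tf in tf_directions:
        roles[tf] = "tf"
    planted: dict[str, tuple[str, str]] = {}  # gene -> (role, tf)
    for tf, counts in config.planted_targets.items():
        tf = tf.upper()
        for role in PLANTED_ROLES:
            for i in range(counts.get(role, 0)):
                g = f"{tf}.{role.upper().replace('_CASE', '')}{i + 1:02d}"
                planted[g] = (role, tf)
                roles[g] = f"{role}:{tf}"
    if config.n_decoy_candidates > config.n_background_genes:
        raise ValueError(
            "more decoy candidates requested than background genes available"
        )
    genes = background + sorted(fg_direction) + sorted(tf_directions) + sorted(planted)
    genes = sorted(set(genes))
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # --- baseline abundance (log2 scale) ---------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=n_genes)
    for g, (role, tf) in planted.items():
        if role == "gp_case":  # top baseline-abundance quantile
            baseline[gene_idx[g]] = config.baseline_log2_mean + 2.0 * config.baseline_log2_sd
        elif role == "ga_case":  # bottom quantile
            baseline[gene_idx[g]] = config.baseline_log2_mean - 2.0 * config.baseline_log2_sd

    # --- per-(gene, CP) fold change and abundance shift -------------------
    n_cps = len(layout)
    delta = np.zeros((n_genes, n_cps))
    shift = np.zeros((n_genes, n_cps))
    true_direction: dict[str, dict[int, int]] = {}

    def code_instance(i: int, j: int, d: int, coded: bool) -> None:
        if coded:
            delta[i, j] = -d * config.coded_fold_change
            shift[i, j] = d * config.coded_abundance_shift
        else:
            delta[i, j] = d * config.effect_size

    for g in genes:
        i = gene_idx[g]
        role = roles[g]
        if role == "background":
            delta[i, :] = rng.normal(0.0, config.background_drift_sd, size=n_cps)
            continue
        dirs: dict[int, int] = {}
        for j, (cp_id, context, _) in enumerate(layout):
            if role == "fg":
                d = expected_label(fg_direction[g], context)
                coded = rng.random() < config.abundance_coded_fraction
            elif role == "tf":
                d = tf_directions[g][context]
                coded = False
            else:
                p_role, tf = planted[g]
                base = tf_directions[tf][context]
                if p_role == "opposer":
                    d = -base
                    coded = False
                else:
                    d = base
                    # gp_case: abundance-coded wherever the true direction is
                    # up; ga_case: wherever it is down
                    coded = (p_role == "gp_case" and d == 1) or \
                            (p_role == "ga_case" and d == -1)
            dirs[cp_id] = d
            code_instance(i, j, d, coded)
        true_direction[g] = dirs

    # --- expected calls and candidate lists ------------------------------
    expected_call: dict[tuple[str, str], str] = {}
    candidates: dict[str, tuple[str, ...]] = {}
    decoy_pool = list(background)
    for tf in sorted(tf_directions):
        mine = sorted(g for g, (_, t) in planted.items() if t == tf)
        for g in mine:
            p_role, _ = planted[g]
            expected_call[(tf, g)] = "Down" if p_role == "opposer" else "Up"
        n_decoys = min(config.n_decoy_candidates, len(decoy_pool))
        decoys = rng.choice(decoy_pool, size=n_decoys, replace=False) if n_decoys else []
        candidates[tf] = tuple(mine + sorted(str(d) for d in decoys))

    # --- sample-level intensities per study -------------------------------
    study_ids = sorted({s for _, _, s in layout})
    gains = {
        s: rng.uniform(*config.platform_log2_gain_range) for s in study_ids
    }
    offsets = {
        s: rng.uniform(*config.platform_offset_range) for s in study_ids
    }
    r = config.replicates_per_population
    study_cols: dict[str, dict[str, np.ndarray]] = {s: {} for s in study_ids}
    cp_specs: list[CPSpec] = []
    for j, (cp_id, context, study) in enumerate(layout):
        ctrl_samples = tuple(f"CP{cp_id:02d}.C{k + 1}" for k in range(r))
        test_samples = tuple(f"CP{cp_id:02d}.T{k + 1}" for k in range(r))
        cp_specs.append(CPSpec(
            cp_id=cp_id, study_id=study, context=context,
            platform_id=f"SIMPL{(study_ids.index(study) % 7) + 1}",
            control=PopulationSpec(label=f"control CP{cp_id}", sample_ids=ctrl_samples),
            test=PopulationSpec(label=f"test CP{cp_id}", sample_ids=test_samples),
        ))
        base_log2 = baseline + gains[study] + shift[:, j]
        for samples, with_delta in ((ctrl_samples, False), (test_samples, True)):
            mean_log2 = base_log2 + (delta[:, j] if with_delta else 0.0)
            for s in samples:
                noise = rng.normal(0.0, config.noise_sd, size=n_genes) \
                    if config.noise_sd > 0 else 0.0
                study_cols[study][s] = np.exp2(mean_log2 + noise) + offsets[study]

    studies = []
    for s in study_ids:
        frame = pd.DataFrame(study_cols[s], index=genes)
        studies.append(ExpressionStudy(study_id=s, platform_id="", values=frame))

    truth = SimTruth(
        roles=roles,
        true_direction=true_direction,
        expected_call=expected_call,
        candidates=candidates,
    )
    return studies, cp_specs, truth


def simulated_cohort(
    config: SimConfig, tqn_params: TQNParams | None = None
) -> tuple[Cohort, SimTruth]:
    """Simulate and assemble in one step."""
    studies, cp_specs, truth = simulate_cohort(config)
    return assemble_cohort(studies, cp_specs, tqn_params), truth


def truth_evaluation(
    calls: Sequence[TargetCall],
    truth: SimTruth,
    tf: str,
    *,
    universe: Sequence[str] | None = None,
) -> dict[str, object]:
    """Precision/recall of Up/Down calls against the planted ground truth.

    ``universe`` restricts the truth side to the candidate genes actually
    evaluated (default: every planted gene of the TF).  An empty called set
    has precision reported as 1.0 by convention, flagged via
    ``"no_calls": True``.
    """
    tf = tf.upper()
    expected = {g: d for (t, g), d in truth.expected_call.items() if t == tf}
    if universe is not None:
        allowed = {g.upper() for g in universe}
        expected = {g: d for g, d in expected.items() if g in allowed}
    out: dict[str, object] = {"no_calls": not calls}
    for direction in ("Up", "Down"):
        called = {c.gene for c in calls if c.direction == direction}
        truth_set = {g for g, d in expected.items() if d == direction}
        tp = len(called & truth_set)
        out[f"precision_{direction.lower()}"] = (
            tp / len(called) if called else 1.0
        )
        out[f"recall_{direction.lower()}"] = (
            tp / len(truth_set) if truth_set else 1.0
        )
    return out
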