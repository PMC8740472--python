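"""Functional groups, FG scores, and the total functional group score.

A functional group (FG) is a curated set of marker genes expected to move
collectively — all up or all down — in a given biological context.  The FG
score quantifies that collective movement for one comparison pair as the
signed square of the mean member log2 fold change:

    FGS = (mean R)^2   if mean R >= 0, else  -(mean R)^2

A positive score reads as activation, a negative one as inhibition.  The
total functional group score (TFGS) counts, over all comparison pairs, the
(CP, FG) cells whose score sign matches the group's expected state for that
CP's context.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "STATES",
    "FunctionalGroup",
    "FGScore",
    "TFGSResult",
    "fg_score",
    "fg_state",
    "tfgs",
    "expected_label",
    "fg_agreement_fraction",
    "load_fg_registry",
    "bundled_fg_registry",
    "DEFAULT_TF_DIRECTIONS",
]

STATES = ("Activation", "Inhibition")

# Known regulation direction of the two studied transcription factors per
# context: IRF8 suppresses osteoclastogenesis (down when differentiation is
# up-regulated), NFATc1 is its master activator.
DEFAULT_TF_DIRECTIONS: dict[str, dict[str, int]] = {
    "IRF8": {"OCU": -1, "OCD": +1},
    "NFATC1": {"OCU": +1, "OCD": -1},
}


@dataclass(frozen=True)
class FunctionalGroup:
    """Named marker-gene set with an expected state per context."""

    name: str
    genes: tuple[str, ...]
    expected_state: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"functional group {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"functional group {self.name!r} has duplicate genes")
        for ctx, state in self.expected_state.items():
            if state not in STATES:
                raise ValueError(
                    f"functional group {self.name!r}: state {state!r} for "
                    f"context {ctx!r} not in {STATES}"
                )


@dataclass(frozen=True)
class FGScore:
    value: float
    group: str
    cp_id: int


@dataclass(frozen=True)
class TFGSResult:
    """TFGS total and its per-CP breakdown."""

    count: int
    per_cp_counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.count != sum(self.per_cp_counts.values()):
            raise ValueError("TFGS count does not match per-CP breakdown")


def fg_score(log2fcs: Sequence[float]) -> float:
    """Signed square of the mean log2 fold change over a group's members."""
    values = np.asarray(list(log2fcs), dtype=float)
    if values.size == 0:
        raise ValueError("empty functional group")
    mean = values.mean()
    return float(mean**2 if mean >= 0 else -(mean**2))


def fg_state(score: float, expected: str) -> bool:
    """Does a group's score follow its expected state?

    Activation is followed by a strictly positive score, Inhibition by a
    strictly negative one; a zero score carries no directional evidence and
    follows neither.
    """
    if expected not in STATES:
        raise ValueError(f"expected state {expected!r} not in {STATES}")
    if expected == "Activation":
        return score > 0
    return score < 0


def tfgs(states: Mapping[int, Mapping[str, bool]]) -> TFGSResult:
    """Count expectation-following (CP, FG) cells.

    ``states`` maps cp_id -> {group name -> follows_expectation}.  Two CPs
    with 5 and 6 following groups give a TFGS of 11.
    """
    per_cp = {cp: int(sum(bool(v) for v in row.values()))
              for cp, row in states.items()}
    return TFGSResult(count=sum(per_cp.values()), per_cp_counts=per_cp)


def expected_label(fg: FunctionalGroup, context: str) -> int:
    """Training label of a group's members in a context: +1 up, -1 down."""
    if context not in fg.expected_state:
        raise KeyError(
            f"functional group {fg.name!r} declares no state for {context!r}"
        )
    return +1 if fg.expected_state[context] == "Activation" else -1


def fg_agreement_fraction(log2fcs: Sequence[float], expected: str) -> float:
    """Fraction of member genes whose fold-change sign matches the expected
    state — a diagnostic for how unanimously a group moves (zero fold changes
    never agree)."""
    values = np.asarray(list(log2fcs), dtype=float)
    if values.size == 0:
        raise ValueError("empty functional group")
    if expected == "Activation":
        return float((values > 0).mean())
    if expected == "Inhibition":
        return float((values < 0).mean())
    raise ValueError(f"expected state {expected!r} not in {STATES}")


def load_fg_registry(path: str | Path) -> list[FunctionalGroup]:
    """Load a functional-group registry from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ValueError(f"{path}: expected a top-level 'groups' list")
    groups = []
    for entry in doc["groups"]:
        groups.append(FunctionalGroup(
            name=str(entry["name"]),
            genes=tuple(str(g).upper() for g in entry["genes"]),
            expected_state=dict(entry["expected_state"]),
        ))
    if not groups:
        raise ValueError(f"{path}: no functional groups declared")
    return groups


def bundled_fg_registry() -> list[FunctionalGroup]:
    """The bundled 14-group osteoclast-differentiation registry."""
    path = importlib.resources.files("ctap").joinpath(
        "data", "functional_groups_osteoclast.yaml"
    )
    return load_fg_registry(Path(str(path)))
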