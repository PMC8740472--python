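"""Reading expression studies and cohort configuration.

Expression studies arrive as tab-separated series-matrix-style tables (rows =
probe identifiers, columns = samples) together with a platform annotation
mapping probe identifiers to official gene symbols.  The cohort configuration
declares, per study, which samples form the control and test populations of
each comparison pair (CP) and the pair's biological context label.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionStudy",
    "PopulationSpec",
    "CPSpec",
    "SeriesMatrixError",
    "ConfigError",
    "read_series_matrix",
    "write_series_matrix",
    "read_annotation",
    "load_cohort_config",
    "load_candidate_list",
    "bundled_cohort_config",
]

CONTEXTS = ("OCU", "OCD")


class SeriesMatrixError(ValueError):
    """Malformed series-matrix or annotation input."""


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class ExpressionStudy:
    """One expression study: gene symbols x samples, non-negative intensities.

    ``values`` is a DataFrame indexed by uppercase gene symbol with one column
    per sample, in the file's sample order.
    """

    study_id: str
    platform_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise SeriesMatrixError(f"duplicate gene symbols: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise SeriesMatrixError("non-finite intensity values")
        if (arr < 0).any():
            raise SeriesMatrixError("negative intensity values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class PopulationSpec:
    """A named group of replicate samples within one study."""

    label: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ConfigError(f"population {self.label!r} has no samples")


@dataclass(frozen=True)
class CPSpec:
    """Declaration of one comparison pair: control vs test in a context."""

    cp_id: int
    study_id: str
    control: PopulationSpec
    test: PopulationSpec
    context: str
    platform_id: str = ""

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ConfigError(
                f"CP {self.cp_id}: context {self.context!r} not in {CONTEXTS}"
            )
        overlap = set(self.control.sample_ids) & set(self.test.sample_ids)
        if overlap:
            raise ConfigError(
                f"CP {self.cp_id}: control/test populations share samples {sorted(overlap)}"
            )


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated platform annotation (probe, symbol).

    Rows with an empty symbol are dropped; symbols are uppercased.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SeriesMatrixError(
                    f"{path}: line {lineno}: expected two tab-separated columns"
                )
            probe, symbol = parts[0].strip(), parts[1].strip()
            if symbol:
                mapping[probe] = symbol.upper()
    return mapping


def read_series_matrix(
    path: str | Path | IO[str],
    annotation: Mapping[str, str] | None,
    *,
    study_id: str = "",
    platform_id: str = "",
    collapse: str = "mean",
) -> ExpressionStudy:
    """Read a series-matrix-style table and map probes to gene symbols.

    ``annotation=None`` treats row identifiers as gene symbols directly (for
    tables already keyed by symbol).  Probes absent from ``annotation`` are
    dropped.  Multiple probes mapping to
    the same symbol are collapsed with the arithmetic mean (``collapse="mean"``;
    ``"median"`` and ``"max"`` are accepted alternatives).  The collapse is
    independent of probe order.

    Raises
    ------
    SeriesMatrixError
        On ragged rows, non-numeric or missing cells, or when no probe maps
        to a gene symbol.
    """
    if collapse not in ("mean", "median", "max"):
        raise ValueError(f"unknown collapse rule {collapse!r}")
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path)
        close = True
        name = str(path)
    else:
        fh = path
        name = getattr(path, "name", "<stream>")
    try:
        header = fh.readline().rstrip("\n")
        if not header:
            raise SeriesMatrixError(f"{name}: empty file")
        cols = header.split("\t")
        samples = [c.strip() for c in cols[1:]]
        if not samples or any(not s for s in samples):
            raise SeriesMatrixError(f"{name}: line 1: malformed header")
        probes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise SeriesMatrixError(
                    f"{name}: line {lineno}: expected {len(samples) + 1} fields, "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise SeriesMatrixError(
                    f"{name}: line {lineno}: non-numeric intensity ({exc})"
                ) from None
            probes.append(parts[0].strip())
            rows.append(vals)
    finally:
        if close:
            fh.close()

    frame = pd.DataFrame(rows, index=probes, columns=samples, dtype=float)
    if annotation is None:
        symbols = pd.Series(frame.index, index=frame.index).str.upper()
    else:
        symbols = pd.Series(
            [annotation.get(p, "") for p in frame.index], index=frame.index
        ).str.upper()
    frame = frame[symbols != ""]
    symbols = symbols[symbols != ""]
    if frame.empty:
        raise SeriesMatrixError(f"{name}: no mappable probes")
    grouped = frame.groupby(symbols.values, sort=True)
    if collapse == "mean":
        collapsed = grouped.mean()
    elif collapse == "median":
        collapsed = grouped.median()
    else:
        collapsed = grouped.max()
    return ExpressionStudy(
        study_id=study_id, platform_id=platform_id, values=collapsed
    )


def write_series_matrix(study: ExpressionStudy, path: str | Path) -> None:
    """Write a study back to the tab-separated dialect (symbols as row ids)."""
    study.values.to_csv(path, sep="\t", index_label="ID_REF")


def load_cohort_config(path: str | Path) -> list[CPSpec]:
    """Load the CP declarations from a YAML cohort configuration.

    Returns the CPs in file order.  Raises :class:`ConfigError` on duplicate
    CP ids, unknown context labels, or control/test overlap.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "cps" not in doc:
        raise ConfigError(f"{path}: expected a top-level 'cps' list")
    specs: list[CPSpec] = []
    seen: set[int] = set()
    for entry in doc["cps"]:
        try:
            spec = CPSpec(
                cp_id=int(entry["cp_id"]),
                study_id=str(entry["study_id"]),
                platform_id=str(entry.get("platform_id", "")),
                context=str(entry["context"]),
                control=PopulationSpec(
                    label=str(entry["control"].get("label", "control")),
                    sample_ids=tuple(entry["control"]["samples"]),
                ),
                test=PopulationSpec(
                    label=str(entry["test"].get("label", "test")),
                    sample_ids=tuple(entry["test"]["samples"]),
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: CP entry missing key {exc}") from None
        if spec.cp_id in seen:
            raise ConfigError(f"{path}: duplicate cp_id {spec.cp_id}")
        seen.add(spec.cp_id)
        specs.append(spec)
    if not specs:
        raise ConfigError(f"{path}: no CPs declared")
    return specs


def load_candidate_list(path: str | Path, tf: str = "") -> list[str]:
    """Read a candidate-target gene list: one symbol per line, '#' comments.

    Symbols are uppercased and de-duplicated preserving first occurrence.
    """
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            sym = line.split("#")[0].strip().upper()
            if sym:
                seen.setdefault(sym, None)
    if not seen:
        raise ConfigError(f"{path}: empty candidate list")
    return list(seen)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("ctap").joinpath("data", name)))


def bundled_cohort_config() -> list[CPSpec]:
    """The bundled 16-CP osteoclast-differentiation cohort design."""
    return load_cohort_config(_data_path("cohort_osteoclast_16cp.yaml"))


def bundled_casp1_example() -> pd.DataFrame:
    """The CASP1 worked example: its published log2 fold change in each of
    the 16 cohort CPs (columns cp_id, context, log2fc)."""
    return pd.read_csv(_data_path("casp1_log2fc.tsv"), sep="\t")
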