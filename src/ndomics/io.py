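"""TSV dialects, configuration, and shared table helpers.

Expression tables carry one row per EST with columns ``est_id``,
``annotation``, ``pathways`` (semicolon-joined pathway ids, may be empty),
``ec`` (may be empty) and one TPM column per condition x replicate named
``<COND>_<i>`` (e.g. ``ND_1`` .. ``ND_3``, ``NR_1`` .. ``NR_3``).  Lipid
tables carry ``species`` (shorthand such as ``DGDG(20:5/16:1)``),
``lipid_class`` and the same level-column layout, in moles per million cells.
All files are UTF-8 tab-separated with optional '#'-prefixed metadata header
lines.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

#: pseudo-count (TPM) shared by every ratio computation in the package
PSEUDO_COUNT = 0.01


def safe_ratio(numerator, denominator, pseudo_count: float = PSEUDO_COUNT):
    """ND/NR ratio of means with a pseudo-count substituted for zero terms.

    The pseudo-count replaces a zero mean rather than being added throughout,
    so 8 vs 0 gives 8/0.01 = 800 while 8 vs 2 stays exactly 4.
    """
    import numpy as _np

    num = _np.where(_np.asarray(numerator) > 0, numerator, pseudo_count)
    den = _np.where(_np.asarray(denominator) > 0, denominator, pseudo_count)
    out = num / den
    return float(out) if _np.ndim(out) == 0 else out

CONDITIONS = ("ND", "NR")


def level_columns(table: pd.DataFrame, condition: str) -> list[str]:
    """Replicate level columns for a condition, in replicate order."""
    cols = [c for c in table.columns if c.startswith(f"{condition}_")]
    if not cols:
        raise ValueError(f"no level columns for condition {condition!r}")
    return sorted(cols, key=lambda c: int(c.rsplit("_", 1)[1]))


def condition_means(table: pd.DataFrame, condition: str) -> pd.Series:
    """Per-row mean level over a condition's replicates."""
    return table[level_columns(table, condition)].mean(axis=1)


def pathway_sets(table: pd.DataFrame) -> dict[str, set]:
    """pathway id -> set of member est_ids, from the ``pathways`` column."""
    mapping: dict[str, set] = {}
    for est_id, cell in zip(table["est_id"], table["pathways"].fillna("")):
        for pw in str(cell).split(";"):
            pw = pw.strip()
            if pw:
                mapping.setdefault(pw, set()).add(est_id)
    return mapping


def ec_groups(table: pd.DataFrame) -> dict[str, list[str]]:
    """EC id -> ordered list of member est_ids, from the ``ec`` column."""
    groups: dict[str, list[str]] = {}
    for est_id, ec in zip(table["est_id"], table["ec"].fillna("")):
        ec = str(ec).strip()
        if ec:
            groups.setdefault(ec, []).append(est_id)
    return groups


def _validate_levels(table: pd.DataFrame, path) -> None:
    n_reps = {cond: len(level_columns(table, cond)) for cond in CONDITIONS}
    if len(set(n_reps.values())) != 1:
        raise ValueError(f"{path}: ragged replicate counts across conditions: {n_reps}")
    for cond in CONDITIONS:
        for col in level_columns(table, cond):
            levels = pd.to_numeric(table[col], errors="raise")
            bad = levels.index[levels < 0]
            if len(bad):
                raise ValueError(
                    f"{path}: negative level in column {col}, row {int(bad[0]) + 2}"
                )
            table[col] = levels.astype(float)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"est_id": str})


def read_expression_table(path) -> pd.DataFrame:
    """Read and validate an expression TSV.

    Rejects duplicate est_ids (naming the id), negative TPM (naming the row)
    and ragged replicate counts.
    """
    table = _read_tsv(path)
    required = {"est_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dupes = table["est_id"][table["est_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate est_id {dupes.iloc[0]!r}")
    for optional in ("annotation", "pathways", "ec"):
        if optional not in table.columns:
            table[optional] = ""
    table[["annotation", "pathways", "ec"]] = (
        table[["annotation", "pathways", "ec"]].fillna("").astype(str)
    )
    _validate_levels(table, path)
    return table


def read_lipid_table(path) -> pd.DataFrame:
    """Read and validate a lipidome TSV; every species name must parse."""
    from .lipids import parse_lipid_name  # deferred: lipids imports io

    table = _read_tsv(path)
    if "species" not in table.columns:
        raise ValueError(f"{path}: missing required column 'species'")
    dupes = table["species"][table["species"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate species {dupes.iloc[0]!r}")
    classes = []
    for row, name in enumerate(table["species"], start=2):
        try:
            classes.append(parse_lipid_name(name).lipid_class)
        except ValueError as exc:
            raise ValueError(f"{path}: row {row}: {exc}") from exc
    table["lipid_class"] = classes
    _validate_levels(table, path)
    return table


def _metadata_header(metadata: Mapping | None) -> str:
    if not metadata:
        return ""
    return "".join(f"# {key} = {value}\n" for key, value in metadata.items())


def write_table(table: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a TSV with '#'-prefixed metadata header lines, UTF-8, LF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(_metadata_header(metadata))
    table.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="")


# kept as explicit names so readers and writers pair up obviously
write_expression_table = write_table
write_lipid_table = write_table


def read_map_tsv(path, key_col: int = 0, value_col: int = 1) -> dict[str, set]:
    """Two-column TSV (e.g. est_id<TAB>pathway) -> value -> set of keys."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    mapping: dict[str, set] = {}
    for key, value in zip(table.iloc[:, key_col], table.iloc[:, value_col]):
        mapping.setdefault(str(value), set()).add(str(key))
    return mapping


@dataclass
class AnalysisConfig:
    """Every numeric cutoff used by the pipeline, with study defaults.

    Fold thresholds are strict (> t).  ``de_alpha_preset`` selects between
    the two published differential-expression screens: ``fdr`` (> 4-fold,
    BH-FDR q < 0.01) and ``raw`` (> 4-fold, p < 0.05).
    """

    de_fold: float = 4.0
    de_alpha_preset: str = "fdr"  # "fdr": q<0.01; "raw": p<0.05
    enzyme_fold: float = 1.5
    enzyme_alpha: float = 0.05
    class_fold: float = 1.2  # presets 1.2, 1.25, 1.5
    species_fold: float = 1.5
    lipid_alpha: float = 0.05
    window_fold: float = 2.0
    window_alpha: float = 0.05
    window_frac: float = 0.10
    step_frac: float = 0.05
    min_pathway_size_level: int = 60
    min_pathway_size_ratio: int = 25
    pseudo_count: float = PSEUDO_COUNT
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_frac", "step_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for name in ("de_fold", "enzyme_fold", "class_fold", "species_fold", "window_fold"):
            v = getattr(self, name)
            if not v > 1:
                raise ValueError(f"{name} must be > 1, got {v}")
        for name in ("enzyme_alpha", "lipid_alpha", "window_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.de_alpha_preset not in ("fdr", "raw"):
            raise ValueError(f"de_alpha_preset must be 'fdr' or 'raw', got {self.de_alpha_preset!r}")

    @property
    def de_alpha(self) -> float:
        return 0.01 if self.de_alpha_preset == "fdr" else 0.05

    @property
    def de_adjust(self) -> str:
        return "fdr" if self.de_alpha_preset == "fdr" else "none"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)
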