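"""Lipid shorthand parsing, change calling, pathway-of-origin classification,
and membrane-to-neutral-lipid signature tracing.

Species are written in the usual CLASS(C:D/C:D[/C:D]) shorthand with acyl
chains listed by stereospecific glycerol position: sn1/sn2 for diacyl
classes, sn1/sn2/sn3 for triacylglycerol, where sn1 and sn3 are chemically
indistinguishable and are canonicalized.  The sn2 chain diagnoses the
synthesis route: a 16-carbon chain marks the plastidic "prokaryotic"
pathway, an 18-carbon (or ER-elongated 20/22-carbon) chain the
ER "eukaryotic" pathway.

Tracing asks whether a membrane lipid (DGDG/MGDG/PG) that falls under
nitrogen deprivation leaves its diacyl signature in a rising neutral lipid:
an exact positional match in DAG, or an embedded match in TAG where the sn2
chains agree and the source sn1 chain sits at either TAG terminal position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flux import differential_call, differential_table
from .io import level_columns

__all__ = [
    "AcylChain",
    "LipidSpecies",
    "OriginCall",
    "TraceMatch",
    "MONOACYL_CLASSES",
    "DIACYL_CLASSES",
    "TRIACYL_CLASSES",
    "LIPID_CLASSES",
    "parse_lipid_name",
    "classify_origin",
    "species_change_calls",
    "class_change_calls",
    "select_major_species",
    "trace_signatures",
    "origin_fraction_of_increase",
    "pufa_sn2_profile",
]

MONOACYL_CLASSES = frozenset({"MGMG", "LPC", "LPE", "LPG", "FFA"})
DIACYL_CLASSES = frozenset({"DGDG", "MGDG", "DAG", "PC", "PE", "PG"})
TRIACYL_CLASSES = frozenset({"TAG"})
LIPID_CLASSES = MONOACYL_CLASSES | DIACYL_CLASSES | TRIACYL_CLASSES

_CHAIN_RE = re.compile(r"(\d+):(\d+)(n-\d+)?")


@dataclass(frozen=True)
class AcylChain:
    """An acyl chain in C:D shorthand, e.g. 20:5 with optional omega n-3."""

    carbons: int
    double_bonds: int
    omega: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 12 or self.carbons % 2:
            raise ValueError(f"chain carbons must be even and >= 12, got {self.carbons}")
        if not 0 <= self.double_bonds < self.carbons / 2:
            raise ValueError(
                f"double bonds must satisfy 0 <= D < C/2, got {self.carbons}:{self.double_bonds}"
            )

    @property
    def signature(self) -> tuple[int, int]:
        """(carbons, double_bonds) — omega labels do not enter matching."""
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        return f"{self.carbons}:{self.double_bonds}{self.omega or ''}"


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class plus positionally assigned chains, in canonical form.

    TAG terminal chains (sn1/sn3) are stored sorted by (carbons, double
    bonds) so string equality coincides with structural equality.
    """

    lipid_class: str
    chains: tuple[AcylChain, ...]

    def __post_init__(self) -> None:
        arity = _class_arity(self.lipid_class)
        if len(self.chains) != arity:
            raise ValueError(
                f"{self.lipid_class} takes {arity} chain(s), got {len(self.chains)}"
            )
        if self.lipid_class in TRIACYL_CLASSES:
            sn1, sn2, sn3 = self.chains
            key = lambda c: (c.carbons, c.double_bonds, c.omega or "")
            ordered = tuple(sorted((sn1, sn3), key=key))
            object.__setattr__(self, "chains", (ordered[0], sn2, ordered[1]))

    @property
    def sn1(self) -> AcylChain:
        return self.chains[0]

    @property
    def sn2(self) -> AcylChain:
        if len(self.chains) < 2:
            raise ValueError(f"{self} has no sn2 position")
        return self.chains[1]

    @property
    def sn3(self) -> AcylChain:
        if len(self.chains) < 3:
            raise ValueError(f"{self} has no sn3 position")
        return self.chains[2]

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({'/'.join(str(c) for c in self.chains)})"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class OriginCall:
    species: LipidSpecies
    origin: str  # prokaryotic | eukaryotic | undetermined
    flagged: bool = False  # sn2 outside every stated carbon class


@dataclass(frozen=True)
class TraceMatch:
    source: LipidSpecies
    target: LipidSpecies
    match_kind: str  # exact-diacyl | embedded-in-TAG
    direction_consistent: bool  # source called down AND target called up


def _class_arity(lipid_class: str) -> int:
    if lipid_class in MONOACYL_CLASSES:
        return 1
    if lipid_class in DIACYL_CLASSES:
        return 2
    if lipid_class in TRIACYL_CLASSES:
        return 3
    raise ValueError(f"unknown lipid class {lipid_class!r}")


def parse_lipid_name(text: str) -> LipidSpecies:
    """Parse CLASS(C:D[n-x]/C:D[n-x][/C:D[n-x]]) shorthand.

    Errors name the character position at which parsing failed.
    """
    text = text.strip()
    open_paren = text.find("(")
    if open_paren < 0 or not text.endswith(")"):
        raise ValueError(f"{text!r}: expected CLASS(...) (position {max(open_paren, 0)})")
    lipid_class = text[:open_paren]
    if lipid_class not in LIPID_CLASSES:
        raise ValueError(f"{text!r}: unknown lipid class {lipid_class!r} (position 0)")
    body = text[open_paren + 1 : -1]
    chains: list[AcylChain] = []
    pos = open_paren + 1
    for part in body.split("/"):
        m = _CHAIN_RE.fullmatch(part.strip())
        if m is None:
            raise ValueError(f"{text!r}: garbled chain {part!r} (position {pos})")
        try:
            chains.append(AcylChain(int(m.group(1)), int(m.group(2)), m.group(3)))
        except ValueError as exc:
            raise ValueError(f"{text!r}: {exc} (position {pos})") from exc
        pos += len(part) + 1
    try:
        return LipidSpecies(lipid_class, tuple(chains))
    except ValueError as exc:
        raise ValueError(f"{text!r}: {exc} (position {open_paren + 1})") from exc


def classify_origin(species: LipidSpecies | str) -> OriginCall:
    """Synthesis-pathway call from the sn2 chain length.

    Di-/tri-acyl glycerolipids with a 16-carbon sn2 chain are assigned to the
    plastidic prokaryotic pathway; 18-, 20- or 22-carbon sn2 chains to the ER
    eukaryotic pathway (C20/C22 PUFAs arise from ER elongation of C18).
    Mono-acyl classes and free fatty acids carry no positional information
    and stay undetermined, as do sn2 chains outside both carbon classes
    (those are additionally flagged).
    """
    if isinstance(species, str):
        species = parse_lipid_name(species)
    if species.lipid_class in MONOACYL_CLASSES:
        return OriginCall(species, "undetermined")
    sn2_c = species.sn2.carbons
    if sn2_c == 16:
        return OriginCall(species, "prokaryotic")
    if sn2_c in (18, 20, 22):
        return OriginCall(species, "eukaryotic")
    return OriginCall(species, "undetermined", flagged=True)


def species_change_calls(
    table: pd.DataFrame, fold_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-species change call (shared Welch-on-log2 machinery, raw p)."""
    calls = differential_table(table, fold_threshold, alpha, "none", id_col="species")
    return calls.rename(columns={"est_id": "species"})


def class_change_calls(
    table: pd.DataFrame,
    fold_threshold: float = 1.2,
    alpha: float = 0.05,
    *,
    origin: str | None = None,
    species_fold_threshold: float = 1.5,
    species_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-class change call on replicate-wise sums of member species.

    ``origin`` restricts the sum to one synthesis-pathway stratum
    (prokaryotic/eukaryotic/undetermined).  Preset thresholds in use are 1.2
    (whole-class screen, the ">20%" wording), 1.25 (origin-stratified and
    sn2-PUFA screens) and 1.5.  n_up/n_dn count member species individually
    significant at (species_fold_threshold, species_alpha).
    """
    nd_cols, nr_cols = level_columns(table, "ND"), level_columns(table, "NR")
    sub = table
    if origin is not None:
        keep = [classify_origin(s).origin == origin for s in sub["species"]]
        sub = sub[np.asarray(keep, dtype=bool)]
    rows = []
    for lipid_class, group in sub.groupby("lipid_class", sort=True):
        call = differential_call(
            group[nd_cols].sum(axis=0).to_numpy(dtype=float),
            group[nr_cols].sum(axis=0).to_numpy(dtype=float),
            fold_threshold,
            alpha,
        )
        members = species_change_calls(group, species_fold_threshold, species_alpha)
        rows.append(
            {
                "lipid_class": lipid_class,
                "origin": origin or "all",
                "n_species": len(group),
                "mean_nd": call.mean_nd,
                "mean_nr": call.mean_nr,
                "ratio": call.ratio,
                "fold": call.fold,
                "p": call.p,
                "direction": call.direction,
                "significant": call.significant,
                "n_up": int((members["direction"] == "up").sum()),
                "n_dn": int((members["direction"] == "down").sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lipid_class", "origin", "n_species", "mean_nd", "mean_nr",
            "ratio", "fold", "p", "direction", "significant", "n_up", "n_dn",
        ],
    )


def select_major_species(class_table: pd.DataFrame) -> tuple[list[str], bool]:
    """Major species of one lipid class by mean level over all samples.

    Classes of five or fewer species keep everything; classes of ten or more
    keep the top half.  The 6-9 species gap is filled with the same top
    ceil(n/2) rule and flagged (second return value) as falling outside the
    stated cases.  Ties break by species name.
    """
    n = len(class_table)
    if n == 0:
        return [], False
    all_cols = level_columns(class_table, "ND") + level_columns(class_table, "NR")
    abundance = class_table[all_cols].mean(axis=1)
    order = pd.DataFrame(
        {"species": class_table["species"].to_numpy(), "abundance": abundance.to_numpy()}
    ).sort_values(["abundance", "species"], ascending=[False, True], kind="mergesort")
    if n <= 5:
        return list(order["species"]), False
    keep = ceil(n / 2)
    return list(order["species"].iloc[:keep]), n < 10


def _diacyl_signature(species: LipidSpecies) -> tuple:
    return (species.sn1.signature, species.sn2.signature)


def trace_signatures(
    table: pd.DataFrame,
    source_classes: Iterable[str] = ("DGDG", "MGDG", "PG"),
    target_classes: Iterable[str] = ("DAG", "TAG"),
    require_direction: bool = True,
    *,
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    major_sources_only: bool = True,
) -> list[TraceMatch]:
    """Find membrane-lipid signatures embedded in neutral lipids.

    A source diacyl species matches a DAG when both positions agree
    (exact-diacyl) and matches a TAG when the sn2 chains agree and the source
    sn1 chain occupies either TAG terminal position (embedded-in-TAG).
    Chains match on (carbons, double bonds); omega labels are display-only.

    Sources are restricted to each class's major species (the search the
    study ran); with ``require_direction`` only pairs where the source is
    called down and the target up at the species thresholds are returned.
    Matches are ordered by (source name, target name).
    """
    source_classes, target_classes = set(source_classes), set(target_classes)
    calls = species_change_calls(table, fold_threshold, alpha)
    direction = dict(zip(calls["species"], calls["direction"]))

    sources: list[LipidSpecies] = []
    for cls in sorted(source_classes):
        class_rows = table[table["lipid_class"] == cls]
        if major_sources_only:
            names, _ = select_major_species(class_rows)
        else:
            names = sorted(class_rows["species"])
        sources.extend(parse_lipid_name(nm) for nm in sorted(names))
    targets = [
        parse_lipid_name(nm)
        for nm in sorted(table.loc[table["lipid_class"].isin(target_classes), "species"])
    ]

    matches = []
    for src in sources:
        if len(src.chains) != 2:
            continue
        for tgt in targets:
            if tgt.lipid_class in TRIACYL_CLASSES:
                hit = tgt.sn2.signature == src.sn2.signature and src.sn1.signature in (
                    tgt.sn1.signature,
                    tgt.sn3.signature,
                )
                kind = "embedded-in-TAG"
            else:
                hit = _diacyl_signature(tgt) == _diacyl_signature(src)
                kind = "exact-diacyl"
            if not hit:
                continue
            consistent = (
                direction.get(src.name) == "down" and direction.get(tgt.name) == "up"
            )
            if require_direction and not consistent:
                continue
            matches.append(
                TraceMatch(
                    source=src, target=tgt, match_kind=kind, direction_consistent=consistent
                )
            )
    return matches


def origin_fraction_of_increase(
    table: pd.DataFrame, target_class: str = "TAG"
) -> float | None:
    """Share of a class's net level increase carried by prokaryotic species.

    Sums the positive (ND - NR) mean-level deltas over prokaryotic-origin
    species of the class and divides by the positive deltas over all its
    species.  Returns None (undefined) when no species of the class
    increased.
    """
    sub = table[table["lipid_class"] == target_class]
    deltas = (
        sub[level_columns(table, "ND")].mean(axis=1)
        - sub[level_columns(table, "NR")].mean(axis=1)
    ).to_numpy(dtype=float)
    positive = deltas > 0
    total = deltas[positive].sum()
    if not positive.any() or total <= 0:
        return None
    prokaryotic = np.array(
        [classify_origin(s).origin == "prokaryotic" for s in sub["species"]], dtype=bool
    )
    return float(deltas[positive & prokaryotic].sum() / total)


def pufa_sn2_profile(
    table: pd.DataFrame,
    lipid_class: str = "PC",
    pufa_set: Sequence[str] = ("18:3n-6", "20:4n-6", "20:5n-3"),
    fold_threshold: float = 1.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Aggregate levels of each PUFA found at sn2 in one class, with calls.

    For each PUFA in ``pufa_set`` (C:D with optional omega), member species
    of the class carrying it at sn2 are summed replicate-wise and the sum is
    change-called at ``fold_threshold``.  A species chain with no omega label
    matches on C:D alone; when both sides carry omega labels they must agree.
    A PUFA absent from the class reports zero levels and 'unchanged'.
    """
    if not len(pufa_set):
        raise ValueError("pufa_set is empty")
    sub = table[table["lipid_class"] == lipid_class]
    nd_cols, nr_cols = level_columns(table, "ND"), level_columns(table, "NR")
    sn2 = [parse_lipid_name(s).sn2 for s in sub["species"]]
    rows = []
    for pufa_text in pufa_set:
        m = _CHAIN_RE.fullmatch(pufa_text.strip())
        if m is None:
            raise ValueError(f"garbled PUFA {pufa_text!r}")
        pufa = AcylChain(int(m.group(1)), int(m.group(2)), m.group(3))
        hit = np.array(
            [
                c.signature == pufa.signature
                and (c.omega is None or pufa.omega is None or c.omega == pufa.omega)
                for c in sn2
            ],
            dtype=bool,
        )
        nd = sub.loc[hit, nd_cols].sum(axis=0).to_numpy(dtype=float)
        nr = sub.loc[hit, nr_cols].sum(axis=0).to_numpy(dtype=float)
        if not hit.any():
            nd = np.zeros(len(nd_cols))
            nr = np.zeros(len(nr_cols))
        call = differential_call(nd, nr, fold_threshold, alpha)
        rows.append(
            {
                "pufa": str(pufa),
                "n_species": int(hit.sum()),
                "mean_nd": call.mean_nd,
                "mean_nr": call.mean_nr,
                "fold": call.fold,
                "p": call.p,
                "direction": call.direction,
                "significant": call.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pufa", "n_species", "mean_nd", "mean_nr", "fold", "p", "direction", "significant"],
    )
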