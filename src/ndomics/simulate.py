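"""Synthetic expression and lipidome tables with known ground truth.

The expression generator emulates the shape of a de-novo assembled
transcriptome quantified under nitrogen-replete (NR) and nitrogen-deprived
(ND) conditions: ~12,609 annotated ESTs with heavy-tailed TPM (log-normal
baseline), KEGG-style pathway memberships, multi-copy EC groups averaging
~4.4 gene copies per enzyme, and three replicates per condition with
multiplicative log-normal noise.  Effects are planted on the log2 scale
before noise: whole-pathway ND/NR fold shifts (for differential and
ratio-window recovery) and rank-band placements that pin a pathway's
baseline abundance into a quantile band of the ranked list (for
level-window recovery).

The lipidome generator emulates an LC-MS/MS species table of ~80 species in
12 classes with positional acyl-chain assignments, and plants the membrane
to neutral-lipid remodeling the downstream analyses are meant to recover:
galactolipid species fall under ND, matched DAG/TAG species rise, and a
configurable fraction of the net TAG gain is carried by species with
16-carbon sn2 chains (the plastidic "prokaryotic" signature).

Everything is driven by one integer seed; identical configs give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import make_windows
from .lipids import AcylChain, LipidSpecies, classify_origin

__all__ = [
    "ExpressionConfig",
    "LipidomeConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_null_expression",
    "generate_lipidome",
    "DEFAULT_CHAIN_POOL",
    "DEFAULT_LIPID_CLASSES",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted effects recorded alongside a generated table."""

    seed: int
    differential_est_ids: frozenset = frozenset()
    enriched_window_pathways: frozenset = frozenset()  # {(window index, pathway)}
    planted_trace_pairs: tuple = ()  # ((source species, target species), ...)
    planted_f_prokaryotic: float | None = None
    planted_tag_increases: tuple = ()  # TAG species carrying planted increase


@dataclass(frozen=True)
class ExpressionConfig:
    """Shape and planted effects of a synthetic expression table.

    ``effect_pathways`` maps a pathway name (``pw00``, ``pw01``, ...) to a
    log2 ND-vs-NR fold shift applied to all of its members;
    ``rank_band_pathways`` maps a pathway to a (lo, hi) quantile band of
    baseline abundance measured from the top of the ranked list, so band
    (0.0, 0.1) places members among the top 10% most abundant ESTs.
    Members of effect/band pathways are assigned disjointly so planted
    effects do not overlap; remaining pathways draw members uniformly.
    """

    n_ests: int = 12609
    n_pathways: int = 30
    pathway_size_range: tuple = (30, 150)
    n_ec_groups: int = 400
    copies_per_ec_mean: float = 4.4
    baseline_log_mean: float = 1.5  # natural-log TPM scale
    baseline_log_sd: float = 2.0
    effect_pathways: Mapping = field(default_factory=dict)
    rank_band_pathways: Mapping = field(default_factory=dict)
    replicate_cv: float = 0.2
    n_replicates: int = 3
    seed: int = 0

    def pathway_names(self) -> list[str]:
        return [f"pw{i:02d}" for i in range(self.n_pathways)]

    def validate(self) -> None:
        if self.n_ests <= 0:
            raise ValueError(f"invariant n_ests > 0 violated: n_ests={self.n_ests}")
        if self.replicate_cv <= 0:
            raise ValueError(f"invariant replicate_cv > 0 violated: {self.replicate_cv}")
        if self.n_replicates < 2:
            raise ValueError(f"invariant n_replicates >= 2 violated: {self.n_replicates}")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.n_ests:
            raise ValueError(
                f"invariant pathway sizes <= n_ests violated: range={self.pathway_size_range}"
            )
        if self.copies_per_ec_mean < 1:
            raise ValueError(
                f"invariant copies_per_ec_mean >= 1 violated: {self.copies_per_ec_mean}"
            )
        names = set(self.pathway_names())
        for mapping, label in (
            (self.effect_pathways, "effect_pathways"),
            (self.rank_band_pathways, "rank_band_pathways"),
        ):
            unknown = set(mapping) - names
            if unknown:
                raise ValueError(f"{label} references unknown pathways {sorted(unknown)}")
        for pw, (band_lo, band_hi) in self.rank_band_pathways.items():
            if not 0 <= band_lo < band_hi <= 1:
                raise ValueError(
                    f"invariant 0 <= band_lo < band_hi <= 1 violated for {pw}: "
                    f"({band_lo}, {band_hi})"
                )


def _cv_sigma(cv: float) -> float:
    # log-normal sigma for multiplicative noise with the given CV
    return float(np.sqrt(np.log1p(cv**2)))


def _noisy_replicates(means: np.ndarray, cv: float, n_reps: int, rng) -> np.ndarray:
    """Mean-preserving multiplicative log-normal replicate noise."""
    sigma = _cv_sigma(cv)
    noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=(len(means), n_reps))
    return means[:, None] * noise


def generate_expression(config: ExpressionConfig):
    """Generate an expression table plus the truth of its planted effects."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_ests
    est_ids = np.array([f"EST{i:05d}" for i in range(n)])

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)

    # pathway sizes, then membership: planted pathways take disjoint members
    lo, hi = config.pathway_size_range
    names = config.pathway_names()
    sizes = dict(zip(names, rng.integers(lo, hi + 1, size=len(names))))
    planted = sorted(set(config.effect_pathways) | set(config.rank_band_pathways))
    if sum(sizes[pw] for pw in planted) > n:
        raise ValueError("planted pathway sizes exceed n_ests")
    pool = rng.permutation(n)
    members: dict[str, np.ndarray] = {}
    offset = 0
    for pw in planted:
        members[pw] = np.sort(pool[offset : offset + sizes[pw]])
        offset += sizes[pw]
    for pw in names:
        if pw not in members:
            members[pw] = np.sort(rng.choice(n, size=sizes[pw], replace=False))

    # rank-band pathways: permute the baseline values so each band pathway's
    # members occupy rank positions drawn uniformly inside its band, with rank
    # 0 the most abundant EST; the value multiset is unchanged
    if config.rank_band_pathways:
        sorted_vals = np.sort(baseline)[::-1]
        rank_taken = np.zeros(n, dtype=bool)
        placed = np.zeros(n, dtype=bool)
        new_baseline = baseline.copy()
        for pw, (band_lo, band_hi) in sorted(config.rank_band_pathways.items()):
            lo_i, hi_i = int(np.floor(band_lo * n)), int(np.ceil(band_hi * n))
            avail = np.flatnonzero(~rank_taken[lo_i:hi_i]) + lo_i
            if len(avail) < len(members[pw]):
                raise ValueError(
                    f"rank band ({band_lo}, {band_hi}) too narrow for pathway {pw} "
                    f"({len(members[pw])} members, {len(avail)} free ranks)"
                )
            picked = rng.choice(avail, size=len(members[pw]), replace=False)
            rank_taken[picked] = True
            new_baseline[members[pw]] = sorted_vals[np.sort(picked)]
            placed[members[pw]] = True
        free_ests = np.flatnonzero(~placed)
        free_ranks = np.flatnonzero(~rank_taken)
        # remaining ESTs keep their relative order among the remaining values
        order = free_ests[np.argsort(-baseline[free_ests], kind="stable")]
        new_baseline[order] = sorted_vals[free_ranks]
        baseline = new_baseline

    mean_nr = baseline.copy()
    mean_nd = baseline.copy()
    differential = set()
    for pw, shift in sorted(config.effect_pathways.items()):
        mean_nd[members[pw]] = baseline[members[pw]] * 2.0**shift
        if shift != 0:
            differential.update(est_ids[members[pw]])

    nd = _noisy_replicates(mean_nd, config.replicate_cv, config.n_replicates, rng)
    nr = _noisy_replicates(mean_nr, config.replicate_cv, config.n_replicates, rng)

    # multi-copy EC groups: copy counts from a shifted Poisson
    ec = np.full(n, "", dtype=object)
    if config.n_ec_groups > 0:
        copies = 1 + rng.poisson(config.copies_per_ec_mean - 1.0, config.n_ec_groups)
        if copies.sum() > n:
            raise ValueError("EC group copies exceed n_ests; reduce n_ec_groups")
        carriers = rng.permutation(n)[: copies.sum()]
        pos = 0
        for g, c in enumerate(copies):
            ec[carriers[pos : pos + c]] = f"ec{g:04d}"
            pos += c

    pathway_col = np.full(n, "", dtype=object)
    membership: dict[int, list[str]] = {}
    for pw in names:
        for i in members[pw]:
            membership.setdefault(int(i), []).append(pw)
    for i, pws in membership.items():
        pathway_col[i] = ";".join(sorted(pws))

    table = pd.DataFrame({"est_id": est_ids, "annotation": [f"protein_{i:05d}" for i in range(n)],
                          "pathways": pathway_col, "ec": ec})
    for r in range(config.n_replicates):
        table[f"ND_{r + 1}"] = nd[:, r]
    for r in range(config.n_replicates):
        table[f"NR_{r + 1}"] = nr[:, r]

    enriched = set()
    if config.rank_band_pathways:
        windows = make_windows(n, 0.10, 0.05)
        for pw, (band_lo, band_hi) in config.rank_band_pathways.items():
            b_start, b_end = band_lo * n, band_hi * n
            for w in windows:
                if w.start < b_end and b_start < w.end:  # overlap
                    enriched.add((w.index, pw))

    truth = SyntheticTruth(
        seed=config.seed,
        differential_est_ids=frozenset(differential),
        enriched_window_pathways=frozenset(enriched),
    )
    return table, truth


def generate_null_expression(config: ExpressionConfig):
    """Same data shape with no planted effects; membership is uniform.

    Used for type-I-error calibration of the downstream enrichment and
    differential screens.
    """
    null_config = replace(config, effect_pathways={}, rank_band_pathways={})
    table, _ = generate_expression(null_config)
    return table, SyntheticTruth(seed=config.seed)


# --- lipidome ---------------------------------------------------------------

#: the eight acyl chains seen as major FAME peaks in this organism
DEFAULT_CHAIN_POOL = (
    (14, 0, None),
    (16, 0, None),
    (16, 1, "n-5"),
    (18, 0, None),
    (18, 1, "n-9"),
    (18, 2, "n-6"),
    (18, 3, "n-6"),
    (20, 4, "n-6"),
    (20, 5, "n-3"),
)

#: 80 species across the 12 observed lipid classes
DEFAULT_LIPID_CLASSES = (
    ("DGDG", 5), ("MGDG", 8), ("MGMG", 1), ("DAG", 6), ("TAG", 20),
    ("PC", 15), ("PE", 6), ("PG", 4), ("LPC", 4), ("LPE", 3), ("LPG", 2),
    ("FFA", 6),
)


@dataclass(frozen=True)
class LipidomeConfig:
    """Shape and planted remodeling of a synthetic lipidome table.

    ``f_prokaryotic`` is the fraction of the planted net TAG increase carried
    by species with a 16-carbon sn2 chain; ``remodel_pairs`` plants that many
    falling galactolipid species whose diacyl signature reappears in a rising
    DAG (exact) or TAG (embedded) species.  ``tag_increase_fold`` sets the
    planted whole-class TAG gain (ND approx. tag_increase_fold x NR, the
    five-fold rise seen three days after nitrogen removal).
    """

    classes: tuple = DEFAULT_LIPID_CLASSES
    chain_pool: tuple = DEFAULT_CHAIN_POOL
    f_prokaryotic: float = 0.7
    remodel_pairs: int = 5
    tag_increase_fold: float = 5.0
    effect_sd: float = 0.1
    replicate_cv: float = 0.1
    baseline_log_mean: float = 1.0  # natural-log moles per million cells
    baseline_log_sd: float = 1.2
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.chain_pool:
            raise ValueError("invariant chain_pool non-empty violated")
        if not 0.0 <= self.f_prokaryotic <= 1.0:
            raise ValueError(
                f"invariant 0 <= f_prokaryotic <= 1 violated: {self.f_prokaryotic}"
            )
        if any(count < 0 for _, count in self.classes):
            raise ValueError("invariant class species counts >= 0 violated")
        if self.remodel_pairs < 0:
            raise ValueError("invariant remodel_pairs >= 0 violated")
        if self.replicate_cv <= 0:
            raise ValueError(f"invariant replicate_cv > 0 violated: {self.replicate_cv}")
        if self.tag_increase_fold <= 1:
            raise ValueError("tag_increase_fold must exceed 1")


def _pool_chains(config: LipidomeConfig) -> list[AcylChain]:
    return [AcylChain(c, d, o) for c, d, o in config.chain_pool]


def _pick(chains: Sequence[AcylChain], rng) -> AcylChain:
    return chains[int(rng.integers(len(chains)))]


def _make_species(lipid_class: str, config: LipidomeConfig, rng, taken: set, idx: int):
    """One unique species of a class under its sn2 composition rules."""
    pool = _pool_chains(config)
    c16 = [c for c in pool if c.carbons == 16] or pool
    long = [c for c in pool if c.carbons >= 18] or pool
    # PC carries the sn2 PUFAs profiled downstream (one 18:3, three 20:4, one 20:5)
    pc_sn2_plan = [
        AcylChain(18, 3, "n-6"), AcylChain(20, 4, "n-6"), AcylChain(20, 4, "n-6"),
        AcylChain(20, 4, "n-6"), AcylChain(20, 5, "n-3"),
    ]
    for _ in range(300):
        if lipid_class == "DGDG":  # plastid-made: prokaryotic sn2
            chains = (_pick(pool, rng), _pick(c16, rng))
        elif lipid_class == "MGDG":  # mostly prokaryotic, some ER-derived
            sn2 = _pick(c16, rng) if idx % 4 else _pick(long, rng)
            chains = (_pick(pool, rng), sn2)
        elif lipid_class in ("PC", "PE"):  # ER-made: long sn2
            sn2 = pc_sn2_plan[idx] if lipid_class == "PC" and idx < len(pc_sn2_plan) else _pick(long, rng)
            chains = (_pick(pool, rng), sn2)
        elif lipid_class == "PG":
            chains = (AcylChain(16, 0), AcylChain(20, 5, "n-3")) if idx == 0 else (
                _pick(pool, rng), _pick(pool, rng))
        elif lipid_class == "DAG":
            sn2 = _pick(c16, rng) if rng.random() < 0.7 else _pick(pool, rng)
            chains = (_pick(pool, rng), sn2)
        elif lipid_class == "TAG":  # half prokaryotic, half eukaryotic sn2
            sn2 = _pick(c16, rng) if idx % 2 == 0 else _pick(long, rng)
            chains = (_pick(pool, rng), sn2, _pick(pool, rng))
        else:  # mono-acyl classes
            chains = (_pick(pool, rng),)
        species = LipidSpecies(lipid_class, chains)
        if species.name not in taken:
            taken.add(species.name)
            return species
    return None  # pool exhausted for this class


def generate_lipidome(config: LipidomeConfig):
    """Generate a lipidome table plus the truth of its planted remodeling.

    Class-level ND/NR trends mirror nitrogen deprivation in this organism:
    neutral lipids (DAG, TAG) and the acyl-editing phospholipids (PC, PE)
    rise, photosynthetic membrane and lyso-lipids fall, MGDG splits by
    origin stratum (prokaryotic down, eukaryotic up), and PC species with
    PUFA at sn2 fall.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    taken: set = set()
    species: list[LipidSpecies] = []
    for lipid_class, count in config.classes:
        for idx in range(count):
            sp = _make_species(lipid_class, config, rng, taken, idx)
            if sp is not None:
                species.append(sp)

    def jitter() -> float:
        return float(rng.normal(0.0, config.effect_sd))

    # planted membrane -> neutral remodeling: falling DGDG/MGDG sources whose
    # signature reappears in a rising DAG (exact) or TAG (embedded) target
    baseline = {sp.name: float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))
                for sp in species}
    # sources are drawn from the prokaryotic, within-class-major galactolipid
    # pool, so every TAG trace target inherits a 16-carbon sn2 chain and every
    # source survives the major-species filter of the downstream trace search
    galacto: list[LipidSpecies] = []
    for cls in ("DGDG", "MGDG"):
        cls_species = sorted(
            (sp for sp in species if sp.lipid_class == cls),
            key=lambda sp: (-baseline[sp.name], sp.name),
        )
        n_major = len(cls_species) if len(cls_species) <= 5 else -(-len(cls_species) // 2)
        galacto.extend(
            sp
            for sp in cls_species[:n_major]
            if classify_origin(sp).origin == "prokaryotic"
        )
    galacto.sort(key=lambda sp: (-baseline[sp.name], sp.name))
    log2_shift: dict[str, float] = {}
    trace_pairs: list = []
    tag_targets: list[LipidSpecies] = []
    for i, src in enumerate(galacto[: config.remodel_pairs]):
        log2_shift[src.name] = -(1.4 + abs(jitter()))  # ~2.6-fold drop
        if i % 2 == 0:
            target = LipidSpecies("DAG", src.chains)
            log2_shift[target.name] = 1.8 + abs(jitter())  # ~3.5-fold rise
        else:
            extra = _pool_chains(config)[int(rng.integers(len(config.chain_pool)))]
            target = LipidSpecies("TAG", (src.sn1, src.sn2, extra))
            tag_targets.append(target)
        if target.name not in taken:
            taken.add(target.name)
            species.append(target)
            baseline[target.name] = float(
                rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
            )
        trace_pairs.append((src.name, target.name))

    # class-level trends planted as log2 shifts on the ND mean (TAG handled
    # separately through the additive increase budget below)
    for sp in species:
        if sp.name in log2_shift or sp.lipid_class == "TAG":
            continue
        cls = sp.lipid_class
        if cls == "PC":
            pufa_sn2 = sp.sn2.double_bonds >= 3
            log2_shift[sp.name] = (-1.0 if pufa_sn2 else 0.6) + jitter()
        elif cls in ("PE", "DAG"):
            log2_shift[sp.name] = 0.5 + jitter()
        elif cls == "MGDG":
            stratum = classify_origin(sp).origin
            log2_shift[sp.name] = (-0.5 if stratum == "prokaryotic" else 0.5) + jitter()
        elif cls in ("DGDG", "PG", "LPC", "LPE", "LPG", "FFA", "MGMG"):
            log2_shift[sp.name] = -0.5 + jitter()
        else:
            log2_shift[sp.name] = 0.0

    mean_nr = {name: level for name, level in baseline.items()}
    mean_nd = {
        sp.name: baseline[sp.name] * 2.0 ** log2_shift.get(sp.name, 0.0) for sp in species
    }

    # distribute the planted net TAG increase across origin strata so that a
    # fraction f_prokaryotic of the gain sits on 16-carbon-sn2 species
    tag_species = [sp for sp in species if sp.lipid_class == "TAG"]
    total_tag_nr = sum(mean_nr[sp.name] for sp in tag_species)
    budget = (config.tag_increase_fold - 1.0) * total_tag_nr
    prok = [sp for sp in tag_species if classify_origin(sp).origin == "prokaryotic"]
    euk = [sp for sp in tag_species if classify_origin(sp).origin == "eukaryotic"]
    prok_carriers = tag_targets or sorted(prok, key=lambda sp: (-mean_nr[sp.name], sp.name))[:3]
    euk_carriers = sorted(euk, key=lambda sp: (-mean_nr[sp.name], sp.name))[:3]
    planted_tag: list[str] = []
    f = config.f_prokaryotic
    if budget > 0 and f > 0:
        if not prok_carriers:
            raise ValueError("no prokaryotic TAG species available to carry the increase")
        for sp in prok_carriers:
            mean_nd[sp.name] += f * budget / len(prok_carriers)
            planted_tag.append(sp.name)
    if budget > 0 and f < 1:
        if not euk_carriers:
            raise ValueError("no eukaryotic TAG species available to carry the increase")
        for sp in euk_carriers:
            mean_nd[sp.name] += (1.0 - f) * budget / len(euk_carriers)
            planted_tag.append(sp.name)

    order = sorted(species, key=lambda sp: (sp.lipid_class, sp.name))
    nd_means = np.array([mean_nd[sp.name] for sp in order])
    nr_means = np.array([mean_nr[sp.name] for sp in order])
    nd = _noisy_replicates(nd_means, config.replicate_cv, config.n_replicates, rng)
    nr = _noisy_replicates(nr_means, config.replicate_cv, config.n_replicates, rng)

    table = pd.DataFrame(
        {"species": [sp.name for sp in order], "lipid_class": [sp.lipid_class for sp in order]}
    )
    for r in range(config.n_replicates):
        table[f"ND_{r + 1}"] = nd[:, r]
    for r in range(config.n_replicates):
        table[f"NR_{r + 1}"] = nr[:, r]

    truth = SyntheticTruth(
        seed=config.seed,
        differential_est_ids=frozenset(log2_shift) | frozenset(planted_tag),
        planted_trace_pairs=tuple(trace_pairs),
        planted_f_prokaryotic=f if budget > 0 else None,
        planted_tag_increases=tuple(sorted(planted_tag)),
    )
    return table, truth
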