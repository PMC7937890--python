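"""Synthetic genomes, planted Rsm regulons and pulldown/control tag libraries.

The generator emulates the structure of a bacterial RAP-Seq experiment on a
single-chromosome genome: a feature catalogue with coding genes, ncRNAs,
head-to-head divergent gene pairs and multi-copy IS-like repeat elements;
three RNA-binding proteins whose planted target sets realise a designed
seven-class Venn partition; and, per protein and biological replicate, one
total-RNA control plus three technical-replicate pulldown libraries drawn
multinomially from a log-normal transcript abundance model with a uniform
background floor.  Pulldown libraries multiply each planted target's
abundance by its enrichment factor before renormalisation, so deep
libraries recover the factor only up to the normalisation constant -- as in
a real pulldown, where enrichment is relative to the sampled RNA pool.

Every operation is deterministic in (config, seed): per-library random
substreams are derived from the master seed by fixed-order keys, so adding
a library never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .formats import Feature, GenomeAnnotation, TagLibrary

REPLICON = "replicon_1"

VennDesign = Mapping[tuple[str, ...], int]

#: desk-scale default regulon design: set sizes 17/18/14, union 30 -- the
#: published-study shape (241/261/206, union 437) scaled by ~1/15, keeping
#: the exclusive fractions (~35% / ~39% / ~21%) and the dominant triple class
DEFAULT_VENN_DESIGN: dict[tuple[str, ...], int] = {
    ("RsmA", "RsmE", "RsmI"): 5,
    ("RsmA", "RsmE"): 3,
    ("RsmA", "RsmI"): 3,
    ("RsmE", "RsmI"): 3,
    ("RsmA",): 6,
    ("RsmE",): 7,
    ("RsmI",): 3,
}

#: full-scale design reproducing the published per-protein set sizes
#: 241/261/206 with 75 triple-shared targets, union 437 and every pairwise
#: class inside 36..45 (forced to AE=36, AI=40, EI=45 by inclusion-exclusion)
FULL_SCALE_VENN_DESIGN: dict[tuple[str, ...], int] = {
    ("RsmA", "RsmE", "RsmI"): 75,
    ("RsmA", "RsmE"): 36,
    ("RsmA", "RsmI"): 40,
    ("RsmE", "RsmI"): 45,
    ("RsmA",): 90,
    ("RsmE",): 105,
    ("RsmI",): 46,
}


def design_set_sizes(design: VennDesign) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for cls, n in design.items():
        for p in cls:
            sizes[p] = sizes.get(p, 0) + n
    return sizes


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Defaults are a desk-scale rendition of the study design: an ~500 kb
    single-replicon genome with 300 features, tag depths of 200,000
    (pulldown) / 400,000 (control) per library, three technical replicate
    extractions per culture, and 2/3/2 biological replicates for
    RsmA/RsmE/RsmI (one RsmA and one RsmI culture failed QC in the study).
    """

    genome_length: int = 500_000
    n_features: int = 240
    frac_ncrna: float = 0.08
    n_divergent_pairs: int = 15
    n_repeat_groups: int = 3
    repeat_copies: int = 3
    gene_length_range: tuple[int, int] = (300, 800)
    ncrna_length_range: tuple[int, int] = (80, 300)
    venn_design: VennDesign = field(
        default_factory=lambda: dict(DEFAULT_VENN_DESIGN)
    )
    enrichment_lo: float = 4.0
    enrichment_hi: float = 16.0
    abundance_sigma: float = 1.0
    #: planted targets are drawn from the expressed transcriptome: their
    #: abundance is floored at this multiple of the median transcript level
    #: (an RNA the experiment can identify must be sequenced deeply enough
    #: in the control; sub-floor transcripts stay in the background model)
    target_expression_floor: float = 0.9
    bio_rep_sigma: float = 0.1
    background_fraction: float = 0.05
    #: per technical replicate, this many random loci receive a mild
    #: nonspecific enrichment drawn log-uniformly from
    #: ``carryover_factor_range`` -- single-extraction affinity artifacts.
    #: They are what the three-technical-replicate consensus rule removes,
    #: and they populate the sub-cut-off tail of the score distributions.
    carryover_n_loci: int = 8
    carryover_factor_range: tuple[float, float] = (1.5, 3.5)
    #: forbid two planted targets of the same protein on adjacent features,
    #: so each planted locus is identifiable as its own peak (adjacent
    #: same-protein targets would merge into one enriched region)
    space_planted_targets: bool = True
    pulldown_depth: int = 200_000
    control_depth: int = 400_000
    n_bio_reps: Mapping[str, int] = field(
        default_factory=lambda: {"RsmA": 2, "RsmE": 3, "RsmI": 2}
    )
    n_tech_reps: int = 3
    resample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_features < 0:
            raise ValueError("genome_length and n_features must be positive")
        if not (0.0 < self.resample_fraction <= 1.0):
            raise ValueError("resample_fraction must lie in (0, 1]")
        if self.pulldown_depth <= 0 or self.control_depth <= 0:
            raise ValueError("tag depths must be > 0")
        if any(n < 0 for n in self.venn_design.values()):
            raise ValueError("Venn class counts must be >= 0")
        for prot, n in self.n_bio_reps.items():
            if n not in (2, 3):
                raise ValueError(f"{prot}: 2 or 3 biological replicates supported")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError("background_fraction must lie in [0, 1)")
        if self.enrichment_lo < 1.0 or self.enrichment_hi < self.enrichment_lo:
            raise ValueError("enrichment range must satisfy 1 <= lo <= hi")

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_bio_reps))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-protein target sets with enrichment factors."""

    target_sets: dict[str, frozenset[str]]
    enrichment: dict[tuple[str, str], float]  # (protein, locus) -> factor
    venn_class: dict[str, tuple[str, ...]]  # locus -> membership class

    def __post_init__(self) -> None:
        for (prot, locus), f in self.enrichment.items():
            if f < 1.0:
                raise ValueError(f"enrichment factor < 1 for {prot}/{locus}")
        for locus, cls in self.venn_class.items():
            for p in cls:
                if locus not in self.target_sets[p]:
                    raise ValueError(f"{locus} missing from {p} despite class {cls}")


class CapacityError(ValueError):
    """Feature demand exceeds the genome length."""


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def generate_genome_annotation(
    config: SimulationConfig, seed: Optional[int] = None
) -> GenomeAnnotation:
    """Lay out a non-overlapping feature catalogue on one replicon.

    Features are separated by intergenic gaps; divergent pairs are adjacent
    (-,+) gene pairs sharing a short upstream gap; repeat copies within a
    group are position-only exact duplicates (identical length, shared
    group name) dispersed across the genome.
    """
    seed = config.seed if seed is None else seed
    rng = _child_rng(seed, 1)
    n_ncrna = int(round(config.frac_ncrna * config.n_features))
    n_repeat = config.n_repeat_groups * config.repeat_copies
    n_divergent = 2 * config.n_divergent_pairs
    n_pseudo = min(2, max(0, config.n_features - n_ncrna - n_repeat - n_divergent))
    n_plain = config.n_features - n_ncrna - n_repeat - n_divergent - n_pseudo
    if n_plain < 0:
        raise CapacityError("feature composition exceeds n_features")

    g_lo, g_hi = config.gene_length_range
    nc_lo, nc_hi = config.ncrna_length_range
    repeat_lengths = {
        g: int(rng.integers(600, 1201)) for g in range(config.n_repeat_groups)
    }
    # layout units: a unit is one feature or one divergent head-to-head pair
    # (two genes with a short shared upstream gap); units are shuffled, then
    # spread over the whole replicon by scaling the inter-unit gaps
    plan: list[tuple[str, object]] = (
        [("divergent", None)] * config.n_divergent_pairs
        + [("ncRNA", None)] * n_ncrna
        + [("repeat", g) for g in range(config.n_repeat_groups)
           for _ in range(config.repeat_copies)]
        + [("pseudogene", None)] * n_pseudo
        + [("coding", None)] * n_plain
    )
    rng.shuffle(plan)

    units: list[list[tuple[str, int, str, Optional[str]]]] = []
    for kind, payload in plan:
        if kind == "divergent":
            len1 = int(rng.integers(g_lo, g_hi + 1))
            len2 = int(rng.integers(g_lo, g_hi + 1))
            shared_gap = int(rng.integers(80, 151))
            units.append(
                [("coding_gene", len1, "-", None),
                 ("coding_gene", -shared_gap, "", None),  # sentinel: gap
                 ("coding_gene", len2, "+", None)]
            )
            continue
        if kind == "ncRNA":
            length, ftype, name = int(rng.integers(nc_lo, nc_hi + 1)), "ncRNA", None
        elif kind == "repeat":
            length = repeat_lengths[payload]  # type: ignore[index]
            ftype, name = "repeat_element", f"ISgrp{payload}"
        elif kind == "pseudogene":
            length, ftype, name = int(rng.integers(300, 801)), "pseudogene", None
        else:
            length, ftype, name = int(rng.integers(g_lo, g_hi + 1)), "coding_gene", None
        strand = "+" if rng.random() < 0.5 else "-"
        units.append([(ftype, length, strand, name)])

    unit_spans = [
        sum(abs(length) for _, length, _, _ in unit) for unit in units
    ]
    min_gap = 300  # keeps extended-fragment bleed from bridging units
    n_gaps = len(units) + 1
    leftover = config.genome_length - sum(unit_spans) - min_gap * n_gaps
    if leftover < 0:
        raise CapacityError(
            f"feature layout needs {sum(unit_spans) + min_gap * n_gaps} nt "
            f"but the genome is {config.genome_length} nt"
        )
    weights = rng.uniform(0.5, 1.5, size=n_gaps)
    extra = np.floor(weights / weights.sum() * leftover).astype(int)

    raw: list[tuple[str, int, int, str, Optional[str]]] = []
    cursor = 0
    for i, unit in enumerate(units):
        cursor += min_gap + int(extra[i])
        for ftype, length, strand, name in unit:
            if length < 0:  # intra-pair shared gap
                cursor += -length
                continue
            raw.append((ftype, cursor, cursor + length, strand, name))
            cursor += length
    if cursor + min_gap > config.genome_length:
        raise CapacityError("feature layout overflow")
    features = tuple(
        Feature(
            locus_id=f"SYN_{i + 1:04d}",
            type=ftype,
            replicon=REPLICON,
            start=start,
            end=end,
            strand=strand,
            name=name,
        )
        for i, (ftype, start, end, strand, name) in enumerate(raw)
    )
    return GenomeAnnotation(
        replicons=((REPLICON, config.genome_length),), features=features
    )


def plant_targets(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> SyntheticTruth:
    """Sample planted target sets realising the designed Venn partition.

    Loci are drawn without replacement; membership classes are assigned so
    the partition of the three sets equals the design exactly.  Enrichment
    factors are i.i.d. log-uniform over the configured range, drawn
    independently per (protein, locus).
    """
    seed = config.seed if seed is None else seed
    rng = _child_rng(seed, 2)
    design = {tuple(sorted(cls)): n for cls, n in config.venn_design.items()}
    n_union = sum(design.values())
    pool = [f.locus_id for f in annotation.features]  # coordinate order
    if n_union > len(pool):
        biggest = max(design, key=design.get)  # type: ignore[arg-type]
        raise ValueError(
            f"infeasible Venn design: {n_union} loci needed, {len(pool)} "
            f"available (largest class {biggest} = {design[biggest]})"
        )
    slots: list[tuple[str, ...]] = [
        cls for cls in sorted(design) for _ in range(design[cls])
    ]
    venn_class = _place_targets(
        rng, pool, slots, spaced=config.space_planted_targets
    )
    sets: dict[str, set[str]] = {p: set() for p in ("RsmA", "RsmE", "RsmI")}
    for locus, cls in venn_class.items():
        for p in cls:
            sets[p].add(locus)
    log_lo, log_hi = math.log(config.enrichment_lo), math.log(config.enrichment_hi)
    enrichment = {
        (p, locus): float(np.exp(rng.uniform(log_lo, log_hi)))
        for p in sorted(sets)
        for locus in sorted(sets[p])
    }
    return SyntheticTruth(
        target_sets={p: frozenset(s) for p, s in sets.items()},
        enrichment=enrichment,
        venn_class=venn_class,
    )


def _place_targets(
    rng: np.random.Generator,
    pool: Sequence[str],
    slots: Sequence[tuple[str, ...]],
    spaced: bool,
    max_attempts: int = 50,
) -> dict[str, tuple[str, ...]]:
    """Assign membership classes to loci sampled without replacement.

    With ``spaced`` on, no two loci planted for the same protein may be
    adjacent in genome order (their enriched regions would merge into one
    peak and become inseparable); assignment is greedy over a shuffled pool
    with restarts.
    """
    index = {locus: i for i, locus in enumerate(pool)}
    for _ in range(max_attempts):
        order = list(rng.permutation(len(pool)))
        assigned: dict[int, tuple[str, ...]] = {}
        ok = True
        for cls in slots:
            placed = False
            for pos, i in enumerate(order):
                if i in assigned:
                    continue
                if spaced:
                    clash = False
                    for j in (i - 1, i + 1):
                        if j in assigned and set(assigned[j]) & set(cls):
                            clash = True
                            break
                    if clash:
                        continue
                assigned[i] = cls
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return {pool[i]: cls for i, cls in sorted(assigned.items())}
    raise ValueError(
        "could not place the designed targets with the spacing constraint; "
        "reduce the design or disable space_planted_targets"
    )


def _base_abundances(
    annotation: GenomeAnnotation, config: SimulationConfig, seed: int
) -> np.ndarray:
    """Log-normal transcript abundances (median 1); repeat copies share one
    draw split uniformly across copies."""
    rng = _child_rng(seed, 3)
    feats = annotation.features
    a = np.empty(len(feats))
    group_draw: dict[str, float] = {}
    group_size: dict[str, int] = {}
    for f in feats:
        if f.type == "repeat_element" and f.name:
            group_size[f.name] = group_size.get(f.name, 0) + 1
    for i, f in enumerate(feats):
        if f.type == "repeat_element" and f.name:
            if f.name not in group_draw:
                group_draw[f.name] = float(
                    rng.lognormal(0.0, config.abundance_sigma)
                )
            a[i] = group_draw[f.name] / group_size[f.name]
        else:
            a[i] = float(rng.lognormal(0.0, config.abundance_sigma))
    return a


_ROLE_IDX = {"pulldown": 0, "total_control": 1}
_PROT_IDX = {"RsmA": 0, "RsmE": 1, "RsmI": 2}


def _draw_library(
    rng: np.random.Generator,
    annotation: GenomeAnnotation,
    weights: np.ndarray,
    depth: int,
    config: SimulationConfig,
) -> tuple[tuple[str, int, str], ...]:
    """Multinomial draw of ``depth`` unstranded tag 5' positions."""
    feats = annotation.features
    bg = config.background_fraction
    probs = np.concatenate((weights / weights.sum() * (1.0 - bg), [bg]))
    counts = rng.multinomial(depth, probs)
    genome_len = annotation.replicon_lengths[REPLICON]
    positions = np.empty(depth, dtype=np.int64)
    off = 0
    for i, f in enumerate(feats):
        n = counts[i]
        if n:
            positions[off:off + n] = rng.integers(f.start, f.end, size=n)
            off += n
    n_bg = counts[-1]
    if n_bg:
        positions[off:off + n_bg] = rng.integers(0, genome_len, size=n_bg)
    strands = rng.random(depth) < 0.5
    return tuple(
        (REPLICON, int(p), "+" if s else "-") for p, s in zip(positions, strands)
    )


def simulate_tag_libraries(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> list[TagLibrary]:
    """Simulate, per protein and biological replicate, one total-RNA control
    and ``n_tech_reps`` pulldown libraries.

    Controls draw from the abundance model alone; pulldowns multiply each
    planted target's abundance by its enrichment factor before the
    multinomial normalisation.  Technical replicates share the biological
    replicate's expectation; with ``resample_fraction`` < 1 a fixed portion
    of each technical replicate is copied from a shared master draw and
    only the remainder is resampled.
    """
    seed = config.seed if seed is None else seed
    feats = annotation.features
    base = _base_abundances(annotation, config, seed)
    locus_index = {f.locus_id: i for i, f in enumerate(feats)}
    # planted targets belong to the expressed transcriptome: floor their
    # abundance at target_expression_floor x the median transcript level
    planted_union = set().union(*truth.target_sets.values())
    for locus in planted_union:
        i = locus_index[locus]
        base[i] = max(base[i], config.target_expression_floor)
    libraries: list[TagLibrary] = []
    for protein in config.proteins:
        factors = np.ones(len(feats))
        for locus in truth.target_sets.get(protein, frozenset()):
            factors[locus_index[locus]] = truth.enrichment[(protein, locus)]
        for bio in range(1, config.n_bio_reps[protein] + 1):
            rng_bio = _child_rng(seed, 4, _PROT_IDX[protein], bio)
            bio_abund = base * rng_bio.lognormal(
                0.0, config.bio_rep_sigma, size=len(feats)
            )
            ctrl_rng = _child_rng(seed, 5, _PROT_IDX[protein], bio, 1, 0)
            libraries.append(
                TagLibrary(
                    sample_id=f"{protein}_b{bio}_ctrl",
                    protein=protein,
                    role="total_control",
                    bio_rep=bio,
                    tech_rep=1,
                    replicons=annotation.replicons,
                    tags=_draw_library(
                        ctrl_rng, annotation, bio_abund, config.control_depth, config
                    ),
                )
            )
            pd_weights = bio_abund * factors
            master: tuple[tuple[str, int, str], ...] | None = None
            if config.resample_fraction < 1.0:
                master_rng = _child_rng(seed, 5, _PROT_IDX[protein], bio, 0, 2)
                master = _draw_library(
                    master_rng, annotation, pd_weights, config.pulldown_depth, config
                )
            for tech in range(1, config.n_tech_reps + 1):
                rng_t = _child_rng(seed, 5, _PROT_IDX[protein], bio, tech, 1)
                tech_weights = pd_weights
                if config.carryover_n_loci > 0:
                    tech_weights = pd_weights.copy()
                    picks = rng_t.choice(
                        len(feats),
                        size=min(config.carryover_n_loci, len(feats)),
                        replace=False,
                    )
                    lo, hi = config.carryover_factor_range
                    tech_weights[picks] *= np.exp(
                        rng_t.uniform(np.log(lo), np.log(hi), size=picks.size)
                    )
                n_fresh = int(round(config.resample_fraction * config.pulldown_depth))
                fresh = _draw_library(
                    rng_t, annotation, tech_weights, n_fresh, config
                ) if n_fresh else ()
                kept = master[: config.pulldown_depth - n_fresh] if master else ()
                libraries.append(
                    TagLibrary(
                        sample_id=f"{protein}_b{bio}_t{tech}_pd",
                        protein=protein,
                        role="pulldown",
                        bio_rep=bio,
                        tech_rep=tech,
                        replicons=annotation.replicons,
                        tags=kept + fresh,
                    )
                )
    return libraries
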