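"""Cross-protein regulon comparison and recovery scoring.

Operates on per-protein sets of unique target loci: three-set Venn
partitioning with exact inclusion-exclusion, per-protein exclusive
fractions, confusion-matrix scoring against a planted truth, and the
ratio-of-ratios competitive colonization fitness index used for the plant
assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotate import UniqueTarget

#: the 7 disjoint membership classes of a three-set Venn diagram, keyed by
#: the sorted tuple of member proteins
VENN_CLASSES = (
    ("RsmA",),
    ("RsmE",),
    ("RsmI",),
    ("RsmA", "RsmE"),
    ("RsmA", "RsmI"),
    ("RsmE", "RsmI"),
    ("RsmA", "RsmE", "RsmI"),
)


@dataclass(frozen=True)
class VennSummary:
    """Set sizes, disjoint class counts and exclusivity of three regulons."""

    set_sizes: dict[str, int]
    class_counts: dict[tuple[str, ...], int]
    union_size: int
    exclusive_fractions: dict[str, Optional[float]]

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.union_size:
            raise AssertionError("disjoint class counts do not sum to the union")
        for prot, size in self.set_sizes.items():
            implied = sum(
                c for cls, c in self.class_counts.items() if prot in cls
            )
            if implied != size:
                raise AssertionError(
                    f"inclusion-exclusion violated for {prot}: {implied} != {size}"
                )


@dataclass(frozen=True)
class RecoveryReport:
    """Per-protein confusion-matrix scores against the planted truth."""

    per_protein: dict[str, dict[str, float]]


def venn_partition(target_sets: Mapping[str, set[str]]) -> VennSummary:
    """Exact disjoint-class counts for the per-protein target sets."""
    proteins = sorted(target_sets)
    all_loci = set().union(*target_sets.values()) if target_sets else set()
    counts: dict[tuple[str, ...], int] = {
        cls: 0 for cls in VENN_CLASSES if all(p in proteins for p in cls)
    }
    if not counts:  # arbitrary protein names: build classes on the fly
        counts = {}
    for locus in all_loci:
        cls = tuple(sorted(p for p in proteins if locus in target_sets[p]))
        counts[cls] = counts.get(cls, 0) + 1
    sizes = {p: len(s) for p, s in target_sets.items()}
    exclusive = {}
    for p in proteins:
        only = counts.get((p,), 0)
        exclusive[p] = round(100.0 * only / sizes[p], 1) if sizes[p] else None
    return VennSummary(
        set_sizes=sizes,
        class_counts=counts,
        union_size=len(all_loci),
        exclusive_fractions=exclusive,
    )


def exclusivity_fractions(summary: VennSummary) -> dict[str, Optional[float]]:
    """Percent of each protein's targets bound by no other protein (1 dp)."""
    return dict(summary.exclusive_fractions)


def recovery_metrics(
    called: Mapping[str, Sequence[UniqueTarget] | set[str]],
    truth_sets: Mapping[str, set[str]],
    strict: bool = False,
) -> RecoveryReport:
    """Precision/recall/F1 of called targets against planted truth sets.

    ``called`` maps protein to either a set of locus ids or a list of
    :class:`UniqueTarget`.  By default an ambiguous assignment counts as a
    true positive when any of its candidate loci is planted; ``strict``
    requires the primary label itself to be planted.
    """
    per: dict[str, dict[str, float]] = {}
    for protein, truth in truth_sets.items():
        calls = called.get(protein, set())
        tp = 0
        fp = 0
        matched: set[str] = set()
        if isinstance(calls, set):
            items: list[tuple[str, tuple[str, ...]]] = [(c, (c,)) for c in calls]
        else:
            items = [
                (u.locus_id, u.candidate_loci if not strict else (u.locus_id,))
                for u in calls
            ]
        for label, cands in items:
            hit = {c for c in cands if c in truth}
            if label in truth:
                hit.add(label)
            if hit:
                tp += 1
                matched.update(hit)
            else:
                fp += 1
        fn = len(truth - matched)
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / len(truth) if truth else None
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision and recall
            else 0.0
        )
        per[protein] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return RecoveryReport(per_protein=per)


def competition_index(
    pct_wt_out: float,
    pct_mut_out: float,
    pct_wt_in: float,
    pct_mut_in: float,
) -> float:
    """Competitive colonization fitness index (ratio of ratios).

    index = (wt/mutant share in the inoculum) / (wt/mutant share recovered
    from the plant); 1 means equal colonization capacity, values below 1 a
    colonization defect of the mutant's competitor ratio.  All percentages
    must be positive -- a strain that is not recovered leaves the index
    undefined.
    """
    for v in (pct_wt_out, pct_mut_out, pct_wt_in, pct_mut_in):
        if v <= 0:
            raise ValueError("all percentages must be > 0")
    return (pct_wt_in / pct_mut_in) / (pct_wt_out / pct_mut_out)
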