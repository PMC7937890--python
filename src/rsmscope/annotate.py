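"""Assignment of enriched regions to RNA molecules and redundancy collapse.

Because the libraries are unstranded, an enriched region is compared against
features on both strands.  When a region overlaps several features -- the
typical case being divergently transcribed gene pairs sharing an upstream
intergenic stretch -- the feature containing the summit wins; without summit
containment the longest overlap wins, and an exact tie is flagged ambiguous
with every tied candidate reported.  Regions overlapping nothing are
first-class intergenic targets labelled by their flanking loci.  Multiple
regions falling in one RNA molecule are collapsed to a single unique target,
keeping the best-scoring region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .consensus import FilteredTarget
from .formats import Feature, GenomeAnnotation


@dataclass(frozen=True)
class FeatureAssignment:
    """Mapping of one enriched region to its most likely RNA molecule."""

    target: FilteredTarget
    candidates: tuple[tuple[str, int], ...]  # (locus_id, overlap length)
    chosen: tuple[str, ...]  # one locus, or several when ambiguous
    label: str  # chosen locus, or "intergenic:left|right"
    ambiguous: bool
    summit_in_feature: bool
    shared_repeat_copies: tuple[str, ...] = ()

    @property
    def intergenic(self) -> bool:
        return self.label.startswith("intergenic:")


@dataclass(frozen=True)
class UniqueTarget:
    """One record per RNA molecule per protein after redundancy collapse."""

    locus_id: str
    best: FilteredTarget
    fe_per_rep: tuple[float, ...]
    pv_per_rep: tuple[float, ...]
    ambiguous: bool
    candidate_loci: tuple[str, ...]
    n_collapsed: int = 1


def _overlap_len(f: Feature, start: int, end: int) -> int:
    return max(0, min(f.end, end) - max(f.start, start))


def assign_feature(
    target: FilteredTarget,
    annotation: GenomeAnnotation,
    summit_override: bool = True,
) -> FeatureAssignment:
    """Assign one enriched region to a feature or an intergenic label.

    Candidates are all features overlapping the region on either strand.
    The feature containing the summit is chosen when ``summit_override`` is
    on (the default); otherwise, and when no feature contains the summit,
    the maximal overlap length decides, with exact ties flagged ambiguous.
    Zero overlap yields an intergenic label carrying the nearest flanking
    locus on each side.
    """
    feats = annotation.features_on(target.replicon)
    overlapping = [
        (f, _overlap_len(f, target.start, target.end))
        for f in feats
        if _overlap_len(f, target.start, target.end) > 0
    ]
    if not overlapping:
        left = max(
            (f for f in feats if f.end <= target.start),
            key=lambda f: f.end,
            default=None,
        )
        right = min(
            (f for f in feats if f.start >= target.end),
            key=lambda f: f.start,
            default=None,
        )
        label = (
            f"intergenic:{left.locus_id if left else '.'}"
            f"|{right.locus_id if right else '.'}"
        )
        return FeatureAssignment(
            target=target,
            candidates=(),
            chosen=(),
            label=label,
            ambiguous=False,
            summit_in_feature=False,
        )

    containing = [f for f, _ in overlapping if f.start <= target.summit < f.end]
    if summit_override and containing:
        chosen = [containing[0]]
        summit_in = True
        ambiguous = False
    else:
        best_len = max(ov for _, ov in overlapping)
        tied = [f for f, ov in overlapping if ov == best_len]
        chosen = tied
        ambiguous = len(tied) > 1
        summit_in = any(f.start <= target.summit < f.end for f in tied)

    # identical repeat copies elsewhere share the placement
    shared: tuple[str, ...] = ()
    if len(chosen) == 1 and chosen[0].type == "repeat_element" and chosen[0].name:
        group = chosen[0].name
        shared = tuple(
            f.locus_id
            for f in annotation.features
            if f.type == "repeat_element"
            and f.name == group
            and f.locus_id != chosen[0].locus_id
        )

    return FeatureAssignment(
        target=target,
        candidates=tuple((f.locus_id, ov) for f, ov in overlapping),
        chosen=tuple(f.locus_id for f in chosen),
        label=chosen[0].locus_id if not ambiguous else "|".join(
            f.locus_id for f in chosen
        ),
        ambiguous=ambiguous,
        summit_in_feature=summit_in,
        shared_repeat_copies=shared,
    )


def collapse_to_unique(
    assignments: Sequence[FeatureAssignment],
) -> list[UniqueTarget]:
    """Collapse several regions falling in one RNA molecule to one target.

    Grouping is by assignment label (chosen locus, joined loci for
    ambiguous assignments, or the intergenic label); within a group the
    region with the highest PV is kept.  The operation is idempotent.
    """
    groups: dict[str, list[FeatureAssignment]] = {}
    for a in assignments:
        groups.setdefault(a.label, []).append(a)
    out = []
    for label, group in groups.items():
        best = max(group, key=lambda a: a.target.best_pv)
        out.append(
            UniqueTarget(
                locus_id=label,
                best=best.target,
                fe_per_rep=best.target.fe_per_rep,
                pv_per_rep=best.target.pv_per_rep,
                ambiguous=best.ambiguous,
                candidate_loci=best.chosen,
                n_collapsed=len(group),
            )
        )
    out.sort(key=lambda u: (u.best.replicon, u.best.start))
    return out
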