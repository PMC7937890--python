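"""Replicate-consensus filtering and distribution-based cut-off selection.

The analysis keeps only peaks reproduced in every technical replicate of a
pulldown, summarises the fold-enrichment (FE) and -10*log10(p) (PV) score
distributions of the consensus peaks, derives per-biological-replicate
lower confidence limits, turns those limits into one FE and one PV cut-off
per protein, and finally discards any target that misses either cut-off in
any biological replicate.

Two interpretations of "95% confidence interval of the distribution" are
supported for the per-replicate lower limit:

``t_mean``
    Classic t-based confidence interval for the mean of the per-replicate
    score distribution (lower limit = mean - t_{0.975, n-1} * s / sqrt(n)).
``percentile``
    Lower limit of the central (1 - alpha) mass of the observed
    distribution, taken at the largest observed value not exceeding the
    alpha/2 quantile (no interpolation beyond the data).

Given the limits, the cut-off rule is: FE cut-off = minimum across
replicates, rounded down to the nearest 0.05; PV cut-off = arithmetic mean
across replicates, rounded down to the nearest multiple of 5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import FormatError, Peak


@dataclass(frozen=True)
class ConsensusPeak:
    """A peak supported by one member from every technical replicate."""

    replicon: str
    start: int
    end: int
    summit: int
    fe: float
    pv: float
    members: tuple[Peak, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HistogramSummary:
    """Binned score distribution with cumulative percents.

    Bins follow the upper-limit convention: bin ``i`` holds values in
    ``(upper[i-1], upper[i]]`` with the first bin open below.
    """

    statistic: str  # "FE" or "PV"
    bin_upper_limits: tuple[float, ...]
    frequencies: tuple[int, ...]
    cumulative_percent: tuple[float, ...]


@dataclass(frozen=True)
class CutoffSet:
    """Per-protein cut-offs and the per-replicate limits they derive from."""

    protein: str
    fe_ci_limits: tuple[float, ...]
    pv_ci_limits: tuple[float, ...]
    fe_cutoff: float
    pv_cutoff: float


@dataclass(frozen=True)
class FilteredTarget:
    """A target present in every biological replicate and above both cut-offs."""

    replicon: str
    start: int
    end: int
    summit: int
    fe_per_rep: tuple[float, ...]
    pv_per_rep: tuple[float, ...]
    members: tuple[ConsensusPeak, ...]

    @property
    def best_pv(self) -> float:
        return max(self.pv_per_rep)


def _check_sorted_nonoverlapping(peaks: Sequence, label: str) -> None:
    for a, b in zip(peaks, peaks[1:]):
        if (a.replicon, a.start) > (b.replicon, b.start):
            raise ValueError(f"{label}: peak list is not coordinate-sorted")
        if a.replicon == b.replicon and a.end > b.start:
            raise ValueError(f"{label}: overlapping peaks within one replicate")


def _overlaps(a, b) -> bool:
    return a.replicon == b.replicon and a.start < b.end and b.start < a.end


def technical_consensus(
    peak_lists: Sequence[Sequence[Peak]],
    aggregate: Literal["mean", "median"] = "mean",
) -> list[ConsensusPeak]:
    """Keep regions reproduced in every technical replicate.

    A consensus peak is formed when a peak of the first replicate can be
    chained with exactly one unused peak from every other replicate such
    that all chosen members pairwise overlap by at least one nucleotide.
    Matching is greedy left-to-right; the consensus interval is the union of
    the members and FE/PV are their aggregate (mean by default).
    """
    if len(peak_lists) < 2:
        raise ValueError("need at least two technical replicates")
    for i, lst in enumerate(peak_lists):
        _check_sorted_nonoverlapping(lst, f"replicate {i + 1}")
    agg = np.mean if aggregate == "mean" else np.median
    used = [np.zeros(len(lst), dtype=bool) for lst in peak_lists]
    out: list[ConsensusPeak] = []
    for i0, anchor in enumerate(peak_lists[0]):
        members = [anchor]
        chosen_idx = [(0, i0)]
        ok = True
        for r in range(1, len(peak_lists)):
            found = None
            for j, cand in enumerate(peak_lists[r]):
                if used[r][j]:
                    continue
                if all(_overlaps(cand, m) for m in members):
                    found = j
                    break
                if cand.replicon == anchor.replicon and cand.start >= max(
                    m.end for m in members
                ):
                    break
            if found is None:
                ok = False
                break
            members.append(peak_lists[r][found])
            chosen_idx.append((r, found))
        if not ok:
            continue
        for r, j in chosen_idx:
            used[r][j] = True
        best = max(members, key=lambda p: p.pv_score)
        out.append(
            ConsensusPeak(
                replicon=anchor.replicon,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                summit=best.summit,
                fe=float(agg([m.fold_enrichment for m in members])),
                pv=float(agg([m.pv_score for m in members])),
                members=tuple(members),
            )
        )
    out.sort(key=lambda c: (c.replicon, c.start))
    return out


def default_bins(values: Sequence[float], n_bins: int = 20) -> tuple[float, ...]:
    """Equal-width upper limits covering the data, rounded to two decimals."""
    hi = float(max(values))
    lo = float(min(values))
    width = (hi - lo) / n_bins or 1.0
    uppers = [round(lo + width * (i + 1), 2) for i in range(n_bins)]
    uppers[-1] = max(uppers[-1], math.ceil(hi * 100.0) / 100.0)
    return tuple(uppers)


def score_distributions(
    peaks: Sequence[ConsensusPeak],
    fe_bins: Sequence[float] | None = None,
    pv_bins: Sequence[float] | None = None,
) -> tuple[HistogramSummary, HistogramSummary]:
    """Histograms of FE and PV with cumulative percents (upper-limit bins)."""
    if not peaks:
        raise ValueError("no peaks to summarise")
    out = []
    for label, values, bins in (
        ("FE", [p.fe for p in peaks], fe_bins),
        ("PV", [p.pv for p in peaks], pv_bins),
    ):
        uppers = tuple(bins) if bins is not None else default_bins(values)
        if max(values) > uppers[-1]:
            raise ValueError(
                f"{label}: value {max(values)} above last bin limit {uppers[-1]}"
            )
        freqs = [0] * len(uppers)
        for v in values:
            for i, u in enumerate(uppers):
                if v <= u:
                    freqs[i] += 1
                    break
        total = len(values)
        cum = tuple(round(100.0 * c / total, 4) for c in np.cumsum(freqs))
        out.append(
            HistogramSummary(
                statistic=label,
                bin_upper_limits=uppers,
                frequencies=tuple(freqs),
                cumulative_percent=cum,
            )
        )
    return out[0], out[1]


def ci_lower_limit(
    values: Sequence[float],
    alpha: float = 0.05,
    method: Literal["t_mean", "percentile"] = "t_mean",
) -> float:
    """Lower limit of the two-sided (1 - alpha) interval for a score sample.

    ``t_mean`` gives the textbook t-interval for the mean; ``percentile``
    gives the largest observed value not above the alpha/2 quantile of the
    empirical distribution (conservative, no interpolation past the data).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values")
    if method == "percentile":
        return float(np.percentile(vals, 100.0 * alpha / 2.0, method="lower"))
    if np.all(vals == vals[0]):
        return float(vals[0])  # zero variance: the common value itself
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    t = stats.t.ppf(1.0 - alpha / 2.0, vals.size - 1)
    return mean - t * sd / math.sqrt(vals.size)


def _floor_to(x: float, step: float) -> float:
    return round(math.floor(round(x / step, 9)) * step, 4)


def select_cutoffs(
    fe_ci_limits: Sequence[float],
    pv_ci_limits: Sequence[float],
    protein: str,
) -> CutoffSet:
    """Turn per-replicate lower confidence limits into one cut-off pair.

    FE cut-off: minimum across replicate limits, rounded down to the nearest
    multiple of 0.05.  PV cut-off: arithmetic mean across replicate limits,
    rounded down to the nearest multiple of 5.
    """
    if not fe_ci_limits or not pv_ci_limits:
        raise ValueError("need at least one replicate limit per statistic")
    fe_cut = _floor_to(min(fe_ci_limits), 0.05)
    pv_cut = _floor_to(float(np.mean(pv_ci_limits)), 5.0)
    if fe_cut > min(fe_ci_limits):
        raise AssertionError("FE cut-off exceeds the smallest replicate limit")
    return CutoffSet(
        protein=protein,
        fe_ci_limits=tuple(float(v) for v in fe_ci_limits),
        pv_ci_limits=tuple(float(v) for v in pv_ci_limits),
        fe_cutoff=fe_cut,
        pv_cutoff=max(0.0, pv_cut),
    )


def filter_targets(
    per_rep_consensus: Sequence[Sequence[ConsensusPeak]],
    cutoffs: CutoffSet,
) -> list[FilteredTarget]:
    """Keep targets present in every biological replicate and above cut-off.

    Biological replicates are matched by interval overlap (greedy
    left-to-right chains, one member per replicate, all pairwise
    overlapping).  A matched target survives only if FE >= fe_cutoff and
    PV > pv_cutoff in every replicate.
    """
    if not per_rep_consensus:
        raise ValueError("need at least one biological replicate table")
    reps = [sorted(lst, key=lambda c: (c.replicon, c.start)) for lst in per_rep_consensus]
    used = [np.zeros(len(lst), dtype=bool) for lst in reps]
    out: list[FilteredTarget] = []
    for i0, anchor in enumerate(reps[0]):
        members = [anchor]
        chosen = [(0, i0)]
        ok = True
        for r in range(1, len(reps)):
            found = None
            for j, cand in enumerate(reps[r]):
                if used[r][j]:
                    continue
                if all(_overlaps(cand, m) for m in members):
                    found = j
                    break
                if cand.replicon == anchor.replicon and cand.start >= max(
                    m.end for m in members
                ):
                    break
            if found is None:
                ok = False
                break
            members.append(reps[r][found])
            chosen.append((r, found))
        if not ok:
            continue
        for r, j in chosen:
            used[r][j] = True
        if any(m.fe < cutoffs.fe_cutoff or m.pv <= cutoffs.pv_cutoff for m in members):
            continue
        best = max(members, key=lambda c: c.pv)
        out.append(
            FilteredTarget(
                replicon=anchor.replicon,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                summit=best.summit,
                fe_per_rep=tuple(m.fe for m in members),
                pv_per_rep=tuple(m.pv for m in members),
                members=tuple(members),
            )
        )
    out.sort(key=lambda t: (t.replicon, t.start))
    return out


# ---------------------------------------------------------------------------
# Table / JSON serialisation
# ---------------------------------------------------------------------------

CONSENSUS_COLUMNS = ["replicon", "start", "end", "length", "summit", "fe", "pv"]


def write_consensus_table(
    peaks: Sequence[ConsensusPeak], path: str | Path
) -> None:
    rows = [
        {
            "replicon": c.replicon,
            "start": c.start,
            "end": c.end,
            "length": c.length,
            "summit": c.summit,
            "fe": round(c.fe, 4),
            "pv": round(c.pv, 4),
        }
        for c in peaks
    ]
    pd.DataFrame(rows, columns=CONSENSUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_consensus_table(path: str | Path) -> list[ConsensusPeak]:
    """Read a consensus table back; per-replicate member peaks are not
    serialised, so ``members`` is empty on round-trip."""
    df = pd.read_csv(path, sep="\t", dtype={"replicon": str})
    missing = [c for c in CONSENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing consensus columns {missing}")
    return [
        ConsensusPeak(
            replicon=r.replicon,
            start=int(r.start),
            end=int(r.end),
            summit=int(r.summit),
            fe=float(r.fe),
            pv=float(r.pv),
            members=(),
        )
        for r in df.itertuples(index=False)
    ]


def write_histogram_tsv(summary: HistogramSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_upper_limit": summary.bin_upper_limits,
            "frequency": summary.frequencies,
            "cumulative_percent": summary.cumulative_percent,
        }
    ).to_csv(path, sep="\t", index=False)


def cutoffs_to_dict(cutoffs: Sequence[CutoffSet]) -> dict:
    return {
        c.protein: {
            "fe_ci_limits": [round(v, 4) for v in c.fe_ci_limits],
            "pv_ci_limits": [round(v, 4) for v in c.pv_ci_limits],
            "fe_cutoff": c.fe_cutoff,
            "pv_cutoff": c.pv_cutoff,
        }
        for c in cutoffs
    }


def write_cutoffs_json(cutoffs: Sequence[CutoffSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cutoffs_to_dict(cutoffs), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cutoffs_json(path: str | Path) -> dict[str, CutoffSet]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        prot: CutoffSet(
            protein=prot,
            fe_ci_limits=tuple(d["fe_ci_limits"]),
            pv_ci_limits=tuple(d["pv_ci_limits"]),
            fe_cutoff=d["fe_cutoff"],
            pv_cutoff=d["pv_cutoff"],
        )
        for prot, d in raw.items()
    }
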