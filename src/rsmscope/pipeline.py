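"""End-to-end orchestration: simulate (or load) -> call peaks per technical
replicate -> technical consensus per biological replicate -> distribution
summaries and cut-off selection -> cross-replicate filtering -> target
annotation -> regulon comparison and (for simulated data) recovery scoring.

Every artifact is written under one output directory and listed, with a
SHA-256 content hash, in ``manifest.json``; identical configuration and
seed reproduce identical hashes.  Each stage logs the counts and thresholds
it produced, mirroring the per-stage audit trail of a bench notebook.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

from . import annotate as _annotate
from . import compare as _compare
from . import consensus as _consensus
from . import peakcall as _peakcall
from . import synthio as _synthio
from .formats import (
    GenomeAnnotation,
    TagLibrary,
    load_annotation,
    load_tag_library,
    write_annotation,
    write_peak_table,
)

logger = logging.getLogger("rsmscope")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending sample."""


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration object for the whole cascade.

    Exactly one of ``simulation`` (a :class:`~rsmscope.synthio.SimulationConfig`)
    or ``inputs`` (path to a JSON manifest naming a GFF3 annotation and the
    per-sample BED files with their protein/role/replicate metadata) must be
    given.
    """

    out_dir: str
    simulation: Optional[_synthio.SimulationConfig] = None
    inputs: Optional[str] = None
    peak_params: _peakcall.PeakCallParams = field(
        default_factory=_peakcall.PeakCallParams
    )
    ci_alpha: float = 0.05
    ci_method: Literal["t_mean", "percentile"] = "percentile"
    aggregate: Literal["mean", "median"] = "mean"
    summit_override: bool = True
    write_tag_beds: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of simulation config or input manifest is required"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(manifest_path: str) -> tuple[GenomeAnnotation, list[TagLibrary]]:
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = Path(manifest_path).parent
    annotation = load_annotation(base / manifest["annotation"])
    libs = []
    for s in manifest["samples"]:
        libs.append(
            load_tag_library(
                base / s["bed"],
                sample_id=s["sample_id"],
                protein=s["protein"],
                role=s["role"],
                bio_rep=int(s["bio_rep"]),
                tech_rep=int(s.get("tech_rep", 1)),
                replicons=annotation.replicon_lengths,
            )
        )
    return annotation, libs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def save(path: Path) -> None:
        artifacts.append(path)

    # ----- stage: inputs -------------------------------------------------
    truth: Optional[_synthio.SyntheticTruth] = None
    if config.simulation is not None:
        sim = config.simulation
        try:
            annotation = _synthio.generate_genome_annotation(sim, config.seed)
            truth = _synthio.plant_targets(annotation, sim, config.seed)
            libraries = _synthio.simulate_tag_libraries(
                annotation, truth, sim, config.seed
            )
        except Exception as exc:
            raise PipelineError(f"stage simulate: {exc}") from exc
        write_annotation(annotation, out / "annotation.gff3")
        save(out / "annotation.gff3")
        _write_truth(truth, out / "truth.tsv")
        save(out / "truth.tsv")
        if config.write_tag_beds:
            from .formats import write_tag_library

            for lib in libraries:
                p = out / f"{lib.sample_id}.bed"
                write_tag_library(lib, p)
                save(p)
    else:
        try:
            annotation, libraries = _load_inputs(config.inputs)
        except Exception as exc:
            raise PipelineError(f"stage load: {exc}") from exc

    proteins = sorted({l.protein for l in libraries if l.role == "pulldown"})
    by_key: dict[tuple[str, int, str, int], TagLibrary] = {
        (l.protein, l.bio_rep, l.role, l.tech_rep): l for l in libraries
    }

    cutoff_sets: list[_consensus.CutoffSet] = []
    all_unique: dict[str, list[_annotate.UniqueTarget]] = {}
    counts_log: dict[str, dict] = {}

    for protein in proteins:
        bio_reps = sorted({l.bio_rep for l in libraries if l.protein == protein})
        per_bio_consensus: list[list[_consensus.ConsensusPeak]] = []
        fe_limits: list[float] = []
        pv_limits: list[float] = []
        protein_counts: dict[str, dict] = {}
        for bio in bio_reps:
            control = by_key.get((protein, bio, "total_control", 1))
            if control is None:
                raise PipelineError(
                    f"stage consensus: no total_control for {protein} bio_rep {bio}"
                )
            tech_reps = sorted(
                t for (p, b, role, t) in by_key if (p, b, role) == (protein, bio, "pulldown")
            )
            peak_lists = []
            for tech in tech_reps:
                treatment = by_key[(protein, bio, "pulldown", tech)]
                try:
                    peaks = _peakcall.call_peaks(treatment, control, config.peak_params)
                except Exception as exc:
                    raise PipelineError(
                        f"stage callpeaks: sample {treatment.sample_id}: {exc}"
                    ) from exc
                path = out / f"{protein}_b{bio}_t{tech}_peaks.tsv"
                write_peak_table(peaks, path)
                save(path)
                peak_lists.append(peaks)
                logger.info(
                    "%s bio %d tech %d: %d peaks", protein, bio, tech, len(peaks)
                )
            cons = (
                _consensus.technical_consensus(peak_lists, config.aggregate)
                if len(peak_lists) >= 2
                else []
            )
            path = out / f"{protein}_b{bio}_consensus.tsv"
            _consensus.write_consensus_table(cons, path)
            save(path)
            protein_counts[f"bio_{bio}"] = {
                "peaks_per_tech": [len(p) for p in peak_lists],
                "consensus": len(cons),
            }
            per_bio_consensus.append(cons)
            if len(cons) >= 2:
                fe_hist, pv_hist = _consensus.score_distributions(cons)
                _consensus.write_histogram_tsv(
                    fe_hist, out / f"{protein}_b{bio}_fe_hist.tsv"
                )
                _consensus.write_histogram_tsv(
                    pv_hist, out / f"{protein}_b{bio}_pv_hist.tsv"
                )
                save(out / f"{protein}_b{bio}_fe_hist.tsv")
                save(out / f"{protein}_b{bio}_pv_hist.tsv")
            # the confidence limits are computed per technical replicate on
            # the raw peak-score distributions (which include the
            # irreproducible single-extraction peaks that the consensus
            # removes) and summarised per biological replicate by their mean
            if all(len(pl) >= 2 for pl in peak_lists) and peak_lists:
                fe_limits.append(
                    float(
                        sum(
                            _consensus.ci_lower_limit(
                                [p.fold_enrichment for p in pl],
                                config.ci_alpha,
                                config.ci_method,
                            )
                            for pl in peak_lists
                        )
                        / len(peak_lists)
                    )
                )
                pv_limits.append(
                    float(
                        sum(
                            _consensus.ci_lower_limit(
                                [p.pv_score for p in pl],
                                config.ci_alpha,
                                config.ci_method,
                            )
                            for pl in peak_lists
                        )
                        / len(peak_lists)
                    )
                )

        if fe_limits and len(fe_limits) == len(bio_reps):
            cutoffs = _consensus.select_cutoffs(fe_limits, pv_limits, protein)
            logger.info(
                "%s cut-offs: FE >= %.2f, PV > %.0f",
                protein,
                cutoffs.fe_cutoff,
                cutoffs.pv_cutoff,
            )
            surviving = _consensus.filter_targets(per_bio_consensus, cutoffs)
        else:
            # a replicate yielded too few consensus peaks to summarise a
            # distribution; nothing can clear the replicate-presence rule
            cutoffs = None
            surviving = []
            logger.info("%s: insufficient consensus peaks, no targets", protein)
        if cutoffs is not None:
            cutoff_sets.append(cutoffs)
        assignments = [
            _annotate.assign_feature(t, annotation, config.summit_override)
            for t in surviving
        ]
        unique = _annotate.collapse_to_unique(assignments)
        all_unique[protein] = unique
        protein_counts["surviving_targets"] = len(surviving)
        protein_counts["unique_targets"] = len(unique)
        counts_log[protein] = protein_counts
        path = out / f"{protein}_unique_targets.tsv"
        _write_unique_targets(unique, path)
        save(path)

    _consensus.write_cutoffs_json(cutoff_sets, out / "cutoffs.json")
    save(out / "cutoffs.json")

    # ----- stage: compare ------------------------------------------------
    target_sets = {
        p: {u.locus_id for u in targets} for p, targets in all_unique.items()
    }
    venn = _compare.venn_partition(target_sets)
    venn_dict = {
        "set_sizes": venn.set_sizes,
        "class_counts": {"&".join(cls): n for cls, n in venn.class_counts.items()},
        "union_size": venn.union_size,
        "exclusive_percent": venn.exclusive_fractions,
    }
    with open(out / "venn.json", "w") as fh:
        json.dump(venn_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    save(out / "venn.json")

    if truth is not None:
        report = _compare.recovery_metrics(
            all_unique, {p: set(s) for p, s in truth.target_sets.items()}
        )
        with open(out / "recovery.json", "w") as fh:
            json.dump(report.per_protein, fh, indent=2, sort_keys=True)
            fh.write("\n")
        save(out / "recovery.json")

    manifest = {
        "seed": config.seed,
        "counts": counts_log,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_truth(truth: _synthio.SyntheticTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tvenn_class\tprotein\tenrichment\n")
        for locus in sorted(truth.venn_class):
            cls = "&".join(truth.venn_class[locus])
            for protein in truth.venn_class[locus]:
                fh.write(
                    f"{locus}\t{cls}\t{protein}\t"
                    f"{truth.enrichment[(protein, locus)]:.4f}\n"
                )


def read_truth(path: str | Path) -> dict[str, set[str]]:
    """Planted per-protein locus sets from a truth TSV."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            locus, _cls, protein, _f = line.rstrip("\n").split("\t")
            sets.setdefault(protein, set()).add(locus)
    return sets


def _write_unique_targets(
    targets: Sequence[_annotate.UniqueTarget], path: Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus\tlabel\treplicon\tstart\tend\tsummit\t"
            "fe_per_rep\tpv_per_rep\tambiguity\tn_collapsed\n"
        )
        for u in targets:
            fh.write(
                "\t".join(
                    [
                        u.locus_id,
                        "|".join(u.candidate_loci) or u.locus_id,
                        u.best.replicon,
                        str(u.best.start),
                        str(u.best.end),
                        str(u.best.summit),
                        ",".join(f"{v:.4f}" for v in u.fe_per_rep),
                        ",".join(f"{v:.4f}" for v in u.pv_per_rep),
                        "ambiguous" if u.ambiguous else "unique",
                        str(u.n_collapsed),
                    ]
                )
                + "\n"
            )
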