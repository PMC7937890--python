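"""Published summary values for the P. putida KT2440 Rsm RAP-Seq study.

These constants transcribe the per-biological-replicate 95% confidence
lower limits, the established cut-offs, and the regulon set sizes reported
for the RsmA/RsmE/RsmI pulldown experiment in P. putida KT2440.  They are
inputs for consistency checks (the cut-off selection rule must reproduce
the published cut-offs from the published limits) and for the full-scale
Venn design in :mod:`rsmscope.synthio`; nothing in the pipeline itself
depends on them.

One RsmA and one RsmI biological replicate failed quality control in the
study, so RsmE carries three limits per statistic while RsmI carries two
(from its first and third cultures).
"""

#: per-protein, per-retained-replicate 95% CI lower limits of the
#: fold-enrichment (fe) and -10*log10(p) score (pv) distributions
REFERENCE_CI_LIMITS: dict[str, dict[str, tuple[float, ...]]] = {
    "RsmA": {"fe": (2.15, 2.33, 2.33), "pv": (130.0, 135.0, 128.0)},
    "RsmE": {"fe": (4.0, 4.22, 4.62), "pv": (180.0, 150.0, 181.0)},
    "RsmI": {"fe": (2.68, 2.53), "pv": (153.0, 137.0)},
}

#: the cut-offs established in the study: FE >= fe, PV > pv
REFERENCE_CUTOFFS: dict[str, dict[str, float]] = {
    "RsmA": {"fe": 2.15, "pv": 130.0},
    "RsmE": {"fe": 4.0, "pv": 170.0},
    "RsmI": {"fe": 2.5, "pv": 145.0},
}

#: unique RNA targets per protein after cut-off filtering and redundancy
#: collapse, the triple-shared count and the union of unique transcripts
REFERENCE_SET_SIZES: dict[str, int] = {"RsmA": 241, "RsmE": 261, "RsmI": 206}
REFERENCE_TRIPLE_SHARED = 75
REFERENCE_UNION = 437
#: each pairwise-exclusive Venn class lies in this closed range
REFERENCE_PAIRWISE_RANGE = (36, 45)

#: per-replicate FE values reported for the cfcR transcript in the RsmA
#: pulldown -- enriched, but below the RsmA fold-enrichment cut-off
CFCR_RSMA_FE = (1.82, 1.88)
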