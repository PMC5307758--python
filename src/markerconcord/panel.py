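"""The six-gene RT-qPCR panel and its marker/assay vocabulary.

Four target transcripts (ESR1, PGR, MKI67, ERBB2) are quantified relative
to two reference genes (B2M, CALM2) that are stably expressed in breast
tissue.  Three of the targets have a protein-level counterpart scored by
immunohistochemistry: the estrogen receptor (ER), the progesterone
receptor (PR) and the proliferation antigen Ki-67.
"""

from __future__ import annotations

TARGET_GENES: tuple[str, ...] = ("ESR1", "PGR", "MKI67", "ERBB2")
REF_GENES: tuple[str, ...] = ("B2M", "CALM2")
GENE_PANEL: tuple[str, ...] = TARGET_GENES + REF_GENES

#: IHC markers and the transcript each one reports on.
MARKERS: tuple[str, ...] = ("ER", "PR", "Ki67")
MARKER_GENE: dict[str, str] = {"ER": "ESR1", "PR": "PGR", "Ki67": "MKI67"}

#: Measurement routes compared by the study design.
ASSAY_RTQPCR = "rt_qpcr"   # 40-ddCq mRNA expression
ASSAY_QIHC = "qihc"        # digital image analysis of IHC slides
ASSAY_VIHC = "vihc"        # conventional visual IHC scoring
ASSAYS: tuple[str, ...] = (ASSAY_RTQPCR, ASSAY_QIHC, ASSAY_VIHC)
IHC_METHODS: tuple[str, ...] = ("visual", "digital")
METHOD_ASSAY: dict[str, str] = {"visual": ASSAY_VIHC, "digital": ASSAY_QIHC}

#: Reserved sample identifier for per-run calibrator wells.
CALIBRATOR_ID = "CALIBRATOR"

#: Number of amplification cycles; Cq values live in (0, CYCLE_CEILING].
CYCLE_CEILING = 40.0
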