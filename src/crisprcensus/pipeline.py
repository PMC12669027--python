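"""End-to-end convenience: hit tables -> annotated proteins -> classified loci."""

from __future__ import annotations

import pandas as pd

from .annotation import ProfileMap, annotate_proteins
from .io import PipelineConfig
from .locus import (CrisprArray, Locus, LocusClassification, assemble_neighborhoods,
                    classify_all, locus_report, trim_boundaries)
from .registry import Registry


def classify_genomes(genes: pd.DataFrame, hits: pd.DataFrame,
                     arrays: list[CrisprArray], registry: Registry,
                     config: PipelineConfig | None = None,
                     profile_map: ProfileMap | None = None
                     ) -> tuple[list[Locus], list[LocusClassification], pd.DataFrame]:
    """Annotate, assemble, trim and classify every CRISPR-cas locus.

    Returns (loci, classifications, report table).
    """
    cfg = config or PipelineConfig()
    pmap = profile_map or ProfileMap.from_registry(registry)
    annotations = annotate_proteins(hits, genes, evalue_max=cfg.evalue_max,
                                    overlap_tolerance=cfg.overlap_tolerance)
    loci = assemble_neighborhoods(genes, annotations, arrays, registry, pmap,
                                  flank=cfg.flank_genes)
    loci = [trim_boundaries(l, genes, pmap) for l in loci]
    classifications = classify_all(loci, registry, pmap)
    return loci, classifications, locus_report(loci, classifications)
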