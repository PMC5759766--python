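"""End-to-end orchestration: normalization -> contrasts -> DEG selection ->
classification -> class-spectrum summary -> enrichment -> qPCR validation.

Outputs are written under ``config.out_dir`` with fixed filenames:
``contrasts_*.tsv``, ``gene_action_calls.tsv``, ``triad_summary.json``,
``enrichment_<class>.tsv``, ``qpcr_validation.tsv``, ``concordance.tsv``
and ``manifest.json``.  The run is deterministic given the inputs and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import classify, de, enrichment, qpcr
from .errors import TriadExprError
from .io import PipelineConfig, read_count_matrix, read_design, write_manifest

logger = logging.getLogger(__name__)

CONTRAST_FILES = {"p12": "contrasts_p2_vs_p1.tsv",
                  "hp1": "contrasts_hybrid_vs_p1.tsv",
                  "hp2": "contrasts_hybrid_vs_p2.tsv",
                  "mid": "contrasts_hybrid_vs_midparent.tsv"}


class _Stage:
    """Context manager labelling failures with the stage that caused them."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, TriadExprError):
            raise TriadExprError(f"stage {self.name!r} failed: {exc}") from exc
        if isinstance(exc, TriadExprError):
            raise TriadExprError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full triad analysis described by ``config``.

    Returns a result bundle: contrasts, calls, summary, enrichment tables
    and qPCR validation results (where inputs were provided).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    inputs = {"counts": config.counts, "design": config.design}

    with _Stage("read"):
        counts = read_count_matrix(config.counts)
        design = read_design(config.design)

    with _Stage("normalize"):
        factors = de.estimate_size_factors(counts)
        dispersions = de.estimate_dispersion(
            counts, design, factors, shrink_weight=config.shrink_weight)

    with _Stage("contrasts"):
        contrasts = classify.triad_contrasts(
            counts, design, factors, dispersions,
            alpha=config.alpha_de, pseudocount=config.pseudocount)
        for key, cdf in contrasts.items():
            cdf.to_csv(out_dir / CONTRAST_FILES[key], sep="\t")
        bundle["contrasts"] = contrasts

    with _Stage("classify"):
        calls = classify.classify_gene_action(
            contrasts["p12"], contrasts["hp1"], contrasts["hp2"],
            contrasts["mid"] if config.midparent_test else None,
            require_midparent_test=config.midparent_test)
        calls.to_csv(out_dir / "gene_action_calls.tsv", sep="\t")
        summary = classify.summarize_classes(calls)
        with open(out_dir / "triad_summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        bundle["calls"] = calls
        bundle["summary"] = summary

    if config.annotation:
        with _Stage("enrich"):
            inputs["annotation"] = config.annotation
            ann = enrichment.AnnotationMap.from_tsv(config.annotation)
            bundle["enrichment"] = {}
            for klass in classify.CLASS_LABELS:
                genes = calls.index[calls["class"] == klass]
                if len(genes) == 0:
                    continue
                table = enrichment.enrich_terms(
                    genes, ann, alpha=config.alpha_enrich,
                    min_term_size=config.min_term_size)
                table.to_csv(out_dir / f"enrichment_{klass}.tsv", sep="\t",
                             index=False)
                bundle["enrichment"][klass] = table

    if config.qpcr:
        with _Stage("qpcr"):
            inputs["qpcr"] = config.qpcr
            triads = qpcr.triads_from_long(config.qpcr)
            table = qpcr.validation_table(triads, alpha=config.alpha_qpcr)
            table.to_csv(out_dir / "qpcr_validation.tsv", sep="\t")
            bundle["qpcr"] = table
            shared = set(table.index) & set(calls.index)
            if shared:
                conc = qpcr.concordance(calls, dict(table["class"]))
                conc.to_csv(out_dir / "concordance.tsv", sep="\t")
                bundle["concordance"] = conc

    with _Stage("manifest"):
        bundle["manifest"] = write_manifest(
            config, out_dir / "manifest.json", inputs)
    return bundle
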