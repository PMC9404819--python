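"""End-to-end orchestration of the locus analysis stages.

``run_pipeline`` wires the stages together — window extraction, variant
catalog, coding effects, windowed neutrality statistics, differential TFBS,
splice-element diffing — and writes TSV reports plus a machine-readable
summary JSON.  Any stage failure aborts with the stage name; outputs written
before the failure are marked partial in the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .coding_effects import (
    codon_context,
    load_codon_usage,
    rarity_call,
    rarity_transition,
)
from .errors import LocusKitError, OutsideRegionError, UnsupportedVariantError
from .locus_model import build_window, load_gene_model
from .popgen import allele_frequency, sliding_windows, zygosity_audit
from .regulatory_diff import differential_tfbs, load_pwms, promoter_interval
from .splice_kit import diff_splice_elements, load_motif_sets, load_splice_matrices
from .variant_catalog import (
    catalog_table,
    classify_variant,
    read_variants,
    summarize_catalog,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("catalog", "coding", "popgen", "tfbs", "splice")


class StageError(LocusKitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Output bundle of one run: report tables, summary dict, run log."""

    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    log: dict[str, Any] = field(default_factory=dict)


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> PipelineResult:
    """Run the requested stages on the inputs named in *config*.

    Required config keys: ``fasta``, ``gff3``, ``vcf``, ``gene_id``.
    Optional: ``flank`` (5000), ``stages`` (all), ``tajima_window`` (2000),
    ``promoter_span`` (2000), ``tfbs_threshold`` (0.85), ``pwm_file``,
    ``splice_matrix_file``, ``motif_set_file``, ``codon_usage_file``,
    ``codon_rarity_threshold`` (10 per-mille).
    """
    stages = tuple(config.get("stages", ALL_STAGES))
    flank = int(config.get("flank", 5000))

    result = PipelineResult(summary={}, log={
        "locuskit_version": __version__,
        "stages": list(stages),
        "inputs": {k: str(config[k]) for k in ("fasta", "gff3", "vcf") if k in config},
        "matrix_pack_checksums": {
            "pwm_file": _checksum(config.get("pwm_file")),
            "splice_matrix_file": _checksum(config.get("splice_matrix_file")),
            "motif_set_file": _checksum(config.get("motif_set_file")),
        },
        "completed": [],
    })

    def run_stage(name, fn):
        try:
            fn()
        except Exception as exc:
            result.log["partial"] = True
            raise StageError(name, exc) from exc
        result.log["completed"].append(name)

    gene = load_gene_model(str(config["gff3"]), config["gene_id"])
    window = build_window(str(config["fasta"]), gene, flank=flank)
    variants = read_variants(str(config["vcf"]), window)
    result.summary["window"] = {
        "chrom": window.chrom, "start": window.start, "end": window.end,
        "length": window.length, "gene_length": gene.gene_length, "flank": flank,
    }
    result.summary["n_variants"] = len(variants)

    if "catalog" in stages:
        def _catalog():
            cat = summarize_catalog(variants, gene, window)
            result.tables["catalog"] = catalog_table(variants, gene, window)
            result.summary["catalog"] = {
                "total": cat.total,
                "n_snps": cat.n_snps,
                "n_indels": cat.n_indels,
                "by_vclass": cat.by_vclass,
                "by_localization": cat.by_localization,
                "snp_density_denominator": cat.snp_density_denominator,
            }
        run_stage("catalog", _catalog)

    if "coding" in stages:
        def _coding():
            usage = load_codon_usage(config.get("codon_usage_file"))
            thr = float(config.get("codon_rarity_threshold", 10.0))
            rows, tally = [], {}
            for v in variants:
                loc = classify_variant(v, gene, window)
                if not loc.is_exonic:
                    continue
                try:
                    ctx = codon_context(v, gene, window)
                except (UnsupportedVariantError, OutsideRegionError) as exc:
                    rows.append({"vid": v.vid, "note": str(exc)})
                    continue
                tally[ctx.effect] = tally.get(ctx.effect, 0) + 1
                rows.append({
                    "vid": v.vid,
                    "codon_index": ctx.codon_index,
                    "codon_pos": ctx.codon_pos,
                    "ref_codon": ctx.ref_codon,
                    "alt_codon": ctx.alt_codon,
                    "ref_aa": ctx.ref_aa,
                    "alt_aa": ctx.alt_aa,
                    "effect": ctx.effect,
                    "ref_rarity": rarity_call(ctx.ref_codon, usage, thr).status,
                    "alt_rarity": rarity_call(ctx.alt_codon, usage, thr).status,
                    "rarity_transition": rarity_transition(ctx, usage, thr),
                })
            result.tables["coding"] = pd.DataFrame(rows)
            result.summary["coding"] = {"effects": tally}
        run_stage("coding", _coding)

    if "popgen" in stages:
        def _popgen():
            win = int(config.get("tajima_window", 2000))
            tiles = sliding_windows(variants, window=win)
            result.tables["tajima"] = pd.DataFrame(
                [{"chrom": t.chrom, "start": t.win_start, "end": t.win_end,
                  "S": t.S, "pi": t.pi, "D": t.D, "call": t.call} for t in tiles]
            )
            audits = [zygosity_audit(v) for v in variants]
            result.tables["zygosity"] = pd.DataFrame(
                [{"vid": a.vid, "carriers": a.carriers, "het": a.het,
                  "hom_alt": a.hom_alt, "all_het": a.all_het} for a in audits]
            )
            result.summary["popgen"] = {
                "tajima_window": win,
                "n_tiles": len(tiles),
                "calls": {c: sum(1 for t in tiles if t.call == c)
                          for c in ("balancing", "directional", "neutral", "undefined")},
                "n_all_het": sum(1 for a in audits if a.all_het),
            }
        run_stage("popgen", _popgen)

    if "tfbs" in stages:
        def _tfbs():
            pwms = load_pwms(config.get("pwm_file"))
            span = int(config.get("promoter_span", 2000))
            thr = float(config.get("tfbs_threshold", 0.85))
            lo, hi = promoter_interval(window, span)
            rows, total = [], 0
            for v in variants:
                off = window.to_gene_sense(v.effective_pos)
                if not lo <= off <= hi:
                    continue
                rep = differential_tfbs(window, v, pwms, span, thr)
                total += rep.n_differential
                for kind, hits in (("gained", rep.gained), ("lost", rep.lost)):
                    for h in hits:
                        rows.append({
                            "vid": v.vid, "matrix": h.matrix_id, "tf": h.tf_name,
                            "event": kind, "score": h.score, "strand": h.strand,
                            "muscle": h.muscle_flag,
                        })
            df = pd.DataFrame(rows)
            result.tables["tfbs"] = df
            result.summary["tfbs"] = {
                "n_differential": total,
                "n_unique_matrices": int(df["matrix"].nunique()) if len(df) else 0,
                "n_muscle": int(df["muscle"].sum()) if len(df) else 0,
            }
        run_stage("tfbs", _tfbs)

    if "splice" in stages:
        def _splice():
            matrices = load_splice_matrices(config.get("splice_matrix_file"))
            motif_sets = load_motif_sets(config.get("motif_set_file"))
            rows = []
            for v in variants:
                loc = classify_variant(v, gene, window)
                if not loc.is_genic:
                    continue
                for d in diff_splice_elements(window, v, matrices, motif_sets):
                    rows.append({
                        "vid": d.vid, "category": d.category, "event": d.event,
                        "motif": d.motif, "value": d.value, "allele": d.allele,
                    })
            df = pd.DataFrame(rows)
            result.tables["splice"] = df
            result.summary["splice"] = {
                "n_events": len(df),
                "by_category": df["category"].value_counts().to_dict() if len(df) else {},
            }
        run_stage("splice", _splice)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(result.summary, indent=1, sort_keys=True) + "\n"
        )
        (out / "run_log.json").write_text(
            json.dumps(result.log, indent=1, sort_keys=True) + "\n"
        )
    return result
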