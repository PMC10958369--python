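"""End-to-end comparative workflow over a set of annotated mitogenomes.

``run_compare`` wires the stages in their natural order — composition
and skew, codon usage (RSCU) and amino-acid frequencies, per-gene K2P
distances with summaries, the Nei–Gojobori Ka/Ks screen, sliding-window
nucleotide diversity, synteny and junction accounting, and the PCG
supermatrix with an NJ sanity tree — writing one TSV per stage plus a
machine-readable JSON summary of the headline numbers. Stage failures
are isolated: the bundle records which stages completed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codons import aa_frequencies, codon_counts, rscu_fraction_above
from .composition import composition, positional_skew, skew
from .distances import per_gene_k2p, summarize_k2p
from .diversity import gene_order, compare_orders, junction_table, sliding_pi, windows_to_frame
from .genbank_io import (
    DEFAULT_CODE,
    GeneticCode,
    MitoGenome,
    PCG_NAMES,
    write_tsv,
)
from .alignment import progressive_align
from .selection import selection_screen
from .supermatrix import build_supermatrix, export_for_inference, supermatrix_nj
from .trees import is_monophyletic

logger = logging.getLogger("mitocompare")

__all__ = ["RunConfig", "run_compare"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str | Path = "mitocompare_out"
    genetic_code: int = 5
    window: int = 200
    step: int = 20
    rscu_threshold: float = 1.0
    min_span_reads: int = 5
    gap_open: float = 10.0
    gap_extend: float = 1.0
    scheme: str = "PCG123"
    monophyly_taxa: tuple[str, ...] = ()
    seed: int = 0

    def provenance(self) -> dict:
        d = {k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
             for k, v in asdict(self).items()}
        d["package_version"] = __version__
        # the hash covers analysis parameters, not the output location
        hashed = {k: v for k, v in d.items() if k != "out_dir"}
        blob = json.dumps(hashed, sort_keys=True).encode()
        d["config_hash"] = hashlib.sha256(blob).hexdigest()[:12]
        return d


def _fmt(x: float | None, digits: int = 6) -> float | None:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), digits)


def run_compare(
    genomes: Sequence[MitoGenome], config: RunConfig = RunConfig()
) -> dict:
    """Run the full comparative pipeline; returns the summary dict.

    With a single genome the comparative stages (K2P, Ka/Ks, diversity,
    supermatrix) are skipped with an explicit notice; per-genome stages
    still run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = GeneticCode.from_table(config.genetic_code)
    prov = config.provenance()
    (out / "run_config.json").write_text(json.dumps(prov, indent=2) + "\n")
    comparative = len(genomes) >= 2
    completed: list[str] = []
    failed: dict[str, str] = {}
    summary: dict = {
        "package_version": __version__,
        "config_hash": prov["config_hash"],
        "n_genomes": len(genomes),
        "genomes": {},
        "notices": [] if comparative else
        ["single genome: comparative stages skipped"],
    }

    def stage(name: str):
        def deco(fn):
            t0 = time.monotonic()
            try:
                fn()
                completed.append(name)
                logger.info("stage %s done in %.2fs", name, time.monotonic() - t0)
            except Exception as exc:  # noqa: BLE001 - stage isolation
                failed[name] = f"{type(exc).__name__}: {exc}"
                logger.error("stage %s failed: %s", name, exc)
            return fn
        return deco

    @stage("composition_skew")
    def _composition() -> None:
        rows = []
        for g in genomes:
            comp = composition(g.sequence)
            sk = skew(g.sequence)
            summary["genomes"][g.id] = {
                "taxon": g.source_taxon,
                "length_bp": g.length,
                "at_content": _fmt(comp.at_content),
                "at_percent": f"{100 * comp.at_content:.1f}" if comp.at_content is not None else None,
                "n_features": len(g.features),
            }
            rows.append(
                {
                    "accession": g.id, "taxon": g.source_taxon,
                    "length": g.length,
                    **{f"frac_{b}": comp.fractions.get(b) for b in "ACGT"},
                    "at_content": comp.at_content,
                    "at_skew": sk.at_skew, "gc_skew": sk.gc_skew,
                }
            )
        write_tsv(pd.DataFrame(rows), out / "composition.tsv")
        write_tsv(positional_skew(genomes, code=code), out / "skew_by_position.tsv")

    @stage("codon_usage")
    def _codons() -> None:
        frames = []
        rscu_summary = {}
        for g in genomes:
            table = codon_counts(g, code)
            frame = table.as_frame()
            frame.insert(0, "accession", g.id)
            frames.append(frame)
            frac = rscu_fraction_above(table, config.rscu_threshold)
            rscu_summary[g.id] = {
                "fraction_above": _fmt(frac.fraction),
                "numerator": frac.numerator,
                "denominator": frac.denominator,
            }
        write_tsv(pd.concat(frames, ignore_index=True), out / "rscu.tsv")
        write_tsv(aa_frequencies(genomes, code), out / "aa_frequencies.tsv")
        summary["rscu_fraction_above_1"] = rscu_summary

    if comparative:
        @stage("k2p_distances")
        def _k2p() -> None:
            table = per_gene_k2p(genomes, PCG_NAMES, code=code)
            write_tsv(table, out / "k2p.tsv")
            s = summarize_k2p(table)
            write_tsv(s["per_gene"], out / "k2p_per_gene.tsv")
            summary["k2p"] = {
                "mean": _fmt(s["mean"]),
                "mean_percent": f"{100 * s['mean']:.1f}",
                "min": {**s["min"], "value": _fmt(s["min"]["value"])},
                "max": {**s["max"], "value": _fmt(s["max"]["value"])},
                "n_undefined": s["n_undefined"],
            }

        @stage("kaks_screen")
        def _kaks() -> None:
            pairwise, per_gene = selection_screen(genomes, PCG_NAMES, code=code)
            write_tsv(pairwise, out / "kaks_pairwise.tsv")
            write_tsv(per_gene, out / "kaks_per_gene.tsv")
            summary["purifying_genes"] = sorted(
                per_gene.loc[per_gene["classification"] == "purifying", "gene"]
            )
            summary["non_purifying_genes"] = sorted(
                per_gene.loc[per_gene["classification"] != "purifying", "gene"]
            )

        @stage("sliding_pi")
        def _pi() -> None:
            aligned = _pcg_concat_alignment(genomes, code)
            windows = sliding_pi(aligned, config.window, config.step)
            write_tsv(windows_to_frame(windows), out / "pi_windows.tsv")
            defined = [w.pi for w in windows if w.pi is not None]
            summary["pi"] = {
                "n_windows": len(windows),
                "mean": _fmt(float(np.mean(defined)) if defined else None),
                "max": _fmt(max(defined) if defined else None),
            }

        @stage("synteny")
        def _synteny() -> None:
            tables = []
            for g in genomes:
                jt = junction_table(g)
                jt.insert(0, "accession", g.id)
                tables.append(jt)
            write_tsv(pd.concat(tables, ignore_index=True), out / "junctions.tsv")
            ref = gene_order(genomes[0])
            orders = {
                g.id: compare_orders(ref, gene_order(g)) for g in genomes[1:]
            }
            summary["synteny"] = {
                "reference": genomes[0].id,
                "identical_order": {k: v["identical"] for k, v in orders.items()},
                "breakpoints": {k: v["breakpoint_count"] for k, v in orders.items()},
            }

        if len(genomes) >= 3:
            @stage("supermatrix")
            def _supermatrix() -> None:
                matrix = build_supermatrix(genomes, config.scheme, code=code)
                export_for_inference(matrix, out / "supermatrix")
                tree = supermatrix_nj(matrix)
                (out / "nj_tree.nwk").write_text(tree.newick() + "\n")
                summary["nj_tree"] = tree.newick()
                if config.monophyly_taxa:
                    summary["monophyly"] = {
                        ",".join(config.monophyly_taxa): is_monophyletic(
                            tree, config.monophyly_taxa
                        )
                    }
        else:
            summary["notices"].append("fewer than 3 genomes: supermatrix skipped")

    summary["stages_completed"] = completed
    summary["stages_failed"] = failed
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def _pcg_concat_alignment(genomes: Sequence[MitoGenome], code: GeneticCode):
    """Per-gene codon-aware alignments concatenated in canonical order.

    This is the alignable comparative backbone the sliding-Pi stage runs
    on: whole-mitogenome alignment would founder on the control region,
    and the PCG concatenation is what dominates published Pi profiles.
    Genes absent from any genome are skipped with a warning.
    """
    from .alignment import MultipleAlignment
    from .genbank_io import gene_sequences

    ids = [g.id for g in genomes]
    blocks: list[dict[str, str]] = []
    for gene in PCG_NAMES:
        have = {
            g.id: s for g in genomes
            for s in [gene_sequences(g, [gene]).get(gene)] if s
        }
        if len(have) < len(genomes):
            warnings.warn(f"{gene}: not present in all genomes; skipped",
                          stacklevel=2)
            continue
        aln = progressive_align(have, code=code)
        blocks.append({tid: aln.get(tid) for tid in ids})
    if not blocks:
        raise ValueError("no gene shared by all genomes")
    return MultipleAlignment(
        ids=tuple(ids),
        seqs=tuple("".join(b[tid] for b in blocks) for tid in ids),
        alphabet="codon",
    )
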