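"""End-to-end orchestration: partition -> hairpins -> SI calling -> SSR ->
sliding-window pi -> character mapping, with a manifest of outputs.

All inter-stage data passes through declared files in the output
directory; a fatal error in one stage aborts with the stage named, and
reruns on identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import diversity, quadripartite, si_caller, ssr
from .char_evolution import CharacterMap, classify_characters, read_newick
from .hairpin import find_hairpins
from .io import read_alignment, read_fasta_many, read_genbank

log = logging.getLogger("plastoflip")


@dataclass
class RunConfig:
    genomes: list[str]                 # FASTA or GenBank paths
    alignment: Optional[str] = None
    tree: Optional[str] = None
    outgroup: Optional[str] = None
    outdir: str = "plastoflip_out"
    min_ir_len: int = 10_000
    min_stem: int = 8
    min_loop: int = 4
    max_loop: int = 30
    window: int = 600
    step: int = 200
    pi_threshold: float = 0.015
    min_taxa_with_stem: int = 15
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for path in self.genomes + [p for p in (self.alignment, self.tree)
                                    if p]:
            if not os.path.exists(path):
                raise FileNotFoundError(f"input not found: {path}")
        if not (self.window >= self.step >= 1):
            raise ValueError("window/step out of range")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genomes(paths: list[str]):
    records = []
    for p in paths:
        if p.endswith((".gb", ".gbk", ".genbank")):
            records.append(read_genbank(p))
        else:
            records.extend(read_fasta_many(p))
    return records


def run_all(config: RunConfig) -> dict:
    """Run every stage the inputs allow; returns the manifest dict."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    manifest: dict = {"inputs": {p: _sha256(p) for p in config.genomes},
                      "outputs": {}, "parameters": {
                          k: v for k, v in vars(config).items()
                          if isinstance(v, (int, float, str))}}
    log.info("parameters: %s", manifest["parameters"])

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out(name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"][name] = _sha256(path)

    try:
        records = _load_genomes(config.genomes)
    except Exception as exc:
        raise StageError("load_genomes", exc) from exc

    # --- partition
    try:
        rows = []
        for rec in records:
            try:
                part = quadripartite.detect_partition(
                    rec, min_ir_len=config.min_ir_len)
                rec.partition = part
                rows.append({"taxon": rec.taxon_label,
                             "total": rec.length_bp,
                             "LSC": part.lsc_len, "IR": part.ir_len,
                             "SSC": part.ssc_len,
                             "AT_percent": round(100 * part.at_content, 1)})
            except quadripartite.NoQuadripartiteStructure as exc:
                log.warning("%s", exc)
        emit("partition.tsv", pd.DataFrame(rows))
    except Exception as exc:
        raise StageError("partition", exc) from exc

    # --- hairpins per taxon
    try:
        rows = []
        for rec in records:
            for h in find_hairpins(rec.sequence, min_stem=config.min_stem,
                                   min_loop=config.min_loop,
                                   max_loop=config.max_loop):
                rows.append({"taxon": rec.taxon_label,
                             "start_1based": h.genome_start + 1,
                             "end_1based": h.genome_end,
                             "stem_len": h.stem_len, "stem": h.stem_seq,
                             "loop": h.loop_seq})
        emit("hairpins.tsv", pd.DataFrame(rows))
    except Exception as exc:
        raise StageError("hairpins", exc) from exc

    # --- SSRs
    try:
        all_loci = {}
        rows = []
        for rec in records:
            loci = ssr.scan_ssrs(rec)
            all_loci[rec.taxon_label] = loci
            for l in loci:
                rows.append({"taxon": rec.taxon_label, "motif": l.motif,
                             "unit_len": l.unit_len, "copies": l.copies,
                             "start_1based": l.start + 1, "end_1based": l.end,
                             "functional": l.region.functional if l.region
                             else "", "compartment": l.region.compartment
                             if l.region else ""})
        emit("ssr.tsv", pd.DataFrame(rows))
        summaries = []
        for rec in records:
            s = ssr.ssr_summary(all_loci[rec.taxon_label], rec.partition)
            s.insert(0, "taxon", rec.taxon_label)
            summaries.append(s)
        emit("ssr_summary.tsv", pd.concat(summaries, ignore_index=True))
    except Exception as exc:
        raise StageError("ssr", exc) from exc

    alignment = None
    if config.alignment:
        try:
            alignment = read_alignment(config.alignment)
        except Exception as exc:
            raise StageError("read_alignment", exc) from exc

        # --- nucleotide diversity
        try:
            windows = diversity.pi_sliding(alignment, window=config.window,
                                           step=config.step)
            emit("pi.tsv", diversity.pi_table(windows))
        except Exception as exc:
            raise StageError("pi", exc) from exc

        # --- SI calling
        try:
            profiles = si_caller.call_si_loci(
                alignment, records,
                hairpin_params={"min_stem": config.min_stem,
                                "min_loop": config.min_loop,
                                "max_loop": config.max_loop},
                min_taxa_with_stem=config.min_taxa_with_stem)
            emit("si_table.tsv", si_caller.si_report(profiles))
            matrix = si_caller.si_character_matrix(
                profiles, [r.taxon_label for r in records])
            matrix.index.name = "taxon"
            path = out("si_matrix.tsv")
            matrix.to_csv(path, sep="\t")
            manifest["outputs"]["si_matrix.tsv"] = _sha256(path)
        except Exception as exc:
            raise StageError("si_call", exc) from exc

        # --- character mapping
        if config.tree:
            try:
                tree = read_newick(config.tree, outgroup=config.outgroup)
                if matrix.shape[1]:
                    cmap = CharacterMap.fit(matrix, tree)
                    emit("charmap.tsv", classify_characters(cmap))
            except Exception as exc:
                raise StageError("charmap", exc) from exc
    elif config.tree:
        raise StageError("charmap", ValueError(
            "character mapping requires an alignment for SI calling"))

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
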