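"""Pipeline orchestration: annotate -> classify -> promoters -> repeats ->
parity vs comparators -> phylogeny, driven by one declarative configuration.

The run configuration is a plain mapping (typically loaded from YAML/JSON):

    genome: path or {id, seq}          # required
    comparators: [path, ...]           # optional, enables parity + phylogeny
    panels: {core37: path, ...}        # optional, enables classification
    annotation: {min_orf_nt, max_overlap_fraction}
    promoters: {window_nt}
    repeats: {min_unit_nt, ...}
    phylogeny: {bootstrap, seed}
    output_dir: path

Every stage writes its tables under ``output_dir`` and contributes to a
JSON report; the manifest records parameters, seeds, input checksums and
the output inventory so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .genome_io import CircularGenome, genome_stats, read_genome
from .orf_annotation import (AnnotationConfig, GenomeAnnotation, annotate,
                             annotation_stats, write_gff3, write_protein_fasta)
from .gene_classification import classify_genes, ortholog_map, read_panel
from .synteny_parity import collinearity_score, detect_inversions, parity_coordinates
from .promoter_scan import PromoterConfig, scan_promoters
from .repeat_finder import RepeatConfig, classify_region, find_direct_repeats, intergenic_spacers
from .core_phylogeny import bootstrap_support, build_supermatrix, center_star_align

__all__ = ["PipelineConfigError", "PipelineStageError", "RunManifest", "run_pipeline"]

_KNOWN_KEYS = {"genome", "comparators", "panels", "annotation", "promoters",
               "repeats", "phylogeny", "output_dir", "topology"}


class PipelineConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict[str, str]
    stages: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_genome(spec, topology: str | None) -> CircularGenome:
    if isinstance(spec, dict):
        return CircularGenome(id=spec["id"], seq=spec["seq"],
                              topology=spec.get("topology", topology or "circular"))
    p = Path(spec)
    fmt = "genbank" if p.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    return read_genome(p, fmt, topology)


def run_pipeline(config: dict) -> tuple[RunManifest, dict]:
    """Execute all runnable stages in dependency order; return (manifest, report)."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "genome" not in config:
        raise PipelineConfigError("configuration must name a 'genome'")
    outdir = Path(config.get("output_dir", "gvcompare_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    checksums = {}
    for key in ("genome",):
        if isinstance(config[key], (str, Path)) and Path(config[key]).exists():
            checksums[str(config[key])] = _sha256(Path(config[key]))
    for p in config.get("comparators", []):
        if Path(p).exists():
            checksums[str(p)] = _sha256(Path(p))

    manifest = RunManifest(version=__version__, config={k: str(v) for k, v in config.items()},
                           input_checksums=checksums)
    report: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise PipelineStageError(name, exc) from exc
            manifest.stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return deco

    state: dict = {}

    @stage("genome")
    def _genome():
        g = _load_genome(config["genome"], config.get("topology"))
        st = genome_stats(g)
        state["genome"] = g
        report["genome"] = {"id": g.id, "length": st.length,
                            "gc_pct": round(100 * st.gc_fraction, 1),
                            "topology": g.topology}

    @stage("annotate")
    def _annotate():
        acfg = AnnotationConfig(**config.get("annotation", {}))
        ann = annotate(state["genome"], acfg)
        state["annotation"] = ann
        st = annotation_stats(ann)
        gff = outdir / "annotation.gff3"
        faa = outdir / "proteins.faa"
        write_gff3(ann, gff)
        write_protein_fasta(ann, faa)
        manifest.outputs += [str(gff), str(faa)]
        report["orfs"] = {"n": st.n_orfs, "plus": st.n_plus, "minus": st.n_minus,
                          "coding_pct": round(100 * st.coding_fraction, 1),
                          "adjacent_overlaps": len(st.adjacent_overlaps)}

    if config.get("panels"):
        @stage("classify")
        def _classify():
            panels = [read_panel(path, pid) for pid, path in config["panels"].items()]
            table = classify_genes(state["annotation"], panels)
            out = outdir / "gene_classes.tsv"
            table.to_frame().to_csv(out, sep="\t", index=False)
            manifest.outputs.append(str(out))
            report["gene_classes"] = table.counts
            report["family_presence"] = {p: table.n_present(p) for p in table.family_presence}

    @stage("promoters")
    def _promoters():
        pcfg = PromoterConfig(**config.get("promoters", {}))
        hits = scan_promoters(state["annotation"], pcfg)
        from .promoter_scan import hits_table
        out = outdir / "promoters.tsv"
        hits_table(hits).to_csv(out, sep="\t", index=False)
        manifest.outputs.append(str(out))
        report["promoters"] = {
            "late_hits": sum(1 for h in hits if h.kind == "late"),
            "early_hits": sum(1 for h in hits if h.kind == "early"),
            "orfs_with_hit": len({h.orf_id for h in hits}),
        }

    @stage("repeats")
    def _repeats():
        rcfg = RepeatConfig(**config.get("repeats", {}))
        ann = state["annotation"]
        rows = []
        for sp in intergenic_spacers(ann, min_len=rcfg.min_unit_nt * rcfg.min_copies):
            sub = _spacer_seq(ann.genome, sp)
            for reg in find_direct_repeats(sub, rcfg):
                cls = classify_region(reg, rcfg, seq=sub)
                rows.append({
                    "spacer_start": sp.start, "left_orf": sp.left_orf_id,
                    "right_orf": sp.right_orf_id,
                    "start": _offset(sp.start, reg.start, ann.genome.length),
                    "end": _offset(sp.start, reg.end, ann.genome.length),
                    "n_copies": reg.n_full_copies, "truncated": reg.has_truncated_copy,
                    "at_pct": round(100 * reg.at_fraction, 1), "classification": cls,
                })
        import pandas as pd
        out = outdir / "repeat_regions.tsv"
        pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
        manifest.outputs.append(str(out))
        report["repeat_regions"] = rows

    comparators = config.get("comparators", [])
    if comparators:
        @stage("parity")
        def _parity():
            acfg = AnnotationConfig(**config.get("annotation", {}))
            out_rows = {}
            state["comparator_annotations"] = {}
            for path in comparators:
                g = _load_genome(path, config.get("topology"))
                ann_b = annotate(g, acfg)
                state["comparator_annotations"][g.id] = ann_b
                table = ortholog_map(state["annotation"], ann_b)
                parity = parity_coordinates(table, state["annotation"], ann_b)
                entry = {"n_orthologs": len(parity.pairs)}
                if len(parity.pairs) >= 2:
                    entry["collinearity"] = round(collinearity_score(parity), 3)
                    entry["inversions"] = [asdict(s) for s in
                                           detect_inversions(parity, state["annotation"])]
                out_rows[g.id] = entry
                tsv = outdir / f"parity_{g.id}.tsv"
                parity.to_frame().to_csv(tsv, sep="\t", index=False)
                manifest.outputs.append(str(tsv))
            report["parity"] = out_rows

        @stage("phylogeny")
        def _phylo():
            anns = [state["annotation"]] + list(state["comparator_annotations"].values())
            if len(anns) < 3:
                manifest.stages.append({"stage": "phylogeny", "skipped": "needs >= 3 genomes"})
                return
            pcfg = config.get("phylogeny", {})
            tree = _concatenated_tree(anns, n_boot=int(pcfg.get("bootstrap", 100)),
                                      seed=int(pcfg.get("seed", 0)))
            nwk = outdir / "core_tree.nwk"
            nwk.write_text(tree.newick() + "\n")
            manifest.outputs.append(str(nwk))
            report["tree"] = tree.newick()
    else:
        manifest.stages.append({"stage": "parity", "skipped": "no comparator genomes"})
        manifest.stages.append({"stage": "phylogeny", "skipped": "no comparator genomes"})

    mpath = outdir / "manifest.json"
    rpath = outdir / "report.json"
    manifest.outputs += [str(mpath), str(rpath)]
    rpath.write_text(json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n")
    mpath.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True,
                                default=_json_default) + "\n")
    return manifest, report


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _spacer_seq(genome: CircularGenome, sp) -> str:
    from .genome_io import circular_subsequence
    return circular_subsequence(genome, sp.start, sp.end, "+")


def _offset(spacer_start: int, rel: int, L: int) -> int:
    return (spacer_start - 1 + rel - 1) % L + 1


def _concatenated_tree(annotations, n_boot: int = 100, seed: int = 0):
    """Genes shared across all genomes -> aligned blocks -> NJ + bootstrap."""
    ref = annotations[0]
    maps = [{i: j for i, j, _s in ortholog_map(ref, ann).pairs} for ann in annotations[1:]]
    blocks = []
    for orf in ref.orfs:
        if all(orf.orf_id in m for m in maps):
            family = {ref.genome.id: orf.protein}
            for ann, m in zip(annotations[1:], maps):
                family[ann.genome.id] = ann.orf(m[orf.orf_id]).protein
            blocks.append((f"orf{orf.orf_id}", center_star_align(family)))
    if not blocks:
        raise PipelineStageError("phylogeny", ValueError("no shared single-copy genes"))
    sm = build_supermatrix(blocks)
    return bootstrap_support(sm, n_replicates=n_boot, seed=seed)
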