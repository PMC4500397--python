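#!/usr/bin/env python
"""Reproduce the published ClasGV-B genome numbers from the deposited record.

The deposited genome (GenBank accession KR091910) is not bundled with the
package; this script fetches it (network required) or uses a local copy,
then recomputes with the library:

* genome length and G+C content,
* the selected ORF set (count, orientation split, coding fraction,
  adjacent overlaps and the largest overlap lengths),
* intergenic spacers and non-hr style repeat regions (extent, copy count,
  truncated-copy flag, AT fraction, classification),
* optionally, gene-family presence against user-supplied reference panels
  (``family|member`` FASTA; e.g. a curated 37-core-gene panel and a
  19-betabaculovirus-specific panel built from public proteomes).

Usage:
    python scripts/reproduce_reference.py --fetch            # downloads to data/reference/
    python scripts/reproduce_reference.py --genbank my.gb
    python scripts/reproduce_reference.py --fetch --panel core37=core37.faa --panel beta19=beta19.faa
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSION = "KR091910"
EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")
DEFAULT_DIR = Path(__file__).resolve().parent.parent / "data" / "reference"


def fetch(dest: Path) -> Path:
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = EFETCH.format(acc=ACCESSION)
    print(f"fetching {ACCESSION} from NCBI ...", file=sys.stderr)
    with urllib.request.urlopen(url, timeout=120) as resp:
        dest.write_bytes(resp.read())
    return dest


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fetch", action="store_true", help="download the record from NCBI")
    ap.add_argument("--genbank", type=Path, default=DEFAULT_DIR / f"{ACCESSION}.gb")
    ap.add_argument("--panel", action="append", default=[],
                    help="panel_id=path.faa (repeatable)")
    args = ap.parse_args()

    if args.fetch and not args.genbank.exists():
        fetch(args.genbank)
    if not args.genbank.exists():
        sys.exit(f"{args.genbank} not found; run with --fetch (needs network) "
                 "or pass --genbank <file>")

    from gvcompare.genome_io import circular_subsequence, gc_content, read_genome
    from gvcompare.orf_annotation import annotate, annotation_stats
    from gvcompare.repeat_finder import (RepeatConfig, classify_region,
                                         find_direct_repeats, intergenic_spacers)

    g = read_genome(args.genbank, "genbank")
    print(f"genome\t{g.id}\t{g.length} bp\tG+C {100 * gc_content(g.seq):.1f}%")

    ann = annotate(g)
    st = annotation_stats(ann)
    print(f"orfs\t{st.n_orfs}\t(+{st.n_plus} / -{st.n_minus})"
          f"\tcoding {100 * st.coding_fraction:.1f}%"
          f"\tadjacent overlaps {len(st.adjacent_overlaps)}")
    big = sorted((ov, a, b) for a, b, ov in st.adjacent_overlaps if ov > 75)
    for ov, a, b in big:
        print(f"overlap\torf{a}/orf{b}\t{ov} bp")

    cfg = RepeatConfig()
    for sp in intergenic_spacers(ann, min_len=100):
        sub = circular_subsequence(g, sp.start, sp.end, "+")
        for reg in find_direct_repeats(sub, cfg):
            cls = classify_region(reg, cfg, seq=sub)
            s = (sp.start - 1 + reg.start - 1) % g.length + 1
            e = (sp.start - 1 + reg.end - 1) % g.length + 1
            print(f"repeat\torf{sp.left_orf_id}..orf{sp.right_orf_id}\t{s}-{e}"
                  f"\t{reg.length} bp\t{reg.n_full_copies} copies"
                  f"\ttruncated={reg.has_truncated_copy}"
                  f"\tAT {100 * reg.at_fraction:.0f}%\t{cls}")

    if args.panel:
        from gvcompare.gene_classification import classify_genes, read_panel
        panels = []
        for spec in args.panel:
            pid, _, path = spec.partition("=")
            panels.append(read_panel(path, pid))
        table = classify_genes(ann, panels)
        for p in panels:
            print(f"panel\t{p.panel_id}\t{table.n_present(p.panel_id)}"
                  f"/{len(p.families)} families present")
        print(f"classes\t{table.counts}")


if __name__ == "__main__":
    main()
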