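"""Packaged reference tables for the corn-rootworm nudivirus study.

Two small TSVs ship with the package:

* ``duhnv_fragments.tsv`` — the five assembled DuhNV genome fragments with
  their published lengths, GC%, CDS counts and mapped-read counts (the
  inputs of the coverage arithmetic);
* ``duhnv_orfs.tsv`` — the 110 ORF records of the DuhNV annotation with
  their OrNV homolog assignments (the inputs of the synteny/split-gene
  scaffolding worked example). ``split=1`` marks records that are one part
  of a gene split across two fragments.

The OrNV reference encodes 139 annotated ORFs (gp001..gp139); homolog
tokens like ``OrNV_gp129/gp136`` resolve to the first index.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

#: Number of annotated ORFs in the OrNV reference genome.
ORNV_GENE_COUNT = 139


def _load(name: str) -> pd.DataFrame:
    with resources.files("nudimine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def duhnv_fragments() -> pd.DataFrame:
    """Published per-fragment stats: fragment, length_bp, gc_percent,
    n_cds, reads_mapped."""
    return _load("duhnv_fragments.tsv")


def duhnv_orfs() -> pd.DataFrame:
    """Published ORF table: orf, fragment, gene, length_aa, ornv_homolog,
    core, split."""
    return _load("duhnv_orfs.tsv")


def ornv_index(homolog_token: str) -> int | None:
    """0-based OrNV gene-order index from a homolog token.

    "OrNV_gp129/gp136" -> 128; unnumbered tokens ("no hit", "OrNV_orfC20")
    -> None.
    """
    m = re.search(r"gp(\d+)", str(homolog_token))
    return int(m.group(1)) - 1 if m else None


def duhnv_gene_maps():
    """The published fragment gene maps as scaffolder input.

    ORFs carry their OrNV gene-order index; the two halves of the split
    DNA-polymerase gene (3'-terminal on F1, 5'-terminal on F2) carry the
    partial flags that make them a split-gene adjacency link.
    """
    from .scaffold import FragmentGeneMap, MappedOrf

    orfs = duhnv_orfs()
    frags = duhnv_fragments()
    maps = []
    for _, frow in frags.iterrows():
        fid = frow["fragment"]
        sub = orfs[orfs["fragment"] == fid]
        entries = []
        n = len(sub)
        for pos, (_, row) in enumerate(sub.iterrows()):
            partial5 = bool(row["split"]) and pos == 0
            partial3 = bool(row["split"]) and pos == n - 1
            entries.append(
                MappedOrf(row["orf"], ornv_index(row["ornv_homolog"]), "+",
                          partial5=partial5, partial3=partial3)
            )
        maps.append(FragmentGeneMap(fid, entries, int(frow["length_bp"])))
    return maps
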