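"""Three-taxon Venn partitioning of ortholog-group membership.

Given a table stating, for each screened gene and each taxon, whether the
gene belongs to an ortholog group in that taxon, the gene set is partitioned
into the eight regions of a three-set Venn diagram.  Ortholog inference
itself (database lookups, reciprocal BLAST) is upstream of this module.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .core_io import ConfigError, FormatError

logger = logging.getLogger("germscreen")

__all__ = ["read_ortholog_table", "venn_partition", "render_venn_text"]

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (gene_id, taxon, has_ortholog_group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["gene_id", "taxon", "has_ortholog_group"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["gene_id", "taxon"]).any():
        raise FormatError(f"{path}: duplicate (gene_id, taxon) rows")
    vals = df["has_ortholog_group"].str.strip().str.lower()
    bad = ~vals.isin(_TRUTHY | _FALSY)
    if bad.any():
        raise FormatError(f"{path}: non-boolean membership value {df.loc[bad.idxmax(), 'has_ortholog_group']!r}")
    df["has_ortholog_group"] = vals.isin(_TRUTHY)
    return df[needed]


def venn_partition(table: pd.DataFrame, genes, taxa: tuple[str, str, str]) -> dict:
    """Counts of the 2**3 membership regions for a gene set across 3 taxa.

    Region keys are strings like ``"A&B"`` (present in A and B but not the
    third taxon) built from the given taxon labels, plus ``"none"``.  Genes
    absent from the table count as members of no taxon (logged).  Also
    reports how many genes have an ortholog group in at least one taxon and
    in all three.
    """
    if len(taxa) != 3 or len(set(taxa)) != 3:
        raise ConfigError("exactly three distinct taxa required")
    known = set(table["taxon"].unique())
    unknown = [t for t in taxa if t not in known]
    if unknown:
        raise ConfigError(f"taxa not present in the ortholog table: {unknown}")
    genes = list(dict.fromkeys(genes))
    member = {
        t: set(table.loc[(table["taxon"] == t) & table["has_ortholog_group"], "gene_id"])
        for t in taxa
    }
    in_table = set(table["gene_id"])
    absent = [g for g in genes if g not in in_table]
    if absent:
        logger.warning("venn_partition: %d gene(s) absent from the ortholog table "
                       "counted as having no orthologs: %s", len(absent), absent[:5])
    regions: dict[str, int] = {}
    for bits in range(8):
        present = [taxa[i] for i in range(3) if bits >> i & 1]
        key = "&".join(present) if present else "none"
        regions[key] = 0
    n_any = n_all = 0
    for g in genes:
        present = [t for t in taxa if g in member[t]]
        key = "&".join(present) if present else "none"
        regions[key] += 1
        if present:
            n_any += 1
        if len(present) == 3:
            n_all += 1
    return {
        "taxa": list(taxa),
        "n_genes": len(genes),
        "regions": regions,
        "n_with_any_taxon": n_any,
        "n_in_all_taxa": n_all,
    }


def render_venn_text(partition: dict) -> str:
    """Plain-text rendering of a three-set Venn partition."""
    a, b, c = partition["taxa"]
    r = partition["regions"]
    lines = [
        f"Venn partition of {partition['n_genes']} genes across {a}, {b}, {c}",
        f"  {a} only          : {r[a]}",
        f"  {b} only          : {r[b]}",
        f"  {c} only          : {r[c]}",
        f"  {a}&{b}           : {r[f'{a}&{b}']}",
        f"  {a}&{c}           : {r[f'{a}&{c}']}",
        f"  {b}&{c}           : {r[f'{b}&{c}']}",
        f"  all three         : {r[f'{a}&{b}&{c}']}",
        f"  none              : {r['none']}",
        f"  >=1 taxon         : {partition['n_with_any_taxon']}",
    ]
    return "\n".join(lines)
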