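"""Promoter cis-regulatory element (CRE) scanning and per-group summaries.

Elements are matched as exact IUPAC consensus signatures on both strands
(the PlantCARE reporting convention), with no position-weight scoring.
The bundled catalog carries literature-standard consensi assigned to the
seven functional groups used for reporting (light-responsive,
hormone-responsive, environmental-stress, development, promoter-related,
site-binding, other); it is a plain TSV and fully user-replaceable.  An
'N' in the promoter never matches.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

FUNCTIONAL_GROUPS = (
    "light-responsive",
    "hormone-responsive",
    "environmental-stress",
    "development",
    "promoter-related",
    "site-binding",
    "other",
)

IUPAC_NUCLEOTIDES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CREMotif:
    name: str
    consensus: str
    group: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4 nt")
        if self.group not in FUNCTIONAL_GROUPS:
            raise ValueError(f"{self.name}: unknown functional group {self.group!r}")
        for ch in self.consensus:
            if ch not in IUPAC_NUCLEOTIDES:
                raise ValueError(f"{self.name}: invalid IUPAC symbol {ch!r}")


@dataclass(frozen=True)
class CREHit:
    gene_id: str
    motif_name: str
    position: int  # 0-based offset of the match start in the promoter
    strand: str  # + | -


def load_catalog(path: str | Path | None = None) -> list[CREMotif]:
    """Load a motif catalog TSV (columns: name, consensus, group)."""
    if path is None:
        text = resources.files("gfam.data").joinpath("plantcare_catalog.tsv").read_text()
    else:
        text = Path(path).read_text()
    motifs = [
        CREMotif(name=row["name"], consensus=row["consensus"].upper(), group=row["group"])
        for row in csv.DictReader(text.splitlines(), delimiter="\t")
    ]
    if not motifs:
        raise ValueError("empty CRE catalog")
    return motifs


def _iupac_regex(consensus: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all reported
    body = "".join(
        ch if len(IUPAC_NUCLEOTIDES[ch]) == 1 else f"[{IUPAC_NUCLEOTIDES[ch]}]"
        for ch in consensus
    )
    return re.compile(f"(?=({body}))")


def scan_promoter(
    gene_id: str, promoter_seq: str, catalog: Sequence[CREMotif]
) -> list[CREHit]:
    """All catalog matches in one promoter, both strands, overlaps included.

    A '-'-strand hit is a match of the reverse complement of the consensus;
    its position is still the match start on the forward promoter string.
    """
    if not catalog:
        raise ValueError("empty CRE catalog")
    seq = promoter_seq.upper()
    hits: list[CREHit] = []
    for motif in catalog:
        for strand, pattern_source in (
            ("+", motif.consensus),
            ("-", str(Seq(motif.consensus).reverse_complement())),
        ):
            for m in _iupac_regex(pattern_source).finditer(seq):
                hits.append(
                    CREHit(
                        gene_id=gene_id,
                        motif_name=motif.name,
                        position=m.start(),
                        strand=strand,
                    )
                )
    hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str], catalog: Sequence[CREMotif]
) -> list[CREHit]:
    return [
        hit
        for gene_id, seq in promoters.items()
        for hit in scan_promoter(gene_id, seq, catalog)
    ]


def summarize_cre(
    hits: Iterable[CREHit], catalog: Sequence[CREMotif]
) -> dict[str, object]:
    """Counts per motif, per functional group, and per gene.

    Returns a dict with 'per_motif' and 'per_group' count Series, a
    'per_gene' motif-count DataFrame, a boolean 'presence' matrix, and
    'total' hits.  The motif and group counts each sum to the hit count.
    """
    by_name = {m.name: m for m in catalog}
    hits = list(hits)
    for hit in hits:
        if hit.motif_name not in by_name:
            raise ValueError(f"hit names motif {hit.motif_name!r} absent from catalog")
    motif_names = [m.name for m in catalog]
    frame = pd.DataFrame(
        [(h.gene_id, h.motif_name) for h in hits], columns=["gene_id", "motif"]
    )
    if frame.empty:
        per_gene = pd.DataFrame(columns=motif_names)
    else:
        per_gene = (
            frame.groupby(["gene_id", "motif"]).size().unstack(fill_value=0)
            .reindex(columns=motif_names, fill_value=0)
        )
    per_motif = per_gene.sum(axis=0).astype(int) if not per_gene.empty else pd.Series(
        0, index=motif_names, dtype=int
    )
    group_of = {m.name: m.group for m in catalog}
    per_group = pd.Series(0, index=list(FUNCTIONAL_GROUPS), dtype=int)
    for name, count in per_motif.items():
        per_group[group_of[name]] += int(count)
    return {
        "per_motif": per_motif,
        "per_group": per_group,
        "per_gene": per_gene,
        "presence": per_gene.astype(bool) if not per_gene.empty else per_gene,
        "total": len(hits),
    }
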