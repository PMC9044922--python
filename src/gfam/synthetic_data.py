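"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and mirrors
the study design the pipeline targets: proteomes with planted AP2/B3
domains of controlled 14th/19th residues and WLG triples, gene coordinate
sets with planted duplicate pairs (tandem pairs a few kb apart), 2-kb
promoters with planted motif counts, Ct tables for 2 tolerant + 2
susceptible genotypes x 2 treatments x 3 replicates with planted per-gene
Log2FC effects, and root-depth tables with planted heat damage indices.

A single root seed fans out to fixed, named substreams so adding a
generator never perturbs the data an existing one produces.  Background
sequence is rejection-sampled so it cannot reproduce a planted signal by
accident: at zero noise, every pipeline stage recovers its planted truth
exactly rather than probabilistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import GeneLocus, ProteinRecord
from .domain_annotation import (
    AP2_CONSENSUS,
    B3_CONSENSUS,
    AA_ALPHABET,
    default_profiles,
    scan_domains,
)
from .phenotype import PhenotypeRecord
from .phylogeny import DistanceMatrix, PhyloTree, TreeNode
from .promoter_cre import CREMotif, IUPAC_NUCLEOTIDES, load_catalog, scan_promoter
from .qpcr_expression import CONTROL, HEAT, SUSCEPTIBLE, TOLERANT, CtTable

import pandas as pd

logger = logging.getLogger("gfam")

NUCLEOTIDES = "ACGT"

# fixed substream ids: appending new generators must not renumber old ones
_STREAMS = {
    "proteome": 1,
    "duplicates": 2,
    "promoters": 3,
    "ct_table": 4,
    "root_depth": 5,
    "alignment": 6,
    "tree": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def ap2_domain_sequence(r14: str = "A", r19: str = "D", wlg: str = "WLG") -> str:
    """The bundled AP2 consensus with controlled residues at columns
    14, 19 and the WLG triple (columns 28-30)."""
    seq = list(AP2_CONSENSUS)
    seq[13] = r14
    seq[18] = r19
    seq[27:30] = list(wlg)
    return "".join(seq)


@dataclass(frozen=True)
class PlantedDomain:
    domain: str  # AP2 | B3
    offset: int  # 0-based offset in the protein
    r14: str = "-"
    r19: str = "-"
    wlg: str = "-"


@dataclass(frozen=True)
class ProteomeTruth:
    domains: dict[str, tuple[PlantedDomain, ...]]
    families: dict[str, str]  # expected family label (incl. DISCARDED)
    subfamilies: dict[str, str]  # expected sub-family (NA outside ERF_DREB)


_FAMILY_KEYS = ("DREB", "ERF", "AP2", "RAV", "other", "decoy")
_SUBFAMILY_RESIDUES = {"DREB": ("V", "E"), "ERF": ("A", "D"), "other": ("G", "G")}


def generate_proteome(
    n_per_family: Mapping[str, int],
    seed: int,
    wlg_variants: Mapping[str, str] | None = None,
) -> tuple[list[ProteinRecord], ProteomeTruth]:
    """Proteome with planted consensus domains and known family labels.

    ``n_per_family`` maps 'DREB'/'ERF'/'AP2'/'RAV'/'other'/'decoy' to
    counts.  DREB members carry Val-14/Glu-19, ERF members Ala-14/Asp-19,
    'other' members neither; AP2-family members carry two AP2 copies, RAV
    members one AP2 plus one B3, decoys no domain.  ``wlg_variants`` can
    replace the WLG triple per planted protein id.  Each protein is
    verified to yield exactly its planted architecture with the default
    profiles (background redrawn otherwise).
    """
    rng = _rng(seed, "proteome")
    profiles = default_profiles()
    wlg_variants = dict(wlg_variants or {})
    records: list[ProteinRecord] = []
    domains: dict[str, tuple[PlantedDomain, ...]] = {}
    families: dict[str, str] = {}
    subfamilies: dict[str, str] = {}
    for key in _FAMILY_KEYS:
        for i in range(int(n_per_family.get(key, 0))):
            pid = f"SYN_{key.upper()}_{i:03d}"
            wlg = wlg_variants.get(pid, "WLG")
            if key in _SUBFAMILY_RESIDUES:
                r14, r19 = _SUBFAMILY_RESIDUES[key]
                cores = [("AP2", ap2_domain_sequence(r14, r19, wlg), r14, r19, wlg)]
                expected_family, expected_sub = "ERF_DREB", (
                    key if key != "other" else "OTHER"
                )
            elif key == "AP2":
                cores = [
                    ("AP2", ap2_domain_sequence(wlg=wlg), "A", "D", wlg),
                    ("AP2", ap2_domain_sequence(wlg=wlg), "A", "D", wlg),
                ]
                expected_family, expected_sub = "AP2", "NA"
            elif key == "RAV":
                cores = [
                    ("AP2", ap2_domain_sequence(wlg=wlg), "A", "D", wlg),
                    ("B3", B3_CONSENSUS, "-", "-", "-"),
                ]
                expected_family, expected_sub = "RAV", "NA"
            else:  # decoy
                cores = []
                expected_family, expected_sub = "DISCARDED", "NA"
            for _attempt in range(50):
                planted: list[PlantedDomain] = []
                if not cores:
                    sequence = _random_protein(rng, int(rng.integers(150, 250)))
                else:
                    parts = [_random_protein(rng, int(rng.integers(40, 80)))]
                    for domain, core, r14_, r19_, wlg_ in cores:
                        offset = sum(len(p) for p in parts)
                        planted.append(
                            PlantedDomain(domain, offset, r14_, r19_, wlg_)
                        )
                        parts.append(core)
                        parts.append(_random_protein(rng, int(rng.integers(40, 80))))
                    sequence = "".join(parts)
                record = ProteinRecord(id=pid, sequence=sequence)
                hits = scan_domains(record, profiles)
                recovered = [(h.domain, h.start) for h in hits]
                if recovered == [(p.domain, p.offset) for p in planted]:
                    break
            else:  # pragma: no cover - rejection virtually never exhausts
                raise RuntimeError(f"could not generate clean background for {pid}")
            records.append(record)
            domains[pid] = tuple(planted)
            families[pid] = expected_family
            subfamilies[pid] = expected_sub
    logger.info("generate_proteome: %d proteins", len(records))
    return records, ProteomeTruth(domains=domains, families=families, subfamilies=subfamilies)


@dataclass(frozen=True)
class DuplicateTruth:
    pairs: tuple[dict, ...]  # id_a, id_b, call, mutation_rate, distance_bp


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    out = list(sequence)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            choices = [c for c in AA_ALPHABET if c != aa]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def generate_loci_with_duplicates(
    n_genes: int,
    n_segmental: int,
    n_tandem: int,
    mutation_rate: float,
    seed: int,
    tandem_gap_bp: int = 2510,
) -> tuple[list[ProteinRecord], list[GeneLocus], DuplicateTruth]:
    """Gene set in which the first ``n_segmental`` genes have a mutated copy.

    Duplicate partners are point-mutated copies (each selected site forced
    to a different residue).  The first ``n_tandem`` pairs sit adjacently
    on one chromosome separated by ``tandem_gap_bp`` (2.51 kb by default);
    the remaining segmental pairs are placed on different chromosomes.
    """
    if n_tandem > n_segmental or n_segmental > n_genes:
        raise ValueError("need n_tandem <= n_segmental <= n_genes")
    rng = _rng(seed, "duplicates")
    chromosomes = [f"{num}{sub}" for num in range(1, 8) for sub in "ABD"]
    records: list[ProteinRecord] = []
    loci: list[GeneLocus] = []
    truth_pairs: list[dict] = []
    cursor: dict[str, int] = {c: 1_000_000 for c in chromosomes}

    def place(gene_id: str, chromosome: str, length_bp: int, at: int | None = None) -> GeneLocus:
        start = cursor[chromosome] if at is None else at
        end = start + length_bp
        cursor[chromosome] = max(cursor[chromosome], end) + 1_000_000
        locus = GeneLocus(
            gene_id=gene_id,
            chromosome=chromosome,
            start=start,
            end=end,
            strand="+",
            exon_intervals=((start, end),),
        )
        loci.append(locus)
        return locus

    for i in range(n_genes):
        gid = f"SYNGENE{i:03d}"
        seq = _random_protein(rng, int(rng.integers(250, 350)))
        records.append(ProteinRecord(id=gid, sequence=seq))
        chrom = chromosomes[i % len(chromosomes)]
        locus = place(gid, chrom, len(seq) * 3)
        if i < n_segmental:
            did = f"{gid}_dup"
            dup_seq = _mutate(rng, seq, mutation_rate)
            records.append(ProteinRecord(id=did, sequence=dup_seq))
            if i < n_tandem:
                dup_locus = place(did, chrom, len(dup_seq) * 3, at=locus.end + tandem_gap_bp)
                call, distance = "TANDEM", tandem_gap_bp
            else:
                other = chromosomes[(i + 7) % len(chromosomes)]
                place(did, other, len(dup_seq) * 3)
                call, distance = "SEGMENTAL", None
            truth_pairs.append(
                {
                    "id_a": gid,
                    "id_b": did,
                    "call": call,
                    "mutation_rate": mutation_rate,
                    "distance_bp": distance,
                }
            )
    logger.info(
        "generate_loci_with_duplicates: %d genes, %d planted pairs", len(records), len(truth_pairs)
    )
    return records, loci, DuplicateTruth(pairs=tuple(truth_pairs))


@dataclass(frozen=True)
class PromoterTruth:
    offsets: dict[str, dict[str, tuple[int, ...]]]  # promoter -> motif -> offsets

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            pid: {name: len(offs) for name, offs in plan.items()}
            for pid, plan in self.offsets.items()
        }


def _instantiate_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        ch if len(IUPAC_NUCLEOTIDES[ch]) == 1
        else IUPAC_NUCLEOTIDES[ch][int(rng.integers(len(IUPAC_NUCLEOTIDES[ch])))]
        for ch in consensus
    )


def generate_promoters(
    n: int,
    motif_plan: Mapping[str, int],
    seed: int,
    length: int = 2000,
    catalog: Sequence[CREMotif] | None = None,
) -> tuple[list[ProteinRecord], PromoterTruth]:
    """2-kb promoters with planted, non-overlapping motif occurrences.

    Every promoter receives ``motif_plan[name]`` forward-strand copies of
    each planned motif at recorded offsets.  The assembled promoter is
    rescanned against the planned motifs and redrawn until the
    forward-strand hits are exactly the planted ones, so planted counts
    are recovered exactly.  Plans whose motifs contain one another (e.g.
    ABRE inside G-box) can never satisfy that contract and will exhaust
    the redraw budget; plant such motifs in separate promoter sets.
    """
    if catalog is None:
        catalog = load_catalog()
    by_name = {m.name: m for m in catalog}
    for name in motif_plan:
        if name not in by_name:
            raise ValueError(f"motif {name!r} absent from catalog")
    total_len = sum(len(by_name[m].consensus) * k for m, k in motif_plan.items())
    if total_len > length // 2:
        raise ValueError("requested motifs cannot fit without crowding the promoter")
    rng = _rng(seed, "promoters")
    planned_catalog = [by_name[m] for m in motif_plan]
    records: list[ProteinRecord] = []
    offsets: dict[str, dict[str, tuple[int, ...]]] = {}
    for i in range(n):
        pid = f"SYNPROM{i:03d}"
        seq = list(_random_dna(rng, length))
        taken: list[tuple[int, int]] = []
        planted: dict[str, list[int]] = {name: [] for name in motif_plan}
        for name, count in motif_plan.items():
            consensus = by_name[name].consensus
            for _ in range(count):
                for _try in range(1000):
                    pos = int(rng.integers(0, length - len(consensus) + 1))
                    span = (pos, pos + len(consensus))
                    if all(span[1] <= s or span[0] >= e for s, e in taken):
                        break
                else:
                    raise RuntimeError(f"cannot place motifs without overlap in {pid}")
                taken.append(span)
                seq[span[0] : span[1]] = list(_instantiate_iupac(rng, consensus))
                planted[name].append(pos)
        is_planted = [False] * length
        for s, e in taken:
            for k in range(s, e):
                is_planted[k] = True
        # scrub accidental background matches by redrawing only the
        # offending windows (planted positions stay fixed)
        for _attempt in range(500):
            promoter = "".join(seq)
            hits = scan_promoter(pid, promoter, planned_catalog)
            unwanted = [
                h for h in hits
                if h.strand == "+" and h.position not in planted[h.motif_name]
            ]
            if not unwanted:
                break
            for h in unwanted:
                width = len(by_name[h.motif_name].consensus)
                free = [
                    k for k in range(h.position, h.position + width)
                    if not is_planted[k]
                ]
                if not free:
                    raise RuntimeError(
                        f"{pid}: planned motifs imply each other "
                        f"({h.motif_name} inside a planted span); "
                        "plant such motifs in separate promoter sets"
                    )
                for k in free:
                    seq[k] = NUCLEOTIDES[int(rng.integers(4))]
        else:
            raise RuntimeError(f"could not build clean promoter {pid}")
        records.append(ProteinRecord(id=pid, sequence=promoter))
        offsets[pid] = {name: tuple(sorted(v)) for name, v in planted.items()}
    return records, PromoterTruth(offsets=offsets)


@dataclass(frozen=True)
class CtTruth:
    effects: dict[str, dict[str, float]]  # gene -> class -> Log2FC
    reference_gene: str
    noise_sd: float


DEFAULT_GENOTYPES = (
    ("Perenjori", TOLERANT),
    ("W156", TOLERANT),
    ("Brazil32", SUSCEPTIBLE),
    ("Yitpi", SUSCEPTIBLE),
)


def generate_ct_table(
    genes_with_effects: Mapping[str, tuple[float, float]],
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    reference_gene: str = "beta-actin",
    reference_ct: float = 20.0,
) -> tuple[CtTable, CtTruth]:
    """Ct table with planted per-gene (tolerant, susceptible) Log2FC effects.

    Design: 2 tolerant + 2 susceptible genotypes x 2 treatments x
    ``n_replicates`` biological replicates.  The reference gene is constant;
    each gene's control dCt is drawn once per genotype; heat-treatment dCt
    is the control dCt minus the class effect plus Gaussian replicate noise.
    At zero noise the analysis recovers the planted Log2FC exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed, "ct_table")
    rows = []
    for genotype, cls in DEFAULT_GENOTYPES:
        for rep in range(1, n_replicates + 1):
            for treatment in (CONTROL, HEAT):
                rows.append(
                    {
                        "genotype": genotype,
                        "cls": cls,
                        "treatment": treatment,
                        "replicate": rep,
                        "gene": reference_gene,
                        "ct": reference_ct,
                    }
                )
    effects: dict[str, dict[str, float]] = {}
    for gene, (effect_tol, effect_sus) in genes_with_effects.items():
        effects[gene] = {TOLERANT: float(effect_tol), SUSCEPTIBLE: float(effect_sus)}
        for genotype, cls in DEFAULT_GENOTYPES:
            control_dct = float(rng.uniform(2.0, 8.0))
            effect = effects[gene][cls]
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "genotype": genotype,
                        "cls": cls,
                        "treatment": CONTROL,
                        "replicate": rep,
                        "gene": gene,
                        "ct": reference_ct + control_dct,
                    }
                )
                noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "genotype": genotype,
                        "cls": cls,
                        "treatment": HEAT,
                        "replicate": rep,
                        "gene": gene,
                        "ct": reference_ct + control_dct - effect + noise,
                    }
                )
    table = CtTable(data=pd.DataFrame(rows), reference_gene=reference_gene)
    return table, CtTruth(effects=effects, reference_gene=reference_gene, noise_sd=noise_sd)


@dataclass(frozen=True)
class RootDepthTruth:
    class_hdi: dict[str, float]
    noise_sd: float


def generate_root_depths(
    class_hdi: Mapping[str, float],
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    base_depth_mm: float = 100.0,
) -> tuple[list[PhenotypeRecord], RootDepthTruth]:
    """Root-depth records with planted per-class heat damage indices (%).

    Control depths sit around 100 mm (drawn once per genotype); heat depths
    are the control depth scaled by (1 - HDI/100) plus Gaussian noise.
    """
    for cls, hdi in class_hdi.items():
        if not 0 <= hdi < 100:
            raise ValueError(f"class HDI must be in [0, 100); got {hdi} for {cls}")
    rng = _rng(seed, "root_depth")
    records: list[PhenotypeRecord] = []
    for genotype, cls in DEFAULT_GENOTYPES:
        control = base_depth_mm * float(rng.uniform(0.9, 1.1))
        heat_mean = control * (1.0 - class_hdi[cls] / 100.0)
        for rep in range(1, n_replicates + 1):
            records.append(
                PhenotypeRecord(genotype, cls, CONTROL, rep, control)
            )
            noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            records.append(
                PhenotypeRecord(genotype, cls, HEAT, rep, max(0.0, heat_mean + noise))
            )
    return records, RootDepthTruth(class_hdi=dict(class_hdi), noise_sd=noise_sd)


def generate_clade_alignment(
    n_clades: int,
    taxa_per_clade: int,
    block_length: int,
    seed: int,
) -> list[ProteinRecord]:
    """Gap-free alignment in which members of a clade are identical.

    Clade sequences differ at every block, so every clade bipartition is
    saturated with signal and bootstraps to 100% support.
    """
    rng = _rng(seed, "alignment")
    records = []
    for c in range(n_clades):
        block = _random_protein(rng, block_length)
        for t in range(taxa_per_clade):
            records.append(ProteinRecord(id=f"clade{c}_taxon{t}", sequence=block))
    return records


def random_additive_tree(
    n_taxa: int, seed: int
) -> tuple[DistanceMatrix, set[frozenset[str]]]:
    """Random binary unrooted tree -> its exact (additive) distance matrix.

    Branch lengths are drawn from U(0.5, 2.0), so distances are additive by
    construction; returns the leaf distance matrix (taxa sorted) and the
    tree's internal bipartitions for topology checks.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for a non-trivial topology")
    rng = _rng(seed, "tree")

    def bl() -> float:
        return float(rng.uniform(0.5, 2.0))

    taxa = [f"T{i:02d}" for i in range(n_taxa)]
    root = TreeNode(children=[(TreeNode(name=taxa[0]), bl()),
                              (TreeNode(name=taxa[1]), bl()),
                              (TreeNode(name=taxa[2]), bl())])
    edges: list[tuple[TreeNode, int]] = [(root, 0), (root, 1), (root, 2)]
    for name in taxa[3:]:
        parent, idx = edges[int(rng.integers(len(edges)))]
        child, length = parent.children[idx]
        u = float(rng.uniform(0.3, 0.7))
        middle = TreeNode(children=[(child, length * u), (TreeNode(name=name), bl())])
        parent.children[idx] = (middle, length * (1.0 - u))
        edges = []

        def collect(node: TreeNode) -> None:
            for i, (c, _) in enumerate(node.children):
                edges.append((node, i))
                collect(c)

        collect(root)
    tree = PhyloTree(root=root, taxa=tuple(taxa))
    return tree.path_distances(), set(tree.bipartitions())
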