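"""Seeded generators for synthetic inputs with planted ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — planted DNA-binding categories, planted intron patterns,
diverged subgenome pairs, planted expression classes — and records its
truth so the paired analysis module can be round-trip tested with no
external downloads. Every generator is a bit-reproducible function of its
spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .binding_classifier import BindingCategory
from .domain_model import DEFAULT_REFERENCE_DOMAIN
from .expression_analysis import ExpressionMatrix
from .intron_architecture import PatternCatalog, default_catalog
from .io_formats import DomainHit, SequenceSet, format_fasta
from .orthologue_mapper import GeneRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NON_BASIC = "ACDEFGILMNPQSTVWY"  # no H/K/R
BASES = "ACGT"

#: one common codon per amino acid, for reverse translation
PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCA",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODONS_OF = {}
for codon, aa in _STANDARD.forward_table.items():
    CODONS_OF.setdefault(aa, []).append(codon)
for aa in CODONS_OF:
    CODONS_OF[aa].sort()


# ---------------------------------------------------------------------------
# Planted DNA-binding categories


@dataclass
class FamilySpec:
    """A synthetic protein family with planted binding categories."""

    category_counts: dict[str, int]
    reference_domain: str = DEFAULT_REFERENCE_DOMAIN
    flank_length_range: tuple[int, int] = (20, 80)
    substitution_rate: float = 0.15  # outside the basic-region rule columns
    min_basic_count: int = 5
    seed: int = 0
    id_prefix: str = "bhlh"

    @property
    def n_proteins(self) -> int:
        return sum(self.category_counts.values())


@dataclass
class FamilyBundle:
    sequences: SequenceSet
    hits: list[DomainHit]
    truth: pd.DataFrame  # protein_id, category, domain_start, domain_end

    def to_files(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "proteins.fasta"), "wt") as fh:
            fh.write(format_fasta(self.sequences))
        with open(os.path.join(directory, "domain_hits.tsv"), "wt") as fh:
            for h in self.hits:
                fh.write(f"{h.protein_id}\t{h.env_start}\t{h.env_end}\n")
        self.truth.to_csv(
            os.path.join(directory, "family_truth.tsv"), sep="\t", index=False
        )


def _planted_domain(
    category: str, reference: str, rate: float, rng: np.random.Generator
) -> str:
    """Build one domain forcing the planted category via columns 1-17."""
    dom = list(reference)
    # mutate only outside the basic region, so planted counts survive
    for i in range(17, len(dom)):
        if rng.random() < rate:
            dom[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    if category == BindingCategory.NON_BINDING.value:
        # lacking the basic region: wipe every basic residue
        for i in range(17):
            if dom[i] in "HKR":
                dom[i] = NON_BASIC[rng.integers(len(NON_BASIC))]
    elif category == BindingCategory.NON_EBOX_BINDER.value:
        dom[12] = "Q" if rng.random() < 0.5 else dom[12]
        if dom[12] == "E":  # must break at least one E-box requirement
            dom[15] = "L"
        else:
            if rng.random() < 0.5:
                dom[15] = "L"
    elif category == BindingCategory.EBOX_NON_GBOX.value:
        dom[8] = "A"  # no His-9
        dom[12], dom[15] = "E", "R"
    elif category == BindingCategory.GBOX_BINDER.value:
        dom[8], dom[12], dom[15] = "H", "E", "R"
    else:
        raise ValueError(f"unknown category {category}")
    return "".join(dom)


def generate_family(spec: FamilySpec) -> FamilyBundle:
    """Proteins = random flanks + a planted domain; truth labels recorded.

    With the default reference the guaranteed basic count for binding
    categories is 6 (and 0 for non-binders), so min_basic_count above 6 is
    an impossible request and raises.
    """
    if spec.min_basic_count > 6:
        raise ValueError(
            "cannot guarantee a binding category with min_basic_count > 6"
        )
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str, str]] = []
    hits: list[DomainHit] = []
    rows: list[dict] = []
    i = 0
    for category, count in spec.category_counts.items():
        BindingCategory(category)  # validates the label
        for _ in range(count):
            i += 1
            pid = f"{spec.id_prefix}{i:04d}"
            lo, hi = spec.flank_length_range
            n_len = int(rng.integers(lo, hi + 1))
            c_len = int(rng.integers(lo, hi + 1))
            nflank = "".join(
                AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=n_len)
            )
            cflank = "".join(
                AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=c_len)
            )
            domain = _planted_domain(
                category, spec.reference_domain, spec.substitution_rate, rng
            )
            protein = nflank + domain + cflank
            start, end = n_len + 1, n_len + len(domain)
            records.append((pid, f"planted={category}", protein))
            hits.append(DomainHit(pid, start, end))
            rows.append(
                {
                    "protein_id": pid,
                    "category": category,
                    "domain_start": start,
                    "domain_end": end,
                }
            )
    return FamilyBundle(
        sequences=SequenceSet(records, alphabet="protein"),
        hits=hits,
        truth=pd.DataFrame(
            rows, columns=["protein_id", "category", "domain_start", "domain_end"]
        ),
    )


# ---------------------------------------------------------------------------
# Planted intron patterns


@dataclass
class LocusSpec:
    """Synthetic gene loci with introns planted at catalog slots."""

    pattern_counts: dict[str, int]
    catalog: PatternCatalog | None = None
    flank_aa_range: tuple[int, int] = (10, 30)
    intron_length: int = 120
    substitution_rate: float = 0.05
    seed: int = 0
    id_prefix: str = "locus"


@dataclass
class LocusBundle:
    gff3: str
    genome: SequenceSet
    cds: SequenceSet
    proteins: SequenceSet
    domain_ranges: dict[str, tuple[int, int]]  # per protein, 1-based aa
    truth: pd.DataFrame  # gene_id, pattern, strand

    def to_files(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "loci.gff3"), "wt") as fh:
            fh.write(self.gff3)
        for name, seqs in (
            ("genome", self.genome),
            ("cds", self.cds),
            ("proteins", self.proteins),
        ):
            with open(os.path.join(directory, f"{name}.fasta"), "wt") as fh:
                fh.write(format_fasta(seqs))
        self.truth.to_csv(
            os.path.join(directory, "locus_truth.tsv"), sep="\t", index=False
        )


def _mutate_domain(reference: str, rate: float, rng: np.random.Generator) -> str:
    """Point mutations only (no indels), leaving the anchoring gapless."""
    dom = list(reference)
    for i in range(len(dom)):
        if rng.random() < rate:
            dom[i] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    return "".join(dom)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(PREFERRED_CODON[aa] for aa in protein)


def generate_gene_models(spec: LocusSpec) -> LocusBundle:
    """Loci whose domain-region introns sit at the planted catalog slots.

    Each locus gets its own contig; strands alternate so both orientations
    are exercised. A slot at canonical column c with phase 0 puts the
    junction after domain codon c; phase 1 interrupts codon c after its
    first nucleotide.
    """
    catalog = spec.catalog or default_catalog()
    entries = {e.label: e for e in catalog.entries}
    rng = np.random.default_rng(spec.seed)
    gff_lines = ["##gff-version 3"]
    genome_recs, cds_recs, prot_recs = [], [], []
    domain_ranges: dict[str, tuple[int, int]] = {}
    rows: list[dict] = []
    i = 0
    for label, count in spec.pattern_counts.items():
        if label not in entries:
            raise ValueError(f"pattern {label} not in catalog")
        slots = entries[label].slots
        for col, _phase in slots:
            if not 1 <= col <= 60:
                raise ValueError(f"slot column {col} outside the domain")
        for _ in range(count):
            i += 1
            gene = f"{spec.id_prefix}{i:04d}"
            contig = f"ctg{i:04d}"
            strand = "+" if i % 2 else "-"
            lo, hi = spec.flank_aa_range
            n_len = int(rng.integers(lo, hi + 1))
            c_len = int(rng.integers(lo, hi + 1))
            rand_aa = lambda n: "".join(
                AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=n)
            )
            domain = _mutate_domain(
                DEFAULT_REFERENCE_DOMAIN, spec.substitution_rate, rng
            )
            protein = rand_aa(n_len) + domain + rand_aa(c_len)
            cds = _reverse_translate(protein, rng)
            # coding-nucleotide offsets of the planted junctions, 5'->3'
            cuts = sorted(
                n_len * 3 + (col * 3 if phase == 0 else (col - 1) * 3 + 1)
                for col, phase in slots
            )
            pieces = []
            prev = 0
            for cut in cuts:
                pieces.append(cds[prev:cut])
                prev = cut
            pieces.append(cds[prev:])
            intron = lambda: "GT" + "".join(
                BASES[k] for k in rng.integers(4, size=spec.intron_length - 4)
            ) + "AG"
            pad5 = "".join(BASES[k] for k in rng.integers(4, size=int(rng.integers(50, 151))))
            pad3 = "".join(BASES[k] for k in rng.integers(4, size=int(rng.integers(50, 151))))
            contig_seq = pad5
            exon_coords: list[tuple[int, int]] = []  # 0-based half-open, + sense
            pos = len(pad5)
            for k, piece in enumerate(pieces):
                exon_coords.append((pos, pos + len(piece)))
                contig_seq += piece
                pos += len(piece)
                if k < len(pieces) - 1:
                    ivs = intron()
                    contig_seq += ivs
                    pos += len(ivs)
            contig_seq += pad3
            if strand == "-":
                L = len(contig_seq)
                contig_seq = str(Seq(contig_seq).reverse_complement())
                exon_coords = [(L - e, L - s) for s, e in exon_coords][::-1]
            gene_start = min(s for s, _ in exon_coords)
            gene_end = max(e for _, e in exon_coords)
            # GFF3 is 1-based inclusive
            gff_lines.append(
                f"{contig}\tsynth\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\tID={gene}"
            )
            mrna = f"{gene}.t1"
            gff_lines.append(
                f"{contig}\tsynth\tmRNA\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t"
                f"ID={mrna};Parent={gene};protein_id={gene}.p1"
            )
            for s, e in exon_coords:
                gff_lines.append(
                    f"{contig}\tsynth\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={mrna}"
                )
            for s, e in exon_coords:
                gff_lines.append(
                    f"{contig}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={mrna}"
                )
            genome_recs.append((contig, "", contig_seq))
            cds_recs.append((mrna, "", cds))
            prot_recs.append((f"{gene}.p1", "", protein))
            domain_ranges[f"{gene}.p1"] = (n_len + 1, n_len + 60)
            rows.append({"gene_id": gene, "pattern": label, "strand": strand})
    return LocusBundle(
        gff3="\n".join(gff_lines) + "\n",
        genome=SequenceSet(genome_recs, alphabet="dna"),
        cds=SequenceSet(cds_recs, alphabet="dna"),
        proteins=SequenceSet(prot_recs, alphabet="protein"),
        domain_ranges=domain_ranges,
        truth=pd.DataFrame(rows, columns=["gene_id", "pattern", "strand"]),
    )


# ---------------------------------------------------------------------------
# Diverged subgenome pairs


@dataclass
class SubgenomeBundle:
    set_a: list[GeneRecord]
    set_b: list[GeneRecord]
    truth_pairs: pd.DataFrame  # aa_gene, bb_gene, syntenic


def _random_protein(n_aa: int, rng: np.random.Generator) -> str:
    return "M" + "".join(
        AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=n_aa - 1)
    )


def _codon_mutate(
    codons: list[str], divergence: float, rng: np.random.Generator,
    synonymous_bias: float = 0.5,
) -> list[str]:
    """Codon-level mutation with a synonymous bias, so CDS identity stays
    above what the protein divergence alone would suggest."""
    out = []
    for codon in codons:
        if rng.random() < min(1.0, 3.0 * divergence):
            aa = _STANDARD.forward_table.get(codon)
            syn = [c for c in CODONS_OF.get(aa, []) if c != codon]
            if syn and rng.random() < synonymous_bias:
                codon = syn[rng.integers(len(syn))]
            else:
                new_aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
                codon = CODONS_OF[new_aa][rng.integers(len(CODONS_OF[new_aa]))]
        out.append(codon)
    return out


def generate_subgenome_pair(
    n_pairs: int,
    divergence: float = 0.05,
    n_decoys: int = 10,
    n_cross_chromosome: int = 0,
    n_aa: int = 100,
    seed: int = 0,
) -> SubgenomeBundle:
    """Paired gene sets at controlled divergence plus unrelated decoys.

    The first ``n_cross_chromosome`` true pairs land on different
    chromosome numbers (non-syntenic); the rest are syntenic. Decoy genes
    are independent random sequences on both sides.
    """
    rng = np.random.default_rng(seed)
    set_a: list[GeneRecord] = []
    set_b: list[GeneRecord] = []
    rows: list[dict] = []
    for i in range(n_pairs):
        prot_a = _random_protein(n_aa, rng)
        codons_a = [PREFERRED_CODON[aa] for aa in prot_a]
        codons_b = _codon_mutate(codons_a, divergence, rng)
        cds_a = "".join(codons_a)
        cds_b = "".join(codons_b)
        prot_b = str(Seq(cds_b).translate())
        chrom_num = i % 10 + 1
        a_chrom = f"A{chrom_num:02d}"
        if i < n_cross_chromosome:
            b_chrom = f"B{(chrom_num % 10) + 1:02d}"
        else:
            b_chrom = f"B{chrom_num:02d}"
        a_id, b_id = f"genA{i + 1:04d}", f"genB{i + 1:04d}"
        start = 10_000 * (i + 1)
        set_a.append(GeneRecord(a_id, cds_a, prot_a, a_chrom, start, start + len(cds_a)))
        set_b.append(GeneRecord(b_id, cds_b, prot_b, b_chrom, start, start + len(cds_b)))
        rows.append(
            {"aa_gene": a_id, "bb_gene": b_id, "syntenic": i >= n_cross_chromosome}
        )
    for i in range(n_decoys):
        for prefix, records, chrom_letter in (
            ("decA", set_a, "A"),
            ("decB", set_b, "B"),
        ):
            prot = _random_protein(n_aa, rng)
            cds = "".join(PREFERRED_CODON[aa] for aa in prot)
            records.append(
                GeneRecord(
                    f"{prefix}{i + 1:04d}",
                    cds,
                    prot,
                    f"{chrom_letter}{i % 10 + 1:02d}",
                    500_000 + 10_000 * i,
                    500_000 + 10_000 * i + len(cds),
                )
            )
    return SubgenomeBundle(
        set_a=set_a,
        set_b=set_b,
        truth_pairs=pd.DataFrame(rows, columns=["aa_gene", "bb_gene", "syntenic"]),
    )


# ---------------------------------------------------------------------------
# Planted expression classes

TISSUES = ["root", "stem", "leaf", "flower", "peg", "pericarp", "seed", "nodule"]
STAGES = ["S1", "S2", "S3", "S4", "S5", "S6"]
STAGE_REPS = [2, 2, 2, 2, 3, 3]  # 14 stage samples + 8 tissue samples = 22

#: default tissue allocation of the planted tissue-specific genes
SPECIFIC_ALLOCATION = {
    "leaf": 3, "flower": 5, "root": 2, "nodule": 5, "pericarp": 1, "seed": 6,
}


@dataclass
class ExpressionBundle:
    matrix: ExpressionMatrix
    truth_expressed: set[str]
    truth_specific: dict[str, str]  # gene -> tissue
    truth_trends: dict[str, str]  # gene -> increasing | decreasing

    def to_files(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.matrix.rpkm.round(4).to_csv(
            os.path.join(directory, "rpkm.tsv"), sep="\t"
        )
        with open(os.path.join(directory, "groups.tsv"), "wt") as fh:
            fh.write("sample\ttissue\tstage_order\n")
            for s in self.matrix.samples:
                tissue = self.matrix.tissue_of[s]
                order = (
                    str(STAGES.index(tissue) + 1) if tissue in STAGES else ""
                )
                fh.write(f"{s}\t{tissue}\t{order}\n")


def generate_expression(
    n_genes: int = 132,
    n_expressed: int = 99,
    specific_allocation: dict[str, int] | None = None,
    n_increasing: int = 8,
    n_decreasing: int = 8,
    noise_sigma: float = 0.15,
    seed: int = 0,
    id_prefix: str = "gene",
) -> ExpressionBundle:
    """An RPKM matrix over 22 samples (8 tissues + 6 staged gynophore
    groups) with planted expressed / tissue-specific / stage-trend genes.

    Log-normal multiplicative noise (sigma on the natural-log scale) is
    applied everywhere. Construction keeps the planted classes separated
    from the rule boundaries by design: silent genes peak below ~0.8 RPKM
    against a threshold of 2; specific genes sit ~25-fold over other
    tissues against a 2-fold rule; trend genes double per stage with
    near-peak expression in non-stage tissues so they cannot double as
    tissue-specific calls.
    """
    allocation = specific_allocation or dict(SPECIFIC_ALLOCATION)
    n_specific = sum(allocation.values())
    n_trend = n_increasing + n_decreasing
    if n_specific + n_trend > n_expressed:
        raise ValueError("planted classes exceed the expressed gene budget")
    if n_expressed > n_genes:
        raise ValueError("more expressed genes than genes")
    rng = np.random.default_rng(seed)

    samples: list[str] = [f"{t}_1" for t in TISSUES]
    tissue_of: dict[str, str] = {f"{t}_1": t for t in TISSUES}
    for stage, reps in zip(STAGES, STAGE_REPS):
        for r in range(1, reps + 1):
            samples.append(f"{stage}_{r}")
            tissue_of[f"{stage}_{r}"] = stage
    genes = [f"{id_prefix}{i + 1:04d}" for i in range(n_genes)]

    specific_genes: dict[str, str] = {}
    gi = 0
    for tissue, count in allocation.items():
        for _ in range(count):
            specific_genes[genes[gi]] = tissue
            gi += 1
    trend_genes: dict[str, str] = {}
    for _ in range(n_increasing):
        trend_genes[genes[gi]] = "increasing"
        gi += 1
    for _ in range(n_decreasing):
        trend_genes[genes[gi]] = "decreasing"
        gi += 1
    plain_expressed = set(genes[gi:n_expressed])
    expressed = set(genes[:n_expressed])

    base = np.zeros((n_genes, len(samples)))
    stage_of = {s: tissue_of[s] for s in samples if tissue_of[s] in STAGES}
    for row, gene in enumerate(genes):
        if gene in specific_genes:
            target = specific_genes[gene]
            for col, s in enumerate(samples):
                base[row, col] = 30.0 if tissue_of[s] == target else 1.2
        elif gene in trend_genes:
            levels = [2.5 * 2.0 ** k for k in range(len(STAGES))]
            if trend_genes[gene] == "decreasing":
                levels = levels[::-1]
            peak = max(levels)
            for col, s in enumerate(samples):
                if s in stage_of:
                    base[row, col] = levels[STAGES.index(stage_of[s])]
                else:
                    base[row, col] = 0.8 * peak
        elif gene in plain_expressed:
            level = float(rng.uniform(4.0, 40.0))
            base[row, :] = level
        else:
            level = float(rng.uniform(0.05, 0.8))
            base[row, :] = level
    noise = np.exp(rng.normal(0.0, noise_sigma, size=base.shape))
    rpkm = pd.DataFrame(base * noise, index=genes, columns=samples)
    matrix = ExpressionMatrix(
        rpkm=rpkm, tissue_of=tissue_of, stage_order=list(STAGES)
    )
    return ExpressionBundle(
        matrix=matrix,
        truth_expressed=expressed,
        truth_specific=specific_genes,
        truth_trends=trend_genes,
    )


# ---------------------------------------------------------------------------
# Subfamily-structured alignments


def generate_subfamily_alignment(
    n_subfamilies: int = 5,
    members_per_subfamily: int = 4,
    block_columns: int = 12,
    seed: int = 0,
) -> tuple[list[str], list[str], dict[str, int]]:
    """A gap-free protein alignment with subfamily-specific column blocks.

    Column block g carries a residue unique to subfamily g (everyone else
    shares the background residue there), and every member additionally
    owns one private diagnostic column. The design is exactly symmetric:
    all between-subfamily member distances are equal and all
    within-subfamily distances are equal, so the only consistent signal
    across bootstrap replicates is the n_subfamilies clades themselves —
    any grouping above them is a resampling accident whose support stays
    far below 50%. (Member-level noise is deliberately avoided: under
    column resampling even one coincidental residue match between two
    subfamilies re-appears in every replicate and can push a spurious
    super-clade past 50%.) Returns (ids, aligned rows, truth subfamily
    index per id).
    """
    rng = np.random.default_rng(seed)
    n_members = n_subfamilies * members_per_subfamily
    L = n_subfamilies * block_columns + n_members
    background = [AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=L)]

    def non_background(col: int) -> str:
        choices = [a for a in AMINO_ACIDS if a != background[col]]
        return choices[rng.integers(len(choices))]

    marker = [
        [non_background(g * block_columns + j) for j in range(block_columns)]
        for g in range(n_subfamilies)
    ]
    private_base = n_subfamilies * block_columns
    private = [non_background(private_base + m) for m in range(n_members)]
    ids: list[str] = []
    rows: list[str] = []
    truth: dict[str, int] = {}
    idx = 0
    for g in range(n_subfamilies):
        for m in range(members_per_subfamily):
            name = f"fam{g + 1}_{m + 1}"
            seq = list(background)
            for j in range(block_columns):
                seq[g * block_columns + j] = marker[g][j]
            seq[private_base + idx] = private[idx]
            ids.append(name)
            rows.append("".join(seq))
            truth[name] = g
            idx += 1
    return ids, rows, truth
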