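"""Genome and annotation I/O.

Reads and writes GenBank flat files and FASTA, extracts proteomes, and
provides a naive ORF caller for unannotated sequences.  Coordinates are
0-based half-open internally; GenBank files use the usual 1-based
inclusive convention at the I/O boundary.

Circular replicons may carry a single CDS spanning the origin; such
records are flagged ``wraparound`` and their ``end`` coordinate refers to
the position after wrapping (``end < start``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

TRANSLATION_TABLE = 11

_DNA_ALPHABET = set("ACGTN")

# table 11 start/stop codons used by the naive ORF caller
_START_CODONS = ("ATG", "GTG", "TTG")
_STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeParseError(ValueError):
    """Raised when a genome record cannot be parsed."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, where: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise GenomeParseError(
            f"{where} contains unsupported characters {sorted(bad)}; "
            "only A, C, G, T and N are accepted"
        )
    return seq


@dataclass
class GeneRecord:
    """A CDS annotation on a genome."""

    gene_id: str
    genome_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive; < start only when wraparound
    strand: str  # '+' or '-'
    product: str = ""
    protein: str = ""
    wraparound: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraparound and not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )

    def nucleotide_span(self, genome_length: int) -> int:
        if self.wraparound:
            return genome_length - self.start + self.end
        return self.end - self.start

    def extract(self, sequence: str) -> str:
        """CDS nucleotide sequence in coding orientation."""
        if self.wraparound:
            nt = sequence[self.start :] + sequence[: self.end]
        else:
            nt = sequence[self.start : self.end]
        return revcomp(nt) if self.strand == "-" else nt


@dataclass
class Genome:
    """A virus or host replicon with sequence, topology and annotations."""

    id: str
    sequence: str
    name: str = ""
    topology: str = "linear"
    genes: list[GeneRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence, f"genome {self.id}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        for g in self.genes:
            hi = max(g.start, g.end if not g.wraparound else g.start)
            if not (0 <= g.start < len(self.sequence)) or hi > len(self.sequence):
                raise ValueError(
                    f"gene {g.gene_id} coordinates outside genome {self.id}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


def translate_cds(nt: str, table: int = TRANSLATION_TABLE) -> str:
    """Translate a coding sequence, trimming the trailing stop if present."""
    # tolerate a dangling partial codon at the end
    nt = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


# ---------------------------------------------------------------------------
# GenBank


def _feature_to_gene(feat: SeqFeature, genome: Genome, idx: int) -> GeneRecord | None:
    loc = feat.location
    wraparound = False
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join on a circular genome: a part ending at L and
        # a part starting at 0, same strand
        if (
            len(parts) == 2
            and int(parts[-1].end) == genome.length
            and int(parts[0].start) == 0
            and genome.topology == "circular"
        ):
            wraparound = True
            start = int(parts[-1].start)
            end = int(parts[0].end)
        else:
            start, end = int(loc.start), int(loc.end)
    else:
        start, end = int(loc.start), int(loc.end)
    strand = "-" if loc.strand == -1 else "+"

    gene_id = (
        feat.qualifiers.get("locus_tag", [None])[0]
        or feat.qualifiers.get("gene", [None])[0]
        or f"cds{idx:04d}"
    )
    product = feat.qualifiers.get("product", [""])[0]
    rec = GeneRecord(
        gene_id=gene_id,
        genome_id=genome.id,
        start=start,
        end=end,
        strand=strand,
        product=product,
        wraparound=wraparound,
    )
    protein = feat.qualifiers.get("translation", [None])[0]
    if protein is None:
        nt = rec.extract(genome.sequence)
        if len(nt) < 3:
            warnings.warn(f"CDS {gene_id} too short to translate; skipped")
            return None
        protein = translate_cds(nt)
    if not protein:
        warnings.warn(f"CDS {gene_id} has no resolvable protein; skipped")
        return None
    rec.protein = protein
    return rec


def read_genbank(path: str | Path) -> list[Genome]:
    """Parse a (possibly multi-record) GenBank flat file into Genomes."""
    genomes: list[Genome] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeParseError(f"malformed GenBank file {path}: {exc}") from exc
    for rec in records:
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        genome = Genome(
            id=rec.id if rec.id != "<unknown id>" else rec.name,
            sequence=str(rec.seq),
            name=rec.description,
            topology=topology,
        )
        if genome.id in seen:
            raise GenomeParseError(f"duplicate genome id {genome.id!r} in {path}")
        seen.add(genome.id)
        idx = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            idx += 1
            try:
                gene = _feature_to_gene(feat, genome, idx)
            except (ValueError, KeyError) as exc:
                raise GenomeParseError(
                    f"malformed CDS feature #{idx} in locus {genome.id}: {exc}"
                ) from exc
            if gene is not None:
                genome.genes.append(gene)
        genomes.append(genome)
    return genomes


def write_genbank(genomes: Iterable[Genome], path: str | Path) -> None:
    records = []
    for g in genomes:
        rec = SeqRecord(
            Seq(g.sequence),
            id=g.id,
            name=g.id[:16].replace("|", "_"),
            description=g.name or g.id,
            annotations={"molecule_type": "DNA", "topology": g.topology},
        )
        for gene in g.genes:
            strand = -1 if gene.strand == "-" else 1
            if gene.wraparound:
                p1 = SimpleLocation(gene.start, g.length, strand)
                p2 = SimpleLocation(0, gene.end, strand)
                loc = CompoundLocation([p1, p2] if strand == 1 else [p2, p1])
            else:
                loc = SimpleLocation(gene.start, gene.end, strand)
            feat = SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "locus_tag": [gene.gene_id],
                    "product": [gene.product or "hypothetical protein"],
                    "transl_table": [str(TRANSLATION_TABLE)],
                    "translation": [gene.protein],
                },
            )
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_genomes(path: str | Path, topology: str = "linear") -> list[Genome]:
    return [Genome(id=n, sequence=s, topology=topology) for n, s in read_fasta(path)]


# ---------------------------------------------------------------------------
# ORF calling


def call_orfs(sequence: str, min_aa: int = 50, genome_id: str = "seq") -> list[GeneRecord]:
    """All maximal ORFs (table 11 starts, both strands) of >= min_aa residues.

    Within each reading frame, one ORF per stop-to-stop interval: the first
    start codon after the previous stop opens the ORF (ORFs are therefore
    non-nested per frame).  Coordinates refer to the forward strand and
    include the stop codon.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    sequence = validate_dna(sequence)
    n = len(sequence)
    orfs: list[GeneRecord] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for frame in range(3):
            start_of_orf: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                if start_of_orf is None:
                    if codon in _START_CODONS:
                        start_of_orf = pos
                elif codon in _STOP_CODONS:
                    aa_len = (pos - start_of_orf) // 3
                    if aa_len >= min_aa:
                        s, e = start_of_orf, pos + 3
                        if strand == "-":
                            s, e = n - e, n - s
                        nt = seq[start_of_orf : pos + 3]
                        orfs.append(
                            GeneRecord(
                                gene_id="",
                                genome_id=genome_id,
                                start=s,
                                end=e,
                                strand=strand,
                                protein=translate_cds(nt),
                            )
                        )
                    start_of_orf = None
    orfs.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, g in enumerate(orfs, start=1):
        g.gene_id = f"orf{i:04d}"
    return orfs


# ---------------------------------------------------------------------------
# Proteome extraction


def extract_proteome(genome: Genome) -> list[tuple[str, str]]:
    """(protein_id, sequence) pairs in coordinate order; ids genomeId|geneId."""
    out: list[tuple[str, str]] = []
    used: set[str] = set()
    for gene in sorted(genome.genes, key=lambda g: (g.start, g.end)):
        if not gene.protein:
            continue
        pid = f"{genome.id}|{gene.gene_id}"
        if pid in used:
            k = 2
            while f"{pid}.{k}" in used:
                k += 1
            logger.warning("duplicate gene id %s; suffixed .%d", pid, k)
            pid = f"{pid}.{k}"
        used.add(pid)
        out.append((pid, gene.protein))
    return out


def write_proteome_fasta(genome: Genome, path: str | Path) -> None:
    write_fasta(extract_proteome(genome), path)
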