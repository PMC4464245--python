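"""Genome I/O and assembly QC arithmetic.

Reads and writes FASTA and a GFF3 subset, provides coordinate-safe CDS
extraction and translation under the yeast mitochondrial genetic code
(NCBI translation table 3), GC content, contig end-overlap detection for
circularity checks, and the qPCR mtDNA enrichment ratio.

Coordinate conventions: all intervals are 0-based half-open internally;
GFF3 is 1-based inclusive at the file boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

FEATURE_KINDS = {"gene", "exon", "intron", "tRNA", "GC_cluster", "ori"}

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Contract violation in a genome, feature set or numeric input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated interval on a genome.

    ``start``/``end`` are 0-based half-open. ``gene_name`` groups exons and
    introns belonging to the same gene.
    """

    kind: str
    gene_name: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval ({self.start}, {self.end}) for {self.gene_name}"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """One strain's mtDNA sequence plus feature table and circularity flag."""

    strain_id: str
    sequence: str
    circular: bool = False
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"{self.strain_id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"{self.strain_id}: illegal characters {sorted(bad)}"
            )
        self.validate_features()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"{self.strain_id}: feature {f.gene_name} [{f.start},{f.end}) "
                    f"outside genome of length {n}"
                )
        # exons of one gene: non-overlapping, consistently stranded
        for gene in {f.gene_name for f in self.features if f.kind == "exon"}:
            exons = sorted(self.exons(gene), key=lambda f: f.start)
            strands = {e.strand for e in exons}
            if len(strands) > 1:
                raise ValidationError(f"{self.strain_id}: {gene} exons on mixed strands")
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValidationError(f"{self.strain_id}: {gene} exons overlap")
        # introns nest within their gene's span
        gene_spans = {
            f.gene_name: (f.start, f.end) for f in self.features if f.kind == "gene"
        }
        for f in self.features:
            if f.kind == "intron" and f.gene_name in gene_spans:
                gs, ge = gene_spans[f.gene_name]
                if f.start < gs or f.end > ge:
                    raise ValidationError(
                        f"{self.strain_id}: intron of {f.gene_name} not nested in gene span"
                    )

    def gene_names(self) -> list:
        return [f.gene_name for f in self.features if f.kind == "gene"]

    def features_for(self, gene_name: str, kind: Optional[str] = None) -> list:
        return [
            f
            for f in self.features
            if f.gene_name == gene_name and (kind is None or f.kind == kind)
        ]

    def exons(self, gene_name: str) -> list:
        return self.features_for(gene_name, "exon")

    def introns(self, gene_name: str) -> list:
        return self.features_for(gene_name, "intron")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "ACGTN") -> list:
    """Read a FASTA file into a list of ``(id, sequence)`` tuples.

    Sequences are uppercased; characters outside ``alphabet`` raise
    :class:`ParseError` rather than being silently masked. An empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    records = []
    allowed = set(alphabet)
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - allowed
            if bad:
                raise ParseError(
                    f"{path}: record {rec.id!r} contains illegal characters "
                    f"{sorted(bad)}"
                )
            records.append((rec.id, seq))
    except ValueError as e:
        if isinstance(e, ParseError):
            raise
        raise ParseError(f"{path}: {e}") from e
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable, path, wrap: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3 subset


def write_gff3(genome: AnnotatedGenome, path) -> None:
    """Write the genome's feature table as GFF3 (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"##sequence-region {genome.strain_id} 1 {len(genome.sequence)}\n"
        )
        if genome.circular:
            fh.write(f"##circular {genome.strain_id}\n")
        for f in sorted(genome.features, key=lambda f: (f.start, f.end, f.kind)):
            attrs = [f"gene={f.gene_name}"]
            for k, v in sorted(f.attributes.items()):
                attrs.append(f"{k}={v}")
            fh.write(
                "\t".join(
                    [
                        genome.strain_id,
                        "mitopop",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> dict:
    """Read the GFF3 subset written by :func:`write_gff3`.

    Returns ``{seqid: (features, circular)}`` with features converted to
    0-based half-open coordinates.
    """
    path = Path(path)
    out: dict = {}
    circular: set = set()
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ParseError(f"{path}:1: missing ##gff-version pragma")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##circular"):
                    parts = line.split()
                    if len(parts) > 1:
                        circular.add(parts[1])
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, kind, start, end, _score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if kind not in FEATURE_KINDS:
                raise ParseError(f"{path}:{lineno}: unknown feature type {kind!r}")
            attributes = {}
            gene_name = ""
            for item in attrs.split(";"):
                if not item:
                    continue
                k, _, v = item.partition("=")
                if k == "gene":
                    gene_name = v
                else:
                    attributes[k] = v
            feat = Feature(kind, gene_name, start_i - 1, end_i, strand, attributes)
            out.setdefault(seqid, []).append(feat)
    for seqid in out:
        out[seqid] = (sorted(out[seqid], key=lambda f: f.start), seqid in circular)
    return out


def read_annotated_genome(fasta_path, gff_path) -> AnnotatedGenome:
    """Assemble an :class:`AnnotatedGenome` from a FASTA + GFF3 pair."""
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ParseError(f"{fasta_path}: expected exactly one record")
    strain_id, seq = records[0]
    table = read_gff3(gff_path)
    feats, circ = table.get(strain_id, ([], False))
    return AnnotatedGenome(strain_id, seq, circular=circ, features=feats)


# ---------------------------------------------------------------------------
# CDS extraction and translation


def extract_cds(genome: AnnotatedGenome, gene_name: str) -> str:
    """Splice a gene's exons into its coding sequence.

    Exons are concatenated in transcription order; minus-strand genes are
    reverse complemented. Raises ``KeyError`` for a missing gene and
    :class:`ValidationError` when a CDS marked complete is out of frame.
    """
    exons = sorted(genome.exons(gene_name), key=lambda f: f.start)
    if not exons:
        raise KeyError(f"{genome.strain_id}: no exons for gene {gene_name!r}")
    spliced = "".join(genome.sequence[e.start : e.end] for e in exons)
    if exons[0].strand == "-":
        spliced = reverse_complement(spliced)
    gene_feats = genome.features_for(gene_name, "gene")
    complete = any(f.attributes.get("complete") in ("1", "true", True) for f in gene_feats)
    if complete and len(spliced) % 3 != 0:
        raise ValidationError(
            f"{genome.strain_id}: complete CDS {gene_name} length {len(spliced)} "
            "not divisible by 3"
        )
    return spliced


def translate_mito(cds: str, complete: bool = False) -> str:
    """Translate a CDS under the yeast mitochondrial code (table 3).

    Table 3 departs from the standard code at ATA (Met), TGA (Trp) and the
    CTN box (Thr). With ``complete=True`` an internal stop raises
    :class:`ValidationError`.
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate(table=3))
    if complete and "*" in protein[:-1]:
        raise ValidationError("internal stop codon in complete CDS")
    return protein


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from the denominator."""
    if not sequence:
        raise ValidationError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    return gc / denom


# ---------------------------------------------------------------------------
# Assembly QC: end overlaps / circularity


@dataclass
class OverlapReport:
    length: int
    matches: int
    identity: float


def _overlap_match_counts(a: str, b: str) -> np.ndarray:
    """matches[L] = number of equal positions between suffix(a, L) and prefix(b, L).

    Computed for all L in one pass with FFT cross-correlation over one-hot
    base channels (N never matches).
    """
    na, nb = len(a), len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    total = np.zeros(na + nb - 1)
    for base in b"ACGT":
        x = (aa == base).astype(float)
        y = (bb == base).astype(float)
        total += fftconvolve(x, y[::-1])
    max_l = min(na, nb)
    # conv index for overlap length L is nb - 1 + na - L
    idx = nb - 1 + na - np.arange(1, max_l + 1)
    counts = np.rint(total[idx]).astype(int)
    out = np.zeros(max_l + 1, dtype=int)
    out[1:] = counts
    return out


def find_end_overlap(
    contig_a: str,
    contig_b: str,
    min_len: int = 360,
    min_identity: float = 0.80,
    max_len: Optional[int] = None,
) -> Optional[OverlapReport]:
    """Longest suffix(a)/prefix(b) ungapped overlap meeting the thresholds.

    Returns ``None`` when no overlap qualifies (a valid result, not an
    error). Used both for joining contigs and, via
    :func:`check_circularity`, for detecting circular genomes.
    """
    a, b = contig_a.upper(), contig_b.upper()
    if min(len(a), len(b)) < min_len:
        return None
    counts = _overlap_match_counts(a, b)
    hi = len(counts) - 1 if max_len is None else min(max_len, len(counts) - 1)
    best = None
    for L in range(min_len, hi + 1):
        identity = counts[L] / L
        if identity >= min_identity:
            key = (int(counts[L]), identity)
            if best is None or key > best[0]:
                best = (key, L)
    if best is None:
        return None
    (matches, identity), L = best
    return OverlapReport(length=L, matches=matches, identity=identity)


def check_circularity(
    sequence: str, min_len: int = 360, min_identity: float = 0.80
) -> Optional[OverlapReport]:
    """Self end-overlap check: suffix vs prefix, capped at half the length."""
    return find_end_overlap(
        sequence, sequence, min_len=min_len, min_identity=min_identity,
        max_len=len(sequence) // 2,
    )


# ---------------------------------------------------------------------------
# qPCR enrichment


@dataclass
class EnrichmentInput:
    """Cycle thresholds for the mitochondrial (cox1) and nuclear (ACT1)
    amplicons plus the two genome sizes in bp."""

    ct_mt: float
    ct_nuc: float
    size_mt: float
    size_nuc: float

    def __post_init__(self):
        if min(self.ct_mt, self.ct_nuc, self.size_mt, self.size_nuc) <= 0:
            raise ValidationError("all enrichment inputs must be positive")


def enrichment_ratio(x: EnrichmentInput) -> float:
    """mtDNA copies per nuclear genome copy.

    ratio = 2**(ct_nuc - ct_mt) * (size_nuc / size_mt): the CT difference
    gives the relative template abundance in log2 units, then the per-bp
    abundance is corrected to per-genome-copy by the size ratio.
    """
    return 2.0 ** (x.ct_nuc - x.ct_mt) * (x.size_nuc / x.size_mt)
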