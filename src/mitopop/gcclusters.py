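"""Mobile GC-cluster detection, classification, and population statistics.

Yeast mtDNA is ~84 % AT, interspersed with short (30-80 bp) GC-rich mobile
elements ("GC clusters") that fall into consensus families
(M1, M1', M2, M2', M2'', M3, M4, G, V). This module scans genomes for
GC-rich regions with a sliding window, classifies them against a
configurable table of degenerate (IUPAC) class consensi by semi-global
alignment, calls tandem arrays and unclassified regions, builds
per-strain count tables, tests per-class population effects with one-way
ANOVA, finds positions conserved across a multiple alignment, analyzes
M4-M1 pairing, and runs canonical k-mer repeat scans.

The shipped consensus table is a synthetic placeholder set: the
historical class consensi are not reproduced here, so all class-level
results are defined relative to the configured table. This is what makes
planted-truth testing possible - the simulator plants instantiations of
the same configured consensi that the scanner is asked to recover.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import AnnotatedGenome, ValidationError, reverse_complement

logger = logging.getLogger(__name__)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

CLASS_LABELS = ("M1", "M1'", "M2", "M2'", "M2''", "M3", "M4", "G", "V")

# Placeholder class consensi (synthetic, editable via ConsensusTable).
DEFAULT_CONSENSI = {
    "M1": "CCGGGGRCGTCSGCCCCCGGACGGCGGCTTTSCGCGATGGCGCGCC",
    "M1'": "TGSCCCGGATSCTGGGAGCCCCTTRTTGGCCCCCCCGTCGTCCCCGGTTGGA",
    "M2": "GCCCRAGCTCGSTGTRAGCCGCGCCCCGCGGGGCACCG",
    "M2'": "CTACGCCGACCTGRCGRCGGTCGCGCCGGCCGCYGCGAGGGCTG",
    "M2''": "CGAAGCGGCGGACTCCTCCCAGGCTYCACSSTGGCCACCC",
    "M3": "GGCGCACCGTCGGCACGGCGGCYGTTSCGRCACACA",
    "M4": "TCCCCCCTACRGCACRCTASCGGTCCTCTTGAG",
    # G is optionally found near ori elements, V only inside rps3 (in frame:
    # length divisible by 3, no stop codon in any instantiation).
    "G": "GGGCGCGGGGGCCGGCGTGGGACCTGCGCAGTGGCYACCGSACGSTAGGG",
    "V": "GACTCCRACYCCGCCGCTCCTRGGACCGCGGCCTCGGTGCCCACCCTC",
}


@dataclass
class ConsensusEntry:
    label: str
    consensus: str
    min_identity: float = 0.80
    min_coverage: float = 0.80

    def __post_init__(self):
        self.consensus = self.consensus.upper()
        bad = set(self.consensus) - set(IUPAC_SETS)
        if bad:
            raise ValidationError(f"{self.label}: non-IUPAC characters {sorted(bad)}")
        if not 20 <= len(self.consensus) <= 120:
            raise ValidationError(
                f"{self.label}: consensus length {len(self.consensus)} outside [20, 120]"
            )
        for thr in (self.min_identity, self.min_coverage):
            if not 0 < thr <= 1:
                raise ValidationError(f"{self.label}: threshold {thr} outside (0, 1]")


@dataclass
class ConsensusTable:
    entries: List[ConsensusEntry]

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate class labels in consensus table")
        if not self.entries:
            raise ValidationError("empty consensus table")

    @property
    def labels(self) -> list:
        return [e.label for e in self.entries]

    def get(self, label: str) -> ConsensusEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            [(e.label, e.consensus, e.min_identity, e.min_coverage) for e in self.entries],
            columns=["class", "consensus", "min_identity", "min_coverage"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConsensusTable":
        df = pd.read_csv(path, sep="\t")
        return cls([
            ConsensusEntry(r["class"], r.consensus, float(r.min_identity),
                           float(r.min_coverage))
            for r in df.itertuples()
        ])


def default_consensus_table() -> ConsensusTable:
    return ConsensusTable([ConsensusEntry(k, v) for k, v in DEFAULT_CONSENSI.items()])


def instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC codes uniformly at random into a concrete sequence."""
    return "".join(
        c if c in "ACGT" else IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))]
        for c in consensus.upper()
    )


# ---------------------------------------------------------------------------
# GC-rich region scan


@dataclass
class GCRichRegion:
    start: int
    end: int
    gc: float

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


def gc_rich_regions(sequence: str, window: int = 30, gc_threshold: float = 0.60,
                    circular: bool = False) -> list:
    """Maximal regions formed by merging all GC-rich sliding windows.

    Every window of size ``window`` (step 1) whose GC fraction exceeds
    ``gc_threshold`` is marked; overlapping or bookended marked windows
    are merged and per-region GC is recomputed over the merged interval.
    For circular sequences the scan wraps by appending the first
    window-1 bases; a region spanning the origin is reported with
    ``end > len(sequence)``.
    """
    seq = sequence.upper()
    n = len(seq)
    if window > n:
        logger.warning("window %d exceeds sequence length %d", window, n)
        return []
    scan_seq = seq + (seq[: window - 1] if circular else "")
    arr = np.frombuffer(scan_seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(is_gc)])
    n_windows = len(scan_seq) - window + 1
    counts = csum[window:] - csum[:-window]
    marked = np.flatnonzero(counts > gc_threshold * window)
    regions = []
    for start in marked:
        if regions and start <= regions[-1][1]:
            regions[-1][1] = start + window
        else:
            regions.append([int(start), int(start) + window])
    if circular and len(regions) > 1 and regions[0][0] == 0 and regions[-1][1] >= n:
        first = regions.pop(0)
        regions[-1][1] = max(regions[-1][1], first[1] + n)
    out = []
    for s, e in regions:
        gc = float((csum[min(e, len(scan_seq))] - csum[s]) / (min(e, len(scan_seq)) - s))
        out.append(GCRichRegion(s, e, gc))
    return out


# ---------------------------------------------------------------------------
# Classification against degenerate consensi


@dataclass
class GCClusterHit:
    label: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    array_id: Optional[str] = None

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)


_ALPHABET = "ACGTRYSWKMBDHVN"


def _iupac_matrix():
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for q in _ALPHABET:
        for t in _ALPHABET:
            # target characters are concrete bases (or N = unknown)
            if t in "ACGT" and t in IUPAC_SETS[q]:
                m[q, t] = 1.0
            else:
                m[q, t] = -1.0
    return m


_classify_aligner = None


def _get_classify_aligner() -> Align.PairwiseAligner:
    global _classify_aligner
    if _classify_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _iupac_matrix()
        aligner.open_internal_gap_score = -4
        aligner.extend_internal_gap_score = -1
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
        _classify_aligner = aligner
    return _classify_aligner


def _best_consensus_hit(consensus: str, segment: str):
    """Best semi-global placement of an IUPAC consensus in a segment.

    Returns (seg_start, seg_end, identity, coverage) of the best alignment
    or None for an empty segment."""
    if not segment:
        return None
    aligner = _get_classify_aligner()
    try:
        aln = aligner.align(consensus, segment)[0]
    except (IndexError, ValueError):
        return None
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    matches = 0
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        for qc, tc in zip(consensus[q0:q1], segment[t0:t1]):
            if tc in IUPAC_SETS.get(qc, ""):
                matches += 1
    q_span = qblocks[-1][1] - qblocks[0][0]
    t_start, t_end = tblocks[0][0], tblocks[-1][1]
    if q_span == 0:
        return None
    # identity over all internal alignment columns: gap columns (either
    # side) count against identity, so classification is dominated by
    # substitutions rather than gap-stitched partial matches
    aligned_cols = sum(q1 - q0 for q0, q1 in qblocks)
    span = aligned_cols + (q_span - aligned_cols) + (
        (t_end - t_start) - sum(t1 - t0 for t0, t1 in tblocks)
    )
    identity = matches / span
    coverage = q_span / len(consensus)
    return (t_start, t_end, identity, coverage)


def classify_clusters(sequence: str, regions: Sequence[GCRichRegion],
                      table: ConsensusTable, pad: int = 20,
                      max_hits_per_region: int = 8) -> list:
    """Classify GC-rich regions against every class consensus.

    Each region (padded by ``pad`` bp) is searched on both strands with
    every consensus; same-class matches are enumerated iteratively by
    masking previous hits, so tandem copies of one class are all found.
    Overlapping hits of *different* classes are all retained; overlapping
    hits of the same class keep only the best identity.
    """
    if not table.entries:
        raise ValidationError("empty consensus table")
    seq = sequence.upper()
    hits: list = []
    for region in regions:
        seg_start = max(0, region.start - pad)
        seg_end = min(len(seq), region.end + pad)
        segment = seq[seg_start:seg_end]
        for entry in table.entries:
            class_hits = []
            for strand in "+-":
                target = segment if strand == "+" else reverse_complement(segment)
                masked = list(target)
                for _ in range(max_hits_per_region):
                    res = _best_consensus_hit(entry.consensus, "".join(masked))
                    if res is None:
                        break
                    t0, t1, identity, coverage = res
                    if identity < entry.min_identity or coverage < entry.min_coverage:
                        break
                    if strand == "+":
                        s, e = seg_start + t0, seg_start + t1
                    else:
                        s, e = seg_start + len(segment) - t1, seg_start + len(segment) - t0
                    class_hits.append(
                        GCClusterHit(entry.label, s, e, strand, identity, coverage)
                    )
                    for i in range(t0, t1):
                        masked[i] = "N"
            # dedupe overlapping same-class hits (keep best identity)
            class_hits.sort(key=lambda h: (-h.identity, h.start))
            kept: list = []
            for h in class_hits:
                if any(h.start < k.end and k.start < h.end for k in kept):
                    continue
                kept.append(h)
            hits.extend(kept)
    hits.sort(key=lambda h: (h.start, h.end, h.label))
    return hits


def tandem_arrays(regions: Sequence[GCRichRegion], hits: Sequence[GCClusterHit]):
    """GC-rich regions overlapped by >= 2 classified hits become arrays.

    Member hits get an ``array_id``; returns (arrays, n_arrays) where each
    array is a (region, member_hits) pair."""
    arrays = []
    for region in regions:
        members = [h for h in hits if h.start < region.end and region.start < h.end]
        if len(members) >= 2:
            array_id = f"array{len(arrays)}"
            for h in members:
                h.array_id = array_id
            arrays.append((region, members))
    return arrays, len(arrays)


def unclassified_regions(regions: Sequence[GCRichRegion],
                         hits: Sequence[GCClusterHit]) -> list:
    """Regions with zero overlapping classified hits."""
    return [
        r for r in regions
        if not any(h.start < r.end and r.start < h.end for h in hits)
    ]


@dataclass
class ScanResult:
    strain_id: str
    regions: list
    hits: list
    arrays: list
    unclassified: list


def scan_genome(genome: AnnotatedGenome, table: Optional[ConsensusTable] = None,
                window: int = 30, gc_threshold: float = 0.60,
                pad: int = 20) -> ScanResult:
    """Full GC-cluster scan of one genome (wraps for circular genomes)."""
    if table is None:
        table = default_consensus_table()
    regions = gc_rich_regions(genome.sequence, window=window,
                              gc_threshold=gc_threshold, circular=genome.circular)
    # extend the sequence so padded segments of wrapped regions resolve
    seq = genome.sequence
    if genome.circular:
        seq = seq + seq[: max(window, 200)]
    hits = classify_clusters(seq, regions, table, pad=pad)
    arrays, _ = tandem_arrays(regions, hits)
    unclass = unclassified_regions(regions, hits)
    return ScanResult(genome.strain_id, regions, hits, arrays, unclass)


def cluster_count_table(genomes: Iterable[AnnotatedGenome],
                        table: Optional[ConsensusTable] = None,
                        window: int = 30, gc_threshold: float = 0.60,
                        pad: int = 20,
                        scans: Optional[Dict[str, ScanResult]] = None) -> pd.DataFrame:
    """Per-strain counts per class plus unclassified regions, tandem
    arrays, and the total of classifiable hits.

    Pass precomputed ``scans`` to avoid rescanning.
    """
    if table is None:
        table = default_consensus_table()
    rows = []
    index = []
    for genome in genomes:
        if scans is not None and genome.strain_id in scans:
            scan = scans[genome.strain_id]
        else:
            scan = scan_genome(genome, table, window, gc_threshold, pad)
        counts = {label: 0 for label in table.labels}
        for h in scan.hits:
            counts[h.label] += 1
        counts["unclassified"] = len(scan.unclassified)
        counts["tandem_arrays"] = len(scan.arrays)
        counts["total"] = sum(counts[label] for label in table.labels)
        rows.append(counts)
        index.append(genome.strain_id)
    return pd.DataFrame(rows, index=index)


# ---------------------------------------------------------------------------
# Population statistics


@dataclass
class AnovaResult:
    label: str
    F: float
    p: float
    p_bonferroni: float
    group_means: dict


def anova_by_population(counts: pd.DataFrame, populations: Dict[str, str],
                        n_classes_for_bonferroni: Optional[int] = None,
                        columns: Optional[Sequence[str]] = None) -> list:
    """One-way ANOVA (count ~ population) for each cluster class.

    Populations with fewer than 2 strains are excluded with a warning.
    All-identical counts give F = 0, p = 1; zero within-group variance
    with differing means gives F = inf, p = 0. Bonferroni multiplies p by
    the number of classes tested (capped at 1).
    """
    if columns is None:
        columns = [c for c in counts.columns if c != "total"]
    if n_classes_for_bonferroni is None:
        n_classes_for_bonferroni = len(columns)
    labels = pd.Series({s: populations[s] for s in counts.index})
    sizes = labels.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding populations with <2 strains: %s", small)
    keep = labels[~labels.isin(small)]
    if keep.nunique() < 2:
        raise ValidationError("need >= 2 populations with >= 2 strains")
    results = []
    for col in columns:
        groups = [counts.loc[keep[keep == pop].index, col].to_numpy(dtype=float)
                  for pop in sorted(keep.unique())]
        means = {pop: float(np.mean(g))
                 for pop, g in zip(sorted(keep.unique()), groups)}
        values = np.concatenate(groups)
        if np.ptp(values) == 0:
            f_stat, p = 0.0, 1.0
        elif all(np.ptp(g) == 0 for g in groups):
            f_stat, p = np.inf, 0.0
        else:
            f_stat, p = stats.f_oneway(*groups)
            f_stat, p = float(f_stat), float(p)
        results.append(AnovaResult(col, f_stat, p,
                                   min(1.0, p * n_classes_for_bonferroni), means))
    return results


# ---------------------------------------------------------------------------
# Conservation across a multiple alignment


def conserved_positions(alignment, per_genome_regions: Dict[str, Sequence]) -> list:
    """Alignment intervals where every genome has a GC-rich region.

    ``per_genome_regions`` maps each taxon to its regions (objects with
    start/end or plain (start, end) tuples) in that genome's own
    coordinates; they are mapped through the alignment's coordinate maps.
    Maximal runs of fully covered columns are returned as (start, end)
    column intervals.
    """
    covered_all = np.ones(alignment.n_cols, dtype=bool)
    for taxon in alignment.taxa:
        if taxon not in per_genome_regions:
            raise ValidationError(f"no region set for {taxon}")
        glen = len(alignment.ungapped(taxon))
        cov = np.zeros(glen, dtype=bool)
        for r in per_genome_regions[taxon]:
            s, e = (r.start, r.end) if hasattr(r, "start") else r
            cov[s % glen: min(e, glen)] = True
            if e > glen:  # wrapped region on a circular genome
                cov[: e - glen] = True
        pos = alignment.col_to_pos(taxon)
        col_cov = np.zeros(alignment.n_cols, dtype=bool)
        nongap = pos >= 0
        col_cov[nongap] = cov[pos[nongap]]
        covered_all &= col_cov
    out = []
    idx = np.flatnonzero(covered_all)
    for i in idx:
        if out and i == out[-1][1]:
            out[-1][1] = i + 1
        else:
            out.append([int(i), int(i) + 1])
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# M4-M1 pairing


def m4_pairing(hits: Sequence[GCClusterHit], arrays) -> tuple:
    """(n_m4, n_upstream_of_M1, n_downstream_of_M1, n_unpaired).

    Each M4 hit sharing a tandem array with >= 1 M1 hit is oriented
    against the nearest M1 in that array by start coordinate."""
    array_members: dict = {}
    for _, members in arrays:
        for h in members:
            array_members.setdefault(h.array_id, []).append(h)
    m4_hits = [h for h in hits if h.label == "M4"]
    n_up = n_down = n_unpaired = 0
    for h in m4_hits:
        partners = [m for m in array_members.get(h.array_id, [])
                    if m.label == "M1"] if h.array_id else []
        if not partners:
            n_unpaired += 1
            continue
        nearest = min(partners, key=lambda m: abs(m.start - h.start))
        if h.start < nearest.start:
            n_up += 1
        else:
            n_down += 1
    return (len(m4_hits), n_up, n_down, n_unpaired)


# ---------------------------------------------------------------------------
# k-mer repeat scan


def kmer_repeat_scan(sequence: str, k: int, min_count: int = 5) -> list:
    """Exact canonical k-mer counts (lexicographic min of k-mer and its
    reverse complement); entries with count >= min_count, sorted by count
    descending then k-mer."""
    seq = sequence.upper()
    if k > len(seq):
        raise ValidationError(f"k={k} exceeds sequence length {len(seq)}")
    counts: dict = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        canon = min(kmer, reverse_complement(kmer))
        counts[canon] = counts.get(canon, 0) + 1
    out = [(kmer, c, _gc_frac(kmer)) for kmer, c in counts.items() if c >= min_count]
    out.sort(key=lambda x: (-x[1], x[0]))
    return out


def _gc_frac(s: str) -> float:
    gc = s.count("G") + s.count("C")
    return gc / len(s) if s else 0.0


# ---------------------------------------------------------------------------
# Report writers


def write_hits_bed(hits: Sequence[GCClusterHit], strain_id: str, path) -> None:
    """BED6: name = class, score = round(identity * 1000)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{strain_id}\t{h.start}\t{h.end}\t{h.label}\t"
                f"{round(h.identity * 1000)}\t{h.strand}\n"
            )


def write_hits_tsv(scans: Dict[str, ScanResult], path) -> None:
    rows = []
    for strain, scan in scans.items():
        for h in scan.hits:
            rows.append((strain, h.label, h.start + 1, h.end, h.strand,
                         round(h.identity, 4), round(h.coverage, 4),
                         h.array_id or ""))
    pd.DataFrame(rows, columns=["strain", "class", "start", "end", "strand",
                                "identity", "coverage", "array_id"]
                 ).to_csv(path, sep="\t", index=False)


def write_anova_tsv(results: Sequence[AnovaResult], path) -> None:
    rows = [(r.label, r.F, r.p, r.p_bonferroni) for r in results]
    pd.DataFrame(rows, columns=["class", "F", "p", "p_bonferroni"]
                 ).to_csv(path, sep="\t", index=False)
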