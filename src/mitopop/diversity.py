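"""Nucleotide diversity, polymorphism scans, pN/pS, and pairwise indels.

Nucleotide diversity is computed per alignment column by allele-frequency
summation with the unbiased n/(n-1) factor, so it equals the mean number
of pairwise differences per usable site. Gaps are optionally treated as a
fifth allele state (``with_indels``) or dropped (``without_indels``); N is
always dropped. pN/pS uses Nei-Gojobori counting of synonymous and
nonsynonymous sites and polymorphisms under the yeast mitochondrial
genetic code, averaging over minimal mutational paths.
"""
from __future__ import annotations

import itertools
import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Data import CodonTable

from .io import ValidationError, read_fasta, write_fasta

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")

REGION_LABELS = ("exon", "intron", "intergenic", "mixed")


class AlignmentFailure(RuntimeError):
    """No colinear anchor chain could be built between two sequences."""


# ---------------------------------------------------------------------------
# Multiple alignment container


class MultipleAlignment:
    """Aligned sequences plus optional per-column region labels.

    Rows are stored as a (n_taxa, n_cols) uint8 matrix over
    ``{A,C,G,T,N,-}``. Column-to-genome coordinate maps are derived from
    the gap structure on demand.
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str],
                 region_labels: Optional[Sequence[str]] = None):
        if len(taxa) != len(rows):
            raise ValidationError("taxa/rows length mismatch")
        if len(set(taxa)) != len(taxa):
            raise ValidationError("duplicate taxon labels")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValidationError(f"unequal row lengths: {sorted(lengths)}")
        self.taxa = list(taxa)
        if isinstance(rows, np.ndarray):
            self.array = np.asarray(rows, dtype=np.uint8)
        else:
            self.array = np.array(
                [np.frombuffer(r.upper().encode(), dtype=np.uint8) for r in rows]
            )
        allowed = np.frombuffer(b"ACGTN-", dtype=np.uint8)
        if not np.isin(self.array, allowed).all():
            raise ValidationError("alignment rows contain characters outside ACGTN-")
        if region_labels is not None:
            region_labels = np.asarray(region_labels)
            if region_labels.shape[0] != self.n_cols:
                raise ValidationError("region_labels length mismatch")
        self.region_labels = region_labels
        self._col_to_pos: dict = {}

    @property
    def n_taxa(self) -> int:
        return self.array.shape[0]

    @property
    def n_cols(self) -> int:
        return self.array.shape[1]

    def row(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return self.array[i].tobytes().decode()

    def ungapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")

    def column(self, j: int) -> str:
        return self.array[:, j].tobytes().decode()

    def col_to_pos(self, taxon: str) -> np.ndarray:
        """Genome position for each column of ``taxon`` (-1 at gaps)."""
        if taxon not in self._col_to_pos:
            i = self.taxa.index(taxon)
            nongap = self.array[i] != _GAP
            pos = np.cumsum(nongap) - 1
            pos[~nongap] = -1
            self._col_to_pos[taxon] = pos
        return self._col_to_pos[taxon]

    def pos_to_col(self, taxon: str) -> np.ndarray:
        i = self.taxa.index(taxon)
        return np.flatnonzero(self.array[i] != _GAP)

    def to_fasta(self, path) -> None:
        write_fasta(((t, self.row(t)) for t in self.taxa), path)

    @classmethod
    def from_fasta(cls, path, region_labels=None) -> "MultipleAlignment":
        records = read_fasta(path, alphabet="ACGTN-")
        return cls([r[0] for r in records], [r[1] for r in records],
                   region_labels=region_labels)


@dataclass
class DiversityEstimate:
    region: str
    mode: str
    pi: float
    n_sites: int
    n_polymorphic: int


# ---------------------------------------------------------------------------
# Per-site diversity


def _check_mode(mode: str) -> bool:
    if mode not in {"with_indels", "without_indels"}:
        raise ValueError(f"unknown mode {mode!r}")
    return mode == "with_indels"


def site_pi(column, mode: str = "without_indels") -> Optional[float]:
    """Unbiased per-site diversity of one alignment column.

    pi = (n/(n-1)) * (1 - sum_a p_a^2) over usable characters; equals the
    mean pairwise difference. Returns ``None`` (skip marker) when fewer
    than 2 usable characters remain.
    """
    gap_state = _check_mode(mode)
    if not isinstance(column, str):
        column = "".join(column)
    states = "ACGT-" if gap_state else "ACGT"
    counts = np.array([column.upper().count(s) for s in states], dtype=float)
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - (p ** 2).sum()))


def _column_pi_array(arr: np.ndarray, with_indels: bool):
    """Vectorized site_pi over all columns of a (n_taxa, n_cols) matrix.

    Returns (pi per column with NaN where skipped, polymorphic bool)."""
    states = list(_BASES) + ([_GAP] if with_indels else [])
    counts = np.stack([(arr == s).sum(axis=0) for s in states]).astype(float)
    n = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p2 = (counts / n) ** 2
        pi = n / (n - 1.0) * (1.0 - p2.sum(axis=0))
    pi[n < 2] = np.nan
    polymorphic = ((counts > 0).sum(axis=0) >= 2) & (n >= 2)
    return pi, polymorphic


def _select_columns(alignment: MultipleAlignment, region) -> np.ndarray:
    """Resolve a region spec (label, interval list, bool mask, or None=all)
    to a column index array."""
    if region is None:
        return np.arange(alignment.n_cols)
    if isinstance(region, str):
        if alignment.region_labels is None:
            raise ValidationError("alignment has no region labels")
        return np.flatnonzero(alignment.region_labels == region)
    region = list(region) if not isinstance(region, np.ndarray) else region
    if isinstance(region, np.ndarray) and region.dtype == bool:
        return np.flatnonzero(region)
    cols = []
    for start, end in region:
        cols.append(np.arange(start, end))
    return np.unique(np.concatenate(cols)) if cols else np.array([], dtype=int)


def region_pi(alignment: MultipleAlignment, region=None,
              mode: str = "without_indels") -> DiversityEstimate:
    """Mean site_pi over the non-skipped columns of a region.

    ``region`` may be a region label, a list of (start, end) column
    intervals, a boolean column mask, or None for the whole alignment.
    """
    with_indels = _check_mode(mode)
    cols = _select_columns(alignment, region)
    label = region if isinstance(region, str) else "all" if region is None else "custom"
    if len(cols) == 0:
        return DiversityEstimate(label, mode, 0.0, 0, 0)
    pi, poly = _column_pi_array(alignment.array[:, cols], with_indels)
    ok = ~np.isnan(pi)
    mean_pi = float(pi[ok].mean()) if ok.any() else 0.0
    return DiversityEstimate(label, mode, mean_pi, int(ok.sum()), int(poly.sum()))


def count_polymorphic_sites(alignment: MultipleAlignment, region=None,
                            mode: str = "without_indels") -> int:
    """Columns with >= 2 distinct usable states (gap a state iff with_indels)."""
    with_indels = _check_mode(mode)
    cols = _select_columns(alignment, region)
    if len(cols) == 0:
        return 0
    _, poly = _column_pi_array(alignment.array[:, cols], with_indels)
    return int(poly.sum())


@dataclass
class WindowCount:
    start: int
    end: int
    count: int
    partial: bool


def window_polymorphism(alignment: MultipleAlignment, window: int = 100,
                        step: int = 50, mode: str = "with_indels") -> list:
    """Polymorphic-site counts in sliding windows over alignment columns.

    Windows start at 0, step ``step``; the last partial window is included
    and flagged.
    """
    with_indels = _check_mode(mode)
    _, poly = _column_pi_array(alignment.array, with_indels)
    out = []
    for start in range(0, alignment.n_cols, step):
        end = min(start + window, alignment.n_cols)
        out.append(WindowCount(start, end, int(poly[start:end].sum()),
                               partial=end - start < window))
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori pN/pS under the yeast mitochondrial code

_TABLE3 = CodonTable.unambiguous_dna_by_id[3]
_STOPS = set(_TABLE3.stop_codons)


def _aa(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _TABLE3.forward_table[codon]


def _codon_sites(codon: str):
    """Expected (nonsyn, syn) site counts of one codon: at each position the
    three possible changes are classified; changes to a stop count as
    nonsynonymous."""
    n = s = 0.0
    aa0 = _aa(codon)
    for pos in range(3):
        syn = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if _aa(mut) != "*" and _aa(mut) == aa0:
                syn += 1
        s += syn / 3.0
        n += (3 - syn) / 3.0
    return n, s


def _pair_path_counts(c1: str, c2: str):
    """Average (nonsyn, syn) change counts over minimal mutational paths
    between two codons. Paths passing through a stop codon are excluded
    unless every path does."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        nd = sd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if _aa(nxt) == "*" and nxt != c2:
                blocked = True
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, nd, sd))
    usable = [p for p in paths if not p[0]] or paths
    nd = float(np.mean([p[1] for p in usable]))
    sd = float(np.mean([p[2] for p in usable]))
    return nd, sd


@dataclass
class PnPsResult:
    gene: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: Optional[float]
    ratio: Optional[float]


def pnps(cds_alignment, gene: str = "", codon_valid=None) -> PnPsResult:
    """Nei-Gojobori polymorphism counting on an in-frame CDS alignment.

    ``cds_alignment`` is a :class:`MultipleAlignment` or a list of
    ``(name, aligned_cds)`` tuples; the alignment length must be a
    multiple of 3. A codon containing a gap or N in one sequence is
    dropped for that sequence only. ``ratio`` is None when Sd = 0.
    """
    if isinstance(cds_alignment, MultipleAlignment):
        rows = [cds_alignment.row(t) for t in cds_alignment.taxa]
    else:
        rows = [s.upper() for _, s in cds_alignment]
    if not rows:
        raise ValidationError("empty alignment")
    L = len(rows[0])
    if L % 3 != 0:
        raise ValidationError(f"alignment length {L} not divisible by 3")
    n_codons = L // 3

    valid = set("ACGT")
    # expected sites, averaged over sequences
    per_seq_n, per_seq_s = [], []
    codons = [[row[3 * c: 3 * c + 3] for c in range(n_codons)] for row in rows]
    for seq_codons in codons:
        tn = ts = 0.0
        for cod in seq_codons:
            if set(cod) <= valid and cod not in _STOPS:
                a, b = _codon_sites(cod)
                tn += a
                ts += b
        per_seq_n.append(tn)
        per_seq_s.append(ts)
    N = float(np.mean(per_seq_n))
    S = float(np.mean(per_seq_s))

    nd_total = sd_total = 0.0
    for c in range(n_codons):
        observed = sorted({codons[i][c] for i in range(len(rows))
                           if set(codons[i][c]) <= valid})
        if len(observed) < 2:
            continue
        # parsimony lower bound on the number of segregating changes
        min_changes = sum(
            len({cod[p] for cod in observed}) - 1 for p in range(3)
        )
        pair_nd, pair_sd = [], []
        for c1, c2 in itertools.combinations(observed, 2):
            a, b = _pair_path_counts(c1, c2)
            pair_nd.append(a)
            pair_sd.append(b)
        mean_nd, mean_sd = float(np.mean(pair_nd)), float(np.mean(pair_sd))
        tot = mean_nd + mean_sd
        if tot > 0:
            scale = min_changes / tot
            nd_total += mean_nd * scale
            sd_total += mean_sd * scale

    pn = nd_total / N if N > 0 else 0.0
    ps = sd_total / S if S > 0 else None
    ratio = (pn / ps) if (ps is not None and sd_total > 0) else None
    return PnPsResult(gene, N, S, nd_total, sd_total, pn,
                      ps if sd_total > 0 else None, ratio)


# ---------------------------------------------------------------------------
# Pairwise indel accounting via anchored alignment


@dataclass
class IndelEvent:
    """A maximal gap run in one sequence of a pairwise alignment.

    ``gap_in`` names the sequence carrying the gap ('a' or 'b');
    ``start``/``end`` is the inserted interval in the other sequence."""

    gap_in: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IndelSummary:
    n_events: int
    total_bp: int
    min_bp: int
    max_bp: int
    events: list = field(default_factory=list)


def _unique_kmer_positions(seq: str, k: int) -> dict:
    pos: dict = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        if kmer in dup:
            continue
        if kmer in pos:
            del pos[kmer]
            dup.add(kmer)
        else:
            pos[kmer] = i
    return pos


def _chain_anchors(pa: dict, pb: dict, k: int) -> list:
    """Colinear chain of shared unique k-mers (longest increasing
    subsequence on b-positions, then pruned to non-overlapping)."""
    shared = sorted((pa[m], pb[m]) for m in pa.keys() & pb.keys())
    if not shared:
        return []
    # LIS over b positions
    tails: list = []
    backref = [0] * len(shared)
    idx_at: list = []
    for i, (_, b) in enumerate(shared):
        j = bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            idx_at.append(i)
        else:
            tails[j] = b
            idx_at[j] = i
        backref[i] = idx_at[j - 1] if j > 0 else -1
    chain = []
    i = idx_at[len(tails) - 1]
    while i != -1:
        chain.append(shared[i])
        i = backref[i]
    chain.reverse()
    # prune overlaps in either sequence
    pruned = [chain[0]]
    for a, b in chain[1:]:
        pa_, pb_ = pruned[-1]
        if a >= pa_ + k and b >= pb_ + k:
            pruned.append((a, b))
    return pruned


_pairwise_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _pairwise_aligner
    if _pairwise_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -4
        aligner.extend_gap_score = -1
        _pairwise_aligner = aligner
    return _pairwise_aligner


def _segment_events(sa: str, sb: str, off_a: int, off_b: int) -> list:
    """Indel events from globally aligning two inter-anchor segments."""
    if not sa and not sb:
        return []
    if not sa:
        return [IndelEvent("a", off_b, off_b + len(sb))]
    if not sb:
        return [IndelEvent("b", off_a, off_a + len(sa))]
    aln = _get_aligner().align(sa, sb)[0]
    events = []
    a_pos, b_pos = 0, 0
    blocks_a, blocks_b = aln.aligned
    prev_a_end, prev_b_end = 0, 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if a0 > prev_a_end:
            events.append(IndelEvent("b", off_a + prev_a_end, off_a + a0))
        if b0 > prev_b_end:
            events.append(IndelEvent("a", off_b + prev_b_end, off_b + b0))
        prev_a_end, prev_b_end = a1, b1
    if len(sa) > prev_a_end:
        events.append(IndelEvent("b", off_a + prev_a_end, off_a + len(sa)))
    if len(sb) > prev_b_end:
        events.append(IndelEvent("a", off_b + prev_b_end, off_b + len(sb)))
    return events


def pairwise_indels(seq_a: str, seq_b: str, anchor_k: int = 20) -> IndelSummary:
    """Indel events between two genomes via unique-k-mer anchor chaining.

    Shared k-mers unique in both sequences are chained colinearly; the
    inter-anchor segments are aligned globally with affine gap costs and
    each maximal gap run becomes one event.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if a == b:
        return IndelSummary(0, 0, 0, 0, [])
    chain = _chain_anchors(
        _unique_kmer_positions(a, anchor_k), _unique_kmer_positions(b, anchor_k),
        anchor_k,
    )
    if not chain:
        raise AlignmentFailure("no colinear anchor chain between sequences")
    events: list = []
    cur_a, cur_b = 0, 0
    for pa, pb in chain:
        events.extend(_segment_events(a[cur_a:pa], b[cur_b:pb], cur_a, cur_b))
        cur_a, cur_b = pa + anchor_k, pb + anchor_k
    events.extend(_segment_events(a[cur_a:], b[cur_b:], cur_a, cur_b))
    sizes = [e.length for e in events]
    return IndelSummary(
        n_events=len(events),
        total_bp=int(sum(sizes)),
        min_bp=min(sizes) if sizes else 0,
        max_bp=max(sizes) if sizes else 0,
        events=events,
    )
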