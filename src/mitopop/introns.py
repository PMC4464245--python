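"""Intron presence/absence genotyping at defined insertion sites.

Yeast mitochondrial group I and group II introns interrupt cox1, cob, and
rnl at known insertion sites and are optionally present per strain. The
caller anchors reference exon flanks around each insertion point and
measures the intervening distance: a clear intervening sequence means the
intron is present, contiguous exon sequence means absent, and
unanchorable sites are reported missing (partial assemblies). Presence is
positional - an intron with no homology to the usual occupant of a site
still counts as present at that site.

Insertion sites are 1-based: site s means the intron sits between CDS
bases s and s+1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import Align

from .io import AnnotatedGenome, ValidationError, reverse_complement
from .phylo import DistanceMatrix

logger = logging.getLogger(__name__)

#: minimum flank piece length that can be searched for on its own;
#: shorter inter-site pieces are resolved jointly with the next site
STRONG_ANCHOR_LEN = 20


@dataclass
class IntronSite:
    site_id: str
    host_gene: str
    insertion_site: int  # 1-based CDS base preceding the insertion
    group: str  # "I" or "II" (config metadata only)
    flank5: str
    flank3: str

    def __post_init__(self):
        if self.insertion_site < 1:
            raise ValidationError(f"{self.site_id}: insertion_site must be >= 1")
        if self.group not in {"I", "II"}:
            raise ValidationError(f"{self.site_id}: group must be I or II")
        for name, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not 20 <= len(flank) <= 60:
                raise ValidationError(
                    f"{self.site_id}: {name} length {len(flank)} outside [20, 60]"
                )


@dataclass
class IntronSiteTable:
    sites: List[IntronSite]

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate site ids")

    @property
    def site_ids(self) -> list:
        return [s.site_id for s in self.sites]

    def sites_for(self, gene: str) -> list:
        return sorted((s for s in self.sites if s.host_gene == gene),
                      key=lambda s: s.insertion_site)

    @property
    def host_genes(self) -> list:
        seen = []
        for s in self.sites:
            if s.host_gene not in seen:
                seen.append(s.host_gene)
        return seen

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(s.site_id, s.host_gene, s.insertion_site, s.group, s.flank5, s.flank3)
             for s in self.sites],
            columns=["site_id", "host_gene", "insertion_site", "group",
                     "flank5", "flank3"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IntronSiteTable":
        df = pd.read_csv(path, sep="\t")
        return cls([
            IntronSite(r.site_id, r.host_gene, int(r.insertion_site), r.group,
                       r.flank5, r.flank3)
            for r in df.itertuples()
        ])


# ---------------------------------------------------------------------------
# Flank anchoring


_search_aligner = None


def _get_search_aligner() -> Align.PairwiseAligner:
    global _search_aligner
    if _search_aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -4
        aligner.extend_gap_score = -1
        _search_aligner = aligner
    return _search_aligner


def _local_search(query: str, target: str):
    """Best local placement of query in target.

    Returns (start, end, identity, coverage) or None; identity is over the
    aligned query span, coverage the fraction of the query aligned."""
    if not query or not target or len(target) < 4:
        return None
    aln = _get_search_aligner().align(target, query)
    if len(aln) == 0:
        return None
    best = aln[0]
    tblocks, qblocks = best.aligned
    if len(qblocks) == 0:
        return None
    matches = 0
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        matches += sum(a == b for a, b in zip(target[t0:t1], query[q0:q1]))
    q_span = qblocks[-1][1] - qblocks[0][0]
    if q_span == 0:
        return None
    return (tblocks[0][0], tblocks[-1][1], matches / q_span, q_span / len(query))


def _identity_at(piece: str, target: str, pos: int) -> float:
    """Ungapped identity of piece against target at a fixed position."""
    window = target[pos: pos + len(piece)]
    if len(window) < len(piece):
        return 0.0
    return sum(a == b for a, b in zip(piece, window)) / len(piece)


@dataclass
class SiteCall:
    presence: Optional[int]  # 1, 0, or None (missing)
    intron_length: int = 0
    atypical: bool = False


def _truncated_flank3(site: IntronSite, next_site: Optional[IntronSite]) -> str:
    flank = site.flank3
    if next_site is not None:
        gap = next_site.insertion_site - site.insertion_site
        flank = flank[:gap]
    return flank


def _call_gene_sites(sequence: str, sites: Sequence[IntronSite],
                     min_flank_identity: float, min_intron_len: int,
                     max_intron_len: int, slack: int) -> Dict[str, SiteCall]:
    """Call all insertion sites of one gene on one oriented sequence.

    Proceeds left to right, keeping a cursor at the genome position of the
    current CDS coordinate. Absence is tested at a fixed position
    (contiguous exon), presence by searching the downstream window for the
    resumption of exon sequence. Two sites closer together than a usable
    anchor are resolved jointly against the next strong anchor.
    """
    calls: Dict[str, SiteCall] = {s.site_id: SiteCall(None) for s in sites}

    def anchor_site5(i: int, window=None) -> Optional[int]:
        """Genome position of site i's insertion point via its 5' flank."""
        target = sequence if window is None else sequence[window[0]:window[1]]
        res = _local_search(sites[i].flank5, target)
        if res is None or res[2] < min_flank_identity or res[3] < 0.8:
            return None
        return res[1] + (0 if window is None else window[0])

    cursor = anchor_site5(0)
    i = 0
    while i < len(sites):
        site = sites[i]
        if cursor is None:
            calls[site.site_id] = SiteCall(None)
            i += 1
            if i < len(sites):
                cursor = anchor_site5(i)
            continue
        next_site = sites[i + 1] if i + 1 < len(sites) else None
        piece = _truncated_flank3(site, next_site)

        if len(piece) >= STRONG_ANCHOR_LEN:
            if _identity_at(piece, sequence, cursor) >= min_flank_identity:
                calls[site.site_id] = SiteCall(0)
                boundary = cursor + len(piece)
            else:
                w0 = cursor
                w1 = min(len(sequence), cursor + max_intron_len + len(piece) + slack)
                res = _local_search(piece, sequence[w0:w1])
                if res is None or res[2] < min_flank_identity or res[3] < 0.8:
                    calls[site.site_id] = SiteCall(None)
                    boundary = None
                else:
                    d = res[0] + w0 - cursor
                    presence = 1 if d > min_intron_len else 0
                    calls[site.site_id] = SiteCall(
                        presence, intron_length=d if presence else 0,
                        atypical=slack < d <= min_intron_len,
                    )
                    boundary = res[1] + w0
            cursor = self_advance = None
            if boundary is not None:
                cursor = _advance_to_next(sequence, sites, i, boundary, piece,
                                          anchor_site5, min_flank_identity)
            elif next_site is not None:
                cursor = anchor_site5(i + 1)
            i += 1
        else:
            # weak inter-site piece: resolve this site and the next jointly
            assert next_site is not None
            gap = next_site.insertion_site - site.insertion_site
            nxt = sites[i + 2] if i + 2 < len(sites) else None
            nxt_piece = _truncated_flank3(next_site, nxt)
            w0 = cursor
            w1 = min(len(sequence),
                     cursor + 2 * max_intron_len + gap + len(nxt_piece) + slack)
            res = _local_search(nxt_piece, sequence[w0:w1])
            if res is None or res[2] < min_flank_identity or res[3] < 0.8:
                calls[site.site_id] = SiteCall(None)
                calls[next_site.site_id] = SiteCall(None)
                cursor = anchor_site5(i + 2) if nxt is not None else None
                i += 2
                continue
            R = res[0] + w0  # genome position of next_site's insertion point
            excess = (R - cursor) - gap
            id_left = _identity_at(piece, sequence, cursor)
            id_right = _identity_at(piece, sequence, R - gap)
            if excess <= slack:
                calls[site.site_id] = SiteCall(0)
                calls[next_site.site_id] = SiteCall(0)
            elif id_left >= min_flank_identity and id_left >= id_right:
                calls[site.site_id] = SiteCall(0)
                calls[next_site.site_id] = SiteCall(1, intron_length=excess)
            elif id_right >= min_flank_identity:
                calls[site.site_id] = SiteCall(1, intron_length=excess)
                calls[next_site.site_id] = SiteCall(0)
            else:
                calls[site.site_id] = SiteCall(1)
                calls[next_site.site_id] = SiteCall(1)
            boundary = res[1] + w0
            cursor = _advance_to_next(sequence, sites, i + 1, boundary, nxt_piece,
                                      anchor_site5, min_flank_identity)
            i += 2
    return calls


def _advance_to_next(sequence: str, sites: Sequence[IntronSite], i: int,
                     boundary: int, piece: str, anchor_site5,
                     min_flank_identity: float) -> Optional[int]:
    """Cursor for site i+1 given the genome position just past site i's
    resolved 3' piece."""
    if i + 1 >= len(sites):
        return None
    gap = sites[i + 1].insertion_site - sites[i].insertion_site
    remaining = gap - len(piece)
    if remaining <= 0:
        return boundary
    estimate = boundary + remaining
    w0 = max(0, estimate - 200)
    w1 = min(len(sequence), estimate + 200)
    pos = anchor_site5(i + 1, window=(w0, w1))
    return pos if pos is not None else estimate


def call_introns(genome_or_contigs: Union[AnnotatedGenome, str, Sequence[str]],
                 site_table: IntronSiteTable,
                 min_flank_identity: float = 0.90,
                 min_intron_len: int = 50,
                 max_intron_len: int = 5000,
                 slack: int = 10) -> Dict[str, SiteCall]:
    """Call intron presence at every site of the table.

    Accepts an :class:`AnnotatedGenome`, a raw sequence, or a list of
    contig sequences (partial assemblies). Both strands are tried per
    gene; the orientation anchoring the most sites wins. Sites whose
    flanks cannot be anchored are reported missing.
    """
    if isinstance(genome_or_contigs, AnnotatedGenome):
        contigs = [genome_or_contigs.sequence]
    elif isinstance(genome_or_contigs, str):
        contigs = [genome_or_contigs]
    else:
        contigs = list(genome_or_contigs)
    result: Dict[str, SiteCall] = {}
    for gene in site_table.host_genes:
        sites = site_table.sites_for(gene)
        best: Optional[Dict[str, SiteCall]] = None
        for contig in contigs:
            for oriented in (contig.upper(), reverse_complement(contig.upper())):
                calls = _call_gene_sites(oriented, sites, min_flank_identity,
                                         min_intron_len, max_intron_len, slack)
                n_called = sum(1 for c in calls.values() if c.presence is not None)
                if best is None or n_called > sum(
                    1 for c in best.values() if c.presence is not None
                ):
                    best = calls
                if n_called == len(sites):
                    break
            else:
                continue
            break
        result.update(best)
    return result


# ---------------------------------------------------------------------------
# Profile matrix and summaries


def build_profile_matrix(genomes: Iterable, site_table: IntronSiteTable,
                         **call_kwargs) -> pd.DataFrame:
    """Strains x sites presence matrix (1.0 / 0.0 / NaN for missing).

    Row order follows input order; accepts AnnotatedGenomes or
    (strain_id, contigs) pairs."""
    rows = {}
    for item in genomes:
        if isinstance(item, AnnotatedGenome):
            strain, data = item.strain_id, item
        else:
            strain, data = item
        calls = call_introns(data, site_table, **call_kwargs)
        rows[strain] = {
            sid: (np.nan if calls[sid].presence is None else float(calls[sid].presence))
            for sid in site_table.site_ids
        }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=site_table.site_ids)


def intron_frequency_by_population(matrix: pd.DataFrame,
                                   populations: Dict[str, str]) -> pd.DataFrame:
    """Percentage of strains carrying each intron, per population.

    percentage = 100 * present / non-missing. Rows are populations plus an
    'all' row; an 'n' column gives population sizes."""
    missing = set(matrix.index) - set(populations)
    if missing:
        raise ValidationError(f"unlabeled strains: {sorted(missing)}")
    labels = pd.Series({s: populations[s] for s in matrix.index})
    out = {}
    for pop in sorted(labels.unique()):
        sub = matrix.loc[labels[labels == pop].index]
        out[pop] = 100.0 * sub.sum(axis=0, skipna=True) / sub.notna().sum(axis=0)
        out[pop]["n"] = len(sub)
    out["all"] = 100.0 * matrix.sum(axis=0, skipna=True) / matrix.notna().sum(axis=0)
    out["all"]["n"] = len(matrix)
    table = pd.DataFrame(out).T
    table["n"] = table["n"].astype(int)
    return table[["n"] + site_table_columns(matrix)]


def site_table_columns(matrix: pd.DataFrame) -> list:
    return list(matrix.columns)


def format_frequency_table(freq: pd.DataFrame) -> pd.DataFrame:
    """Render frequencies for reporting: populations with n = 1 become
    +/- marks instead of percentages."""
    out = freq.copy().astype(object)
    for pop in freq.index:
        if freq.loc[pop, "n"] == 1:
            for col in freq.columns:
                if col == "n":
                    continue
                v = freq.loc[pop, col]
                out.loc[pop, col] = "?" if pd.isna(v) else ("+" if v > 0 else "-")
    return out


def binary_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise distance = proportion of mutually non-missing sites where
    presence differs. A pair with zero shared sites is an error."""
    strains = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    n = len(strains)
    d = np.zeros((n, n))
    ok = ~np.isnan(vals)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            m = int(shared.sum())
            if m == 0:
                raise ValidationError(
                    f"no shared non-missing sites between {strains[i]} and {strains[j]}"
                )
            d[i, j] = d[j, i] = float((vals[i][shared] != vals[j][shared]).sum()) / m
    return DistanceMatrix(strains, d)
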