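"""Synthetic mtDNA strain sets with planted ground truth.

The generator emulates the statistical structure of intraspecific yeast
mitochondrial variation: AT-rich (~84 % AT) circular genomes of 70-90 kb
with a fixed syntenic 8-gene coding core (cox1-atp8-atp6-cob-atp9-rps3-
cox2-cox3) plus the rnl rRNA gene, optional group I/II introns at 18
known insertion sites with population-specific presence probabilities,
mobile GC clusters instantiated from class consensi and scattered through
intergenic DNA with population-specific class counts (including a West-
African-like M4 expansion in which each M4 is planted immediately 5' of
an M1 partner), substitutions accumulated along a population tree, and
intergenic indels.

Every planted feature is recorded in a :class:`TruthRecord`, including
the true multiple alignment of the strain set, so downstream scanners and
statistics can be verified against known truth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .diversity import MultipleAlignment
from .gcclusters import (ConsensusTable, default_consensus_table,
                         instantiate_consensus)
from .introns import IntronSite, IntronSiteTable
from .io import AnnotatedGenome, Feature, ValidationError

logger = logging.getLogger(__name__)


class SizingError(ValueError):
    """genome_length_target too small to host the gene templates."""


class PlacementError(RuntimeError):
    """Insufficient intergenic space for a requested insertion."""


GENE_ORDER = ("cox1", "atp8", "atp6", "cob", "atp9", "rps3", "cox2", "cox3")

#: realistic CDS lengths (bp, multiples of 3) for the syntenic core
GENE_LENGTHS = {
    "cox1": 1605, "atp8": 147, "atp6": 780, "cob": 1158,
    "atp9": 228, "rps3": 1344, "cox2": 756, "cox3": 810,
}

RNL_LENGTH = 3402

#: (site_id, host gene, 1-based CDS base preceding the insertion, group)
INTRON_SITE_DEFS = (
    ("cox1-aI1", "cox1", 169, "II"),
    ("cox1-aI2", "cox1", 205, "II"),
    ("cox1-aI3a", "cox1", 243, "I"),
    ("cox1-aI3b", "cox1", 386, "I"),
    ("cox1-aI3g", "cox1", 709, "I"),
    ("cox1-aI4a", "cox1", 720, "I"),
    ("cox1-aI4b", "cox1", 900, "I"),
    ("cox1-aI4g", "cox1", 927, "I"),
    ("cox1-aI5a", "cox1", 972, "I"),
    ("cox1-aI5b", "cox1", 1107, "I"),
    ("cox1-aI5g", "cox1", 1132, "II"),
    ("cob-bI1a", "cob", 393, "II"),
    ("cob-bI1b", "cob", 415, "II"),
    ("cob-bI2", "cob", 429, "I"),
    ("cob-bI3", "cob", 506, "I"),
    ("cob-bI4", "cob", 756, "I"),
    ("cob-bI5", "cob", 807, "I"),
    ("rnl-omega", "rnl", 2716, "I"),
)

#: default per-population intron presence probabilities. Patterns follow
#: the field's known population trends: aI1 universal in sake and West
#: African strains but rare in wine/European and absent in North American
#: ones; bI4/bI5 invariably present; bI1b/bI2 nearly absent in sake;
#: aI5b/aI5g absent in West African strains; aI3b and aI4g never present.
DEFAULT_INTRON_PROFILES = {
    "wine_euro": {
        "cox1-aI1": 0.38, "cox1-aI2": 0.59, "cox1-aI3a": 0.94, "cox1-aI3b": 0.0,
        "cox1-aI3g": 0.41, "cox1-aI4a": 0.21, "cox1-aI4b": 0.12, "cox1-aI4g": 0.0,
        "cox1-aI5a": 0.97, "cox1-aI5b": 0.68, "cox1-aI5g": 0.40,
        "cob-bI1a": 0.0, "cob-bI1b": 1.0, "cob-bI2": 1.0, "cob-bI3": 1.0,
        "cob-bI4": 1.0, "cob-bI5": 1.0, "rnl-omega": 0.09,
    },
    "west_african": {
        "cox1-aI1": 1.0, "cox1-aI2": 0.2, "cox1-aI3a": 0.8, "cox1-aI3b": 0.0,
        "cox1-aI3g": 0.2, "cox1-aI4a": 1.0, "cox1-aI4b": 0.0, "cox1-aI4g": 0.0,
        "cox1-aI5a": 0.8, "cox1-aI5b": 0.0, "cox1-aI5g": 0.0,
        "cob-bI1a": 0.0, "cob-bI1b": 0.4, "cob-bI2": 1.0, "cob-bI3": 1.0,
        "cob-bI4": 1.0, "cob-bI5": 1.0, "rnl-omega": 0.0,
    },
    "sake": {
        "cox1-aI1": 1.0, "cox1-aI2": 0.8, "cox1-aI3a": 1.0, "cox1-aI3b": 0.0,
        "cox1-aI3g": 0.4, "cox1-aI4a": 0.4, "cox1-aI4b": 0.0, "cox1-aI4g": 0.0,
        "cox1-aI5a": 0.2, "cox1-aI5b": 1.0, "cox1-aI5g": 1.0,
        "cob-bI1a": 0.0, "cob-bI1b": 0.2, "cob-bI2": 0.2, "cob-bI3": 0.8,
        "cob-bI4": 1.0, "cob-bI5": 1.0, "rnl-omega": 0.0,
    },
    "mosaic_a": {
        "cox1-aI1": 0.66, "cox1-aI2": 0.47, "cox1-aI3a": 0.97, "cox1-aI3b": 0.0,
        "cox1-aI3g": 0.34, "cox1-aI4a": 0.81, "cox1-aI4b": 0.59, "cox1-aI4g": 0.0,
        "cox1-aI5a": 0.38, "cox1-aI5b": 0.94, "cox1-aI5g": 0.72,
        "cob-bI1a": 0.0, "cob-bI1b": 0.81, "cob-bI2": 0.81, "cob-bI3": 0.91,
        "cob-bI4": 1.0, "cob-bI5": 1.0, "rnl-omega": 0.63,
    },
    "north_american": {
        "cox1-aI1": 0.0, "cox1-aI2": 1.0, "cox1-aI3a": 0.0, "cox1-aI3b": 0.0,
        "cox1-aI3g": 0.0, "cox1-aI4a": 0.0, "cox1-aI4b": 0.0, "cox1-aI4g": 0.0,
        "cox1-aI5a": 1.0, "cox1-aI5b": 1.0, "cox1-aI5g": 1.0,
        "cob-bI1a": 0.0, "cob-bI1b": 1.0, "cob-bI2": 1.0, "cob-bI3": 1.0,
        "cob-bI4": 1.0, "cob-bI5": 1.0, "rnl-omega": 0.0,
    },
}


def distinct_intron_profiles() -> dict:
    """Sharpened population signatures: presence probabilities binarized
    at 0.5. Within-population intron vectors become (near) deterministic,
    the regime under which binary-character trees can recover population
    clades; the default frequency-faithful profiles carry too much
    within-population polymorphism for that (as real wine/European
    strains do)."""
    return {
        pop: {sid: (1.0 if p >= 0.5 else 0.0) for sid, p in prof.items()}
        for pop, prof in DEFAULT_INTRON_PROFILES.items()
    }

#: default per-population (mean, sd) GC-cluster counts per class. The
#: West-African-like population carries the M4 expansion (mean 18 vs ~2
#: elsewhere), paired 5' of M1 partners.
DEFAULT_GC_PROFILES = {
    "wine_euro": {
        "M1": (47.2, 4.5), "M2": (23.7, 2.7), "M3": (15.3, 2.0), "M4": (2.7, 0.9),
        "M1'": (6.2, 1.9), "M2'": (13.9, 1.6), "M2''": (4.5, 1.3),
        "G": (3.5, 0.9), "V": (3.0, 0.6),
    },
    "west_african": {
        "M1": (49.5, 3.3), "M2": (31.3, 3.4), "M3": (20.5, 4.4), "M4": (18.0, 5.8),
        "M1'": (2.75, 0.96), "M2'": (20.3, 3.0), "M2''": (5.5, 1.0),
        "G": (3.3, 0.5), "V": (2.3, 0.5),
    },
    "sake": {
        "M1": (43.2, 3.0), "M2": (33.8, 3.1), "M3": (18.2, 4.3), "M4": (1.8, 0.5),
        "M1'": (2.6, 0.9), "M2'": (19.8, 2.8), "M2''": (5.2, 1.8),
        "G": (4.8, 0.5), "V": (3.2, 0.5),
    },
    "mosaic_a": {
        "M1": (38.0, 7.8), "M2": (25.2, 6.1), "M3": (14.4, 3.0), "M4": (2.2, 1.0),
        "M1'": (3.5, 1.6), "M2'": (14.6, 4.0), "M2''": (7.8, 2.0),
        "G": (2.4, 1.9), "V": (3.3, 0.7),
    },
    "north_american": {
        "M1": (25.0, 1.0), "M2": (17.0, 1.0), "M3": (11.0, 1.0), "M4": (1.0, 0.5),
        "M1'": (3.0, 1.0), "M2'": (10.0, 1.0), "M2''": (7.0, 1.0),
        "G": (0.0, 0.0), "V": (2.0, 0.5),
    },
}

#: balanced population tree over the four populations large enough (n >= 5
#: strains in the source data) to estimate count dispersions from;
#: tip-to-tip divergence ~0.02 substitutions/site
DEFAULT_POPULATION_TREE = (
    "((wine_euro:0.008,west_african:0.008):0.002,"
    "(sake:0.008,mosaic_a:0.008):0.002);"
)

_TEMPLATE_SEED = 7_123_401  # fixed: templates are constants, not per-run draws
_STOP_CODONS = {"TAA", "TAG"}  # table 3: TGA codes Trp, not stop

_FLANK_LEN = 40
_INTRON_START = "GTAGCG"
_INTRON_END = "ATCAAT"

_T3 = CodonTable.unambiguous_dna_by_id[3]


def _codon_aa(codon: str) -> str:
    return "*" if codon in _T3.stop_codons else _T3.forward_table[codon]


def _draw_at_rich(rng: np.random.Generator, n: int, at_fraction: float = 0.84) -> str:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(rng.choice(list("ATCG"), size=n, p=[p_at, p_at, p_gc, p_gc]))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random in-frame CDS: ATG start, TAA end, no internal stop, AT-rich."""
    assert length % 3 == 0
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        cod = _draw_at_rich(rng, 3, 0.80)
        if cod not in _STOP_CODONS:
            codons.append(cod)
    codons.append("TAA")
    return "".join(codons)


def default_gene_templates() -> tuple:
    """The fixed 8-gene syntenic core as (name, CDS) pairs."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    return tuple((g, _random_cds(rng, GENE_LENGTHS[g])) for g in GENE_ORDER)


def default_rnl_template() -> str:
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    return _draw_at_rich(rng, RNL_LENGTH, 0.80)


def default_intron_sequences() -> dict:
    """Simulated intron sequences: AT-rich random interiors with fixed
    terminal motifs, 800-2500 bp, one fixed sequence per site (shared by
    every strain carrying that intron)."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 2)
    out = {}
    for site_id, _, _, _ in INTRON_SITE_DEFS:
        n = int(rng.integers(800, 2501))
        interior = _draw_at_rich(rng, n - len(_INTRON_START) - len(_INTRON_END))
        out[site_id] = _INTRON_START + interior + _INTRON_END
    return out


def default_intron_site_table(gene_templates=None, rnl_template=None) -> IntronSiteTable:
    """Site table with reference exon flanks cut from the gene templates."""
    templates = dict(gene_templates or default_gene_templates())
    templates["rnl"] = rnl_template or default_rnl_template()
    sites = []
    for site_id, gene, pos, group in INTRON_SITE_DEFS:
        cds = templates[gene]
        if pos >= len(cds):
            raise ValidationError(f"{site_id}: site {pos} beyond CDS length {len(cds)}")
        flank5 = cds[max(0, pos - _FLANK_LEN): pos]
        flank3 = cds[pos: pos + _FLANK_LEN]
        sites.append(IntronSite(site_id, gene, pos, group, flank5, flank3))
    return IntronSiteTable(sites)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimConfig:
    """Study conditions for one simulated strain set.

    Branch lengths of ``population_tree`` are expected substitutions per
    intergenic site; coding positions evolve at ``cds_rate_scale`` times
    that rate (a crude stand-in for purifying selection).
    ``intergenic_indel_rate`` is events per kb of intergenic DNA per unit
    branch length; indel sizes are geometric with mean
    ``indel_mean_size``.
    """

    n_strains_per_population: int = 10
    population_tree: str = DEFAULT_POPULATION_TREE
    genome_length_target: int = 80_000
    at_fraction: float = 0.84
    gene_templates: Optional[tuple] = None
    rnl_template: Optional[str] = None
    intron_site_profiles: Optional[dict] = None
    gc_class_count_profiles: Optional[dict] = None
    intergenic_indel_rate: float = 50.0
    indel_mean_size: float = 8.0
    within_population_divergence: float = 0.001
    cds_rate_scale: float = 0.5
    nonsynonymous_acceptance: float = 0.15
    m4_pairing: bool = True
    m4_downstream_prob: float = 0.05
    n_conserved_clusters: int = 2
    min_insert_separation: int = 120
    consensus_table: Optional[ConsensusTable] = None
    intron_sequences: Optional[dict] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.gene_templates is None:
            self.gene_templates = default_gene_templates()
        if self.rnl_template is None:
            self.rnl_template = default_rnl_template()
        if self.intron_site_profiles is None:
            self.intron_site_profiles = DEFAULT_INTRON_PROFILES
        if self.gc_class_count_profiles is None:
            self.gc_class_count_profiles = DEFAULT_GC_PROFILES
        if self.consensus_table is None:
            self.consensus_table = default_consensus_table()
        if self.intron_sequences is None:
            self.intron_sequences = default_intron_sequences()
        self.validate()

    def validate(self) -> None:
        if not 0.5 < self.at_fraction < 1.0:
            raise ValidationError(f"at_fraction {self.at_fraction} outside (0.5, 1)")
        if self.n_strains_per_population < 1:
            raise ValidationError("need at least one strain per population")
        names = [g for g, _ in self.gene_templates]
        if tuple(names) != GENE_ORDER:
            raise ValidationError(
                f"gene order must be {'-'.join(GENE_ORDER)}, got {'-'.join(names)}"
            )
        for profile in self.intron_site_profiles.values():
            for sid, p in profile.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"intron probability {p} for {sid}")
        core = sum(len(s) for _, s in self.gene_templates) + len(self.rnl_template)
        min_spacer = 200 * (len(self.gene_templates) + 2)
        if self.genome_length_target < core + min_spacer:
            raise SizingError(
                f"genome_length_target {self.genome_length_target} cannot host "
                f"{core} bp of genes plus minimal spacers"
            )

    @property
    def populations(self) -> list:
        tree = _parse_population_tree(self.population_tree)
        return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def zero_rate_config(**overrides) -> SimConfig:
    """All mutation/indel/insertion rates zero: every genome equals the
    ancestor. Useful as a null condition."""
    base = dict(
        population_tree="(popA:0.0,popB:0.0);",
        intron_site_profiles={"popA": {}, "popB": {}},
        gc_class_count_profiles={"popA": {}, "popB": {}},
        intergenic_indel_rate=0.0,
        within_population_divergence=0.0,
        n_conserved_clusters=0,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass
class PlantedCluster:
    label: str
    start: int  # genome coordinates of the carrying strain
    end: int
    pair_role: Optional[str] = None  # 'upstream' / 'downstream' of its M1 partner


@dataclass
class PlantedIndel:
    kind: str  # 'insertion' or 'deletion'
    ancestor_pos: int
    length: int


@dataclass
class TruthRecord:
    """Complete planted truth for one simulated strain set."""

    strains: list
    populations: dict
    clusters: dict  # strain -> list[PlantedCluster]
    intron_presence: pd.DataFrame  # strains x site_ids, values 0/1
    alignment: MultipleAlignment
    column_gene: np.ndarray  # per alignment column: host gene name or ''
    population_tree: str
    ancestor: str
    indels: dict  # strain -> list[PlantedIndel]
    conserved_cluster_count: int


@dataclass
class _Insertion:
    anchor: int  # ancestor position the block precedes
    key: tuple  # grouping key: shared blocks have equal keys
    seq: str
    kind: str  # 'intron' | 'gc' | 'gc_pair' | 'indel'
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Simulation


def _parse_population_tree(newick: str):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _evolve(seq: np.ndarray, n_sub: int, rng: np.random.Generator,
            cds_mask: np.ndarray, frame_start: np.ndarray,
            at_fraction: float, cds_rate_scale: float,
            nonsyn_acceptance: float) -> np.ndarray:
    """Apply ~n_sub substitutions (on a copy).

    Coding positions mutate at ``cds_rate_scale`` times the intergenic
    rate; nonsynonymous changes are additionally accepted only with
    probability ``nonsyn_acceptance`` (a crude purifying-selection
    filter), and in-frame stops (TAA/TAG under table 3) are never
    created."""
    out = seq.copy()
    if n_sub == 0:
        return out
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    bases = np.frombuffer(b"ATCG", dtype=np.uint8)
    probs = np.array([p_at, p_at, p_gc, p_gc])
    positions = rng.integers(0, len(seq), size=n_sub)
    draws = rng.random(size=n_sub)
    for pos, u in zip(positions, draws):
        if cds_mask[pos] and u > cds_rate_scale:
            continue
        cur = out[pos]
        for _ in range(8):
            new = bases[rng.choice(4, p=probs)]
            if new != cur:
                break
        else:
            continue
        if cds_mask[pos]:
            cod_start = pos - (pos - frame_start[pos]) % 3
            codon = out[cod_start: cod_start + 3].copy()
            old = codon.tobytes().decode()
            codon[pos - cod_start] = new
            mut = codon.tobytes().decode()
            if mut in _STOP_CODONS:
                continue
            if _codon_aa(mut) != _codon_aa(old) \
                    and rng.random() > nonsyn_acceptance:
                continue
        out[pos] = new
    return out


def _sample_positions(rng: np.random.Generator, candidates: np.ndarray,
                      n: int, taken: list, separation: int,
                      what: str) -> list:
    """Sample n positions from candidates keeping pairwise separation from
    each other and from already taken positions."""
    chosen: list = []
    occupied = sorted(taken)
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * max(n, 1) + 1000:
            raise PlacementError(f"cannot place {n} {what} insertions")
        pos = int(candidates[rng.integers(len(candidates))])
        if all(abs(pos - t) >= separation for t in occupied):
            chosen.append(pos)
            occupied.append(pos)
    return chosen


def simulate_population_set(config: SimConfig):
    """Simulate a full strain set.

    Returns ``(genomes, truth)`` where genomes is a list of
    :class:`AnnotatedGenome` (one per strain, population blocks in tree
    tip order) and truth is the :class:`TruthRecord`. Deterministic for a
    fixed ``config.rng_seed``.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    (ss_layout, ss_tree, ss_conserved, ss_strains) = ss.spawn(4)
    layout_rng = np.random.default_rng(ss_layout)

    # --- ancestor layout -------------------------------------------------
    gene_seqs = dict(config.gene_templates)
    gene_seqs["rnl"] = config.rnl_template
    order = list(GENE_ORDER) + ["rnl"]
    total_genes = sum(len(gene_seqs[g]) for g in order)
    total_intergenic = config.genome_length_target - total_genes
    n_spacers = len(order) + 1
    # spacer lengths: roughly even with +-20 % jitter
    weights = 0.8 + 0.4 * layout_rng.random(n_spacers)
    spacer_lens = np.floor(weights / weights.sum() * total_intergenic).astype(int)
    spacer_lens[-1] += total_intergenic - spacer_lens.sum()

    parts = []
    gene_spans: Dict[str, tuple] = {}
    cursor = 0
    for i, g in enumerate(order):
        spacer = _draw_at_rich(layout_rng, int(spacer_lens[i]), config.at_fraction)
        parts.append(spacer)
        cursor += len(spacer)
        gene_spans[g] = (cursor, cursor + len(gene_seqs[g]))
        parts.append(gene_seqs[g])
        cursor += len(gene_seqs[g])
    parts.append(_draw_at_rich(layout_rng, int(spacer_lens[-1]), config.at_fraction))
    ancestor = "".join(parts)
    L = len(ancestor)
    anc = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()

    cds_mask = np.zeros(L, dtype=bool)
    frame_start = np.zeros(L, dtype=np.int64)
    for g in GENE_ORDER:
        s, e = gene_spans[g]
        cds_mask[s:e] = True
        frame_start[s:e] = s
    gene_mask = cds_mask.copy()
    rs, re = gene_spans["rnl"]
    gene_mask[rs:re] = True
    intergenic_positions = np.flatnonzero(~gene_mask)

    # --- evolve backbone along the population tree ----------------------
    tree = _parse_population_tree(config.population_tree)
    tree_rng = np.random.default_rng(ss_tree)
    tip_backbones: Dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            n_sub = tree_rng.poisson(bl * L)
            child_seq = _evolve(seq, n_sub, tree_rng, cds_mask, frame_start,
                                config.at_fraction, config.cds_rate_scale,
                                config.nonsynonymous_acceptance)
            if child.is_leaf():
                tip_backbones[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    root = tree.seed_node
    if root.is_leaf():
        tip_backbones[root.taxon.label] = anc.copy()
    else:
        descend(root, anc)
    populations = list(tip_backbones)
    # root-to-tip path lengths (drive per-strain indel counts)
    depth = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node is not None:
            if node.edge is not None and node.edge.length:
                d += node.edge.length
            node = node.parent_node
        depth[leaf.taxon.label] = d

    site_table = default_intron_site_table(config.gene_templates, config.rnl_template)
    site_ids = site_table.site_ids
    class_labels = config.consensus_table.labels

    # --- conserved clusters: same anchor and sequence in every strain ----
    conserved_rng = np.random.default_rng(ss_conserved)
    conserved: List[_Insertion] = []
    taken_global: list = []
    if config.n_conserved_clusters:
        anchors = _sample_positions(
            conserved_rng, intergenic_positions, config.n_conserved_clusters,
            [], config.min_insert_separation, "conserved cluster",
        )
        for idx, anchor in enumerate(anchors):
            label = class_labels[idx % len(class_labels)]
            seq = instantiate_consensus(
                config.consensus_table.get(label).consensus, conserved_rng
            )
            conserved.append(_Insertion(anchor, ("cons", idx), seq, "gc",
                                        {"label": label}))
            taken_global.append(anchor)

    # --- per-strain events ----------------------------------------------
    n_total = len(populations) * config.n_strains_per_population
    strain_seeds = ss_strains.spawn(n_total)
    strains: list = []
    strain_pop: Dict[str, str] = {}
    strain_backbone: Dict[str, np.ndarray] = {}
    strain_deleted: Dict[str, np.ndarray] = {}
    strain_insertions: Dict[str, list] = {}
    intron_truth: Dict[str, dict] = {}
    indel_truth: Dict[str, list] = {}

    rps3_start, rps3_end = gene_spans["rps3"]
    intron_seqs = config.intron_sequences
    si = 0
    for pop in populations:
        profile = config.intron_site_profiles.get(pop, {})
        gc_profile = config.gc_class_count_profiles.get(pop, {})
        for k in range(config.n_strains_per_population):
            strain = f"{pop}_s{k:02d}"
            rng = np.random.default_rng(strain_seeds[si])
            si += 1
            strains.append(strain)
            strain_pop[strain] = pop

            n_sub = rng.poisson(config.within_population_divergence * L)
            backbone = _evolve(tip_backbones[pop], n_sub, rng, cds_mask,
                               frame_start, config.at_fraction,
                               config.cds_rate_scale,
                               config.nonsynonymous_acceptance)
            strain_backbone[strain] = backbone

            deleted = np.zeros(L, dtype=bool)
            insertions: List[_Insertion] = []
            serial = 0

            # introns (shared blocks keyed by site id)
            presence = {}
            for site in site_table.sites:
                p = profile.get(site.site_id, 0.0)
                present = bool(rng.random() < p) if p > 0 else False
                presence[site.site_id] = int(present)
                if present:
                    gs, _ = gene_spans[site.host_gene]
                    insertions.append(_Insertion(
                        gs + site.insertion_site, ("intron", site.site_id),
                        intron_seqs[site.site_id], "intron",
                        {"site_id": site.site_id, "gene": site.host_gene},
                    ))
            intron_truth[strain] = presence

            # indels (intergenic only)
            branch = depth.get(pop, 0.0) + config.within_population_divergence
            intergenic_kb = len(intergenic_positions) / 1000.0
            n_indel = rng.poisson(config.intergenic_indel_rate * intergenic_kb * branch)
            indel_truth[strain] = []
            taken = list(taken_global)
            for _ in range(n_indel):
                size = int(rng.geometric(1.0 / config.indel_mean_size))
                if rng.random() < 0.5:  # deletion
                    for _try in range(50):
                        pos = int(intergenic_positions[
                            rng.integers(len(intergenic_positions))])
                        span = np.arange(pos, min(pos + size, L))
                        if (gene_mask[span].any() or deleted[span].any()
                                or any(pos <= t < pos + size for t in taken)):
                            continue
                        deleted[span] = True
                        indel_truth[strain].append(
                            PlantedIndel("deletion", pos, len(span)))
                        break
                else:  # insertion
                    pos = _sample_positions(rng, intergenic_positions, 1, taken,
                                            config.min_insert_separation,
                                            "indel")[0]
                    taken.append(pos)
                    seq = _draw_at_rich(rng, size, config.at_fraction)
                    insertions.append(_Insertion(
                        pos, ("priv", strain, serial), seq, "indel"))
                    serial += 1
                    indel_truth[strain].append(PlantedIndel("insertion", pos, size))

            # GC clusters
            counts = {}
            for label in class_labels:
                mean, sd = gc_profile.get(label, (0.0, 0.0))
                counts[label] = max(0, int(round(rng.normal(mean, sd)))) \
                    if mean > 0 or sd > 0 else 0
            n_m4 = counts.get("M4", 0)
            n_m1 = counts.get("M1", 0)
            n_pairs = min(n_m4, n_m1) if config.m4_pairing else 0
            table = config.consensus_table

            def plant(label, anchor, serial, pair_role=None):
                seq = instantiate_consensus(table.get(label).consensus, rng)
                insertions.append(_Insertion(
                    anchor, ("priv", strain, serial), seq, "gc",
                    {"label": label, "pair_role": pair_role},
                ))
                return serial + 1

            for label in class_labels:
                n = counts[label]
                if label == "M4" and config.m4_pairing:
                    n -= n_pairs
                elif label == "M1" and config.m4_pairing:
                    n -= n_pairs
                if n <= 0:
                    continue
                if label == "V":
                    # in-frame insertions inside rps3, at codon boundaries
                    codon_anchors = np.arange(rps3_start + 3, rps3_end - 3, 3)
                    anchors = _sample_positions(rng, codon_anchors, n, taken,
                                                60, "V cluster")
                    taken.extend(anchors)
                    for a in anchors:
                        serial = plant("V", a, serial)
                else:
                    anchors = _sample_positions(rng, intergenic_positions, n,
                                                taken,
                                                config.min_insert_separation,
                                                label)
                    taken.extend(anchors)
                    for a in anchors:
                        serial = plant(label, a, serial)
            # M4-M1 tandem pairs: single insertion event, M4 5' of M1
            # (rarely reversed), forming one GC-rich region with two hits
            for _ in range(n_pairs):
                anchor = _sample_positions(rng, intergenic_positions, 1, taken,
                                           config.min_insert_separation,
                                           "M4-M1 pair")[0]
                taken.append(anchor)
                m4 = instantiate_consensus(table.get("M4").consensus, rng)
                m1 = instantiate_consensus(table.get("M1").consensus, rng)
                downstream = bool(rng.random() < config.m4_downstream_prob)
                seq = (m1 + m4) if downstream else (m4 + m1)
                insertions.append(_Insertion(
                    anchor, ("priv", strain, serial), seq, "gc_pair",
                    {"m4_len": len(m4), "m1_len": len(m1),
                     "m4_downstream": downstream},
                ))
                serial += 1

            insertions.extend(conserved)
            strain_deleted[strain] = deleted
            strain_insertions[strain] = insertions

    # --- assemble the true alignment -------------------------------------
    genomes, truth = _assemble(
        config, strains, strain_pop, strain_backbone, strain_deleted,
        strain_insertions, intron_truth, indel_truth, gene_spans, order, L,
        site_table, ancestor,
    )
    truth.conserved_cluster_count = len(conserved)
    return genomes, truth


def _assemble(config, strains, strain_pop, strain_backbone, strain_deleted,
              strain_insertions, intron_truth, indel_truth, gene_spans,
              gene_order, L, site_table, ancestor):
    """Build the joint alignment, per-strain genomes, features and truth."""
    # group insertion blocks by (anchor, key); shared keys appear once
    blocks: Dict[tuple, dict] = {}
    strain_index = {s: i for i, s in enumerate(strains)}
    for strain in strains:
        for ins in strain_insertions[strain]:
            bkey = (ins.anchor, ins.key)
            if bkey not in blocks:
                blocks[bkey] = {"ins": ins, "carriers": []}
            blocks[bkey]["carriers"].append(strain)

    def block_sort_key(bkey):
        anchor, key = bkey
        if key[0] in ("intron", "cons"):
            return (anchor, 0, str(key[1]), 0)
        return (anchor, 1, str(strain_index[key[1]]).zfill(6), key[2])

    ordered = sorted(blocks, key=block_sort_key)
    ins_width = np.zeros(L + 1, dtype=np.int64)
    for bkey in ordered:
        ins_width[bkey[0]] += len(blocks[bkey]["ins"].seq)
    prefix = np.cumsum(ins_width)
    anc_cols = np.arange(L) + prefix[:L]
    n_cols = int(L + prefix[L])

    n_strains = len(strains)
    aln = np.full((n_strains, n_cols), ord("-"), dtype=np.uint8)
    labels = np.empty(n_cols, dtype="<U10")
    column_gene = np.empty(n_cols, dtype="<U8")
    labels[:] = "intergenic"
    column_gene[:] = ""

    # ancestor columns
    anc_labels = np.full(L, "intergenic", dtype="<U10")
    anc_gene = np.full(L, "", dtype="<U8")
    for g in gene_order:
        s, e = gene_spans[g]
        anc_labels[s:e] = "exon"
        anc_gene[s:e] = g
    labels[anc_cols] = anc_labels
    column_gene[anc_cols] = anc_gene

    for strain in strains:
        i = strain_index[strain]
        kept = ~strain_deleted[strain]
        cols = anc_cols[kept]
        aln[i, cols] = strain_backbone[strain][kept]

    # insertion block columns
    cursor_by_anchor: Dict[int, int] = {}
    block_cols: Dict[tuple, tuple] = {}
    for bkey in ordered:
        anchor, key = bkey
        ins = blocks[bkey]["ins"]
        w = len(ins.seq)
        start = cursor_by_anchor.get(anchor)
        if start is None:
            start = int(anc_cols[anchor] - ins_width[anchor]) if anchor < L \
                else int(n_cols - ins_width[L])
        block_cols[bkey] = (start, start + w)
        cursor_by_anchor[anchor] = start + w
        seq_bytes = np.frombuffer(ins.seq.encode(), dtype=np.uint8)
        for strain in blocks[bkey]["carriers"]:
            aln[strain_index[strain], start:start + w] = seq_bytes
        if ins.kind == "intron":
            labels[start:start + w] = "intron"
            column_gene[start:start + w] = ins.meta["gene"]
        elif ins.kind in ("gc", "gc_pair"):
            host = anc_gene[anchor] if anchor < L else ""
            labels[start:start + w] = "exon" if host else "intergenic"
            column_gene[start:start + w] = host
        # plain indels stay intergenic

    alignment = MultipleAlignment(strains, aln, region_labels=labels)

    # --- per-strain genomes, features, cluster truth ----------------------
    genomes = []
    cluster_truth: Dict[str, list] = {s: [] for s in strains}
    for strain in strains:
        i = strain_index[strain]
        row = aln[i]
        nongap = row != ord("-")
        gpos = np.cumsum(nongap) - 1  # genome position per column (if nongap)
        sequence = row[nongap].tobytes().decode()

        def g(col):
            return int(gpos[col])

        features = []
        for gene in list(gene_order):
            s, e = gene_spans[gene]
            g_start, g_end = g(anc_cols[s]), g(anc_cols[e - 1]) + 1
            attrs = {"complete": "1"} if gene in GENE_ORDER else {}
            features.append(Feature("gene", gene, g_start, g_end, "+", attrs))
            # exon/intron structure from planted introns
            carried = [
                site for site in site_table.sites_for(gene)
                if intron_truth[strain].get(site.site_id)
            ]
            bounds = [g_start]
            for site in carried:
                bkey = (gene_spans[gene][0] + site.insertion_site,
                        ("intron", site.site_id))
                c0, c1 = block_cols[bkey]
                i_start, i_end = g(c0), g(c1 - 1) + 1
                bounds.extend([i_start, i_end])
                features.append(Feature("intron", gene, i_start, i_end, "+",
                                        {"site_id": site.site_id}))
            bounds.append(g_end)
            for x0, x1 in zip(bounds[::2], bounds[1::2]):
                features.append(Feature("exon", gene, x0, x1, "+"))
        genome = AnnotatedGenome(strain, sequence, circular=True,
                                 features=sorted(features, key=lambda f: f.start))
        genomes.append(genome)

        for ins in strain_insertions[strain]:
            bkey = (ins.anchor, ins.key)
            c0, c1 = block_cols[bkey]
            s0, s1 = g(c0), g(c1 - 1) + 1
            if ins.kind == "gc":
                cluster_truth[strain].append(
                    PlantedCluster(ins.meta["label"], s0, s1))
            elif ins.kind == "gc_pair":
                m4_len = ins.meta["m4_len"]
                m1_len = ins.meta["m1_len"]
                if ins.meta["m4_downstream"]:
                    cluster_truth[strain].append(
                        PlantedCluster("M1", s0, s0 + m1_len))
                    cluster_truth[strain].append(
                        PlantedCluster("M4", s0 + m1_len, s1, "downstream"))
                else:
                    cluster_truth[strain].append(
                        PlantedCluster("M4", s0, s0 + m4_len, "upstream"))
                    cluster_truth[strain].append(
                        PlantedCluster("M1", s0 + m4_len, s1))
        cluster_truth[strain].sort(key=lambda c: c.start)

    intron_df = pd.DataFrame.from_dict(
        {s: intron_truth[s] for s in strains}, orient="index",
        columns=site_table.site_ids,
    )
    truth = TruthRecord(
        strains=strains,
        populations=strain_pop,
        clusters=cluster_truth,
        intron_presence=intron_df,
        alignment=alignment,
        column_gene=column_gene,
        population_tree=config.population_tree,
        ancestor=ancestor,
        indels=indel_truth,
        conserved_cluster_count=0,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# Standalone planting operations (single genome)


def _cds_to_genome_pos(genome: AnnotatedGenome, gene: str, cds_pos: int) -> int:
    """Genome coordinate of the point after 1-based CDS base ``cds_pos``
    (plus strand genes only)."""
    exons = sorted(genome.exons(gene), key=lambda f: f.start)
    if not exons:
        raise KeyError(f"no exons for {gene}")
    if exons[0].strand != "+":
        raise ValidationError("planting supports plus-strand genes only")
    remaining = cds_pos
    for e in exons:
        if remaining <= e.length:
            return e.start + remaining
        remaining -= e.length
    raise ValidationError(
        f"{gene}: CDS position {cds_pos} beyond spliced length"
    )


def _shift_features(features, at: int, by: int) -> list:
    out = []
    for f in features:
        start = f.start + by if f.start >= at else f.start
        end = f.end + by if f.end > at else f.end
        out.append(Feature(f.kind, f.gene_name, start, end, f.strand,
                           dict(f.attributes)))
    return out


def plant_introns(genome: AnnotatedGenome, presence: Dict[str, bool],
                  intron_sequences: Dict[str, str],
                  site_table: IntronSiteTable) -> AnnotatedGenome:
    """Insert introns at the requested sites of a single genome.

    Exon reading frames are preserved: the exon containing each insertion
    point is split in two and an intron feature is added. Splicing the
    result reproduces the original CDS exactly.
    """
    out_seq = genome.sequence
    features = [Feature(f.kind, f.gene_name, f.start, f.end, f.strand,
                        dict(f.attributes)) for f in genome.features]
    wanted = [s for s in site_table.sites if presence.get(s.site_id)]
    # all insertion points computed on the original genome, then applied
    # right to left so earlier coordinates stay valid
    placements = sorted(
        ((_cds_to_genome_pos(genome, s.host_gene, s.insertion_site), s)
         for s in wanted),
        key=lambda x: -x[0],
    )
    for pos, site in placements:
        seq = intron_sequences[site.site_id]
        ilen = len(seq)
        out_seq = out_seq[:pos] + seq + out_seq[pos:]
        split = []
        for f in features:
            if f.kind == "exon" and f.gene_name == site.host_gene \
                    and f.start < pos < f.end:
                split.append(Feature("exon", f.gene_name, f.start, pos, f.strand))
                split.append(Feature("exon", f.gene_name, pos, f.end, f.strand))
            else:
                split.append(f)
        features = _shift_features(split, pos, ilen)
        features.append(Feature("intron", site.host_gene, pos, pos + ilen,
                                "+", {"site_id": site.site_id}))
    return AnnotatedGenome(genome.strain_id, out_seq, genome.circular,
                           sorted(features, key=lambda f: f.start))


def plant_gc_clusters(genome: AnnotatedGenome, class_counts: Dict[str, int],
                      consensus_table: ConsensusTable,
                      pairing_rule: bool = False,
                      rng: Optional[np.random.Generator] = None,
                      min_separation: int = 120):
    """Insert concrete GC-cluster instantiations into one genome.

    Returns ``(new_genome, planted)``. IUPAC codes are resolved uniformly
    at random; with ``pairing_rule`` each M4 is planted immediately 5' of
    an M1 partner. V-class clusters go in frame inside rps3; everything
    else goes to intergenic positions with ``min_separation`` spacing.
    """
    if rng is None:
        rng = np.random.default_rng()
    gene_mask = np.zeros(len(genome.sequence), dtype=bool)
    for f in genome.features:
        if f.kind in ("gene", "tRNA"):
            gene_mask[f.start:f.end] = True
    intergenic = np.flatnonzero(~gene_mask)
    if len(intergenic) == 0 and any(
        n > 0 for label, n in class_counts.items() if label != "V"
    ):
        raise PlacementError("no intergenic space available")

    requests = []  # (anchor, seq, label, pair_role)
    taken: list = []
    counts = dict(class_counts)
    n_pairs = 0
    if pairing_rule:
        n_pairs = min(counts.get("M4", 0), counts.get("M1", 0))
        counts["M4"] = counts.get("M4", 0) - n_pairs
        counts["M1"] = counts.get("M1", 0) - n_pairs
    for label, n in counts.items():
        if n <= 0:
            continue
        entry = consensus_table.get(label)
        if label == "V":
            rps3 = [f for f in genome.features
                    if f.kind == "gene" and f.gene_name == "rps3"]
            if not rps3:
                raise PlacementError("V clusters require an rps3 gene")
            anchors = _sample_positions(
                rng, np.arange(rps3[0].start + 3, rps3[0].end - 3, 3), n,
                taken, 60, "V cluster")
        else:
            anchors = _sample_positions(rng, intergenic, n, taken,
                                        min_separation, label)
        taken.extend(anchors)
        for a in anchors:
            requests.append((a, instantiate_consensus(entry.consensus, rng),
                             label, None))
    for _ in range(n_pairs):
        a = _sample_positions(rng, intergenic, 1, taken, min_separation,
                              "M4-M1 pair")[0]
        taken.append(a)
        m4 = instantiate_consensus(consensus_table.get("M4").consensus, rng)
        m1 = instantiate_consensus(consensus_table.get("M1").consensus, rng)
        # one contiguous insertion: M4 immediately 5' of its M1 partner
        requests.append((a, m4 + m1, "M4+M1", len(m4)))

    # apply right to left so earlier anchors stay valid
    seq = genome.sequence
    features = list(genome.features)
    planted = []
    for anchor, ins_seq, label, extra in sorted(requests, key=lambda r: -r[0]):
        seq = seq[:anchor] + ins_seq + seq[anchor:]
        features = _shift_features(features, anchor, len(ins_seq))
        planted = [PlantedCluster(p.label,
                                  p.start + len(ins_seq) if p.start >= anchor else p.start,
                                  p.end + len(ins_seq) if p.end > anchor else p.end,
                                  p.pair_role)
                   for p in planted]
        if label == "M4+M1":
            planted.append(PlantedCluster("M4", anchor, anchor + extra, "upstream"))
            planted.append(PlantedCluster("M1", anchor + extra,
                                          anchor + len(ins_seq), None))
        else:
            planted.append(PlantedCluster(label, anchor, anchor + len(ins_seq),
                                          extra))
    planted.sort(key=lambda p: p.start)
    new_genome = AnnotatedGenome(genome.strain_id, seq, genome.circular, features)
    return new_genome, planted
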