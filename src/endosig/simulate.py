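"""Synthetic multi-species inputs with planted, parameterized signals.

Every downstream stage of the pipeline consumes one of the shapes produced
here: ortholog-cluster presence/absence matrices with planted
lifestyle-enriched rows, annotation count tables with planted
overrepresented accessions, a repeat-annotated genome mutated by a CpA->TpA
RIP process, and per-gene homolog hit tables with planted
non-fungal-dominated genes. Each generator returns the dataset together
with the ground truth of what was planted, so recovery can be scored.

Randomness: one global seed; each generator derives an independent stream
from ``(seed, stage-tag)`` so stages can be regenerated in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .io import IntervalSet
from .species import Lifestyle, SpeciesPanel, default_panel

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults give moderate, detectable effects.

    Counts follow a negative binomial (mean ``baseline_count_mean``,
    dispersion ``count_dispersion``; Poisson is the dispersion -> infinity
    limit), matching the overdispersion of domain counts across genomes.
    """

    seed: int = 0
    # ortholog cluster matrix
    n_clusters: int = 500
    n_planted_pathogen_clusters: int = 20
    n_planted_saprotroph_clusters: int = 20
    background_presence_prob: float = 0.5
    # annotation counts
    n_accessions: int = 1000
    baseline_count_mean: float = 5.0
    count_dispersion: float = 10.0
    overrep_fold: float = 4.0
    n_planted_overrep: int = 50
    # ripped genome
    genome_length: int = 500_000
    gc_content: float = 0.46
    n_repeats: int = 50
    repeat_length: int = 2000
    rip_rate: float = 0.5
    n_gene_intervals: int = 100
    gene_length: int = 1500
    # homolog hit tables
    n_genes_hit_tables: int = 200
    n_planted_hgt: int = 10
    hits_per_gene: int = 100
    null_fungal_fraction: float = 0.75
    hgt_fungal_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "n_clusters", "n_planted_pathogen_clusters", "n_planted_saprotroph_clusters",
            "n_accessions", "n_planted_overrep", "genome_length", "n_repeats",
            "repeat_length", "n_gene_intervals", "gene_length",
            "n_genes_hit_tables", "n_planted_hgt", "hits_per_gene",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("background_presence_prob", "gc_content", "rip_rate",
                     "null_fungal_fraction", "hgt_fungal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_count_mean <= 0:
            raise ConfigurationError("baseline_count_mean must be positive")
        if self.count_dispersion <= 0:
            raise ConfigurationError("count_dispersion must be positive")
        if self.overrep_fold <= 0:
            raise ConfigurationError("overrep_fold must be positive")
        total_planted = self.n_planted_pathogen_clusters + self.n_planted_saprotroph_clusters
        if total_planted > self.n_clusters:
            raise ConfigurationError(
                f"planted clusters ({total_planted}) exceed n_clusters ({self.n_clusters})"
            )
        if self.n_planted_overrep > self.n_accessions:
            raise ConfigurationError("n_planted_overrep exceeds n_accessions")
        if self.n_planted_hgt > self.n_genes_hit_tables:
            raise ConfigurationError("n_planted_hgt exceeds n_genes_hit_tables")


@dataclass
class GroundTruth:
    """What the generators planted, keyed by generated object ids."""

    planted_cluster_ids: dict[str, list[str]] = field(default_factory=dict)
    planted_accession_ids: dict[str, float] = field(default_factory=dict)
    planted_hgt_gene_ids: list[str] = field(default_factory=list)
    rip_mutated_positions: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class RepeatAnnotatedGenome:
    """Scaffold sequences plus half-open interval sets for repeats and genes."""

    sequences: dict[str, str]
    repeats: IntervalSet
    genes: IntervalSet

    def length_of(self, scaffold: str) -> int:
        return len(self.sequences[scaffold])


def stage_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one generator stage."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])


# ---------------------------------------------------------------------------
# Ortholog cluster matrix

def _planted_row(rng: np.random.Generator, panel: SpeciesPanel,
                 target: Lifestyle, min_present: int) -> dict[str, int]:
    """One presence row satisfying the target-lifestyle enrichment rule exactly."""
    row = {c: 0 for c in panel.codes}
    target_group = panel.group(target)
    n_present = int(rng.integers(min_present, len(target_group) + 1))
    for c in rng.choice(target_group, size=n_present, replace=False):
        row[c] = 1
    for other in (Lifestyle.PATHOGEN, Lifestyle.SAPROTROPH, Lifestyle.MYCORRHIZAL):
        if other is target:
            continue
        group = panel.group(other)
        n_other = int(rng.integers(0, 2))  # at most one species of each other lifestyle
        if n_other and group:
            row[str(rng.choice(group))] = 1
    row[panel.focal] = 1
    return row


def simulate_cluster_matrix(
    panel: SpeciesPanel | None = None, cfg: SimulationConfig | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Binary cluster x species matrix with planted lifestyle-enriched rows.

    Planted pathogen rows have >=4/5 pathogens, <=1 saprotroph, <=1
    mycorrhizal species and the focal species present; saprotroph rows use
    the proportional analogue (>=5/6). Non-planted rows are i.i.d.
    Bernoulli(background_presence_prob) per cell.
    """
    panel = panel or default_panel()
    cfg = cfg or SimulationConfig()
    rng = stage_rng(cfg.seed, "cluster_matrix")
    n = cfg.n_clusters
    ids = [f"cl{i:05d}" for i in range(n)]
    cells = (rng.random((n, len(panel.codes))) < cfg.background_presence_prob).astype(np.int8)
    m = pd.DataFrame(cells, index=ids, columns=panel.codes)

    planted_positions = rng.choice(
        n, size=cfg.n_planted_pathogen_clusters + cfg.n_planted_saprotroph_clusters,
        replace=False,
    )
    truth = GroundTruth(planted_cluster_ids={"pathogen": [], "saprotroph": []})
    specs = [(Lifestyle.PATHOGEN, 4, "pathogen")] * cfg.n_planted_pathogen_clusters + [
        (Lifestyle.SAPROTROPH, 5, "saprotroph")
    ] * cfg.n_planted_saprotroph_clusters
    for pos, (target, min_present, key) in zip(planted_positions, specs):
        row = _planted_row(rng, panel, target, min_present)
        m.iloc[pos] = [row[c] for c in panel.codes]
        truth.planted_cluster_ids[key].append(ids[pos])
    for key in truth.planted_cluster_ids:
        truth.planted_cluster_ids[key].sort()
    return m, truth


# ---------------------------------------------------------------------------
# Annotation count tables

def _nbinom(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_annotation_counts(
    panel: SpeciesPanel | None = None, cfg: SimulationConfig | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Accession x species count table with planted focal overrepresentation.

    Counts are negative binomial around ``baseline_count_mean``; for planted
    accessions the focal species' mean is multiplied by ``overrep_fold``.
    With ``overrep_fold == 1`` nothing is planted and the ground truth is
    empty.
    """
    panel = panel or default_panel()
    cfg = cfg or SimulationConfig()
    rng = stage_rng(cfg.seed, "annotation_counts")
    ids = [f"ACC{i:05d}" for i in range(cfg.n_accessions)]
    counts = _nbinom(rng, cfg.baseline_count_mean, cfg.count_dispersion,
                     (cfg.n_accessions, len(panel.codes)))
    t = pd.DataFrame(counts, index=ids, columns=panel.codes)
    truth = GroundTruth()
    if cfg.overrep_fold != 1.0 and cfg.n_planted_overrep > 0:
        planted = rng.choice(cfg.n_accessions, size=cfg.n_planted_overrep, replace=False)
        boosted = _nbinom(rng, cfg.baseline_count_mean * cfg.overrep_fold,
                          cfg.count_dispersion, cfg.n_planted_overrep)
        t.loc[[ids[i] for i in planted], panel.focal] = boosted
        truth.planted_accession_ids = {ids[i]: cfg.overrep_fold for i in sorted(planted)}
    return t, truth


# ---------------------------------------------------------------------------
# RIP-mutated genome

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=probs)


def _place_intervals(rng: np.random.Generator, genome_length: int, n: int,
                     length: int, occupied: list[tuple[int, int]],
                     max_tries: int = 10_000) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    blocked = list(occupied)
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n} non-overlapping {length} bp intervals "
                f"in {genome_length} bp after {max_tries} tries"
            )
        tries += 1
        start = int(rng.integers(0, genome_length - length + 1))
        iv = (start, start + length)
        if any(s < iv[1] and iv[0] < e for s, e in blocked):
            continue
        placed.append(iv)
        blocked.append(iv)
    return sorted(placed)


def apply_rip(seq: np.ndarray, rip_rate: float, rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Mutate CpA -> TpA and TpG -> TpA sites in place-copy at ``rip_rate``.

    Both forward-strand CpA and its reverse-complement image TpG are hit
    symmetrically: C of CpA becomes T, G of TpG becomes A. Returns the new
    sequence and the 0-based positions of mutated bases. Sites are the
    dinucleotide occurrences in the unmutated sequence, scanned left to
    right; each is mutated independently.
    """
    out = seq.copy()
    positions: list[int] = []
    first, second = seq[:-1], seq[1:]
    cpa = np.flatnonzero((first == "C") & (second == "A"))
    tpg = np.flatnonzero((first == "T") & (second == "G"))
    for idx in cpa:
        if rng.random() < rip_rate:
            out[idx] = "T"
            positions.append(int(idx))
    for idx in tpg:
        if rng.random() < rip_rate:
            out[idx + 1] = "A"
            positions.append(int(idx) + 1)
    return out, sorted(positions)


def simulate_ripped_genome(
    cfg: SimulationConfig | None = None,
) -> tuple[RepeatAnnotatedGenome, GroundTruth]:
    """Single-scaffold genome with RIP-mutated repeats and gene intervals."""
    cfg = cfg or SimulationConfig()
    if cfg.genome_length <= cfg.repeat_length * cfg.n_repeats:
        raise GenerationError(
            "genome_length must exceed total repeat length "
            f"({cfg.repeat_length} x {cfg.n_repeats})"
        )
    rng = stage_rng(cfg.seed, "ripped_genome")
    scaffold = "scf1"
    seq = _random_sequence(rng, cfg.genome_length, cfg.gc_content)

    repeat_ivs = _place_intervals(rng, cfg.genome_length, cfg.n_repeats, cfg.repeat_length, [])
    truth = GroundTruth()
    repeats = IntervalSet()
    for i, (start, end) in enumerate(repeat_ivs):
        rid = f"rep{i:04d}"
        mutated, positions = apply_rip(seq[start:end], cfg.rip_rate, rng)
        seq[start:end] = mutated
        truth.rip_mutated_positions[rid] = [start + p for p in positions]
        repeats.add(scaffold, start, end, rid)

    genes = IntervalSet()
    if cfg.n_gene_intervals:
        gene_ivs = _place_intervals(
            rng, cfg.genome_length, cfg.n_gene_intervals, cfg.gene_length, repeat_ivs
        )
        for i, (start, end) in enumerate(gene_ivs):
            genes.add(scaffold, start, end, f"gene{i:04d}")

    genome = RepeatAnnotatedGenome({scaffold: "".join(seq)}, repeats, genes)
    return genome, truth


# ---------------------------------------------------------------------------
# Homolog hit tables

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    out[hits] = rng.choice(AMINO_ACIDS, size=len(hits))
    return out


def simulate_hit_tables(
    cfg: SimulationConfig | None = None, seq_length: int = 120
) -> tuple[list["HitTable"], dict[str, str], GroundTruth]:
    """Per-gene homolog hit tables plus protein sequences for tree tests.

    Null genes receive majority-fungal hits whose bit scores stochastically
    dominate the non-fungal ones; planted HGT genes receive <15% fungal
    hits, a top non-fungal bit score, and hit sequences arranged so the
    focal protein is closest to the non-fungal homologs. Returns the hit
    tables, a gene_id -> focal protein sequence map, and the ground truth.
    """
    from .hgt import Hit, HitTable  # local import to avoid a cycle

    cfg = cfg or SimulationConfig()
    if cfg.hits_per_gene < 2:
        raise ConfigurationError("hits_per_gene must be >= 2")
    rng = stage_rng(cfg.seed, "hit_tables")
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes_hit_tables)]
    planted = set(
        rng.choice(cfg.n_genes_hit_tables, size=cfg.n_planted_hgt, replace=False).tolist()
    )
    tables: list[HitTable] = []
    focal_seqs: dict[str, str] = {}
    truth = GroundTruth()
    for gi, gene_id in enumerate(gene_ids):
        is_hgt = gi in planted
        focal = rng.choice(AMINO_ACIDS, size=seq_length)
        focal_seqs[gene_id] = "".join(focal)
        frac = cfg.hgt_fungal_fraction if is_hgt else cfg.null_fungal_fraction
        kingdoms = np.array(["fungal" if rng.random() < frac else "non_fungal"
                             for _ in range(cfg.hits_per_gene)])
        if is_hgt:
            # keep the planted signal unambiguous: strictly below the 15% rule
            while (kingdoms == "fungal").mean() >= 0.15:
                kingdoms[int(rng.integers(0, len(kingdoms)))] = "non_fungal"
        hits = []
        for hi, kingdom in enumerate(kingdoms):
            fungal = kingdom == "fungal"
            if is_hgt:
                bit = rng.normal(450, 25) if not fungal else rng.normal(250, 25)
                close = not fungal
            else:
                bit = rng.normal(420, 25) if fungal else rng.normal(280, 25)
                close = fungal
            mut_rate = 0.05 if close else 0.40
            hit_seq = "".join(_mutate(rng, focal, mut_rate))
            hits.append(
                Hit(
                    hit_id=f"{gene_id}_h{hi:04d}",
                    taxon_name=("fungus_sp" if fungal else "bacterium_sp") + f"_{hi}",
                    kingdom=kingdom,
                    bit_score=max(float(bit), 25.0),
                    identity=1.0 - mut_rate,
                    query_coverage=1.0,
                    sequence=hit_seq,
                )
            )
        tables.append(HitTable(gene_id=gene_id, hits=hits))
        if is_hgt:
            truth.planted_hgt_gene_ids.append(gene_id)
    truth.planted_hgt_gene_ids.sort()
    return tables, focal_seqs, truth
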