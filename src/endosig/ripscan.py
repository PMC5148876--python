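"""Dinucleotide skew analysis for repeat-induced point mutation (RIP).

RIP leaves a diagnostic footprint in fungal repeats: C->T transitions at
CpA sites (and the reverse-complement TpG image) deplete CpA/TpG and
enrich TpA relative to non-repetitive control sequence. This module counts
dinucleotides in repeat and control regions, computes per-dinucleotide
fold changes (repeat frequency / control frequency), samples length-matched
non-repeat controls, builds 1 kb sliding-window tracks of gene/repeat/GC
content, and applies the length / copy-number / redundancy filters used to
build interspersed-repeat libraries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyProfileError, EndosigError, FormatError
from .io import IntervalSet
from .simulate import RepeatAnnotatedGenome, stage_rng

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass
class DinucleotideProfile:
    """Counts and frequencies of the 16 dinucleotides over a set of sequences.

    Overlapping dinucleotides are counted within each sequence, never across
    sequence boundaries; pairs containing N (or any non-ACGT symbol) are
    skipped so assembly gaps do not dilute frequencies.
    """

    counts: dict[str, int]
    n_sites: int

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_sites == 0:
            return {d: float("nan") for d in DINUCLEOTIDES}
        return {d: self.counts[d] / self.n_sites for d in DINUCLEOTIDES}


def count_dinucleotides(sequences: list[str]) -> DinucleotideProfile:
    """Count overlapping forward-strand dinucleotides in a set of sequences."""
    if not sequences:
        raise EmptyProfileError("no sequences given")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    n_sites = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - 1):
            pair = s[i : i + 2]
            if pair in counts:
                counts[pair] += 1
                n_sites += 1
    if n_sites == 0:
        raise EmptyProfileError("no countable dinucleotide sites (empty or all-N input)")
    return DinucleotideProfile(counts=counts, n_sites=n_sites)


def fold_change(
    repeats: DinucleotideProfile,
    controls: DinucleotideProfile,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-dinucleotide fold change (repeat freq / control freq) and difference.

    Returns a 16-row frame with columns ``repeat_freq``, ``control_freq``,
    ``fold`` (NaN where the control frequency is zero, with ``flag`` set to
    ``undefined``), ``diff``, and a significance call per dinucleotide: a
    chi-square goodness-of-fit of the repeat count against the control
    frequency, Bonferroni-corrected over the 16 dinucleotides.
    """
    rows = []
    rf, cf = repeats.frequencies, controls.frequencies
    n_tests = len(DINUCLEOTIDES)
    for d in DINUCLEOTIDES:
        fold = np.nan
        flag = "ok"
        if cf[d] > 0:
            fold = rf[d] / cf[d]
        else:
            flag = "undefined"
        expected = cf[d] * repeats.n_sites
        pvalue = np.nan
        if 0 < expected < repeats.n_sites:
            observed = repeats.counts[d]
            chi2 = (observed - expected) ** 2 / expected + (
                (repeats.n_sites - observed) - (repeats.n_sites - expected)
            ) ** 2 / (repeats.n_sites - expected)
            pvalue = float(stats.chi2.sf(chi2, df=1))
        significant = bool(pvalue < alpha / n_tests) if np.isfinite(pvalue) else False
        rows.append(
            {
                "dinucleotide": d,
                "repeat_freq": rf[d],
                "control_freq": cf[d],
                "fold": fold,
                "diff": rf[d] - cf[d],
                "p": pvalue,
                "significant": significant,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows).set_index("dinucleotide")


def overrepresented(table: pd.DataFrame) -> list[str]:
    return sorted(table.index[table["fold"] > 1.0])


def underrepresented(table: pd.DataFrame) -> list[str]:
    return sorted(table.index[table["fold"] < 1.0])


# ---------------------------------------------------------------------------
# Control sampling

def repeat_sequences(genome: RepeatAnnotatedGenome) -> list[str]:
    return [
        genome.sequences[scaffold][start:end]
        for scaffold, start, end, _ in genome.repeats
    ]


def sample_controls(genome: RepeatAnnotatedGenome, seed: int = 0,
                    max_tries_per_segment: int = 10_000) -> list[str]:
    """Length-matched non-repeat control segments, one per repeat.

    Segments are drawn uniformly from the non-repeat portion of the genome
    without overlapping repeats or each other, so the control set matches
    the repeat set in total mass and length distribution. Deterministic
    under ``seed``.
    """
    repeat_lengths = [(scaffold, end - start) for scaffold, start, end, _ in genome.repeats]
    non_repeat = sum(len(s) for s in genome.sequences.values()) - genome.repeats.total_length()
    if non_repeat < sum(l for _, l in repeat_lengths):
        raise EndosigError("insufficient non-repeat sequence to sample controls")
    rng = stage_rng(seed, "sample_controls")
    blocked: dict[str, list[tuple[int, int]]] = {
        scaffold: [(s, e) for s, e, _ in genome.repeats.on(scaffold)]
        for scaffold in genome.sequences
    }
    scaffolds = sorted(genome.sequences)
    controls: list[str] = []
    for _, length in repeat_lengths:
        for attempt in range(max_tries_per_segment):
            scaffold = scaffolds[int(rng.integers(0, len(scaffolds)))]
            seq = genome.sequences[scaffold]
            if len(seq) < length:
                continue
            start = int(rng.integers(0, len(seq) - length + 1))
            iv = (start, start + length)
            if any(s < iv[1] and iv[0] < e for s, e in blocked[scaffold]):
                continue
            blocked[scaffold].append(iv)
            controls.append(seq[iv[0]:iv[1]])
            break
        else:
            raise EndosigError(
                f"could not place a {length} bp control segment after "
                f"{max_tries_per_segment} tries"
            )
    return controls


# ---------------------------------------------------------------------------
# Sliding-window tracks

def _merge(intervals: list[tuple[int, int, str]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping half-open intervals (input sorted by start)."""
    merged: list[tuple[int, int]] = []
    for start, end, _ in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _covered_in_window(merged: list[tuple[int, int]], wstart: int, wend: int) -> int:
    covered = 0
    for start, end in merged:
        covered += max(0, min(end, wend) - max(start, wstart))
    return covered


def window_tracks(genome: RepeatAnnotatedGenome, window: int = 1000, step: int = 1000) -> pd.DataFrame:
    """Per-window gene, repeat and GC fractions for every scaffold.

    Windows start at 0 and advance by ``step``; a final window shorter than
    ``window`` is emitted truncated and flagged ``partial``. GC fraction
    ignores N bases.
    """
    if window <= 0 or step <= 0:
        raise FormatError("window and step must be positive")
    rows = []
    for scaffold in sorted(genome.sequences):
        seq = genome.sequences[scaffold]
        length = len(seq)
        gene_ivs = _merge(genome.genes.on(scaffold))
        repeat_ivs = _merge(genome.repeats.on(scaffold))
        start = 0
        while start < length:
            end = min(start + window, length)
            span = end - start
            chunk = seq[start:end]
            acgt = sum(chunk.count(b) for b in "ACGT")
            gc = (chunk.count("G") + chunk.count("C")) / acgt if acgt else np.nan
            rows.append(
                {
                    "scaffold": scaffold,
                    "start": start,
                    "end": end,
                    "gene_frac": _covered_in_window(gene_ivs, start, end) / span,
                    "repeat_frac": _covered_in_window(repeat_ivs, start, end) / span,
                    "gc_frac": gc,
                    "partial": span < window,
                }
            )
            start += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeat candidate filtering

@dataclass(frozen=True)
class RepeatCandidate:
    id: str
    sequence: str
    genome_hits: int

    @property
    def length(self) -> int:
        return len(self.sequence)


def filter_repeat_candidates(
    cands: list[RepeatCandidate],
    min_len: int = 50,
    min_hits: int = 10,
    cluster_identity: float = 0.90,
    cluster_coverage: float = 0.90,
) -> list[RepeatCandidate]:
    """Length / copy-number filter plus redundancy collapse of repeat candidates.

    Candidates shorter than ``min_len`` or with fewer than ``min_hits``
    genomic hits are excluded. Survivors are clustered greedily (longest
    first; global-alignment identity >= ``cluster_identity`` over >=
    ``cluster_coverage`` of the shorter sequence) and the longest member
    (ties: lexicographically smallest id) represents each cluster.
    """
    from .hgt import pairwise_identity  # shared identity routine

    survivors = [c for c in cands if c.length >= min_len and c.genome_hits >= min_hits]
    survivors.sort(key=lambda c: (-c.length, c.id))
    representatives: list[RepeatCandidate] = []
    for cand in survivors:
        for rep in representatives:
            short = min(cand.length, rep.length)
            identity, aligned_cols = pairwise_identity(
                cand.sequence, rep.sequence, return_aligned_columns=True
            )
            if identity >= cluster_identity and aligned_cols / short >= cluster_coverage:
                break
        else:
            representatives.append(cand)
    return representatives
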