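"""Lifestyle enrichment on ortholog-cluster presence/absence matrices.

Given a binary cluster x species matrix over a lifestyle-labelled panel,
this module selects clusters enriched for a target lifestyle (the pathogen
preset asks for >=4 of 5 pathogens present, at most one saprotroph, at
most one mycorrhizal species, and the focal species present; the
saprotroph preset uses the proportional analogue >=5 of 6), computes
pairwise cluster-sharing tables, summarizes functional-catalogue
annotations of selected gene sets, and places species by centered PCA so
the focal species' affinity to a lifestyle group can be read off the first
two components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EndosigError, FormatError
from .species import Lifestyle, SpeciesPanel


@dataclass(frozen=True)
class EnrichmentRule:
    target: Lifestyle
    min_present_in_target: int
    max_present_per_other: tuple[tuple[Lifestyle, int], ...]
    require_focal: bool = True

    def caps(self) -> dict[Lifestyle, int]:
        return dict(self.max_present_per_other)


def pathogen_preset() -> EnrichmentRule:
    return EnrichmentRule(
        target=Lifestyle.PATHOGEN,
        min_present_in_target=4,
        max_present_per_other=((Lifestyle.SAPROTROPH, 1), (Lifestyle.MYCORRHIZAL, 1)),
    )


def saprotroph_preset() -> EnrichmentRule:
    """Proportional analogue of the pathogen preset: >=5 of 6 saprotrophs."""
    return EnrichmentRule(
        target=Lifestyle.SAPROTROPH,
        min_present_in_target=5,
        max_present_per_other=((Lifestyle.PATHOGEN, 1), (Lifestyle.MYCORRHIZAL, 1)),
    )


def _check_matrix(m: pd.DataFrame, panel: SpeciesPanel) -> None:
    if set(m.columns) != set(panel.codes):
        raise FormatError("matrix columns must match the species panel codes")
    values = m.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError("presence/absence matrix cells must be 0 or 1")


def select_enriched_clusters(
    m: pd.DataFrame, panel: SpeciesPanel, rule: EnrichmentRule
) -> list[str]:
    """Cluster ids whose presence pattern satisfies the enrichment rule."""
    _check_matrix(m, panel)
    target_group = panel.group(rule.target)
    if not target_group:
        raise EndosigError(f"panel has no species with lifestyle {rule.target}")
    mask = m[target_group].sum(axis=1) >= rule.min_present_in_target
    for lifestyle, cap in rule.caps().items():
        group = panel.group(lifestyle)
        if not group:
            raise EndosigError(f"panel has no species with lifestyle {lifestyle}")
        mask &= m[group].sum(axis=1) <= cap
    if rule.require_focal:
        mask &= m[panel.focal] == 1
    return list(m.index[mask])


def sharing_table(m: pd.DataFrame) -> pd.DataFrame:
    """Species x species co-presence counts; diagonal = per-species totals."""
    values = m.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError("presence/absence matrix cells must be 0 or 1")
    shared = values.T @ values
    return pd.DataFrame(shared, index=m.columns, columns=m.columns)


# ---------------------------------------------------------------------------
# PCA placement

@dataclass
class PcaPlacement:
    scores: pd.DataFrame            # species x PC
    loadings: pd.DataFrame          # feature x PC
    variance_ratio: np.ndarray
    nearest_centroid: dict[str, str]  # species -> lifestyle of nearest centroid
    degenerate: bool = False


def pca_placement(
    feature_matrix: pd.DataFrame, panel: SpeciesPanel, scale: bool = False
) -> PcaPlacement:
    """Centered PCA of a species x feature matrix with lifestyle centroids.

    Features are centered (optionally scaled to unit variance); species
    scores come from the singular value decomposition. Sign convention:
    within each component the loading of largest magnitude is positive.
    Nearest lifestyle centroids are computed in PC1-PC2 space with the
    focal species excluded from centroid definitions.
    """
    if feature_matrix.shape[0] < 2 or feature_matrix.shape[1] < 2:
        raise FormatError("need at least 2 species and 2 features")
    if feature_matrix.isna().any().any():
        raise FormatError("feature matrix must have no missing cells")
    x = feature_matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    degenerate = bool(np.allclose(x, 0))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic signs: largest-|loading| entry positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k][pivot] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    scores = u * s
    total = (s ** 2).sum()
    variance_ratio = (s ** 2) / total if total > 0 else np.zeros_like(s)
    pcs = [f"PC{k + 1}" for k in range(len(s))]
    scores_df = pd.DataFrame(scores, index=feature_matrix.index, columns=pcs)
    loadings_df = pd.DataFrame(vt.T, index=feature_matrix.columns, columns=pcs)

    plane = scores_df[pcs[: min(2, len(pcs))]]
    centroids: dict[str, np.ndarray] = {}
    for lifestyle in (Lifestyle.PATHOGEN, Lifestyle.SAPROTROPH, Lifestyle.MYCORRHIZAL):
        group = [c for c in panel.group(lifestyle) if c in plane.index]
        if group:
            centroids[lifestyle.value] = plane.loc[group].mean(axis=0).to_numpy()
    nearest: dict[str, str] = {}
    for code in plane.index:
        if not centroids:
            break
        dists = {
            ls: float(np.linalg.norm(plane.loc[code].to_numpy() - c))
            for ls, c in centroids.items()
        }
        nearest[code] = min(sorted(dists), key=dists.get)
    return PcaPlacement(scores_df, loadings_df, variance_ratio, nearest, degenerate)


# ---------------------------------------------------------------------------
# Functional-catalogue rollups

def funcat_top_categories(
    gene_to_categories: dict[str, list[str]],
    selected_genes: list[str],
    k: int = 10,
) -> list[tuple[str, int]]:
    """Top-k functional categories by distinct-gene count.

    Each (gene, category) pair counts once even if annotated repeatedly;
    categories are ranked by gene count descending, ties broken by category
    id ascending. If fewer than ``k`` distinct categories exist, all are
    returned.
    """
    counts: dict[str, set[str]] = {}
    for gene in selected_genes:
        for cat in set(gene_to_categories.get(gene, ())):
            counts.setdefault(cat, set()).add(gene)
    ranked = sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(cat, len(genes)) for cat, genes in ranked[:k]]
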