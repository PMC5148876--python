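"""Protein-domain (InterPro-style) accession enrichment across genomes.

The focal genome's per-accession counts are compared against the mean of
the comparison genomes with a Z-test: z = (focal - mean) / sd with the
sample standard deviation (n-1) over the comparison species and a
two-sided normal p-value. Companion screens flag accessions whose focal
count exceeds a fold threshold of the comparison mean, mine accessions
overrepresented in one lifestyle group, build distinct-vs-total accession
saturation curves, and roll enriched accessions up to GO terms.

The normal approximation with ~13 comparison genomes is anticonservative
(the null flag rate runs near 0.08 rather than the nominal 0.05); an
optional Benjamini-Hochberg correction is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EndosigError, FormatError
from .species import Lifestyle, SpeciesPanel


def _check_counts(t: pd.DataFrame) -> None:
    values = t.to_numpy()
    if (values < 0).any():
        raise FormatError("annotation counts must be non-negative")


def ztest_enrichment(
    t: pd.DataFrame, focal: str, alpha: float = 0.05, bh_correct: bool = False
) -> pd.DataFrame:
    """Per-accession Z-test of the focal species against the comparison mean.

    Returns a frame indexed by accession with columns ``focal``, ``mean``,
    ``sd``, ``z``, ``p``, ``fold`` and ``status``. Status is ``over`` /
    ``under`` when p < alpha with the matching sign, ``ns`` otherwise.
    Accessions with zero comparison variance are ``ns`` when the focal
    count equals the common value and ``degenerate_over``/``degenerate_under``
    otherwise (counted as significant since the deviation is unambiguous).
    """
    if focal not in t.columns:
        raise FormatError(f"focal species {focal!r} not in table columns")
    _check_counts(t)
    comparison = [c for c in t.columns if c != focal]
    if len(comparison) < 3:
        raise EndosigError("need at least 3 comparison species")
    comp = t[comparison].to_numpy(dtype=float)
    fc = t[focal].to_numpy(dtype=float)
    mu = comp.mean(axis=1)
    sd = comp.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (fc - mu) / np.where(sd > 0, sd, 1.0), np.nan)
        fold = np.where(mu > 0, fc / np.where(mu > 0, mu, 1.0), np.inf)
    p = 2 * stats.norm.sf(np.abs(z))
    p_eff = p.copy()
    if bh_correct:
        finite = np.isfinite(p_eff)
        adj = stats.false_discovery_control(p_eff[finite], method="bh")
        p_eff[finite] = adj
    status = np.full(len(t), "ns", dtype=object)
    over = (sd > 0) & (p_eff < alpha) & (fc > mu)
    under = (sd > 0) & (p_eff < alpha) & (fc < mu)
    status[over] = "over"
    status[under] = "under"
    status[(sd == 0) & (fc > mu)] = "degenerate_over"
    status[(sd == 0) & (fc < mu)] = "degenerate_under"
    return pd.DataFrame(
        {
            "focal": fc,
            "mean": mu,
            "sd": sd,
            "z": z,
            "p": p_eff,
            "fold": fold,
            "status": status,
        },
        index=t.index,
    )


def significant(result: pd.DataFrame, direction: str = "over") -> list[str]:
    """Accessions flagged in the given direction (degenerate calls included)."""
    mask = result["status"].isin([direction, f"degenerate_{direction}"])
    return list(result.index[mask])


def fold_screen(
    t: pd.DataFrame, focal: str, fold_threshold: float, min_absolute: int = 3
) -> list[str]:
    """Accessions with focal count strictly above fold_threshold x comparison mean.

    Zero-mean accessions qualify only when the focal count reaches
    ``min_absolute`` (a single focal-specific copy is not a fold effect).
    """
    if fold_threshold <= 1:
        raise FormatError("fold_threshold must exceed 1")
    _check_counts(t)
    comparison = [c for c in t.columns if c != focal]
    mu = t[comparison].mean(axis=1)
    fc = t[focal]
    passes = ((mu > 0) & (fc > fold_threshold * mu)) | ((mu == 0) & (fc >= min_absolute))
    return list(t.index[passes])


def lifestyle_fold_screen(
    t: pd.DataFrame,
    panel: SpeciesPanel,
    target_lifestyle: Lifestyle | str,
    fold_threshold: float = 2.0,
) -> list[str]:
    """Accessions overrepresented in one lifestyle group of comparison species.

    An accession passes when its mean count over the target-lifestyle
    species strictly exceeds ``fold_threshold`` times its mean over all
    other comparison species; the focal species is excluded from both
    sides. The selected accessions define the feature matrix for PCA
    placement of the focal species.
    """
    target_lifestyle = Lifestyle(target_lifestyle)
    _check_counts(t)
    target = [c for c in panel.group(target_lifestyle) if c != panel.focal]
    others = [
        c for c in panel.comparison_codes
        if panel.lifestyle_of(c) is not target_lifestyle
    ]
    if not target or not others:
        raise EndosigError("lifestyle groups must be non-empty")
    target_mean = t[target].mean(axis=1)
    other_mean = t[others].mean(axis=1)
    passes = target_mean > fold_threshold * other_mean
    return list(t.index[passes])


def saturation_curve(t: pd.DataFrame) -> pd.DataFrame:
    """Per species: total annotated accession instances and distinct accessions."""
    _check_counts(t)
    return pd.DataFrame(
        {"total": t.sum(axis=0), "distinct": (t > 0).sum(axis=0)},
        index=t.columns,
    )


def go_rollup(
    enriched_accessions: list[str],
    accession_to_go: dict[str, list[str]],
    focal_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Distinct enriched accessions (and focal gene models) per GO term.

    Accessions without a GO mapping fall into an ``NA`` bin. An accession
    mapped to several terms contributes to each. Rows are ranked by
    accession count descending (ties: GO id ascending, NA last).
    """
    acc_by_term: dict[str, set[str]] = {}
    for acc in enriched_accessions:
        terms = accession_to_go.get(acc) or ["NA"]
        for term in set(terms):
            acc_by_term.setdefault(term, set()).add(acc)
    rows = []
    for term, accs in acc_by_term.items():
        n_models = (
            sum(focal_counts.get(a, 0) for a in accs) if focal_counts is not None else np.nan
        )
        rows.append({"go_id": term, "n_accessions": len(accs), "n_focal_gene_models": n_models})
    df = pd.DataFrame(rows)
    df["_na"] = df["go_id"] == "NA"
    df = df.sort_values(["n_accessions", "_na", "go_id"], ascending=[False, True, True])
    return df.drop(columns="_na").set_index("go_id")
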