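"""CAZyme module counting and plant-cell-wall substrate profiling.

Carbohydrate-active enzyme (CAZyme) annotations assign each gene one or
more family modules (GH glycoside hydrolases, GT glycosyltransferases, PL
polysaccharide lyases, CE carbohydrate esterases, AA auxiliary activities,
CBM carbohydrate-binding modules). Counting happens at the module level —
a gene with two GH5 modules contributes two — because substrate capacity
scales with modules, not gene models. Family counts are then summed into
plant-cell-wall-degrading-enzyme (PCWDE) substrate classes (cellulose,
hemicellulose, pectin, cutin, plus families acting on multiple substrates)
whose per-species totals feed PCA placement.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError

FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)[0-9]+$")

#: Substrate classes of PCWDE families.
DEFAULT_SUBSTRATE_CLASSES: dict[str, frozenset[str]] = {
    "cellulose": frozenset({"GH6", "GH7", "GH45"}),
    "hemicellulose": frozenset({"GH10", "GH11", "GH26", "GH31", "GH67", "GH115", "GH134"}),
    "pectin": frozenset({
        "GH28", "GH53", "GH78", "GH79", "GH88", "GH105", "GH106", "GH127",
        "PL1", "PL3", "PL4", "PL9", "PL11", "CE8", "CE12",
    }),
    "cutin": frozenset({"CE5"}),
    "multiple": frozenset({"GH12", "GH30", "GH43", "GH5", "GH51", "GH54", "GH62", "GH74", "GH93"}),
}

ENZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")


def module_counts(
    annotation: Mapping[str, Iterable[tuple[str, Iterable[str]]]]
) -> pd.DataFrame:
    """Species x family module-count table from per-gene family assignments.

    ``annotation`` maps species code -> iterable of (gene id, family
    modules). Every module occurrence is counted, including repeats within
    a gene. Malformed family codes raise an error naming the record.
    """
    counts: dict[str, dict[str, int]] = {}
    for species, genes in annotation.items():
        col = counts.setdefault(species, {})
        for gene_id, modules in genes:
            for fam in modules:
                if not FAMILY_RE.match(fam):
                    raise FormatError(
                        f"malformed CAZyme family code {fam!r} on gene {gene_id!r} "
                        f"of species {species!r}"
                    )
                col[fam] = col.get(fam, 0) + 1
    families = sorted({f for col in counts.values() for f in col})
    df = pd.DataFrame(
        {sp: [counts[sp].get(f, 0) for f in families] for sp in counts},
        index=families,
    ).T
    df.index.name = "species"
    return df.astype(int)


def enzyme_class_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-species subtotals by enzyme class (GH/GT/PL/CE/AA/CBM) and grand total."""
    out = pd.DataFrame(index=counts.index)
    for cls in ENZYME_CLASSES:
        members = [f for f in counts.columns if re.match(f"^{cls}[0-9]+$", f)]
        out[cls] = counts[members].sum(axis=1) if members else 0
    out["total"] = counts.sum(axis=1)
    return out


def substrate_profile(
    counts: pd.DataFrame,
    class_map: Mapping[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Species x substrate-class totals; unmapped families reported as unassigned.

    Raises on a custom map with overlapping classes. Conservation: the sum
    of all substrate-class columns plus ``unassigned`` equals the total
    module count per species.
    """
    class_map = dict(class_map) if class_map is not None else DEFAULT_SUBSTRATE_CLASSES
    seen: set[str] = set()
    for name, fams in class_map.items():
        overlap = seen & set(fams)
        if overlap:
            raise FormatError(f"substrate classes overlap on families {sorted(overlap)}")
        seen |= set(fams)
    out = pd.DataFrame(index=counts.index)
    for name, fams in class_map.items():
        members = [f for f in counts.columns if f in fams]
        out[name] = counts[members].sum(axis=1) if members else 0
    unmapped = [f for f in counts.columns if f not in seen]
    out["unassigned"] = counts[unmapped].sum(axis=1) if unmapped else 0
    return out


def pca_features(profile: pd.DataFrame) -> pd.DataFrame:
    """Substrate-class features for PCA placement (unassigned excluded)."""
    return profile.drop(columns=[c for c in ("unassigned",) if c in profile.columns])
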