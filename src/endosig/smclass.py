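"""Secondary-metabolite key-gene classification from domain architectures.

Fungal polyketide synthases (PKS) and non-ribosomal peptide synthetases
(NRPS) are multi-domain megasynthases whose class can be read from the
ordered domain string: ketosynthase (KS) and acyltransferase (AT) domains
mark a PKS, with the reducing loop (KR ketoreductase, ER enoylreductase)
separating reducing from non-reducing type I PKSs; condensation (C),
adenylation (A) and thiolation (T) domains mark an NRPS; a PKS module
fused to an NRPS module (KS with C and A) is a hybrid; A-T cores with a
terminal reductase/thioesterase but no condensation domain are NRPS-like.
Neighborhood scanning for tailoring enzymes sketches putative
secondary-metabolite clusters, and copy-number summaries compare
genome-defense gene families (RNAi/RIP machinery) across genomes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import EndosigError, FormatError

DOMAIN_VOCABULARY = frozenset({
    "SAT", "KS", "AT", "DH", "MT", "ER", "KR", "PT", "T", "TE", "TH",
    "C", "A", "R", "DUF", "Kinase", "Acyltransferase",
})

CLASSES = (
    "NRPS",
    "NRPS-like",
    "PKS-NRPS hybrid",
    "nonreducing type I PKS",
    "reducing type I PKS",
    "unclassified",
)

#: Tags recognized as tailoring enzymes when scanning gene neighborhoods.
TAILORING_TAGS = frozenset({
    "acyltransferase", "methyltransferase", "oxidoreductase", "p450",
})


def parse_architecture(arch: str | list[str]) -> list[str]:
    symbols = arch.split("-") if isinstance(arch, str) else list(arch)
    if not symbols or symbols == [""]:
        raise FormatError("domain architecture must be non-empty")
    for sym in symbols:
        if sym not in DOMAIN_VOCABULARY:
            raise FormatError(f"unknown domain symbol {sym!r}")
    return symbols


def classify_architecture(arch: str | list[str]) -> str:
    """Classify an ordered PKS/NRPS domain string into its enzyme class.

    Strict rule priority:

    1. KS together with both C and A domains -> ``PKS-NRPS hybrid``
       (a true hybrid carries a full NRPS module, not just a stray C).
    2. KS or AT present -> type I PKS, ``nonreducing`` when neither KR nor
       ER is present, else ``reducing`` (a reducing PKS may lack an
       annotated KS when the domain call is partial, hence AT suffices).
    3. C present together with A and T -> ``NRPS``.
    4. A and T without C or KS -> ``NRPS-like`` (A-T-R, A-T-TE, A-T-DUF
       cores and variants).
    5. Otherwise ``unclassified``.
    """
    symbols = set(parse_architecture(arch))
    if "KS" in symbols and "C" in symbols and "A" in symbols:
        return "PKS-NRPS hybrid"
    if "KS" in symbols or "AT" in symbols:
        if symbols.isdisjoint({"KR", "ER"}):
            return "nonreducing type I PKS"
        return "reducing type I PKS"
    if "C" in symbols and "A" in symbols and "T" in symbols:
        return "NRPS"
    if "A" in symbols and "T" in symbols:
        return "NRPS-like"
    return "unclassified"


def reference_architectures() -> pd.DataFrame:
    """The shipped table of focal-genome PKS/NRPS key genes.

    Columns: ``gene_id``, ``printed_class``, ``architecture`` — the
    curated domain strings of the 48 NRPS/NRPS-like/hybrid/PKS key genes
    of the focal root-endophyte genome, with the classes assigned by the
    original curators. Used as a golden regression set for the classifier.
    """
    path = resources.files("endosig.data") / "sm_key_gene_architectures.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Cluster detection by gene neighborhood

@dataclass
class SmCluster:
    key_gene: str
    member_genes: list[str]          # maximal run from first to last qualifying gene
    tailoring_genes: list[str]


def detect_sm_clusters(
    neighborhood: list[tuple[str, frozenset[str] | set[str]]],
    key_genes: list[str],
    window_genes: int = 10,
) -> list[SmCluster]:
    """Scan up/downstream of each key gene for tailoring-enzyme genes.

    ``neighborhood`` is the coordinate-ordered gene list of one scaffold,
    each gene with a set of functional tags. A cluster is reported when at
    least two tailoring-enzyme genes (acyl-/methyltransferase,
    oxidoreductase, cytochrome P450) lie within ``window_genes`` genes of
    the key gene; the cluster spans the maximal run from the first to the
    last qualifying gene.
    """
    index_of = {gene: i for i, (gene, _) in enumerate(neighborhood)}
    clusters: list[SmCluster] = []
    for key in key_genes:
        if key not in index_of:
            raise EndosigError(f"key gene {key!r} absent from neighborhood")
        ki = index_of[key]
        lo = max(0, ki - window_genes)
        hi = min(len(neighborhood), ki + window_genes + 1)
        tailoring = [
            (i, gene)
            for i, (gene, tags) in enumerate(neighborhood[lo:hi], start=lo)
            if i != ki and set(tags) & TAILORING_TAGS
        ]
        if len(tailoring) < 2:
            continue
        first = min(ki, min(i for i, _ in tailoring))
        last = max(ki, max(i for i, _ in tailoring))
        clusters.append(
            SmCluster(
                key_gene=key,
                member_genes=[g for g, _ in neighborhood[first:last + 1]],
                tailoring_genes=[g for _, g in tailoring],
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Copy-number summaries

_AMBIGUOUS_RE = re.compile(r"^(\d+)\((\d+)\)$")


def _resolve_cell(value, family: str, species: str) -> int:
    if isinstance(value, str):
        m = _AMBIGUOUS_RE.match(value.strip())
        if m:
            warnings.warn(
                f"ambiguous copy number {value!r} for {family}/{species}: "
                f"using {m.group(1)}",
                stacklevel=3,
            )
            return int(m.group(1))
        return int(value)
    return int(value)


def copy_number_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Median (and range) of gene-family copy numbers over species columns.

    The median includes the focal species column; even-length medians are
    the mean of the central pair. Ambiguous cells such as ``"2(3)"``
    (alternative annotations) are resolved to their first integer with a
    warning.
    """
    resolved = pd.DataFrame(
        {
            sp: [_resolve_cell(counts.at[fam, sp], fam, sp) for fam in counts.index]
            for sp in counts.columns
        },
        index=counts.index,
    )
    return pd.DataFrame(
        {
            "median": resolved.median(axis=1),
            "min": resolved.min(axis=1),
            "max": resolved.max(axis=1),
        },
        index=counts.index,
    )
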