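"""Published comparison figures for the focal root-endophyte genome.

Small printed tables from the *Phialocephala subalpina* genome project
that serve as worked-example inputs: copy numbers of RNAi/RIP machinery
genes across nine fungal genomes, the transposable-element family census,
and headline assembly/annotation counts. These are inputs to the
package's summary routines (medians, printed-percentage parity), not
outputs it claims to re-derive from sequence.
"""

from __future__ import annotations

import pandas as pd

#: Copy numbers of RNAi and RIP core gene families across nine fungal
#: genomes (columns: focal endophyte Ps, then Om, Ssc, Bc, Bg, Nc, Ca, Sc,
#: Sp). Cells like "2(3)" record an alternative annotation.
RNAI_RIP_SPECIES = ["Ps", "Om", "Ssc", "Bc", "Bg", "Nc", "Ca", "Sc", "Sp"]

RNAI_RIP_COPY_NUMBERS: dict[str, list] = {
    "Argonaute": [4, 2, 2, 3, "2(3)", 2, 1, 0, 1],
    "Dicer": [4, 2, 2, 2, 2, 2, 0, 0, 1],
    "RdRP": [5, 3, 3, 3, 1, 3, 0, 0, 1],
    "Dnmt1": [4, 3, 3, "2(3)", 0, 2, 0, 0, 0],
}

#: Published medians for the same rows; the Dnmt1 row's printed median (1)
#: does not match any single computation convention and is flagged rather
#: than reproduced.
RNAI_RIP_PUBLISHED_MEDIANS = {"Argonaute": 2, "Dicer": 2, "RdRP": 3, "Dnmt1": 1}


def rnai_rip_table() -> pd.DataFrame:
    return pd.DataFrame(RNAI_RIP_COPY_NUMBERS, index=RNAI_RIP_SPECIES).T


#: Transposable-element family census of the focal genome:
#: (percent of all TEs, cumulative length in kb).
TE_FAMILIES: dict[str, tuple[float, int]] = {
    "Gypsy": (28.9, 1452),
    "Copia": (26.1, 1308),
    "non_LTR": (4.6, 229),
    "Tc1_Mariner": (8.2, 411),
    "Helitron": (3.9, 194),
    "MITE": (1.2, 59),
    "hAT": (0.6, 32),
    "Mutator": (0.4, 18),
    "not_classified": (26.2, 1284),
}


def te_table() -> pd.DataFrame:
    return pd.DataFrame(
        [(fam, pct, kb) for fam, (pct, kb) in TE_FAMILIES.items()],
        columns=["family", "pct_of_tes", "length_kb"],
    ).set_index("family")


#: Headline assembly/annotation counts of the focal genome and its
#: 13-genome comparison.
GENOME_SIZE_KB = 69_690                 # 69.69 Mb assembly
N_ORTHOLOG_CLUSTERS = 20_555            # clusters over all 14 proteomes
N_FOCAL_CLUSTERS = 12_932               # clusters containing the focal species
N_INTERPRO_ACCESSIONS = 6_556           # distinct accessions over the panel
N_ACCESSIONS_OVER_3X = 386              # focal count > 3x comparison mean
N_ASSEMBLED_TRANSCRIPTS = 28_092
N_MAPPED_TRANSCRIPTS = 28_045
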