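"""Species panels for comparative analysis.

A panel is an ordered list of species codes with lifestyle labels. The
default panel mirrors the 14-genome comparison around the root endophyte
*Phialocephala subalpina* (code ``Ps``): five plant pathogens, six
saprotrophs, two ectomycorrhizal species, and the focal endophyte. The
ericoid-mycorrhizal/peat saprotroph *Oidiodendron maius* is counted with
the saprotrophs, which yields the six-species saprotroph group the
enrichment rules assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ConfigurationError


class Lifestyle(str, Enum):
    PATHOGEN = "pathogen"
    SAPROTROPH = "saprotroph"
    MYCORRHIZAL = "mycorrhizal"
    FOCAL = "focal"


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered species codes with lifestyle labels; exactly one focal species."""

    species: tuple[tuple[str, Lifestyle], ...]

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.species]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("species codes must be unique")
        n_focal = sum(1 for _, ls in self.species if ls is Lifestyle.FOCAL)
        if n_focal != 1:
            raise ConfigurationError(
                f"panel must contain exactly one focal species, got {n_focal}"
            )

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.species]

    @property
    def focal(self) -> str:
        return next(c for c, ls in self.species if ls is Lifestyle.FOCAL)

    def lifestyle_of(self, code: str) -> Lifestyle:
        for c, ls in self.species:
            if c == code:
                return ls
        raise KeyError(code)

    def group(self, lifestyle: Lifestyle | str) -> list[str]:
        lifestyle = Lifestyle(lifestyle)
        return [c for c, ls in self.species if ls is lifestyle]

    @property
    def comparison_codes(self) -> list[str]:
        """All species codes except the focal one."""
        return [c for c, ls in self.species if ls is not Lifestyle.FOCAL]


def default_panel() -> SpeciesPanel:
    """The 14-species panel: 5 pathogens, 6 saprotrophs, 2 ectomycorrhizal, 1 focal."""
    P, S, M, F = (
        Lifestyle.PATHOGEN,
        Lifestyle.SAPROTROPH,
        Lifestyle.MYCORRHIZAL,
        Lifestyle.FOCAL,
    )
    return SpeciesPanel(
        (
            ("Bc", P),   # Botrytis cinerea (necrotroph)
            ("Ssc", P),  # Sclerotinia sclerotiorum (necrotroph)
            ("Bg", P),   # Blumeria graminis (obligate biotroph)
            ("Mb", P),   # Marssonina brunnea (hemi-biotroph)
            ("Fo", P),   # Fusarium oxysporum (hemi-biotroph)
            ("Af", S),   # Aspergillus flavus
            ("Tr", S),   # Trichoderma reesei
            ("Chg", S),  # Chaetomium globosum
            ("Pc", S),   # Penicillium chrysogenum
            ("Gl", S),   # Glarea lozoyensis
            ("Om", S),   # Oidiodendron maius (saprotroph/ericoid mycorrhizal)
            ("Tm", M),   # Tuber melanosporum
            ("Ceg", M),  # Cenococcum geophilum
            ("Ps", F),   # Phialocephala subalpina (focal root endophyte)
        )
    )
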