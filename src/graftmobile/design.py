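"""Experimental design of a reciprocal two-species grafting study.

A grafted plant is written ``scion/rootstock`` (e.g. ``Csa/Cmo`` is a
cucumber scion on a pumpkin rootstock).  The full factorial design crosses
the four graft combinations of two species with two tissues (leaf above the
junction, root below it), two conditions (control and 6-h chilling) and a
fixed number of biological replicates.

Every tissue sample has a *resident* species — the graft partner the tissue
physically belongs to: the leaf belongs to the scion, the root to the
rootstock.  In a heterograft the other partner is the *foreign* species;
transcripts of the foreign species detected in a tissue are the evidence of
cross-junction mRNA movement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

SPECIES = ("Csa", "Cmo")
TISSUES = ("leaf", "root")
CONDITIONS = ("control", "chilling")

#: condition label used for the unchilled baseline
CONTROL = "control"
#: condition label used for the 6-h chilling treatment
CHILLING = "chilling"


@dataclass(frozen=True, order=True)
class GraftSample:
    """One sequenced or measured sample in the grafting design."""

    scion: str
    rootstock: str
    tissue: str
    condition: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.scion not in SPECIES or self.rootstock not in SPECIES:
            raise ValueError(f"unknown species in {self.scion}/{self.rootstock}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")

    @property
    def graft(self) -> str:
        """Graft combination in scion/rootstock notation, e.g. ``Csa/Cmo``."""
        return f"{self.scion}/{self.rootstock}"

    @property
    def is_heterograft(self) -> bool:
        return self.scion != self.rootstock

    @property
    def resident_species(self) -> str:
        """Species the sampled tissue belongs to (scion for leaf, rootstock for root)."""
        return self.scion if self.tissue == "leaf" else self.rootstock

    @property
    def foreign_species(self) -> str | None:
        """The other graft partner, or None in a homograft."""
        if not self.is_heterograft:
            return None
        return self.rootstock if self.resident_species == self.scion else self.scion

    @property
    def key(self) -> str:
        """Stable sample identifier ``scion_rootstock.tissue.condition.repN``."""
        return f"{self.scion}_{self.rootstock}.{self.tissue}.{self.condition}.rep{self.replicate}"

    @classmethod
    def from_key(cls, key: str) -> "GraftSample":
        graft, tissue, condition, rep = key.split(".")
        scion, rootstock = graft.split("_")
        if not rep.startswith("rep"):
            raise ValueError(f"malformed sample key {key!r}")
        return cls(scion, rootstock, tissue, condition, int(rep[3:]))

    def matched_homograft(self) -> "GraftSample":
        """The homograft of the resident species with identical tissue/condition/replicate.

        This is the background sample used to veto mapping artifacts: reads in
        a pure homograft that still look foreign cannot have crossed a graft
        junction.
        """
        s = self.resident_species
        return GraftSample(s, s, self.tissue, self.condition, self.replicate)


def full_design(n_replicates: int = 3) -> list[GraftSample]:
    """Enumerate all 4 graft combinations x 2 tissues x 2 conditions x replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        GraftSample(sc, rs, ti, co, rep)
        for sc, rs in itertools.product(SPECIES, SPECIES)
        for ti in TISSUES
        for co in CONDITIONS
        for rep in range(1, n_replicates + 1)
    ]


def heterograft_samples(design: list[GraftSample]) -> list[GraftSample]:
    return [s for s in design if s.is_heterograft]


def other_species(species: str) -> str:
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    return SPECIES[1 - SPECIES.index(species)]


def resident_heterograft(species: str, tissue: str) -> tuple[str, str]:
    """The (scion, rootstock) of the heterograft whose *tissue* belongs to *species*."""
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}")
    if tissue == "leaf":
        return species, other_species(species)
    return other_species(species), species
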