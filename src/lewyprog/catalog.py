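"""Canonical anatomical region panel for Lewy pathology staging.

The pipeline scores phosphorylated-alpha-synuclein pathology in 16 anatomical
regions spanning the central and peripheral autonomic nervous systems: ten
CNS regions, the olfactory bulb (OB), the sympathetic trunk/ganglia (SY) and
four peripheral organs (heart, esophagus, adrenal gland, skin).
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Canonical region identifiers, in panel order.
REGIONS: tuple[str, ...] = (
    "DMV", "LC", "SN", "NBM", "AMY", "TrE", "CIN", "T", "F", "P",
    "OB", "SY", "HE", "ESO", "ADR", "SKIN",
)

_CNS: frozenset[str] = frozenset(
    {"DMV", "LC", "SN", "NBM", "AMY", "TrE", "CIN", "T", "F", "P", "OB"}
)
_PNS: frozenset[str] = frozenset({"SY", "HE", "ESO", "ADR", "SKIN"})


@dataclass(frozen=True)
class RegionCatalog:
    """The 16-region panel with its role tags.

    Attributes
    ----------
    regions
        Ordered tuple of the 16 canonical region identifiers.
    peripheral_organs
        The four peripheral organ biopsies (heart, esophagus, adrenal, skin).
    brain_markers / body_markers
        The two region pairs used by the a priori brain-first vs body-first
        classification (amygdala + olfactory bulb vs dorsal motor nucleus of
        the vagus + sympathetic trunk).
    cns10
        The ten-region CNS subset used for the restricted, CNS-only analysis
        (the CNS panel minus the olfactory bulb).
    """

    regions: tuple[str, ...] = REGIONS
    peripheral_organs: frozenset[str] = frozenset({"HE", "ESO", "ADR", "SKIN"})
    brain_markers: frozenset[str] = frozenset({"AMY", "OB"})
    body_markers: frozenset[str] = frozenset({"DMV", "SY"})
    cns10: tuple[str, ...] = (
        "DMV", "LC", "SN", "NBM", "AMY", "TrE", "CIN", "T", "F", "P",
    )
    class_of: dict[str, str] = field(default_factory=lambda: {
        r: ("CNS" if r in _CNS else "PNS") for r in REGIONS
    })

    def __post_init__(self) -> None:
        if len(self.regions) != 16 or len(set(self.regions)) != 16:
            raise ValueError("catalog must contain exactly 16 unique regions")
        if not self.peripheral_organs <= {r for r in self.regions
                                          if self.class_of[r] == "PNS"}:
            raise ValueError("peripheral organs must be PNS regions")
        if self.brain_markers & self.body_markers:
            raise ValueError("brain and body marker sets must be disjoint")
        if len(self.cns10) != 10 or any(self.class_of[r] != "CNS"
                                        for r in self.cns10):
            raise ValueError("cns10 must be 10 CNS regions")

    def resolve(self, name: str) -> str:
        """Map a case-insensitive alias (e.g. ``Skin``) onto its canonical id."""
        upper = name.strip().upper()
        for r in self.regions:
            if r.upper() == upper:
                return r
        raise KeyError(f"unknown region identifier: {name!r}")


#: Module-level default catalog; all pipeline stages share it.
CATALOG = RegionCatalog()
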