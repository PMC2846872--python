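"""The 41-analyte serum chemistry panel.

Every cohort, classifier and report in this package works over a fixed panel of
41 blood-chemistry measures, indexed 1..41.  The panel order is load-bearing:
cohort CSV columns, feature indices in elimination orders and vote tallies all
refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PanelEntry", "FeaturePanel", "PANEL"]

# (index, analyte code, units).  Units are reporting metadata only; the
# analysis is unit-agnostic (features are z-scored before classification).
_PANEL_ROWS = [
    (1, "TP", "g/L"),
    (2, "ALB", "g/L"),
    (3, "ALT", "U/L"),
    (4, "AST", "U/L"),
    (5, "TB", "umol/L"),
    (6, "GLU", "mmol/L"),
    (7, "UN", "mmol/L"),
    (8, "Cr", "umol/L"),
    (9, "UA", "umol/L"),
    (10, "ALP", "U/L"),
    (11, "GGT", "U/L"),
    (12, "CK", "U/L"),
    (13, "LDH", "U/L"),
    (14, "HDL", "mmol/L"),
    (15, "LDL", "mmol/L"),
    (16, "Ca", "mmol/L"),
    (17, "PHOS", "mmol/L"),
    (18, "Mg", "mmol/L"),
    (19, "CHOL", "mmol/L"),
    (20, "TG", "mmol/L"),
    (21, "TCO2", "mmol/L"),
    (22, "UIBC", "umol/L"),
    (23, "Fe", "umol/L"),
    (24, "APOA1", "g/L"),
    (25, "APOB", "g/L"),
    (26, "CK-MB", "U/L"),
    (27, "APOA2", "mg/dL"),
    (28, "APOC2", "mg/dL"),
    (29, "APOC3", "mg/dL"),
    (30, "APOE", "mg/dL"),
    (31, "LP(a)", "mg/dL"),
    (32, "MAO", "U/L"),
    (33, "PLIP", "mmol/L"),
    (34, "FRUC", "umol/L"),
    (35, "DB", "umol/L"),
    (36, "TBA", "umol/L"),
    (37, "ADA", "U/L"),
    (38, "Na", "mmol/L"),
    (39, "K", "mmol/L"),
    (40, "Cl", "mmol/L"),
    (41, "TIBC", "umol/L"),
]


@dataclass(frozen=True)
class PanelEntry:
    index: int
    name: str
    units: str


class FeaturePanel:
    """Ordered, validated collection of the 41 panel analytes.

    Parameters
    ----------
    entries
        ``(index, name, units)`` triples.  Indices must be exactly 1..41, each
        used once, with unique names.
    """

    N_FEATURES = 41

    def __init__(self, entries=_PANEL_ROWS):
        entries = [PanelEntry(*e) if not isinstance(e, PanelEntry) else e
                   for e in entries]
        if len(entries) != self.N_FEATURES:
            raise ValueError(
                f"panel must have exactly {self.N_FEATURES} entries, "
                f"got {len(entries)}"
            )
        indices = [e.index for e in entries]
        if sorted(indices) != list(range(1, self.N_FEATURES + 1)):
            raise ValueError("panel indices must be exactly 1..41, each once")
        names = [e.name for e in entries]
        if len(set(names)) != self.N_FEATURES:
            raise ValueError("panel analyte names must be unique")
        self.entries = sorted(entries, key=lambda e: e.index)
        self._by_index = {e.index: e for e in self.entries}
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        """Analyte codes in panel (index) order."""
        return [e.name for e in self.entries]

    @property
    def indices(self) -> list[int]:
        return [e.index for e in self.entries]

    def name_of(self, index: int) -> str:
        return self._by_index[index].name

    def index_of(self, name: str) -> int:
        if name not in self._by_name:
            raise KeyError(f"unknown panel analyte {name!r}")
        return self._by_name[name].index

    def resolve(self, key) -> int:
        """Map an analyte name or 1-based index to its panel index."""
        if isinstance(key, str):
            return self.index_of(key)
        key = int(key)
        if key not in self._by_index:
            raise KeyError(f"panel index {key} out of range 1..41")
        return key


#: The canonical panel instance used throughout the package.
PANEL = FeaturePanel()
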