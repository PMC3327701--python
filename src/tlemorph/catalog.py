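"""Canonical structure catalog for the 83-region whole-brain parcellation.

The catalog fixes the region names used throughout the package, the subset
of regions whose volumes are full-structure volumes rather than grey-matter
portions, and the left/right mirror map used to reflect lateralized effect
definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources

__all__ = ["StructureCatalog", "default_catalog"]


@dataclass(frozen=True)
class StructureCatalog:
    """The named regions of the parcellation.

    Parameters
    ----------
    names
        Canonical region names in canonical order. Paired structures carry
        ``_L``/``_R`` suffixes; midline structures carry none.
    gm_exempt
        Regions whose volume is the full structure volume (no grey-matter
        masking): ventricles, corpus callosum, deep grey nuclei, brainstem.
    lobes
        Optional map region -> anatomical grouping, informational only.
    """

    names: tuple[str, ...]
    gm_exempt: frozenset[str]
    lobes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog names must be unique")
        unknown = self.gm_exempt - set(self.names)
        if unknown:
            raise ValueError(f"gm_exempt entries not in catalog: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def mirror(self, name: str) -> str:
        """Return the contralateral homologue; midline names map to themselves."""
        if name.endswith("_L"):
            out = name[:-2] + "_R"
        elif name.endswith("_R"):
            out = name[:-2] + "_L"
        else:
            return name
        if out not in set(self.names):
            raise KeyError(f"no contralateral homologue for {name!r}")
        return out

    def mirror_effects(self, effects: dict[str, float]) -> dict[str, float]:
        """Reflect an effect map across the midline (L <-> R swap)."""
        return {self.mirror(k): v for k, v in effects.items()}


def default_catalog() -> StructureCatalog:
    """Load the shipped 83-region catalog."""
    ref = _importlib_resources.files("tlemorph.resources").joinpath("structures.json")
    data = json.loads(ref.read_text())
    return StructureCatalog(
        names=tuple(data["names"]),
        gm_exempt=frozenset(data["gm_exempt"]),
        lobes=dict(data.get("lobes", {})),
    )
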