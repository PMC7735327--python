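"""Ordered bank of already-segmented reference subjects (the "atlas")."""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import SegmentationMask, Volume3D

__all__ = ["AtlasBank", "AtlasEntry"]


@dataclass
class AtlasEntry:
    id: str
    image: Volume3D
    mask: SegmentationMask

    def __post_init__(self) -> None:
        self.image.require_same_grid(self.mask)


@dataclass
class AtlasBank:
    """Ordered (id, image, mask) triplets on compatible grids with unique ids."""

    entries: list[AtlasEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("atlas ids must be unique")
        for e in self.entries[1:]:
            self.entries[0].image.require_same_grid(e.image)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> AtlasEntry:
        return self.entries[i]

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def subset(self, ids) -> "AtlasBank":
        wanted = list(ids)
        by_id = {e.id: e for e in self.entries}
        missing = [i for i in wanted if i not in by_id]
        if missing:
            raise KeyError(f"unknown atlas ids: {missing}")
        return AtlasBank([by_id[i] for i in wanted])

    def without(self, id_: str) -> "AtlasBank":
        if id_ not in self.ids:
            raise KeyError(f"unknown atlas id: {id_}")
        return AtlasBank([e for e in self.entries if e.id != id_])

    def extended(self, extra: "AtlasBank | list[AtlasEntry]") -> "AtlasBank":
        more = list(extra.entries) if isinstance(extra, AtlasBank) else list(extra)
        return AtlasBank(list(self.entries) + more)
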