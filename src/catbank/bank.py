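"""Item-bank container: calibrated polytomous items on a common latent metric.

An :class:`ItemBank` holds, per item, the generalized partial credit model
(GPCM) parameters — a discrimination ``a`` and ``K-1`` step thresholds ``b`` —
plus bookkeeping the pipeline needs (reverse-coding flags, category-collapsing
maps).  Banks serialize to a small JSON schema so every pipeline stage can be
re-run from its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["Item", "ItemBank"]


@dataclass
class Item:
    """One calibrated polytomous item.

    ``thresholds`` are the GPCM step parameters b_ik, k = 1..K-1, on the
    latent scale; they need not be ordered after calibration (disordered
    steps signal never-modal categories).
    """

    id: str
    n_categories: int
    discrimination: float
    thresholds: list[float]
    reverse_coded: bool = False
    collapse_map: list[int] | None = None  # original code -> analysis code
    text: str | None = None

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.id}: need >= 2 categories")
        if len(self.thresholds) != self.n_categories - 1:
            raise ValueError(
                f"item {self.id}: expected {self.n_categories - 1} thresholds, "
                f"got {len(self.thresholds)}"
            )
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(f"item {self.id}: discrimination must be > 0")
        if self.collapse_map is not None:
            tgt = sorted(set(self.collapse_map))
            if tgt != list(range(len(tgt))) or len(tgt) < 2:
                raise ValueError(
                    f"item {self.id}: collapse map must be surjective onto 0..K'-1 "
                    "with K' >= 2"
                )


@dataclass
class ItemBank:
    items: list[Item]
    # affine 0-100 transform metadata: theta clipped to [lo, hi]
    transform: dict = field(default_factory=lambda: {"theta_lo": -4.0, "theta_hi": 4.0})

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> Item:
        return self.items[i]

    @property
    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def discriminations(self) -> np.ndarray:
        return np.array([it.discrimination for it in self.items])

    @property
    def thresholds(self) -> list[np.ndarray]:
        return [np.asarray(it.thresholds, dtype=float) for it in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items])

    def index_of(self, item_id: str) -> int:
        try:
            return self.ids.index(item_id)
        except ValueError:
            raise KeyError(f"item {item_id!r} not in bank") from None

    def subset(self, indices) -> "ItemBank":
        return ItemBank([self.items[i] for i in indices], transform=dict(self.transform))

    def to_dict(self) -> dict:
        return {"items": [asdict(it) for it in self.items], "transform": dict(self.transform)}

    @classmethod
    def from_dict(cls, d: dict) -> "ItemBank":
        return cls(
            items=[Item(**it) for it in d["items"]],
            transform=dict(d.get("transform", {"theta_lo": -4.0, "theta_hi": 4.0})),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "ItemBank":
        return cls.from_dict(json.loads(Path(path).read_text()))
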