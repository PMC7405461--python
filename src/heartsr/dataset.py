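"""Paired high/low-resolution dataset container with an HDF5 archive format.

Layout: ``/hr/{i}`` and ``/lr/{i}`` hold the volumes (spacing as an
attribute), ``/meta/{i}`` holds the per-item provenance as a JSON string
attribute, and ``/masks/{i}`` the integer label map (1=blood, 2=myocardium,
3=lung) when region masks are present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .phantom import RegionMasks
from .volume import Volume

__all__ = ["PairItem", "PairedDataset"]


@dataclass
class PairItem:
    hr: Volume
    lr: Volume
    meta: dict
    masks: RegionMasks | None = None

    @property
    def item_id(self) -> str:
        return str(self.meta.get("item_id", ""))


@dataclass
class PairedDataset:
    items: list[PairItem] = field(default_factory=list)
    master_seed: int | None = None

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> PairItem:
        return self.items[i]

    def __iter__(self):
        return iter(self.items)

    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, indices) -> "PairedDataset":
        return PairedDataset(items=[self.items[i] for i in indices], master_seed=self.master_seed)

    def save(self, path) -> None:
        with h5py.File(str(path), "w") as f:
            if self.master_seed is not None:
                f.attrs["master_seed"] = int(self.master_seed)
            f.attrs["n_items"] = len(self.items)
            for i, it in enumerate(self.items):
                for name, vol in (("hr", it.hr), ("lr", it.lr)):
                    d = f.create_dataset(f"/{name}/{i}", data=np.asarray(vol.data, dtype=np.float32))
                    d.attrs["spacing"] = np.asarray(vol.spacing, dtype=np.float64)
                    d.attrs["normalized"] = bool(vol.normalized)
                g = f.require_group("/meta")
                g.attrs[str(i)] = json.dumps(it.meta, sort_keys=True)
                if it.masks is not None:
                    f.create_dataset(f"/masks/{i}", data=it.masks.to_labelmap())

    @classmethod
    def load(cls, path) -> "PairedDataset":
        items: list[PairItem] = []
        with h5py.File(str(path), "r") as f:
            n = int(f.attrs["n_items"])
            master = int(f.attrs["master_seed"]) if "master_seed" in f.attrs else None
            for i in range(n):
                vols = {}
                for name in ("hr", "lr"):
                    d = f[f"/{name}/{i}"]
                    vols[name] = Volume(
                        data=np.asarray(d[...], dtype=np.float64),
                        spacing=tuple(d.attrs["spacing"]),
                        normalized=bool(d.attrs["normalized"]),
                    )
                meta = json.loads(f["/meta"].attrs[str(i)])
                masks = None
                if "masks" in f and str(i) in f["masks"]:
                    masks = RegionMasks.from_labelmap(np.asarray(f[f"/masks/{i}"][...]))
                items.append(PairItem(hr=vols["hr"], lr=vols["lr"], meta=meta, masks=masks))
        return cls(items=items, master_seed=master)
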