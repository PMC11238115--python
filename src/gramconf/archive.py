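"""Hierarchical archive of per-molecule Gram matrices.

Layout (HDF5): one group per molecule, keyed by molecule id, holding
``gram`` — the N x N row-major float64 Gram matrix in A^2 — and ``elements``
— length-N fixed-ASCII element symbols; the group attribute ``n_atoms``
stores N. Any HDF5 reader can consume the file without this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import GramMatrix


@dataclass
class GramRecord:
    id: str
    gram: GramMatrix
    elements: list[str]

    def __post_init__(self) -> None:
        if len(self.elements) != self.gram.n_atoms:
            raise ValueError("elements length must match Gram dimension")


def write_gram_archive(path, records: list[GramRecord]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gramconf-gram-archive"
        f.attrs["version"] = 1
        for rec in records:
            grp = f.create_group(rec.id)
            grp.attrs["n_atoms"] = rec.gram.n_atoms
            grp.create_dataset("gram", data=rec.gram.values, dtype=np.float64)
            grp.create_dataset("elements",
                               data=np.array(rec.elements, dtype="S4"))


def read_gram_archive(path) -> list[GramRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for mol_id in f.keys():
            grp = f[mol_id]
            elements = [e.decode() for e in grp["elements"][()]]
            records.append(GramRecord(mol_id, GramMatrix(grp["gram"][()]), elements))
    return records
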