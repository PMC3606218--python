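"""Cortical/subcortical parcellation tables and lobar groupings.

The full-resolution node set mirrors the gyral atlas used for structural
connectomes at "scale 33": 33 cortical regions per hemisphere plus the
hippocampus and amygdala bilaterally, 70 nodes in total.  Five
lobe-hemisphere units per hemisphere (frontal, parietal, temporal,
occipital, limbic) support the lobar aggregation; the limbic unit
comprises the four cingulate parts, the entorhinal and parahippocampal
gyri, the hippocampus and the amygdala.

The frontal pole, temporal pole and banks of the superior temporal
sulcus carry ``excluded=True``: they stay nodes of every matrix but are
dropped from regional statistics (their delineation is unreliable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic")
HEMISPHERES = ("L", "R")

# 33 cortical gyral regions per hemisphere, grouped by lobe.
_CORTICAL_BY_LOBE = {
    "frontal": [
        "caudalmiddlefrontal",
        "frontalpole",
        "lateralorbitofrontal",
        "medialorbitofrontal",
        "paracentral",
        "parsopercularis",
        "parsorbitalis",
        "parstriangularis",
        "precentral",
        "rostralmiddlefrontal",
        "superiorfrontal",
    ],
    "parietal": [
        "inferiorparietal",
        "postcentral",
        "precuneus",
        "superiorparietal",
        "supramarginal",
    ],
    "temporal": [
        "bankssts",
        "fusiform",
        "inferiortemporal",
        "middletemporal",
        "superiortemporal",
        "temporalpole",
        "transversetemporal",
    ],
    "occipital": [
        "cuneus",
        "lateraloccipital",
        "lingual",
        "pericalcarine",
    ],
    "limbic": [
        "caudalanteriorcingulate",
        "isthmuscingulate",
        "posteriorcingulate",
        "rostralanteriorcingulate",
        "entorhinal",
        "parahippocampal",
    ],
}

_SUBCORTICAL = ["hippocampus", "amygdala"]  # per hemisphere, limbic

_EXCLUDED = {"frontalpole", "temporalpole", "bankssts"}


@dataclass
class Parcellation:
    """A labelled node set, optionally backed by a voxel label volume.

    ``roi_table`` columns: id (1-based, matches label-volume values),
    name, hemisphere (L/R), lobe, cls (cortical/subcortical), excluded.
    """

    roi_table: pd.DataFrame
    label_volume: Optional[np.ndarray] = None
    name: str = "custom"

    def __post_init__(self) -> None:
        required = {"id", "name", "hemisphere", "lobe", "cls", "excluded"}
        missing = required - set(self.roi_table.columns)
        if missing:
            raise ValueError(f"roi_table missing columns: {sorted(missing)}")
        if self.roi_table["id"].duplicated().any():
            raise ValueError("duplicate ROI ids")

    @property
    def n_nodes(self) -> int:
        return len(self.roi_table)

    @property
    def n_cortical(self) -> int:
        return int((self.roi_table["cls"] == "cortical").sum())

    def index_of(self, roi_id: int) -> int:
        """0-based matrix index of an ROI id."""
        idx = self._id_index().get(roi_id)
        if idx is None:
            raise KeyError(f"unknown ROI id {roi_id}")
        return idx

    def _id_index(self) -> dict:
        if not hasattr(self, "_id_idx"):
            self._id_idx = {
                int(r): i for i, r in enumerate(self.roi_table["id"].to_numpy())
            }
        return self._id_idx

    def lobar_units(self) -> list[tuple[str, str]]:
        """The 10 lobe-hemisphere units, left lobes first."""
        return [(lobe, hemi) for hemi in HEMISPHERES for lobe in LOBES]

    def node_unit_indices(self) -> np.ndarray:
        """Map each node (matrix index) to its lobar-unit index (0..9)."""
        units = {u: k for k, u in enumerate(self.lobar_units())}
        out = np.empty(self.n_nodes, dtype=int)
        for i, row in enumerate(self.roi_table.itertuples(index=False)):
            key = (row.lobe, row.hemisphere)
            if key not in units:
                raise ValueError(f"node {row.name!r} has no lobar unit {key}")
            out[i] = units[key]
        return out


def connectome_atlas() -> Parcellation:
    """The 70-node whole-brain atlas (66 cortical + 4 subcortical).

    Node order: all left-hemisphere regions (cortical by lobe, then
    hippocampus and amygdala), then the right hemisphere in the same
    order.  Within a lobe, anatomically grouped regions are adjacent,
    so near-diagonal cells of the connection matrix correspond to
    short-range connections.
    """
    rows = []
    rid = 1
    for hemi in HEMISPHERES:
        for lobe in LOBES:
            for name in _CORTICAL_BY_LOBE[lobe]:
                rows.append(
                    dict(
                        id=rid,
                        name=f"{hemi.lower()}h.{name}",
                        hemisphere=hemi,
                        lobe=lobe,
                        cls="cortical",
                        excluded=name in _EXCLUDED,
                    )
                )
                rid += 1
        for name in _SUBCORTICAL:
            rows.append(
                dict(
                    id=rid,
                    name=f"{hemi.lower()}h.{name}",
                    hemisphere=hemi,
                    lobe="limbic",
                    cls="subcortical",
                    excluded=False,
                )
            )
            rid += 1
    table = pd.DataFrame(rows)
    return Parcellation(roi_table=table, name="connectome70")


def toy_parcellation(label_volume: np.ndarray, lobes: dict[int, tuple[str, str]] | None = None) -> Parcellation:
    """Small parcellation over an arbitrary label volume (phantom tests).

    ``lobes`` maps label id -> (lobe, hemisphere); defaults to frontal/L.
    """
    ids = sorted(int(v) for v in np.unique(label_volume) if v != 0)
    lobes = lobes or {}
    rows = [
        dict(
            id=i,
            name=f"roi{i}",
            hemisphere=lobes.get(i, ("frontal", "L"))[1],
            lobe=lobes.get(i, ("frontal", "L"))[0],
            cls="cortical",
            excluded=False,
        )
        for i in ids
    ]
    return Parcellation(roi_table=pd.DataFrame(rows), label_volume=label_volume, name="toy")
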