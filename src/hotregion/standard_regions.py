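"""Ground-truth (standard) hot regions from sphere-contact connectivity.

Each true hot spot is modeled as a sphere centered on its alpha-carbon whose
radius comes from the residue's mean volume, r = (3V / 4 pi)^(1/3). Two hot
spots are in contact when the distance between their centers is strictly less
than the sum of their radii plus a 2 A tolerance. The contact graph's
connected components with at least three members are the standard hot
regions; smaller components are discarded.

The bundled volume table is the Chothia-style set of mean residue volumes
(cubic angstroms) commonly used for this construction; it can be overridden
to match any published volume set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .clustering import HotRegion
from .labeling import LabeledResidue

DEFAULT_CONTACT_TOLERANCE = 2.0  # angstrom
MIN_REGION_SIZE = 3

#: Mean residue volumes, cubic angstroms (Chothia-style set).
RESIDUE_VOLUMES: dict[str, float] = {
    "ALA": 91.5, "ARG": 202.1, "ASN": 135.2, "ASP": 124.5, "CYS": 105.6,
    "GLN": 161.1, "GLU": 155.1, "GLY": 66.4, "HIS": 167.3, "ILE": 168.8,
    "LEU": 167.9, "LYS": 171.3, "MET": 170.8, "PHE": 203.4, "PRO": 129.3,
    "SER": 99.1, "THR": 122.1, "TRP": 237.6, "TYR": 203.6, "VAL": 141.7,
}


class VolumeLookupError(KeyError):
    """Raised for an amino acid missing from the volume table."""


def radius_from_volume(volume: float) -> float:
    """Radius of a sphere of the given volume, (3V / 4 pi)^(1/3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ResidueSphere:
    """A hot spot as a sphere: alpha-carbon center, volume-derived radius."""

    complex_id: str
    chain: str
    position: int
    center: np.ndarray
    radius: float

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.complex_id, self.chain, self.position)


def sphere_for_residue(
    residue: LabeledResidue, volumes: Optional[Mapping[str, float]] = None
) -> ResidueSphere:
    table = RESIDUE_VOLUMES if volumes is None else volumes
    try:
        volume = table[residue.wild_aa]
    except KeyError:
        raise VolumeLookupError(
            f"no volume for amino acid {residue.wild_aa!r} at {residue.site}"
        ) from None
    if residue.ca is None:
        raise ValueError(f"residue {residue.site} has no coordinate")
    return ResidueSphere(
        complex_id=residue.complex_id,
        chain=residue.chain,
        position=residue.position,
        center=np.asarray(residue.ca, dtype=float),
        radius=radius_from_volume(volume),
    )


def in_contact(
    a: ResidueSphere, b: ResidueSphere, tolerance: float = DEFAULT_CONTACT_TOLERANCE
) -> bool:
    """Strict contact test: center distance < r_a + r_b + tolerance."""
    dist = float(np.linalg.norm(a.center - b.center))
    return dist < a.radius + b.radius + tolerance


def build_standard_regions(
    hot_residues: Sequence[LabeledResidue],
    min_size: int = MIN_REGION_SIZE,
    tolerance: float = DEFAULT_CONTACT_TOLERANCE,
    volumes: Optional[Mapping[str, float]] = None,
) -> list[HotRegion]:
    """Connected components of the per-complex sphere-contact graph.

    Only components with at least ``min_size`` hot spots become standard
    regions. Contact never crosses complex boundaries. Region ids are
    ``<complex>:S<k>`` ordered by the smallest (chain, position) member.
    """
    spheres_by_complex: dict[str, list[ResidueSphere]] = {}
    for r in hot_residues:
        spheres_by_complex.setdefault(r.complex_id, []).append(
            sphere_for_residue(r, volumes)
        )
    regions: list[HotRegion] = []
    for cid in sorted(spheres_by_complex):
        spheres = sorted(spheres_by_complex[cid], key=lambda s: (s.chain, s.position))
        graph = nx.Graph()
        graph.add_nodes_from(range(len(spheres)))
        for i in range(len(spheres)):
            for j in range(i + 1, len(spheres)):
                if in_contact(spheres[i], spheres[j], tolerance):
                    graph.add_edge(i, j)
        components = sorted(
            (sorted(c) for c in nx.connected_components(graph)),
            key=lambda c: (spheres[c[0]].chain, spheres[c[0]].position),
        )
        k = 0
        for comp in components:
            if len(comp) < min_size:
                continue
            regions.append(
                HotRegion(
                    region_id=f"{cid}:S{k}",
                    members=[spheres[i].site for i in comp],
                    source="standard",
                    complex_id=cid,
                )
            )
            k += 1
    return regions


def export_pymol_script(regions: Sequence[HotRegion], path) -> None:
    """Write PyMOL selection commands for visual inspection of regions."""
    lines = []
    for reg in regions:
        sel = " or ".join(
            f"(chain {chain} and resi {pos})" for _, chain, pos in reg.members
        )
        name = reg.region_id.replace(":", "_")
        lines.append(f"select {name}, {sel}")
        lines.append(f"show spheres, {name}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
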