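"""Alpha-carbon extraction, interface membership, and derived per-residue features.

Raw geometric and evolutionary descriptors (solvent-accessible surface area,
protrusion index, conservation, hydrophobicity, side-chain class, interaction
counts) come from external programs and are consumed as delimited tables; this
module computes the derived quantities on top of them:

* ``rct_asa`` — relative change of total ASA between unbound and bound states,
* ``rct_mpi`` — relative change of mean protrusion index,
* a one-hot encoding of the categorical side-chain class.

A residue is an interface residue when complex formation buries strictly more
than ``min_delta`` (default 1.0 A^2) of its accessible surface area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UndefinedFeatureError(ValueError):
    """Raised when a derived feature has a zero denominator."""


class VocabularyError(ValueError):
    """Raised for a side-chain class outside the closed vocabulary."""


#: Closed vocabulary of side-chain classes, in fixed one-hot column order.
SIDE_CHAIN_CLASSES = (
    "Acid",
    "Aliphatic",
    "Amid",
    "Aromatic",
    "Basic",
    "Basic aromatic",
    "Cyclic",
    "Hydroxyl-containing",
    "Sulfur-containing",
)

#: Side-chain class of each standard amino acid.
SIDE_CHAIN_CLASS_BY_AA = {
    "ALA": "Aliphatic", "GLY": "Aliphatic", "ILE": "Aliphatic",
    "LEU": "Aliphatic", "VAL": "Aliphatic",
    "PHE": "Aromatic", "TYR": "Aromatic", "TRP": "Aromatic",
    "HIS": "Basic aromatic",
    "ARG": "Basic", "LYS": "Basic",
    "ASP": "Acid", "GLU": "Acid",
    "ASN": "Amid", "GLN": "Amid",
    "SER": "Hydroxyl-containing", "THR": "Hydroxyl-containing",
    "CYS": "Sulfur-containing", "MET": "Sulfur-containing",
    "PRO": "Cyclic",
}

RAW_FEATURE_COLUMNS = [
    "unbound_total_asa",
    "bound_total_asa",
    "unbound_mean_pi",
    "bound_mean_pi",
    "conservation",
    "hydrophobicity",
    "interaction_count",
]


@dataclass(frozen=True)
class ResidueCoordinate:
    """One residue's alpha-carbon position in a complex."""

    complex_id: str
    chain: str
    position: int
    aa_code: str
    ca: np.ndarray

    @property
    def site(self) -> tuple[str, str, int]:
        return (self.complex_id, self.chain, self.position)


def read_ca_coordinates(
    pdb_file, chains: Optional[set[str]] = None, complex_id: Optional[str] = None
) -> list[ResidueCoordinate]:
    """Extract one alpha-carbon per residue from a PDB file.

    Only the first model is used. For alternate locations the highest-occupancy
    conformer wins, ties going to altloc "A". Residues without a CA atom (e.g.
    ligands, waters) are skipped with a log message. Insertion codes are folded
    into the position key by the caller's numbering; author numbering is kept.
    """
    structure = gemmi.read_pdb(str(pdb_file))
    if complex_id is None:
        complex_id = structure.name or "UNK"
    if not structure:
        return []
    model = structure[0]
    out: list[ResidueCoordinate] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            best = None
            for atom in residue:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ or (
                    atom.occ == best.occ and atom.altloc == "A"
                ):
                    best = atom
            if best is None:
                logger.info(
                    "residue %s %s%d has no CA atom; skipped",
                    residue.name, chain.name, residue.seqid.num,
                )
                continue
            out.append(
                ResidueCoordinate(
                    complex_id=complex_id,
                    chain=chain.name,
                    position=residue.seqid.num,
                    aa_code=residue.name,
                    ca=np.array([best.pos.x, best.pos.y, best.pos.z]),
                )
            )
    if chains is not None and not out:
        warnings.warn(f"no residues found for chains {sorted(chains)}", stacklevel=2)
    return out


def is_interface(
    unbound_total_asa: float, bound_total_asa: float, min_delta: float = 1.0
) -> bool:
    """True iff complex formation buries strictly more than ``min_delta`` A^2."""
    if unbound_total_asa < 0 or bound_total_asa < 0:
        raise ValueError("ASA values must be non-negative")
    if bound_total_asa > unbound_total_asa:
        logger.warning(
            "bound ASA %.2f exceeds unbound %.2f", bound_total_asa, unbound_total_asa
        )
    return (unbound_total_asa - bound_total_asa) > min_delta


def rct_asa(unbound_total_asa: float, bound_total_asa: float) -> float:
    """Relative change of total ASA, (unbound - bound) / unbound."""
    if unbound_total_asa <= 0:
        raise UndefinedFeatureError("unbound total ASA must be positive")
    return (unbound_total_asa - bound_total_asa) / unbound_total_asa


def rct_mpi(unbound_mean_pi: float, bound_mean_pi: float) -> float:
    """Relative change of mean protrusion index, (unbound - bound) / unbound."""
    if unbound_mean_pi == 0:
        raise UndefinedFeatureError("unbound mean protrusion index must be nonzero")
    return (unbound_mean_pi - bound_mean_pi) / unbound_mean_pi


def one_hot_side_chain(side_chain_class: str) -> np.ndarray:
    """Unit indicator vector over the fixed side-chain class vocabulary."""
    try:
        idx = SIDE_CHAIN_CLASSES.index(side_chain_class)
    except ValueError:
        raise VocabularyError(
            f"unknown side-chain class {side_chain_class!r}; "
            f"expected one of {SIDE_CHAIN_CLASSES}"
        ) from None
    vec = np.zeros(len(SIDE_CHAIN_CLASSES))
    vec[idx] = 1.0
    return vec


def one_hot_column_names() -> list[str]:
    return [f"side_chain={c}" for c in SIDE_CHAIN_CLASSES]


@dataclass
class FeatureTable:
    """n residues x p features with aligned labels and site identities.

    ``x`` carries no missing values; the one-hot block rows sum to 1.
    """

    x: pd.DataFrame
    labels: np.ndarray  # 0 = non-hot, 1 = hot
    sites: list[tuple[str, str, int]]

    @property
    def feature_names(self) -> list[str]:
        return list(self.x.columns)

    @property
    def n(self) -> int:
        return len(self.x)

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.x[list(names)], self.labels, self.sites)

    def subset_rows(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.x.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            [self.sites[i] for i in idx],
        )


def assemble_feature_table(
    raw_rows: pd.DataFrame, labeled: pd.DataFrame
) -> FeatureTable:
    """Join raw feature rows with labels and append derived columns.

    ``raw_rows`` must carry site identity columns (complex, chain, position),
    the raw feature columns, and ``side_chain_class``; extra numeric columns
    pass through untouched. Rows with any missing required value are dropped
    (and counted in the log) — no imputation. Labels align by site identity;
    a labeled site without features, or vice versa, is dropped from the join.
    """
    key = ["complex", "chain", "position"]
    required = key + RAW_FEATURE_COLUMNS + ["side_chain_class"]
    missing_cols = set(required) - set(raw_rows.columns)
    if missing_cols:
        raise ValueError(f"raw feature table missing columns: {sorted(missing_cols)}")
    n_before = len(raw_rows)
    rows = raw_rows.dropna(subset=[c for c in required if c != "position"])
    dropped = n_before - len(rows)
    if dropped:
        logger.info("dropped %d rows with missing raw features", dropped)

    merged = rows.merge(labeled[key + ["label"]], on=key, how="inner", validate="one_to_one")
    if merged.empty:
        return FeatureTable(pd.DataFrame(), np.array([], dtype=int), [])

    merged = merged.sort_values(key).reset_index(drop=True)
    derived = pd.DataFrame(
        {
            "rct_asa": [
                rct_asa(u, b)
                for u, b in zip(merged.unbound_total_asa, merged.bound_total_asa)
            ],
            "rct_mpi": [
                rct_mpi(u, b)
                for u, b in zip(merged.unbound_mean_pi, merged.bound_mean_pi)
            ],
        }
    )
    onehot = pd.DataFrame(
        np.vstack([one_hot_side_chain(c) for c in merged.side_chain_class]),
        columns=one_hot_column_names(),
    )
    numeric_cols = [
        c
        for c in merged.columns
        if c not in key + ["side_chain_class", "label"]
        and pd.api.types.is_numeric_dtype(merged[c])
    ]
    x = pd.concat([merged[numeric_cols], derived, onehot], axis=1)
    labels = (merged.label == "hot").to_numpy().astype(int)
    sites = [
        (str(r.complex), str(r.chain), int(r.position))
        for r in merged.itertuples(index=False)
    ]
    return FeatureTable(x, labels, sites)
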