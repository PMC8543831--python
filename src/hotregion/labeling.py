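"""Turn raw alanine-scanning affinity measurements into labeled hot/non-hot residues.

The binding free energy of a complex with dissociation constant Kd measured at
temperature T is ``dG = -R*T*ln(Kd)`` with the gas constant expressed in
kcal/(K*mol); the effect of a mutation is ``ddG = dG_mut - dG_wt``. Interface
residues whose mutation to alanine costs more than a threshold (1.0 kcal/mol by
default) are labeled *hot spots*, the rest *non-hot*. Repeated measurements at
one site are averaged on the ddG scale, and records lacking either affinity are
dropped.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Gas constant in kcal/(K*mol), kept as the exact ratio 8.314 J/(K*mol) over
#: 4184 J/kcal so downstream numbers do not drift from rounding.
GAS_CONSTANT_KCAL = 8.314 / 4184

#: Descriptive experimental temperature range (K); values outside it only warn.
TEMPERATURE_RANGE = (273.0, 323.0)

#: Default hot-spot threshold, kcal/mol.
DEFAULT_THRESHOLD = 1.0

HOT = "hot"
NON_HOT = "non-hot"

Site = tuple[str, str, int]


class InvalidAffinityError(ValueError):
    """Raised for a non-positive dissociation constant."""


class DataConsistencyError(ValueError):
    """Raised when records at one site disagree on the wild-type residue."""


@dataclass(frozen=True)
class MutationRecord:
    """One alanine-scanning measurement at a single interface site.

    ``kd_wt``/``kd_mut`` are molar dissociation constants; ``None`` marks a
    measurement the experiment could not determine.
    """

    complex_id: str
    chain: str
    position: int
    wild_aa: str
    mutant_aa: str
    kd_wt: Optional[float]
    kd_mut: Optional[float]
    temperature: float = 298.0

    @property
    def site(self) -> Site:
        return (self.complex_id, self.chain, self.position)

    @property
    def complete(self) -> bool:
        """True when both affinities were measured."""
        return self.kd_wt is not None and self.kd_mut is not None


@dataclass
class LabeledResidue:
    """An interface residue with its aggregated ddG and hot/non-hot label."""

    complex_id: str
    chain: str
    position: int
    wild_aa: str
    ddg: float
    label: str
    ca: Optional[np.ndarray] = None

    @property
    def site(self) -> Site:
        return (self.complex_id, self.chain, self.position)

    @property
    def is_hot(self) -> bool:
        return self.label == HOT

    def with_coordinate(self, ca: np.ndarray) -> "LabeledResidue":
        return replace(self, ca=np.asarray(ca, dtype=float))


@dataclass
class DatasetSplit:
    training: list[LabeledResidue] = field(default_factory=list)
    testing: list[LabeledResidue] = field(default_factory=list)


def delta_g(kd: float, temperature: float) -> float:
    """Binding free energy -R*T*ln(Kd) in kcal/mol.

    Parameters
    ----------
    kd : float
        Dissociation constant, molar, strictly positive.
    temperature : float
        Experimental temperature, K. Values outside the usual 273-323 K
        experimental window raise a warning but are still computed: the range
        is descriptive of the source data, not a law.
    """
    if kd is None or not kd > 0:
        raise InvalidAffinityError(f"dissociation constant must be > 0, got {kd!r}")
    lo, hi = TEMPERATURE_RANGE
    if not lo <= temperature <= hi:
        warnings.warn(
            f"temperature {temperature} K outside the usual experimental "
            f"range [{lo}, {hi}] K",
            stacklevel=2,
        )
    return -GAS_CONSTANT_KCAL * temperature * math.log(kd)


def delta_delta_g(dg_mut: float, dg_wt: float) -> float:
    """Change in binding free energy on mutation, dG_mut - dG_wt (kcal/mol)."""
    if not (math.isfinite(dg_mut) and math.isfinite(dg_wt)):
        raise ValueError("binding free energies must be finite")
    return dg_mut - dg_wt


def record_ddg(record: MutationRecord) -> float:
    """ddG of a single measurement; both affinities must be present."""
    dg_wt = delta_g(record.kd_wt, record.temperature)
    dg_mut = delta_g(record.kd_mut, record.temperature)
    return delta_delta_g(dg_mut, dg_wt)


def aggregate_sites(
    records: Iterable[MutationRecord],
) -> dict[tuple[str, str, int, str], float]:
    """Average per-record ddG over repeated measurements at each site.

    Records with either affinity missing are dropped. The key carries the
    wild-type residue; two records at the same (complex, chain, position) that
    disagree on the wild type are rejected rather than silently merged.
    """
    wild_by_site: dict[Site, str] = {}
    values: dict[tuple[str, str, int, str], list[float]] = defaultdict(list)
    for rec in records:
        if not rec.complete:
            continue
        seen = wild_by_site.get(rec.site)
        if seen is None:
            wild_by_site[rec.site] = rec.wild_aa
        elif seen != rec.wild_aa:
            raise DataConsistencyError(
                f"site {rec.site} reported with wild types {seen} and {rec.wild_aa}"
            )
        values[rec.site + (rec.wild_aa,)].append(record_ddg(rec))
    return {key: float(np.mean(v)) for key, v in values.items()}


def label_sites(
    ddg_by_site: Mapping[tuple[str, str, int, str], float],
    threshold: float = DEFAULT_THRESHOLD,
    scheme: str = "single",
    window: tuple[float, float] = (0.4, 2.0),
) -> list[LabeledResidue]:
    """Assign hot/non-hot labels from aggregated ddG values.

    ``scheme="single"`` labels hot iff ddG strictly exceeds ``threshold``
    (a residue exactly at the threshold is non-hot). ``scheme="window"`` is
    the stricter two-threshold convention: hot above the upper bound, non-hot
    below the lower bound, and sites in between discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if scheme not in ("single", "window"):
        raise ValueError(f"unknown labeling scheme {scheme!r}")
    out: list[LabeledResidue] = []
    lo, hi = window
    for (complex_id, chain, position, wild_aa), ddg in sorted(ddg_by_site.items()):
        if scheme == "single":
            label = HOT if ddg > threshold else NON_HOT
        else:
            if ddg > hi:
                label = HOT
            elif ddg < lo:
                label = NON_HOT
            else:
                continue
        out.append(LabeledResidue(complex_id, chain, position, wild_aa, ddg, label))
    return out


def split_by_complex(
    residues: Sequence[LabeledResidue],
    expansion_ids: set[str],
    min_interface_size: int = 3,
) -> DatasetSplit:
    """Partition residues into training and testing sets by complex.

    Complexes in ``expansion_ids`` (the newly added part of the mutation
    database) go to testing, except those with fewer than
    ``min_interface_size`` interface residues, which are folded into training
    for model stability. All remaining complexes go to training. All residues
    of one complex always fall on the same side.
    """
    by_complex: dict[str, list[LabeledResidue]] = defaultdict(list)
    for r in residues:
        by_complex[r.complex_id].append(r)
    unknown = expansion_ids - set(by_complex)
    if unknown:
        warnings.warn(
            f"expansion ids not present in data: {sorted(unknown)}", stacklevel=2
        )
    split = DatasetSplit()
    for cid in sorted(by_complex):
        members = by_complex[cid]
        if cid in expansion_ids and len(members) >= min_interface_size:
            split.testing.extend(members)
        else:
            split.training.extend(members)
    return split


def composition_report(residues: Sequence[LabeledResidue]) -> pd.DataFrame:
    """Per-amino-acid hot/non-hot counts and hot ratio, with an ``All`` row.

    The ratio is hot/total rounded to 3 decimals; an amino acid with no
    residues would simply be absent. Column layout mirrors the usual dataset
    composition tables (non-hot, hot, total, ratio).
    """
    rows: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for r in residues:
        rows[r.wild_aa][1 if r.is_hot else 0] += 1
    ordered = sorted(rows.items(), key=lambda kv: (kv[1][1] / sum(kv[1]), kv[0]))
    data = []
    for aa, (non_hot, hot) in ordered:
        total = non_hot + hot
        data.append((aa, non_hot, hot, total, round(hot / total, 3)))
    total_non = sum(d[1] for d in data)
    total_hot = sum(d[2] for d in data)
    grand = total_non + total_hot
    data.append(
        ("All", total_non, total_hot, grand, round(total_hot / grand, 3) if grand else float("nan"))
    )
    return pd.DataFrame(
        data, columns=["amino_acid", "non_hot", "hot", "total", "hot_ratio"]
    )


MUTATION_COLUMNS = [
    "complex",
    "chain",
    "position",
    "wt_aa",
    "mut_aa",
    "kd_wt",
    "kd_mut",
    "temperature_K",
]


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a delimited mutation table (CSV or TSV, sniffed by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            MutationRecord(
                complex_id=str(row.complex),
                chain=str(row.chain),
                position=int(row.position),
                wild_aa=str(row.wt_aa),
                mutant_aa=str(row.mut_aa),
                kd_wt=None if pd.isna(row.kd_wt) else float(row.kd_wt),
                kd_mut=None if pd.isna(row.kd_mut) else float(row.kd_mut),
                temperature=float(row.temperature_K),
            )
        )
    return records


def residues_to_frame(residues: Sequence[LabeledResidue]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "complex": r.complex_id,
                "chain": r.chain,
                "position": r.position,
                "wt_aa": r.wild_aa,
                "ddg": r.ddg,
                "label": r.label,
            }
            for r in residues
        ]
    )


def residues_from_frame(df: pd.DataFrame) -> list[LabeledResidue]:
    return [
        LabeledResidue(
            str(row.complex), str(row.chain), int(row.position), str(row.wt_aa),
            float(row.ddg), str(row.label),
        )
        for row in df.itertuples(index=False)
    ]
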