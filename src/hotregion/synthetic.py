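"""Synthetic complexes with planted hot regions for end-to-end testing.

The generator emulates the three inputs of the real pipeline without any
downloads:

* **geometry** — hot spots placed in tight Gaussian blobs (one blob per
  planted region) with region centers separated far enough that the planted
  clustering is recoverable; non-hot background residues scattered at least
  one separation away from every region center;
* **affinities** — per-site Kd pairs back-solved from a target ddG through
  the -RT ln(Kd) relation at 298 K, so the labeling stage reproduces the
  planted hot/non-hot labels exactly when label noise is zero;
* **features** — raw feature rows whose informative columns are drawn
  class-conditionally (hot vs non-hot Gaussians), plus pure-noise columns,
  plus plausible ASA/protrusion bookkeeping so the derived features carry
  class signal too.

Geometry is three-dimensional blobs rather than a protein surface: every
downstream contract depends only on pairwise distances, so blobs are
sufficient. All randomness flows from one explicit seed; there is no global
random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .features import SIDE_CHAIN_CLASS_BY_AA
from .labeling import (
    GAS_CONSTANT_KCAL,
    HOT,
    NON_HOT,
    LabeledResidue,
    MutationRecord,
)

AMINO_ACIDS = sorted(SIDE_CHAIN_CLASS_BY_AA)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small, clearly separable benchmark: two complexes of
    two planted regions each, five hot spots per region, a 20-residue
    non-hot background, blob spread 1.5 A against 30 A center separation
    (comfortably above twice the largest clustering radius searched, 9.5 A),
    three informative features separated by three standard deviations, and
    hot/non-hot ddG drawn clear of the 1.0 kcal/mol threshold by a 0.2
    kcal/mol margin.
    """

    n_complexes: int = 2
    n_regions: int = 2
    hot_per_region: int = 5
    n_background: int = 20
    sigma_geom: float = 1.5  # A, blob spread
    separation: float = 30.0  # A, between region centers
    n_informative: int = 3
    n_noise_features: int = 5
    mu_non_hot: float = 0.0
    mu_hot: float = 3.0  # 3 sigma away at feature_sigma = 1
    feature_sigma: float = 1.0
    label_noise: float = 0.0
    ddg_margin: float = 0.2  # kcal/mol clear of the 1.0 threshold
    ddg_hot_max: float = 5.0
    temperature: float = 298.0
    kd_wt: float = 1e-9

    def validate(self) -> None:
        if self.hot_per_region < 3:
            raise ValueError("a planted region needs at least 3 hot spots")
        if self.separation < 6 * self.sigma_geom:
            raise ValueError(
                "separation too small for the blob spread; planted regions "
                "would not be recoverable"
            )
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")


@dataclass
class SyntheticComplex:
    complex_id: str
    residues: list[LabeledResidue]  # planted truth labels, coordinates attached
    records: list[MutationRecord]
    raw_features: pd.DataFrame
    truth_regions: list[list[tuple[str, str, int]]]  # planted hot-region sites


def _kd_pair_for_ddg(ddg: float, temperature: float, kd_wt: float) -> tuple[float, float]:
    """Back-solve the mutant Kd giving the requested ddG at fixed wild-type Kd."""
    rt = GAS_CONSTANT_KCAL * temperature
    dg_wt = -rt * math.log(kd_wt)
    dg_mut = dg_wt + ddg
    return kd_wt, math.exp(-dg_mut / rt)


def _draw_ddg(rng: np.random.Generator, hot: bool, spec: SyntheticSpec) -> float:
    if hot:
        return float(rng.uniform(1.0 + spec.ddg_margin, spec.ddg_hot_max))
    return float(rng.uniform(0.0, 1.0 - spec.ddg_margin))


def generate_complex(
    spec: SyntheticSpec, seed: int, complex_id: str = "SYN1"
) -> SyntheticComplex:
    """Generate one synthetic complex with planted regions and ground truth.

    Residues live on chain A with sequential positions: region blobs first,
    then background. ``label_noise`` flips the ddG class of that fraction of
    residues (their coordinates and features keep the planted geometry), so
    the labeling stage disagrees with the planted truth at roughly that rate.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[i * spec.separation, 0.0, 0.0] for i in range(spec.n_regions)]
    )

    coords: list[np.ndarray] = []
    planted_hot: list[bool] = []
    region_of: list[Optional[int]] = []
    for ridx in range(spec.n_regions):
        for _ in range(spec.hot_per_region):
            coords.append(centers[ridx] + rng.normal(0, spec.sigma_geom, 3))
            planted_hot.append(True)
            region_of.append(ridx)
    # background: rejection-sample points >= separation from every center
    box = spec.separation * (spec.n_regions + 2)
    placed = 0
    tries = 0
    while placed < spec.n_background:
        tries += 1
        if tries > 1000 * max(spec.n_background, 1):
            raise ValueError("infeasible geometry: cannot place background residues")
        pt = rng.uniform(-box, box, 3)
        if np.min(np.linalg.norm(centers - pt, axis=1)) >= spec.separation:
            coords.append(pt)
            planted_hot.append(False)
            region_of.append(None)
            placed += 1

    n = len(coords)
    aa_codes = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n)]
    noisy = rng.random(n) < spec.label_noise

    residues: list[LabeledResidue] = []
    records: list[MutationRecord] = []
    feature_rows = []
    truth_regions: list[list[tuple[str, str, int]]] = [
        [] for _ in range(spec.n_regions)
    ]
    for i in range(n):
        position = i + 1
        observed_hot = planted_hot[i] ^ bool(noisy[i])
        ddg = _draw_ddg(rng, observed_hot, spec)
        kd_wt, kd_mut = _kd_pair_for_ddg(ddg, spec.temperature, spec.kd_wt)
        records.append(
            MutationRecord(
                complex_id=complex_id,
                chain="A",
                position=position,
                wild_aa=aa_codes[i],
                mutant_aa="ALA",
                kd_wt=kd_wt,
                kd_mut=kd_mut,
                temperature=spec.temperature,
            )
        )
        residues.append(
            LabeledResidue(
                complex_id=complex_id,
                chain="A",
                position=position,
                wild_aa=aa_codes[i],
                ddg=ddg,
                label=HOT if planted_hot[i] else NON_HOT,
                ca=np.asarray(coords[i]),
            )
        )
        if planted_hot[i]:
            truth_regions[region_of[i]].append((complex_id, "A", position))

        # class-conditional raw features follow the observed (possibly noisy) class
        mu = spec.mu_hot if observed_hot else spec.mu_non_hot
        informative = rng.normal(mu, spec.feature_sigma, spec.n_informative)
        noise = rng.normal(0, 1, spec.n_noise_features)
        unbound_asa = float(rng.uniform(80, 140))
        burial = float(
            np.clip(rng.normal(0.55 if observed_hot else 0.30, 0.08), 0.05, 0.95)
        )
        unbound_pi = float(rng.uniform(1.0, 3.0))
        pi_drop = float(
            np.clip(rng.normal(0.5 if observed_hot else 0.25, 0.08), 0.02, 0.95)
        )
        row = {
            "complex": complex_id,
            "chain": "A",
            "position": position,
            "unbound_total_asa": unbound_asa,
            "bound_total_asa": unbound_asa * (1 - burial),
            "unbound_mean_pi": unbound_pi,
            "bound_mean_pi": unbound_pi * (1 - pi_drop),
            "conservation": float(informative[0]) if spec.n_informative else 0.0,
            "hydrophobicity": float(rng.normal(0, 1)),
            "interaction_count": int(rng.integers(1, 12)),
            "side_chain_class": SIDE_CHAIN_CLASS_BY_AA[aa_codes[i]],
        }
        for j in range(1, spec.n_informative):
            row[f"signal_{j}"] = float(informative[j])
        for j in range(spec.n_noise_features):
            row[f"noise_{j}"] = float(noise[j])
        feature_rows.append(row)

    return SyntheticComplex(
        complex_id=complex_id,
        residues=residues,
        records=records,
        raw_features=pd.DataFrame(feature_rows),
        truth_regions=truth_regions,
    )


@dataclass
class SyntheticDataset:
    complexes: list[SyntheticComplex] = field(default_factory=list)

    @property
    def residues(self) -> list[LabeledResidue]:
        return [r for c in self.complexes for r in c.residues]

    @property
    def records(self) -> list[MutationRecord]:
        return [r for c in self.complexes for r in c.records]

    @property
    def raw_features(self) -> pd.DataFrame:
        return pd.concat(
            [c.raw_features for c in self.complexes], ignore_index=True
        )

    @property
    def truth_regions(self) -> list[list[tuple[str, str, int]]]:
        return [reg for c in self.complexes for reg in c.truth_regions]


def generate_dataset(spec: SyntheticSpec, seed: int) -> SyntheticDataset:
    """Generate ``spec.n_complexes`` complexes, each from a derived seed."""
    child_seeds = np.random.SeedSequence(seed).spawn(spec.n_complexes)
    complexes = [
        generate_complex(
            spec,
            seed=int(child.generate_state(1)[0] % (2**31)),
            complex_id=f"SYN{i + 1}",
        )
        for i, child in enumerate(child_seeds)
    ]
    return SyntheticDataset(complexes=complexes)


def write_fixture_pdb(residues, path) -> None:
    """Write minimal CA-only ATOM records that round-trip through PDB parsing.

    Coordinates are stored at the format's 3-decimal precision; chain and
    author residue numbering are preserved.
    """
    lines = []
    serial = 1
    for r in residues:
        x, y, z = (float(v) for v in r.ca)
        aa = getattr(r, "wild_aa", None) or getattr(r, "aa_code", "GLY")
        lines.append(
            f"ATOM  {serial:>5}  CA  {aa:<3} {r.chain}{r.position:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_truth_json(dataset: SyntheticDataset, path) -> None:
    payload = [
        [list(site) for site in region] for region in dataset.truth_regions
    ]
    with open(path, "w") as fh:
        json.dump({"planted_regions": payload}, fh, indent=2)
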