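"""Binding-pocket selection, radius-convergence scan and energy profiles.

The pocket is delineated by spheres of increasing radius around the ligand
(default 2.0–8.0 Å in 0.5 Å steps): a residue belongs to the shell at radius
r when the minimum distance over all ligand-atom/residue-atom pairs
(hydrogens included) is ≤ r. The total interaction energy at each radius is
the sum of the MFCC per-residue energies of the shell members; the scan is
declared converged at the first successor radius where the relative change
of the total falls below the tolerance (default 10%) at every dielectric
simultaneously. Each residue's energy is evaluated once and reused across
shells — the fragment quartet does not depend on the shell.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .backends import EnergyBackend
from .errors import MfccPocketError
from .fragmentation import CapSpec, build_quartet, mfcc_interaction_energy
from .structure import ComplexStructure, ResidueKey

logger = logging.getLogger(__name__)

DEFAULT_DIELECTRICS = (10.0, 20.0, 40.0)


def default_radii(start: float = 2.0, stop: float = 8.0, step: float = 0.5) -> tuple[float, ...]:
    """Radius schedule r = n/2 spanning 2.0–8.0 Å by default."""
    n = int(round((stop - start) / step))
    return tuple(round(start + i * step, 6) for i in range(n + 1))


@dataclass
class ScanConfig:
    radii: tuple[float, ...] = field(default_factory=default_radii)
    tolerance: float = 0.10
    dielectrics: tuple[float, ...] = DEFAULT_DIELECTRICS
    cap_spec: CapSpec = field(default_factory=CapSpec)

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if radii and radii[0] <= 0:
            raise ValueError("radii must be positive")
        self.radii = radii
        self.dielectrics = tuple(float(d) for d in self.dielectrics)


@dataclass
class ProfileEntry:
    residue_key: ResidueKey
    min_distance: float
    energies: dict[float, float]  # dielectric -> E_I, kcal/mol


@dataclass
class ResidueEnergyProfile:
    """Per-residue interaction energies at each dielectric, with distances."""

    entries: list[ProfileEntry]
    dielectrics: tuple[float, ...] = DEFAULT_DIELECTRICS

    def entry(self, key: ResidueKey) -> ProfileEntry:
        for e in self.entries:
            if e.residue_key == key:
                return e
        raise KeyError(f"no profile entry for residue {key}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            chain, seq, name = e.residue_key
            row = {"chain": chain, "seq_id": seq, "res_name": name,
                   "min_distance": e.min_distance}
            for eps in self.dielectrics:
                row[f"EI_eps{eps:g}"] = e.energies.get(eps, math.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ConvergenceScan:
    """Shell membership and cumulative totals of the radius scan."""

    radii: tuple[float, ...]
    shell_members: dict[float, set[ResidueKey]]
    totals: dict[tuple[float, float], float]  # (radius, dielectric) -> kcal/mol
    converged_radius: float | None
    tolerance: float
    failures: dict[ResidueKey, str] = field(default_factory=dict)

    def total(self, radius: float, dielectric: float) -> float:
        return self.totals[(radius, dielectric)]

    def to_json_dict(self) -> dict:
        return {
            "radii": list(self.radii),
            "tolerance": self.tolerance,
            "shell_sizes": {f"{r:g}": len(self.shell_members[r]) for r in self.radii},
            "shell_members": {
                f"{r:g}": sorted(f"{c}:{s}:{n}" for c, s, n in self.shell_members[r])
                for r in self.radii
            },
            "totals": {
                f"{r:g}": {
                    f"{eps:g}": self.totals[(r, eps)]
                    for (rr, eps) in self.totals
                    if rr == r
                }
                for r in self.radii
            },
            "converged_radius": self.converged_radius,
            "failures": {f"{c}:{s}:{n}": msg for (c, s, n), msg in self.failures.items()},
        }


def min_distances(complex_structure: ComplexStructure) -> dict[ResidueKey, float]:
    """Minimum ligand–residue atom-pair distance, Å, for every polymer residue."""
    lig = complex_structure.ligand.coords_array()
    out: dict[ResidueKey, float] = {}
    for group in complex_structure.polymer:
        d = cdist(lig, group.coords_array())
        out[group.key] = float(d.min())
    return out


def residues_within(
    complex_structure: ComplexStructure, radius: float
) -> dict[ResidueKey, float]:
    """Residues whose minimum distance to any ligand atom is ≤ ``radius``.

    Hydrogens count; the returned mapping carries the minimum distances.
    An empty result is legitimate (radius below the closest contact).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return {k: d for k, d in min_distances(complex_structure).items() if d <= radius}


def find_converged_radius(
    radii: Sequence[float],
    totals: dict[tuple[float, float], float],
    dielectrics: Sequence[float],
    tolerance: float,
) -> float | None:
    """First successor radius where the relative total change < tolerance at all ε.

    Comparisons with a zero previous total are skipped (logged); the strict
    ``<`` means a tolerance of 0 never converges.
    """
    for prev, curr in zip(radii, radii[1:]):
        ok = True
        compared = False
        for eps in dielectrics:
            t_prev = totals[(prev, eps)]
            t_curr = totals[(curr, eps)]
            if t_prev == 0.0:
                logger.info(
                    "convergence check at r=%g, eps=%g skipped (zero total)", curr, eps
                )
                continue
            compared = True
            if abs(t_curr - t_prev) / abs(t_prev) >= tolerance:
                ok = False
        if ok and compared:
            return curr
    return None


def run_scan(
    complex_structure: ComplexStructure,
    backend: EnergyBackend,
    config: ScanConfig | None = None,
) -> tuple[ConvergenceScan, ResidueEnergyProfile]:
    """Run the incremental-radius convergence scan.

    Every residue inside the largest shell is fragmented once; its MFCC
    energy at each dielectric is cached and summed into the shell totals.
    Backend failures are recorded per residue and the scan continues without
    that residue (partial results with a failure log).
    """
    config = config or ScanConfig()
    dists = min_distances(complex_structure)
    largest = config.radii[-1]
    pocket_keys = [k for k in complex_structure.residue_keys if dists[k] <= largest]

    energies: dict[ResidueKey, dict[float, float]] = {}
    failures: dict[ResidueKey, str] = {}
    for key in pocket_keys:
        try:
            quartet = build_quartet(complex_structure, key, config.cap_spec)
            energies[key] = {
                eps: mfcc_interaction_energy(quartet, backend, eps)
                for eps in config.dielectrics
            }
        except MfccPocketError as exc:
            logger.error("residue %s skipped: %s", key, exc)
            failures[key] = str(exc)

    shell_members = {
        r: {k for k in pocket_keys if dists[k] <= r and k in energies}
        for r in config.radii
    }
    totals = {
        (r, eps): float(math.fsum(energies[k][eps] for k in shell_members[r]))
        for r in config.radii
        for eps in config.dielectrics
    }
    converged = find_converged_radius(
        config.radii, totals, config.dielectrics, config.tolerance
    )
    scan = ConvergenceScan(
        radii=config.radii,
        shell_members=shell_members,
        totals=totals,
        converged_radius=converged,
        tolerance=config.tolerance,
        failures=failures,
    )
    profile = ResidueEnergyProfile(
        entries=[
            ProfileEntry(residue_key=k, min_distance=dists[k], energies=energies[k])
            for k in pocket_keys
            if k in energies
        ],
        dielectrics=config.dielectrics,
    )
    return scan, profile


def rank_residues(
    profile: ResidueEnergyProfile, dielectric: float
) -> list[ProfileEntry]:
    """Entries sorted most attractive (most negative E_I) first.

    Ties break on (chain, seq_id).
    """
    if dielectric not in profile.dielectrics:
        raise ValueError(f"dielectric {dielectric} not in profile {profile.dielectrics}")
    return sorted(
        profile.entries,
        key=lambda e: (e.energies[dielectric], e.residue_key[0], e.residue_key[1]),
    )


def group_sum(
    profile: ResidueEnergyProfile,
    residue_keys: Sequence[ResidueKey],
    dielectric: float,
) -> float:
    """Arithmetic sum of the named residues' E_I at one dielectric, kcal/mol."""
    if dielectric not in profile.dielectrics:
        raise ValueError(f"dielectric {dielectric} not in profile {profile.dielectrics}")
    return float(math.fsum(profile.entry(k).energies[dielectric] for k in residue_keys))


# ---------------------------------------------------------------------------
# run-directory outputs


def write_profile_tsv(profile: ResidueEnergyProfile, path: str | Path) -> None:
    frame = profile.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format="%.8f")


def write_scan_json(scan: ConvergenceScan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scan.to_json_dict(), indent=2, sort_keys=True) + "\n")
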