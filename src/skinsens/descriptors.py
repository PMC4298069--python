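"""The nine quantum descriptors, log parsing, and min-max normalization.

Descriptors (all from a ground-state single-point calculation on the
optimized geometry): frontier orbital energies epsilon_HOMO, epsilon_LUMO
and their neighbors epsilon_HOMO-1, epsilon_LUMO+1 (hartree); Mulliken
charge extremes q_min / q_max, the charge on the aniline N or phenol O
(q_hetero), and the mean absolute charge over all atoms q_mean_abs
(electron units); and the total dipole moment (Debye).

This module reads descriptors out of Gaussian-style text logs; it never
runs quantum chemistry. Energies stay in hartree throughout — the
discriminant's units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from .domain import _ANILINE_SMARTS, _PHENOL_SMARTS, mol_from_smiles
from .errors import (
    DegenerateDescriptorError,
    DescriptorParseError,
    NotFittedError,
    SkinsensError,
    StructureError,
)

__all__ = [
    "DESCRIPTOR_NAMES",
    "QuantumDescriptors",
    "NormalizationParams",
    "parse_qm_log",
    "assign_q_hetero",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
]

#: Canonical descriptor order (also the CSV column order).
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "epsilon_homo",
    "epsilon_lumo",
    "epsilon_homo_minus1",
    "epsilon_lumo_plus1",
    "q_min",
    "q_max",
    "q_hetero",
    "q_mean_abs",
    "dipole",
)


@dataclass
class QuantumDescriptors:
    """Container for the nine descriptors; any subset may be present."""

    epsilon_homo: float | None = None
    epsilon_lumo: float | None = None
    epsilon_homo_minus1: float | None = None
    epsilon_lumo_plus1: float | None = None
    q_min: float | None = None
    q_max: float | None = None
    q_hetero: float | None = None
    q_mean_abs: float | None = None
    dipole: float | None = None

    def as_dict(self, drop_none: bool = True) -> dict[str, float]:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            out = {k: v for k, v in out.items() if v is not None}
        return out

    def validate(self) -> None:
        """Check physical ordering/sign constraints on the fields present."""
        d = self.as_dict()

        def both(a, b):
            return a in d and b in d

        if both("epsilon_homo_minus1", "epsilon_homo") and not (
            d["epsilon_homo_minus1"] <= d["epsilon_homo"]
        ):
            raise SkinsensError("epsilon_homo_minus1 > epsilon_homo")
        if both("epsilon_homo", "epsilon_lumo") and not (
            d["epsilon_homo"] < d["epsilon_lumo"]
        ):
            raise SkinsensError("epsilon_homo >= epsilon_lumo")
        if both("epsilon_lumo", "epsilon_lumo_plus1") and not (
            d["epsilon_lumo"] <= d["epsilon_lumo_plus1"]
        ):
            raise SkinsensError("epsilon_lumo > epsilon_lumo_plus1")
        if both("q_min", "q_max") and d["q_min"] > d["q_max"]:
            raise SkinsensError("q_min > q_max")
        if d.get("q_mean_abs", 0.0) < 0:
            raise SkinsensError("q_mean_abs < 0")
        if d.get("dipole", 0.0) < 0:
            raise SkinsensError("dipole < 0")


_OCC_RE = re.compile(r"Alpha\s+occ\.\s+eigenvalues\s*--\s*(.*)")
_VIRT_RE = re.compile(r"Alpha\s+virt\.\s+eigenvalues\s*--\s*(.*)")
_MULLIKEN_RE = re.compile(r"Mulliken\s+(atomic\s+)?charges", re.IGNORECASE)
_CHARGE_LINE_RE = re.compile(r"^\s*\d+\s+[A-Za-z]{1,2}\s+(-?\d+\.\d+)\s*$")
_DIPOLE_HDR_RE = re.compile(r"Dipole\s+moment", re.IGNORECASE)
_DIPOLE_TOT_RE = re.compile(r"Tot=\s*(-?\d+\.\d+)")
_FLOAT_RE = re.compile(r"-?\d+\.\d+")


def parse_qm_log(path) -> tuple[QuantumDescriptors, list[float]]:
    """Extract descriptors from a Gaussian-style output log.

    Uses the LAST eigenvalue group, Mulliken block and dipole line in the
    file, so intermediate printings from an optimization are ignored and the
    final geometry wins. Returns the descriptors (q_hetero left unset — it
    needs the structure, see :func:`assign_q_hetero`) and the per-atom
    Mulliken charges in file order.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()

    # Eigenvalues come in groups of consecutive occ-lines then virt-lines.
    groups: list[dict[str, list[float]]] = []
    current: dict[str, list[float]] | None = None
    for line in lines:
        m_occ = _OCC_RE.search(line)
        m_virt = _VIRT_RE.search(line)
        if m_occ:
            if current is None or current["virt"]:
                current = {"occ": [], "virt": []}
                groups.append(current)
            current["occ"].extend(float(x) for x in _FLOAT_RE.findall(m_occ.group(1)))
        elif m_virt:
            if current is None:
                current = {"occ": [], "virt": []}
                groups.append(current)
            current["virt"].extend(float(x) for x in _FLOAT_RE.findall(m_virt.group(1)))
    complete = [g for g in groups if len(g["occ"]) >= 2 and len(g["virt"]) >= 2]
    if not groups:
        raise DescriptorParseError(f"{path}: no orbital eigenvalues block found")
    if not complete:
        raise DescriptorParseError(
            f"{path}: need at least 2 occupied and 2 virtual eigenvalues"
        )
    eig = complete[-1]

    # Last Mulliken charge block.
    charges: list[float] | None = None
    i = 0
    while i < len(lines):
        if _MULLIKEN_RE.search(lines[i]):
            block: list[float] = []
            j = i + 1
            while j < len(lines):
                m = _CHARGE_LINE_RE.match(lines[j])
                if m:
                    block.append(float(m.group(1)))
                    j += 1
                elif not block and lines[j].strip() and not _FLOAT_RE.search(lines[j]):
                    j += 1  # column-header line, e.g. "     1"
                else:
                    break
            if block:
                charges = block
            i = j
        else:
            i += 1
    if charges is None:
        raise DescriptorParseError(f"{path}: no Mulliken charges block found")

    # Last dipole total magnitude.
    dipole: float | None = None
    for i, line in enumerate(lines):
        if _DIPOLE_HDR_RE.search(line):
            for cand in lines[i : i + 3]:
                m = _DIPOLE_TOT_RE.search(cand)
                if m:
                    dipole = float(m.group(1))
                    break
    if dipole is None:
        raise DescriptorParseError(f"{path}: no dipole block found")

    arr = np.asarray(charges)
    desc = QuantumDescriptors(
        epsilon_homo=eig["occ"][-1],
        epsilon_homo_minus1=eig["occ"][-2],
        epsilon_lumo=eig["virt"][0],
        epsilon_lumo_plus1=eig["virt"][1],
        q_min=float(arr.min()),
        q_max=float(arr.max()),
        q_mean_abs=float(np.abs(arr).mean()),
        dipole=dipole,
    )
    desc.validate()
    return desc, list(map(float, charges))


def assign_q_hetero(
    smiles: str,
    charges: Sequence[float],
    atom_order: Sequence[int] | None = None,
) -> float:
    """Charge of the aniline N (preferred) or phenol O defining q_hetero.

    ``atom_order`` maps RDKit atom index -> position in ``charges``; by
    default the orders are assumed identical (heavy atoms first, as RDKit
    and most QM engines write them). With several candidate atoms the most
    negative charge wins — a deterministic, chemistry-plausible tie-break.
    """
    mol = mol_from_smiles(smiles)
    if atom_order is None:
        atom_order = range(mol.GetNumAtoms())
    order = list(atom_order)

    def charge_of(atom_idx: int) -> float:
        pos = order[atom_idx]
        if pos >= len(charges):
            raise SkinsensError("charge list shorter than atom map")
        return float(charges[pos])

    for smarts in (_ANILINE_SMARTS, _PHENOL_SMARTS):
        matches = mol.GetSubstructMatches(smarts)
        if matches:
            return min(charge_of(m[0]) for m in matches)
    raise StructureError(f"no aniline or phenol moiety in {smiles!r}")


@dataclass
class NormalizationParams:
    """Per-descriptor (min, max) fitted on training rows."""

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    fitted: bool = False

    def range_of(self, name: str) -> tuple[float, float]:
        if not self.fitted:
            raise NotFittedError("normalization parameters are not fitted")
        if name not in self.ranges:
            raise NotFittedError(f"no normalization range for descriptor {name!r}")
        return self.ranges[name]


def _descriptor_values(table, name: str, train_only: bool) -> np.ndarray:
    vals = []
    for rec in table.records:
        if train_only and getattr(rec, "split", "none") != "train":
            continue
        d = rec.descriptors
        v = getattr(d, name, None) if d is not None else None
        if v is not None:
            vals.append(float(v))
    return np.asarray(vals, dtype=float)


def minmax_fit(table, names: Sequence[str] | None = None) -> NormalizationParams:
    """Fit min-max ranges on the table's training rows only.

    Test rows reuse the training ranges, so no information leaks from the
    held-out set into the normalization. A constant descriptor is an error
    (it cannot be scaled to [0, 1]).
    """
    if names is None:
        names = [
            n for n in DESCRIPTOR_NAMES if _descriptor_values(table, n, True).size > 0
        ]
    params = NormalizationParams()
    for name in names:
        vals = _descriptor_values(table, name, train_only=True)
        if vals.size < 2:
            raise DegenerateDescriptorError(
                f"descriptor {name!r}: fewer than 2 training values"
            )
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            raise DegenerateDescriptorError(f"descriptor {name!r} is constant ({lo})")
        params.ranges[name] = (lo, hi)
    params.fitted = True
    return params


def minmax_apply(params: NormalizationParams, name: str, x) -> np.ndarray:
    """x' = (x - min) / (max - min). Out-of-range values are NOT clipped."""
    lo, hi = params.range_of(name)
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def minmax_invert(params: NormalizationParams, name: str, x_norm) -> np.ndarray:
    """Inverse of :func:`minmax_apply`."""
    lo, hi = params.range_of(name)
    return np.asarray(x_norm, dtype=float) * (hi - lo) + lo


def out_of_range(params: NormalizationParams, name: str, x) -> np.ndarray:
    """Boolean mask flagging values outside the training range."""
    z = minmax_apply(params, name, x)
    return (z < 0.0) | (z > 1.0)
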