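"""Synthetic descriptor data with the statistical structure the model assumes.

The generator draws the HOMO energy from class-conditional Gaussians — one
for sensitizers, one for non-sensitizers — whose default means and
standard deviations are estimated at run time from the training rows of
the packaged reference table (sensitizer mean ~ -0.279 hartree,
non-sensitizer mean ~ -0.327 hartree), not hard-coded. Up to eight further
descriptors are drawn independently of the label as uninformative nuisance
variables, filling the remaining quantum-descriptor columns, so stepwise
selection has something to reject. No structures, quantum noise models or
dose-response curves are simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .descriptors import DESCRIPTOR_NAMES, QuantumDescriptors
from .errors import SkinsensError
from .records import ChemicalRecord, ChemTable

__all__ = ["ClassParams", "SimConfig", "estimate_class_params", "default_config", "simulate_dataset"]

_NUISANCE_NAMES = tuple(n for n in DESCRIPTOR_NAMES if n != "epsilon_homo")


class ClassParams(NamedTuple):
    mu_s: float
    sigma_s: float
    mu_n: float
    sigma_n: float


def estimate_class_params(table) -> ClassParams:
    """Per-class mean and sample SD of the HOMO energy.

    Uses the training rows when the table carries a split, otherwise all
    rows. A zero SD is flagged as degenerate with a warning (the class
    collapses to a point mass).
    """
    use_split = any(getattr(r, "split", "none") == "train" for r in table)
    values = {"sensitizer": [], "non-sensitizer": []}
    for r in table:
        if use_split and r.split != "train":
            continue
        eps = r.epsilon_homo
        if eps is None or r.label not in values:
            continue
        values[r.label].append(float(eps))
    for label, vals in values.items():
        if len(vals) < 2:
            raise SkinsensError(
                f"class {label!r}: need >= 2 records with a HOMO energy"
            )
    s = np.asarray(values["sensitizer"])
    n = np.asarray(values["non-sensitizer"])
    params = ClassParams(
        mu_s=float(s.mean()),
        sigma_s=float(s.std(ddof=1)),
        mu_n=float(n.mean()),
        sigma_n=float(n.std(ddof=1)),
    )
    if params.sigma_s == 0 or params.sigma_n == 0:
        warnings.warn("degenerate class: zero standard deviation", stacklevel=2)
    return params


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters (hartree for the Gaussian class-conditionals)."""

    n_sensitizer: int
    n_nonsensitizer: int
    mu_s: float
    sigma_s: float
    mu_n: float
    sigma_n: float
    n_nuisance: int = 8
    nuisance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sensitizer < 0 or self.n_nonsensitizer < 0:
            raise SkinsensError("counts must be >= 0")
        if self.sigma_s <= 0 or self.sigma_n <= 0 or self.nuisance_sigma <= 0:
            raise SkinsensError("sigmas must be > 0")
        if not 0 <= self.n_nuisance <= len(_NUISANCE_NAMES):
            raise SkinsensError(
                f"n_nuisance must be in [0, {len(_NUISANCE_NAMES)}]"
            )


def default_config(
    n_sensitizer: int = 100, n_nonsensitizer: int = 100, seed: int = 0, **overrides
) -> SimConfig:
    """SimConfig with class parameters estimated from the packaged table."""
    from .records import load_fixture

    cp = estimate_class_params(load_fixture("table1"))
    base = dict(
        n_sensitizer=n_sensitizer,
        n_nonsensitizer=n_nonsensitizer,
        mu_s=cp.mu_s,
        sigma_s=cp.sigma_s,
        mu_n=cp.mu_n,
        sigma_n=cp.sigma_n,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def simulate_dataset(config: SimConfig) -> ChemTable:
    """Draw a labeled synthetic descriptor table.

    Deterministic under a fixed seed; the split is a random 50/50
    assignment; the generator parameters are logged into the table's
    provenance string.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sensitizer + config.n_nonsensitizer
    labels = ["sensitizer"] * config.n_sensitizer + [
        "non-sensitizer"
    ] * config.n_nonsensitizer
    eps = np.concatenate(
        [
            rng.normal(config.mu_s, config.sigma_s, config.n_sensitizer),
            rng.normal(config.mu_n, config.sigma_n, config.n_nonsensitizer),
        ]
    )
    nuisance = rng.normal(0.0, config.nuisance_sigma, size=(n, config.n_nuisance))
    splits = np.array(["test"] * n, dtype=object)
    order = rng.permutation(n)
    splits[order[: n // 2]] = "train"

    records = []
    for i in range(n):
        desc = {"epsilon_homo": float(eps[i])}
        for j in range(config.n_nuisance):
            desc[_NUISANCE_NAMES[j]] = float(nuisance[i, j])
        records.append(
            ChemicalRecord(
                id=f"sim-{i + 1:05d}",
                cas="",
                name=f"synthetic compound {i + 1}",
                label=labels[i],
                split=str(splits[i]),
                descriptors=QuantumDescriptors(**desc),
            )
        )
    provenance = (
        f"simulated(seed={config.seed}, n_s={config.n_sensitizer}, "
        f"n_n={config.n_nonsensitizer}, mu_s={config.mu_s:.6g}, "
        f"sigma_s={config.sigma_s:.6g}, mu_n={config.mu_n:.6g}, "
        f"sigma_n={config.sigma_n:.6g}, n_nuisance={config.n_nuisance}, "
        f"nuisance_sigma={config.nuisance_sigma:.6g})"
    )
    return ChemTable(records, provenance=provenance, schema="chemical")
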