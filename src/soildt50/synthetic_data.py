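"""Seeded generators for synthetic compound sets and half-life tables.

The generators produce data with the statistical structure the pipeline
assumes — per-compound replicate counts in a configurable range,
log10-normal half-lives around a compound-level mean, and optional
right-censored observations — so that every module can be exercised
without any external download. Ground truth is emitted in a separate
table that the pipeline never reads (leakage hygiene: tests only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .core_data import (
    Censor,
    CompoundRecord,
    Observation,
    check_applicability_domain,
    standardize_structure,
    write_halflife_table,
)

# Combinatorial vocabulary: disubstituted aromatic/aliphatic scaffolds.
_SCAFFOLDS = (
    "{a}c1ccc({b})cc1",        # para-benzene
    "{a}c1cccc({b})c1",        # meta-benzene
    "{a}c1ccc({b})cn1",        # pyridine
    "{a}c1ccc({b})s1",         # thiophene
    "{a}c1ccc2ccccc2c1{b}",    # naphthalene
    "{a}C1CCC({b})CC1",        # cyclohexane
)
_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)OC", "C(=O)N", "S", "SC",
    "C(F)(F)F", "[N+](=O)[O-]", "CO", "CCO", "C=C", "CC#N",
)


def build_vocabulary() -> list[str]:
    """Deterministic list of >= 500 distinct AD-passing canonical SMILES."""
    seen: dict[str, None] = {}
    for scaffold in _SCAFFOLDS:
        for a in _SUBSTITUENTS:
            for b in _SUBSTITUENTS:
                smi = scaffold.format(a=a, b=b)
                if Chem.MolFromSmiles(smi) is None:
                    continue
                can = standardize_structure(smi)
                if can not in seen and check_applicability_domain(can).in_domain:
                    seen[can] = None
    return list(seen)


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape of the synthetic data set."""

    n_compounds: int = 100
    replicate_range: tuple[int, int] = (1, 59)
    true_sigma_range: tuple[float, float] = (0.1, 0.5)
    censor_fraction: float = 0.0
    signal_model: str = "linear_in_descriptors"  # or "lookup"
    noise_sd: float = 0.3
    seed: int = 0
    left_censoring: bool = False  # right-censoring only by default

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        lo, hi = self.replicate_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid replicate_range")
        slo, shi = self.true_sigma_range
        if not (0 < slo <= shi):
            raise ValueError("invalid true_sigma_range")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise ValueError("censor_fraction must be in [0, 1)")
        if self.signal_model not in ("linear_in_descriptors", "lookup"):
            raise ValueError("unknown signal_model")


def _descriptor_signal(smiles_list: list[str], rng: np.random.Generator) -> np.ndarray:
    """Affine function of a fixed descriptor subset, standardized so the
    true means center near 1.2 log10 days with ~0.8 spread."""
    desc = np.array(
        [
            [
                Descriptors.MolWt(m),
                Descriptors.MolLogP(m),
                Descriptors.TPSA(m),
                Descriptors.NumRotatableBonds(m),
            ]
            for m in (Chem.MolFromSmiles(s) for s in smiles_list)
        ]
    )
    mu = desc.mean(axis=0)
    sd = np.where(desc.std(axis=0) == 0, 1.0, desc.std(axis=0))
    z = (desc - mu) / sd
    weights = np.array([0.45, 0.35, -0.25, 0.15])
    signal = z @ weights
    spread = signal.std() or 1.0
    return 1.2 + 0.8 * signal / spread


def generate_compounds(
    spec: SyntheticSpec,
) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Generate compound records plus a ground-truth table.

    Per compound: a true mean ``mu_star`` (affine in a fixed descriptor
    subset plus Normal(0, noise_sd), or an iid draw under the ``lookup``
    model), a true replicate SD ``sigma_star`` uniform in
    ``true_sigma_range``, and ``n_i ~ Uniform(replicate_range)``
    observations ``y_ij ~ Normal(mu_star, sigma_star^2)``. With
    probability *censor_fraction* an observation becomes a right-censor at
    its own value (left-censor when ``left_censoring`` is set).

    Returns ``(records, truth)`` where *truth* has columns
    ``compound_id, smiles, mu_star, sigma_star, n``.
    """
    vocab = build_vocabulary()
    if spec.n_compounds > len(vocab):
        raise ValueError(
            f"vocabulary has {len(vocab)} structures; "
            f"requested {spec.n_compounds} compounds"
        )
    rng = np.random.default_rng(spec.seed)
    smiles = [vocab[i] for i in rng.choice(len(vocab), spec.n_compounds, replace=False)]

    if spec.signal_model == "linear_in_descriptors":
        mu_star = _descriptor_signal(smiles, rng) + rng.normal(0, spec.noise_sd, spec.n_compounds)
    else:
        mu_star = rng.normal(1.2, 0.8, spec.n_compounds)
    sigma_star = rng.uniform(*spec.true_sigma_range, spec.n_compounds)
    n_obs = rng.integers(spec.replicate_range[0], spec.replicate_range[1] + 1,
                         spec.n_compounds)

    records, truth_rows = [], []
    censor_kind = Censor.LEFT if spec.left_censoring else Censor.RIGHT
    for i, smi in enumerate(smiles):
        cid = f"SYNTH-{i:04d}"
        ys = rng.normal(mu_star[i], sigma_star[i], int(n_obs[i]))
        censored = rng.random(int(n_obs[i])) < spec.censor_fraction
        obs = [
            Observation(
                value_days=float(10.0 ** y),
                censor=censor_kind if c else Censor.EXACT,
            )
            for y, c in zip(ys, censored)
        ]
        records.append(CompoundRecord(compound_id=cid, smiles=smi, observations=obs))
        truth_rows.append(
            {"compound_id": cid, "smiles": smi, "mu_star": mu_star[i],
             "sigma_star": sigma_star[i], "n": int(n_obs[i])}
        )
    return records, pd.DataFrame(truth_rows)


def write_synthetic_dataset(
    spec: SyntheticSpec, table_path: str | Path, truth_path: Optional[str | Path] = None
) -> None:
    """Emit the exact CSV dialect ``read_halflife_table`` consumes, and the
    ground truth to a separate file (never read by the pipeline)."""
    records, truth = generate_compounds(spec)
    write_halflife_table(records, table_path)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
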