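"""Emission-yield normalization and replicate combination.

Chemical samples are collected as a few puffs drawn through a single set of
media, with a replicate pair per topography condition; analytical masses
from the pair are combined so that they represent the pooled puff count (two
3-puff samples become the sum of 6 puffs). Yields are reported per puff
(µg/puff) and as airborne concentration (µg/m³, mass over total drawn
volume — the inhaled-dose-relevant denominator). With only two replicates
per condition, the within-pair spread is summarized as the half-range of the
per-puff yields, which for n = 2 coincides with the mean absolute deviation.

Between-product comparisons (e.g. organic carbon in unfiltered hemp vs a
filtered reference tobacco cigarette) use matched pairwise ratios: each
replicate's per-puff yield is divided by its counterpart's and the mean and
sample standard deviation of those ratios are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

#: Recognized analyte classes.
SPECIES_CLASSES = frozenset(
    {"PAH", "NPAH", "carbonyl", "cannabinoid", "OC", "EC", "TC", "grav_mass"}
)


@dataclass
class EmissionSample:
    """Per-sample species masses from one collection run.

    ``masses`` maps species name to µg collected on the media; ``classes``
    maps species name to its analyte class (PAH, carbonyl, OC, ...).
    """

    sample_id: str
    condition: str
    n_puffs: int
    sampled_volume_ml: float
    masses: dict[str, float]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_puffs < 1:
            raise ValueError("n_puffs must be >= 1")
        if self.sampled_volume_ml <= 0:
            raise ValueError("sampled_volume_ml must be positive")
        if any(m < 0 for m in self.masses.values()):
            raise ValueError("species masses must be non-negative")
        unknown = set(self.classes.values()) - SPECIES_CLASSES
        if unknown:
            raise ValueError(f"unknown species classes: {sorted(unknown)}")

    @property
    def per_puff(self) -> dict[str, float]:
        """µg per puff for every species in this sample."""
        return {s: m / self.n_puffs for s, m in self.masses.items()}


@dataclass
class EmissionSummary:
    """Replicate-combined yields for one topography condition."""

    condition: str
    n_puffs_total: int
    sampled_volume_ml: float
    total_mass_ug: dict[str, float]
    per_puff_yield: dict[str, float]
    concentration_ug_m3: dict[str, float]
    pair_variation: dict[str, float]
    classes: dict[str, str] = field(default_factory=dict)


def combine_replicates(a: EmissionSample, b: EmissionSample) -> EmissionSummary:
    """Pool a replicate pair: sum masses, puffs, and volumes.

    The pair must share a condition and species set. Pair variation per
    species is the half-range of the two per-puff yields.
    """
    if a.condition != b.condition:
        raise ValueError(
            f"condition mismatch: {a.condition!r} vs {b.condition!r}"
        )
    only_a = sorted(set(a.masses) - set(b.masses))
    only_b = sorted(set(b.masses) - set(a.masses))
    if only_a or only_b:
        raise ValueError(
            "species mismatch between replicates: "
            f"only in {a.sample_id}: {only_a}; only in {b.sample_id}: {only_b}"
        )
    n_total = a.n_puffs + b.n_puffs
    vol_total = a.sampled_volume_ml + b.sampled_volume_ml
    total = {s: a.masses[s] + b.masses[s] for s in a.masses}
    per_puff = {s: m / n_total for s, m in total.items()}
    pa, pb = a.per_puff, b.per_puff
    variation = {s: abs(pa[s] - pb[s]) / 2.0 for s in total}
    # µg per ml -> µg per m³ (1 m³ = 1e6 ml)
    conc = {s: m / vol_total * 1e6 for s, m in total.items()}
    classes = dict(b.classes)
    classes.update(a.classes)
    return EmissionSummary(
        condition=a.condition,
        n_puffs_total=n_total,
        sampled_volume_ml=vol_total,
        total_mass_ug=total,
        per_puff_yield=per_puff,
        concentration_ug_m3=conc,
        pair_variation=variation,
        classes=classes,
    )


def species_fraction(
    summary: EmissionSummary, species: str, within_class: str
) -> float:
    """Mass fraction of one species within its analyte class, in [0, 1]."""
    if species not in summary.total_mass_ug:
        raise ValueError(f"species {species!r} not in summary")
    class_total = sum(
        m
        for s, m in summary.total_mass_ug.items()
        if summary.classes.get(s) == within_class
    )
    if class_total <= 0:
        raise ValueError(f"class {within_class!r} has zero total mass")
    return summary.total_mass_ug[species] / class_total


def ratio_with_uncertainty(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Matched pairwise ratio of two yield series: mean and sample sd.

    Each x_i is divided by its matched y_i; the spread is the n-1 standard
    deviation of the individual ratios (undefined for a single pair).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have matching lengths")
    if len(x) < 2:
        raise ValueError("need >= 2 matched pairs for a spread estimate")
    if np.any(y <= 0):
        raise ValueError("denominator yields must be positive")
    r = x / y
    return float(r.mean()), float(r.std(ddof=1))


# ---------------------------------------------------------------------------
# Delimited-text emission tables
# ---------------------------------------------------------------------------

_COLUMNS = ["sample_id", "condition", "n_puffs", "volume_ml", "species", "class", "mass_ug"]


def read_emission_samples(path: Union[str, Path]) -> list[EmissionSample]:
    """Read a long-format emission table (one row per sample x species)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    samples = []
    for sid, g in df.groupby("sample_id", sort=False):
        if g["condition"].nunique() > 1 or g["n_puffs"].nunique() > 1:
            raise ValueError(f"{path}: inconsistent metadata for sample {sid}")
        samples.append(
            EmissionSample(
                sample_id=str(sid),
                condition=str(g["condition"].iloc[0]),
                n_puffs=int(g["n_puffs"].iloc[0]),
                sampled_volume_ml=float(g["volume_ml"].iloc[0]),
                masses=dict(zip(g["species"], g["mass_ug"].astype(float))),
                classes=dict(zip(g["species"], g["class"])),
            )
        )
    return samples


def write_emission_summary(summary: EmissionSummary, path: Union[str, Path]) -> None:
    """Write a combined summary as delimited text, one row per species."""
    rows = [
        {
            "condition": summary.condition,
            "species": s,
            "class": summary.classes.get(s, ""),
            "n_puffs_total": summary.n_puffs_total,
            "total_mass_ug": summary.total_mass_ug[s],
            "per_puff_ug": summary.per_puff_yield[s],
            "concentration_ug_m3": summary.concentration_ug_m3[s],
            "pair_variation_ug_per_puff": summary.pair_variation[s],
        }
        for s in sorted(summary.total_mass_ug)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
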