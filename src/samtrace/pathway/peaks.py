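"""Instrument-facing peak-area emission.

Maps simulated pool amounts to LC-MS-like peak areas: one row per
sample x metabolite x isotopologue class, with per-metabolite response
factors, multiplicative log-normal noise behind a single explicit seed, and
a detection floor.  Homocysteine is emitted flagged as non-detected with no
area, matching what the instrument panel can actually measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import TraceResult


@dataclass
class NoiseSpec:
    """Multiplicative measurement noise: ``area * exp(N(0, sd))``.

    ``sd`` may be a scalar (applied to every metabolite) or a mapping
    metabolite -> log-scale sd.  ``sd=0`` makes emission bit-identical
    across calls; equal seeds give identical noisy tables.
    """

    sd: float | dict[str, float] = 0.15
    detection_floor: float = 0.0
    seed: int = 0

    def sd_for(self, metabolite: str) -> float:
        if isinstance(self.sd, dict):
            val = float(self.sd.get(metabolite, 0.0))
        else:
            val = float(self.sd)
        if val < 0:
            raise ValueError("noise sd must be non-negative")
        return val


def emit_peak_table(
    results: dict[str, tuple[str, TraceResult]],
    noise: NoiseSpec | None = None,
    response_factors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Emit an intracellular peak-area table from simulation endpoints.

    Parameters
    ----------
    results:
        Mapping ``sample_id -> (group_label, TraceResult)``.
    noise:
        Noise specification; ``None`` means noise off.
    response_factors:
        Per-metabolite instrument response (area units per amount unit);
        default 1.0.  Negative factors are rejected.

    Returns
    -------
    DataFrame with columns ``sample_id, group, metabolite, isotopologue,
    peak_area, detected``.
    """
    noise = noise or NoiseSpec(sd=0.0)
    rf = dict(response_factors or {})
    for met, v in rf.items():
        if v < 0:
            raise ValueError(f"negative response factor for {met}")
    rng = np.random.default_rng(noise.seed)

    rows = []
    for sample_id, (group, result) in results.items():
        net = result.network
        for pool in net.pools:
            if pool.metabolite is None:
                continue
            met = pool.metabolite
            if not pool.detectable:
                for c in pool.label_classes:
                    rows.append((sample_id, group, met, f"m+{c}", np.nan, False))
                continue
            amount = result.endpoint_amount(pool.name)
            fractions = result.class_fractions(pool.name)
            factor = rf.get(met, 1.0)
            sd = noise.sd_for(met)
            # one multiplicative draw per sample x metabolite: extraction and
            # response vary per compound while coeluting isotopologues keep
            # their ratios
            if sd > 0:
                factor *= float(np.exp(rng.normal(0.0, sd)))
            for c in pool.label_classes:
                area = amount * fractions.get(f"m+{c}", 0.0) * factor
                detected = area >= noise.detection_floor
                rows.append((sample_id, group, met, f"m+{c}",
                             area if detected else 0.0, detected))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "metabolite", "isotopologue",
                       "peak_area", "detected"])


def emit_supernatant_table(
    results: dict[str, tuple[str, TraceResult]],
    noise: NoiseSpec | None = None,
    protein_mass: dict[str, float] | float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Emit the ex vivo supernatant measurements (adenosine + inosine).

    Returns the supernatant peak table and a per-sample protein-mass series
    (BCA-style) used downstream for per-protein normalization.
    """
    noise = noise or NoiseSpec(sd=0.0)
    rng = np.random.default_rng(noise.seed + 1)
    rows, prot = [], {}
    for sample_id, (group, result) in results.items():
        exported = result.exported_purines()
        for met in ("adenosine", "inosine"):
            area = exported[met]
            sd = noise.sd_for(met)
            if sd > 0:
                area *= float(np.exp(rng.normal(0.0, sd)))
            rows.append((sample_id, group, met, area, True))
        prot[sample_id] = (protein_mass.get(sample_id, np.nan)
                           if isinstance(protein_mass, dict)
                           else float(protein_mass))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "metabolite",
                                     "peak_area", "detected"])
    return df, pd.Series(prot, name="protein_mass")
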