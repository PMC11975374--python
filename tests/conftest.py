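"""Shared fixtures: cached tracer simulations (each deterministic scenario
is simulated once per session) and small helper tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from samtrace.pathway import build_scenario, simulate_tracer


@pytest.fixture(scope="session")
def sim():
    """Memoized scenario simulator: ``sim(genotype=..., infected=..., ...)``."""
    cache: dict = {}

    def get(**kwargs):
        def freeze(v):
            if isinstance(v, dict):
                return tuple(sorted(v.items()))
            return v
        key = tuple(sorted((k, freeze(v)) for k, v in kwargs.items()))
        if key not in cache:
            cache[key] = simulate_tracer(build_scenario(**kwargs))
        return cache[key]

    return get


@pytest.fixture()
def toy_peak_table() -> pd.DataFrame:
    """Two samples, two metabolites; sample s2 is exactly 2x the reference."""
    rows = []
    for sample, scale in (("s1", 1.0), ("s2", 2.0)):
        for met, area in (("SAM", 10.0), ("SAH", 5.0)):
            rows.append((sample, "g", met, "m+0", area * scale, True))
    return pd.DataFrame(rows, columns=["sample_id", "group", "metabolite",
                                       "isotopologue", "peak_area",
                                       "detected"])


def make_cohort_frame(times_a, times_b, arm_a="A", arm_b="B",
                      pupated_a=None, pupated_b=None) -> pd.DataFrame:
    """Hand-built two-arm cohort table for the phenotype statistics."""
    rows = []
    for arm, times, pupated in ((arm_a, times_a, pupated_a),
                                (arm_b, times_b, pupated_b)):
        if pupated is None:
            pupated = [True] * len(times)
        for i, (t, p) in enumerate(zip(times, pupated)):
            rows.append((f"{arm}{i}", arm, arm, False, float(t), bool(p),
                         False, False, 0))
    return pd.DataFrame(rows, columns=[
        "larva_id", "arm", "genotype", "infected", "pupation_h_AEL",
        "pupated", "adult", "egg_present", "lamellocytes"])
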