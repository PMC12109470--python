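"""Shared fixtures: scaled-down synthetic cohorts and feature tables.

Monte-Carlo suites run on reduced problem sizes (fewer subjects, shorter
recordings at 128 Hz, 8 s epochs) so the whole suite stays desk-scale;
full-scale defaults (19 ch × 256 Hz × 160 s, 32 s epochs) are exercised by
the smoke/end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegmdd import (
    CohortSpec,
    EffectMap,
    FeatureTable,
    apply_average_reference,
    build_feature_table,
    crop_recording,
    epoch_recording,
    filter_recording,
    generate_cohort,
    qc_epochs,
)


def clean_effect(**kwargs) -> EffectMap:
    """Effect map with nuisance sources off (for runs that skip ICA)."""
    kwargs.setdefault("blink_rate", 0.0)
    kwargs.setdefault("line_noise_amplitude", 0.0)
    return EffectMap(**kwargs)


def null_effect(**kwargs) -> EffectMap:
    kwargs.setdefault("blink_rate", 0.0)
    kwargs.setdefault("line_noise_amplitude", 0.0)
    return EffectMap.null(**kwargs)


def quick_cohort_table(
    n_mdd: int,
    n_hc: int,
    seed: int,
    effect: EffectMap,
    duration: float = 17.0,
    fs: float = 128.0,
    window: float = 8.0,
    overlap: float = 1.0,
    preprocess: bool = False,
) -> FeatureTable:
    """Generate → (optionally filter) → segment → featurize, scaled down."""
    spec = CohortSpec(
        n_mdd=n_mdd, n_hc=n_hc, duration_seconds=duration, fs=fs,
        effect=effect, seed=seed,
    )
    sets = []
    for rec in generate_cohort(spec):
        if preprocess:
            rec = filter_recording(apply_average_reference(rec))
        eps = qc_epochs(epoch_recording(rec, window, overlap))
        sets.append(eps)
    return build_feature_table(sets)


@pytest.fixture(scope="session")
def small_effect_table() -> FeatureTable:
    """One strong-effect cohort reused by several classification tests."""
    eff = clean_effect(band_factors={
        "delta": 1.0, "theta": 1.5, "alpha": 1.5,
        "beta1": 1.5, "beta2": 1.5, "gamma": 1.0,
    })
    return quick_cohort_table(10, 10, seed=11, effect=eff)


@pytest.fixture(scope="session")
def gaussian_table() -> FeatureTable:
    """Pure-noise feature table (no signal), for null/permutation checks."""
    rng = np.random.default_rng(7)
    import pandas as pd

    n_sub, n_ep, n_feat = 20, 4, 30
    rows = rng.standard_normal((n_sub * n_ep, n_feat))
    values = pd.DataFrame(rows, columns=[f"R__f{i}" for i in range(n_feat)])
    labels = ["MDD" if s < n_sub // 2 else "HC"
              for s in range(n_sub) for _ in range(n_ep)]
    subjects = [f"s{s}" for s in range(n_sub) for _ in range(n_ep)]
    return FeatureTable(values, labels, subjects)
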