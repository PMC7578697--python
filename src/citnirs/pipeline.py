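"""End-to-end convenience: synthetic cohort -> preprocessed feature table."""

from __future__ import annotations

from .preprocess import FeatureTable, PreprocessConfig, build_dataset, preprocess_session
from .synthetic import (
    CohortSpec,
    EffectSpec,
    HrfSpec,
    NoiseSpec,
    SyntheticDataset,
    generate_cohort,
)

__all__ = ["features_from_cohort", "simulate_features"]


def features_from_cohort(
    dataset: SyntheticDataset,
    cfg: PreprocessConfig = PreprocessConfig(),
    include_cits: tuple[str, ...] = ("CIT1", "CIT2"),
) -> FeatureTable:
    """Filter, baseline-standardize and reduce every session to features."""
    labels = dataset.labels.set_index("subject_id")
    vectors = []
    for series in dataset.sessions:
        row = labels.loc[series.subject_id]
        vectors.extend(
            preprocess_session(
                series, dataset.layout, cfg,
                group=str(row["group"]), mhe=bool(row["mhe"]),
            )
        )
    return build_dataset(vectors, include_cits=include_cits)


def simulate_features(
    cohort: CohortSpec = CohortSpec(),
    hrf: HrfSpec = HrfSpec(),
    effect: EffectSpec = EffectSpec(),
    noise: NoiseSpec = NoiseSpec(),
    cfg: PreprocessConfig = PreprocessConfig(),
    include_cits: tuple[str, ...] = ("CIT1", "CIT2"),
) -> tuple[SyntheticDataset, FeatureTable]:
    """Simulate a cohort and run the preprocessing chain on it."""
    dataset = generate_cohort(cohort, hrf=hrf, effect=effect, noise=noise)
    table = features_from_cohort(dataset, cfg=cfg, include_cits=include_cits)
    return dataset, table
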