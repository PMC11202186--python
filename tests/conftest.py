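import numpy as np
import pandas as pd
import pytest

from cfdna_tss import (
    SimConfig,
    SplitSpec,
    apply_normalization,
    build_coverage_matrix,
    fit_normalization,
    simulate_cohort,
    stratified_split,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 28-sample, 200-TSS cohort with 20 + 20 planted features."""
    cfg = SimConfig(
        n_healthy=12,
        n_cancer_per_stage={"I": 4, "II": 4, "III": 4, "IV": 4},
        n_tss=200,
        n_informative_up=20,
        n_informative_down=20,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return build_coverage_matrix(small_cohort.fragment_items(), small_cohort.annotation)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return stratified_split(small_cohort.sample_sheet, SplitSpec(seed=7))


@pytest.fixture(scope="session")
def small_normalized(small_cohort, small_matrix, small_split):
    train_ids, _ = small_split
    params = fit_normalization(small_matrix, train_ids)
    return apply_normalization(small_matrix, params)


@pytest.fixture(scope="session")
def small_sheet(small_cohort):
    return small_cohort.sample_sheet.set_index("sample_id")


def naive_relative_coverage(frags: pd.DataFrame, chrom: str, tss: int) -> float:
    """Independent per-base double-loop oracle for the coverage statistic."""
    def depth(lo, hi):
        total = 0
        for b in range(lo, hi):
            for _, f in frags.iterrows():
                if f["chrom"] == chrom and f["start"] <= b < f["end"]:
                    total += 1
        return total

    central = depth(tss - 500, tss + 500)
    flanks = depth(tss - 1500, tss - 500) + depth(tss + 500, tss + 1500)
    if flanks == 0:
        return float("nan")
    return (central / 1000) / (flanks / 2000)
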