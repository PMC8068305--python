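import numpy as np
import pytest

from imctme import phenotype, synth


@pytest.fixture(scope="session")
def rendered_tissue():
    """One rendered default tissue sample: (spec, stack, mask, truth)."""
    spec = synth.default_tissue_spec(seed=2)
    stack, mask, truth = synth.generate_tissue(spec)
    return spec, stack, mask, truth


@pytest.fixture(scope="session")
def cell_table(rendered_tissue):
    """Quantified + z-scored cell table of the rendered tissue."""
    _, stack, mask, _ = rendered_tissue
    table = phenotype.quantify_cells(mask, stack, sample_id="s1")
    return phenotype.zscore_normalize(table)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort (6 LTS + 6 STS) for fast feature tests."""
    tissue = synth.default_tissue_spec(seed=0)
    spec = synth.CohortSpec(
        n_samples_per_class={"LTS": 6, "STS": 6},
        planted_density_effects={"CD8_4": 0.10},
        planted_interaction_effects={("CD8_4", "tu_1"): 0.6},
        seed=5,
    )
    cohort = synth.generate_cohort(tissue, spec, render=False)
    return tissue, spec, cohort


def brute_force_logrank(months_a, events_a, months_b, events_b):
    """Independent log-rank oracle: explicit observed/expected sums over
    event times (hypergeometric variance), for small n."""
    months_a = np.asarray(months_a, dtype=float)
    months_b = np.asarray(months_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    event_times = np.unique(
        np.concatenate([months_a[events_a == 1], months_b[events_b == 1]])
    )
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = int((months_a >= t).sum())
        n_b = int((months_b >= t).sum())
        n = n_a + n_b
        d_a = int(((months_a == t) & (events_a == 1)).sum())
        d_b = int(((months_b == t) & (events_b == 1)).sum())
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2
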