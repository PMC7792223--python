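import numpy as np
import pytest

from crossmeth.types import GenomicSite, MethylationCountTable, SampleMeta


def make_samples(tissue="RBC", n_per_time=2, times=(1, 2, 3)):
    samples = []
    for t in times:
        for j in range(n_per_time):
            fem = f"F{t}{j}"
            samples.append(
                SampleMeta(
                    sample_id=f"{fem}_{tissue}",
                    female_id=fem,
                    tissue=tissue,
                    time_point=t,
                    temperature_env="warm" if j % 2 == 0 else "cold",
                    family_id=f"fam{j}",
                )
            )
    return samples


def make_table(coverage, methylated, tissue="RBC", times=None, n_per_time=None):
    coverage = np.asarray(coverage)
    n_sites, n_samples = coverage.shape
    if times is None:
        # spread samples evenly over as many time points as needed
        per = n_per_time or max(n_samples // 3, 1)
        times = tuple(sorted({min((j // per) + 1, 3) for j in range(n_samples)}))
        samples = []
        for j in range(n_samples):
            t = min(j // per + 1, 3)
            samples.append(
                SampleMeta(
                    sample_id=f"s{j}",
                    female_id=f"f{j}",
                    tissue=tissue,
                    time_point=t,
                    temperature_env="warm" if j % 2 == 0 else "cold",
                    family_id=f"fam{j}",
                )
            )
    else:
        samples = []
        for j, t in enumerate(times):
            samples.append(
                SampleMeta(
                    sample_id=f"s{j}",
                    female_id=f"f{j}",
                    tissue=tissue,
                    time_point=t,
                    temperature_env="warm" if j % 2 == 0 else "cold",
                    family_id=f"fam{j}",
                )
            )
    sites = [GenomicSite("chr1", 100 + 10 * i, "+") for i in range(n_sites)]
    return MethylationCountTable(sites, samples, coverage, np.asarray(methylated))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
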