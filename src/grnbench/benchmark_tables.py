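"""Published whole-network accuracy tables for the yeast benchmark.

These package data files carry the reported sensitivity|specificity and
PPV|NPV pairs (2 decimals, as printed) for the 18 statistical approaches
applied to 13 *S. cerevisiae* microarray datasets, evaluated against the
most conservative knockout-and-binding gold standard.  They serve as fixed
reference inputs for the table-summarization operations — method averages,
dataset averages and data-type averages of the combined Euclidean
distances — and are not produced by this package's own inference runs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "BENCHMARK_APPROACHES",
    "BENCHMARK_DATASETS",
    "load_sens_spec_pairs",
    "load_ppv_npv_pairs",
    "load_dataset_types",
]

BENCHMARK_APPROACHES: tuple[str, ...] = (
    "BIVARIATE_Z_FDR_AND", "BIVARIATE_Z_FDR_OR", "BIVARIATE_Z_ALPHA",
    "GLL_Z_1_AND", "GLL_Z_1_OR", "GLL_Z_2_AND", "GLL_Z_2_OR",
    "GLL_Z_3_AND", "GLL_Z_3_OR",
    "BIVARIATE_G_FDR_AND", "BIVARIATE_G_FDR_OR", "BIVARIATE_G_ALPHA",
    "GLL_G_1_AND", "GLL_G_1_OR", "GLL_G_2_AND", "GLL_G_2_OR",
    "GLL_G_3_AND", "GLL_G_3_OR",
)

BENCHMARK_DATASETS: tuple[str, ...] = (
    "Holstege1", "Holstege2", "Gresham", "Gasch", "Smith", "Yeung",
    "M3D", "GPL90", "Hughes1", "Hughes2", "Hu", "Holstege3", "Holstege4",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("grnbench.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_sens_spec_pairs() -> pd.DataFrame:
    """Long table: approach, dataset, sensitivity, specificity."""
    return _load("benchmark_sens_spec.tsv")


def load_ppv_npv_pairs() -> pd.DataFrame:
    """Long table: approach, dataset, ppv, npv."""
    return _load("benchmark_ppv_npv.tsv")


def load_dataset_types() -> dict[str, str]:
    """Dataset → data-type (replicates / environment_time / compendium / perturbation)."""
    df = _load("benchmark_datasets.tsv")
    return dict(zip(df["dataset"], df["data_type"]))
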