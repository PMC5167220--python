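"""Bundled reference tables from the clinical study design this package emulates.

Two small tables ship with the package:

* ``reference_tract_summaries.tsv`` — per-bundle percent-tract-affected
  and mean effect size r for each DTI metric, for the bvFTD-vs-control
  and EOAD-vs-control comparisons.  These published per-tract summaries
  serve as arithmetic fixtures for the ranking layer (the subject-level
  images behind them are not distributable).
* ``cohort_demographics.tsv`` — group sizes, age, sex and MMSE
  distributions of the three diagnostic groups (33 controls, 20 bvFTD,
  23 EOAD), used to parameterize the synthetic cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_reference_summaries",
    "load_demographics",
    "pooled_mean",
    "pooled_mmse_mean",
]

_METRIC_COLS = {"FA": "fa", "MD": "md", "RD": "rd", "AX": "ax"}


def _read(name: str) -> pd.DataFrame:
    source = resources.files("tractometry.data") / name
    with resources.as_file(source) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_summaries() -> pd.DataFrame:
    """Reference per-tract summaries in the tidy layout used by the
    ranking layer: columns comparison, metric, bundle, percent_tract,
    mean_r."""
    wide = _read("reference_tract_summaries.tsv")
    records = []
    for _, row in wide.iterrows():
        for metric, col in _METRIC_COLS.items():
            records.append(
                {
                    "comparison": row["comparison"],
                    "metric": metric,
                    "bundle": row["abbreviation"],
                    "percent_tract": row[f"{col}_percent_tract"],
                    "mean_r": row[f"{col}_r"],
                }
            )
    return pd.DataFrame.from_records(records)


def load_demographics() -> pd.DataFrame:
    """Group-level demographic parameters (indexed by group name)."""
    return _read("cohort_demographics.tsv").set_index("group")


def pooled_mean(means, sizes) -> float:
    """Size-weighted pooled mean of per-group means."""
    import numpy as np

    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    return float(np.sum(means * sizes) / np.sum(sizes))


def pooled_mmse_mean(demographics: pd.DataFrame | None = None) -> float:
    """Pooled mean MMSE over all three groups, from group means and sizes."""
    demo = demographics if demographics is not None else load_demographics()
    return pooled_mean(demo["mmse_mean"], demo["n"])
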