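"""Bundle registry: the 21 named white-matter tracts and their atlas fiber counts.

The registry mirrors the atlas template used by the analysis design this
package emulates: 21 major bundles (bilateral anterior thalamic
radiations, six corpus callosum segments, cingulum and parahippocampal
cingulum bilaterally, corticospinal tracts, inferior fronto-occipital and
inferior longitudinal fasciculi bilaterally, left superior longitudinal
fasciculus, and the uncinate fasciculus bilaterally) totalling 5859
template fibers.  Registry order is the canonical bundle order and the
deterministic tie-break for ambiguous fiber assignments.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_registry", "registry_order", "total_fibers", "DEFAULT_K"]

#: Number of equidistant sample points per fiber.
DEFAULT_K = 15


def load_registry(path: str | Path | None = None) -> pd.DataFrame:
    """Load the bundle registry as a DataFrame.

    Columns: ``index`` (1-based registry position), ``abbreviation``,
    ``name``, ``n_fibers``.  With no path the packaged registry of 21
    bundles is returned.
    """
    if path is None:
        source = resources.files("tractometry.data") / "bundle_registry.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"index", "abbreviation", "name", "n_fibers"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns {sorted(missing)}")
    if df["abbreviation"].duplicated().any():
        dupes = df.loc[df["abbreviation"].duplicated(), "abbreviation"].tolist()
        raise ValueError(f"duplicate bundle abbreviations {dupes}")
    if (df["n_fibers"] <= 0).any():
        bad = df.loc[df["n_fibers"] <= 0, "abbreviation"].tolist()
        raise ValueError(f"non-positive fiber counts for {bad}")
    return df.sort_values("index").reset_index(drop=True)


def registry_order(registry: pd.DataFrame | None = None) -> list[str]:
    """Bundle abbreviations in canonical registry order."""
    if registry is None:
        registry = load_registry()
    return registry["abbreviation"].tolist()


def total_fibers(registry: pd.DataFrame | None = None) -> int:
    if registry is None:
        registry = load_registry()
    return int(registry["n_fibers"].sum())
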