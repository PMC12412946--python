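"""Packaged worked-example data.

``table2_votes.csv`` and ``reference_relationships.csv`` hold the published
per-edge polarity vote counts (over 100 competing models) and the
literature-documented effects for the 11 directed relationships of the COPD
serum study's 15-protein oxidative-stress subnetwork.

``undocumented_votes_synthetic.csv`` is a SYNTHETIC stand-in for the
unpublished per-edge votes of the remaining 39 candidate pairs: rows are
constructed to match the study's reported aggregates (24 recruited by
majority vote, 17 of them unanimously; 3 unanimously absent), not any
measured vote counts.  Node identifiers U01A/U01B etc. are placeholders.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .data_model_io import read_reference_table

__all__ = [
    "load_documented_votes",
    "load_reference_relationships",
    "load_undocumented_votes_synthetic",
    "load_full_vote_table",
]


def _path(name: str):
    return files("dynastab.data").joinpath(name)


def load_documented_votes() -> pd.DataFrame:
    """Published polarity vote counts for the 11 documented directed pairs."""
    return pd.read_csv(_path("table2_votes.csv"))


def load_reference_relationships() -> list:
    """Literature effects (positive/negative/unknown) for the 11 documented pairs."""
    return read_reference_table(_path("reference_relationships.csv"))


def load_undocumented_votes_synthetic() -> pd.DataFrame:
    """Synthetic vote counts for the 39 undocumented pairs (see module docstring)."""
    return pd.read_csv(_path("undocumented_votes_synthetic.csv"))


def load_full_vote_table() -> pd.DataFrame:
    """All 50 directed candidate pairs: published documented rows + synthetic rest."""
    return pd.concat(
        [load_documented_votes(), load_undocumented_votes_synthetic()],
        ignore_index=True,
    )
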