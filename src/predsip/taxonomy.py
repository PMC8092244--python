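"""Predator-group assignment from rank-annotated lineage strings.

Six bacterial groups are treated as putatively predatory: the obligate
predators *Bdellovibrionales* and *Vampirovibrionales*, and the
facultative predators *Cytophagales*, *Lysobacter*, *Myxococcales* and
*Streptomycetales*.  Assignment is by case-insensitive name occurrence
at the class, order or family rank (genus for *Lysobacter*), the ranks
at which 16S-based taxonomy is most reliable.  The token table mapping
name variants and rank synonyms (e.g. the class Cytophagia vs the order
Cytophagales) ships as an editable CSV data file, not code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import AmbiguousLineageError

__all__ = [
    "PREDATOR_GROUPS",
    "GROUP_MODES",
    "PredatorAssignment",
    "PredatorLineageClassifier",
    "load_group_table",
    "classify",
    "classify_table",
    "prevalence",
]

#: Canonical group names, in the order used for reporting.
PREDATOR_GROUPS = (
    "Bdellovibrionales",
    "Cytophagales",
    "Lysobacter",
    "Myxococcales",
    "Streptomycetales",
    "Vampirovibrionales",
)

#: Trophic mode per canonical group.
GROUP_MODES = {
    "Bdellovibrionales": "obligate",
    "Vampirovibrionales": "obligate",
    "Cytophagales": "facultative",
    "Lysobacter": "facultative",
    "Myxococcales": "facultative",
    "Streptomycetales": "facultative",
}

#: Rank search order: coarsest matching rank wins.
RANK_PRIORITY = ("class", "order", "family", "genus")

_RANK_PREFIXES = {
    "k__": "kingdom",
    "d__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}


@dataclass(frozen=True)
class PredatorAssignment:
    """Assignment of one taxon to a predator group (or none)."""

    group: str | None
    mode: str  # obligate | facultative | none
    matched_rank: str | None

    @property
    def is_predator(self) -> bool:
        return self.group is not None


NON_PREDATOR = PredatorAssignment(group=None, mode="none", matched_rank=None)


def load_group_table() -> pd.DataFrame:
    """Load the shipped token table (columns group, token, rank, mode)."""
    with resources.files("predsip.data").joinpath("predator_groups.csv").open() as fh:
        table = pd.read_csv(fh)
    bad = set(table["group"]) - set(PREDATOR_GROUPS)
    if bad:
        raise ValueError(f"unknown groups in token table: {sorted(bad)}")
    return table


def parse_lineage(lineage: str) -> dict:
    """Parse a rank-prefixed lineage string into ``{rank: name}``.

    Accepts Greengenes/SILVA-style strings such as
    ``"k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Myxococcales"``.
    Unprefixed tokens are ignored.
    """
    out = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        prefix = token[:3].lower()
        if prefix in _RANK_PREFIXES and len(token) > 3:
            out[_RANK_PREFIXES[prefix]] = token[3:].strip()
    return out


def classify(lineage: str, table: pd.DataFrame | None = None) -> PredatorAssignment:
    """Classify one lineage string.

    Matching is case-insensitive against the token table, searched by
    rank from class down to genus; the coarsest matching rank wins.  A
    lineage matching two distinct groups raises
    :class:`AmbiguousLineageError`.  Lineages with no parseable ranks
    return the non-predator assignment with a warning.
    """
    if table is None:
        table = _default_table()
    if not str(lineage).strip():
        raise ValueError("empty lineage string")
    ranks = parse_lineage(lineage)
    if not ranks:
        warnings.warn(f"unparseable lineage {lineage!r}; assigned none", stacklevel=2)
        return NON_PREDATOR
    hits = []  # (rank, group)
    for rank in RANK_PRIORITY:
        name = ranks.get(rank)
        if name is None:
            continue
        name_l = name.lower()
        sel = table[(table["rank"] == rank) & (table["token"] == name_l)]
        for group in sel["group"].unique():
            hits.append((rank, group))
    if not hits:
        return NON_PREDATOR
    groups = {g for _, g in hits}
    if len(groups) > 1:
        raise AmbiguousLineageError(
            f"lineage {lineage!r} matches multiple predator groups: {sorted(groups)}"
        )
    rank, group = hits[0]  # coarsest rank first by construction
    return PredatorAssignment(group=group, mode=GROUP_MODES[group], matched_rank=rank)


_TABLE_CACHE = None


def _default_table() -> pd.DataFrame:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        table = load_group_table()
        table = table.assign(token=table["token"].str.lower())
        _TABLE_CACHE = table
    return _TABLE_CACHE


def classify_table(taxonomy: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify a taxonomy table with columns ``taxon_id``, ``lineage``."""
    out = []
    for _, row in taxonomy.iterrows():
        a = classify(row["lineage"], table)
        out.append(
            {
                "taxon_id": row["taxon_id"],
                "group": a.group,
                "mode": a.mode,
                "matched_rank": a.matched_rank,
            }
        )
    return pd.DataFrame(out)


class PredatorLineageClassifier(BaseEstimator):
    """Rule-based predator classifier over lineage strings.

    A stateless estimator: :meth:`fit` only loads (or accepts) the token
    table, so the class composes with scikit-learn pipelines and keeps
    the table swappable.
    """

    def __init__(self, table: pd.DataFrame | None = None):
        self.table = table

    def fit(self, X=None, y=None):
        self.table_ = (
            self.table.assign(token=self.table["token"].str.lower())
            if self.table is not None
            else _default_table()
        )
        return self

    def predict(self, X) -> pd.DataFrame:
        """Classify an iterable of lineage strings into a DataFrame."""
        if not hasattr(self, "table_"):
            self.fit()
        rows = []
        for lineage in X:
            a = classify(lineage, self.table_)
            rows.append(
                {"group": a.group, "mode": a.mode, "matched_rank": a.matched_rank}
            )
        return pd.DataFrame(rows)


def prevalence(
    assignments: pd.DataFrame, abundances: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-site predator prevalence.

    ``assignments`` needs ``taxon_id``, ``site_id`` and ``group``
    columns; ``abundances`` (optional) needs ``taxon_id``, ``site_id``,
    ``rel_abundance`` for the abundance-weighted percentage.  Returns one
    row per site with ``pct_taxa`` and (if available) ``pct_abundance``.
    """
    rows = []
    for site_id, sub in assignments.groupby("site_id", sort=True):
        n = sub["taxon_id"].nunique()
        if n == 0:
            warnings.warn(f"site {site_id!r} has no taxa; omitted", stacklevel=2)
            continue
        pred_taxa = set(sub.loc[sub["group"].notna(), "taxon_id"])
        row = {"site_id": site_id, "pct_taxa": 100.0 * len(pred_taxa) / n}
        if abundances is not None:
            ab = abundances[abundances["site_id"] == site_id]
            total = ab["rel_abundance"].sum()
            if total > 0:
                pred = ab[ab["taxon_id"].isin(pred_taxa)]["rel_abundance"].sum()
                row["pct_abundance"] = 100.0 * pred / total
        rows.append(row)
    return pd.DataFrame(rows)
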