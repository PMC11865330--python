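"""Core tabular containers: abundance tables, taxonomy, rrn lookup.

An :class:`AbundanceTable` holds a taxon x sample matrix (integer counts or
relative abundances) together with a taxonomy frame giving the lineage of
every taxon.  All downstream modules consume these containers; plain TSV is
the on-disk format throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: taxonomic ranks carried by every table, coarsest first
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix with per-taxon taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id, one column per sample.  Entries are
        non-negative counts or relative abundances.
    taxonomy
        DataFrame indexed by taxon id with the columns in :data:`RANKS`.
        Unknown ranks carry the string ``"unclassified"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                "unclassified", index=self.counts.index, columns=list(RANKS)
            )
        if (self.counts.values < 0).any():
            raise ValueError("abundance table contains negative entries")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"taxonomy missing for {len(missing)} taxa")
        self.taxonomy = self.taxonomy.loc[self.counts.index]

    # -- basic views -------------------------------------------------------
    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return len(self.counts.index)

    @property
    def n_samples(self) -> int:
        return len(self.counts.columns)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.counts.copy(), self.taxonomy.copy())

    def subset(self, taxa) -> "AbundanceTable":
        taxa = pd.Index(taxa)
        return AbundanceTable(self.counts.loc[taxa], self.taxonomy.loc[taxa])

    def aggregate_by(self, rank: str) -> "AbundanceTable":
        """Sum rows sharing the same name at ``rank`` (e.g. genus level)."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        groups = self.taxonomy[rank]
        agg = self.counts.groupby(groups).sum()
        tax = pd.DataFrame("unclassified", index=agg.index, columns=list(RANKS))
        tax[rank] = agg.index
        return AbundanceTable(agg, tax)

    # -- IO ----------------------------------------------------------------
    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(
            0, "taxonomy", self.taxonomy[list(RANKS)].agg(";".join, axis=1)
        )
        out.to_csv(path, sep="\t", index_label="taxon_id")

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        raw = pd.read_csv(path, sep="\t", index_col="taxon_id")
        lineage = raw.pop("taxonomy").str.split(";", expand=True)
        lineage.columns = list(RANKS)
        return cls(raw, lineage)


class RrnLookup:
    """(name, rank) -> 16S rRNA operon copy number lookup.

    Mirrors an rrndb-style table: entries exist at species, genus and/or
    family rank and are matched most-specific-first by :func:`assign_rrn`.
    """

    MATCH_RANKS = ("species", "genus", "family")

    def __init__(self, entries: pd.DataFrame):
        req = {"name", "rank", "copies"}
        if not req.issubset(entries.columns):
            raise ValueError(f"lookup needs columns {sorted(req)}")
        if (entries["copies"] < 1).any():
            raise ValueError("rrn copy numbers must be >= 1")
        bad = set(entries["rank"]) - set(self.MATCH_RANKS)
        if bad:
            raise ValueError(f"unsupported ranks in lookup: {sorted(bad)}")
        if not len(entries):
            raise ValueError("empty rrn lookup")
        self.entries = entries.reset_index(drop=True)
        self._map = {
            (row["rank"], row["name"]): float(row["copies"])
            for _, row in self.entries.iterrows()
        }

    def get(self, rank: str, name: str):
        return self._map.get((rank, name))

    def write_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "RrnLookup":
        return cls(pd.read_csv(path, sep="\t"))


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Column-normalize to relative abundances (each sample sums to 1)."""
    sums = table.counts.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"degenerate all-zero sample(s): {bad}")
    rel = table.counts / sums
    return AbundanceTable(rel, table.taxonomy.copy())


def write_tidy_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
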