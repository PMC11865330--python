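"""Abundance-table preprocessing and taxon screening.

Covers rarefaction, relative-abundance conversion, the three-way core-genus
screen (ubiquitous / overall abundant / frequently abundant), the
marker-correlation screen for candidate comammox taxa, dominant-oxidizer
classification from guild amoA copies, rrn copy-number assignment and the
abundance-weighted mean copy number (MCN) per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, RrnLookup, to_relative

__all__ = [
    "rarefy", "to_relative", "CoreCriteria", "screen_core_genera",
    "screen_pc_taxa", "classify_dominant_oxidizer", "assign_rrn", "compute_mcn",
]


def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample each sample (column) to ``depth`` reads without replacement.

    Samples shallower than ``depth`` are dropped with a warning.  Sampling is
    multivariate hypergeometric, so retained columns sum exactly to ``depth``
    and the expected count of each taxon is ``depth * count / total``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.counts.sum(axis=0)
    keep = sums.index[sums >= depth]
    dropped = sums.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} sample(s) shallower than depth={depth}: "
            f"{list(dropped)}"
        )
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.taxa)
    return AbundanceTable(counts, table.taxonomy.copy())


# ---------------------------------------------------------------------------
# core-genus screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreCriteria:
    """The three-way core screen thresholds.

    ubiquity_frac
        present in more than this fraction of samples (default 0.80).
    abundant_mode / abundant_cutoff
        "mean_above": mean relative abundance > cutoff (default 0.001);
        "top_quantile": within the top ``abundant_cutoff`` fraction of genera
        ranked by mean relative abundance.
    frequent_rank_quantile / frequent_sample_frac
        abundance rank within the top quantile of genera in more than
        ``frequent_sample_frac`` of samples.
    """

    ubiquity_frac: float = 0.80
    abundant_mode: str = "mean_above"
    abundant_cutoff: float = 0.001
    frequent_rank_quantile: float = 0.80
    frequent_sample_frac: float = 0.50

    def __post_init__(self):
        for name in ("ubiquity_frac", "frequent_rank_quantile",
                     "frequent_sample_frac", "abundant_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.abundant_mode not in ("mean_above", "top_quantile"):
            raise ValueError("abundant_mode must be 'mean_above' or 'top_quantile'")


def screen_core_genera(table: AbundanceTable, criteria: CoreCriteria = CoreCriteria()):
    """Screen a genus-level table for core genera.

    Returns ``(core_set, flags)`` where ``flags`` is a per-genus truth table
    with boolean columns ``ubiquitous``, ``abundant``, ``frequent`` and
    ``core`` (the conjunction).  The input should already be aggregated to
    genus level (see :meth:`AbundanceTable.aggregate_by`).
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        flags = pd.DataFrame(columns=["ubiquitous", "abundant", "frequent", "core"])
        return set(), flags
    rel = to_relative(table).counts
    n_s = rel.shape[1]

    present = (rel > 0)
    ubiquitous = present.sum(axis=1) > criteria.ubiquity_frac * n_s

    mean_ab = rel.mean(axis=1)
    if criteria.abundant_mode == "mean_above":
        abundant = mean_ab > criteria.abundant_cutoff
    else:
        k = max(1, int(np.ceil(criteria.abundant_cutoff * len(mean_ab))))
        cut = mean_ab.nlargest(k).min()
        abundant = mean_ab >= cut

    # rank within sample (1 = most abundant); genus counts as "in the top
    # quantile" only if it is actually detected in that sample
    ranks = rel.rank(axis=0, ascending=False, method="min")
    in_top = (ranks <= criteria.frequent_rank_quantile * rel.shape[0]) & present
    frequent = in_top.sum(axis=1) > criteria.frequent_sample_frac * n_s

    flags = pd.DataFrame(
        {"ubiquitous": ubiquitous, "abundant": abundant, "frequent": frequent}
    )
    flags["core"] = flags.all(axis=1)
    return set(flags.index[flags["core"]]), flags


# ---------------------------------------------------------------------------
# marker-correlation (PC taxon) screen
# ---------------------------------------------------------------------------

def screen_pc_taxa(
    table: AbundanceTable,
    lineage_filter,
    marker,
    r_min: float = 0.5,
    p_max: float = 0.05,
):
    """Select lineage-restricted taxa whose abundance tracks a marker gene.

    ``lineage_filter`` is the externally supplied candidate taxon set (e.g.
    Nitrospira lineage II members); ``marker`` is a per-sample copy-number
    vector (e.g. comammox amoA qPCR).  A taxon is selected when the Pearson
    correlation between its relative abundance and the marker satisfies
    ``r >= r_min`` and two-sided ``p <= p_max``.

    Returns ``(selected, stats_frame, group_abundance)`` where
    ``group_abundance`` is the per-sample summed relative abundance of the
    selected taxa (for downstream correlation with pH).
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape[0] != table.n_samples:
        raise ValueError("marker length must equal number of samples")
    if np.std(marker) == 0:
        raise ValueError("marker vector is constant; correlation undefined")
    rel = to_relative(table).counts
    cand = [t for t in lineage_filter if t in rel.index]
    rows = []
    for t in cand:
        x = rel.loc[t].to_numpy()
        if np.std(x) == 0:
            rows.append((t, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, marker)
        rows.append((t, r, p, bool(r >= r_min and p <= p_max)))
    frame = pd.DataFrame(rows, columns=["taxon", "r", "p", "selected"]).set_index("taxon")
    selected = list(frame.index[frame["selected"]])
    group = rel.loc[selected].sum(axis=0) if selected else pd.Series(0.0, index=rel.columns)
    return selected, frame, group


# ---------------------------------------------------------------------------
# dominant oxidizer
# ---------------------------------------------------------------------------

def classify_dominant_oxidizer(guild_copies: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dominant ammonia-oxidizer guild and relative shares.

    ``guild_copies`` holds non-negative linear copy numbers, one column per
    guild.  The label is the argmax guild; exact ties are broken
    alphabetically and flagged; all-zero samples are flagged unclassifiable.
    Shares are each guild's fraction of the summed copies.
    """
    if (guild_copies.values < 0).any():
        raise ValueError("guild copy numbers must be non-negative")
    guilds = sorted(guild_copies.columns)
    g = guild_copies[guilds]
    total = g.sum(axis=1)
    out = pd.DataFrame(index=g.index)
    for c in guilds:
        out[f"share_{c}"] = np.where(total > 0, g[c] / total.replace(0, np.nan), np.nan)
    maxval = g.max(axis=1)
    out["label"] = [
        None if total.iloc[i] == 0 else
        next(c for c in guilds if g[c].iloc[i] == maxval.iloc[i])
        for i in range(len(g))
    ]
    out["tie"] = (g.eq(maxval, axis=0).sum(axis=1) > 1) & (total > 0)
    out["unclassifiable"] = total == 0
    return out


# ---------------------------------------------------------------------------
# rrn assignment and mean copy number
# ---------------------------------------------------------------------------

def assign_rrn(table: AbundanceTable, lookup: RrnLookup) -> pd.DataFrame:
    """Assign an rrn copy number to each taxon by most-specific lineage match.

    Matching order is species, then genus, then family (mirroring rrndb
    practice: a taxon unclassified at species/genus falls back to its
    family-level value).  Unmatched taxa get ``provenance="unmatched"`` and a
    NaN copy number; they are excluded from MCN with a logged count.
    """
    rows = []
    for taxon in table.taxa:
        copies, prov = np.nan, "unmatched"
        for rank in RrnLookup.MATCH_RANKS:
            name = table.taxonomy.loc[taxon, rank]
            if name == "unclassified":
                continue
            hit = lookup.get(rank, name)
            if hit is not None:
                copies, prov = hit, rank
                break
        rows.append((taxon, copies, prov))
    out = pd.DataFrame(rows, columns=["taxon", "copies", "provenance"]).set_index("taxon")
    n_un = int((out["provenance"] == "unmatched").sum())
    if n_un:
        warnings.warn(f"{n_un} taxa unmatched in rrn lookup; excluded from MCN")
    return out


def compute_mcn(
    table: AbundanceTable,
    rrn: pd.Series,
    renormalize: bool = True,
    min_coverage: float = 0.5,
) -> pd.Series:
    """Abundance-weighted community mean rrn copy number per sample.

    ``MCN_s = sum_i p_is * rrn_i / sum_i p_is`` over taxa with a defined rrn
    value (``renormalize=True``, the default, divides by the matched
    abundance mass so unmatched taxa do not bias the mean downward; with
    ``renormalize=False`` the raw weighted sum over the full sample mass is
    returned).  Samples whose matched coverage is below ``min_coverage``
    trigger a warning; samples with no matched taxa return NaN.
    """
    rel = to_relative(table).counts
    rrn = pd.Series(rrn).dropna()
    matched = rel.index.intersection(rrn.index)
    if len(matched) == 0:
        return pd.Series(np.nan, index=rel.columns, name="MCN")
    w = rel.loc[matched]
    mass = w.sum(axis=0)
    low = mass.index[mass < min_coverage]
    if len(low):
        warnings.warn(
            f"matched rrn coverage below {min_coverage:.0%} in {len(low)} sample(s)"
        )
    num = w.mul(rrn.loc[matched], axis=0).sum(axis=0)
    mcn = num / mass.replace(0, np.nan) if renormalize else num
    mcn.name = "MCN"
    return mcn
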