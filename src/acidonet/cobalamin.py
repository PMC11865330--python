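"""Cobalamin supply/demand screening of genomes (MAGs or contig bins).

A genome is cobalamin-dependent (CD) if it encodes at least one of the marker
dependence genes (mutA, metH, rsmB) and a cobalamin synthesizer (CS) if it
carries the complete biosynthesis pathway (steps A, B and C all present).
Per-sample summaries weight these classes by genome relative abundance and
attribute the CS pool to supplier labels (e.g. the comammox share).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import GenomeFeatureTable, ph_group


def classify_cd_cs(features: GenomeFeatureTable) -> pd.DataFrame:
    """Per-genome CD/CS classification and partial synthesis steps.

    Returns columns ``is_CD`` (any dependence gene), ``is_CS`` (all three
    synthesis steps) and ``partial_steps`` (comma-joined present steps, e.g.
    ``"B,C"`` for the final-synthesis+DMB class).
    """
    f = features.features
    is_cd = f[list(GenomeFeatureTable.CD_GENES)].any(axis=1)
    steps = f[list(GenomeFeatureTable.CS_STEPS)]
    is_cs = steps.all(axis=1)
    partial = steps.apply(
        lambda row: ",".join(s[-1] for s in GenomeFeatureTable.CS_STEPS if row[s]),
        axis=1,
    )
    return pd.DataFrame({"is_CD": is_cd, "is_CS": is_cs, "partial_steps": partial})


def supply_demand_summary(
    features: GenomeFeatureTable,
    meta: pd.DataFrame | None = None,
    supplier_label: str = "comammox",
) -> pd.DataFrame:
    """Per-sample CD/CS abundance and the supplier's share of the CS pool.

    ``relAb_CD(s)`` and ``relAb_CS(s)`` sum the relative abundance of CD/CS
    genomes in sample s; ``supplier_share(s)`` is the fraction of CS
    abundance carried by genomes labelled ``supplier_label`` (NaN and flagged
    where the sample has zero CS abundance).  If ``meta`` with a pH column is
    given, pH and group are joined and group means stored in
    ``result.attrs['group_means']``.
    """
    cls = classify_cd_cs(features)
    if not cls["is_CS"].any():
        raise ValueError("no CS genome present; supplier share undefined")
    ab = features.abundance
    cd_ab = ab.loc[cls.index[cls["is_CD"]]].sum(axis=0)
    cs_genomes = cls.index[cls["is_CS"]]
    cs_ab = ab.loc[cs_genomes].sum(axis=0)
    sup = cs_genomes[features.labels.loc[cs_genomes] == supplier_label]
    sup_ab = ab.loc[sup].sum(axis=0) if len(sup) else pd.Series(0.0, index=ab.columns)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = sup_ab / cs_ab.replace(0, np.nan)
    out = pd.DataFrame(
        {"relAb_CD": cd_ab, "relAb_CS": cs_ab, "supplier_share": share,
         "cs_zero": cs_ab == 0}
    )
    if out["cs_zero"].any():
        warnings.warn(f"{int(out['cs_zero'].sum())} sample(s) have zero CS abundance")
    if meta is not None and "pH" in meta.columns:
        out = out.join(meta[["pH"]])
        out["group"] = [ph_group(p) for p in out["pH"]]
        out.attrs["group_means"] = (
            out.groupby("group")[["relAb_CD", "relAb_CS", "supplier_share"]].mean()
        )
    return out


def gene_set_tpm(expression: pd.DataFrame, gene_sets: dict) -> pd.DataFrame:
    """Per-sample TPM totals over named gene sets.

    ``expression`` is gene x sample TPM (columns should each total ~1e6;
    a >1% deviation raises).  Unknown genes in a set are skipped with a
    warning.  Returns sample x set totals.
    """
    col_sums = expression.sum(axis=0)
    if ((col_sums - 1e6).abs() > 1e4).any():
        raise ValueError("TPM columns must each sum to 1e6 (within 1%)")
    out = {}
    for name, genes in gene_sets.items():
        genes = list(genes)
        known = [g for g in genes if g in expression.index]
        missing = set(genes) - set(known)
        if missing:
            warnings.warn(f"gene set {name!r}: skipping unknown genes {sorted(missing)}")
        out[name] = expression.loc[known].sum(axis=0) if known else pd.Series(
            0.0, index=expression.columns
        )
    return pd.DataFrame(out)
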