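"""Null-model-corrected connectedness and per-sample cohesion.

Cohesion summarizes how strongly a sample's community is built from taxa that
co-vary with others.  For every taxon pair the observed Pearson correlation
is corrected by the mean correlation under a "taxa shuffle" null (each
partner's abundances permuted across samples), removing the correlation that
compositionality and abundance structure alone would produce.  A taxon's
positive (negative) connectedness is the mean of its strictly positive
(negative) corrected correlations; a sample's positive (negative) cohesion is
the abundance-weighted sum of connectedness over its taxa.  Positive cohesion
proxies cooperation, negative cohesion competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import AbundanceTable, to_relative


def _standardize_rows(x: np.ndarray):
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - mu) / sd
    z[constant, :] = 0.0
    return z, constant


def null_corrected_correlations(
    table: AbundanceTable,
    n_iter: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed minus null-mean Pearson correlation for every taxon pair.

    For the ordered pair (i, j) the null correlation is between observed row
    i and a row-permuted j ("taxa shuffle": each taxon's abundances shuffled
    independently across samples); the corrected matrix is symmetrized by
    averaging the two directions.  Deterministic under ``seed``.  Constant
    taxa are flagged in ``result.attrs['constant_taxa']`` with zero rows.
    """
    if n_iter < 50:
        raise ValueError("n_iter must be >= 50 for a stable null mean")
    if table.n_samples < 5:
        raise ValueError("need >= 5 samples")
    rel = to_relative(table).counts
    x = rel.to_numpy(dtype=float)
    n_t, n_s = x.shape
    z, constant = _standardize_rows(x)
    r_obs = z @ z.T / n_s

    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(r_obs)
    for _ in range(n_iter):
        idx = rng.random((n_t, n_s)).argsort(axis=1)
        zp = np.take_along_axis(z, idx, axis=1)
        # entry (i, j): corr(observed i, shuffled j)
        null_sum += z @ zp.T
    null_mean = null_sum / (n_iter * n_s)

    corrected = r_obs - null_mean
    corrected = (corrected + corrected.T) / 2.0
    corrected[constant, :] = 0.0
    corrected[:, constant] = 0.0
    np.fill_diagonal(corrected, 0.0)
    out = pd.DataFrame(corrected, index=rel.index, columns=rel.index)
    out.attrs["constant_taxa"] = list(rel.index[constant])
    return out


def connectedness(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon mean positive and mean negative corrected correlation.

    The positive (negative) connectedness of taxon j is the mean over the
    strictly positive (strictly negative) corrected correlations with its
    partners; 0 when the set is empty.
    """
    c = corrected.to_numpy()
    if not np.allclose(c, c.T, atol=1e-12):
        raise ValueError("corrected matrix must be symmetric")
    pos_mask = c > 0
    neg_mask = c < 0
    n_pos = pos_mask.sum(axis=0)
    n_neg = neg_mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conn_pos = np.where(n_pos > 0, (c * pos_mask).sum(axis=0) / np.maximum(n_pos, 1), 0.0)
        conn_neg = np.where(n_neg > 0, (c * neg_mask).sum(axis=0) / np.maximum(n_neg, 1), 0.0)
    return pd.DataFrame(
        {"connectedness_pos": conn_pos, "connectedness_neg": conn_neg},
        index=corrected.index,
    )


@dataclass
class CohesionResult:
    """Per-taxon connectedness and per-sample cohesion."""

    connectedness: pd.DataFrame   # taxon x (pos, neg)
    cohesion: pd.DataFrame        # sample x (pos, neg, net, total)


def sample_cohesion(table: AbundanceTable, conn: pd.DataFrame) -> CohesionResult:
    """Abundance-weighted cohesion per sample.

    ``C_pos(s) = sum_j a_js * conn_pos(j)`` and analogously for negative;
    ``total = C_pos + |C_neg|`` and ``net = C_pos + C_neg`` (the signed sum,
    zero-centred under the null) are also reported.
    """
    rel = to_relative(table).counts
    common = rel.index.intersection(conn.index)
    if len(common) != len(rel.index):
        raise ValueError("taxa of table and connectedness are not aligned")
    a = rel.loc[common].to_numpy()
    cp = conn.loc[common, "connectedness_pos"].to_numpy()
    cn = conn.loc[common, "connectedness_neg"].to_numpy()
    pos = a.T @ cp
    neg = a.T @ cn
    coh = pd.DataFrame(
        {
            "cohesion_pos": pos,
            "cohesion_neg": neg,
            "cohesion_net": pos + neg,
            "cohesion_total": pos + np.abs(neg),
        },
        index=rel.columns,
    )
    return CohesionResult(connectedness=conn, cohesion=coh)


def cohesion_pipeline(
    table: AbundanceTable, n_iter: int = 200, seed: int = 0
) -> CohesionResult:
    """Convenience wrapper: corrected correlations -> connectedness -> cohesion."""
    corrected = null_corrected_correlations(table, n_iter=n_iter, seed=seed)
    return sample_cohesion(table, connectedness(corrected))
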