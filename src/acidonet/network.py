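"""Co-occurrence network construction and node-role analysis.

Pipeline: prevalence-filter the abundance table, compute Pearson correlations
on log-transformed relative abundances, pick the correlation cut-off by a
random-matrix-theory (RMT) spectral criterion, build the signed weighted
network, detect modules by greedy modularity maximization, and classify node
roles in the Zi-Pi (within-module degree z-score vs among-module
connectivity) plane.

The RMT criterion scans thresholds: below the transition the retained
correlation matrix behaves like a full random (GOE-like) matrix whose
nearest-neighbour eigenvalue spacings follow the Wigner-Dyson distribution;
once only genuine modular structure remains, the spectrum decomposes into
nearly independent blocks and the spacings become Poisson, exp(-s).  The
selected threshold is the smallest one whose unfolded spacings are consistent
with Poisson by a chi-square test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, to_relative

# Zi-Pi role thresholds (Guimera-Amaral convention used by soil network studies)
ZI_HUB = 2.5
PI_CONNECTOR = 0.62


def prevalence_filter(table: AbundanceTable, min_frac: float = 0.5) -> AbundanceTable:
    """Keep taxa detected (nonzero) in at least ``min_frac`` of samples."""
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    present = (table.counts > 0).sum(axis=1)
    keep = table.taxa[present >= min_frac * table.n_samples]
    return table.subset(keep)


def correlation_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pearson correlations of log-transformed relative abundances.

    Zeros are replaced by half the smallest nonzero relative abundance in the
    table before the log (a scale-stable pseudo-abundance).  Constant taxa get
    zero correlations (flagged via ``result.attrs['constant_taxa']``).
    """
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples for correlations")
    rel = to_relative(table).counts.to_numpy(dtype=float)
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("table is all zeros")
    pseudo = nz.min() / 2.0
    logged = np.log(np.where(rel > 0, rel, pseudo))
    sd = logged.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(logged)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    out = pd.DataFrame(r, index=table.taxa, columns=table.taxa)
    out.attrs["constant_taxa"] = list(table.taxa[constant])
    return out


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def _unfolded_spacings(eigs: np.ndarray, poly_degree: int = 10,
                       dedup_tol: float = 1e-8):
    """Nearest-neighbour spacings after polynomial unfolding of the spectrum.

    The empirical cumulative eigenvalue count (the "staircase") is fitted with
    a smooth polynomial; spacings are differences of the fitted count at
    consecutive unique eigenvalues, which have unit mean by construction.
    Near-degenerate eigenvalues are collapsed first.
    """
    lam = np.sort(eigs)
    scale = max(lam[-1] - lam[0], 1.0)
    uniq = [lam[0]]
    for v in lam[1:]:
        if v - uniq[-1] > dedup_tol * scale:
            uniq.append(v)
    lam = np.asarray(uniq)
    m = len(lam)
    if m < 12:
        return np.array([])
    deg = int(min(poly_degree, m - 2))
    ranks = np.arange(1, m + 1, dtype=float)
    fit = np.polynomial.Polynomial.fit(lam, ranks, deg)
    unfolded = fit(lam)
    s = np.diff(unfolded)
    s = s[s > 0]
    if s.size == 0:
        return s
    return s / s.mean()


def _chisq_gof(spacings: np.ndarray, dist: str, n_bins: int = 10):
    """Chi-square goodness of fit of spacings to Poisson or Wigner-Dyson.

    Bins are equal-probability under the candidate distribution so expected
    counts are uniform; returns ``(chi2, p)``.
    """
    n = spacings.size
    if n < 5 * n_bins:
        n_bins = max(3, n // 5)
    if n < 15:
        return np.inf, 0.0
    q = np.arange(1, n_bins) / n_bins
    if dist == "poisson":          # CDF 1 - exp(-s)
        edges = -np.log(1.0 - q)
    elif dist == "wigner":         # GOE surmise CDF 1 - exp(-pi s^2 / 4)
        edges = np.sqrt(-4.0 * np.log(1.0 - q) / np.pi)
    else:
        raise ValueError(dist)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    obs, _ = np.histogram(spacings, bins=edges)
    exp = np.full(n_bins, n / n_bins)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=n_bins - 1))
    return chi2, p


def spacing_statistics(r: np.ndarray, threshold: float,
                       poly_degree: int = 10) -> dict:
    """Spectral spacing diagnostics of ``|r|`` thresholded at ``threshold``.

    Nodes with no off-diagonal entry surviving the threshold are removed
    before the eigendecomposition (their trivial eigenvalues would flood the
    spectrum with degenerate values).
    """
    a = np.abs(np.asarray(r, dtype=float)).copy()
    np.fill_diagonal(a, 0.0)
    a[a < threshold] = 0.0
    deg = (a > 0).sum(axis=0)
    keep = deg > 0
    out = {"threshold": threshold, "n_nodes": int(keep.sum()),
           "n_spacings": 0, "chi2_poisson": np.nan, "p_poisson": np.nan,
           "chi2_wigner": np.nan, "p_wigner": np.nan}
    if keep.sum() < 12:
        return out
    a = a[np.ix_(keep, keep)]
    np.fill_diagonal(a, 1.0)
    eigs = np.linalg.eigvalsh(a)
    s = _unfolded_spacings(eigs, poly_degree=poly_degree)
    out["n_spacings"] = int(s.size)
    if s.size:
        out["chi2_poisson"], out["p_poisson"] = _chisq_gof(s, "poisson")
        out["chi2_wigner"], out["p_wigner"] = _chisq_gof(s, "wigner")
    return out


def select_rmt_threshold(
    r: pd.DataFrame,
    t_grid=None,
    alpha: float = 0.05,
    poly_degree: int = 10,
    min_size: int = 30,
    fallback: float = 0.7,
):
    """Smallest threshold at which eigenvalue spacings become Poisson.

    Scans ``t_grid`` (default 0.30..0.99 step 0.01); at each threshold the
    spacing distribution of the retained ``|r|`` matrix is tested against
    Poisson; the first threshold with chi-square p > ``alpha`` is selected.

    Returns ``(threshold, diagnostics)``; ``diagnostics.attrs['flag']`` is
    ``"ok"``, ``"no-transition"`` (no threshold qualified; max grid value
    returned), or ``"too-small"`` (matrix under ``min_size``; ``fallback``
    returned).
    """
    mat = r.to_numpy() if isinstance(r, pd.DataFrame) else np.asarray(r)
    if t_grid is None:
        t_grid = np.round(np.arange(0.30, 1.00, 0.01), 2)
    if mat.shape[0] < min_size:
        warnings.warn(
            f"matrix smaller than {min_size}x{min_size}; spectra uninformative, "
            f"falling back to fixed threshold {fallback}"
        )
        diag = pd.DataFrame()
        diag.attrs["flag"] = "too-small"
        return fallback, diag
    rows = []
    chosen = None
    for t in t_grid:
        st = spacing_statistics(mat, float(t), poly_degree=poly_degree)
        st["qualifies"] = bool(np.isfinite(st["p_poisson"]) and st["p_poisson"] > alpha)
        rows.append(st)
        if chosen is None and st["qualifies"]:
            chosen = float(t)
    diag = pd.DataFrame(rows)
    if chosen is None:
        diag.attrs["flag"] = "no-transition"
        return float(t_grid[-1]), diag
    diag.attrs["flag"] = "ok"
    return chosen, diag


# ---------------------------------------------------------------------------
# network construction, modules, roles, topology
# ---------------------------------------------------------------------------

def build_network(r: pd.DataFrame, threshold: float) -> nx.Graph:
    """Signed weighted graph with edges where ``|r| >= threshold``.

    Edge attributes: ``weight`` (signed r) and ``sign`` (+1/-1).  Isolated
    nodes are dropped; their count is stored in ``G.graph['n_isolated']``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    labels = list(r.index) if isinstance(r, pd.DataFrame) else list(range(len(r)))
    mat = r.to_numpy() if isinstance(r, pd.DataFrame) else np.asarray(r)
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = mat[i, j]
            if abs(w) >= threshold:
                g.add_edge(labels[i], labels[j], weight=float(w),
                           sign=1 if w > 0 else -1)
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    g.remove_nodes_from(isolated)
    g.graph["threshold"] = float(threshold)
    g.graph["n_isolated"] = len(isolated)
    return g


def detect_modules(g: nx.Graph) -> tuple[dict, float]:
    """Greedy modularity modules on the |weight| graph.

    Returns ``(partition, Q)`` with a deterministic node->module-id mapping
    (modules numbered by size then lexicographic smallest member) and the
    modularity of the partition.  Disconnected components never share a
    module (greedy modularity cannot merge across components, since merging
    zero-edge communities never increases Q).
    """
    if g.number_of_nodes() == 0:
        return {}, 0.0
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, weight=abs(d["weight"]))
    if h.number_of_edges() == 0:
        comms = [{v} for v in h.nodes]
    else:
        comms = [set(c) for c in
                 nx.community.greedy_modularity_communities(h, weight="weight")]
    comms.sort(key=lambda c: (-len(c), sorted(map(str, c))[0]))
    partition = {v: k for k, c in enumerate(comms) for v in c}
    q = nx.community.modularity(h, comms, weight="weight") if h.number_of_edges() else 0.0
    return partition, float(q)


@dataclass
class NodeRole:
    """Zi-Pi coordinates and role of one network node."""

    node: object
    zi: float
    pi: float
    role: str
    is_key: bool


def role_from_zipi(zi: float, pi: float) -> str:
    """Role rule: Zi >= 2.5 -> module hub; Pi >= 0.62 -> connector; both ->
    network hub; neither -> peripheral."""
    hub = zi >= ZI_HUB
    conn = pi >= PI_CONNECTOR
    if hub and conn:
        return "network hub"
    if hub:
        return "module hub"
    if conn:
        return "connector"
    return "peripheral"


def compute_zipi(g: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and among-module connectivity (Pi).

    Degrees are unweighted.  ``Zi = (k_within - mean) / sd`` over the node's
    module (Zi = 0 when the module's within-degree sd is 0);
    ``Pi = 1 - sum_t (k_it / k_i)^2`` over modules t.  ``is_key`` marks nodes
    with Zi >= 2.5 or Pi >= 0.62.
    """
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover {len(missing)} node(s)")
    nodes = list(g.nodes)
    k_within = {}
    per_module = {}
    rows = []
    for v in nodes:
        kw = sum(1 for u in g[v] if partition[u] == partition[v])
        k_within[v] = kw
        per_module.setdefault(partition[v], []).append(kw)
    mod_stats = {
        m: (float(np.mean(ks)), float(np.std(ks))) for m, ks in per_module.items()
    }
    for v in nodes:
        mu, sd = mod_stats[partition[v]]
        zi = (k_within[v] - mu) / sd if sd > 0 else 0.0
        k = g.degree(v)
        counts = {}
        for u in g[v]:
            counts[partition[u]] = counts.get(partition[u], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in counts.values())
        role = role_from_zipi(zi, pi)
        rows.append((v, partition[v], zi, pi, role, zi >= ZI_HUB or pi >= PI_CONNECTOR))
    return pd.DataFrame(
        rows, columns=["node", "module", "Zi", "Pi", "role", "is_key"]
    ).set_index("node")


def topology_summary(g: nx.Graph) -> dict:
    """Standard topological indices of a signed co-occurrence network."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    n, m = g.number_of_nodes(), g.number_of_edges()
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    pos = sum(1 for _, _, d in g.edges(data=True) if d["weight"] > 0)
    return {
        "n_nodes": n,
        "n_edges": m,
        "mean_degree": 2.0 * m / n,
        "clustering": nx.average_clustering(g),
        "mean_path_largest_component": (
            nx.average_shortest_path_length(sub) if sub.number_of_nodes() > 1 else 0.0
        ),
        "positive_edge_fraction": pos / m if m else np.nan,
        "neighbors": {v: sorted(map(str, g[v])) for v in g.nodes},
    }


def export_edges(g: nx.Graph) -> pd.DataFrame:
    """Edge list frame (source, target, r, sign) for TSV/Gephi-style export."""
    rows = [
        (u, v, d["weight"], d["sign"]) for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])
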